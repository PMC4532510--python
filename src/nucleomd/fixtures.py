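"""Deterministic toy systems for tests, validation and desk-scale runs.

Four fixtures are provided:

``harmonic-dimer``
    Two bonded beads; the minimal integrator/force test system.
``mini-protein``
    A 12-residue helical Calpha chain with i,i+4 native contacts.
``duplex-10bp``
    A 10-bp ideal B-form duplex with charged phosphates.
``wrapped-arc``
    A short B-form duplex bent around a compact two-chain protein scaffold
    with a cationic DNA-facing surface and tail extensions — a miniature
    nucleoprotein "nucleosome surrogate" that populates every energy term.
    Like the real nucleosome, the bent DNA stores elastic energy that is
    balanced by protein-DNA contacts and screened electrostatics, so its
    terminal base pairs detach more readily at high salt.

All geometry here is construction-time design; bonded reference values for
the protein are measured on the built coordinates, and the DNA keeps its
straight-helix reference values so the bent arc is pre-stressed exactly as
a crystal-derived nucleosome topology would be.
"""

from __future__ import annotations

import numpy as np

from .bdna import angle_value, build_ideal_bdna, dihedral_value
from .params import ForceFieldParameters
from .structure import assign_charges, build_native_contacts
from .topology import AMINO, CGTopology

FIXTURE_KINDS = ("harmonic-dimer", "mini-protein", "duplex-10bp", "wrapped-arc")


def make_fixture(kind: str, params: ForceFieldParameters | None = None,
                 ) -> tuple[CGTopology, np.ndarray]:
    """Build a named fixture; returns ``(topology, coordinates)``."""
    if params is None:
        params = ForceFieldParameters.default()
    if kind == "harmonic-dimer":
        return _harmonic_dimer(params)
    if kind == "mini-protein":
        return _mini_protein(params)
    if kind == "duplex-10bp":
        coords, topo = build_ideal_bdna("ATGCATGCAT", params)
        assign_charges(topo)
        topo.metadata["fixture"] = kind
        return topo, coords
    if kind == "wrapped-arc":
        return _wrapped_arc(params)
    raise ValueError(f"unknown fixture kind: {kind!r} (choose from {FIXTURE_KINDS})")


def _protein_chain_topology(coords: np.ndarray, resnames: list[str],
                            params: ForceFieldParameters, chain_id: str = "A",
                            tail_flags: np.ndarray | None = None) -> CGTopology:
    """Assemble a single-chain Calpha topology with bonded reference values
    measured on ``coords``."""
    n = len(coords)
    bonds = np.array([(i, i + 1) for i in range(n - 1)], int).reshape(-1, 2)
    angles = np.array([(i, i + 1, i + 2) for i in range(n - 2)], int).reshape(-1, 3)
    dihedrals = np.array([(i, i + 1, i + 2, i + 3) for i in range(n - 3)],
                         int).reshape(-1, 4)
    topo = CGTopology(
        kind=np.array([AMINO] * n), chain_id=np.array([chain_id] * n),
        residue_index=np.arange(1, n + 1), residue_name=np.array(resnames),
        charge=np.zeros(n),
        mass=np.array([params.mass_of(r) for r in resnames]),
        ref_coords=coords.copy(),
        tail=(tail_flags if tail_flags is not None else np.zeros(n, bool)),
        bonds_pro=bonds,
        bonds_pro_r0=np.array([np.linalg.norm(coords[i] - coords[j])
                               for i, j in bonds]),
        angles_pro=angles,
        angles_pro_t0=np.array([angle_value(coords, *ijk) for ijk in angles]),
        dihedrals_pro=dihedrals,
        dihedrals_pro_p0=np.array([dihedral_value(coords, *ijkl)
                                   for ijkl in dihedrals]),
    )
    return topo


def _harmonic_dimer(params: ForceFieldParameters) -> tuple[CGTopology, np.ndarray]:
    coords = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
    topo = _protein_chain_topology(coords, ["GLY", "GLY"], params)
    assign_charges(topo)
    topo.metadata["fixture"] = "harmonic-dimer"
    return topo, coords


def _mini_protein(params: ForceFieldParameters) -> tuple[CGTopology, np.ndarray]:
    # idealised alpha-helical Calpha trace: radius 2.3 A, rise 1.5 A,
    # 100 degrees per residue -> i,i+4 pairs fall inside the contact cutoff
    n = 12
    t = np.radians(100.0) * np.arange(n)
    coords = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1)
    resnames = ["ALA", "LYS", "ALA", "GLU", "ALA", "ALA",
                "LYS", "ALA", "ALA", "GLU", "ALA", "LYS"]
    topo = _protein_chain_topology(coords, resnames, params)
    topo = build_native_contacts(topo, params=params)
    assign_charges(topo)
    topo.metadata["fixture"] = "mini-protein"
    return topo, coords


def bend_around_axis(coords: np.ndarray, radius: float) -> np.ndarray:
    """Map the z-axis onto a circle of the given radius (x-z plane).

    A point (x, y, z) goes to ((R+x) sin s, y, R - (R+x) cos s), s = z/R:
    straight helical DNA built along z becomes an arc wrapped toward the
    centre (0, 0, R).
    """
    s = coords[:, 2] / radius
    r = radius + coords[:, 0]
    return np.stack([r * np.sin(s), coords[:, 1], radius - r * np.cos(s)], axis=1)


DEFAULT_TAIL = ("LYS", "LYS", "ARG", "LYS", "LYS")


def _wrapped_arc(params: ForceFieldParameters,
                 n_bp: int = 24, bend_radius: float = 34.0,
                 clearance: float = 4.3, tail_clearance: float = 8.0,
                 tail_residues: tuple[str, ...] = DEFAULT_TAIL,
                 ) -> tuple[CGTopology, np.ndarray]:
    sequence = ("ATGCA" * ((n_bp + 4) // 5))[:n_bp]
    straight, dna_topo = build_ideal_bdna(sequence, params)
    bent = bend_around_axis(straight, bend_radius)
    centre = np.array([0.0, 0.0, bend_radius])

    # protein core: three serpentine rows of beads hugging the inside of
    # the arc (one in the bend plane, one either side of it), each bead
    # pushed inward until it clears every DNA site by ``clearance``. Beads
    # end up within the contact cutoff of several sugar/base sites, which
    # is what creates the dense native-contact interface.
    arc_span = (n_bp - 1) * params.dna_geometry["rise"] / bend_radius
    r_start = bend_radius - params.dna_geometry["sugar_radius"] + 1.0
    stations = np.arange(-0.06 * arc_span, 1.06 * arc_span, 3.8 / (r_start - 4))
    rows = []
    for shell in (0.0, 4.5):            # outer shell touches DNA, inner packs it
        for y_off in (-4.0, 0.0, 4.0):
            row = []
            for s in stations:
                direction = np.array([np.sin(s), 0.0, -np.cos(s)])
                r = r_start
                while r > 6.0:
                    pos = centre + direction * r + np.array([0.0, y_off, 0.0])
                    if np.linalg.norm(bent - pos, axis=1).min() >= clearance:
                        break
                    r -= 0.25
                row.append(pos - direction * shell)
            row = np.asarray(row)
            # small alternating wobble so no four consecutive beads are coplanar
            row[:, 1] += 0.3 * (-1.0) ** np.arange(len(row))
            rows.append(row)
    # two protein chains, mirroring the octamer's paired organisation:
    # chain A = DNA-facing (charged) shell, chain B = neutral packing
    # shell; each chain starts with a lysine/arginine-rich N-terminal tail
    # that lies alongside the wrapped terminal DNA segment of one arc end,
    # so both duplex ends are guarded by a tail as in the nucleosome.
    def serpentine(row_set, from_end: bool):
        ordered = []
        for k, r in enumerate(row_set):
            rr = r[::-1] if (k % 2 == 0) == from_end else r
            ordered.append(rr)
        return np.vstack(ordered)

    core_a = serpentine(rows[:3], from_end=False)    # starts at arc start
    core_b = serpentine(rows[3:], from_end=True)     # starts at arc end

    def make_tail(anchor: np.ndarray, s0: float, direction: float,
                  n_tail: int) -> np.ndarray:
        """Tail path from the core surface up and over the side of the
        duplex, then along the wrapped terminal segment at a stand-off
        distance (``tail_clearance``). Close-range cationic beads would
        compete with the core for the short, bending-stressed terminal
        DNA; the stand-off keeps their attraction diffuse."""
        beads = []
        pos = anchor.copy()
        for k in range(n_tail):
            if k < 2:        # climb outward and sideways from the root
                step = np.array([np.sin(s0), 0.0, -np.cos(s0)]) \
                    + np.array([0.0, -1.0, 0.0])
            else:            # march along the duplex side, drifting outward
                s = s0 + direction * (k - 1) * 3.8 / bend_radius
                step = direction * np.array([np.cos(s), 0.0, np.sin(s)]) \
                    + 0.35 * np.array([np.sin(s), 0.0, -np.cos(s)])
            pos = pos + step / np.linalg.norm(step) * 3.8
            while np.linalg.norm(bent - pos, axis=1).min() < tail_clearance:
                pos = pos + np.array([0.0, -0.5, 0.0])
            beads.append(pos.copy())
        return np.asarray(beads[::-1])     # N-terminus distal, root last

    tail_names = list(tail_residues)
    n_tail = len(tail_names)
    s_a = float(stations[0])
    s_b = float(stations[-1])
    tail_a = make_tail(core_a[0], s_a, +1.0, n_tail)
    tail_b = make_tail(core_b[0], s_b, -1.0, n_tail)

    def names_for(n: int, pattern: list[str]) -> list[str]:
        return (pattern * ((n + len(pattern) - 1) // len(pattern)))[:n]
    # DNA-facing shell carries the basic residues; the packing shell is
    # mostly neutral with a few acidic beads (a real octamer core is
    # charge-mixed; a uniformly cationic cluster would repel itself apart)
    names_a = tail_names + names_for(len(core_a), ["ARG", "ALA", "LYS", "ALA"])
    names_b = tail_names + names_for(len(core_b),
                                     ["ALA", "ALA", "ALA", "ALA", "ALA", "ASP"])
    coords_a = np.vstack([tail_a, core_a])
    coords_b = np.vstack([tail_b, core_b])
    flags_a = np.array([True] * n_tail + [False] * len(core_a))
    flags_b = np.array([True] * n_tail + [False] * len(core_b))
    topo_a = _protein_chain_topology(coords_a, names_a, params,
                                     chain_id="A", tail_flags=flags_a)
    topo_b = _protein_chain_topology(coords_b, names_b, params,
                                     chain_id="B", tail_flags=flags_b)
    pro_topo = _merge_proteins(topo_a, coords_a, topo_b, coords_b)
    pro_coords = np.vstack([coords_a, coords_b])

    topo = _merge(pro_topo, pro_coords, dna_topo, bent)
    topo.metadata["histone_map"] = {"A": "H3", "B": "H2B"}
    topo = build_native_contacts(topo, params=params)
    assign_charges(topo)
    topo.metadata["fixture"] = "wrapped-arc"
    topo.metadata["bend_radius"] = bend_radius
    topo.metadata["n_bp"] = n_bp
    coords = topo.ref_coords.copy()
    return topo, coords


def _merge_proteins(a: CGTopology, coords_a: np.ndarray,
                    b: CGTopology, coords_b: np.ndarray) -> CGTopology:
    off = a.n_beads

    def cat(name):
        return np.concatenate([getattr(a, name), getattr(b, name)])

    return CGTopology(
        kind=cat("kind"), chain_id=cat("chain_id"),
        residue_index=cat("residue_index"), residue_name=cat("residue_name"),
        charge=cat("charge"), mass=cat("mass"),
        ref_coords=np.vstack([coords_a, coords_b]), tail=cat("tail"),
        bonds_pro=np.vstack([a.bonds_pro, b.bonds_pro + off]),
        bonds_pro_r0=np.concatenate([a.bonds_pro_r0, b.bonds_pro_r0]),
        angles_pro=np.vstack([a.angles_pro, b.angles_pro + off]),
        angles_pro_t0=np.concatenate([a.angles_pro_t0, b.angles_pro_t0]),
        dihedrals_pro=np.vstack([a.dihedrals_pro, b.dihedrals_pro + off]),
        dihedrals_pro_p0=np.concatenate([a.dihedrals_pro_p0, b.dihedrals_pro_p0]),
    )


def _merge(pro: CGTopology, pro_coords: np.ndarray,
           dna: CGTopology, dna_coords: np.ndarray) -> CGTopology:
    """Concatenate a protein topology and a DNA topology (protein first)."""
    off = pro.n_beads

    def shift(arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr, int) + off

    return CGTopology(
        kind=np.concatenate([pro.kind, dna.kind]),
        chain_id=np.concatenate([pro.chain_id, dna.chain_id]),
        residue_index=np.concatenate([pro.residue_index, dna.residue_index]),
        residue_name=np.concatenate([pro.residue_name, dna.residue_name]),
        charge=np.concatenate([pro.charge, dna.charge]),
        mass=np.concatenate([pro.mass, dna.mass]),
        ref_coords=np.vstack([pro_coords, dna_coords]),
        tail=np.concatenate([pro.tail, dna.tail]),
        bonds_pro=pro.bonds_pro, bonds_pro_r0=pro.bonds_pro_r0,
        angles_pro=pro.angles_pro, angles_pro_t0=pro.angles_pro_t0,
        dihedrals_pro=pro.dihedrals_pro, dihedrals_pro_p0=pro.dihedrals_pro_p0,
        bonds_dna=shift(dna.bonds_dna), bonds_dna_r0=dna.bonds_dna_r0,
        angles_dna=shift(dna.angles_dna), angles_dna_t0=dna.angles_dna_t0,
        dihedrals_dna=shift(dna.dihedrals_dna), dihedrals_dna_p0=dna.dihedrals_dna_p0,
        stacks=shift(dna.stacks), stacks_r0=dna.stacks_r0,
        basepairs=shift(dna.basepairs), basepair_type=dna.basepair_type,
        solv_pairs=shift(dna.solv_pairs),
        metadata={"sequence": dna.metadata.get("sequence")},
    )
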