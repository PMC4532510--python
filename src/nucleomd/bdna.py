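"""Ideal B-form DNA construction for the three-site-per-nucleotide model.

The helix is generated per base-pair frame: each frame is the previous one
rotated by the helical twist about the axis and advanced by the rise. Within
a frame the six sites (phosphate/sugar/base of both strands) sit at fixed
cylindrical positions taken from the parameter file; the complementary
strand is the dyad image (y -> -y, local z -> -z) of the first, which makes
the two strands antiparallel by construction.

All DNA bonded and stacking reference values used anywhere in the package
are measured on this helix, so the generated duplex is the exact minimum of
every DNA bonded term.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ForceFieldParameters
from .topology import BASE, CGTopology, PHOSPHATE, SUGAR

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
BASE_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
GROUP_MASS_KEY = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}


def complement(sequence: str) -> str:
    """Complementary strand sequence, 5'->3' (reverse complement)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


def _local_sites(geom: dict[str, float]) -> dict[str, np.ndarray]:
    """Per-frame site positions; strand 2 is the dyad image of strand 1."""

    def cyl(radius: float, az_deg: float, z: float) -> np.ndarray:
        a = math.radians(az_deg)
        return np.array([radius * math.cos(a), radius * math.sin(a), z])

    p = cyl(geom["phosphate_radius"], geom["phosphate_azimuth_deg"], geom["phosphate_z"])
    s = cyl(geom["sugar_radius"], geom["sugar_azimuth_deg"], geom["sugar_z"])
    b = cyl(geom["base_radius"], geom["base_azimuth_deg"], geom["base_z"])
    # strand 2 is the dyad image rotated by a groove-asymmetry offset
    # (equal grooves would place the two backbones on top of each other)
    off = math.radians(geom["strand2_azimuth_offset_deg"])
    c, sn = math.cos(off), math.sin(off)
    rot = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
    flip = np.array([1.0, -1.0, -1.0])
    return {"P1": p, "S1": s, "B1": b,
            "P2": rot @ (p * flip), "S2": rot @ (s * flip), "B2": rot @ (b * flip)}


def helix_site_positions(n_bp: int, geom: dict[str, float]) -> dict[str, np.ndarray]:
    """Global positions of each site family, arrays of shape (n_bp, 3).

    ``P1[n]`` is the phosphate between base pairs n-1 and n of strand 1
    (absent for n = 0); ``P2[n]`` lies between base pairs n and n+1 (absent
    for n = n_bp - 1). Entries that do not exist are still returned (the
    caller drops terminal phosphates).
    """
    local = _local_sites(geom)
    rise, twist = geom["rise"], math.radians(geom["twist_deg"])
    out = {k: np.zeros((n_bp, 3)) for k in local}
    for n in range(n_bp):
        c, s = math.cos(n * twist), math.sin(n * twist)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, n * rise])
        for key, pos in local.items():
            out[key][n] = rot @ pos + shift
    return out


def build_ideal_bdna(sequence: str, params: ForceFieldParameters | None = None,
                     chain_ids: tuple[str, str] = ("I", "J"),
                     ) -> tuple[np.ndarray, CGTopology]:
    """Build a regular B-form duplex for ``sequence`` (strand 1, 5'->3').

    Returns ``(coords, topology)`` where ``topology.ref_coords`` equals
    ``coords`` and every DNA bonded term evaluates to zero on them.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = sorted(set(seq) - set("ACGT"))
    if bad:
        raise ValueError(f"invalid nucleotide(s): {bad}")
    if params is None:
        params = ForceFieldParameters.default()
    geom = params.dna_geometry
    n_bp = len(seq)
    sites = helix_site_positions(n_bp, geom)

    kind, chain, resi, resn, mass, coords = [], [], [], [], [], []
    # index maps: (strand, bp, site) -> bead index
    idx: dict[tuple[int, int, str], int] = {}

    def add(strand: int, bp: int, site: str, pos: np.ndarray,
            res_index: int, base: str) -> None:
        idx[(strand, bp, site)] = len(kind)
        kind.append({"P": PHOSPHATE, "S": SUGAR, "B": BASE}[site])
        chain.append(chain_ids[strand - 1])
        resi.append(res_index)
        resn.append(BASE_RESNAME[base])
        key = {"P": "DP", "S": "DS", "B": GROUP_MASS_KEY[base]}[site]
        mass.append(params.mass_of(key))
        coords.append(pos)

    # strand 1, 5'->3' with increasing bp index; 5'-terminal lacks phosphate
    for n in range(n_bp):
        base = seq[n]
        if n > 0:
            add(1, n, "P", sites["P1"][n], n + 1, base)
        add(1, n, "S", sites["S1"][n], n + 1, base)
        add(1, n, "B", sites["B1"][n], n + 1, base)
    # strand 2, 5'->3' runs from bp n_bp-1 down to 0
    for m in range(n_bp):
        n = n_bp - 1 - m
        base = COMPLEMENT[seq[n]]
        if m > 0:
            add(2, n, "P", sites["P2"][n], m + 1, base)
        add(2, n, "S", sites["S2"][n], m + 1, base)
        add(2, n, "B", sites["B2"][n], m + 1, base)

    coords_arr = np.asarray(coords)

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords_arr[i] - coords_arr[j]))

    bonds, bonds_r0 = [], []
    angles, angles_t0 = [], []
    dihedrals, dihedrals_p0 = [], []

    def add_bond(i: int, j: int) -> None:
        bonds.append((i, j))
        bonds_r0.append(dist(i, j))

    def add_angle(i: int, j: int, k: int) -> None:
        angles.append((i, j, k))
        angles_t0.append(angle_value(coords_arr, i, j, k))

    def add_dih(i: int, j: int, k: int, l: int) -> None:
        dihedrals.append((i, j, k, l))
        dihedrals_p0.append(dihedral_value(coords_arr, i, j, k, l))

    for strand in (1, 2):
        # along-strand bp order (5'->3')
        order = range(n_bp) if strand == 1 else range(n_bp - 1, -1, -1)
        order = list(order)
        for pos, n in enumerate(order):
            s_n = idx[(strand, n, "S")]
            add_bond(s_n, idx[(strand, n, "B")])
            if pos > 0:
                prev = order[pos - 1]
                p_n = idx[(strand, n, "P")]
                add_bond(idx[(strand, prev, "S")], p_n)   # sugar(5') - phosphate
                add_bond(p_n, s_n)                        # phosphate - sugar(3')
        # angles
        for pos, n in enumerate(order):
            s_n = idx[(strand, n, "S")]
            b_n = idx[(strand, n, "B")]
            p_n = idx.get((strand, n, "P"))
            nxt = order[pos + 1] if pos + 1 < n_bp else None
            p_nxt = idx.get((strand, nxt, "P")) if nxt is not None else None
            if p_n is not None:
                prev = order[pos - 1]
                add_angle(idx[(strand, prev, "S")], p_n, s_n)       # S-P-S
                add_angle(p_n, s_n, b_n)                            # P-S-B
            if p_n is not None and p_nxt is not None:
                add_angle(p_n, s_n, p_nxt)                          # P-S-P
            if p_nxt is not None:
                add_angle(b_n, s_n, p_nxt)                          # B-S-P
        # backbone dihedrals: P-S-P-S and S-P-S-P
        for pos in range(n_bp - 1):
            n, nxt = order[pos], order[pos + 1]
            p_n = idx.get((strand, n, "P"))
            p_nxt = idx[(strand, nxt, "P")]
            s_n, s_nxt = idx[(strand, n, "S")], idx[(strand, nxt, "S")]
            if p_n is not None:
                add_dih(p_n, s_n, p_nxt, s_nxt)
            if pos + 2 < n_bp:
                p_nn = idx[(strand, order[pos + 2], "P")]
                add_dih(s_n, p_nxt, s_nxt, p_nn)

    # stacking: intra-strand neighbouring bases
    stacks, stacks_r0 = [], []
    for strand in (1, 2):
        for n in range(n_bp - 1):
            i, j = idx[(strand, n, "B")], idx[(strand, n + 1, "B")]
            stacks.append((i, j))
            stacks_r0.append(dist(i, j))

    # base pairs across strands
    basepairs, bp_type = [], []
    for n in range(n_bp):
        basepairs.append((idx[(1, n, "B")], idx[(2, n, "B")]))
        bp_type.append("AT" if seq[n] in "AT" else "GC")

    # solvation partners: the far cross-strand diagonal of each base pair
    solv = [(idx[(1, n + 1, "B")], idx[(2, n, "B")]) for n in range(n_bp - 1)]

    n_beads = len(kind)
    topo = CGTopology(
        kind=np.array(kind), chain_id=np.array(chain),
        residue_index=np.array(resi), residue_name=np.array(resn),
        charge=np.zeros(n_beads), mass=np.array(mass),
        ref_coords=coords_arr.copy(), tail=np.zeros(n_beads, bool),
        bonds_dna=np.array(bonds, int).reshape(-1, 2),
        bonds_dna_r0=np.array(bonds_r0),
        angles_dna=np.array(angles, int).reshape(-1, 3),
        angles_dna_t0=np.array(angles_t0),
        dihedrals_dna=np.array(dihedrals, int).reshape(-1, 4),
        dihedrals_dna_p0=np.array(dihedrals_p0),
        stacks=np.array(stacks, int).reshape(-1, 2),
        stacks_r0=np.array(stacks_r0),
        basepairs=np.array(basepairs, int).reshape(-1, 2),
        basepair_type=np.array(bp_type, dtype="U2"),
        solv_pairs=np.array(solv, int).reshape(-1, 2),
        metadata={"builder": "ideal-bdna", "sequence": seq,
                  "rise": geom["rise"], "twist_deg": geom["twist_deg"]},
    )
    return coords_arr, topo


def canonical_dna_reference(params: ForceFieldParameters | None = None,
                            ) -> dict[str, float]:
    """Per-term-type DNA reference values measured on the ideal helix.

    Used when coarse-graining an experimental structure: DNA internal terms
    take their B-form values regardless of the crystal geometry.
    """
    if params is None:
        params = ForceFieldParameters.default()
    coords, topo = build_ideal_bdna("ACGTA", params)
    out: dict[str, float] = {}

    def site_of(i: int) -> str:
        return {PHOSPHATE: "P", SUGAR: "S", BASE: "B"}[str(topo.kind[i])]

    for (i, j), r0 in zip(topo.bonds_dna, topo.bonds_dna_r0):
        out.setdefault("bond_" + "".join(sorted(site_of(i) + site_of(j))), float(r0))
    for (i, j, k), t0 in zip(topo.angles_dna, topo.angles_dna_t0):
        out.setdefault(f"angle_{site_of(i)}{site_of(j)}{site_of(k)}", float(t0))
    for (i, j, k, l), p0 in zip(topo.dihedrals_dna, topo.dihedrals_dna_p0):
        key = f"dihedral_{site_of(i)}{site_of(j)}{site_of(k)}{site_of(l)}"
        out.setdefault(key, float(p0))
    out["stack_BB"] = float(topo.stacks_r0[0])
    return out


# -- geometry helpers shared with the force field ------------------------

def angle_value(coords: np.ndarray, i: int, j: int, k: int) -> float:
    a = coords[i] - coords[j]
    b = coords[k] - coords[j]
    cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def dihedral_value(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))
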