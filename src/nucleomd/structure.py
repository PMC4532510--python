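"""All-atom structure input and coarse-graining.

Proteins are reduced to one site per residue at the Calpha position; each
nucleotide becomes base, sugar and phosphate sites placed at the centre of
mass of the heavy atoms of the corresponding chemical group. Native
contacts (protein-protein and protein-DNA) are enumerated from the
reference geometry with a configurable CG-site distance cutoff. Topology
variants (tail charge deletion, histidine deprotonation, bonds-only tails)
edit charges or tail term lists without changing the bead count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .bdna import angle_value, canonical_dna_reference, dihedral_value
from .params import ForceFieldParameters
from .topology import (AMINO, BASE, CGTopology, NEGATIVE_RESIDUES, PHOSPHATE,
                       POSITIVE_RESIDUES, SUGAR)

AA3 = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}
DNA_RES = {"DA", "DC", "DG", "DT", "A", "C", "G", "T"}
_DNA_CANON = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'", "O5*"}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'",
               "C1*", "C2*", "C3*", "C4*", "C5*", "O4*", "O3*"}

# 1KX5 chain conventions: A/E = H3, B/F = H4, C/G = H2A, D/H = H2B
DEFAULT_HISTONE_CHAINS = {"A": "H3", "E": "H3", "B": "H4", "F": "H4",
                          "C": "H2A", "G": "H2A", "D": "H2B", "H": "H2B"}
# N-terminal tail residue ranges (1-based, inclusive)
TAIL_RANGES = {"H3": (1, 44), "H2B": (4, 36), "H4": (1, 30), "H2A": (1, 26)}


class StructureFormatError(ValueError):
    """The file could not be parsed as a structure."""


class ChainClassificationError(ValueError):
    """A chain contains neither protein nor nucleic residues."""


class BasePairingError(ValueError):
    """The two DNA strands cannot be paired nucleotide-by-nucleotide."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    bfactor: float


@dataclass
class ResidueRecord:
    chain_id: str
    index: int             # author residue number
    name: str
    atoms: dict[str, AtomRecord]


@dataclass
class AtomisticStructure:
    """Parsed all-atom structure with per-chain classification."""

    residues: list[ResidueRecord]
    chain_class: dict[str, str]            # chain id -> "protein" | "dna"
    missing_calpha: list[tuple[str, int, str]] = field(default_factory=list)
    source: str = ""

    def chain_residues(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def protein_chains(self) -> list[str]:
        return [c for c, k in self.chain_class.items() if k == "protein"]

    @property
    def dna_chains(self) -> list[str]:
        return [c for c, k in self.chain_class.items() if k == "dna"]


def read_structure(path: str | Path) -> AtomisticStructure:
    """Parse a PDB file and classify each chain as protein or DNA.

    Residues without a Calpha (protein chains) are reported in
    ``missing_calpha`` and skipped during coarse-graining; B-factors are
    retained for comparison against computed fluctuations.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = parser.get_structure(path.stem, str(path))[0]
    except (PDBConstructionException, ValueError, KeyError, IndexError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    residues: list[ResidueRecord] = []
    chain_names: dict[str, list[str]] = {}
    for chain in model:
        for res in chain:
            if res.id[0].strip():        # skip waters / heteroatoms
                continue
            atoms = {}
            for atom in res:
                if atom.element == "H":
                    continue
                atoms[atom.get_name()] = AtomRecord(
                    atom.get_name(), atom.element or "", np.asarray(atom.coord, float),
                    float(atom.get_bfactor()))
            if not atoms:
                continue
            residues.append(ResidueRecord(chain.id, res.id[1], res.get_resname().strip(),
                                          atoms))
            chain_names.setdefault(chain.id, []).append(res.get_resname().strip())
    if not residues:
        raise StructureFormatError(f"{path}: no polymer residues found")

    chain_class: dict[str, str] = {}
    for cid, names in chain_names.items():
        n_pro = sum(n in AA3 for n in names)
        n_dna = sum(n in DNA_RES for n in names)
        if n_pro == 0 and n_dna == 0:
            raise ChainClassificationError(
                f"chain {cid}: neither protein nor nucleic residues")
        chain_class[cid] = "protein" if n_pro >= n_dna else "dna"

    missing = []
    for res in residues:
        if chain_class[res.chain_id] == "protein" and "CA" not in res.atoms:
            missing.append((res.chain_id, res.index, res.name))
    for coordinate_check in residues:
        for a in coordinate_check.atoms.values():
            if not np.all(np.isfinite(a.coords)):
                raise StructureFormatError(f"non-finite coordinates in {path}")
    return AtomisticStructure(residues, chain_class, missing, source=str(path))


@dataclass
class CoarseGrainOptions:
    """Site-placement and contact policy for coarse-graining."""

    contact_cutoff: float | None = None        # A; default from parameter file
    histone_map: dict[str, str] | None = None  # chain id -> histone name
    his_charge: int = 1
    pair_strands: tuple[str, str] | None = None


def coarse_grain(structure: AtomisticStructure,
                 params: ForceFieldParameters | None = None,
                 options: CoarseGrainOptions | None = None) -> CGTopology:
    """Reduce an all-atom structure to the CG topology with reference values.

    Protein bonded terms take the reference-structure values; DNA internal
    terms take ideal B-form values; contacts are enumerated afterwards via
    :func:`build_native_contacts` and charges via :func:`assign_charges`.
    """
    if params is None:
        params = ForceFieldParameters.default()
    opts = options or CoarseGrainOptions()

    kind: list[str] = []
    chain: list[str] = []
    resi: list[int] = []
    resn: list[str] = []
    mass: list[float] = []
    coords: list[np.ndarray] = []
    tail: list[bool] = []
    bfactors: list[float] = []

    histone_map = opts.histone_map
    if histone_map is None and len(structure.protein_chains) == 8:
        histone_map = {c: DEFAULT_HISTONE_CHAINS[c]
                       for c in structure.protein_chains if c in DEFAULT_HISTONE_CHAINS}
    histone_map = histone_map or {}

    bonds_p, angles_p, dihedrals_p = [], [], []

    # --- protein chains ------------------------------------------------
    for cid in structure.protein_chains:
        chain_start = len(kind)
        htype = histone_map.get(cid)
        t_lo, t_hi = TAIL_RANGES.get(htype, (0, -1))
        for res in structure.chain_residues(cid):
            if "CA" not in res.atoms:
                continue                       # dropped, reported by read_structure
            kind.append(AMINO)
            chain.append(cid)
            resi.append(res.index)
            resn.append(res.name)
            mass.append(params.mass_of(res.name) if res.name in params.masses else 110.0)
            coords.append(res.atoms["CA"].coords)
            tail.append(t_lo <= res.index <= t_hi)
            bfactors.append(res.atoms["CA"].bfactor)
        n_chain = len(kind) - chain_start
        for k in range(chain_start, chain_start + n_chain - 1):
            bonds_p.append((k, k + 1))
        for k in range(chain_start, chain_start + n_chain - 2):
            angles_p.append((k, k + 1, k + 2))
        for k in range(chain_start, chain_start + n_chain - 3):
            dihedrals_p.append((k, k + 1, k + 2, k + 3))

    # --- DNA chains ----------------------------------------------------
    dna_chains = structure.dna_chains
    bonds_d, bonds_d_r0 = [], []
    angles_d, angles_d_t0 = [], []
    dihedrals_d, dihedrals_d_p0 = [], []
    stacks, stacks_r0 = [], []
    basepairs, bp_type = [], []
    solv = []
    if dna_chains:
        if len(dna_chains) != 2:
            raise BasePairingError(f"expected exactly 2 DNA chains, got {dna_chains}")
        ref = canonical_dna_reference(params)
        c1, c2 = opts.pair_strands or tuple(dna_chains)
        strand1 = structure.chain_residues(c1)
        strand2 = structure.chain_residues(c2)
        if len(strand1) != len(strand2):
            raise BasePairingError(
                f"strands {c1} ({len(strand1)} nt) and {c2} ({len(strand2)} nt) "
                "have unequal nucleotide counts")
        n_bp = len(strand1)
        site_index: dict[tuple[int, int, str], int] = {}

        def group_com(res: ResidueRecord, names: set[str]) -> np.ndarray | None:
            pts = [a.coords for a in res.atoms.values() if a.name in names]
            if not pts:
                return None
            return np.mean(pts, axis=0)

        for strand_no, strand in ((1, strand1), (2, strand2)):
            for nt_pos, res in enumerate(strand):
                base_name = _DNA_CANON.get(res.name, res.name)
                bp_index = nt_pos if strand_no == 1 else n_bp - 1 - nt_pos
                p = group_com(res, PHOSPHATE_ATOMS)
                s = group_com(res, SUGAR_ATOMS)
                b_atoms = {a.name for a in res.atoms.values()} - PHOSPHATE_ATOMS - SUGAR_ATOMS
                b = group_com(res, b_atoms)
                if s is None or b is None:
                    raise BasePairingError(
                        f"nucleotide {res.chain_id}{res.index}: missing sugar/base atoms")
                has_p = p is not None and "P" in res.atoms and nt_pos > 0
                entries = ([("P", p)] if has_p else []) + [("S", s), ("B", b)]
                for site, pos in entries:
                    site_index[(strand_no, bp_index, site)] = len(kind)
                    kind.append({"P": PHOSPHATE, "S": SUGAR, "B": BASE}[site])
                    chain.append(res.chain_id)
                    resi.append(res.index)
                    resn.append(base_name)
                    mkey = {"P": "DP", "S": "DS"}.get(site, base_name)
                    mass.append(params.mass_of(mkey))
                    coords.append(pos)
                    tail.append(False)
                    atom_b = res.atoms.get({"P": "P", "S": "C1'"}.get(site, "N1"))
                    bfactors.append(atom_b.bfactor if atom_b else 0.0)

        # bonded terms along each strand with ideal B-form reference values
        for strand_no in (1, 2):
            order = list(range(n_bp)) if strand_no == 1 else list(range(n_bp - 1, -1, -1))
            for pos, n in enumerate(order):
                s_n = site_index[(strand_no, n, "S")]
                b_n = site_index[(strand_no, n, "B")]
                bonds_d.append((s_n, b_n))
                bonds_d_r0.append(ref["bond_BS"])
                p_n = site_index.get((strand_no, n, "P"))
                nxt = order[pos + 1] if pos + 1 < n_bp else None
                p_nxt = site_index.get((strand_no, nxt, "P")) if nxt is not None else None
                if p_n is not None and pos > 0:
                    s_prev = site_index[(strand_no, order[pos - 1], "S")]
                    bonds_d.append((s_prev, p_n))
                    bonds_d_r0.append(ref["bond_PS"])
                    bonds_d.append((p_n, s_n))
                    bonds_d_r0.append(ref["bond_PS"])
                    angles_d.append((s_prev, p_n, s_n))
                    angles_d_t0.append(ref["angle_SPS"])
                    angles_d.append((p_n, s_n, b_n))
                    angles_d_t0.append(ref["angle_PSB"])
                if p_n is not None and p_nxt is not None:
                    angles_d.append((p_n, s_n, p_nxt))
                    angles_d_t0.append(ref["angle_PSP"])
                if p_nxt is not None:
                    angles_d.append((b_n, s_n, p_nxt))
                    angles_d_t0.append(ref["angle_BSP"])
            for pos in range(n_bp - 1):
                n, nxt = order[pos], order[pos + 1]
                p_n = site_index.get((strand_no, n, "P"))
                p_nxt = site_index[(strand_no, nxt, "P")]
                s_n = site_index[(strand_no, n, "S")]
                s_nxt = site_index[(strand_no, nxt, "S")]
                if p_n is not None:
                    dihedrals_d.append((p_n, s_n, p_nxt, s_nxt))
                    dihedrals_d_p0.append(ref["dihedral_PSPS"])
                if pos + 2 < n_bp:
                    p_nn = site_index[(strand_no, order[pos + 2], "P")]
                    dihedrals_d.append((s_n, p_nxt, s_nxt, p_nn))
                    dihedrals_d_p0.append(ref["dihedral_SPSP"])
            for n in range(n_bp - 1):
                stacks.append((site_index[(strand_no, n, "B")],
                               site_index[(strand_no, n + 1, "B")]))
                stacks_r0.append(ref["stack_BB"])

        complement_ok = {("DA", "DT"), ("DT", "DA"), ("DG", "DC"), ("DC", "DG")}
        for n in range(n_bp):
            i = site_index[(1, n, "B")]
            j = site_index[(2, n, "B")]
            pair = (resn[i], resn[j])
            if pair not in complement_ok:
                raise BasePairingError(
                    f"base pair {n + 1}: {pair[0]}/{pair[1]} are not complementary")
            basepairs.append((i, j))
            bp_type.append("AT" if resn[i] in ("DA", "DT") else "GC")
        for n in range(n_bp - 1):
            solv.append((site_index[(1, n + 1, "B")], site_index[(2, n, "B")]))

    coords_arr = np.asarray(coords, float).reshape(-1, 3)

    # protein reference values from the structure itself
    bonds_p_arr = np.array(bonds_p, int).reshape(-1, 2)
    bonds_p_r0 = np.array([np.linalg.norm(coords_arr[i] - coords_arr[j])
                           for i, j in bonds_p_arr])
    angles_p_arr = np.array(angles_p, int).reshape(-1, 3)
    angles_p_t0 = np.array([angle_value(coords_arr, *ijk) for ijk in angles_p_arr])
    dihedrals_p_arr = np.array(dihedrals_p, int).reshape(-1, 4)
    dihedrals_p_p0 = np.array([dihedral_value(coords_arr, *ijkl)
                               for ijkl in dihedrals_p_arr])

    n_beads = len(kind)
    topo = CGTopology(
        kind=np.array(kind), chain_id=np.array(chain),
        residue_index=np.array(resi, int), residue_name=np.array(resn),
        charge=np.zeros(n_beads), mass=np.array(mass, float),
        ref_coords=coords_arr, tail=np.array(tail, bool),
        bonds_pro=bonds_p_arr, bonds_pro_r0=bonds_p_r0,
        angles_pro=angles_p_arr, angles_pro_t0=angles_p_t0,
        dihedrals_pro=dihedrals_p_arr, dihedrals_pro_p0=dihedrals_p_p0,
        bonds_dna=np.array(bonds_d, int).reshape(-1, 2),
        bonds_dna_r0=np.array(bonds_d_r0, float),
        angles_dna=np.array(angles_d, int).reshape(-1, 3),
        angles_dna_t0=np.array(angles_d_t0, float),
        dihedrals_dna=np.array(dihedrals_d, int).reshape(-1, 4),
        dihedrals_dna_p0=np.array(dihedrals_d_p0, float),
        stacks=np.array(stacks, int).reshape(-1, 2),
        stacks_r0=np.array(stacks_r0, float),
        basepairs=np.array(basepairs, int).reshape(-1, 2),
        basepair_type=np.array(bp_type, dtype="U2"),
        solv_pairs=np.array(solv, int).reshape(-1, 2),
        metadata={"source": structure.source,
                  "histone_map": histone_map,
                  "experimental_bfactors": bfactors},
    )
    topo = build_native_contacts(topo, cutoff=opts.contact_cutoff, params=params)
    assign_charges(topo, his_charge=opts.his_charge)
    return topo


def assign_charges(topology: CGTopology, his_charge: int = 1) -> dict[str, int]:
    """Assign standard ionisation states in place; return counts by type.

    Phosphates, Asp and Glu get -1; Lys, Arg get +1; His gets ``his_charge``
    (+1 protonated, 0 deprotonated); everything else 0.
    """
    if his_charge not in (0, 1):
        raise ValueError("his_charge must be 0 or +1")
    counts: dict[str, int] = {}
    charge = np.zeros(topology.n_beads)
    for i in range(topology.n_beads):
        k = str(topology.kind[i])
        name = str(topology.residue_name[i])
        if k == PHOSPHATE:
            charge[i] = -1.0
            counts["phosphate"] = counts.get("phosphate", 0) + 1
        elif k == AMINO:
            if name not in AA3:
                raise ValueError(f"unknown residue name: {name!r}")
            if name in NEGATIVE_RESIDUES:
                charge[i] = -1.0
            elif name == "HIS":
                charge[i] = float(his_charge)
            elif name in POSITIVE_RESIDUES:
                charge[i] = 1.0
            counts[name] = counts.get(name, 0) + 1
        elif name not in ("DA", "DC", "DG", "DT"):
            raise ValueError(f"unknown residue name: {name!r}")
    topology.charge = charge
    topology.metadata["his_charge"] = his_charge
    return counts


def build_native_contacts(topology: CGTopology, coords: np.ndarray | None = None,
                          cutoff: float | None = None,
                          params: ForceFieldParameters | None = None) -> CGTopology:
    """Enumerate native contacts from the reference geometry.

    Protein-protein contacts require sequence separation |i-j| > 3 within a
    chain (inter-chain pairs are always eligible) and must not be bonded.
    Protein-DNA contacts connect protein beads to sugar and base sites only,
    never phosphates. The cutoff rule is a single CG-site distance threshold
    recorded in the topology metadata.
    """
    if params is None:
        params = ForceFieldParameters.default()
    if cutoff is None:
        cutoff = params.contact_cutoff
    min_sep = params.min_seq_separation
    if coords is None:
        coords = topology.ref_coords

    pro_idx = np.nonzero(topology.is_protein)[0]
    dna_ok_idx = np.nonzero(np.isin(topology.kind, (SUGAR, BASE)))[0]

    contacts_pro, contacts_pro_r0 = [], []
    if len(pro_idx) >= 2:
        tree = cKDTree(coords[pro_idx])
        for a, b in sorted(tree.query_pairs(cutoff)):
            i, j = int(pro_idx[a]), int(pro_idx[b])
            same_chain = topology.chain_id[i] == topology.chain_id[j]
            sep = abs(int(topology.residue_index[i]) - int(topology.residue_index[j]))
            if same_chain and sep < min_sep:
                continue
            contacts_pro.append((i, j))
            contacts_pro_r0.append(float(np.linalg.norm(coords[i] - coords[j])))

    contacts_pd, contacts_pd_r0 = [], []
    if len(pro_idx) and len(dna_ok_idx):
        tree = cKDTree(coords[dna_ok_idx])
        for a, neighbours in enumerate(tree.query_ball_point(coords[pro_idx], cutoff)):
            i = int(pro_idx[a])
            for b in neighbours:
                j = int(dna_ok_idx[b])
                contacts_pd.append((i, j))
                contacts_pd_r0.append(float(np.linalg.norm(coords[i] - coords[j])))

    topology.contacts_pro = np.array(contacts_pro, int).reshape(-1, 2)
    topology.contacts_pro_r0 = np.array(contacts_pro_r0, float)
    topology.contacts_prodna = np.array(contacts_pd, int).reshape(-1, 2)
    topology.contacts_prodna_r0 = np.array(contacts_pd_r0, float)
    topology.metadata["contact_cutoff"] = float(cutoff)
    topology.metadata["contact_rule"] = "cg-site-distance"
    return topology


@dataclass
class TopologyVariant:
    """A charge/tail edit of a base topology (bead count unchanged)."""

    topology: CGTopology
    description: str
    tails_uncharged: tuple[str, ...] = ()
    his_charge: int = 1
    tail_mode: str = "go"       # "go" | "bonds-only"


def apply_variant(topology: CGTopology,
                  delete_tail_charges: str | tuple[str, ...] = (),
                  his_charge: int = 1,
                  tail_mode: str = "go") -> TopologyVariant:
    """Produce a modified copy of ``topology``.

    ``delete_tail_charges`` names histones ("H3", "H4", "H2A", "H2B") whose
    N-terminal tail beads lose their charge in both chain copies (the
    acetylation mimic). ``his_charge=0`` deprotonates every histidine
    globally. ``tail_mode="bonds-only"`` removes tail angle, dihedral and
    contact terms but keeps bond terms (the disordered-tail control).
    """
    if isinstance(delete_tail_charges, str):
        delete_tail_charges = (delete_tail_charges,)
    for h in delete_tail_charges:
        if h not in TAIL_RANGES:
            raise ValueError(f"unknown histone name: {h!r}")
    if tail_mode not in ("go", "bonds-only"):
        raise ValueError(f"unknown tail mode: {tail_mode!r}")

    new = CGTopology.from_dict(topology.to_dict())   # deep copy
    assign_charges(new, his_charge=his_charge)

    histone_map: dict[str, str] = new.metadata.get("histone_map", {})
    if delete_tail_charges:
        target_chains = {c for c, h in histone_map.items() if h in delete_tail_charges}
        if target_chains:
            mask = new.tail & np.isin(new.chain_id, sorted(target_chains))
            new.charge[mask] = 0.0
        else:       # histone type absent from this system: degenerate no-op
            warnings.warn(f"no chains mapped to histones {delete_tail_charges}; "
                          "charges unchanged", stacklevel=2)

    if tail_mode == "bonds-only":
        t = new.tail

        def keep(arr: np.ndarray) -> np.ndarray:
            if len(arr) == 0:
                return np.ones(0, bool)
            return ~t[np.asarray(arr, int)].any(axis=1)

        for name, vname in (("angles_pro", "angles_pro_t0"),
                            ("dihedrals_pro", "dihedrals_pro_p0"),
                            ("contacts_pro", "contacts_pro_r0"),
                            ("contacts_prodna", "contacts_prodna_r0")):
            m = keep(getattr(new, name))
            setattr(new, name, getattr(new, name)[m])
            setattr(new, vname, getattr(new, vname)[m])

    desc = []
    if delete_tail_charges:
        desc.append("dch:" + "+".join(delete_tail_charges))
    if his_charge == 0:
        desc.append("his0")
    if tail_mode != "go":
        desc.append(tail_mode)
    new.metadata["variant"] = ",".join(desc) or "canonical"
    return TopologyVariant(new, new.metadata["variant"],
                           tuple(delete_tail_charges), his_charge, tail_mode)


def write_pdb(topology: CGTopology, coords: np.ndarray, path: str | Path) -> None:
    """Write CG beads as a PDB-compatible coordinate file for inspection."""
    name_of = {AMINO: "CA", PHOSPHATE: "DP", SUGAR: "DS", BASE: "DB"}
    lines = []
    for i in range(topology.n_beads):
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:>5d} {name_of[str(topology.kind[i])]:<4s} "
            f"{str(topology.residue_name[i])[:3]:>3s} {str(topology.chain_id[i])[:1]}"
            f"{int(topology.residue_index[i]) % 10000:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
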