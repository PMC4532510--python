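"""Coarse-grained topology container.

A :class:`CGTopology` holds the bead table (one Calpha site per amino acid;
base, sugar and phosphate sites per nucleotide), the bonded lists with their
reference values, the attractive non-bonded lists (protein and protein-DNA
native contacts, intra-strand stacking pairs, cross-strand base pairs and
solvation pairs) and bookkeeping needed by the energy evaluators.

Reference values r0/theta0/phi0 are frozen into the topology at build time:
protein terms from the reference structure, DNA internal terms from the
ideal B-form helix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TOPOLOGY_SCHEMA_VERSION = 1

# bead kinds
AMINO = "amino"
BASE = "base"
SUGAR = "sugar"
PHOSPHATE = "phosphate"
DNA_KINDS = (BASE, SUGAR, PHOSPHATE)

NEGATIVE_RESIDUES = ("ASP", "GLU")
POSITIVE_RESIDUES = ("LYS", "ARG", "HIS")


@dataclass
class CGBead:
    """A single coarse-grained site (row view of the bead table)."""

    index: int
    kind: str
    chain_id: str
    residue_index: int
    residue_name: str
    charge: float
    mass: float
    coords: np.ndarray
    tail: bool


@dataclass
class CGTopology:
    # bead table (parallel arrays, length n_beads)
    kind: np.ndarray            # unicode
    chain_id: np.ndarray        # unicode
    residue_index: np.ndarray   # int, 1-based within chain
    residue_name: np.ndarray    # unicode (3-letter AA or DA/DC/DG/DT)
    charge: np.ndarray          # float, elementary charges
    mass: np.ndarray            # float, g/mol
    ref_coords: np.ndarray      # (n, 3) float, Angstrom
    tail: np.ndarray            # bool

    # bonded terms: index arrays plus reference values
    bonds_pro: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    bonds_pro_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    bonds_dna: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    bonds_dna_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    angles_pro: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    angles_pro_t0: np.ndarray = field(default_factory=lambda: np.empty(0))
    angles_dna: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    angles_dna_t0: np.ndarray = field(default_factory=lambda: np.empty(0))
    dihedrals_pro: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))
    dihedrals_pro_p0: np.ndarray = field(default_factory=lambda: np.empty(0))
    dihedrals_dna: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))
    dihedrals_dna_p0: np.ndarray = field(default_factory=lambda: np.empty(0))

    # attractive non-bonded lists
    contacts_pro: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    contacts_pro_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    contacts_prodna: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    contacts_prodna_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    stacks: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    stacks_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    basepairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    basepair_type: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U2"))
    solv_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.kind)

    @property
    def is_protein(self) -> np.ndarray:
        return self.kind == AMINO

    @property
    def is_dna(self) -> np.ndarray:
        return np.isin(self.kind, DNA_KINDS)

    @property
    def charged_indices(self) -> np.ndarray:
        return np.nonzero(self.charge != 0.0)[0]

    def bead(self, i: int) -> CGBead:
        return CGBead(i, str(self.kind[i]), str(self.chain_id[i]),
                      int(self.residue_index[i]), str(self.residue_name[i]),
                      float(self.charge[i]), float(self.mass[i]),
                      self.ref_coords[i].copy(), bool(self.tail[i]))

    def total_charge(self) -> float:
        return float(self.charge.sum())

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(str(c))
        return seen

    def protein_chains(self) -> list[str]:
        mask = self.is_protein
        return [c for c in self.chains() if np.any((self.chain_id == c) & mask)]

    def dna_chains(self) -> list[str]:
        mask = self.is_dna
        return [c for c in self.chains() if np.any((self.chain_id == c) & mask)]

    # ------------------------------------------------------------------
    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Pairs excluded from excluded-volume and electrostatic sums.

        Bonded 1-2 pairs, 1-3 pairs (angle ends) and every pair already in an
        attractive non-bonded list.
        """
        excl: set[tuple[int, int]] = set()

        def add(i: int, j: int) -> None:
            excl.add((i, j) if i < j else (j, i))

        for arr in (self.bonds_pro, self.bonds_dna, self.contacts_pro,
                    self.contacts_prodna, self.stacks, self.basepairs,
                    self.solv_pairs):
            for i, j in np.asarray(arr, int):
                add(int(i), int(j))
        for arr in (self.angles_pro, self.angles_dna):
            for i, _, k in np.asarray(arr, int):
                add(int(i), int(k))
        return excl

    def validate(self) -> None:
        n = self.n_beads
        assert self.ref_coords.shape == (n, 3)
        if not np.all(np.isfinite(self.ref_coords)):
            raise ValueError("non-finite reference coordinates")
        if not np.all(np.isin(self.charge, (-1.0, 0.0, 1.0))):
            raise ValueError("bead charges must be -1, 0 or +1")
        # phosphates never appear in protein-DNA contacts
        if len(self.contacts_prodna):
            kinds = self.kind[np.asarray(self.contacts_prodna, int)]
            if np.any(kinds == PHOSPHATE):
                raise ValueError("protein-DNA contact references a phosphate site")
        # every pair in at most one attractive list
        seen: set[tuple[int, int]] = set()
        for arr in (self.contacts_pro, self.contacts_prodna, self.stacks,
                    self.basepairs, self.solv_pairs):
            for i, j in np.asarray(arr, int):
                key = (int(i), int(j)) if i < j else (int(j), int(i))
                if key in seen:
                    raise ValueError(f"pair {key} appears in two attractive lists")
                seen.add(key)

    # ------------------------------------------------------------------
    _ARRAYS = [
        "kind", "chain_id", "residue_index", "residue_name", "charge", "mass",
        "ref_coords", "tail", "bonds_pro", "bonds_pro_r0", "bonds_dna",
        "bonds_dna_r0", "angles_pro", "angles_pro_t0", "angles_dna",
        "angles_dna_t0", "dihedrals_pro", "dihedrals_pro_p0", "dihedrals_dna",
        "dihedrals_dna_p0", "contacts_pro", "contacts_pro_r0",
        "contacts_prodna", "contacts_prodna_r0", "stacks", "stacks_r0",
        "basepairs", "basepair_type", "solv_pairs",
    ]

    def to_dict(self) -> dict:
        out: dict = {"schema_version": TOPOLOGY_SCHEMA_VERSION,
                     "metadata": self.metadata}
        for name in self._ARRAYS:
            out[name] = np.asarray(getattr(self, name)).tolist()
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "CGTopology":
        if d.get("schema_version") != TOPOLOGY_SCHEMA_VERSION:
            raise ValueError(f"unsupported topology schema: {d.get('schema_version')}")
        kw: dict = {"metadata": d.get("metadata", {})}
        int2 = {"bonds_pro", "bonds_dna", "contacts_pro", "contacts_prodna",
                "stacks", "basepairs", "solv_pairs"}
        for name in cls._ARRAYS:
            val = d[name]
            if name in ("kind", "chain_id", "residue_name", "basepair_type"):
                arr = np.asarray(val, dtype="U16")
            elif name == "tail":
                arr = np.asarray(val, bool)
            elif name == "residue_index":
                arr = np.asarray(val, int)
            elif name in int2 or name.startswith(("angles", "dihedrals")) \
                    and not name.endswith(("_t0", "_p0")):
                arr = np.asarray(val, int)
                cols = {"angles_pro": 3, "angles_dna": 3,
                        "dihedrals_pro": 4, "dihedrals_dna": 4}.get(name, 2)
                arr = arr.reshape(-1, cols)
            else:
                arr = np.asarray(val, float)
                if name == "ref_coords":
                    arr = arr.reshape(-1, 3)
            kw[name] = arr
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "CGTopology":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the topology content, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
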