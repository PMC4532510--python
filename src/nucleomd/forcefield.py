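"""Energy and analytic forces for V_total = V_pro + V_dna + V_pro-dna.

The protein part is a Calpha structure-based (Go) potential: harmonic
bonds and angles, 1- and 3-fold cosine dihedrals, 12-10 native contacts and
r^-12 excluded volume. The DNA part is a three-site-per-nucleotide
potential: quadratic+quartic bonds, harmonic angles, cosine dihedrals,
12-6 stacking at native separation, 12-10 base pairing, truncated-shifted
excluded volume, screened (Debye-Hueckel) Coulomb interactions and a
Morse-like solvation term assisting base pairing. Protein-DNA coupling is
a 12-10 contact potential to sugar/base sites (strength = scaling x the
protein contact strength), r^-12 excluded volume and the same screened
Coulomb term.

A :class:`ForceField` is compiled once from (topology, parameters): all
pair index arrays, reference values and exclusions are frozen, after which
:meth:`energy_forces` is a pure function of coordinates. Exclusions follow
standard CG practice: 1-2 and 1-3 bonded pairs are removed from excluded
volume and electrostatics, pairs on any attractive native list are removed
from excluded volume, and protein excluded volume (like the contacts)
requires sequence separation > 3 within a chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import COULOMB_K, ForceFieldParameters
from .topology import CGTopology

_TERM_KEYS = (
    "pro_bond", "pro_angle", "pro_dihedral", "pro_contact", "pro_ev",
    "dna_bond", "dna_angle", "dna_dihedral", "dna_stack", "dna_bp",
    "dna_ev", "dna_solv", "prodna_contact", "prodna_ev",
    "elec_pro", "elec_dna", "elec_prodna",
)


class OverlapError(FloatingPointError):
    """Two interacting beads are (numerically) on top of each other."""


@dataclass
class EnergyReport:
    """Per-term energies (kcal/mol) and per-bead forces (kcal/mol/A)."""

    terms: dict[str, float]
    forces: np.ndarray

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def net_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    def as_row(self) -> dict[str, float]:
        row = dict(self.terms)
        row["total"] = self.total
        return row


# ----------------------------------------------------------------------
# pairwise primitives: each returns (energies, dE/dr) for distance arrays
# ----------------------------------------------------------------------

def _go_12_10(r: np.ndarray, r0: np.ndarray, eps: float):
    s12 = (r0 / r) ** 12
    s10 = (r0 / r) ** 10
    e = eps * (5.0 * s12 - 6.0 * s10)
    dedr = -60.0 * eps * (s12 - s10) / r
    return e, dedr


def _lj_12_6(r: np.ndarray, sigma: np.ndarray, eps: float):
    s6 = (sigma / r) ** 6
    e = 4.0 * eps * (s6 * s6 - s6)
    dedr = -24.0 * eps * (2.0 * s6 * s6 - s6) / r
    return e, dedr


def _wca(r: np.ndarray, sigma: float, eps: float):
    cut = 2.0 ** (1.0 / 6.0) * sigma
    inside = r < cut
    e = np.zeros_like(r)
    dedr = np.zeros_like(r)
    if np.any(inside):
        s6 = (sigma / r[inside]) ** 6
        e[inside] = 4.0 * eps * (s6 * s6 - s6 + 0.25)
        dedr[inside] = -24.0 * eps * (2.0 * s6 * s6 - s6) / r[inside]
    return e, dedr


def _repulsive_12(r: np.ndarray, sigma: float, eps: float, cutoff: float):
    inside = r < cutoff
    e = np.zeros_like(r)
    dedr = np.zeros_like(r)
    if np.any(inside):
        s12 = (sigma / r[inside]) ** 12
        e[inside] = eps * s12
        dedr[inside] = -12.0 * eps * s12 / r[inside]
    return e, dedr


def _debye_huckel(r: np.ndarray, qq: np.ndarray, dielectric: float,
                  lam: float, cutoff: float):
    inside = r < cutoff
    e = np.zeros_like(r)
    dedr = np.zeros_like(r)
    if np.any(inside):
        ri = r[inside]
        pref = COULOMB_K * qq[inside] / dielectric
        ei = pref * np.exp(-ri / lam) / ri
        e[inside] = ei
        dedr[inside] = -ei * (1.0 / ri + 1.0 / lam)
    return e, dedr


def _solvation(r: np.ndarray, eps_s: float, alpha: float, r_s: float):
    g = np.exp(-alpha * (r - r_s))
    e = eps_s * ((1.0 - g) ** 2 - 1.0)
    dedr = 2.0 * eps_s * alpha * g * (1.0 - g)
    return e, dedr


# ----------------------------------------------------------------------

def _pair_geometry(coords: np.ndarray, pairs: np.ndarray, label: str):
    rij = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(rij, axis=1)
    if np.any(r < 1e-6):
        raise OverlapError(f"overlapping beads in {label} pair list")
    return rij, r



def _accumulate(forces: np.ndarray, idx: np.ndarray, vec: np.ndarray) -> None:
    """Scatter-add vec rows into forces at idx (bincount is much faster
    than np.add.at for repeated indices)."""
    n = forces.shape[0]
    for d in range(3):
        forces[:, d] += np.bincount(idx, weights=vec[:, d], minlength=n)


def _scatter_pair_forces(forces: np.ndarray, pairs: np.ndarray,
                         rij: np.ndarray, r: np.ndarray, dedr: np.ndarray) -> None:
    f = (-dedr / r)[:, None] * rij       # force on pairs[:,0]
    _accumulate(forces, pairs[:, 0], f)
    _accumulate(forces, pairs[:, 1], -f)


def _sum(e):
    return float(np.sum(e))


def _angle_term(coords, triples, theta0, forces, dE_of):
    """Generic angle accumulation; dE_of(theta) -> (E, dE/dtheta) arrays."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    a = coords[i] - coords[j]
    b = coords[k] - coords[j]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ah = a / na[:, None]
    bh = b / nb[:, None]
    cos_t = np.clip(np.sum(ah * bh, axis=1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    e, dedt = dE_of(theta)
    # guarded: the collinear limit has sin(theta) -> 0; the restoring force
    # direction degenerates, and we return zero force there (no NaN)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
    fi = (dedt / (na * sin_t))[:, None] * (bh - cos_t[:, None] * ah)
    fk = (dedt / (nb * sin_t))[:, None] * (ah - cos_t[:, None] * bh)
    _accumulate(forces, i, fi)
    _accumulate(forces, k, fk)
    _accumulate(forces, j, -(fi + fk))
    return e


def _dihedral_angles(coords, quads):
    i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.arctan2(y, x), (b1, b2, b3, n1, n2, nb2)


def _dihedral_term(coords, quads, forces, dE_of):
    """Generic dihedral accumulation; dE_of(phi) -> (E, dE/dphi)."""
    phi, (b1, b2, b3, n1, n2, nb2) = _dihedral_angles(coords, quads)
    e, dedp = dE_of(phi)
    i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    # collinear guard: if either plane degenerates the angle is undefined
    ok = (n1sq > 1e-12) & (n2sq > 1e-12)
    dphi_dri = np.zeros_like(b1)
    dphi_drl = np.zeros_like(b1)
    dphi_dri[ok] = (nb2[ok] / n1sq[ok])[:, None] * n1[ok]
    dphi_drl[ok] = (-nb2[ok] / n2sq[ok])[:, None] * n2[ok]
    c12 = np.sum(b1 * b2, axis=1) / nb2 ** 2
    c32 = np.sum(b3 * b2, axis=1) / nb2 ** 2
    dphi_drj = -(1.0 + c12)[:, None] * dphi_dri + c32[:, None] * dphi_drl
    dphi_drk = c12[:, None] * dphi_dri - (1.0 + c32)[:, None] * dphi_drl
    g = dedp[:, None]
    _accumulate(forces, i, -g * dphi_dri)
    _accumulate(forces, j, -g * dphi_drj)
    _accumulate(forces, k, -g * dphi_drk)
    _accumulate(forces, l, -g * dphi_drl)
    return e


# ----------------------------------------------------------------------

@dataclass
class _PairTable:
    pairs: np.ndarray
    qq: np.ndarray | None = None


class ForceField:
    """Compiled evaluator of the total energy and analytic forces."""

    def __init__(self, topology: CGTopology, params: ForceFieldParameters):
        self.topology = topology
        self.params = params
        t = topology
        n = t.n_beads
        self.n_beads = n

        # base-pair coefficients resolved per pair type
        self.bp_eps = np.array([params.eps_bp[str(k)] for k in t.basepair_type])
        self.bp_sigma = np.array([params.sigma_bp[str(k)] for k in t.basepair_type])

        excl = t.excluded_pairs()
        is_pro = t.is_protein
        pro_idx = np.nonzero(is_pro)[0]
        dna_idx = np.nonzero(t.is_dna)[0]

        excl_keys = np.array(sorted(i * n + j for i, j in excl), dtype=np.int64)

        def candidate_pairs(group_a, group_b, same_group, min_sep_chain=0):
            if same_group:
                ga = np.asarray(group_a, int)
                if len(ga) < 2:
                    return np.empty((0, 2), int)
                ai, bi = np.triu_indices(len(ga), k=1)
                pairs = np.stack([ga[ai], ga[bi]], axis=1)
            else:
                ga = np.asarray(group_a, int)
                gb = np.asarray(group_b, int)
                if not len(ga) or not len(gb):
                    return np.empty((0, 2), int)
                pairs = np.stack(np.meshgrid(ga, gb, indexing="ij"),
                                 axis=-1).reshape(-1, 2)
                pairs = np.sort(pairs, axis=1)
            keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
            keep = ~np.isin(keys, excl_keys)
            if min_sep_chain:
                same_chain = t.chain_id[pairs[:, 0]] == t.chain_id[pairs[:, 1]]
                sep = np.abs(t.residue_index[pairs[:, 0]]
                             - t.residue_index[pairs[:, 1]])
                keep &= ~(same_chain & (sep < min_sep_chain))
            return pairs[keep]

        self.ev_pro = candidate_pairs(pro_idx, None, True,
                                      min_sep_chain=params.min_seq_separation)
        self.ev_dna = candidate_pairs(dna_idx, None, True)
        self.ev_prodna = candidate_pairs(pro_idx, dna_idx, False)

        charged = t.charged_indices
        q = t.charge
        elec_pairs = candidate_pairs(charged, None, True)
        if len(elec_pairs):
            a_pro = is_pro[elec_pairs[:, 0]]
            b_pro = is_pro[elec_pairs[:, 1]]
            self.elec = {
                "elec_pro": _PairTable(elec_pairs[a_pro & b_pro]),
                "elec_dna": _PairTable(elec_pairs[~a_pro & ~b_pro]),
                "elec_prodna": _PairTable(elec_pairs[a_pro ^ b_pro]),
            }
        else:
            self.elec = {k: _PairTable(np.empty((0, 2), int))
                         for k in ("elec_pro", "elec_dna", "elec_prodna")}
        for tab in self.elec.values():
            tab.qq = q[tab.pairs[:, 0]] * q[tab.pairs[:, 1]] if len(tab.pairs) \
                else np.empty(0)

        self._build_fused_tables()

    # ------------------------------------------------------------------
    def _build_fused_tables(self) -> None:
        """Concatenate every pair list so the full evaluation touches the
        coordinates once (single gather, single scatter)."""
        t = self.topology
        blocks: list[tuple[str, int, int, str]] = []
        chunks: list[np.ndarray] = []
        pos = 0

        def add(key: str, pairs: np.ndarray, kind: str) -> None:
            nonlocal pos
            if len(pairs):
                chunks.append(np.asarray(pairs, int))
                blocks.append((key, pos, pos + len(pairs), kind))
                pos += len(pairs)

        add("pro_bond", t.bonds_pro, "bond_pro")
        add("dna_bond", t.bonds_dna, "bond_dna")
        add("pro_contact", t.contacts_pro, "go_pro")
        add("prodna_contact", t.contacts_prodna, "go_prodna")
        add("dna_stack", t.stacks, "lj")
        add("dna_bp", t.basepairs, "bp")
        add("dna_solv", t.solv_pairs, "solv")
        add("pro_ev", self.ev_pro, "rep_pro")
        add("dna_ev", self.ev_dna, "wca")
        add("prodna_ev", self.ev_prodna, "rep_prodna")
        for key in ("elec_pro", "elec_dna", "elec_prodna"):
            add(key, self.elec[key].pairs, "dh")
        self._blocks = blocks
        if chunks:
            pairs = np.vstack(chunks)
            self._pi = np.ascontiguousarray(pairs[:, 0], np.int64)
            self._pj = np.ascontiguousarray(pairs[:, 1], np.int64)
        else:
            self._pi = self._pj = np.empty(0, np.int64)
        qq_parts = [self.elec[k].qq for k in ("elec_pro", "elec_dna", "elec_prodna")]
        self._qq = np.concatenate([q for q in qq_parts if q is not None]) \
            if any(len(q) for q in qq_parts) else np.empty(0)

        # packed per-pair parameters for the jitted kernel
        par = self.params
        m = len(self._pi)
        kind = np.zeros(m, np.int64)
        pa = np.zeros(m)
        pb = np.zeros(m)
        pc = np.zeros(m)
        t_ = self.topology
        n_elec_seen = 0
        for key, a, b, kd in self._blocks:
            if kd == "bond_pro":
                kind[a:b] = 0
                pa[a:b] = par.k_bond_pro
                pb[a:b] = t_.bonds_pro_r0
            elif kd == "bond_dna":
                kind[a:b] = 1
                pa[a:b] = t_.bonds_dna_r0
                pb[a:b] = par.k_bond2_dna
                pc[a:b] = par.k_bond4_dna
            elif kd == "go_pro":
                kind[a:b] = 2
                pa[a:b] = par.eps_go_pro
                pb[a:b] = t_.contacts_pro_r0
            elif kd == "go_prodna":
                kind[a:b] = 2
                pa[a:b] = par.eps_go_prodna
                pb[a:b] = t_.contacts_prodna_r0
            elif kd == "bp":
                kind[a:b] = 2
                pa[a:b] = self.bp_eps
                pb[a:b] = self.bp_sigma
            elif kd == "lj":
                kind[a:b] = 3
                pa[a:b] = par.eps_stack
                pb[a:b] = t_.stacks_r0
            elif kd == "solv":
                kind[a:b] = 4
                pa[a:b] = par.eps_solv
                pb[a:b] = par.alpha_solv
                pc[a:b] = par.r_solv
            elif kd == "rep_pro":
                kind[a:b] = 5
                pa[a:b] = par.eps_ev_pro
                pb[a:b] = par.sigma_ev_pro
                pc[a:b] = par.ev_cutoff_factor_pro * par.sigma_ev_pro
            elif kd == "rep_prodna":
                kind[a:b] = 5
                pa[a:b] = par.eps_ev_prodna
                pb[a:b] = par.sigma_ev_prodna
                pc[a:b] = par.ev_cutoff_factor_prodna * par.sigma_ev_prodna
            elif kd == "wca":
                kind[a:b] = 6
                pa[a:b] = par.eps_ev_dna
                pb[a:b] = par.sigma_ev_dna
            elif kd == "dh":
                kind[a:b] = 7
                pa[a:b] = COULOMB_K * self._qq[n_elec_seen:n_elec_seen + b - a] \
                    / par.dielectric
                n_elec_seen += b - a
        self._kind, self._pa, self._pb, self._pc = kind, pa, pb, pc

        # fused angles: E = c (theta - theta0)^2 with c = k (protein) or k/2
        p = self.params
        ang = [a for a in (t.angles_pro, t.angles_dna) if len(a)]
        if ang:
            self._angles = np.ascontiguousarray(np.vstack(ang), np.int64)
            self._angles_t0 = np.concatenate(
                [a for a in (t.angles_pro_t0, t.angles_dna_t0) if len(a)])
            self._angles_c = np.concatenate(
                [np.full(len(t.angles_pro), p.k_angle_pro),
                 np.full(len(t.angles_dna), 0.5 * p.k_angle_dna)])
            self._angles_split = len(t.angles_pro)
        else:
            self._angles = np.empty((0, 3), int)
        dih = [d for d in (t.dihedrals_pro, t.dihedrals_dna) if len(d)]
        if dih:
            self._dihedrals = np.ascontiguousarray(np.vstack(dih), np.int64)
            self._dihedrals_p0 = np.concatenate(
                [d for d in (t.dihedrals_pro_p0, t.dihedrals_dna_p0) if len(d)])
            self._n_dih_pro = len(t.dihedrals_pro)
            n_dna = len(self._dihedrals) - self._n_dih_pro
            self._dih_k1 = np.concatenate([np.full(self._n_dih_pro, p.k_dih1_pro),
                                           np.full(n_dna, p.k_dih_dna)])
            self._dih_k3 = np.concatenate([np.full(self._n_dih_pro, p.k_dih3_pro),
                                           np.zeros(n_dna)])
        else:
            self._dihedrals = np.empty((0, 4), np.int64)

    def _fused_pair_eval(self, coords: np.ndarray, terms: dict, forces: np.ndarray):
        t, p = self.topology, self.params
        rij = coords[self._pi] - coords[self._pj]
        r = np.sqrt(np.einsum("ij,ij->i", rij, rij))
        if np.any(r < 1e-6):
            raise OverlapError("overlapping beads in pair lists")
        dedr = np.zeros_like(r)
        lam = p.debye_length
        dh_cut = p.cutoff_debye_multiple * lam
        n_elec_seen = 0
        for key, a, b, kind in self._blocks:
            rs = r[a:b]
            if kind == "bond_pro":
                d = rs - t.bonds_pro_r0
                e = p.k_bond_pro * d * d
                de = 2.0 * p.k_bond_pro * d
            elif kind == "bond_dna":
                d = rs - t.bonds_dna_r0
                e = p.k_bond2_dna * d ** 2 + p.k_bond4_dna * d ** 4
                de = 2.0 * p.k_bond2_dna * d + 4.0 * p.k_bond4_dna * d ** 3
            elif kind == "go_pro":
                e, de = _go_12_10(rs, t.contacts_pro_r0, p.eps_go_pro)
            elif kind == "go_prodna":
                e, de = _go_12_10(rs, t.contacts_prodna_r0, p.eps_go_prodna)
            elif kind == "lj":
                e, de = _lj_12_6(rs, t.stacks_r0, p.eps_stack)
            elif kind == "bp":
                s12 = (self.bp_sigma / rs) ** 12
                s10 = (self.bp_sigma / rs) ** 10
                e = self.bp_eps * (5.0 * s12 - 6.0 * s10)
                de = -60.0 * self.bp_eps * (s12 - s10) / rs
            elif kind == "solv":
                e, de = _solvation(rs, p.eps_solv, p.alpha_solv, p.r_solv)
            elif kind == "rep_pro":
                e, de = _repulsive_12(rs, p.sigma_ev_pro, p.eps_ev_pro,
                                      p.ev_cutoff_factor_pro * p.sigma_ev_pro)
            elif kind == "wca":
                e, de = _wca(rs, p.sigma_ev_dna, p.eps_ev_dna)
            elif kind == "rep_prodna":
                e, de = _repulsive_12(rs, p.sigma_ev_prodna, p.eps_ev_prodna,
                                      p.ev_cutoff_factor_prodna * p.sigma_ev_prodna)
            elif kind == "dh":
                qq = self._qq[n_elec_seen:n_elec_seen + (b - a)]
                n_elec_seen += b - a
                e, de = _debye_huckel(rs, qq, p.dielectric, lam, dh_cut)
            else:                                   # pragma: no cover
                raise AssertionError(kind)
            terms[key] = float(e.sum())
            dedr[a:b] = de
        f = (-dedr / r)[:, None] * rij
        _accumulate(forces, self._pi, f)
        _accumulate(forces, self._pj, -f)

    def energy_forces(self, coords: np.ndarray,
                      select: set[str] | None = None) -> EnergyReport:
        """Energies and forces; ``select`` restricts to a subset of terms
        (pair exclusions always reflect the full topology)."""
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_beads, 3):
            raise ValueError(f"coords shape {coords.shape} != ({self.n_beads}, 3)")
        p = self.params
        t = self.topology
        if select is None:
            return self._energy_forces_fused(coords)
        if not np.all(np.isfinite(coords)):
            raise FloatingPointError("non-finite coordinates")
        sel = set(select)
        terms = {k: 0.0 for k in _TERM_KEYS if k in sel}
        forces = np.zeros_like(coords)

        # --- bonded: protein -----------------------------------------
        if "pro_bond" in sel and len(t.bonds_pro):
            rij, r = _pair_geometry(coords, t.bonds_pro, "protein bond")
            d = r - t.bonds_pro_r0
            terms["pro_bond"] = float(np.sum(p.k_bond_pro * d * d))
            _scatter_pair_forces(forces, t.bonds_pro, rij, r, 2.0 * p.k_bond_pro * d)
        if "pro_angle" in sel and len(t.angles_pro):
            t0 = t.angles_pro_t0
            terms["pro_angle"] = _sum(_angle_term(
                coords, t.angles_pro, t0, forces,
                lambda th: (p.k_angle_pro * (th - t0) ** 2,
                            2.0 * p.k_angle_pro * (th - t0))))
        if "pro_dihedral" in sel and len(t.dihedrals_pro):
            p0 = t.dihedrals_pro_p0
            terms["pro_dihedral"] = _sum(_dihedral_term(
                coords, t.dihedrals_pro, forces,
                lambda ph: (p.k_dih1_pro * (1.0 - np.cos(ph - p0))
                            + p.k_dih3_pro * (1.0 - np.cos(3.0 * (ph - p0))),
                            p.k_dih1_pro * np.sin(ph - p0)
                            + 3.0 * p.k_dih3_pro * np.sin(3.0 * (ph - p0)))))

        # --- bonded: DNA ---------------------------------------------
        if "dna_bond" in sel and len(t.bonds_dna):
            rij, r = _pair_geometry(coords, t.bonds_dna, "DNA bond")
            d = r - t.bonds_dna_r0
            terms["dna_bond"] = float(np.sum(p.k_bond2_dna * d ** 2
                                             + p.k_bond4_dna * d ** 4))
            _scatter_pair_forces(forces, t.bonds_dna, rij, r,
                                 2.0 * p.k_bond2_dna * d + 4.0 * p.k_bond4_dna * d ** 3)
        if "dna_angle" in sel and len(t.angles_dna):
            t0 = t.angles_dna_t0
            terms["dna_angle"] = _sum(_angle_term(
                coords, t.angles_dna, t0, forces,
                lambda th: (0.5 * p.k_angle_dna * (th - t0) ** 2,
                            p.k_angle_dna * (th - t0))))
        if "dna_dihedral" in sel and len(t.dihedrals_dna):
            p0 = t.dihedrals_dna_p0
            terms["dna_dihedral"] = _sum(_dihedral_term(
                coords, t.dihedrals_dna, forces,
                lambda ph: (p.k_dih_dna * (1.0 - np.cos(ph - p0)),
                            p.k_dih_dna * np.sin(ph - p0))))

        # --- attractive non-bonded -----------------------------------
        if "pro_contact" in sel and len(t.contacts_pro):
            rij, r = _pair_geometry(coords, t.contacts_pro, "protein contact")
            e, dedr = _go_12_10(r, t.contacts_pro_r0, p.eps_go_pro)
            terms["pro_contact"] = float(e.sum())
            _scatter_pair_forces(forces, t.contacts_pro, rij, r, dedr)
        if "prodna_contact" in sel and len(t.contacts_prodna):
            rij, r = _pair_geometry(coords, t.contacts_prodna, "protein-DNA contact")
            e, dedr = _go_12_10(r, t.contacts_prodna_r0, p.eps_go_prodna)
            terms["prodna_contact"] = float(e.sum())
            _scatter_pair_forces(forces, t.contacts_prodna, rij, r, dedr)
        if "dna_stack" in sel and len(t.stacks):
            rij, r = _pair_geometry(coords, t.stacks, "stack")
            e, dedr = _lj_12_6(r, t.stacks_r0, p.eps_stack)
            terms["dna_stack"] = float(e.sum())
            _scatter_pair_forces(forces, t.stacks, rij, r, dedr)
        if "dna_bp" in sel and len(t.basepairs):
            rij, r = _pair_geometry(coords, t.basepairs, "base pair")
            s12 = (self.bp_sigma / r) ** 12
            s10 = (self.bp_sigma / r) ** 10
            e = self.bp_eps * (5.0 * s12 - 6.0 * s10)
            dedr = -60.0 * self.bp_eps * (s12 - s10) / r
            terms["dna_bp"] = float(e.sum())
            _scatter_pair_forces(forces, t.basepairs, rij, r, dedr)
        if "dna_solv" in sel and len(t.solv_pairs):
            rij, r = _pair_geometry(coords, t.solv_pairs, "solvation")
            e, dedr = _solvation(r, p.eps_solv, p.alpha_solv, p.r_solv)
            terms["dna_solv"] = float(e.sum())
            _scatter_pair_forces(forces, t.solv_pairs, rij, r, dedr)

        # --- excluded volume -----------------------------------------
        if "pro_ev" in sel and len(self.ev_pro):
            rij, r = _pair_geometry(coords, self.ev_pro, "protein EV")
            e, dedr = _repulsive_12(r, p.sigma_ev_pro, p.eps_ev_pro,
                                    p.ev_cutoff_factor_pro * p.sigma_ev_pro)
            terms["pro_ev"] = float(e.sum())
            _scatter_pair_forces(forces, self.ev_pro, rij, r, dedr)
        if "dna_ev" in sel and len(self.ev_dna):
            rij, r = _pair_geometry(coords, self.ev_dna, "DNA EV")
            e, dedr = _wca(r, p.sigma_ev_dna, p.eps_ev_dna)
            terms["dna_ev"] = float(e.sum())
            _scatter_pair_forces(forces, self.ev_dna, rij, r, dedr)
        if "prodna_ev" in sel and len(self.ev_prodna):
            rij, r = _pair_geometry(coords, self.ev_prodna, "protein-DNA EV")
            e, dedr = _repulsive_12(r, p.sigma_ev_prodna, p.eps_ev_prodna,
                                    p.ev_cutoff_factor_prodna * p.sigma_ev_prodna)
            terms["prodna_ev"] = float(e.sum())
            _scatter_pair_forces(forces, self.ev_prodna, rij, r, dedr)

        # --- electrostatics ------------------------------------------
        lam = p.debye_length
        cutoff = p.cutoff_debye_multiple * lam
        for key, tab in self.elec.items():
            if key not in sel or not len(tab.pairs):
                continue
            rij, r = _pair_geometry(coords, tab.pairs, key)
            e, dedr = _debye_huckel(r, tab.qq, p.dielectric, lam, cutoff)
            terms[key] = float(e.sum())
            _scatter_pair_forces(forces, tab.pairs, rij, r, dedr)

        return EnergyReport(terms, forces)

    def _energy_forces_fused(self, coords: np.ndarray) -> EnergyReport:
        if not np.all(np.isfinite(coords)):
            raise FloatingPointError("non-finite coordinates")
        if _kernels.HAVE_NUMBA:
            return self._energy_forces_jit(coords)
        p = self.params
        terms = {k: 0.0 for k in _TERM_KEYS}
        forces = np.zeros_like(coords)
        if len(self._pi):
            self._fused_pair_eval(coords, terms, forces)
        if len(self._angles):
            t0, c = self._angles_t0, self._angles_c

            def de_angle(th):
                d = th - t0
                return c * d * d, 2.0 * c * d

            e = _angle_term(coords, self._angles, t0, forces, de_angle)
            ns = self._angles_split
            terms["pro_angle"] = float(e[:ns].sum())
            terms["dna_angle"] = float(e[ns:].sum())
        if len(self._dihedrals):
            p0, npro = self._dihedrals_p0, self._n_dih_pro

            def de_dih(ph):
                d = ph - p0
                e = np.empty_like(d)
                de = np.empty_like(d)
                dp = d[:npro]
                e[:npro] = (p.k_dih1_pro * (1.0 - np.cos(dp))
                            + p.k_dih3_pro * (1.0 - np.cos(3.0 * dp)))
                de[:npro] = (p.k_dih1_pro * np.sin(dp)
                             + 3.0 * p.k_dih3_pro * np.sin(3.0 * dp))
                dd = d[npro:]
                e[npro:] = p.k_dih_dna * (1.0 - np.cos(dd))
                de[npro:] = p.k_dih_dna * np.sin(dd)
                return e, de

            e = _dihedral_term(coords, self._dihedrals, forces, de_dih)
            terms["pro_dihedral"] = float(e[:npro].sum())
            terms["dna_dihedral"] = float(e[npro:].sum())
        return EnergyReport(terms, forces)

    def _energy_forces_jit(self, coords: np.ndarray) -> EnergyReport:
        """Same sums as the numpy path, via the compiled kernels."""
        p = self.params
        terms = {k: 0.0 for k in _TERM_KEYS}
        forces = np.zeros_like(coords)
        if len(self._pi):
            lam = p.debye_length
            e_pair = np.zeros(len(self._pi))
            bad = _kernels.pair_kernel(coords, self._pi, self._pj, self._kind,
                                       self._pa, self._pb, self._pc, lam,
                                       p.cutoff_debye_multiple * lam,
                                       forces, e_pair)
            if bad >= 0:
                raise OverlapError(
                    f"overlapping beads {self._pi[bad]}-{self._pj[bad]}")
            for key, a, b, _ in self._blocks:
                terms[key] = float(e_pair[a:b].sum())
        if len(self._angles):
            e = np.zeros(len(self._angles))
            _kernels.angle_kernel(coords, self._angles, self._angles_t0,
                                  self._angles_c, forces, e)
            ns = self._angles_split
            terms["pro_angle"] = float(e[:ns].sum())
            terms["dna_angle"] = float(e[ns:].sum())
        if len(self._dihedrals):
            npro = self._n_dih_pro
            e = np.zeros(len(self._dihedrals))
            _kernels.dihedral_kernel(coords, self._dihedrals, self._dihedrals_p0,
                                     self._dih_k1, self._dih_k3, forces, e)
            terms["pro_dihedral"] = float(e[:npro].sum())
            terms["dna_dihedral"] = float(e[npro:].sum())
        return EnergyReport(terms, forces)

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_forces(coords).forces

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords).total


# ----------------------------------------------------------------------
# spec-level operations (thin wrappers selecting term groups)
# ----------------------------------------------------------------------

_GROUPS = {
    "protein_bonded": ("pro_bond", "pro_angle", "pro_dihedral"),
    "protein_contacts": ("pro_contact",),
    "protein_excluded_volume": ("pro_ev",),
    "dna_bonded": ("dna_bond", "dna_angle", "dna_dihedral"),
    "dna_stack_and_basepair": ("dna_stack", "dna_bp"),
    "dna_excluded_volume": ("dna_ev",),
    "dna_solvation": ("dna_solv",),
    "debye_huckel": ("elec_pro", "elec_dna", "elec_prodna"),
    "prodna_terms": ("prodna_contact", "prodna_ev", "elec_prodna"),
}


def _make_fragment_op(name: str):
    keys = _GROUPS[name]

    def op(coords, topology, params) -> EnergyReport:
        """Evaluate one group of energy terms with its analytic forces."""
        ff = ForceField(topology, params)
        return ff.energy_forces(np.asarray(coords, float), select=set(keys))

    op.__name__ = name
    return op


protein_bonded = _make_fragment_op("protein_bonded")
protein_contacts = _make_fragment_op("protein_contacts")
protein_excluded_volume = _make_fragment_op("protein_excluded_volume")
dna_bonded = _make_fragment_op("dna_bonded")
dna_stack_and_basepair = _make_fragment_op("dna_stack_and_basepair")
dna_excluded_volume = _make_fragment_op("dna_excluded_volume")
dna_solvation = _make_fragment_op("dna_solvation")
debye_huckel = _make_fragment_op("debye_huckel")
prodna_terms = _make_fragment_op("prodna_terms")


def total_energy_forces(coords, topology, params) -> EnergyReport:
    """Evaluate every term of V_total with analytic forces."""
    return ForceField(topology, params).energy_forces(np.asarray(coords, float))


def check_forces(coords, topology, params, h: float = 1e-5,
                 forcefield: ForceField | None = None,
                 select: set[str] | None = None) -> float:
    """Validate analytic forces against central differences of the energy.

    ``select`` restricts the check to a term subset (each term can be
    validated independently). Returns the maximum deviation relative to the
    overall force scale (max(1, max |F_numeric|)).
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    ff = forcefield or ForceField(topology, params)
    coords = np.asarray(coords, float)
    analytic = ff.energy_forces(coords, select=select).forces
    numeric = np.zeros_like(analytic)
    x = coords.copy()
    for i in range(coords.shape[0]):
        for d in range(3):
            x[i, d] = coords[i, d] + h
            ep = ff.energy_forces(x, select=select).total
            x[i, d] = coords[i, d] - h
            em = ff.energy_forces(x, select=select).total
            x[i, d] = coords[i, d]
            numeric[i, d] = -(ep - em) / (2.0 * h)
    scale = max(1.0, float(np.abs(numeric).max()))
    return float(np.abs(analytic - numeric).max() / scale)
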