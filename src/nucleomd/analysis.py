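"""Trajectory observables: unwrapping order parameters, free-energy
profiles, histone-tail geometry, deviation/correlation maps, B-factors and
force-distance profiles.

The unwrapping order parameter follows the reference-deviation rule: after
superposing each frame onto the reference structure on the histone-core
(non-tail) protein beads, the per-base-pair deviation d_DX is the distance
of the base-pair representative point from its reference position. The
n-bp unwrapped state requires base pairs 1..n (counted from a duplex end)
to deviate by more than 10 A while base pair n+1 does not.

Free-energy profiles use F(bp) = -ln(N p(bp) + 1) with N the pooled sample
count, so unsampled end positions sit exactly at F = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .topology import CGTopology

UNWRAP_THRESHOLD = 10.0     # A


# ----------------------------------------------------------------------
# superposition
# ----------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: np.ndarray) -> np.ndarray:
    """Best-fit (Kabsch) superposition of ``mobile`` onto ``reference``
    using the given fit set; returns transformed copy of all coordinates."""
    mob = mobile[fit_indices]
    ref = reference[fit_indices]
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    return rot.apply(mobile - mc) + rc


def core_fit_indices(topology: CGTopology) -> np.ndarray:
    """Histone-core bead set used for superposition (protein, tails
    excluded); falls back to all beads for pure-DNA systems."""
    idx = np.nonzero(topology.is_protein & ~topology.tail)[0]
    if len(idx) >= 3:
        return idx
    return np.arange(topology.n_beads)


# ----------------------------------------------------------------------
# unwrapping order parameters
# ----------------------------------------------------------------------

def basepair_points(topology: CGTopology, coords: np.ndarray) -> np.ndarray:
    """Representative point per base pair: centroid of all beads of the two
    paired nucleotides, ordered 1..n_bp from the left end."""
    pts = np.empty((len(topology.basepairs), 3))
    for n, (i, j) in enumerate(topology.basepairs):
        sel = []
        for b in (int(i), int(j)):
            m = (topology.chain_id == topology.chain_id[b]) & \
                (topology.residue_index == topology.residue_index[b])
            sel.append(np.nonzero(m)[0])
        pts[n] = coords[np.concatenate(sel)].mean(axis=0)
    return pts


@dataclass
class _BPIndex:
    """Cached per-nucleotide bead groups for fast d_DX evaluation."""

    groups: list[np.ndarray]

    @classmethod
    def build(cls, topology: CGTopology) -> "_BPIndex":
        groups = []
        for i, j in topology.basepairs:
            sel = []
            for b in (int(i), int(j)):
                m = (topology.chain_id == topology.chain_id[b]) & \
                    (topology.residue_index == topology.residue_index[b])
                sel.append(np.nonzero(m)[0])
            groups.append(np.concatenate(sel))
        return cls(groups)

    def points(self, coords: np.ndarray) -> np.ndarray:
        return np.stack([coords[g].mean(axis=0) for g in self.groups])


def bp_deviation(frame: np.ndarray, reference: np.ndarray,
                 topology: CGTopology,
                 fit_indices: np.ndarray | None = None,
                 _cache: _BPIndex | None = None) -> np.ndarray:
    """d_DX per base pair after core superposition (A)."""
    if frame.shape != reference.shape:
        raise ValueError("frame and reference shapes differ (topology mismatch)")
    if fit_indices is None:
        fit_indices = core_fit_indices(topology)
    bpi = _cache or _BPIndex.build(topology)
    moved = superpose(frame, reference, fit_indices)
    return np.linalg.norm(bpi.points(moved) - bpi.points(reference), axis=1)


def unwrapped_ends(d_dx: np.ndarray,
                   threshold: float = UNWRAP_THRESHOLD) -> tuple[int, int]:
    """(n_left, n_right) from the contiguous-from-end deviation rule.

    n_left is the largest n with d_DX(1..n) all above the threshold and
    d_DX(n+1) not above it; 0 when base pair 1 is below threshold. The
    right end is symmetric. For an all-above array the two ends split the
    duplex (each end claims its half, left taking the extra on odd counts).
    """
    above = np.asarray(d_dx) > threshold
    n = len(above)
    n_left = 0
    while n_left < n and above[n_left]:
        n_left += 1
    n_right = 0
    while n_right < n and above[n - 1 - n_right]:
        n_right += 1
    if n_left + n_right > n:        # fully unwrapped: split the duplex
        n_left = (n + 1) // 2
        n_right = n - n_left
    return n_left, n_right


def unwrap_series(trajectories, topology: CGTopology,
                  reference: np.ndarray | None = None,
                  threshold: float = UNWRAP_THRESHOLD,
                  discard_fraction: float = 0.0):
    """Per-frame (n_left, n_right) pooled over trajectories.

    ``discard_fraction`` drops the leading fraction of each trajectory
    (equilibration) before pooling; failed/empty replicas contribute
    nothing. Returns an integer array of shape (total_frames, 2).
    """
    if reference is None:
        reference = topology.ref_coords
    fit = core_fit_indices(topology)
    bpi = _BPIndex.build(topology)
    out = []
    for traj in np.atleast_1d(trajectories):
        start = int(discard_fraction * traj.n_frames)
        for frame in traj.coords[start:]:
            d = bp_deviation(frame, reference, topology, fit, bpi)
            out.append(unwrapped_ends(d, threshold))
    return np.asarray(out, int).reshape(-1, 2)


# ----------------------------------------------------------------------
# free-energy profiles
# ----------------------------------------------------------------------

def free_energy_profile(end_positions: np.ndarray, n_bp: int) -> np.ndarray:
    """F(bp) = -ln(N p(bp) + 1) over integer bins 0..n_bp.

    ``end_positions`` are per-frame unwrapped counts for one duplex end;
    N is the pooled sample number. Unsampled positions give exactly 0.
    """
    end_positions = np.asarray(end_positions, int)
    if end_positions.size == 0:
        raise ValueError("empty sample set")
    counts = np.bincount(end_positions, minlength=n_bp + 1).astype(float)
    n = float(end_positions.size)
    p = counts / n
    return -np.log(n * p + 1.0)


@dataclass
class UnwrapProfile:
    """Unwrapping statistics of one simulation condition."""

    ends: np.ndarray                  # (frames, 2) n_left, n_right
    n_bp: int
    salt_mM: float | None = None
    label: str = ""

    @property
    def sample_number(self) -> int:
        return len(self.ends)

    def histogram(self, side: str = "left") -> np.ndarray:
        col = 0 if side == "left" else 1
        return np.bincount(self.ends[:, col], minlength=self.n_bp + 1)

    def free_energy(self, side: str = "left") -> np.ndarray:
        col = 0 if side == "left" else 1
        return free_energy_profile(self.ends[:, col], self.n_bp)

    def mean_unwrapped(self) -> float:
        return float(self.ends.mean())

    def fraction_fully_wrapped(self) -> float:
        return float(np.mean(np.all(self.ends == 0, axis=1)))

    def modal_state(self, side: str = "left") -> int:
        return int(np.argmax(self.histogram(side)))


def end_independence(ends: np.ndarray) -> dict[str, np.ndarray]:
    """Observed P(both i-th bp unwrapped) vs the independence expectation.

    For each depth i (1-based), compares the joint probability that base
    pair i from the left and base pair i from the right are both unwrapped
    with the product of the marginals.
    """
    ends = np.asarray(ends, int)
    n_max = int(ends.max()) if ends.size else 0
    depths = np.arange(1, max(n_max, 1) + 1)
    left_u = ends[:, 0][:, None] >= depths[None, :]
    right_u = ends[:, 1][:, None] >= depths[None, :]
    p_left = left_u.mean(axis=0)
    p_right = right_u.mean(axis=0)
    p_both = (left_u & right_u).mean(axis=0)
    expected = p_left * p_right
    return {"depth": depths, "p_both": p_both, "p_expected": expected,
            "max_abs_difference": np.array([np.abs(p_both - expected).max()])}


# ----------------------------------------------------------------------
# histone-tail geometry and correlation
# ----------------------------------------------------------------------

def tail_terminal_indices(topology: CGTopology) -> dict[str, int]:
    """First resolved N-terminal bead of each tail, keyed by chain id."""
    out: dict[str, int] = {}
    for cid in topology.protein_chains():
        m = (topology.chain_id == cid) & topology.tail
        idx = np.nonzero(m)[0]
        if len(idx):
            first = idx[np.argmin(topology.residue_index[idx])]
            out[cid] = int(first)
    return out


def tail_distances(frames: np.ndarray, topology: CGTopology) -> dict[str, np.ndarray]:
    """r_HTO per frame per tail: distance of the tail terminal bead from
    the centre of mass of the histone core (non-tail protein beads)."""
    core = np.nonzero(topology.is_protein & ~topology.tail)[0]
    if not len(core):
        raise ValueError("no histone-core beads present")
    terms = tail_terminal_indices(topology)
    if not terms:
        raise ValueError("no tail beads flagged in this topology")
    w = topology.mass[core]
    frames = np.asarray(frames).reshape(-1, topology.n_beads, 3)
    com = (frames[:, core] * w[None, :, None]).sum(axis=1) / w.sum()
    return {cid: np.linalg.norm(frames[:, i] - com, axis=1)
            for cid, i in terms.items()}


def residue_deviation(frames: np.ndarray, reference: np.ndarray,
                      topology: CGTopology) -> np.ndarray:
    """d_HX: per-frame deviation of every protein bead from the reference
    after core superposition; shape (frames, n_protein_beads)."""
    fit = core_fit_indices(topology)
    pro = np.nonzero(topology.is_protein)[0]
    frames = np.asarray(frames).reshape(-1, topology.n_beads, 3)
    out = np.empty((len(frames), len(pro)))
    for f, frame in enumerate(frames):
        moved = superpose(frame, reference, fit)
        out[f] = np.linalg.norm(moved[pro] - reference[pro], axis=1)
    return out


def pearson_with_flag(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation; zero-variance input returns (0.0, flagged)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def residue_deviation_correlation(frames: np.ndarray, reference: np.ndarray,
                                  topology: CGTopology,
                                  n_left: np.ndarray) -> dict[str, np.ndarray]:
    """Per-residue Pearson correlation between d_HX and the left-end
    unwrapped base-pair count across frames."""
    d_hx = residue_deviation(frames, reference, topology)
    n_res = d_hx.shape[1]
    corr = np.zeros(n_res)
    flags = np.zeros(n_res, bool)
    for r in range(n_res):
        corr[r], flags[r] = pearson_with_flag(d_hx[:, r], n_left)
    pro = np.nonzero(topology.is_protein)[0]
    return {"protein_beads": pro, "mean_d_hx": d_hx.mean(axis=0),
            "correlation": corr, "zero_variance": flags}


# ----------------------------------------------------------------------
# fluctuations / B-factors
# ----------------------------------------------------------------------

def rmsf_bfactor(frames: np.ndarray, reference: np.ndarray,
                 topology: CGTopology,
                 experimental_b: np.ndarray | None = None,
                 b_exclude_above: float = 300.0) -> dict[str, np.ndarray | float]:
    """Per-bead RMSF about the mean structure and B = (8 pi^2 / 3) RMSF^2.

    If experimental B-factors are supplied, returns their Pearson
    correlation with the computed values, excluding beads whose computed B
    exceeds ``b_exclude_above`` and tail beads (disordered in the crystal).
    """
    fit = core_fit_indices(topology)
    frames = np.asarray(frames).reshape(-1, topology.n_beads, 3)
    moved = np.stack([superpose(f, reference, fit) for f in frames])
    mean = moved.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((moved - mean) ** 2, axis=2), axis=0))
    b = (8.0 * np.pi ** 2 / 3.0) * rmsf ** 2
    out: dict[str, np.ndarray | float] = {"rmsf": rmsf, "bfactor": b}
    if experimental_b is not None:
        experimental_b = np.asarray(experimental_b, float)
        keep = (b <= b_exclude_above) & ~topology.tail
        r, flagged = pearson_with_flag(b[keep], experimental_b[keep])
        out["pearson_r"] = r if not flagged else 0.0
        out["n_compared"] = int(keep.sum())
    return out


# ----------------------------------------------------------------------
# pulling profiles
# ----------------------------------------------------------------------

@dataclass
class ForceProfile:
    """Binned force-distance curves from constant-velocity pulling."""

    bin_edges: np.ndarray
    per_trajectory: list[np.ndarray] = field(default_factory=list)
    mean_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak(self) -> tuple[float, float]:
        """(peak force pN, distance A), over bins with data."""
        valid = ~np.isnan(self.mean_curve)
        if not valid.any():
            raise ValueError("no sampled bins")
        idx = np.nanargmax(self.mean_curve)
        return float(self.mean_curve[idx]), float(self.bin_centres[idx])


def force_distance_profile(trajectories, bin_width: float = 5.0) -> ForceProfile:
    """Bin per-frame pulling force against the pulling coordinate d and
    average across trajectories (bins without samples are NaN)."""
    trajectories = list(np.atleast_1d(trajectories))
    d_all = np.concatenate([t.observables["pull_distance"] for t in trajectories])
    lo = np.floor(d_all.min() / bin_width) * bin_width
    hi = np.ceil(d_all.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    curves = []
    for t in trajectories:
        d = t.observables["pull_distance"]
        f = t.observables["pull_force_pN"]
        idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
        sums = np.bincount(idx, weights=f, minlength=len(edges) - 1)
        cnts = np.bincount(idx, minlength=len(edges) - 1)
        with np.errstate(invalid="ignore"):
            curves.append(np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan))
    stack = np.stack(curves)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN bins
        mean = np.nanmean(stack, axis=0)
    return ForceProfile(edges, curves, mean)
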