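"""Observable calculations: order parameters, profiles, tails, B-factors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleomd.analysis import (bp_deviation,
                               end_independence, force_distance_profile,
                               free_energy_profile, pearson_with_flag,
                               residue_deviation_correlation, rmsf_bfactor,
                               superpose, tail_distances, unwrapped_ends)
from nucleomd.dynamics import Trajectory


def brute_force_unwrapped(d, threshold=10.0):
    """Independent oracle: scan all n for the largest prefix/suffix with
    every deviation above threshold and the next one below."""
    n = len(d)
    n_left = 0
    for k in range(n, 0, -1):
        if all(x > threshold for x in d[:k]) and (k == n or d[k] <= threshold):
            n_left = k
            break
    n_right = 0
    rev = d[::-1]
    for k in range(n, 0, -1):
        if all(x > threshold for x in rev[:k]) and (k == n or rev[k] <= threshold):
            n_right = k
            break
    if n_left + n_right > n:
        n_left = (n + 1) // 2
        n_right = n - n_left
    return n_left, n_right


class TestUnwrappedEnds:
    @pytest.mark.parametrize("d, expected", [
        ([12.0, 11.0, 3.0, 1.0], (2, 0)),
        ([1.0, 2.0, 3.0, 4.0], (0, 0)),
        ([12.0, 3.0, 12.0, 3.0], (1, 0)),
        ([3.0, 3.0, 11.0, 12.0], (0, 2)),
        ([11.0, 3.0, 3.0, 12.0], (1, 1)),
    ])
    def test_rule_examples(self, d, expected):
        assert unwrapped_ends(np.array(d)) == expected

    def test_idempotent_and_bounded(self, rng):
        d = rng.uniform(0, 20, 50)
        n_l, n_r = unwrapped_ends(d)
        assert unwrapped_ends(d) == (n_l, n_r)
        assert 0 <= n_l and 0 <= n_r and n_l + n_r <= 50

    def test_matches_brute_force_oracle(self):
        """Exact agreement with an independent exhaustive scan on 1000
        random deviation arrays."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(1, 40)
            d = rng.uniform(0, 20, n)
            assert unwrapped_ends(d) == brute_force_unwrapped(list(d))


class TestFreeEnergyProfile:
    def test_printed_formula_arithmetic(self):
        """N = 100 samples, half at one position: F = -ln(51) there."""
        ends = np.concatenate([np.zeros(50, int), np.full(50, 7, int)])
        f = free_energy_profile(ends, n_bp=10)
        assert f[7] == pytest.approx(-np.log(100 * 0.5 + 1))
        assert f[7] == pytest.approx(-3.9318, abs=1e-4)

    def test_unsampled_bins_exactly_zero(self):
        f = free_energy_profile(np.zeros(10, int), n_bp=5)
        assert np.all(f[1:] == 0.0)
        assert f[0] == pytest.approx(-np.log(11.0))

    def test_all_mass_one_bin(self):
        n = 37
        f = free_energy_profile(np.full(n, 3, int), n_bp=5)
        assert f[3] == pytest.approx(-np.log(n + 1))
        assert np.all(np.delete(f, 3) == 0.0)

    def test_order_reversing_in_probability(self, rng):
        ends = rng.integers(0, 5, 400)
        f = free_energy_profile(ends, n_bp=6)
        counts = np.bincount(ends, minlength=7)
        sampled = counts > 0
        order_p = np.argsort(counts[sampled])
        order_f = np.argsort(-f[sampled])
        assert np.array_equal(order_p, order_f)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            free_energy_profile(np.empty(0, int), n_bp=5)


class TestBpDeviation:
    def test_identity_frame(self, wrapped_arc, params):
        topo, coords = wrapped_arc
        d = bp_deviation(coords, coords, topo)
        assert np.abs(d).max() < 1e-9

    def test_rigid_motion_removed(self, wrapped_arc, params):
        topo, coords = wrapped_arc
        rot = Rotation.from_euler("xyz", [0.4, -0.2, 1.0])
        moved = rot.apply(coords) + np.array([25.0, -3.0, 8.0])
        d = bp_deviation(moved, coords, topo)
        assert np.abs(d).max() < 1e-6

    def test_displaced_terminal_bp(self, wrapped_arc, params):
        """Moving one terminal base pair by 15 A registers ~15 A there and
        nothing elsewhere (oracle: direct distance computation). The
        superposition fits on the protein core, so the DNA displacement is
        not absorbed into the fit."""
        topo, coords = wrapped_arc
        moved = coords.copy()
        i, j = topo.basepairs[0]
        group = []
        for b in (int(i), int(j)):
            m = (topo.chain_id == topo.chain_id[b]) & \
                (topo.residue_index == topo.residue_index[b])
            group.extend(np.nonzero(m)[0])
        moved[group] += np.array([0.0, 15.0, 0.0])
        d = bp_deviation(moved, coords, topo)
        assert d[0] == pytest.approx(15.0, abs=0.2)
        assert np.abs(d[2:]).max() < 1.5

    def test_topology_mismatch(self, duplex, wrapped_arc):
        topo, coords = duplex
        other, other_coords = wrapped_arc
        with pytest.raises(ValueError):
            bp_deviation(other_coords, coords, topo)


class TestEndIndependence:
    def test_independent_ends_agree(self):
        rng = np.random.default_rng(9)
        n = 20000
        ends = np.stack([rng.binomial(5, 0.3, n), rng.binomial(5, 0.3, n)],
                        axis=1)
        res = end_independence(ends)
        # binomial error at n = 20000 is ~0.01 at most depths
        assert res["max_abs_difference"][0] < 0.02

    def test_correlated_ends_detected(self):
        rng = np.random.default_rng(10)
        left = rng.binomial(5, 0.4, 5000)
        ends = np.stack([left, left], axis=1)       # perfectly correlated
        res = end_independence(ends)
        p = res["p_both"]
        exp = res["p_expected"]
        assert np.any(p - exp > 0.05)
        assert np.allclose(exp, p ** 2, atol=1e-12)

    def test_zero_unwrapping(self):
        res = end_independence(np.zeros((100, 2), int))
        assert np.all(res["p_both"] == 0.0)
        assert np.all(res["p_expected"] == 0.0)


class TestTailGeometry:
    def test_terminal_at_core_centre(self, wrapped_arc, params):
        topo, coords = wrapped_arc
        core = np.nonzero(topo.is_protein & ~topo.tail)[0]
        w = topo.mass[core]
        com = (coords[core] * w[:, None]).sum(axis=0) / w.sum()
        frame = coords.copy()
        from nucleomd.analysis import tail_terminal_indices
        terminals = tail_terminal_indices(topo)
        cid, idx = next(iter(terminals.items()))
        frame[idx] = com
        r = tail_distances(frame, topo)
        assert r[cid][0] == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self, wrapped_arc, params):
        topo, coords = wrapped_arc
        r0 = tail_distances(coords, topo)
        r1 = tail_distances(coords + np.array([10.0, 20.0, 30.0]), topo)
        for cid in r0:
            assert r1[cid] == pytest.approx(r0[cid], rel=1e-12)

    def test_synthetic_peak_at_35A(self, wrapped_arc, params, rng):
        """Frames built with the terminal held at 35 A from the core COM
        produce a distance distribution peaked at 35 A."""
        topo, coords = wrapped_arc
        from nucleomd.analysis import tail_terminal_indices
        core = np.nonzero(topo.is_protein & ~topo.tail)[0]
        w = topo.mass[core]
        com = (coords[core] * w[:, None]).sum(axis=0) / w.sum()
        cid, idx = next(iter(tail_terminal_indices(topo).items()))
        frames = np.repeat(coords[None], 200, axis=0)
        directions = rng.normal(size=(200, 3))
        directions /= np.linalg.norm(directions, axis=1)[:, None]
        frames[:, idx] = com + 35.0 * directions
        r = tail_distances(frames, topo)
        hist, edges = np.histogram(r[cid], bins=np.arange(0, 80, 5.0))
        assert edges[np.argmax(hist)] == 35.0


class TestCorrelation:
    def test_zero_variance_flagged(self):
        r, flag = pearson_with_flag(np.ones(10), np.arange(10))
        assert r == 0.0 and flag

    def test_linear_relation_perfect(self):
        x = np.arange(50.0)
        r, flag = pearson_with_flag(3.0 * x + 1.0, x)
        assert r == pytest.approx(1.0) and not flag

    def test_constructed_correlation_map(self, wrapped_arc, params, rng):
        """d_HX built as a.n_left + noise recovers high correlation for the
        moved bead and ~0 for independent beads."""
        topo, coords = wrapped_arc
        n_frames = 120
        n_left = rng.integers(0, 10, n_frames)
        frames = np.repeat(coords[None], n_frames, axis=0)
        pro = np.nonzero(topo.is_protein)[0]
        target = pro[5]
        frames[:, target, 0] += 2.0 * n_left + rng.normal(0, 0.05, n_frames)
        other = pro[40]
        frames[:, other, 1] += rng.normal(0, 2.0, n_frames)
        res = residue_deviation_correlation(frames, coords, topo, n_left)
        i_target = np.nonzero(res["protein_beads"] == target)[0][0]
        i_other = np.nonzero(res["protein_beads"] == other)[0][0]
        assert res["correlation"][i_target] > 0.95
        assert abs(res["correlation"][i_other]) < 0.35


class TestRmsfBfactor:
    def test_identical_frames_zero(self, wrapped_arc, params):
        topo, coords = wrapped_arc
        frames = np.repeat(coords[None], 5, axis=0)
        res = rmsf_bfactor(frames, coords, topo)
        assert np.abs(res["rmsf"]).max() < 1e-9
        assert np.abs(res["bfactor"]).max() < 1e-9

    def test_uniform_oscillation_closed_form(self, wrapped_arc, params):
        """A bead oscillating with amplitude giving <dx^2> = a^2 has
        B = (8 pi^2 / 3) a^2; the core-fit superposition leaves the moving
        DNA bead untouched."""
        topo, coords = wrapped_arc
        a = 1.7
        phases = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        frames = np.repeat(coords[None], 400, axis=0)
        bead = int(np.nonzero(topo.is_dna)[0][0])
        frames[:, bead, 0] += a * np.sqrt(2) * np.sin(phases)
        res = rmsf_bfactor(frames, coords, topo)
        expected_b = (8 * np.pi ** 2 / 3) * (a ** 2)
        assert res["bfactor"][bead] == pytest.approx(expected_b, rel=0.02)

    def test_exclusion_rule(self, duplex, params, rng):
        topo, coords = duplex
        frames = coords[None] + rng.normal(0, 0.3, (50, topo.n_beads, 3))
        frames[:, 3] += rng.normal(0, 12.0, (50, 3))   # huge B for bead 3
        exp_b = rng.uniform(5, 50, topo.n_beads)
        res = rmsf_bfactor(frames, coords, topo, experimental_b=exp_b)
        assert res["bfactor"][3] > 300.0
        assert res["n_compared"] < topo.n_beads


class TestForceDistanceProfile:
    @staticmethod
    def _traj(d, f):
        return Trajectory(np.arange(1.0, len(d) + 1),
                          np.zeros((len(d), 1, 3)),
                          {"pull_distance": np.asarray(d),
                           "pull_force_pN": np.asarray(f)})

    def test_single_trajectory_mean_is_itself(self):
        d = np.linspace(0, 100, 200)
        f = np.sin(d / 10.0)
        prof = force_distance_profile([self._traj(d, f)], bin_width=5.0)
        valid = ~np.isnan(prof.mean_curve)
        assert np.allclose(prof.mean_curve[valid],
                           np.asarray(prof.per_trajectory[0])[valid])

    def test_gaussian_bump_peak_detection(self):
        d = np.linspace(0, 200, 500)
        f = 25.0 * np.exp(-((d - 80.0) ** 2) / (2 * 8.0 ** 2))
        prof = force_distance_profile([self._traj(d, f)], bin_width=5.0)
        peak_f, peak_d = prof.peak()
        assert abs(peak_d - 80.0) <= 5.0
        assert peak_f == pytest.approx(25.0, rel=0.1)

    def test_opposite_noise_cancels(self, rng):
        d = np.linspace(0, 100, 300)
        base = 10.0 + d / 10.0
        noise = rng.normal(0, 3.0, 300)
        prof = force_distance_profile(
            [self._traj(d, base + noise), self._traj(d, base - noise)],
            bin_width=5.0)
        valid = ~np.isnan(prof.mean_curve)
        binned_base = force_distance_profile(
            [self._traj(d, base)], bin_width=5.0).mean_curve
        assert np.allclose(prof.mean_curve[valid], binned_base[valid],
                           atol=1e-9)


class TestSuperpose:
    def test_exact_recovery(self, rng):
        ref = rng.normal(0, 5, (30, 3))
        rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.7])
        moved = rot.apply(ref) + np.array([3.0, 4.0, 5.0])
        back = superpose(moved, ref, np.arange(30))
        assert np.abs(back - ref).max() < 1e-9


class TestPlotting:
    def test_figures_render(self, rng, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from nucleomd.analysis import ForceProfile, UnwrapProfile
        from nucleomd.plotting import (plot_force_distance, plot_free_energy,
                                       plot_tail_distances)
        prof = UnwrapProfile(rng.integers(0, 5, (50, 2)), 10, salt_mM=100)
        ax = plot_free_energy([prof])
        assert ax.get_ylabel()
        fp = ForceProfile(np.arange(0, 50, 5.0), [np.arange(9.0)], np.arange(9.0))
        plot_force_distance(fp)
        plot_tail_distances({"A": rng.normal(40, 5, 100)})
        fig = ax.get_figure()
        fig.savefig(tmp_path / "fe.png")
        assert (tmp_path / "fe.png").stat().st_size > 0


class TestOrderParameterProperty:
    def test_hypothesis_oracle_equivalence(self):
        """Property test: the contiguous-from-end rule equals the
        exhaustive scan for arbitrary deviation arrays."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(st.lists(st.floats(min_value=0.0, max_value=25.0,
                                  allow_nan=False), min_size=1, max_size=60))
        def check(d):
            arr = np.asarray(d)
            assert unwrapped_ends(arr) == brute_force_unwrapped(d)

        check()
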