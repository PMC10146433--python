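"""COW alignment: target selection, DP warping vs exhaustive enumeration,
parameter search and cube-level alignment."""

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from herbscreen import DataCube, WarpSpec, align_cube, cow_warp, optimize_warp_params, select_target_profile
from herbscreen.cowarp import _segment_bounds


def brute_force_cow(sample, target, spec):
    """Exhaustive enumeration over all admissible node paths; completely
    independent scoring (scipy pearsonr + np.interp)."""
    sample = np.asarray(sample, float)
    target = np.asarray(target, float)
    bounds = _segment_bounds(target.size, spec.segment_length)
    scale = (sample.size - 1) / (target.size - 1)
    prop = np.rint(bounds * scale).astype(int)
    n = bounds.size - 1
    s = spec.slack

    def seg_score(a, b, i):
        t0, t1 = bounds[i], bounds[i + 1]
        L = t1 - t0
        warped = np.interp(np.linspace(a, b, L + 1), np.arange(sample.size), sample)
        tseg = target[t0 : t1 + 1]
        if np.std(warped) == 0 or np.std(tseg) == 0:
            return 0.0
        return float(pearsonr(warped, tseg)[0])

    best_score, best_paths = -np.inf, []
    ranges = [range(-s * min(i, n - i), s * min(i, n - i) + 1) for i in range(1, n)]
    for devs in itertools.product(*ranges):
        devs = (0,) + devs + (0,)
        if any(abs(devs[i + 1] - devs[i]) > s for i in range(n)):
            continue
        nodes = [prop[i] + devs[i] for i in range(n + 1)]
        if any(nodes[i + 1] <= nodes[i] for i in range(n)):
            continue
        score = sum(seg_score(nodes[i], nodes[i + 1], i) for i in range(n))
        if score > best_score + 1e-12:
            best_score, best_paths = score, [tuple(nodes)]
        elif abs(score - best_score) <= 1e-12:
            best_paths.append(tuple(nodes))
    return best_score, best_paths


class TestTargetSelection:
    def test_duplicated_trace_wins(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = 0.4 * a + rng.normal(size=50)  # corr(a, b) well below 1
        assert select_target_profile([a, a, b]) == 0

    def test_two_trace_tie_returns_lowest_index(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert select_target_profile([a, b]) == 0

    def test_matches_bruteforce_mean_correlation(self):
        rng = np.random.default_rng(2)
        traces = rng.normal(size=(5, 40))
        table = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    table[i, j] = pearsonr(traces[i], traces[j])[0]
        expected = int(np.argmax(table.sum(axis=1) / 4))
        assert select_target_profile(traces) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            select_target_profile([np.zeros(10), np.zeros(11)])


class TestWarp:
    def test_identity_is_optimal_and_exact(self):
        rng = np.random.default_rng(3)
        trace = np.cumsum(rng.normal(size=120))
        res = cow_warp(trace, trace, WarpSpec(10, 2))
        n_seg = _segment_bounds(trace.size, 10).size - 1
        assert res.score == pytest.approx(n_seg, abs=1e-9)
        np.testing.assert_array_equal(res.warped, trace)

    def test_shifted_triangle_realigned_and_matches_enumeration(self):
        target = np.zeros(41)
        target[10:31] = 1 - np.abs(np.arange(-10, 11)) / 10
        sample = np.zeros(41)
        sample[12:33] = 1 - np.abs(np.arange(-10, 11)) / 10
        spec = WarpSpec(10, 2)
        res = cow_warp(sample, target, spec)
        assert int(np.argmax(res.warped)) == 20
        best_score, best_paths = brute_force_cow(sample, target, spec)
        assert res.score == pytest.approx(best_score, abs=1e-9)
        assert tuple(res.node_positions) in best_paths

    def test_constant_sample_scores_zero(self):
        rng = np.random.default_rng(4)
        target = rng.normal(size=60)
        res = cow_warp(np.full(60, 3.0), target, WarpSpec(10, 2))
        assert res.score == 0.0
        np.testing.assert_allclose(res.warped, 3.0)

    def test_dp_equals_exhaustive_on_random_instances(self):
        # small random instances, <= 5 segments, slack <= 2
        rng = np.random.default_rng(5)
        for trial in range(25):
            m = int(rng.integers(4, 9))
            n_seg = int(rng.integers(2, 6))
            length = m * n_seg + int(rng.integers(0, m))
            slack = int(rng.integers(1, 3))
            target = rng.normal(size=length).cumsum()
            sample = rng.normal(size=length).cumsum()
            spec = WarpSpec(m, slack)
            res = cow_warp(sample, target, spec)
            best_score, best_paths = brute_force_cow(sample, target, spec)
            assert res.score == pytest.approx(best_score, abs=1e-9), trial
            assert tuple(res.node_positions) in best_paths

    def test_nodes_monotone_and_length_preserved(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            length = int(rng.integers(50, 200))
            sample = rng.normal(size=length).cumsum()
            target = rng.normal(size=length).cumsum()
            res = cow_warp(sample, target, WarpSpec(12, 3))
            assert res.warped.size == length
            assert np.all(np.diff(res.node_positions) > 0)
            assert res.node_positions[0] == 0
            assert res.node_positions[-1] == length - 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            cow_warp(np.zeros(15), np.zeros(15), WarpSpec(10, 2))

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            WarpSpec(2, 1)
        with pytest.raises(ValueError):
            WarpSpec(10, 10)


class TestParameterSearch:
    def test_aligned_traces_hit_tie_rule(self):
        rng = np.random.default_rng(7)
        trace = rng.normal(size=100).cumsum()
        traces = np.tile(trace, (3, 1))
        spec = optimize_warp_params(traces, 0, segment_grid=(10, 20), slack_grid=(1, 2))
        assert (spec.segment_length, spec.slack) == (10, 1)

    def test_chosen_spec_dominates_unwarped(self):
        rng = np.random.default_rng(8)
        base = np.exp(-0.5 * ((np.arange(120) - 60) / 6.0) ** 2)
        traces = np.stack([np.roll(base, k) for k in (0, 3, 3)])
        spec = optimize_warp_params(traces, 0, segment_grid=(10, 20), slack_grid=(1, 2))
        warped_corr = np.mean(
            [pearsonr(cow_warp(tr, traces[0], spec).warped, traces[0])[0] for tr in traces[1:]]
        )
        raw_corr = np.mean([pearsonr(tr, traces[0])[0] for tr in traces[1:]])
        assert warped_corr >= raw_corr

    def test_matches_exhaustive_grid_evaluation(self):
        rng = np.random.default_rng(9)
        base = np.exp(-0.5 * ((np.arange(90) - 45) / 5.0) ** 2)
        traces = np.stack(
            [base, np.roll(base, 2) + 0.01 * rng.normal(size=90), np.roll(base, -2)]
        )
        grid_seg, grid_slack = (10, 20), (1, 2)
        spec = optimize_warp_params(traces, 0, grid_seg, grid_slack)
        # independent loop over the 4 cells
        best, best_cell = -np.inf, None
        for m in grid_seg:
            for s in grid_slack:
                scores = [
                    pearsonr(cow_warp(traces[i], traces[0], WarpSpec(m, s)).warped, traces[0])[0]
                    for i in (1, 2)
                ]
                mean = np.mean(scores)
                if mean > best:
                    best, best_cell = mean, (m, s)
        assert (spec.segment_length, spec.slack) == best_cell


class TestAlignCube:
    @staticmethod
    def shifted_peak_cube(n_samples=6, length=300, shift_sd=2.0, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        centers = np.array([60.0, 150.0, 230.0])
        traces = []
        for i in range(n_samples):
            shift = 0.0 if identical else rng.normal(0, shift_sd)
            t = np.arange(length)
            trace = sum(np.exp(-0.5 * ((t - c - shift) / 5.0) ** 2) for c in centers)
            traces.append(trace)
        values = np.stack(traces)[:, None, :]
        return DataCube(
            values=values,
            sample_ids=[f"s{i}" for i in range(n_samples)],
            wavelengths=[254.0],
            times=np.arange(length) / 100.0,
        )

    def test_identical_records_align_to_identity(self):
        cube = self.shifted_peak_cube(identical=True)
        aligned, logs = align_cube(cube, WarpSpec(20, 2))
        np.testing.assert_allclose(aligned.values, cube.values, atol=1e-9)
        assert len(logs) == 1

    def test_jittered_cube_correlation_strictly_increases(self):
        cube = self.shifted_peak_cube(shift_sd=2.5, seed=3)
        aligned, logs = align_cube(cube, WarpSpec(20, 2))
        assert logs[0].mean_corr_after > logs[0].mean_corr_before
        assert aligned.values.shape == cube.values.shape

    def test_one_target_per_channel_logged(self):
        rng = np.random.default_rng(4)
        cube = DataCube(
            values=rng.normal(size=(5, 3, 120)).cumsum(axis=2),
            sample_ids=[f"s{i}" for i in range(5)],
            wavelengths=[210.0, 254.0, 300.0],
            times=np.arange(120) / 100.0,
        )
        aligned, logs = align_cube(cube, WarpSpec(15, 2))
        assert [lg.wavelength for lg in logs] == [210.0, 254.0, 300.0]
        assert all(lg.target_id in cube.sample_ids for lg in logs)

    def test_irregular_grid_rejected(self):
        cube = DataCube(
            values=np.zeros((2, 1, 50)),
            sample_ids=["a", "b"],
            wavelengths=[254.0],
            times=np.sort(np.random.default_rng(0).uniform(0, 1, 50)),
        )
        with pytest.raises(ValueError, match="regular"):
            align_cube(cube, WarpSpec(10, 2))
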