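"""Distance matrices, correlations, separation score, boundaries, filters."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from sbsphase.core import Conformation, Ensemble, PolymerModel, SimulationParams
from sbsphase.metrics import (
    BoundaryParams,
    DistanceMatrix,
    EXPERIMENTAL_BOUNDARY_PARAMS,
    MODEL_BOUNDARY_PARAMS,
    boundary_probability,
    call_boundaries,
    contact_map_from_ensemble,
    distance_corrected_r,
    distance_matrix,
    filter_cells,
    gaussian_smooth,
    median_distance_matrix,
    mw_protocol,
    pearson_r,
    separation_score,
    subtract_diagonal_means,
    track_correlation_significance,
    variability_distributions,
)


def _random_distance_matrix(rng, W=16):
    pts = rng.normal(size=(W, 3)) * 3
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(values=d)


class TestDistanceMatrices:
    def test_window_centroid_reduction(self):
        model = PolymerModel(colors=np.zeros(4, int), n=0, r=2)
        coords = np.array([[0, 0, 0], [2, 0, 0], [10, 0, 0], [12, 0, 0]], float)
        d = distance_matrix(Conformation(coords=coords), model)
        assert d.values.shape == (2, 2)
        assert d.values[0, 1] == pytest.approx(10.0)  # centroid distance

    def test_median_nan_policy(self):
        a = np.array([[0.0, 1], [1, 0]])
        b = np.array([[0.0, 3], [3, 0]])
        c = np.array([[0.0, np.nan], [np.nan, 0]])
        med = median_distance_matrix(
            [DistanceMatrix(values=x) for x in (a, b, c)]
        ).values
        assert med[0, 1] == pytest.approx(2.0)  # median of the two defined
        single = median_distance_matrix([DistanceMatrix(values=a)]).values
        np.testing.assert_array_equal(single, a)

    def test_median_matches_sort_oracle(self, rng):
        stack = rng.uniform(1, 5, size=(7, 4, 4))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for m in stack:
            np.fill_diagonal(m, 0)
        med = median_distance_matrix([DistanceMatrix(values=m) for m in stack]).values
        oracle = np.sort(stack, axis=0)[3]
        np.testing.assert_allclose(med, oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_distance_matrix([])


class TestContactMap:
    def _tiny_ensemble(self):
        model = PolymerModel(colors=np.zeros(3, int), n=0)
        confs = [
            Conformation(coords=np.array([[0, 0, 0], [2.0, 0, 0], [8.0, 0, 0]]))
        ]
        return Ensemble(conformations=confs, params=SimulationParams(), model=model)

    def test_threshold_rule(self):
        ens = self._tiny_ensemble()
        cm = contact_map_from_ensemble(ens, A=3.0)
        assert cm.values[0, 1] == 1.0 and cm.values[0, 2] == 0.0
        cm1 = contact_map_from_ensemble(ens, A=1.0)
        assert cm1.values[0, 1] == 0.0

    def test_monotone_in_A(self, rng):
        model = PolymerModel(colors=np.zeros(10, int), n=0)
        confs = [
            Conformation(coords=rng.normal(size=(10, 3)) * 3) for _ in range(15)
        ]
        ens = Ensemble(conformations=confs, params=SimulationParams(), model=model)
        prev = contact_map_from_ensemble(ens, A=3.0).values
        for A in (5.0, 8.0, 10.0):
            cur = contact_map_from_ensemble(ens, A=A).values
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_matches_brute_recount(self, rng):
        model = PolymerModel(colors=np.zeros(6, int), n=0, r=2)
        confs = [Conformation(coords=rng.normal(size=(6, 3)) * 2) for _ in range(9)]
        ens = Ensemble(conformations=confs, params=SimulationParams(), model=model)
        got = contact_map_from_ensemble(ens, A=3.0).values
        W, r = 3, 2
        oracle = np.zeros((W, W))
        for conf in confs:
            c = conf.coords
            for i in range(W):
                for j in range(W):
                    hit = any(
                        np.linalg.norm(c[i * r + a] - c[j * r + b]) < 3.0
                        for a in range(r)
                        for b in range(r)
                    )
                    oracle[i, j] += hit
        oracle /= len(confs)
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(got, oracle)

    def test_empty_ensemble_rejected(self):
        model = PolymerModel(colors=np.zeros(3, int), n=0)
        ens = Ensemble(conformations=[], params=SimulationParams(), model=model)
        with pytest.raises(ValueError):
            contact_map_from_ensemble(ens)


class TestCorrelations:
    def test_pearson_trivials(self, rng):
        m = _random_distance_matrix(rng)
        assert pearson_r(m, m) == pytest.approx(1.0)
        centered = m.values - m.values[np.triu_indices(16, 1)].mean()
        assert pearson_r(centered, -centered) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self, rng):
        a, b = _random_distance_matrix(rng), _random_distance_matrix(rng)
        iu = np.triu_indices(16, 1)
        x, y = a.values[iu], b.values[iu]
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pearson_r(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_rprime_self_is_one(self, rng):
        m = _random_distance_matrix(rng)
        assert distance_corrected_r(m, m) == pytest.approx(1.0)

    def test_rprime_diagonal_shift_invariance(self, rng):
        a, b = _random_distance_matrix(rng), _random_distance_matrix(rng)
        base = distance_corrected_r(a, b)
        W = 16
        shift = np.zeros((W, W))
        offsets = rng.uniform(-5, 5, W)
        for k in range(1, W):
            idx = (np.arange(W - k), np.arange(k, W))
            shift[idx] = offsets[k]
            shift[(idx[1], idx[0])] = offsets[k]
        shifted = distance_corrected_r(a.values + shift, b)
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_rprime_hand_worked_4x4(self):
        a = np.array(
            [
                [0.0, 1.0, 2.0, 4.0],
                [1.0, 0.0, 1.5, 2.5],
                [2.0, 1.5, 0.0, 1.2],
                [4.0, 2.5, 1.2, 0.0],
            ]
        )
        b = np.array(
            [
                [0.0, 2.0, 3.0, 3.5],
                [2.0, 0.0, 1.0, 2.8],
                [3.0, 1.0, 0.0, 2.2],
                [3.5, 2.8, 2.2, 0.0],
            ]
        )
        # explicit diagonal means, k = 1..3
        am = [np.mean([1.0, 1.5, 1.2]), np.mean([2.0, 2.5]), 4.0]
        bm = [np.mean([2.0, 1.0, 2.2]), np.mean([3.0, 2.8]), 3.5]
        ar = np.array([1.0 - am[0], 2.0 - am[1], 4.0 - am[2],
                       1.5 - am[0], 2.5 - am[1], 1.2 - am[0]])
        br = np.array([2.0 - bm[0], 3.0 - bm[1], 3.5 - bm[2],
                       1.0 - bm[0], 2.8 - bm[1], 2.2 - bm[0]])
        oracle = np.corrcoef(ar, br)[0, 1]
        assert distance_corrected_r(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_rprime_pure_decay_is_undefined(self):
        W = 8
        k = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :]).astype(float)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(distance_corrected_r(k, k * 2.0))

    def test_too_few_common_elements_signaled(self):
        a = np.full((4, 4), np.nan)
        np.fill_diagonal(a, 0)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(distance_corrected_r(a, a))

    def test_subtract_diagonal_means_centers_every_diagonal(self, rng):
        m = _random_distance_matrix(rng).values
        res = subtract_diagonal_means(m)
        for k in range(1, 16):
            assert np.nanmean(np.diagonal(res, k)) == pytest.approx(0.0, abs=1e-12)


class TestSeparationScore:
    def test_two_ball_junction_minimum(self, ball_matrices):
        prof = separation_score(ball_matrices[0], su=5, sl=5)
        interior = prof[5:-5]
        # designed junctions at 10, 20, 30
        assert np.nanargmin(interior) + 5 in {15, 16, 17, 31, 32, 33, 47, 48, 49}
        assert np.nanmin(prof) < 0.5

    def test_coil_profile_flat_near_one(self, coil40_matrices):
        profs = np.stack(
            [separation_score(m, su=5, sl=5) for m in coil40_matrices[:100]]
        )
        mean_prof = np.nanmean(profs, axis=0)
        inner = mean_prof[2:-2]
        assert abs(np.nanmean(inner) - 1.0) < 0.1
        assert np.nanmax(inner) - np.nanmin(inner) < 0.25

    def test_all_nan_gives_nan(self):
        m = np.full((12, 12), np.nan)
        prof = separation_score(m, su=3, sl=3)
        assert np.isnan(prof).all()

    def test_edge_exclusion(self, ball_matrices):
        prof = separation_score(ball_matrices[0], su=4, sl=4, gb=2)
        assert np.isnan(prof[:2]).all() and np.isnan(prof[-2:]).all()


class TestBoundaries:
    def test_two_ball_single_call(self):
        rng = np.random.default_rng(5)
        pts = np.r_[rng.normal(size=(10, 3)) * 0.5,
                    rng.normal(size=(10, 3)) * 0.5 + [12, 0, 0]]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        calls, strengths, prof = call_boundaries(
            DistanceMatrix(values=d), BoundaryParams(gb=1, valley=1, su=5, sl=5)
        )
        assert len(calls) == 1 and 9 <= calls[0] <= 11
        assert strengths[0] > 1.0

    def test_flat_profile_no_calls(self):
        W = 20
        k = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :]).astype(float)
        calls, strengths, _ = call_boundaries(DistanceMatrix(values=k))
        assert len(calls) == 0

    def test_strengths_at_least_one(self, ball_matrices):
        for m in ball_matrices[:10]:
            _, strengths, _ = call_boundaries(m, MODEL_BOUNDARY_PARAMS)
            assert np.all(strengths >= 1.0)

    def test_call_spacing_respects_valley(self, ball_matrices):
        p = BoundaryParams(gb=1, valley=6, su=3, sl=3)
        for m in ball_matrices[:10]:
            calls, _, _ = call_boundaries(m, p)
            assert np.all(np.diff(calls) >= 7)

    def test_probability_trivials(self):
        rng = np.random.default_rng(5)
        pts = np.r_[rng.normal(size=(10, 3)) * 0.5,
                    rng.normal(size=(10, 3)) * 0.5 + [12, 0, 0]]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ms = [DistanceMatrix(values=d)] * 8
        prof = boundary_probability(ms, BoundaryParams(gb=1, valley=1, su=5, sl=5))
        assert prof.raw_probability.max() == 1.0
        flat = [DistanceMatrix(values=np.abs(
            np.subtract.outer(np.arange(20.0), np.arange(20.0))))] * 4
        zero = boundary_probability(flat)
        assert zero.raw_probability.sum() == 0.0

    def test_block_copolymer_peaks_at_junctions(self, ball_matrices):
        prof = boundary_probability(ball_matrices, MODEL_BOUNDARY_PARAMS)
        raw = prof.raw_probability
        for j in (16, 32, 48):
            assert raw[j - 1 : j + 2].sum() > 0.5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BoundaryParams(su=0)


class TestFiltering:
    def test_nan_and_outlier_rules(self, rng):
        base = _random_distance_matrix(rng).values
        stack = []
        for _ in range(8):
            noise = rng.normal(scale=0.05, size=base.shape)
            v = base + (noise + noise.T) / 2
            np.fill_diagonal(v, 0)
            stack.append(DistanceMatrix(values=np.abs(v)))
        all_nan = DistanceMatrix(values=np.full((16, 16), np.nan))
        anti = DistanceMatrix(values=(base.max() - base))
        np.fill_diagonal(anti.values, 0)
        kept, report = filter_cells(stack + [all_nan, anti])
        assert report["nan_removed"] == 1
        assert report["correlation_removed"] >= 1
        assert len(kept) == len(stack)

    def test_identical_stack_untouched(self, rng):
        m = _random_distance_matrix(rng)
        kept, report = filter_cells([m] * 5)
        assert len(kept) == 5 and report["correlation_removed"] == 0

    def test_idempotent(self, rng):
        ms = [_random_distance_matrix(rng) for _ in range(6)]
        ms += [DistanceMatrix(values=np.full((16, 16), np.nan))]
        kept, _ = filter_cells(ms)
        kept2, report2 = filter_cells(kept)
        assert len(kept2) == len(kept)
        assert report2["nan_removed"] == 0 and report2["correlation_removed"] == 0


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        m = np.full((10, 10), 3.0)
        out = gaussian_smooth(DistanceMatrix(values=m), 1.0).values
        np.testing.assert_allclose(out, 3.0, rtol=1e-10)

    def test_delta_impulse_gives_kernel(self):
        m = np.zeros((21, 21))
        m[10, 10] = 1.0
        out = gaussian_smooth(DistanceMatrix(values=m), 1.0).values
        oracle = ndimage.gaussian_filter(m, 1.0, mode="nearest")
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_nan_aware_matches_masked_convolution_oracle(self, rng):
        m = _random_distance_matrix(rng).values
        holes = rng.random(m.shape) < 0.2
        holes = holes | holes.T
        mh = m.copy()
        mh[holes] = np.nan
        out = gaussian_smooth(DistanceMatrix(values=mh), 1.0).values
        filled = np.where(holes, 0.0, m)
        weight = (~holes).astype(float)
        oracle = ndimage.gaussian_filter(filled, 1.0, mode="nearest") / (
            ndimage.gaussian_filter(weight, 1.0, mode="nearest")
        )
        oracle = 0.5 * (oracle + oracle.T)
        ok = ~holes
        np.testing.assert_allclose(out[ok], oracle[ok], atol=1e-10)
        assert np.isnan(out[holes]).all()

    def test_symmetry_preserved(self, rng):
        m = _random_distance_matrix(rng)
        out = gaussian_smooth(m, 1.5).values
        np.testing.assert_allclose(out, out.T, atol=1e-12)


class TestVariabilityAndTests:
    def test_identical_sets_give_unit_rprime(self, rng):
        m = _random_distance_matrix(rng)
        res = variability_distributions([m, m, m], [m, m], seed=0, smooth_sd=0)
        np.testing.assert_allclose(res["exp_exp"]["values"], 1.0)
        np.testing.assert_allclose(res["model_exp"]["values"], 1.0)

    def test_independent_sets_centered_near_zero(self, rng):
        a = [_random_distance_matrix(rng) for _ in range(12)]
        b = [_random_distance_matrix(rng) for _ in range(12)]
        res = variability_distributions(a, b, seed=0, smooth_sd=0)
        assert abs(np.nanmean(res["model_exp"]["values"])) < 0.06
        assert abs(np.nanmean(res["control"]["values"])) < 0.06

    def test_mw_null_behavior(self, rng):
        ps = []
        for k in range(10):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            ps.append(mw_protocol(a, b, n_resamples=5, seed=k))
        assert np.median(ps) > 0.05

    def test_mw_power_on_shifted_distributions(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(loc=2.0, size=100)
        assert mw_protocol(a, b, seed=0) < 0.01

    def test_mw_equal_sample_sizes_forced(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=300)
        # must not raise, and must subsample b down to len(a)
        p = mw_protocol(a, b, n_resamples=3, seed=1)
        assert 0.0 <= p <= 1.0

    def test_mw_independent_pairs(self, rng):
        vals = rng.normal(size=6)
        pairs = [(0, 1), (0, 2), (1, 2), (3, 4)]
        with pytest.raises(ValueError):
            # only 2 disjoint pairs available -> below the minimum
            mw_protocol(vals[:4], vals[:4], pairs_a=pairs, pairs_b=pairs, seed=0)


class TestTrackCorrelation:
    def test_self_track_significant(self, rng):
        track = rng.poisson(3, size=50).astype(float)
        res = track_correlation_significance(track, track, n_boot=200, seed=0)
        assert res["correlation"][0, 0] == pytest.approx(1.0)
        assert res["significant"][0, 0]

    def test_independent_track_mostly_not_significant(self, rng):
        hits = 0
        trials = 10
        for t in range(trials):
            dom = rng.poisson(3, size=60).astype(float)
            feat = rng.normal(size=60)
            res = track_correlation_significance(dom, feat, n_boot=200, seed=t)
            hits += bool(res["significant"][0, 0])
        assert hits <= 0.4 * trials

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            track_correlation_significance(np.ones(5), np.ones(6), n_boot=10)


class TestCorrelationProperties:
    """Property-based checks of the r' algebra."""

    def test_rprime_invariants_under_random_inputs(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(st.integers(min_value=0, max_value=10_000))
        def check(seed):
            g = np.random.default_rng(seed)
            W = int(g.integers(5, 14))
            pts1, pts2 = g.normal(size=(2, W, 3)) * 3
            a = np.sqrt(((pts1[:, None] - pts1[None]) ** 2).sum(-1))
            b = np.sqrt(((pts2[:, None] - pts2[None]) ** 2).sum(-1))
            r = distance_corrected_r(a, b)
            if np.isfinite(r):
                assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
                # symmetry and per-diagonal shift invariance
                assert distance_corrected_r(b, a) == pytest.approx(r, abs=1e-12)
                shift = np.zeros((W, W))
                offs = g.uniform(-4, 4, W)
                for k in range(1, W):
                    idx = (np.arange(W - k), np.arange(k, W))
                    shift[idx] = offs[k]
                    shift[(idx[1], idx[0])] = offs[k]
                assert distance_corrected_r(a + shift, b) == pytest.approx(
                    r, abs=1e-10
                )

        check()
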