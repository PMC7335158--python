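"""Inference: costs, forward map, annealing, selection, overlaps."""

import itertools
import warnings

import numpy as np
import pytest

from sbsphase.core import PolymerModel
from sbsphase.prismr import (
    ContactMatrix,
    SAConfig,
    cost_h0,
    cost_total,
    domain_overlap,
    between_color_overlap,
    forward_contact_map,
    make_split_mask,
    matched_bead_agreement,
    robustness_of_minima,
    sa_optimize,
)
from sbsphase.synth import generate_coloring, synthesize_hic


class TestContactMatrix:
    def test_rejects_asymmetry_nan_negative(self):
        with pytest.raises(ValueError):
            ContactMatrix(values=np.array([[1.0, 2], [3, 1]]))
        with pytest.raises(ValueError):
            ContactMatrix(values=np.array([[1.0, np.nan], [np.nan, 1]]))
        with pytest.raises(ValueError):
            ContactMatrix(values=np.array([[1.0, -2], [-2, 1]]))


class TestCostH0:
    def test_zero_iff_equal(self, noisy60):
        v = noisy60.values
        assert cost_h0(v, v) == pytest.approx(0.0, abs=1e-24)

    def test_hand_computed_3x3(self):
        # target diagonals means: d1 = 0.5, d2 = 0.2; predicted = target + 0.1
        t = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]])
        p = t + 0.1
        # optimal scale a* = sum(w p t)/sum(w p p) over off-diagonal uppers
        w = np.array([1 / 0.5, 1 / 0.2, 1 / 0.5])
        pv = np.array([0.6, 0.3, 0.6])
        tv = np.array([0.5, 0.2, 0.5])
        a = (w * pv * tv).sum() / (w * pv * pv).sum()
        oracle = np.mean(w * (a * pv - tv) ** 2)
        assert cost_h0(p, t) == pytest.approx(oracle, rel=1e-12)

    def test_distance_scaling_upweights_far_diagonals(self):
        # equal absolute error, decaying diagonal mean -> far error costs more
        W = 8
        k = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
        t = 1.0 / (1.0 + k)
        near = t.copy()
        near[k == 1] += 0.05
        near = np.triu(near, 1) + np.triu(near, 1).T + np.diag(np.diag(t))
        far = t.copy()
        far[k == W - 1] += 0.05
        far = np.triu(far, 1) + np.triu(far, 1).T + np.diag(np.diag(t))
        assert cost_h0(far, t) > cost_h0(near, t)

    def test_zero_mean_diagonal_warns(self):
        t = np.eye(4)
        with pytest.warns(RuntimeWarning, match="zero-mean"):
            cost_h0(t + 0.0, t)


class TestCostTotal:
    def test_arithmetic(self):
        m = PolymerModel(colors=np.r_[np.ones(100, int), np.zeros(20, int)], n=1)
        assert cost_total(2.0, m, 0.0) == 2.0
        assert cost_total(2.0, m, 1e-5) == pytest.approx(2.0 + 1e-3)
        colorless = PolymerModel(colors=np.zeros(50, int), n=1)
        assert cost_total(2.0, colorless, 1.0) == 2.0
        with pytest.raises(ValueError):
            cost_total(1.0, m, -0.1)


class TestSplitMask:
    def test_upper_triangle_fraction(self, rng):
        mask = make_split_mask(30, 0.7, rng)
        iu = np.triu_indices(30, 1)
        assert mask[iu].sum() == round(0.7 * len(iu[0]))
        assert not mask[np.tril_indices(30)].any()


class TestForwardMap:
    def test_colorless_is_monotone_baseline(self, templates60):
        m = PolymerModel(colors=np.zeros(60, int), n=0)
        cm = forward_contact_map(m, templates60).values
        prof = np.array([np.mean(np.diagonal(cm, k)) for k in range(1, 40)])
        # non-increasing up to template noise
        assert np.all(np.diff(prof) < 0.02)

    def test_no_cross_block_enrichment_for_disjoint_colors(self, templates60):
        m0 = PolymerModel(colors=np.zeros(60, int), n=2)
        m = PolymerModel(
            colors=np.r_[np.ones(30, int), np.full(30, 2)], n=2
        )
        base = forward_contact_map(m0, templates60).values
        pred = forward_contact_map(m, templates60).values
        cross = np.s_[:30, 30:]
        np.testing.assert_allclose(pred[cross], base[cross], atol=1e-12)
        assert pred[:30, :30].sum() > base[:30, :30].sum()

    def test_template_mismatch_rejected(self, templates60):
        with pytest.raises(ValueError):
            forward_contact_map(PolymerModel(colors=np.ones(10, int), n=1), templates60)

    def test_matches_direct_simulation_of_block_polymer(self):
        """Mean-field prediction vs direct simulation, 50-bead half-colored chain."""
        from sbsphase.core import SimulationParams, simulate_ensemble
        from sbsphase.metrics import contact_map_from_ensemble, pearson_r
        from sbsphase.prismr import get_templates

        tpl = get_templates(50, 1)
        model = PolymerModel(colors=np.r_[np.ones(25, int), np.zeros(25, int)], n=1)
        pred = forward_contact_map(model, tpl)
        params = SimulationParams(
            concentration=0.5e-6,
            seed=404,
            n_steps=9000,
            equilibration_steps=6000,
            samples_per_chain=8,
            decorrelation_sweeps=200,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ens = simulate_ensemble(model, params, 96)
        sim = contact_map_from_ensemble(ens, A=tpl.A)
        assert pearson_r(pred.values, sim.values) >= 0.9


class TestAnnealing:
    def test_recovers_planted_coloring(self, truth60, noisy60, templates60):
        res = sa_optimize(
            noisy60, SAConfig(n=3, lambda_=0.0, seed=0), templates=templates60
        )
        assert matched_bead_agreement(truth60.model, res.coloring) >= 0.9
        assert res.h0_train < 1e-2
        assert res.improved

    def test_deterministic_given_seed(self, noisy60, templates60):
        a = sa_optimize(noisy60, SAConfig(n=2, seed=7), templates=templates60)
        b = sa_optimize(noisy60, SAConfig(n=2, seed=7), templates=templates60)
        np.testing.assert_array_equal(a.coloring.colors, b.coloring.colors)
        np.testing.assert_array_equal(a.cost_trace, b.cost_trace)

    def test_structureless_target_gains_nothing(self, templates60):
        W = 60
        k = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
        t = ContactMatrix(values=1.0 / (1.0 + k))
        res = sa_optimize(t, SAConfig(n=3, seed=1), templates=templates60)
        colorless = cost_h0(
            forward_contact_map(
                PolymerModel(colors=np.zeros(W, int), n=0), templates60
            ),
            t,
            res.split_mask,
        )
        # nothing to explain: best model is not meaningfully better
        assert res.h0_train > 0.5 * colorless or colorless < 1e-6

    def test_invalid_config_rejected(self, noisy60):
        with pytest.raises(ValueError):
            sa_optimize(noisy60, SAConfig(train_fraction=0.4))
        with pytest.raises(ValueError):
            sa_optimize(noisy60, SAConfig(lambda_=-1.0))

    def test_regularization_prunes_superfluous_colors(self, noisy60, templates60):
        # n above truth with lambda > 0: extra colors occupy few beads
        res = sa_optimize(
            noisy60, SAConfig(n=5, lambda_=1e-4, seed=3), templates=templates60
        )
        counts = np.bincount(res.coloring.colors, minlength=6)
        used = np.sort(counts[1:])[::-1]
        assert used[3:].sum() <= 0.05 * res.coloring.n_beads


class TestOverlap:
    def test_identical_matched_is_100(self, truth60):
        res = domain_overlap(truth60.model, truth60.model, matched=True)
        assert res["matched_mean"] == pytest.approx(100.0)

    def test_block_copolymer_between_colors_zero(self):
        from sbsphase.synth import generate_block_copolymer_control

        ctl = generate_block_copolymer_control(40, 4, r=1, seed=2)
        assert between_color_overlap(ctl.model) == 0.0

    def test_matches_exhaustive_permutation_search(self, rng):
        a = PolymerModel(colors=rng.integers(0, 3, 20), n=2)
        b = PolymerModel(colors=rng.integers(0, 3, 20), n=2)
        res = domain_overlap(a, b, matched=True)
        # brute force over color permutations of b
        sets_a = [set(np.where(a.color_counts()[:, c] > 0)[0]) for c in (1, 2)]
        sets_b = [set(np.where(b.color_counts()[:, c] > 0)[0]) for c in (1, 2)]

        def ov(x, y):
            u = x | y
            return 100.0 * len(x & y) / len(u) if u else 100.0

        best = max(
            np.mean([ov(sets_a[i], sets_b[p[i]]) for i in range(2)])
            for p in itertools.permutations(range(2))
        )
        assert res["matched_mean"] == pytest.approx(best)

    def test_window_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            domain_overlap(
                PolymerModel(colors=np.ones(5, int), n=1),
                PolymerModel(colors=np.ones(6, int), n=1),
            )

    def test_bead_agreement_permutation_invariant(self, truth60):
        perm = {0: 0, 1: 3, 2: 1, 3: 2}
        renamed = PolymerModel(
            colors=np.array([perm[c] for c in truth60.model.colors]), n=3
        )
        assert matched_bead_agreement(truth60.model, renamed) == pytest.approx(1.0)


class TestRobustness:
    def test_identical_runs_full_overlap(self, noisy60, templates60):
        res = [
            sa_optimize(noisy60, SAConfig(n=3, seed=5), templates=templates60)
            for _ in range(2)
        ]
        rep = robustness_of_minima(res)
        assert rep["mean_overlap"] == pytest.approx(100.0)

    def test_recovery_battery_is_consistent(self, noisy60, templates60):
        res = [
            sa_optimize(noisy60, SAConfig(n=3, seed=s), templates=templates60)
            for s in range(12)
        ]
        rep = robustness_of_minima(res)
        assert rep["mean_overlap"] >= 80.0

    def test_single_run_degenerate(self, noisy60, templates60):
        rep = robustness_of_minima(
            [sa_optimize(noisy60, SAConfig(n=2, seed=0), templates=templates60)]
        )
        assert rep["n_models"] == 1 and np.isnan(rep["mean_overlap"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            robustness_of_minima([])


def test_monotone_sparsity_in_lambda(noisy60, templates60):
    """Colored-bead count at the optimum does not grow with lambda."""
    counts = []
    for lam in (0.0, 1e-5, 1e-4, 1e-3):
        per_seed = [
            np.count_nonzero(
                sa_optimize(
                    noisy60, SAConfig(n=3, lambda_=lam, seed=s), templates=templates60
                ).coloring.colors
            )
            for s in range(5)
        ]
        counts.append(np.mean(per_seed))
    assert all(b <= a + 1 for a, b in zip(counts, counts[1:]))
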