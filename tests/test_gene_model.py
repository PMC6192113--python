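"""Unit tests for per-gene selection, gating and trend classification."""

import numpy as np
import pytest

from segtrend import (
    TimeVector,
    TrendConfig,
    adjusted_r_squared,
    bic_score,
    classify_segments,
    enforce_min_segment,
    fit_gene,
    fit_matrix,
    fit_segmented,
    segment_pvalue,
    select_model,
)
from segtrend.gene_model import UndefinedFitError, segment_sample_counts
from segtrend.segreg import SegmentedModel


def _dummy_model(k, breakpoints, converged=True, loglik=0.0):
    return SegmentedModel(
        k=k,
        intercept=0.0,
        slopes=np.zeros(k + 1),
        slope_se=np.ones(k + 1),
        breakpoints=np.asarray(breakpoints, dtype=float),
        rss=1.0,
        loglik=loglik,
        fitted=np.zeros(1),
        converged=converged,
        n_iter=1,
    )


class TestBic:
    def test_formula_value(self):
        assert bic_score(-14.18939, 10, 0) == pytest.approx(
            3 * np.log(10) + 2 * 14.18939, abs=1e-9
        )

    def test_extra_breakpoint_costs_two_logn(self):
        n = 25
        assert bic_score(-5.0, n, 2) - bic_score(-5.0, n, 1) == pytest.approx(
            2 * np.log(n)
        )

    def test_perfect_fit_dominates(self):
        assert bic_score(np.inf, 10, 3) == -np.inf


class TestSelectModel:
    def test_only_k0(self):
        assert select_model({0: _dummy_model(0, [])}, 10) == 0

    def test_tie_breaks_to_smaller_k(self):
        # Equal log-likelihood: k=1 pays a larger penalty, so k=0 wins; with
        # identical BIC (engineered loglik offset) the smaller k still wins.
        n = 10
        m0 = _dummy_model(0, [], loglik=-5.0)
        m1 = _dummy_model(1, [5.0], loglik=-5.0 + np.log(n))  # same BIC as m0
        assert select_model({0: m0, 1: m1}, n) == 0

    def test_nonconverged_skipped(self):
        m0 = _dummy_model(0, [], loglik=-50.0)
        m1 = _dummy_model(1, [5.0], loglik=0.0, converged=False)
        assert select_model({0: m0, 1: m1}, 10) == 0

    def test_no_converged_model_returns_none(self):
        assert select_model({0: _dummy_model(0, [], converged=False)}, 10) is None


class TestMinSegmentGuard:
    def test_segment_counts_half_open(self, replicated_times):
        # Break exactly at t=3: samples at 3 belong to the second segment.
        counts = segment_sample_counts(replicated_times, [3.0])
        assert counts.tolist() == [7, 18]

    def test_reduces_to_zero_when_tail_too_small(self, times20):
        models = {0: _dummy_model(0, []), 1: _dummy_model(1, [17.5])}
        # 3 samples after the break < 5 required.
        assert enforce_min_segment(models, 1, times20, 5) == 0

    def test_unchanged_when_all_segments_large(self, times20):
        models = {0: _dummy_model(0, []), 1: _dummy_model(1, [10.5])}
        assert enforce_min_segment(models, 1, times20, 5) == 1

    def test_cascades_to_zero(self, times20):
        # k=2 and the k=1 candidate both violate the guard.
        models = {
            0: _dummy_model(0, []),
            1: _dummy_model(1, [18.5]),
            2: _dummy_model(2, [2.5, 18.5]),
        }
        assert enforce_min_segment(models, 2, times20, 5) == 0

    def test_result_satisfies_guard(self, replicated_times):
        rng = np.random.default_rng(5)
        y = rng.normal(20, 1, replicated_times.n)
        cfg = TrendConfig(seed=5)
        f = fit_gene(y, replicated_times, cfg, gene_id="g")
        counts = segment_sample_counts(replicated_times, f.breakpoints)
        assert np.all(counts >= cfg.min_seg)


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        assert adjusted_r_squared(1.0, 25, 2) == 1.0

    def test_printed_formula_value(self):
        assert adjusted_r_squared(0.9, 25, 2) == pytest.approx(
            1 - 0.1 * 24 / 21, abs=1e-9
        )

    def test_can_be_negative(self):
        assert adjusted_r_squared(0.0, 10, 0) == pytest.approx(-0.125)

    def test_undefined_when_saturated(self):
        with pytest.raises(UndefinedFitError):
            adjusted_r_squared(0.5, 4, 2)


class TestSegmentPvalue:
    def test_df1_matches_cauchy_closed_form(self):
        # For one degree of freedom the t-distribution is Cauchy:
        # p = 2 (0.5 - arctan(|t|)/pi).
        p = segment_pvalue(2.0, 1.0)
        assert p == pytest.approx(2 * (0.5 - np.arctan(2.0) / np.pi), abs=1e-9)

    def test_zero_slope(self):
        assert segment_pvalue(0.0, 1.0) == 1.0

    def test_sign_symmetric(self):
        assert segment_pvalue(1.7, 0.4) == pytest.approx(segment_pvalue(-1.7, 0.4))

    def test_zero_se_cases(self):
        assert segment_pvalue(1.0, 0.0) == 0.0
        assert segment_pvalue(0.0, 0.0) == 1.0

    def test_residual_mode_uses_n_minus_params(self):
        from scipy import stats

        p = segment_pvalue(2.0, 1.0, df_mode="residual", n=20, k=1)
        assert p == pytest.approx(2 * stats.t.sf(2.0, 16), abs=1e-12)


class TestClassification:
    def test_significant_slopes_labelled_by_sign(self, times20):
        y = 3.0 * times20.values
        m = fit_segmented(y + np.random.default_rng(0).normal(0, 0.1, 20), times20, 0)
        labels, s = classify_segments(m, 0.1, n=times20.n)
        assert labels == ["up"] and s == "up"

    def test_noise_slope_is_same(self, times20):
        rng = np.random.default_rng(1)
        m = fit_segmented(rng.normal(5, 1, 20), times20, 0)
        labels, _ = classify_segments(m, 0.1, n=times20.n)
        assert labels == ["same"]

    def test_lower_cutoff_never_creates_up_down(self, times20, hinge_gene):
        rng = np.random.default_rng(2)
        m = fit_segmented(hinge_gene + rng.normal(0, 0.3, 20), times20, 1, seed=0)
        for hi, lo in [(0.5, 0.1), (0.2, 0.05), (0.1, 0.01)]:
            labels_hi, _ = classify_segments(m, hi, n=times20.n)
            labels_lo, _ = classify_segments(m, lo, n=times20.n)
            for a, b in zip(labels_hi, labels_lo):
                if a == "same":
                    assert b == "same"


class TestFitGene:
    def test_noiseless_line_up(self, replicated_times, default_config):
        y = 1.0 * replicated_times.values + 10.0
        f = fit_gene(y, replicated_times, default_config, gene_id="g")
        assert f.k_selected == 0
        assert f.trend_string == "up"
        assert f.adj_r2 == pytest.approx(1.0)

    def test_noiseless_hinge_up_same(self, times20, hinge_gene, default_config):
        f = fit_gene(hinge_gene, times20, default_config, gene_id="g")
        assert f.k_selected == 1
        assert f.trend_string == "up-same"
        assert f.breakpoints[0] == pytest.approx(10.0, abs=0.02)

    def test_selection_consistency_two_breaks(self, default_config):
        tv = TimeVector(np.arange(0.0, 30.0))
        t = tv.values
        y = 20 + np.piecewise(
            t,
            [t < 10, (t >= 10) & (t < 20), t >= 20],
            [lambda x: x, lambda x: 10 - 0.8 * (x - 10), lambda x: 2 + 0.6 * (x - 20)],
        )
        f = fit_gene(y, tv, default_config, gene_id="g")
        assert f.k_selected == 2
        assert f.segment_trends == ["up", "down", "up"]

    def test_pure_noise_gene_scores_low(self, replicated_times, default_config):
        rng = np.random.default_rng(11)
        y = rng.normal(20.0, 1.0, replicated_times.n)
        f = fit_gene(y, replicated_times, default_config, gene_id="g")
        assert f.adj_r2 < 0.5

    def test_bic_trace_reproduces_argmin(self, times20, hinge_gene, default_config):
        f = fit_gene(hinge_gene, times20, default_config, gene_id="g")
        ks = sorted(f.bic_by_k)
        best = min(ks, key=lambda k: (f.bic_by_k[k], k))
        # argmin of the stored trace with small-k tie rule matches selection
        # before the min-segment guard; with ample segments they coincide.
        assert best == f.k_selected

    def test_deterministic_given_seed(self, replicated_times):
        rng = np.random.default_rng(21)
        y = rng.normal(20, 1, replicated_times.n)
        cfg = TrendConfig(seed=33)
        f1 = fit_gene(y, replicated_times, cfg, gene_id="g")
        f2 = fit_gene(y, replicated_times, cfg, gene_id="g")
        assert f1.k_selected == f2.k_selected
        assert np.array_equal(f1.breakpoints, f2.breakpoints)
        assert f1.adj_r2 == f2.adj_r2


class TestFitMatrix:
    def test_order_independent_results(self, replicated_times):
        from segtrend.io import ExpressionMatrix

        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, (6, replicated_times.n))
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(6)], [f"s{j}" for j in range(25)])
        rev = ExpressionMatrix(vals[::-1].copy(), [f"g{i}" for i in range(5, -1, -1)],
                               [f"s{j}" for j in range(25)])
        cfg = TrendConfig(seed=9)
        fits1, _ = fit_matrix(m, replicated_times, cfg)
        fits2, _ = fit_matrix(rev, replicated_times, cfg)
        d1 = {f.gene_id: (f.k_selected, tuple(f.breakpoints), f.adj_r2) for f in fits1}
        d2 = {f.gene_id: (f.k_selected, tuple(f.breakpoints), f.adj_r2) for f in fits2}
        assert d1 == d2
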