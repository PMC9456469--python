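import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats as sps

from tfenrich.dea import (
    ContrastSpec,
    EBayesHyper,
    bh_adjust,
    clamp_negatives,
    classify_degs,
    estimate_hyper,
    filter_expressed,
    fit_contrast,
    intersect_contrasts,
    log2_transform,
    moderated_t,
    noise_filter,
    normalize_p75,
    run_dea,
    select_tf_degs,
)
from tfenrich.matrix import ScaleError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# preprocessing


class TestClampNegatives:
    def test_negative_set_to_one(self):
        m = make_matrix({"c0": [-5.0, 2.0], "c1": [3.0, 4.0]})
        out = clamp_negatives(m)
        assert out.values.iloc[0, 0] == 1.0

    def test_positive_untouched(self):
        m = make_matrix({"c0": [0.5, 2.0], "c1": [3.0, 4.0]})
        out = clamp_negatives(m)
        assert out.values.iloc[0, 0] == 0.5

    def test_all_positive_identity(self):
        m = make_matrix({"c0": [1.5, 2.0], "c1": [3.0, 4.0]})
        out = clamp_negatives(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_zero_clamped(self):
        m = make_matrix({"c0": [0.0, 2.0]})
        assert clamp_negatives(m).values.iloc[0, 0] == 1.0

    def test_rejects_log2_scale(self):
        m = make_matrix({"c0": [1.0, 2.0]}, scale="log2")
        with pytest.raises(ScaleError):
            clamp_negatives(m)


class TestNormalizeP75:
    def test_interpolated_quartile(self):
        # p75 of (2,4,6,8) at position 1+3*0.75 = 3.25 -> 6.5
        m = make_matrix({"c0": [2.0, 4.0, 6.0, 8.0]})
        out = normalize_p75(m)
        expected = np.array([2, 4, 6, 8]) / 6.5
        np.testing.assert_allclose(out.values["c0"], expected, rtol=1e-12)
        np.testing.assert_allclose(
            expected, [0.30769, 0.61538, 0.92308, 1.23077], atol=1e-5
        )

    def test_constant_column_self_normalizes(self):
        m = make_matrix({"c0": [3.0, 3.0, 3.0, 3.0]})
        np.testing.assert_allclose(normalize_p75(m).values["c0"], 1.0)

    def test_p75_becomes_one(self):
        rng = np.random.default_rng(1)
        m = make_matrix({"c0": rng.gamma(2, 50, 101)})
        out = normalize_p75(m)
        assert out.values["c0"].quantile(0.75) == pytest.approx(1.0, abs=1e-12)

    def test_marks_normalized(self):
        m = make_matrix({"c0": [2.0, 4.0, 6.0, 8.0]})
        assert not m.normalized
        assert normalize_p75(m).normalized


class TestFilterExpressed:
    def test_all_absent_removed_one_marginal_kept(self):
        m = make_matrix(
            {"c0": [1.0, 2.0], "c1": [3.0, 4.0]},
            flags={"c0": ["A", "A"], "c1": ["A", "M"]},
        )
        out = filter_expressed(m)
        assert list(out.values.index) == ["g1"]
        assert out.flags.shape == out.values.shape

    def test_all_present_unchanged(self):
        m = make_matrix(
            {"c0": [1.0, 2.0]}, flags={"c0": ["P", "P"]}
        )
        assert list(filter_expressed(m).values.index) == ["g0", "g1"]

    def test_zero_survivors_warns(self):
        m = make_matrix({"c0": [1.0]}, flags={"c0": ["A"]})
        with pytest.warns(UserWarning):
            out = filter_expressed(m)
        assert len(out.values) == 0


class TestLog2Transform:
    def test_values(self):
        m = make_matrix({"c0": [1.0, 8.0]})
        out = log2_transform(m)
        assert out.values["c0"].tolist() == [0.0, 3.0]
        assert out.scale == "log2"

    def test_double_transform_errors(self):
        m = make_matrix({"c0": [1.0, 8.0]})
        with pytest.raises(ScaleError):
            log2_transform(log2_transform(m))

    def test_nonpositive_errors(self):
        m = make_matrix({"c0": [0.0, 8.0]})
        with pytest.raises(ValueError):
            log2_transform(m)


# ---------------------------------------------------------------------------
# contrast fit and moderation


class TestFitContrast:
    def test_hand_computed_pooled_variance(self, contrast):
        m = make_matrix(
            {"c0": [0.9], "c1": [1.1], "c2": [1.0], "c3": [1.0],
             "t0": [2.0], "t1": [2.2]},
            scale="log2",
        )
        out = fit_contrast(m, contrast)
        assert out["log2fc"].iloc[0] == pytest.approx(1.1, abs=1e-12)
        assert out["s2"].iloc[0] == pytest.approx(0.01, abs=1e-12)
        assert out["df_residual"].iloc[0] == 4

    def test_identical_groups_zero_lfc(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [2.0], "t0": [1.0], "t1": [2.0]},
            scale="log2",
        )
        assert fit_contrast(m, contrast)["log2fc"].iloc[0] == 0.0

    def test_constant_groups_zero_variance(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [1.0], "t0": [3.0], "t1": [3.0]},
            scale="log2",
        )
        assert fit_contrast(m, contrast)["s2"].iloc[0] == 0.0

    def test_single_sample_group_errors(self):
        m = make_matrix({"c0": [1.0], "c1": [1.0], "t0": [2.0]}, scale="log2")
        with pytest.raises(ValueError):
            fit_contrast(m, ContrastSpec("treatment", "control"))

    def test_linear_scale_rejected(self, contrast):
        m = make_matrix({"c0": [1.0], "c1": [1.0], "t0": [2.0], "t1": [2.0]})
        with pytest.raises(ScaleError):
            fit_contrast(m, contrast)

    def test_unnormalized_rejected(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [1.0], "t0": [2.0], "t1": [2.0]},
            scale="log2", normalized=False,
        )
        with pytest.raises(ValueError, match="unnormalized"):
            fit_contrast(m, contrast)


class TestEstimateHyper:
    def test_identical_variances_infinite_d0(self):
        h = estimate_hyper([0.02] * 10, df=4)
        assert np.isinf(h.d0)
        # point scale corrects the log-variance bias exactly
        expected = 0.02 * np.exp(-(special.digamma(2.0) - np.log(2.0)))
        assert h.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_recovery_from_prior(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, df = 4.0, 0.05, 4
        sigma2 = d0 * s0_sq / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        h = estimate_hyper(s2, df=df)
        assert h.d0 == pytest.approx(d0, rel=0.15)
        assert h.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_small_spread_gives_infinite_d0(self):
        # var(log s2) below trigamma(df/2): no excess spread to attribute
        # to the prior, so d0 -> infinity
        h = estimate_hyper([0.01, 0.02], df=4)
        assert np.isinf(h.d0)

    def test_finite_d0_solves_trigamma_equation(self):
        rng = np.random.default_rng(3)
        s2 = np.exp(rng.normal(-3, 2.0, 200))  # wide spread -> finite d0
        h = estimate_hyper(s2, df=4)
        assert np.isfinite(h.d0) and h.d0 > 0
        e_var = np.var(np.log(s2), ddof=1)
        # check against a dense grid on the trigamma equation
        grid = np.linspace(h.d0 * 0.5, h.d0 * 2, 20001)
        resid = np.abs(special.polygamma(1, grid / 2)
                       - (e_var - special.polygamma(1, 2.0)))
        assert abs(grid[np.argmin(resid)] - h.d0) < h.d0 * 1e-3

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_hyper([0.0, 0.0], df=4)


class TestModeratedT:
    def _fit(self, contrast, s2_target=0.01):
        m = make_matrix(
            {"c0": [0.9], "c1": [1.1], "c2": [1.0], "c3": [1.0],
             "t0": [2.0], "t1": [2.2]},
            scale="log2",
        )
        return fit_contrast(m, contrast)

    def test_posterior_variance_formula(self, contrast):
        out = moderated_t(self._fit(contrast), EBayesHyper(d0=4, s0_sq=0.05))
        # (4*0.05 + 4*0.01) / 8 = 0.03
        assert out["s2_post"].iloc[0] == pytest.approx(0.03, abs=1e-12)

    def test_d0_zero_equals_classical_t(self, contrast, log2_matrix_4v2):
        fit = fit_contrast(log2_matrix_4v2, contrast)
        out = moderated_t(fit, EBayesHyper(d0=0.0, s0_sq=1.0))
        ctrl = log2_matrix_4v2.values[[f"c{i}" for i in range(4)]]
        trt = log2_matrix_4v2.values[[f"t{i}" for i in range(2)]]
        t_ref, p_ref = sps.ttest_ind(trt, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_critical_t_gives_p_05(self, contrast):
        fit = self._fit(contrast)
        t_crit = 2.776445  # Student t 97.5% point at 4 df
        fit.loc[:, "log2fc"] = t_crit * np.sqrt(0.01 * (1 / 4 + 1 / 2))
        out = moderated_t(fit, EBayesHyper(d0=0.0, s0_sq=1.0))
        assert out["p"].iloc[0] == pytest.approx(0.0500, abs=1e-4)

    def test_zero_variance_flagged_not_error(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [1.0], "c2": [1.0], "c3": [1.0],
             "t0": [3.0], "t1": [3.0]},
            scale="log2",
        )
        fit = fit_contrast(m, contrast)
        out = moderated_t(fit, EBayesHyper(d0=0.0, s0_sq=1.0))
        assert out["degenerate_variance"].iloc[0]
        assert out["p"].iloc[0] == 0.0

    def test_infinite_d0_uses_normal_tail(self, contrast):
        fit = self._fit(contrast)
        out = moderated_t(fit, EBayesHyper(d0=np.inf, s0_sq=0.01))
        se = np.sqrt(0.01 * 0.75)
        t = 1.1 / se
        assert out["t_mod"].iloc[0] == pytest.approx(t, rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(2 * sps.norm.sf(t), rel=1e-12)


class TestBHAdjust:
    def brute_force(self, p):
        # literal step-up definition
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        out = np.empty(n)
        for i in range(n):
            candidates = [
                n / ranks[j] * p[j] for j in range(n) if ranks[j] >= ranks[i]
            ]
            out[i] = min(1.0, min(candidates))
        return out

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), self.brute_force(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        adj = bh_adjust(p)
        adj_perm = bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-14)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_inputs_rejected(self):
        for bad in ([1.5], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestClassifyDegs:
    def make(self, adj_p, log2fc):
        return pd.DataFrame({"adj_p": [adj_p], "log2fc": [log2fc], "p": [adj_p]})

    @pytest.mark.parametrize(
        "adj_p,log2fc,expected",
        [
            (0.04, 0.2, "up"),
            (0.04, 0.05, "ns"),
            (0.05, 2.0, "ns"),      # strict inequality on alpha
            (0.04, 0.1, "ns"),      # strict inequality on lfc
            (0.04, -0.1, "ns"),
            (0.04, -0.2, "down"),
        ],
    )
    def test_threshold_semantics(self, adj_p, log2fc, expected):
        out = classify_degs(self.make(adj_p, log2fc))
        assert out["status"].iloc[0] == expected


class TestNoiseFilter:
    def test_kept_probe(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [1.0], "c2": [1.0], "c3": [1.0],
             "t0": [2.0], "t1": [2.0]},
            scale="log2",
        )
        assert noise_filter(m, contrast) == ["g0"]

    def test_high_sd_dropped(self, contrast):
        m = make_matrix(
            {"c0": [0.0], "c1": [1.0], "c2": [2.0], "c3": [3.0],
             "t0": [2.0], "t1": [2.0]},
            scale="log2",
        )
        assert noise_filter(m, contrast) == []

    def test_distance_boundary_strict(self, contrast):
        m = make_matrix(
            {"c0": [1.0], "c1": [1.0], "c2": [1.0], "c3": [1.0],
             "t0": [1.5], "t1": [1.5]},
            scale="log2",
        )
        assert noise_filter(m, contrast) == []  # distance exactly 0.5


class TestTFSelectionAndIntersection:
    def stats_of(self, mapping):
        return pd.DataFrame(
            {"status": list(mapping.values())}, index=list(mapping.keys())
        )

    def test_select_tf_degs(self):
        stats_df = self.stats_of({"A": "up", "B": "down", "C": "up", "D": "ns"})
        out = select_tf_degs(stats_df, {"B", "C", "D"})
        assert set(out.index) == {"B", "C"}
        assert out.loc["B", "status"] == "down"

    def test_catalog_superset(self):
        stats_df = self.stats_of({"A": "up", "B": "down"})
        assert set(select_tf_degs(stats_df, {"A", "B", "Z"}).index) == {"A", "B"}

    def test_disjoint_and_empty(self):
        stats_df = self.stats_of({"A": "up"})
        assert select_tf_degs(stats_df, {"Z"}).empty
        with pytest.warns(UserWarning):
            assert select_tf_degs(stats_df, set()).empty

    def test_intersect_contrasts(self):
        a = self.stats_of({"x": "up", "y": "down"})
        b = self.stats_of({"x": "up", "y": "up"})
        out = intersect_contrasts(a, b, catalog={"x"})
        assert out["common_up"] == ["x"]
        assert out["common_down"] == []
        assert out["tf_flags"] == {"x": True}

    def test_intersect_idempotent_and_disjoint(self):
        a = self.stats_of({"x": "up", "y": "down"})
        same = intersect_contrasts(a, a)
        assert same["common_up"] == ["x"] and same["common_down"] == ["y"]
        b = self.stats_of({"z": "up"})
        out = intersect_contrasts(a, b)
        assert out["common_up"] == [] and out["common_down"] == []


class TestRunDea:
    def test_monotone_true_positives_in_effect_size(self, contrast):
        from tfenrich.dea import preprocess
        from tfenrich.synthetic import SimConfig, simulate_expression

        tp_counts = []
        for effect in (0.5, 1.0, 1.5, 2.0):
            cfg = SimConfig(n_probes=500, effect_size_log2=effect, seed=3)
            m, truth = simulate_expression(cfg)
            st_df = run_dea(preprocess(m), contrast)
            called = st_df.index[st_df["status"] != "ns"]
            tp_counts.append(int(truth.genes.loc[called, "is_de"].sum()))
        assert tp_counts == sorted(tp_counts)
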