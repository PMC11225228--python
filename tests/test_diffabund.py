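import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protometa.data import FeatureMatrix
from protometa.diffabund import (
    ContrastSpec,
    ModerationParams,
    bh_adjust,
    cell_means_design,
    concordance_t,
    cv_percent,
    estimate_moderation,
    fit_feature_models,
    moderated_t,
    ora_hypergeometric,
    overlap_sets,
    random_split_test,
    wilcoxon_rank_sum,
)
from conftest import make_annotation


def _log_matrix(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        values=pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{i}" for i in range(values.shape[1])],
        ),
        is_log=True,
    )


def _two_group_design(n_per_group):
    cols = {"g1": [1.0] * n_per_group + [0.0] * n_per_group,
            "g2": [0.0] * n_per_group + [1.0] * n_per_group}
    design = pd.DataFrame(cols)
    design.index = [f"s{i}" for i in range(2 * n_per_group)]
    return design


class TestFitFeatureModels:
    def test_two_group_coefficients_are_group_means(self, rng):
        y = rng.normal(size=(10, 8))
        m = _log_matrix(y)
        fit = fit_feature_models(m, _two_group_design(4))
        np.testing.assert_allclose(fit.beta[:, 0], y[:, :4].mean(axis=1))
        np.testing.assert_allclose(fit.beta[:, 1], y[:, 4:].mean(axis=1))

    def test_matches_normal_equations_oracle_with_missing(self, rng):
        n_samp, k = 12, 3
        X = np.column_stack([np.ones(n_samp), rng.normal(size=(n_samp, k - 1))])
        design = pd.DataFrame(X, columns=["int", "a", "b"],
                              index=[f"s{i}" for i in range(n_samp)])
        y = rng.normal(size=(40, n_samp))
        y[rng.random(y.shape) < 0.2] = np.nan
        m = _log_matrix(y)
        fit = fit_feature_models(m, design)
        for g in range(40):
            obs = ~np.isnan(y[g])
            if not fit.ok[g]:
                continue
            Xo, yo = X[obs], y[g, obs]
            beta_oracle = np.linalg.solve(Xo.T @ Xo, Xo.T @ yo)
            np.testing.assert_allclose(fit.beta[g], beta_oracle, atol=1e-10)
            resid = yo - Xo @ beta_oracle
            d = obs.sum() - 3
            if d > 0:
                assert fit.sigma2[g] == pytest.approx(resid @ resid / d, abs=1e-10)
                assert fit.df_residual[g] == d

    def test_saturated_feature_has_zero_residual_df(self, rng):
        y = rng.normal(size=(3, 2))
        m = _log_matrix(y)
        fit = fit_feature_models(m, _two_group_design(1))
        assert (fit.df_residual == 0).all()
        assert np.isnan(fit.sigma2).all()
        assert fit.ok.all()

    def test_rank_deficient_design_lists_aliased_coefficient(self, rng):
        design = _two_group_design(3)
        design["dup"] = design["g1"]
        m = _log_matrix(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError, match="dup"):
            fit_feature_models(m, design)

    def test_unlogged_matrix_rejected(self, rng):
        m = _log_matrix(rng.normal(size=(4, 6)))
        m.is_log = False
        with pytest.raises(ValueError, match="log"):
            fit_feature_models(m, _two_group_design(3))


class TestModeration:
    def test_equal_variances_give_point_mass_prior(self):
        mod = estimate_moderation([0.3] * 50, [5] * 50)
        assert math.isinf(mod.d0)
        assert mod.s0_sq == pytest.approx(0.3)

    def test_parameter_recovery_from_prior_draws(self, rng):
        d0, s0_sq, d_g, n = 4.0, 0.05, 4, 5000
        true_var = d0 * s0_sq / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(d_g, size=n) / d_g
        mod = estimate_moderation(s2, np.full(n, d_g))
        assert mod.d0 == pytest.approx(d0, rel=0.15)
        assert mod.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_heavy_dispersion_gives_small_finite_d0(self, rng):
        # variances spanning orders of magnitude: far more dispersed than
        # chi-square sampling noise, so the prior must be heavy-tailed
        s2 = 10.0 ** rng.uniform(-3, 3, size=500)
        mod = estimate_moderation(s2, np.full(500, 10))
        assert np.isfinite(mod.d0)
        assert mod.d0 < 2.0

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="10"):
            estimate_moderation([0.1] * 5, [4] * 5)


class TestModeratedT:
    def _random_fit(self, rng, n_feat=50, n_per_group=5):
        y = rng.normal(size=(n_feat, 2 * n_per_group))
        m = _log_matrix(y)
        return y, fit_feature_models(m, _two_group_design(n_per_group))

    def test_d0_zero_equals_classical_t(self, rng):
        y, fit = self._random_fit(rng)
        contrast = ContrastSpec("diff", {"g1": 1.0, "g2": -1.0})
        res = moderated_t(fit, contrast, ModerationParams(d0=0.0, s0_sq=1.0))
        classical = stats.ttest_ind(y[:, :5], y[:, 5:], axis=1).statistic
        np.testing.assert_allclose(res.table["t"].to_numpy(), classical, atol=1e-10)

    def test_d0_infinite_uses_pinned_variance_and_normal_reference(self, rng):
        y, fit = self._random_fit(rng)
        contrast = ContrastSpec("diff", {"g1": 1.0, "g2": -1.0})
        s0_sq = 0.7
        res = moderated_t(fit, contrast, ModerationParams(d0=math.inf, s0_sq=s0_sq))
        diff = y[:, :5].mean(axis=1) - y[:, 5:].mean(axis=1)
        expected_t = diff / np.sqrt(s0_sq * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(res.table["t"].to_numpy(), expected_t, atol=1e-10)
        expected_p = 2 * stats.norm.sf(np.abs(expected_t))
        np.testing.assert_allclose(res.table["p"].to_numpy(), expected_p, atol=1e-12)

    def test_matches_brute_force_reimplementation(self, rng):
        y, fit = self._random_fit(rng)
        contrast = ContrastSpec("diff", {"g1": 1.0, "g2": -1.0})
        mod = ModerationParams(d0=3.0, s0_sq=0.5)
        res = moderated_t(fit, contrast, mod)
        # independent oracle straight from the closed form
        for g in range(50):
            a, b = y[g, :5], y[g, 5:]
            beta = np.array([a.mean(), b.mean()])
            d = 8
            s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / d
            s_tilde2 = (mod.d0 * mod.s0_sq + d * s2) / (mod.d0 + d)
            t_oracle = (beta[0] - beta[1]) / np.sqrt(s_tilde2 * (1 / 5 + 1 / 5))
            assert res.table["t"].iloc[g] == pytest.approx(t_oracle, abs=1e-8)
            p_oracle = 2 * stats.t.sf(abs(t_oracle), mod.d0 + d)
            assert res.table["p"].iloc[g] == pytest.approx(p_oracle, abs=1e-10)

    def test_unknown_contrast_coefficient_rejected(self, rng):
        _, fit = self._random_fit(rng, n_feat=5)
        with pytest.raises(ValueError, match="g3"):
            moderated_t(fit, ContrastSpec("bad", {"g3": 1.0}),
                        ModerationParams(d0=1.0, s0_sq=1.0))


def bh_brute_force(p):
    """O(m^2) literal step-up: adj_i = min over j with p_j >= p_i of p_j*m/r_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [
            min(1.0, p[order[k]] * m / (k + 1)) for k in range(pos, m)
        ]
        adj[i] = min(candidates)
    return adj


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passes_through_without_counting(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)


class TestCvPercent:
    def test_constant_vector_is_zero(self):
        assert cv_percent([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computed_population_formula(self):
        # mu = 2, population SD = sqrt(2/3): CV = 40.8248...%
        assert cv_percent([1.0, 2.0, 3.0]) == pytest.approx(40.824829046386306)

    def test_scale_invariance_and_missing_dropped(self, rng):
        x = rng.lognormal(size=20)
        assert cv_percent(3.7 * x) == pytest.approx(cv_percent(x))
        with_nan = np.concatenate([x, [np.nan]])
        assert cv_percent(with_nan) == pytest.approx(cv_percent(x))

    def test_zero_mean_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            cv_percent([-1.0, 1.0])
        with pytest.raises(ValueError, match="2"):
            cv_percent([1.0])


def wilcoxon_exact_p(a, b):
    """Exhaustive-enumeration two-sided exact p for the Mann-Whitney W."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:na].sum() - na * (na + 1) / 2
    mu = na * (n - na) / 2
    count = total = 0
    for comb in itertools.combinations(range(n), na):
        w = ranks[list(comb)].sum() - na * (na + 1) / 2
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_fully_separated_groups_give_w_zero(self):
        w, _ = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == 0.0

    def test_identical_multisets_give_central_w(self):
        a = [1.0, 2.0, 2.0, 5.0]
        w, _ = wilcoxon_rank_sum(a, list(a))
        assert w == pytest.approx(len(a) ** 2 / 2)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 6), (5, 5), (8, 8)])
    def test_asymptotic_p_close_to_exact_enumeration(self, rng, na, nb):
        for _ in range(3):
            a = rng.normal(size=na)
            b = rng.normal(0.5, 1.0, size=nb)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(wilcoxon_exact_p(a, b), abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestOverlapSets:
    def test_identical_sets_share_everything(self):
        s = {"m1": {"A", "B"}, "m2": {"A", "B"}}
        summary = overlap_sets(s)
        assert summary.shared == 2
        assert summary.percent_largest == 100.0

    def test_partial_overlap_matches_enumeration(self):
        summary = overlap_sets({"m1": {"A", "B", "C"}, "m2": {"B", "C", "D"}})
        assert summary.shared == 2
        assert summary.unique == {"m1": 1, "m2": 1}
        assert summary.percent_largest == pytest.approx(50.0)

    def test_empty_sets_all_zero(self):
        summary = overlap_sets({"m1": set(), "m2": set()})
        assert summary.shared == 0
        assert summary.unique == {"m1": 0, "m2": 0}


class TestConcordance:
    def _result(self, t):
        from protometa.diffabund import DiffResult

        table = pd.DataFrame(
            {"t": t}, index=[f"f{i}" for i in range(len(t))]
        )
        return DiffResult(contrast="c", table=table)

    def test_self_and_negated_correlations(self, rng):
        t = rng.normal(size=20)
        res = self._result(t)
        assert concordance_t(res, res)[0] == pytest.approx(1.0)
        assert concordance_t(res, self._result(-t))[0] == pytest.approx(-1.0)
        assert concordance_t(res, res, method="pearson")[0] == pytest.approx(1.0)

    def test_too_few_shared_features_rejected(self):
        res = self._result([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="4"):
            concordance_t(res, res)


class TestRandomSplit:
    def _cohort(self, rng, n_feat=30):
        n_subj = 8
        sample_ids, conditions, methods, subjects = [], [], [], []
        for s in range(n_subj):
            for cond in ("NAT", "TT"):
                for meth in ("autoSP3", "MTBE-SP3"):
                    sample_ids.append(f"S{s}_{cond}_{meth}")
                    conditions.append(cond)
                    methods.append(meth)
                    subjects.append(f"S{s}")
        ann = make_annotation(sample_ids, conditions, methods, subjects)
        y = rng.normal(20, 1, size=(n_feat, len(sample_ids)))
        m = FeatureMatrix(
            values=pd.DataFrame(y, index=[f"f{i}" for i in range(n_feat)], columns=sample_ids),
            is_log=True,
        )
        return m, ann

    def test_same_seed_reproduces_the_split(self, rng):
        m, ann = self._cohort(rng)
        a = random_split_test(m, ann, seed=5)
        b = random_split_test(m, ann, seed=5)
        assert {k: v.groups for k, v in a.items()} == {k: v.groups for k, v in b.items()}

    def test_split_balanced_within_condition(self, rng):
        m, ann = self._cohort(rng)
        out = random_split_test(m, ann, seed=1)
        for method, split in out.items():
            tbl = ann.table[ann.table["method"] == method]
            for cond, stratum in tbl.groupby("condition"):
                labels = [split.groups.get(s) for s in stratum["sample_id"]]
                n1 = sum(1 for x in labels if x == "group1")
                n2 = sum(1 for x in labels if x == "group2")
                assert abs(n1 - n2) <= 1

    def test_null_split_rarely_significant(self, rng):
        m, ann = self._cohort(rng, n_feat=100)
        counts = [
            len(split.result.significant(0.05))
            for seed in range(5)
            for split in random_split_test(m, ann, seed=seed).values()
        ]
        assert np.mean(counts) <= 1.0


class TestOra:
    def test_exact_combinatorial_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        signif = {"g0", "g1", "g2", "g3"}
        sets = {"S": {"g0", "g1", "g2", "g3", "g4"}}
        table = ora_hypergeometric(signif, universe, sets)
        assert table.loc["S", "p"] == pytest.approx(5 / 210)
        assert table.loc["S", "overlap"] == 4

    def test_degenerate_cases_give_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        sets = {"whole": set(universe), "other": {"g0", "g1"}}
        table = ora_hypergeometric(set(), universe, sets)
        assert (table["p"] == 1.0).all()
        table = ora_hypergeometric({"g0", "g1", "g2"}, universe, {"whole": set(universe)})
        assert table.loc["whole", "p"] == pytest.approx(1.0)

    def test_signif_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_hypergeometric({"zz"}, {"g0"}, {"S": {"g0"}})


def test_cell_means_design_full_rank_for_paired_layout():
    sample_ids, conditions, methods, subjects = [], [], [], []
    for s in range(4):
        for cond in ("NAT", "TT"):
            for meth in ("autoSP3", "MTBE-SP3"):
                sample_ids.append(f"S{s}_{cond}_{meth}")
                conditions.append(cond)
                methods.append(meth)
                subjects.append(f"S{s}")
    ann = make_annotation(sample_ids, conditions, methods, subjects)
    design = cell_means_design(ann)
    X = design.to_numpy(dtype=float)
    assert np.linalg.matrix_rank(X) == X.shape[1]
    assert {"NAT_autoSP3", "NAT_MTBE-SP3", "TT_autoSP3", "TT_MTBE-SP3"} <= set(design.columns)


class TestBhProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    pvec = st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)

    @given(p=pvec)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_adjusted_values_dominate_raw_and_preserve_order(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()
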