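"""Correlation family, multiple-testing correction, group and AP tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aupheno import simulate, validate
from conftest import cohort_to_matrix, gaussian_matrix, tiny_cohort_config


def brute_pearson(x, y):
    """r from the definition; p via the exact t transform with n-2 df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def brute_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestPearson:
    def test_perfect_linear(self):
        n, r, p = validate.pearson_with_p([1, 2, 3], [2, 4, 6])
        assert (n, r) == (3, pytest.approx(1.0))

    def test_independent_streams_negligible(self):
        rng = np.random.default_rng(0)
        _, r, _ = validate.pearson_with_p(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(r) < 0.05

    def test_constant_input_is_error_not_zero(self):
        with pytest.raises(ValueError):
            validate.pearson_with_p([1.0, 1.0, 1.0], [1, 2, 3])

    def test_pairwise_complete_cases(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, 8, np.nan]
        n, r, _ = validate.pearson_with_p(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        got_n, got_r, got_p = validate.pearson_with_p(x, y)
        exp_r, exp_p = brute_pearson(x, y)
        assert got_r == pytest.approx(exp_r, abs=1e-12)
        assert got_p == pytest.approx(exp_p, rel=1e-8)


class TestBHAdjust:
    def test_three_value_step_up(self):
        np.testing.assert_allclose(validate.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(validate.bh_adjust([0.2]), [0.2])

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = validate.bh_adjust(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = validate.bh_adjust(p)
            np.testing.assert_allclose(q, brute_bh(p), atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            validate.bh_adjust([0.5, 1.2])


class TestPrimaryValidation:
    def test_family_size_and_bonferroni(self, small_matrix, small_clinical):
        res = validate.primary_validation(small_matrix, small_clinical)
        assert res.attrs["family_size"] == 53
        assert len(res) == 53
        assert res.attrs["bonferroni_alpha"] == pytest.approx(0.05 / 53)
        assert (res["bonferroni_significant"] == (res["p"] < 0.05 / 53)).all()
        # AU28 intensity skipped entirely
        assert not ((res["au"] == "AU28") & (res["metric"] == "intensity")).any()

    def test_family_size_invariant_to_cohort_size(self):
        co = simulate.generate_cohort(tiny_cohort_config(seed=17, n_case=15, n_control=12))
        m, _ = cohort_to_matrix(co)
        res = validate.primary_validation(m, simulate.clinical_frame(co))
        assert res.attrs["family_size"] == 53

    def test_wide_table_layout(self, small_matrix, small_clinical):
        res = validate.primary_validation(small_matrix, small_clinical)
        wide = validate.correlation_table_wide(res)
        assert wide.shape == (18, 3)
        assert np.isnan(wide.loc["AU28", "intensity"])

    def test_planted_coupling_has_minimal_q(self):
        """A cohort whose only rating coupling is r=0.4 with AU12 variation
        should put that test at the smallest q in most seeds."""
        wins = 0
        for seed in range(5):
            cfg = simulate.CohortConfig(
                n_case=120, n_control=80, seed=seed, fps=15, duration_mean_s=20,
                duration_jitter_s=1.0, contamination=0.0, effect_map={},
                rating_couplings={
                    "hisoc_item1": simulate.RatingCoupling(
                        weights={(12, "variation"): 1.0}, target_r=0.4
                    )
                },
            )
            co = simulate.generate_cohort(cfg)
            m, _ = cohort_to_matrix(co)
            res = validate.primary_validation(m, simulate.clinical_frame(co))
            best = res.sort_values("q").iloc[0]
            wins += (best["au"] == "AU12") and (best["metric"] == "variation")
        assert wins >= 4


class TestExploratory:
    def test_case_only_outcomes_restricted(self, small_matrix, small_clinical):
        out = validate.exploratory_correlations(small_matrix, small_clinical)
        n_cases = int((small_clinical["group"] == "case").sum())
        included = small_matrix.X.index
        n_case_inc = sum(
            small_clinical.set_index("id").loc[i, "group"] == "case" for i in included
        )
        assert (out["sans"]["n"] <= n_case_inc).all()
        assert (out["hisoc_total"]["n"] > n_case_inc).all()

    def test_sans_without_cases_errors(self, small_matrix, small_clinical):
        controls_only = small_clinical[small_clinical["group"] == "control"]
        with pytest.raises(ValueError):
            validate.exploratory_correlations(small_matrix, controls_only, outcomes=("sans",))

    def test_null_fdr_controlled(self):
        """Uncoupled cohorts: average fraction of q<0.05 stays below 0.05."""
        fracs = []
        for seed in range(6):
            co = simulate.generate_cohort(
                tiny_cohort_config(seed=seed + 50, n_case=20, n_control=15,
                                   effect_map={}, rating_couplings={})
            )
            m, _ = cohort_to_matrix(co)
            res = validate.primary_validation(m, simulate.clinical_frame(co))
            fracs.append((res["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_planted_negative_coupling_recovered_with_sign(self):
        cfg = simulate.CohortConfig(
            n_case=80, n_control=50, seed=23, fps=15, duration_mean_s=15,
            duration_jitter_s=1.0, contamination=0.0, effect_map={},
            rating_couplings={
                # target_r refers to the weighted composite, so a positive
                # weight with a negative target plants a negative link
                "caarms": simulate.RatingCoupling(
                    weights={(45, "variation"): 1.0}, target_r=-0.45, scope="case"
                )
            },
        )
        co = simulate.generate_cohort(cfg)
        m, _ = cohort_to_matrix(co)
        out = validate.exploratory_correlations(m, simulate.clinical_frame(co), outcomes=("caarms",))
        row = out["caarms"].query("au == 'AU45' and metric == 'variation'").iloc[0]
        assert row["r"] < -0.2


class TestGroupTests:
    def test_label_shuffle_p_not_systematically_small(self):
        rng = np.random.default_rng(3)
        ps = []
        for seed in range(10):
            fm = gaussian_matrix(30, 30, 1, seed)
            res = validate.group_univariate_tests(fm)
            ps.append(res["p"].iloc[0])
        assert (np.array(ps) < 0.05).sum() <= 2

    def test_planted_gap_survives_fdr(self):
        hits = 0
        for seed in range(20):
            fm = gaussian_matrix(75, 75, 10, seed, effect={0: 3.0})
            res = validate.group_univariate_tests(fm)
            hits += res.set_index("feature").loc["f0", "q"] < 0.05
        assert hits >= 19

    def test_irrelevant_covariate_barely_moves_p(self):
        deltas = []
        for seed in range(10):
            fm = gaussian_matrix(40, 40, 3, seed, effect={0: 1.0})
            rng = np.random.default_rng(seed + 100)
            clinical = pd.DataFrame(
                {"id": fm.X.index, "group": fm.labels.values,
                 "noise_cov": rng.normal(size=len(fm))}
            )
            res = validate.group_univariate_tests(fm, clinical, covariates=["noise_cov"])
            deltas.extend((res["p"] - res["p_adjusted"]).abs())
        assert np.mean(deltas) < 0.02

    def test_constant_feature_reported_undefined(self):
        fm = gaussian_matrix(10, 10, 3, 0)
        fm.X["f1"] = 2.0
        res = validate.group_univariate_tests(fm).set_index("feature")
        assert np.isnan(res.loc["f1", "p"]) and np.isnan(res.loc["f1", "q"])
        assert np.isfinite(res.loc["f0", "q"])


class TestAPSensitivity:
    def _cohort(self, seed=31, **kw):
        kw = {"n_case": 40, "n_control": 25, "ap_exposed_fraction": 0.4, **kw}
        cfg = tiny_cohort_config(seed=seed, **kw)
        co = simulate.generate_cohort(cfg)
        m, _ = cohort_to_matrix(co)
        return m, simulate.clinical_frame(co)

    def test_all_naive_errors_with_message(self):
        m, cl = self._cohort(seed=32, ap_exposed_fraction=0.0)
        with pytest.raises(ValueError, match="AP-exposed"):
            validate.ap_sensitivity(m, cl)

    def test_null_gating_near_alpha(self):
        m, cl = self._cohort(seed=33, ap_effect_map={})
        res = validate.ap_sensitivity(m, cl)
        frac = res["stage1"]["significant"].mean()
        assert frac < 0.2  # approximately the alpha fraction under the null

    def test_planted_exposed_suppression_reaches_stage_two(self):
        m, cl = self._cohort(
            seed=34,
            duration_mean_s=20.0,
            ap_effect_map={(23, "intensity"): -1.2, (26, "intensity"): -1.2},
        )
        res = validate.ap_sensitivity(m, cl)
        s1 = res["stage1"]
        flagged = set(s1.loc[s1["significant"], "variable"])
        assert {"AU23_intensity_mean", "AU26_intensity_mean"} <= flagged
        s2 = res["stage2"]
        sig_vs_control = s2[(s2["comparison"] == "exposed_vs_control") & s2["significant"]]
        assert {"AU23_intensity_mean", "AU26_intensity_mean"} <= set(sig_vs_control["variable"])


def test_results_object_summary(small_matrix, small_clinical):
    res = validate.ExpressivityValidation(small_matrix, small_clinical).fit()
    text = res.summary()
    assert "53 Pearson tests" in text
    assert "0.000943" in text
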