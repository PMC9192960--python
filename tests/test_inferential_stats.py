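"""Statistical layer: summary arithmetic, MANCOVA, regressions, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from decpipe.inferential_stats import (
    bonferroni,
    cohens_d_from_t,
    mancova_pillai,
    medication_interaction,
    pearson_test,
    pooled_t_from_summary,
    posthoc_group_regressions,
    required_n,
    symptom_regression,
    yates_chi2,
)


class TestPooledT:
    @pytest.mark.parametrize(
        "summary, expected_t, expected_df",
        [
            # demographic/psychometric group comparisons recomputed from printed summaries
            ((15.28, 9.49, 43, 1.13, 1.23, 24), 7.247, 65),   # depression, larger dataset
            ((33.05, 10.67, 43, 30.96, 11.98, 24), 0.735, 65),  # age
            ((14.71, 9.84, 21, 1.19, 1.52, 16), 5.430, 35),   # depression, smaller dataset
            ((12.42, 5.35, 43, 1.38, 1.21, 24), 9.937, 65),   # anxiety
            ((22.38, 4.40, 21, 22.63, 6.84, 16), -0.132, 35),  # age, smaller dataset
        ],
    )
    def test_printed_group_comparisons_reproduce(self, summary, expected_t, expected_df):
        res = pooled_t_from_summary(*summary)
        assert res.t == pytest.approx(expected_t, abs=0.005)
        assert res.df == expected_df

    def test_equal_means_null(self):
        res = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_unequal_means_refused(self):
        with pytest.raises(ValueError, match="infinite"):
            pooled_t_from_summary(5.0, 0.0, 10, 6.0, 0.0, 10)

    def test_round_trip_from_raw_data_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 20)
        res = pooled_t_from_summary(a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 20)
        ref = spstats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestYatesChi2:
    @pytest.mark.parametrize(
        "table, expected",
        [((21, 22, 10, 14), 0.095), ((18, 3, 12, 4), 0.161)],  # printed gender tables
    )
    def test_printed_gender_tables_reproduce(self, table, expected):
        assert yates_chi2(*table).chi2 == pytest.approx(expected, abs=0.0005)

    def test_proportional_table_is_zero(self):
        assert yates_chi2(10, 10, 5, 5).chi2 == 0.0

    def test_matches_scipy_continuity_corrected(self):
        a, b, c, d = 21, 22, 10, 14
        ref = spstats.chi2_contingency([[a, b], [c, d]], correction=True)
        res = yates_chi2(a, b, c, d)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_margin_refused(self):
        with pytest.raises(ValueError):
            yates_chi2(0, 0, 5, 5)


class TestCohensD:
    @pytest.mark.parametrize(
        "t, n1, n2, d, lo, hi",
        [(-2.908, 43, 24, 0.74, 0.23, 1.26), (-1.595, 21, 16, 0.53, -0.13, 1.19)],
    )
    def test_printed_effect_sizes_reproduce(self, t, n1, n2, d, lo, hi):
        es = cohens_d_from_t(t, n1, n2)
        assert es.d == pytest.approx(d, abs=0.005)
        assert es.ci_low == pytest.approx(lo, abs=0.01)
        assert es.ci_high == pytest.approx(hi, abs=0.01)

    def test_sign_invariance(self):
        assert cohens_d_from_t(2.5, 20, 20) == cohens_d_from_t(-2.5, 20, 20)

    def test_null_t(self):
        es = cohens_d_from_t(0.0, 15, 15)
        assert es.d == 0.0
        assert es.ci_low == pytest.approx(-es.ci_high)


class TestPearson:
    @pytest.mark.parametrize(
        "r, n, p",
        [(0.456, 21, 0.038), (0.608, 14, 0.021), (0.094, 29, 0.628),
         (0.198, 43, 0.203), (0.221, 43, 0.155)],
    )
    def test_printed_p_values_reproduce(self, r, n, p):
        # printed to 3 decimals from unrounded r; allow one unit in the last place extra
        assert pearson_test(r, n).p == pytest.approx(p, abs=0.002)

    @pytest.mark.parametrize(
        "r, n, lo, hi",
        [(0.328, 43, 0.030, 0.572), (0.456, 21, 0.030, 0.742), (0.094, 29, -0.282, 0.445)],
    )
    def test_printed_fisher_intervals_reproduce(self, r, n, lo, hi):
        res = pearson_test(r, n)
        assert res.ci_low == pytest.approx(lo, abs=0.001)
        assert res.ci_high == pytest.approx(hi, abs=0.001)

    def test_null_r(self):
        res = pearson_test(0.0, 30)
        assert res.p == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_degenerate_perfect_correlation(self):
        res = pearson_test(1.0, 10)
        assert res.p == 0.0
        assert res.degenerate

    def test_ci_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (10, 40, 160):
            res = pearson_test(0.4, n)
            assert res.ci_low <= res.r <= res.ci_high
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]


def _toy_cohort(rng, n_pat=43, n_con=24, effect=0.0, slope=0.0):
    n = n_pat + n_con
    group = np.array(["patient"] * n_pat + ["control"] * n_con)
    dec = rng.normal(0.05, 0.15, (n, 3))
    dec[:n_pat, 0] += effect
    ybocs = np.where(group == "patient",
                     25 + slope * dec[:, 0] + rng.normal(0, 4.3, n), np.nan)
    return pd.DataFrame(
        {
            "group": group,
            "age": rng.normal(30, 10, n),
            "gender": rng.integers(0, 2, n),
            "dvars": rng.lognormal(3.4, 0.3, n),
            "c1": dec[:, 0],
            "c2": dec[:, 1],
            "c3": dec[:, 2],
            "ybocs": ybocs,
            "medicated": np.where(group == "patient", rng.integers(0, 2, n), 0),
        }
    )


class TestMancova:
    def test_df_structure_at_n67(self, rng):
        tab = _toy_cohort(rng)
        res = mancova_pillai(tab[["c1", "c2", "c3"]].to_numpy(), tab.group,
                             tab[["age", "gender", "dvars"]].to_numpy())
        assert (res.df_hyp, res.df_err) == (3, 60)
        assert 0.0 <= res.pillai <= 1.0

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        tab = _toy_cohort(rng, effect=-0.11)
        tab["g"] = (tab.group == "patient").astype(float)
        res = mancova_pillai(tab[["c1", "c2", "c3"]].to_numpy(), tab.group,
                             tab[["age", "gender", "dvars"]].to_numpy())
        mv = MANOVA.from_formula("c1 + c2 + c3 ~ g + age + gender + dvars", data=tab)
        frame = mv.mv_test().results["g"]["stat"]
        assert res.pillai == pytest.approx(frame.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res.f == pytest.approx(frame.loc["Pillai's trace", "F Value"], rel=1e-6)
        assert res.df_hyp == int(frame.loc["Pillai's trace", "Num DF"])
        assert res.df_err == int(frame.loc["Pillai's trace", "Den DF"])

    def test_affine_rescaling_of_dv_invariance(self, rng):
        tab = _toy_cohort(rng, effect=-0.11)
        Y = tab[["c1", "c2", "c3"]].to_numpy()
        C = tab[["age", "gender", "dvars"]].to_numpy()
        a = mancova_pillai(Y, tab.group, C)
        Y2 = Y * np.array([10.0, 0.3, 5.0]) + np.array([1.0, -2.0, 0.5])
        b = mancova_pillai(Y2, tab.group, C)
        assert a.pillai == pytest.approx(b.pillai, abs=1e-10)

    def test_type_i_error_calibrated(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(5000 + rep)
            tab = _toy_cohort(rng)
            res = mancova_pillai(tab[["c1", "c2", "c3"]].to_numpy(), tab.group,
                                 tab[["age", "gender", "dvars"]].to_numpy())
            rejections += res.p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08

    def test_rank_deficient_design_refused(self, rng):
        tab = _toy_cohort(rng)
        C = tab[["age", "age", "dvars"]].to_numpy()  # duplicated covariate
        with pytest.raises(ValueError, match="rank"):
            mancova_pillai(tab[["c1", "c2", "c3"]].to_numpy(), tab.group, C)


class TestPosthocRegressions:
    def test_residual_df_62_at_n67(self, rng):
        tab = _toy_cohort(rng)
        res = posthoc_group_regressions(tab, ["c1", "c2", "c3"])
        assert all(r.df_resid == 62 for r in res)
        assert all(r.family_size == 3 for r in res)

    def test_residual_df_32_at_n37(self, rng):
        tab = _toy_cohort(rng, n_pat=21, n_con=16)
        res = posthoc_group_regressions(tab, ["c1"])
        assert res[0].df_resid == 32

    def test_group_sign_recovered_at_printed_effect_size(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(7000 + rep)
            tab = _toy_cohort(rng, effect=-0.74 * 0.15)
            res = posthoc_group_regressions(tab, ["c1"], family_size=1)[0]
            hits += res.term("group").beta < 0
        assert hits > 80

    def test_constant_group_refused(self, rng):
        tab = _toy_cohort(rng)
        tab["group"] = "patient"
        with pytest.raises(ValueError):
            posthoc_group_regressions(tab, ["c1"])

    def test_bonferroni_correction_applied(self, rng):
        tab = _toy_cohort(rng, effect=-0.2)
        res = posthoc_group_regressions(tab, ["c1", "c2", "c3"])[0]
        g = res.term("group")
        assert g.p_corrected == pytest.approx(min(1.0, 3 * g.p))


class TestSymptomRegression:
    def test_residual_df_39_at_n43(self, rng):
        tab = _toy_cohort(rng, slope=12.0)
        res = symptom_regression(tab[tab.group == "patient"], "ybocs", ["c1", "c2", "c3"])
        assert res.df_resid == 39

    def test_generating_connection_has_largest_t(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(9000 + rep)
            tab = _toy_cohort(rng, slope=12.157)
            res = symptom_regression(tab[tab.group == "patient"], "ybocs", ["c1", "c2", "c3"])
            ts = {t.name: abs(t.t) for t in res.terms if t.name != "intercept"}
            hits += max(ts, key=ts.get) == "c1"
        assert hits > 80

    def test_null_familywise_error_controlled(self):
        fw_errors = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(11_000 + rep)
            tab = _toy_cohort(rng, slope=0.0)
            res = symptom_regression(tab[tab.group == "patient"], "ybocs", ["c1", "c2", "c3"])
            fw_errors += any(t.p_corrected < 0.05 for t in res.terms if t.name != "intercept")
        assert fw_errors / n_reps <= 0.08

    def test_collinear_connections_refused(self, rng):
        tab = _toy_cohort(rng, slope=12.0)
        tab["c2"] = 2.0 * tab["c1"]
        with pytest.raises(ValueError, match="rank"):
            symptom_regression(tab[tab.group == "patient"], "ybocs", ["c1", "c2", "c3"])


class TestMedicationInteraction:
    def test_df_39_and_stratum_correlations(self, rng):
        tab = _toy_cohort(rng, slope=12.0)
        pat = tab[tab.group == "patient"]
        res, strata = medication_interaction(pat.ybocs.to_numpy(), pat.c1.to_numpy(),
                                             pat.medicated.to_numpy())
        assert res.df_resid == 39
        assert set(strata) <= {0, 1}

    def test_printed_stratum_p_value(self):
        assert pearson_test(0.608, 14).p == pytest.approx(0.021, abs=0.0005)

    def test_empty_stratum_refused(self, rng):
        tab = _toy_cohort(rng, slope=12.0)
        pat = tab[tab.group == "patient"]
        with pytest.raises(ValueError):
            medication_interaction(pat.ybocs.to_numpy(), pat.c1.to_numpy(),
                                   np.zeros(len(pat)))

    def test_null_interaction_centered_on_zero(self):
        ts = []
        for rep in range(100):
            rng = np.random.default_rng(13_000 + rep)
            tab = _toy_cohort(rng, slope=12.0)
            pat = tab[tab.group == "patient"]
            if pat.medicated.nunique() < 2:
                continue
            res, _ = medication_interaction(pat.ybocs.to_numpy(), pat.c1.to_numpy(),
                                            pat.medicated.to_numpy())
            ts.append(res.term("dec_x_medicated").t)
        assert abs(np.mean(ts)) < 3.0 * np.std(ts) / np.sqrt(len(ts))


class TestRequiredN:
    def test_matches_normal_approximation_oracle(self):
        # oracle: 2 * ceil(2 (z_{1-alpha} + z_{power})^2 / d^2) per the closed form
        z = spstats.norm.ppf
        d = 0.74
        oracle = 2 * int(np.ceil(2 * (z(0.95) + z(0.85)) ** 2 / d**2))
        exact = required_n(d, power=0.85, alpha=0.05, one_sided=True)
        assert abs(exact - oracle) <= 2
        assert exact == 54  # frozen exact noncentral-t answer

    def test_huge_effect_needs_minimum_n(self):
        assert required_n(50.0, power=0.85, alpha=0.05) == 4

    def test_power_half_alpha_half_parity(self):
        # brute-force scan: with one-sided alpha = 0.5 the critical value is ~0,
        # so any positive effect exceeds 50% power at the minimum n
        assert required_n(0.5, power=0.5, alpha=0.5, one_sided=True) == 4

    def test_invalid_inputs_refused(self):
        with pytest.raises(ValueError):
            required_n(-1.0)
        with pytest.raises(ValueError):
            required_n(0.5, power=1.5)


@settings(max_examples=50, deadline=None)
@given(p=st.floats(0.0, 1.0), m=st.integers(1, 20))
def test_bonferroni_cap_and_ordering(p, m):
    corrected = bonferroni(p, m)
    assert p <= corrected <= 1.0
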