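"""Descriptives, Student's t, chi-squared, mixed ANCOVA and Tukey post hocs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from hrvband import (
    CohortGenSpec,
    chi2_2x2,
    describe,
    generate_cohort,
    rm_ancova,
    students_t,
    tukey_posthoc,
)


class TestDescribe:
    def test_dose_vector_moments(self):
        """16 subjects at the 84 mg target and 2 held at 56 mg."""
        mean, sd, n = describe([84.0] * 16 + [56.0] * 2)
        assert mean == pytest.approx(80.9, abs=0.05)
        assert sd == pytest.approx(9.05, abs=0.005)
        assert n == 18

    def test_single_value_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning):
            mean, sd, n = describe([42.0])
        assert (mean, sd, n) == (42.0, 0.0, 1)

    def test_constant_vector_zero_sd(self):
        assert describe([5.0] * 10)[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestStudentsT:
    def test_age_row_from_printed_summaries(self):
        t, df, p = students_t((51.0, 9.4, 8), (59.2, 8.05, 10))
        assert abs(t) == pytest.approx(1.99, abs=0.005)
        assert df == 16

    def test_hrv_row_from_printed_summaries(self):
        t, _, p = students_t((5.37, 0.93, 8), (6.52, 0.91, 10))
        assert abs(t) == pytest.approx(2.62, abs=0.03)
        assert p < 0.05

    def test_identical_groups_give_zero(self):
        t, _, p = students_t((5.0, 1.0, 8), (5.0, 1.0, 10))
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_is_infinite(self):
        t, _, p = students_t((1.0, 0.0, 5), (2.0, 0.0, 5))
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_on_raw_data(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.2, 15)
        t, df, p = students_t(a, b)
        ref = sst.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_raw_equals_summary_input(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 30))
        b = rng.normal(0.3, 1.5, rng.integers(2, 30))
        raw = students_t(a, b)
        summ = students_t(describe(a), describe(b))
        assert raw[0] == pytest.approx(summ[0], abs=1e-10)
        assert raw[2] == pytest.approx(summ[2], abs=1e-10)


class TestChi2:
    def test_occupation_row(self):
        chi2, df, _ = chi2_2x2(4, 4, 6, 4)
        assert chi2 == pytest.approx(0.18, abs=0.005)
        assert df == 1

    def test_marital_status_row(self):
        chi2, _, _ = chi2_2x2(3, 5, 5, 5)
        assert chi2 == pytest.approx(0.28, abs=0.005)

    def test_proportional_table_is_zero(self):
        assert chi2_2x2(2, 2, 5, 5)[0] == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 3, 5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_matches_direct_sum_and_scipy(self, counts):
        a, b, c, d = counts
        chi2, _, p = chi2_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = np.sum((obs - expected) ** 2 / expected)
        assert chi2 == pytest.approx(brute, rel=1e-12)
        ref = sst.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-10)


def _planted_cohort(seed, effect=0.7):
    """Cohort with a pure group-by-time effect: responders shift by ``effect``."""
    rng = np.random.default_rng(seed)
    n = 18
    resp = np.array([True] * 8 + [False] * 10)
    y1 = rng.normal(6.0, 0.9, n)
    y2 = 0.7 * (y1 - 6.0) + 6.0 + rng.normal(0, 0.64, n) + np.where(resp, effect, 0.0)
    return pd.DataFrame({
        "responder": resp, "hrv_baseline": y1, "hrv_month1": y2,
        "age": rng.normal(55, 9, n),
        "gender": np.where(rng.random(n) < 0.5, "male", "female"),
    })


class TestRmAncova:
    def test_effect_table_shape_and_ranges(self, default_cohort):
        fit = rm_ancova(default_cohort)
        expected = {"time", "time_x_age", "time_x_gender", "time_x_group",
                    "age", "gender", "group"}
        assert set(fit.table.index) == expected
        assert (fit.table["F"] >= 0).all()
        assert fit.table["p"].between(0, 1).all()
        assert fit.table["eta2p"].between(0, 1).all()

    def test_matches_pingouin_mixed_anova_without_covariates(self):
        """Balanced two-group, two-timepoint data: F for group, time and the
        interaction agree with an independent mixed-ANOVA implementation."""
        pg = pytest.importorskip("pingouin")
        coh = generate_cohort(CohortGenSpec(n_responders=8, n_nonresponders=8, seed=3))
        fit = rm_ancova(coh, covariates=())
        long = pd.concat([
            pd.DataFrame({"id": coh["id"], "group": coh["responder"],
                          "time": t, "hrv": coh[f"hrv_{t}"]})
            for t in ("baseline", "month1")
        ])
        ref = pg.mixed_anova(long, dv="hrv", within="time", subject="id",
                             between="group").set_index("Source")
        assert fit.table.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert fit.table.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert fit.table.loc["time_x_group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_group_f_equals_squared_pooled_t_of_subject_means(self):
        coh = generate_cohort(CohortGenSpec(n_responders=9, n_nonresponders=9, seed=5))
        fit = rm_ancova(coh, covariates=())
        means = (coh["hrv_baseline"] + coh["hrv_month1"]) / 2
        t, _, _ = students_t(means[coh.responder].to_numpy(),
                             means[~coh.responder].to_numpy())
        assert fit.table.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_constant_outcomes_give_zero_f(self):
        coh = generate_cohort(CohortGenSpec(seed=1))
        coh["hrv_baseline"] = 6.0
        coh["hrv_month1"] = 6.0
        fit = rm_ancova(coh)
        assert (fit.table["F"] == 0).all()

    def test_single_gender_design_is_singular(self):
        coh = generate_cohort(CohortGenSpec(seed=2))
        coh["gender"] = "female"
        with pytest.raises(ValueError, match="singular.*gender"):
            rm_ancova(coh)

    def test_one_subject_per_group_rejected(self):
        coh = generate_cohort(CohortGenSpec(seed=2)).iloc[7:9]
        with pytest.raises(ValueError, match="2 subjects"):
            rm_ancova(coh)

    def test_eta2p_monotone_in_planted_effect(self):
        effects = [0.0, 0.4, 0.8, 1.6]
        med = []
        for e in effects:
            vals = [rm_ancova(_planted_cohort(s, e)).table.loc["time_x_group", "eta2p"]
                    for s in range(40)]
            med.append(np.median(vals))
        assert np.all(np.diff(med) > 0)

    def test_null_rejection_rate_calibrated(self):
        """time-by-group p-values are uniform under the null: alpha-level
        rejection stays near 0.05 (small-n Monte Carlo)."""
        rej = sum(
            rm_ancova(_planted_cohort(s, 0.0)).table.loc["time_x_group", "p"] < 0.05
            for s in range(600)
        )
        assert 0.02 <= rej / 600 <= 0.08

    def test_planted_interaction_detected(self):
        """A responder-only HRV increase yields a significant interaction with a
        large effect size in the median cohort."""
        ps, etas = [], []
        for s in range(80):
            fit = rm_ancova(_planted_cohort(s, 0.7))
            ps.append(fit.table.loc["time_x_group", "p"])
            etas.append(fit.table.loc["time_x_group", "eta2p"])
        assert np.median(ps) < 0.05
        assert np.median(etas) >= 0.14


class TestTukeyPosthoc:
    def test_six_rows_with_adjusted_p_at_least_unadjusted(self, default_cohort):
        ph = tukey_posthoc(rm_ancova(default_cohort))
        assert len(ph) == 6
        assert (ph["p_tukey"] >= ph["p_unadjusted"] - 1e-12).all()

    def test_identical_cells_give_zero_change(self):
        coh = generate_cohort(CohortGenSpec(seed=4))
        coh["hrv_month1"] = coh["hrv_baseline"]
        ph = tukey_posthoc(rm_ancova(coh))
        within = ph[ph.cell_a.str.split(":").str[1] == ph.cell_b.str.split(":").str[1]]
        assert np.allclose(within["mean_change"], 0.0, atol=1e-12)
        assert (within["p_tukey"] > 0.99).all()

    def test_unfitted_model_rejected(self):
        from hrvband.stats import RMAncovaFit

        with pytest.raises(ValueError, match="unfitted"):
            tukey_posthoc(RMAncovaFit(table=pd.DataFrame()))

    def test_familywise_error_controlled_under_null(self):
        """With no true effects, the chance that any of the six adjusted
        contrasts is called significant stays near the nominal 5%."""
        fw = 0
        reps = 300
        for s in range(reps):
            ph = tukey_posthoc(rm_ancova(_planted_cohort(s, 0.0)))
            fw += (ph["p_tukey"] < 0.05).any()
        assert fw / reps <= 0.09  # 0.05 plus three binomial SEs
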