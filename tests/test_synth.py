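"""Synthetic-data generators: determinism, positivity, conservation, distributional fidelity."""

import math

import numpy as np
import pytest

from hrvband import (
    CohortGenSpec,
    IbiGenSpec,
    generate_cohort,
    generate_ibi,
    inject_artifacts,
    render_ecg,
    students_t,
)


class TestGenerateIbi:
    def test_degenerate_spec_yields_constant_series(self):
        spec = IbiGenSpec(rsa_amp_ms=0.0, lf_amp_ms=0.0, noise_sd_ms=0.0)
        ibi = generate_ibi(spec)
        assert np.all(ibi.intervals_ms == spec.mean_ibi_ms)

    def test_same_seed_is_bit_identical(self):
        a = generate_ibi(IbiGenSpec(seed=99))
        b = generate_ibi(IbiGenSpec(seed=99))
        assert np.array_equal(a.intervals_ms, b.intervals_ms)
        assert np.array_equal(a.beat_times_ms, b.beat_times_ms)

    def test_different_seed_differs(self):
        a = generate_ibi(IbiGenSpec(seed=1))
        b = generate_ibi(IbiGenSpec(seed=2))
        assert not np.array_equal(a.intervals_ms, b.intervals_ms)

    def test_duration_and_cumulative_beats(self):
        ibi = generate_ibi(IbiGenSpec(duration_s=120))
        assert ibi.duration_s >= 120
        np.testing.assert_allclose(np.diff(ibi.beat_times_ms), ibi.intervals_ms)

    def test_amplitude_exceeding_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            IbiGenSpec(mean_ibi_ms=100.0, rsa_amp_ms=60.0)

    def test_interval_formula_matches_definition(self):
        spec = IbiGenSpec(rsa_amp_ms=30.0, noise_sd_ms=0.0, duration_s=60)
        ibi = generate_ibi(spec)
        t = ibi.beat_times_ms[:-1] / 1000.0
        expected = spec.mean_ibi_ms + spec.rsa_amp_ms * np.sin(
            2 * math.pi * spec.rsa_freq_hz * t
        )
        np.testing.assert_allclose(ibi.intervals_ms, expected, atol=1e-9)


class TestRenderEcg:
    def test_empty_series_rejected(self):
        from hrvband import IBISeries

        with pytest.raises(ValueError):
            empty = IBISeries(np.array([0.0]), np.array([]))
            render_ecg(empty)

    def test_beat_spacing_below_template_width_rejected(self):
        from hrvband import IBISeries

        tight = IBISeries.from_intervals(np.full(50, 60.0))
        with pytest.raises(ValueError, match="template"):
            render_ecg(tight)

    def test_low_sampling_rate_rejected(self, clean_sinusoid_ibi):
        with pytest.raises(ValueError, match="fs_hz"):
            render_ecg(clean_sinusoid_ibi, fs_hz=50.0)

    def test_record_length_matches_ibi_span(self, clean_sinusoid_ibi):
        ecg = render_ecg(clean_sinusoid_ibi, fs_hz=250.0)
        assert ecg.duration_s == pytest.approx(clean_sinusoid_ibi.duration_s, abs=1.0)


class TestInjectArtifacts:
    def test_missed_beat_sums_two_intervals(self):
        from hrvband import IBISeries

        base = IBISeries.from_intervals(np.array([800.0] * 20))
        out, planted = inject_artifacts(base, 1, 0, seed=0)
        assert out.n_intervals == 19
        assert planted[0].kind == "missed"
        j = planted[0].indices[0]
        assert out.intervals_ms[j] == 1600.0

    def test_zero_artifacts_is_identity(self, noisy_ibi):
        out, planted = inject_artifacts(noisy_ibi, 0, 0)
        assert out is noisy_ibi
        assert planted == []

    @pytest.mark.parametrize("n_missed,n_spurious", [(3, 0), (0, 3), (4, 4)])
    def test_total_time_conserved(self, noisy_ibi, n_missed, n_spurious):
        out, _ = inject_artifacts(noisy_ibi, n_missed, n_spurious, seed=5)
        rounded_total = np.sum(np.rint(noisy_ibi.intervals_ms))
        assert np.sum(out.intervals_ms) == rounded_total

    def test_too_many_artifacts_rejected(self, noisy_ibi):
        with pytest.raises(ValueError, match="too many"):
            inject_artifacts(noisy_ibi, noisy_ibi.n_intervals // 4, 1)

    def test_spurious_split_is_unequal(self):
        from hrvband import IBISeries

        base = IBISeries.from_intervals(np.array([800.0] * 20))
        out, planted = inject_artifacts(base, 0, 1, seed=3)
        i, j = planted[0].indices
        assert out.intervals_ms[i] + out.intervals_ms[j] == 800.0
        assert out.intervals_ms[i] != out.intervals_ms[j]


class TestGenerateCohort:
    def test_group_sizes_and_responder_rule(self, default_cohort):
        assert default_cohort["responder"].sum() == 8
        assert (~default_cohort["responder"]).sum() == 10
        frac = (default_cohort["bdi_baseline"] - default_cohort["bdi_month1"]) \
            / default_cohort["bdi_baseline"]
        assert np.all((frac >= 0.30) == default_cohort["responder"])

    def test_same_seed_reproducible(self):
        a = generate_cohort(CohortGenSpec(seed=11))
        b = generate_cohort(CohortGenSpec(seed=11))
        assert a.equals(b)

    def test_zero_sd_gives_identical_subjects(self):
        spec = CohortGenSpec(
            hrv_baseline={"responder": (5.0, 0.0), "nonresponder": (6.0, 0.0)},
            seed=2,
        )
        coh = generate_cohort(spec)
        assert coh.loc[coh.responder, "hrv_baseline"].nunique() == 1
        assert coh.loc[~coh.responder, "hrv_baseline"].nunique() == 1

    def test_large_sample_moments_match_spec(self):
        """Empirical group means/SDs land within 3 SE of the configured values."""
        spec = CohortGenSpec(n_responders=500, n_nonresponders=500, seed=21)
        coh = generate_cohort(spec)
        for group, flag in (("responder", True), ("nonresponder", False)):
            mu, sd = spec.hrv_baseline[group]
            vals = coh.loc[coh.responder == flag, "hrv_baseline"]
            assert abs(vals.mean() - mu) < 3 * sd / np.sqrt(500)
            assert abs(vals.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * 499)
            mu_a, sd_a = spec.age[group]
            ages = coh.loc[coh.responder == flag, "age"]
            assert abs(ages.mean() - mu_a) < 4 * sd_a / np.sqrt(500)

    def test_monte_carlo_baseline_hrv_t_matches_printed_moments(self):
        """Mean two-sample t across cohorts sits near the value implied by the
        published group means/SDs (5.37 +/- 0.93 vs 6.52 +/- 0.91 at n = 8/10)."""
        ts = []
        for s in range(300):
            coh = generate_cohort(CohortGenSpec(seed=s))
            t, _, _ = students_t(
                coh.loc[~coh.responder, "hrv_baseline"].to_numpy(),
                coh.loc[coh.responder, "hrv_baseline"].to_numpy(),
            )
            ts.append(t)
        assert 2.2 < np.mean(ts) < 3.1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortGenSpec(n_responders=1)
        with pytest.raises(ValueError):
            CohortGenSpec(hrv_rho=1.5)
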