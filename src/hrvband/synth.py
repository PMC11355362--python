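"""Synthetic data generators: IBI series, rendered ECG traces, and two-timepoint cohorts.

The generators produce data with the statistical structure the analysis
pipeline assumes — a respiratory-band (0.12–0.40 Hz) sinusoidal modulation
of heart period, optional low-frequency drift, beat-timing jitter, planted
rhythm artifacts, and responder/non-responder cohorts whose group moments
default to the published baseline characteristics of the esketamine
treatment-resistant-depression sample this pipeline was designed around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ECGRecord, IBISeries

__all__ = [
    "IbiGenSpec",
    "CohortGenSpec",
    "PlantedArtifact",
    "generate_ibi",
    "render_ecg",
    "inject_artifacts",
    "generate_cohort",
]


@dataclass
class IbiGenSpec:
    """Parameters of a synthetic inter-beat-interval series.

    Defaults describe a resting adult: mean heart period 800 ms (75 bpm)
    with a 40 ms respiratory sinus arrhythmia at 0.25 Hz (15 breaths/min)
    and 5 ms of white beat-timing jitter, recorded for 3 minutes.
    """

    duration_s: float = 180.0
    mean_ibi_ms: float = 800.0
    rsa_freq_hz: float = 0.25
    rsa_amp_ms: float = 40.0
    lf_freq_hz: float = 0.05
    lf_amp_ms: float = 0.0
    noise_sd_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 < self.rsa_freq_hz):
            raise ValueError("rsa_freq_hz must be positive")
        if self.lf_amp_ms and not (0.0 < self.lf_freq_hz < 0.12):
            raise ValueError("lf_freq_hz must lie below the 0.12 Hz band edge")
        if self.rsa_amp_ms < 0 or self.lf_amp_ms < 0 or self.noise_sd_ms < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if self.mean_ibi_ms <= 2 * (self.rsa_amp_ms + self.lf_amp_ms):
            raise ValueError(
                "mean_ibi_ms must exceed twice the summed modulation amplitudes "
                f"({self.mean_ibi_ms} <= 2*({self.rsa_amp_ms} + {self.lf_amp_ms})) "
                "so that intervals stay positive"
            )


def generate_ibi(spec: IbiGenSpec) -> IBISeries:
    """Generate a synthetic IBI series.

    Interval ``k``, beginning at beat time ``t_k``, is::

        mean_ibi_ms + rsa_amp_ms*sin(2*pi*rsa_freq_hz*t_k)
                    + lf_amp_ms*sin(2*pi*lf_freq_hz*t_k) + e_k

    with ``e_k`` i.i.d. Gaussian jitter of SD ``noise_sd_ms``. Beats
    accumulate until the series spans at least ``duration_s``. The same
    seed yields a bit-identical series.
    """
    rng = np.random.default_rng(spec.seed)
    intervals: list[float] = []
    t_ms = 0.0
    end_ms = spec.duration_s * 1000.0
    while t_ms < end_ms:
        t_s = t_ms / 1000.0
        iv = (
            spec.mean_ibi_ms
            + spec.rsa_amp_ms * math.sin(2 * math.pi * spec.rsa_freq_hz * t_s)
            + spec.lf_amp_ms * math.sin(2 * math.pi * spec.lf_freq_hz * t_s)
        )
        if spec.noise_sd_ms > 0:
            iv += rng.normal(0.0, spec.noise_sd_ms)
        if iv <= 0:
            raise ValueError(
                f"generated a non-positive interval ({iv:.1f} ms) at t={t_s:.1f} s; "
                "reduce modulation amplitudes or noise SD relative to mean_ibi_ms"
            )
        intervals.append(iv)
        t_ms += iv
    return IBISeries.from_intervals(np.array(intervals))


# -- ECG rendering ------------------------------------------------------------

_QRS_R_WIDTH_MS = 12.0   # half-width of the raised-cosine R deflection
_QRS_S_WIDTH_MS = 24.0
_TEMPLATE_SPAN_MS = 80.0


def _qrs_template(fs_hz: float) -> tuple[np.ndarray, int]:
    """A fixed narrow biphasic QRS-like pulse; returns (template, index of R peak)."""
    half = int(round(_TEMPLATE_SPAN_MS / 2 * fs_hz / 1000.0))
    t_ms = (np.arange(2 * half + 1) - half) * 1000.0 / fs_hz
    r = np.where(
        np.abs(t_ms) <= _QRS_R_WIDTH_MS,
        0.5 * (1 + np.cos(np.pi * t_ms / _QRS_R_WIDTH_MS)),
        0.0,
    )
    s_center = _QRS_R_WIDTH_MS + _QRS_S_WIDTH_MS / 2
    s = np.where(
        np.abs(t_ms - s_center) <= _QRS_S_WIDTH_MS / 2,
        -0.25 * (0.5 * (1 + np.cos(2 * np.pi * (t_ms - s_center) / _QRS_S_WIDTH_MS))),
        0.0,
    )
    return r + s, half


def render_ecg(
    ibi: IBISeries, fs_hz: float = 1000.0, snr_db: Optional[float] = 30.0, seed: int = 0
) -> ECGRecord:
    """Render a synthetic single-lead ECG with one QRS-like pulse per beat.

    The R peak of each pulse is placed at the nearest sample to the beat
    time; Gaussian noise is added at the requested signal-to-noise ratio.
    ``snr_db=-inf`` (or ``None``) produces pure noise with no cardiac
    signal — a negative control for detector failure paths.
    """
    if fs_hz < 100:
        raise ValueError("fs_hz must be at least 100 Hz for R-peak timing")
    if ibi.n_intervals == 0:
        raise ValueError("empty IBI series")
    if np.min(ibi.intervals_ms) < _TEMPLATE_SPAN_MS:
        raise ValueError(
            f"beat spacing ({np.min(ibi.intervals_ms):.0f} ms) shorter than the "
            f"QRS template width ({_TEMPLATE_SPAN_MS:.0f} ms)"
        )
    template, peak_off = _qrs_template(fs_hz)
    margin = len(template)
    n = int(round((ibi.beat_times_ms[-1] - ibi.beat_times_ms[0]) * fs_hz / 1000.0)) + 2 * margin
    x = np.zeros(n)
    rel_ms = ibi.beat_times_ms - ibi.beat_times_ms[0]
    pure_noise = snr_db is None or snr_db == -np.inf
    if not pure_noise:
        for bt in rel_ms:
            c = int(round(bt * fs_hz / 1000.0)) + margin
            lo, hi = c - peak_off, c + peak_off + 1
            x[lo:hi] += template
    sig_power = float(np.mean(x**2)) if not pure_noise else 0.0
    rng = np.random.default_rng(seed)
    if pure_noise:
        x = rng.normal(0.0, 0.2, size=n)
    elif np.isfinite(snr_db):
        noise_sd = math.sqrt(sig_power / 10 ** (snr_db / 10.0))
        x = x + rng.normal(0.0, noise_sd, size=n)
    start_s = ibi.beat_times_ms[0] / 1000.0 - margin / fs_hz
    return ECGRecord(fs_hz=fs_hz, samples=x, start_time_s=start_s)


# -- artifact injection -------------------------------------------------------


@dataclass
class PlantedArtifact:
    """Ground truth for one injected rhythm artifact."""

    kind: str             # "missed" or "spurious"
    indices: list[int]    # interval indices occupied in the *output* series


def inject_artifacts(
    ibi: IBISeries, n_missed: int, n_spurious: int, seed: int = 0
) -> tuple[IBISeries, list[PlantedArtifact]]:
    """Plant missed-beat and spurious-beat artifacts into an IBI series.

    A missed beat replaces two adjacent intervals by their sum; a spurious
    beat splits one interval into two unequal parts (smaller part 25–45%
    of the original). Total elapsed time is conserved exactly: the series
    is rounded to integer milliseconds before injection (the resolution of
    ECG-derived intervals). Returns the modified series together with the
    planted positions as ground truth.
    """
    if n_missed < 0 or n_spurious < 0:
        raise ValueError("artifact counts must be non-negative")
    if n_missed + n_spurious == 0:
        return ibi, []
    if n_missed + n_spurious >= ibi.n_intervals / 4:
        raise ValueError(
            f"too many artifacts ({n_missed + n_spurious}) for {ibi.n_intervals} intervals"
        )
    rng = np.random.default_rng(seed)
    intervals = [int(v) for v in np.rint(ibi.intervals_ms)]
    planted: list[PlantedArtifact] = []

    kinds = ["missed"] * n_missed + ["spurious"] * n_spurious
    rng.shuffle(kinds)

    def occupied() -> set[int]:
        occ: set[int] = set()
        for art in planted:
            for i in art.indices:
                occ.update({i - 1, i, i + 1})
        return occ

    for kind in kinds:
        occ = occupied()
        if kind == "missed":
            candidates = [
                j for j in range(len(intervals) - 1) if j not in occ and (j + 1) not in occ
            ]
        else:
            candidates = [j for j in range(len(intervals)) if j not in occ]
        if not candidates:
            raise ValueError("could not place all artifacts without overlap")
        j = int(rng.choice(candidates))
        if kind == "missed":
            merged = intervals[j] + intervals[j + 1]
            intervals[j : j + 2] = [merged]
            for art in planted:
                art.indices = [i - 1 if i > j else i for i in art.indices]
            planted.append(PlantedArtifact("missed", [j]))
        else:
            frac = rng.uniform(0.25, 0.45)
            if rng.random() < 0.5:
                frac = 1.0 - frac
            a = int(round(intervals[j] * frac))
            b = intervals[j] - a
            intervals[j : j + 1] = [a, b]
            for art in planted:
                art.indices = [i + 1 if i > j else i for i in art.indices]
            planted.append(PlantedArtifact("spurious", [j, j + 1]))

    out = IBISeries.from_intervals(
        np.array(intervals, dtype=float), t0_ms=float(ibi.beat_times_ms[0])
    )
    return out, planted


# -- cohort generation --------------------------------------------------------


def _group_params(resp: tuple, nonresp: tuple) -> dict:
    return {"responder": resp, "nonresponder": nonresp}


@dataclass
class CohortGenSpec:
    """Parameters of a synthetic two-timepoint treatment cohort.

    Defaults reproduce the published group structure of an n=18 intranasal
    esketamine cohort: 8 responders (≥30% BDI reduction at one month) with
    baseline band-limited HRV 5.37 ± 0.93 ln(ms²) rising to 6.04 ± 0.72,
    and 10 non-responders at 6.52 ± 0.91 falling slightly to 6.04 ± 0.80.
    ``hrv_rho`` is the within-subject baseline→follow-up HRV correlation
    (test–retest stability); the default 0.7 matches the paired-contrast
    standard errors such cohorts exhibit. ``hrv_bdi_rho`` couples a
    subject's HRV level to their BDI trajectory and defaults to 0.
    """

    n_responders: int = 8
    n_nonresponders: int = 10
    hrv_baseline: dict = field(default_factory=lambda: _group_params((5.37, 0.93), (6.52, 0.91)))
    hrv_followup: dict = field(default_factory=lambda: _group_params((6.04, 0.72), (6.04, 0.80)))
    bdi_baseline: dict = field(default_factory=lambda: _group_params((37.1, 10.5), (34.4, 8.02)))
    bdi_reduction_fraction: dict = field(default_factory=lambda: _group_params((0.37, 0.10), (0.04, 0.10)))
    age: dict = field(default_factory=lambda: _group_params((51.0, 9.4), (59.2, 8.05)))
    gender_p_male: dict = field(default_factory=lambda: _group_params(0.5, 0.6))
    hrv_rho: float = 0.7
    hrv_bdi_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ValueError("need at least 2 subjects per group")
        for d in (self.hrv_baseline, self.hrv_followup, self.bdi_baseline,
                  self.bdi_reduction_fraction, self.age):
            for g, (_, sd) in d.items():
                if sd < 0:
                    raise ValueError(f"negative SD for group {g!r}")
        if not (-1.0 <= self.hrv_rho <= 1.0 and -1.0 <= self.hrv_bdi_rho <= 1.0):
            raise ValueError("correlations must lie in [-1, 1]")


# Table-1-style auxiliary covariates, (mean, sd) or P(flag) per group.
_AUX_CONTINUOUS = {
    "education_years": _group_params((14.9, 2.6), (14.5, 3.4)),
    "bmi": _group_params((26.8, 5.21), (26.9, 3.99)),
    "lifetime_mde": _group_params((3.75, 2.92), (3.8, 1.75)),
    "flx_equiv_mg": _group_params((60.6, 23.8), (54.5, 24.1)),
}
_AUX_FLAGS = {
    "unemployed": _group_params(0.5, 0.6),
    "unmarried": _group_params(3 / 8, 0.5),
    "smoker": _group_params(0.5, 0.4),
}


def generate_cohort(spec: CohortGenSpec) -> pd.DataFrame:
    """Draw a synthetic cohort as one row per subject.

    HRV at the two timepoints is bivariate normal per group with
    correlation ``hrv_rho``. Follow-up BDI is baseline × (1 − r) with a
    per-subject reduction ``r`` drawn around the group mean and truncated
    so that group membership is consistent with the ≥30% responder rule.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, n in (("responder", spec.n_responders), ("nonresponder", spec.n_nonresponders)):
        mu_b, sd_b = spec.hrv_baseline[group]
        mu_f, sd_f = spec.hrv_followup[group]
        mu_bdi, sd_bdi = spec.bdi_baseline[group]
        mu_r, sd_r = spec.bdi_reduction_fraction[group]
        mu_age, sd_age = spec.age[group]
        p_male = spec.gender_p_male[group]
        for _ in range(n):
            sid += 1
            z1, z2, z3 = rng.normal(size=3)
            hrv_base = mu_b + sd_b * z1
            hrv_month1 = mu_f + sd_f * (
                spec.hrv_rho * z1 + math.sqrt(1 - spec.hrv_rho**2) * z2
            )
            # inclusion criterion: BDI > 19 at baseline
            bdi_base = max(20.0, mu_bdi + sd_bdi * (
                spec.hrv_bdi_rho * z1 + math.sqrt(1 - spec.hrv_bdi_rho**2) * z3
            ))
            r = mu_r + sd_r * rng.normal() if sd_r > 0 else mu_r
            # keep the trajectory consistent with group membership
            if group == "responder":
                r = max(r, 0.305)  # margin keeps the >=30% rule robust to rounding
            else:
                r = min(r, 0.295)
            bdi_month1 = max(0.0, bdi_base * (1.0 - r))
            age = float(np.clip(mu_age + sd_age * rng.normal(), 18, 70)) if sd_age > 0 else mu_age
            row = {
                "id": f"S{sid:03d}",
                "age": age,
                "gender": "male" if rng.random() < p_male else "female",
                "dose_mg": 84.0 if rng.random() < 16 / 18 else 56.0,
                "bdi_baseline": bdi_base,
                "bdi_month1": bdi_month1,
                "hrv_baseline": hrv_base,
                "hrv_month1": hrv_month1,
            }
            for col, params in _AUX_CONTINUOUS.items():
                m, s = params[group]
                v = m + s * rng.normal() if s > 0 else m
                if col == "lifetime_mde":
                    v = max(1, int(round(v)))
                row[col] = v
            for col, params in _AUX_FLAGS.items():
                row[col] = bool(rng.random() < params[group])
            rows.append(row)
    df = pd.DataFrame(rows)
    df["responder"] = (df["bdi_baseline"] - df["bdi_month1"]) / df["bdi_baseline"] >= 0.30
    return df
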