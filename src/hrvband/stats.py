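"""Group-level statistics for two-timepoint treatment cohorts.

Covers the analysis set used for a responder vs non-responder comparison:
descriptive summaries, pooled-variance Student's t (from raw data or from
printed (mean, sd, n) summaries), uncorrected Pearson chi-squared on 2x2
tables, a repeated-measures ANCOVA (between factor = group, within factor
= time with two levels, continuous and dichotomous covariates, Type III
sums of squares, partial eta-squared per error stratum), and Tukey
studentized-range post hocs on the covariate-adjusted group-by-time cell
means.

With exactly two timepoints the mixed model decomposes exactly into two
orthogonal univariate strata: the between stratum analyses the
per-subject mean of the two measurements, the within stratum their
difference. Covariates are centred and the factors effect-coded, so each
single-df Type III sum of squares is the drop-one-column SS and the
"time" main effect is the test of the within-stratum intercept at the
covariate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "Subject", "REQUIRED_COHORT_COLUMNS",
    "describe", "students_t", "chi2_2x2",
    "rm_ancova", "tukey_posthoc",
    "RMAncovaFit",
]


@dataclass
class Subject:
    """One study participant's covariates and outcomes at two timepoints."""

    id: str
    age: float
    gender: str                      # "male" | "female"
    bdi_baseline: float
    bdi_month1: float
    hrv_baseline: float              # ln(ms^2)
    hrv_month1: float                # ln(ms^2)
    education_years: float = np.nan
    unemployed: bool = False
    unmarried: bool = False
    bmi: float = np.nan
    smoker: bool = False
    lifetime_mde: float = np.nan
    flx_equiv_mg: float = np.nan
    dose_mg: float = np.nan
    responder: bool = False


REQUIRED_COHORT_COLUMNS = [
    "id", "age", "gender", "bdi_baseline", "bdi_month1",
    "hrv_baseline", "hrv_month1",
]


# -- simple statistics --------------------------------------------------------

def describe(values) -> tuple[float, float, int]:
    """Return (mean, sample SD, n); SD uses the n-1 denominator."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.size == 1:
        warnings.warn("sample SD undefined for n=1; reporting 0", stacklevel=2)
        return float(values[0]), 0.0, 1
    return float(np.mean(values)), float(np.std(values, ddof=1)), int(values.size)


def _as_summary(x) -> tuple[float, float, int]:
    """Interpret ``x`` as (mean, sd, n) if a 3-tuple, else summarise raw data."""
    if isinstance(x, tuple) and len(x) == 3:
        m, sd, n = x
        if n < 1 or sd < 0:
            raise ValueError(f"invalid summary {x}")
        return float(m), float(sd), int(n)
    return describe(x)


def students_t(group_a, group_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student's t.

    Each group is either raw values or a ``(mean, sd, n)`` tuple, so
    published tables can be checked without raw data. Returns
    ``(t, df, p)`` with ``t`` signed as group_a minus group_b and a
    two-sided p. Zero pooled variance yields t = +/-inf (p = 0) for
    unequal means and t = 0 (p = 1) for equal means.
    """
    ma, sa, na = _as_summary(group_a)
    mb, sb, nb = _as_summary(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = ma - mb
    if se == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, diff)), df, 0.0
    t = diff / se
    p = 2 * sst.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    Table layout: rows are groups, columns are categories, counts
    ``[[a, b], [c, d]]``. Returns ``(chi2, df=1, p)``.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    expected = np.outer(rows, cols) / total
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    return chi2, 1, float(sst.chi2.sf(chi2, 1))


# -- repeated-measures ANCOVA -------------------------------------------------

_WITHIN_EFFECTS = ["time", "time_x_age", "time_x_gender", "time_x_group"]
_BETWEEN_EFFECTS = ["age", "gender", "group"]


@dataclass
class RMAncovaFit:
    """Fitted mixed between-within model (two timepoints).

    ``table`` holds F, p and partial eta-squared per effect; the
    remaining fields carry what the Tukey post hocs need: coefficients
    and covariance per stratum, the group prediction rows at covariate
    means, cell sizes and the residual df.
    """

    table: pd.DataFrame
    group_levels: tuple = ("nonresponder", "responder")
    s_means: dict = field(default_factory=dict)      # adjusted mean of (y1+y2)/2 per group
    d_means: dict = field(default_factory=dict)      # adjusted mean of (y2-y1) per group
    s_cov: dict = field(default_factory=dict)        # prediction variances/covariances
    d_cov: dict = field(default_factory=dict)
    df_error: int = 0
    n_per_group: dict = field(default_factory=dict)


def _drop_column_ss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Type III SS per column of an effect-coded design, plus the full-model SSE."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    sse_full = float(np.sum((y - X @ beta) ** 2))
    ss = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xr = np.delete(X, j, axis=1)
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        ss[j] = float(np.sum((y - Xr @ br) ** 2)) - sse_full
    return ss, sse_full


def _find_aliased(X: np.ndarray, names: list[str]) -> str:
    for j in range(X.shape[1]):
        col = X[:, j]
        others = np.delete(X, j, axis=1)
        bh, _, _, _ = np.linalg.lstsq(others, col, rcond=None)
        resid = col - others @ bh
        if np.sum(resid**2) < 1e-10 * max(1.0, np.sum(col**2)):
            return names[j]
    return "unknown"


def _design(cohort: pd.DataFrame, covariates: tuple,
            between: str = "responder") -> tuple[np.ndarray, list[str], np.ndarray]:
    n = len(cohort)
    g = np.where(cohort[between].to_numpy(bool), 1.0, -1.0)
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "gender":
            ge = np.where(cohort["gender"].astype(str).str.lower() == "male", 1.0, -1.0)
            cols.append(ge - ge.mean())
        else:
            v = cohort[cov].to_numpy(float)
            cols.append(v - v.mean())
        names.append(cov)
    return np.column_stack(cols), names, g


def rm_ancova(
    cohort: pd.DataFrame,
    outcome: str = "hrv",
    within: tuple = ("baseline", "month1"),
    between: str = "responder",
    covariates: tuple = ("age", "gender"),
) -> RMAncovaFit:
    """Mixed between-within ANCOVA for a two-timepoint outcome.

    ``cohort`` needs columns ``{outcome}_{t}`` for each timepoint, a
    boolean ``responder`` column (the between factor) and the covariate
    columns. Effects reported: time, time x covariate interactions,
    time x group (within stratum) and each covariate plus group (between
    stratum), each with F, p and partial eta-squared computed against its
    stratum's error term.
    """
    y1 = cohort[f"{outcome}_{within[0]}"].to_numpy(float)
    y2 = cohort[f"{outcome}_{within[1]}"].to_numpy(float)
    if np.any(~np.isfinite(y1)) or np.any(~np.isfinite(y2)):
        raise ValueError("missing or non-finite outcome values")
    n = len(cohort)
    n_resp = int(cohort[between].astype(bool).sum())
    if n_resp < 2 or n - n_resp < 2:
        raise ValueError("need at least 2 subjects per group")

    X, names, g = _design(cohort, covariates, between)
    df_error = n - X.shape[1]
    if df_error < 1:
        raise ValueError("not enough subjects for the requested model")

    s = (y1 + y2) / 2.0
    d = y2 - y1
    rows = []
    try:
        for stratum, y in (("between", s), ("within", d)):
            ss, sse = _drop_column_ss(X, y)
            mse = sse / df_error
            for j, name in enumerate(names):
                if stratum == "between" and name == "intercept":
                    continue  # grand mean, not a reported effect
                effect = name if stratum == "between" else (
                    "time" if name == "intercept" else f"time_x_{name}"
                )
                F = ss[j] / mse if mse > 0 else 0.0
                rows.append({
                    "effect": effect,
                    "F": float(max(F, 0.0)),
                    "p": float(sst.f.sf(max(F, 0.0), 1, df_error)) if mse > 0 else 1.0,
                    "eta2p": float(ss[j] / (ss[j] + sse)) if (ss[j] + sse) > 0 else 0.0,
                    "df1": 1,
                    "df2": df_error,
                })
    except np.linalg.LinAlgError:
        raise ValueError(
            f"singular design: effect {_find_aliased(X, names)!r} is aliased"
        ) from None

    order = _WITHIN_EFFECTS + _BETWEEN_EFFECTS
    table = (pd.DataFrame(rows).set_index("effect")
             .reindex([e for e in order if e in {r['effect'] for r in rows}]))

    # adjusted group means and their prediction (co)variances per stratum
    fit = RMAncovaFit(table=table, df_error=df_error,
                      n_per_group={"responder": n_resp, "nonresponder": n - n_resp})
    XtX_inv = np.linalg.inv(X.T @ X)
    pred_rows = {}
    for group, code in (("nonresponder", -1.0), ("responder", 1.0)):
        r = np.zeros(X.shape[1])
        r[0] = 1.0
        r[1] = code
        pred_rows[group] = r  # covariates at their means = centred 0
    for label, y in (("s", s), ("d", d)):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        mse = sse / df_error
        means = {grp: float(r @ beta) for grp, r in pred_rows.items()}
        cov = {
            (ga, gb): float(mse * (pred_rows[ga] @ XtX_inv @ pred_rows[gb]))
            for ga in pred_rows for gb in pred_rows
        }
        if label == "s":
            fit.s_means, fit.s_cov = means, cov
        else:
            fit.d_means, fit.d_cov = means, cov
    return fit


# -- Tukey post hocs ----------------------------------------------------------

_CELLS = [
    ("baseline", "nonresponder"), ("baseline", "responder"),
    ("month1", "nonresponder"), ("month1", "responder"),
]
_PAIR_ORDER = [  # published table ordering of the six pairwise contrasts
    (("baseline", "nonresponder"), ("baseline", "responder")),
    (("baseline", "nonresponder"), ("month1", "nonresponder")),
    (("baseline", "nonresponder"), ("month1", "responder")),
    (("baseline", "responder"), ("month1", "nonresponder")),
    (("baseline", "responder"), ("month1", "responder")),
    (("month1", "nonresponder"), ("month1", "responder")),
]


def tukey_posthoc(fit: RMAncovaFit) -> pd.DataFrame:
    """All pairwise Tukey comparisons among the four group-by-time cells.

    Cell means are the covariate-adjusted predictions
    ``s_g -/+ d_g / 2`` (baseline / follow-up). Each contrast's variance
    combines the two orthogonal strata; p-values use the studentized
    range distribution with k = 4 means on the model's residual df, so
    every adjusted p is at least the unadjusted t-based p.
    """
    if not fit.s_means:
        raise ValueError("unfitted model")

    def cell(time: str, group: str) -> tuple[float, float, float]:
        c_t = -0.5 if time == "baseline" else 0.5
        return fit.s_means[group], fit.d_means[group], c_t

    rows = []
    for (ta, ga), (tb, gb) in _PAIR_ORDER:
        sa, da, ca = cell(ta, ga)
        sb, db, cb = cell(tb, gb)
        diff = (sa + ca * da) - (sb + cb * db)
        # between-stratum part: s_ga - s_gb ; within part: ca*d_ga - cb*d_gb
        var_s = fit.s_cov[(ga, ga)] + fit.s_cov[(gb, gb)] - 2 * fit.s_cov[(ga, gb)]
        var_d = (ca**2 * fit.d_cov[(ga, ga)] + cb**2 * fit.d_cov[(gb, gb)]
                 - 2 * ca * cb * fit.d_cov[(ga, gb)])
        se = float(np.sqrt(var_s + var_d))
        if se > 0:
            q = abs(diff) * np.sqrt(2.0) / se
            p_tukey = float(sst.studentized_range.sf(q, len(_CELLS), fit.df_error))
            p_unadj = float(2 * sst.t.sf(abs(diff) / se, fit.df_error))
        else:
            p_tukey = p_unadj = 1.0 if diff == 0 else 0.0
        rows.append({
            "cell_a": f"{ta}:{ga}", "cell_b": f"{tb}:{gb}",
            "mean_change": float(diff), "se": se,
            "p_tukey": min(p_tukey, 1.0), "p_unadjusted": p_unadj,
        })
    return pd.DataFrame(rows)
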