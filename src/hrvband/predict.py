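"""Treatment-response classification and baseline-HRV response prediction.

A patient counts as a responder when their depression score (BDI) falls by
at least 30% of baseline after one month of treatment. Baseline
band-limited HRV is then evaluated as a predictor of that binary outcome
via (i) a univariate logistic regression reported as an odds ratio with a
Wald 95% CI, and (ii) an ROC analysis: tie-corrected rank (Mann–Whitney)
AUC with the operating point chosen by Youden's J. Lower baseline HRV
predicts response, so scores enter the ROC negated by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats as sst

__all__ = ["LogisticFit", "RocSummary", "classify_responder", "logistic_fit",
           "roc_summary", "rank_auc"]

RESPONDER_FRACTION = 0.30


def classify_responder(bdi_baseline: float, bdi_followup: float,
                       fraction: float = RESPONDER_FRACTION) -> bool:
    """True when the score dropped by at least ``fraction`` of baseline (inclusive)."""
    if bdi_baseline <= 0:
        raise ValueError("baseline score must be positive")
    if bdi_followup < 0:
        raise ValueError("follow-up score must be non-negative")
    return (bdi_baseline - bdi_followup) / bdi_baseline >= fraction


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of response on a single score."""

    coef: float                 # slope on the score
    se: float                   # Wald standard error of the slope
    intercept: float
    or_point: float             # exp(coef)
    or_ci_low: float
    or_ci_high: float
    p: float                    # Wald two-sided p for the slope
    converged: bool = True
    separated: bool = False     # complete/quasi-complete separation detected


@dataclass
class RocSummary:
    """ROC discrimination summary at the Youden-optimal operating point."""

    auc: float
    threshold: float            # on the original score scale
    sensitivity: float          # percent
    specificity: float          # percent
    accuracy: float             # percent
    direction: str              # "lower" or "higher" score predicts the positive class
    logistic: Optional[LogisticFit] = None
    n_pos: int = 0
    n_neg: int = 0


def logistic_fit(score, label) -> LogisticFit:
    """Fit ``P(label=1) = expit(a + b*score)`` by maximum likelihood.

    Reports the slope with Wald SE, the odds ratio ``exp(b)`` per unit of
    score and its 95% Wald CI. Complete separation is surfaced via the
    ``separated`` flag (with a warning) rather than a silently divergent
    estimate.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    if len(score) != len(label) or len(score) < 6:
        raise ValueError("need matched score/label arrays with n >= 6")
    if label.min() == label.max():
        raise ValueError("both classes must be present")
    X = sm.add_constant(score)
    separated = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(label, X).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation can abort the optimiser
            res = sm.Logit(label, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
            separated = True
        for w in caught:
            msg = str(w.message).lower()
            if "separation" in msg:
                separated = True
            if "converge" in msg:
                converged = False
    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
    except Exception:
        bse = np.full(2, np.nan)
    coef, se = float(params[1]), float(bse[1])
    if not separated and (abs(coef) > 50 or not np.isfinite(se) or se > 1e4):
        separated = True
    if separated:
        warnings.warn("complete or quasi-complete separation: slope is unbounded",
                      stacklevel=2)
    z = sst.norm.ppf(0.975)
    if np.isfinite(se):
        ci = (np.exp(min(coef - z * se, 700.0)), np.exp(min(coef + z * se, 700.0)))
    else:
        ci = (0.0, np.inf)
    pval = 2 * sst.norm.sf(abs(coef / se)) if np.isfinite(se) and se > 0 else np.nan
    return LogisticFit(
        coef=coef, se=se, intercept=float(params[0]),
        or_point=float(np.exp(coef)), or_ci_low=float(ci[0]), or_ci_high=float(ci[1]),
        p=float(pval), converged=converged and not separated, separated=separated,
    )


def rank_auc(score, label) -> float:
    """Tie-corrected Mann–Whitney AUC: P(score_pos > score_neg) + 0.5*P(tie)."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(bool)
    n_pos = int(label.sum())
    n_neg = int((~label).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sst.rankdata(score)
    return float((ranks[label].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_summary(score, label, direction: str = "lower",
                fit_logistic: bool = True) -> RocSummary:
    """ROC discrimination of a binary outcome by a continuous score.

    ``direction="lower"`` (the default) means a *lower* score predicts
    the positive class, as for baseline HRV and treatment response; the
    score is negated internally so the reported AUC is above 0.5 for an
    informative marker. The operating threshold maximises Youden's
    J = sensitivity + specificity - 1 over all observed cutpoints (ties
    broken towards higher specificity); sensitivity, specificity and
    accuracy are reported at that threshold, in percent.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(bool)
    s = -score if direction == "lower" else score
    auc = rank_auc(s, label)
    n_pos = int(label.sum())
    n_neg = int((~label).sum())

    best = None
    for thr in np.unique(s):
        pred = s >= thr
        sens = float(np.sum(pred & label)) / n_pos
        spec = float(np.sum(~pred & ~label)) / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    pred = s >= thr
    acc = float(np.mean(pred == label))
    logistic = logistic_fit(score, label) if fit_logistic else None
    return RocSummary(
        auc=auc,
        threshold=float(-thr if direction == "lower" else thr),
        sensitivity=100 * sens, specificity=100 * spec, accuracy=100 * acc,
        direction=direction, logistic=logistic, n_pos=n_pos, n_neg=n_neg,
    )
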