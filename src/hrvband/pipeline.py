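"""End-to-end orchestration: cohort table (± recordings) to the four result tables.

``run_pipeline`` reproduces the full analysis layout of a two-timepoint
responder study: a descriptives table with between-group tests, the
repeated-measures ANCOVA table, the Tukey post-hoc table, and the
logistic/ROC summary for baseline HRV as a response predictor. All
outputs are plain pandas DataFrames; ``write_report`` serialises them as
tab-separated text plus a human-readable summary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import stats as cs
from . import predict as rp
from .io import PipelineConfig

__all__ = ["run_pipeline", "write_report"]

_CONTINUOUS_VARS = [
    ("age", "Age (years)"),
    ("education_years", "Education (years)"),
    ("bmi", "BMI"),
    ("lifetime_mde", "Lifetime MDE (n)"),
    ("flx_equiv_mg", "FLX equivalents (mg)"),
    ("dose_mg", "ESK-NS dose (mg)"),
    ("bdi_baseline", "BDI (baseline)"),
    ("hrv_baseline", "HRV (baseline, ln(ms^2))"),
]
_FLAG_VARS = [
    ("gender", "Gender (male)"),
    ("unemployed", "Occupation (unemployed)"),
    ("unmarried", "Marital status (unmarried)"),
    ("smoker", "Smoking"),
]


def _descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    resp = cohort[cohort["responder"]]
    nonresp = cohort[~cohort["responder"]]
    rows = []
    for col, label in _CONTINUOUS_VARS:
        if col not in cohort.columns or cohort[col].isna().any():
            continue
        mr, sr, nr = cs.describe(resp[col])
        mn, sn, nn = cs.describe(nonresp[col])
        t, df, p = cs.students_t((mr, sr, nr), (mn, sn, nn))
        rows.append({
            "variable": label, "kind": "continuous",
            "responders": f"{mr:.2f} +/- {sr:.2f}",
            "nonresponders": f"{mn:.2f} +/- {sn:.2f}",
            "statistic": t, "test": "t", "p": p,
        })
    for col, label in _FLAG_VARS:
        if col not in cohort.columns:
            continue
        flags = (cohort[col].astype(str).str.lower() == "male"
                 if col == "gender" else cohort[col].astype(bool))
        a = int(flags[cohort["responder"]].sum())
        b = int((~flags[cohort["responder"]]).sum())
        c = int(flags[~cohort["responder"]].sum())
        d = int((~flags[~cohort["responder"]]).sum())
        try:
            chi2, _, p = cs.chi2_2x2(a, b, c, d)
        except ValueError:
            continue  # degenerate margin: category absent in the sample
        rows.append({
            "variable": label, "kind": "categorical",
            "responders": f"{a}/{a + b}", "nonresponders": f"{c}/{c + d}",
            "statistic": chi2, "test": "chi2", "p": p,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame) -> dict:
    """Run descriptives, ANCOVA, post hocs and the ROC/logistic prediction.

    ``cohort`` must carry the two-timepoint BDI and HRV columns; the
    responder flag is (re)derived from the configured BDI-reduction rule
    so the grouping is always consistent with the configuration.
    """
    cohort = cohort.copy()
    cohort["responder"] = [
        rp.classify_responder(b, f, config.responder_fraction)
        for b, f in zip(cohort["bdi_baseline"], cohort["bdi_month1"])
    ]
    n_resp = int(cohort["responder"].sum())
    if n_resp < 2 or len(cohort) - n_resp < 2:
        raise ValueError(
            f"need at least 2 subjects per group (responders={n_resp}, "
            f"non-responders={len(cohort) - n_resp})"
        )
    tables: dict = {"descriptives": _descriptives(cohort)}
    fit = cs.rm_ancova(cohort, outcome="hrv")
    tables["ancova"] = fit.table.reset_index()
    tables["posthoc"] = cs.tukey_posthoc(fit)
    roc = rp.roc_summary(cohort["hrv_baseline"].to_numpy(),
                         cohort["responder"].to_numpy(), direction="lower")
    lg = roc.logistic
    tables["roc"] = pd.DataFrame([{
        "auc": roc.auc, "threshold": roc.threshold,
        "sensitivity_pct": roc.sensitivity, "specificity_pct": roc.specificity,
        "accuracy_pct": roc.accuracy,
        "logit_coef": lg.coef, "logit_se": lg.se,
        "or_point": lg.or_point, "or_ci_low": lg.or_ci_low, "or_ci_high": lg.or_ci_high,
        "logit_p": lg.p, "separated": lg.separated,
    }])
    tables["cohort"] = cohort
    return tables


def write_report(tables: dict, out_dir) -> Path:
    """Write each table as TSV plus a human-readable ``report.txt``; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("descriptives", "ancova", "posthoc", "roc", "cohort"):
        tables[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)

    roc = tables["roc"].iloc[0]
    lines = ["HRV treatment-response analysis", "=" * 34, ""]
    lines.append("Baseline descriptives (responders vs non-responders)")
    for _, r in tables["descriptives"].iterrows():
        lines.append(
            f"  {r['variable']:<28} {r['responders']:>16} vs {r['nonresponders']:>16}"
            f"   {r['test']}={r['statistic']:.2f}, p={r['p']:.3f}"
        )
    lines.append("")
    lines.append("Repeated-measures ANCOVA on HRV (time x group, age & gender covariates)")
    for _, r in tables["ancova"].iterrows():
        lines.append(
            f"  {r['effect']:<16} F={r['F']:>7.3f}  p={r['p']:.3f}  eta2p={r['eta2p']:.2f}"
        )
    lines.append("")
    lines.append("Tukey post hocs on adjusted group-by-time cell means")
    for _, r in tables["posthoc"].iterrows():
        lines.append(
            f"  {r['cell_a']:<22} vs {r['cell_b']:<22} "
            f"diff={r['mean_change']:>7.3f} (SE {r['se']:.3f})  p={r['p_tukey']:.3f}"
        )
    lines.append("")
    lines.append("Baseline HRV as response predictor")
    lines.append(
        f"  AUC={roc['auc']:.3f}  threshold={roc['threshold']:.2f} ln(ms^2)  "
        f"sens={roc['sensitivity_pct']:.1f}%  spec={roc['specificity_pct']:.1f}%  "
        f"acc={roc['accuracy_pct']:.1f}%"
    )
    lines.append(
        f"  logistic slope={roc['logit_coef']:.3f} (SE {roc['logit_se']:.3f}), "
        f"OR={roc['or_point']:.3f} [{roc['or_ci_low']:.2f}-{roc['or_ci_high']:.2f}], "
        f"p={roc['logit_p']:.3f}"
    )
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
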