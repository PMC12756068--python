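"""Cohort-level report assembly.

Turns a lesion-by-metric table into the standard result blocks of a
quantitative-DWI lesion study: benign-vs-malignant group statistics with
diagnostic performance per metric, prognostic-label associations among the
malignant lesions, molecular-subtype comparisons with Bonferroni-adjusted
pairwise follow-up, a Spearman correlation matrix between metrics and label
status, inter-reader ICCs when duplicate-reader columns are present, and a
multivariable logistic combination of the significant metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort_stats as cs

__all__ = ["metric_columns", "diagnostic_report", "label_report",
           "subtype_report", "spearman_matrix", "icc_report", "full_report"]

LABEL_COLUMNS = ("ER", "PR", "HER2", "Ki67", "ALN")


def metric_columns(df: pd.DataFrame) -> list[str]:
    """Metric columns of a cohort table (everything numeric and non-auxiliary)."""
    skip = {"lesion_id", "malignant"}
    return [c for c in df.columns
            if c not in skip and not c.endswith("__reader2")
            and np.issubdtype(df[c].dtype, np.number)]


def diagnostic_report(df: pd.DataFrame, metrics=None, alpha: float = 0.05) -> pd.DataFrame:
    """Benign-vs-malignant comparison and ROC performance per metric."""
    metrics = metrics or metric_columns(df)
    mal = df["malignant"].to_numpy(dtype=bool)
    rows = []
    for m in metrics:
        x = df.loc[~df["malignant"], m].to_numpy(dtype=float)   # benign
        y = df.loc[df["malignant"], m].to_numpy(dtype=float)
        test = cs.mann_whitney_u(x, y)
        roc = cs.roc_analysis(df[m].to_numpy(dtype=float), mal, positive_low="auto")
        rows.append({
            "metric": m,
            "benign_mean": x.mean(), "benign_sd": x.std(ddof=1),
            "malignant_mean": y.mean(), "malignant_sd": y.std(ddof=1),
            "U": test.statistic, "p": test.p_value,
            "significant": test.p_value < alpha,
            "auc": roc.auc, "auc_ci_low": roc.ci[0], "auc_ci_high": roc.ci[1],
            "sensitivity_pct": roc.sensitivity, "specificity_pct": roc.specificity,
            "cutoff": roc.cutoff, "positive_low": roc.positive_low,
        })
    return pd.DataFrame(rows)


def label_report(df: pd.DataFrame, label: str, metrics=None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Positive-vs-negative comparison of each metric among malignant lesions."""
    metrics = metrics or metric_columns(df)
    sub = df[df["malignant"]]
    neg = sub[sub[label] == "negative"]
    pos = sub[sub[label] == "positive"]
    rows = []
    for m in metrics:
        x, y = neg[m].to_numpy(dtype=float), pos[m].to_numpy(dtype=float)
        test = cs.mann_whitney_u(x, y)
        rows.append({"metric": m,
                     "negative_mean": x.mean(), "negative_sd": x.std(ddof=1),
                     "positive_mean": y.mean(), "positive_sd": y.std(ddof=1),
                     "U": test.statistic, "p": test.p_value,
                     "significant": test.p_value < alpha})
    return pd.DataFrame(rows)


def subtype_report(df: pd.DataFrame, metrics=None, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis across molecular subtypes with adjusted pairwise p-values."""
    metrics = metrics or metric_columns(df)
    sub = df[df["malignant"]]
    names = [s for s in sub["subtype"].unique() if s]
    rows = []
    for m in metrics:
        groups = [sub.loc[sub["subtype"] == s, m].to_numpy(dtype=float) for s in names]
        omnibus = cs.kruskal_wallis(groups)
        row = {"metric": m, "H": omnibus.statistic, "p": omnibus.p_value,
               "significant": omnibus.p_value < alpha}
        for (a, b), res in cs.pairwise_bonferroni(groups, names).items():
            row[f"p_adj[{a} vs {b}]"] = res.adjusted_p
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_matrix(df: pd.DataFrame, metrics=None,
                    labels=LABEL_COLUMNS) -> pd.DataFrame:
    """Spearman rho between each metric and each binary label (malignant rows)."""
    metrics = metrics or metric_columns(df)
    sub = df[df["malignant"]]
    out = pd.DataFrame(index=metrics, columns=list(labels), dtype=float)
    pvals = out.copy()
    for lab in labels:
        status = (sub[lab] == "positive").to_numpy(dtype=float)
        for m in metrics:
            res = cs.spearman_rho(sub[m].to_numpy(dtype=float), status)
            out.loc[m, lab] = res.statistic
            pvals.loc[m, lab] = res.p_value
    out.attrs["p_values"] = pvals
    return out


def icc_report(df: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Inter-reader ICC(2,1) per metric with a duplicate-reader column."""
    metrics = metrics or metric_columns(df)
    rows = []
    for m in metrics:
        col2 = f"{m}__reader2"
        if col2 not in df.columns:
            continue
        ratings = df[[m, col2]].to_numpy(dtype=float)
        res = cs.icc_two_way_random(ratings)
        rows.append({"metric": m, "icc": res.statistic,
                     "ci_low": res.extra["ci95"][0], "ci_high": res.extra["ci95"][1],
                     "interpretation": res.extra["interpretation"]})
    return pd.DataFrame(rows)


def full_report(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """All report blocks for one cohort table, as plain dict/DataFrame values."""
    metrics = metric_columns(df)
    diag = diagnostic_report(df, metrics, alpha)
    out = {
        "diagnostic": diag,
        "labels": {lab: label_report(df, lab, metrics, alpha)
                   for lab in LABEL_COLUMNS if lab in df.columns},
        "subtype": subtype_report(df, metrics, alpha) if "subtype" in df.columns else None,
        "spearman": spearman_matrix(
            df, metrics, [l for l in LABEL_COLUMNS if l in df.columns]),
    }
    icc = icc_report(df, metrics)
    if len(icc):
        out["icc"] = icc
    sig = diag.loc[diag["significant"], "metric"].tolist()
    if len(sig) >= 2:
        X = df[sig].to_numpy(dtype=float)
        roc = cs.combined_model_auc(X, df["malignant"].to_numpy(dtype=bool))
        out["combined"] = {"metrics": sig, "auc": roc.auc, "auc_ci": roc.ci,
                           "sensitivity_pct": roc.sensitivity,
                           "specificity_pct": roc.specificity,
                           "perfect_separation": roc.extra["perfect_separation"]}
    return out
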