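"""Lesion-level statistical battery.

Nonparametric group comparison (Mann-Whitney U, Kruskal-Wallis with
Bonferroni-adjusted pairwise follow-up), Spearman rank correlation,
inter-reader reproducibility (ICC(2,1), two-way random effects, absolute
agreement, single measure), and diagnostic-performance analysis (empirical
ROC/AUC with Youden-index cutoffs, DeLong variance and paired AUC
comparison, in-sample multivariable logistic combination).

Orientation note: for diffusion metrics in breast lesions *low* values
typically indicate malignancy, so ROC analysis auto-orients by default and
reports the direction it used rather than silently flipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "RocResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "pairwise_bonferroni",
    "spearman_rho",
    "icc_two_way_random",
    "roc_analysis",
    "auc_mann_whitney",
    "delong_variance",
    "delong_test",
    "combined_model_auc",
]

#: pooled-sample size at or below which the Mann-Whitney p-value is computed
#: by exhaustive enumeration of group assignments (exact even under ties)
EXACT_MWU_MAX_N = 10

SPEARMAN_BANDS = [(0.75, "good"), (0.50, "moderate"), (0.25, "mild"), (0.0, "poor")]
ICC_BANDS = [(0.75, "excellent"), (0.60, "good"), (0.40, "fair"), (0.0, "poor")]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    direction: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    cutoff: float
    sensitivity: float          # percent
    specificity: float          # percent
    positive_low: bool
    extra: dict = field(default_factory=dict)


def _band(value: float, bands) -> str:
    for lo, name in bands:
        if abs(value) >= lo:
            return name
    return bands[-1][1]


# ---------------------------------------------------------------------------
# rank tests

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample from midranks (ties get average rank)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return r_x - x.size * (x.size + 1) / 2.0


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For pooled samples of up to ten observations the p-value is exact: every
    assignment of the pooled values to the two groups is enumerated, which
    stays valid under ties.  Larger samples use the normal approximation with
    tie and continuity corrections.  The reported statistic is
    ``min(U_x, U_y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u_x = _u_statistic(x, y)
    u_min = min(u_x, n1 * n2 - u_x)

    if n1 + n2 <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        obs_dev = abs(u_x - center)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"

    direction = "x>y" if u_x > n1 * n2 / 2 else ("x<y" if u_x < n1 * n2 / 2 else "none")
    return TestResult(statistic=float(u_min), p_value=float(min(p, 1.0)),
                      direction=direction, extra={"U_x": float(u_x), "method": method})


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("omnibus test needs >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    # all-identical pooled data: no rank variation, H = 0 by definition
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(statistic=0.0, p_value=1.0)
    h, p = stats.kruskal(*groups)
    return TestResult(statistic=float(h), p_value=float(p))


def pairwise_bonferroni(groups, names=None) -> dict[tuple, TestResult]:
    """All pairwise Mann-Whitney tests, Bonferroni-adjusted (p * n_pairs, capped at 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    names = names if names is not None else list(range(len(groups)))
    pairs = list(combinations(range(len(groups)), 2))
    out = {}
    for i, j in pairs:
        res = mann_whitney_u(groups[i], groups[j])
        res.adjusted_p = min(1.0, res.p_value * len(pairs))
        out[(names[i], names[j])] = res
    return out


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p),
                      direction="positive" if rho >= 0 else "negative",
                      extra={"strength": _band(rho, SPEARMAN_BANDS)})


# ---------------------------------------------------------------------------
# reproducibility

def icc_two_way_random(ratings) -> TestResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is (n_lesions, 2): the same quantity measured by two readers.
    Returns the ICC with its F-based 95% confidence interval and the
    conventional interpretation band (poor/fair/good/excellent).
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError("ratings must be (n_lesions, 2)")
    if r.shape[0] < 5:
        raise ValueError("need >= 5 lesions")
    if not np.isfinite(r).all():
        raise ValueError("missing cells are not allowed")
    n = r.shape[0]
    df = pd.DataFrame({
        "lesion": np.repeat(np.arange(n), 2),
        "reader": np.tile([0, 1], n),
        "value": r.ravel(),
    })
    table = pg.intraclass_corr(data=df, targets="lesion", raters="reader",
                               ratings="value").set_index("Type")
    # two-way random, absolute agreement, single measure; label varies by
    # pingouin version ("ICC2" vs "ICC(A,1)")
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(row["ICC"])
    ci = tuple(float(v) for v in row[ci_col])
    return TestResult(statistic=icc, p_value=float(row["pval"]),
                      extra={"ci95": ci, "interpretation": _band(icc, ICC_BANDS)})


# ---------------------------------------------------------------------------
# ROC / AUC

def auc_mann_whitney(scores, labels) -> float:
    """Empirical AUC via the rank (Mann-Whitney) formulation.

    ``AUC = U_pos / (n_pos * n_neg)`` where U_pos is the U statistic of the
    positive-class scores; ties count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return _u_statistic(pos, neg) / (pos.size * neg.size)


def roc_analysis(scores, labels, positive_low="auto") -> RocResult:
    """Empirical ROC analysis with a Youden-index cutoff and DeLong CI.

    ``positive_low`` — whether low scores indicate the positive class: True,
    False, or "auto" (orient so AUC >= 0.5 and report the direction used).
    The cutoff maximizing ``J = sensitivity + specificity - 1`` is reported
    as the midpoint between adjacent observed scores; J ties break toward
    higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    raw_auc = auc_mann_whitney(scores, labels)
    if positive_low == "auto":
        low = bool(raw_auc < 0.5)
    else:
        low = bool(positive_low)
    oriented = -scores if low else scores
    auc = auc_mann_whitney(oriented, labels)

    var = delong_variance(oriented, labels)
    se = np.sqrt(var)
    ci = (float(np.clip(auc - 1.959964 * se, 0, 1)),
          float(np.clip(auc + 1.959964 * se, 0, 1)))

    pos, neg = oriented[labels], oriented[~labels]
    uniq = np.unique(oriented)
    # candidate thresholds: midpoints between adjacent distinct scores plus
    # open ends (classify-none / classify-all)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for thr in cands:
        sens = float((pos > thr).mean())
        spec = float((neg <= thr).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    cutoff = float(-thr if low else thr)
    return RocResult(auc=float(auc), ci=ci, cutoff=cutoff,
                     sensitivity=100.0 * sens, specificity=100.0 * spec,
                     positive_low=low, extra={"raw_auc": float(raw_auc)})


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[labels], scores[~labels]
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / neg.size for p in pos])
    v01 = np.array([((pos > n).sum() + 0.5 * (pos == n).sum()) / pos.size for n in neg])
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    v10, v01 = _placements(scores, labels)
    if v10.size < 2 or v01.size < 2:
        return float("nan")
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def delong_test(scores_a, scores_b, labels) -> TestResult:
    """DeLong two-sided comparison of two correlated (paired) AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores and labels must be paired (same length)")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    auc_a = auc_mann_whitney(a, labels)
    auc_b = auc_mann_whitney(b, labels)
    v10_a, v01_a = _placements(a, labels)
    v10_b, v01_b = _placements(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        z = 0.0 if abs(diff) < 1e-12 else np.inf
    else:
        z = diff / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)),
                      extra={"auc_a": float(auc_a), "auc_b": float(auc_b),
                             "auc_diff": float(diff), "var": float(var)})


# ---------------------------------------------------------------------------
# multivariable combination

def combined_model_auc(metric_matrix, labels) -> RocResult:
    """AUC of an additive logistic combination of several metrics (in-sample).

    Columns are standardized, a logit model is fit by iteratively reweighted
    least squares, and the ROC is computed on the linear predictor.  The
    in-sample AUC is optimistic by construction — there is no internal
    cross-validation — and is flagged as such in the result.  Perfect
    separation is flagged but the AUC is still computed from the (diverging)
    linear predictor's ordering, which is well defined.
    """
    X = np.atleast_2d(np.asarray(metric_matrix, dtype=float))
    if X.ndim != 2:
        raise ValueError("metric_matrix must be 2D (lesions x metrics)")
    labels = np.asarray(labels).astype(bool)
    n, k = X.shape
    if labels.shape != (n,):
        raise ValueError("labels must align with rows")
    if n <= 5 * (k + 1):
        raise ValueError(f"too few lesions ({n}) for {k} metrics")

    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    design = sm.add_constant(Xs, has_constant="add")
    separated = False
    try:
        import warnings as _warnings
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = sm.GLM(labels.astype(float), design,
                         family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        separated = any("erfect" in str(w.message) for w in caught)
        lp = design @ fit.params
    except Exception:
        # IRLS broke down (perfect separation): rank by a linear discriminant
        separated = True
        mu1, mu0 = Xs[labels].mean(axis=0), Xs[~labels].mean(axis=0)
        lp = Xs @ (mu1 - mu0)

    roc = roc_analysis(lp, labels, positive_low=False)
    roc.extra.update({"in_sample": True, "perfect_separation": separated,
                      "n_metrics": k})
    return roc
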