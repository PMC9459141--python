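"""Diagnostic-performance statistics.

ROC/AUC (rank-based, ties counted half), sensitivity/specificity/precision
with exact Clopper-Pearson 95% intervals (Wilson optional), Cohen's kappa,
the DeLong paired AUC comparison (with a permutation alternative for
model-vs-binary-reader contrasts), and a cohort descriptive summary with
normality-gated group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "roc_auc",
    "binary_metrics",
    "proportion_ci",
    "cohens_kappa",
    "compare_auc",
    "compare_auc_permutation",
    "evaluate_arm",
    "cohort_summary",
]


@dataclass
class EvalReport:
    """Table-of-diagnostic-performance row for one model arm."""

    auc: float
    roc_points: np.ndarray                 # (n_thresholds, 2): FPR, TPR
    sensitivity: tuple[float, float, float]   # point, ci_low, ci_high
    specificity: tuple[float, float, float]
    precision: tuple[float, float, float] | None
    kappa: float
    n: int
    comparisons: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def trip(t):
            return None if t is None else {"point": t[0], "ci_low": t[1], "ci_high": t[2]}
        return {
            "auc": self.auc,
            "sensitivity": trip(self.sensitivity),
            "specificity": trip(self.specificity),
            "precision": trip(self.precision),
            "kappa": self.kappa,
            "n": self.n,
            "comparisons": self.comparisons,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC via the rank (Mann-Whitney) identity, plus the ROC points.

    Ties between a positive and a negative score count half, so the AUC
    of a constant score is exactly 0.5. ROC points are emitted at every
    distinct threshold, (0,0) and (1,1) included.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - m * (m + 1) / 2) / (m * n)
    # ROC points: sweep thresholds from high to low
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / m]
    fpr = np.r_[0.0, fps[distinct] / n]
    return float(auc), np.column_stack([fpr, tpr])


def proportion_ci(x: int, n: int, level: float = 0.95,
                  method: str = "exact") -> tuple[float, float]:
    """Confidence interval for a binomial proportion.

    ``exact`` is Clopper-Pearson from beta quantiles (default; guarantees
    >= nominal coverage), ``wilson`` the score interval.
    """
    if not 0 <= x <= n or n == 0:
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    alpha = 1 - level
    if method == "exact":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lo, hi
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        p = x / n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return float(max(0.0, centre - half)), float(min(1.0, centre + half))
    raise ValueError("method must be 'exact' or 'wilson'")


def binary_metrics(calls: np.ndarray, labels: np.ndarray, level: float = 0.95,
                   ci_method: str = "exact") -> dict:
    """Sensitivity, specificity and precision with binomial CIs.

    Precision is None (reported missing) when no case is called positive.
    """
    labels = _check_labels(labels)
    calls = np.asarray(calls)
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("calls must be binary 0/1")
    tp = int(((calls == 1) & (labels == 1)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    out = {
        "sensitivity": (tp / (tp + fn), *proportion_ci(tp, tp + fn, level, ci_method)),
        "specificity": (tn / (tn + fp), *proportion_ci(tn, tn + fp, level, ci_method)),
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    }
    if tp + fp > 0:
        out["precision"] = (tp / (tp + fp), *proportion_ci(tp, tp + fp, level, ci_method))
    else:
        out["precision"] = None
    return out


def cohens_kappa(calls: np.ndarray, labels: np.ndarray) -> float:
    """Chance-corrected agreement between calls and pathology labels.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 table; defined as 0 when
    the expected agreement is exactly 1 (both margins degenerate).
    """
    labels = _check_labels(labels)
    calls = np.asarray(calls)
    n = len(labels)
    p_o = float((calls == labels).mean())
    p_yes = float((calls == 1).mean()) * float((labels == 1).mean())
    p_no = float((calls == 0).mean()) * float((labels == 0).mean())
    p_e = p_yes + p_no
    if p_e >= 1.0:
        warnings.warn("degenerate margins: expected agreement is 1, kappa set to 0")
        return 0.0
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-case structural components (mid-rank method)."""
    x = scores[pos]         # positives
    y = scores[~pos]        # negatives
    m, n = len(x), len(y)
    all_ranks = stats.rankdata(np.r_[x, y])
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (all_ranks[:m] - rx) / n               # P(X > Y) per positive
    v01 = 1.0 - (all_ranks[m:] - ry) / m         # per negative
    return float(v10.mean()), v10, v01


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> float:
    """Two-sided DeLong test for paired AUCs on identical cases.

    Identical score vectors give p = 1.0. A degenerate variance with a
    nonzero AUC difference cannot be tested and is reported as NaN with a
    warning.
    """
    labels = _check_labels(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired comparison needs equal-length score vectors")
    pos = labels == 1
    auc_a, v10_a, v01_a = _placements(scores_a, pos)
    auc_b, v10_b, v01_b = _placements(scores_b, pos)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))      # 2x2, ddof=1
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 1.0
        warnings.warn("DeLong variance is degenerate; p-value undefined")
        return float("nan")
    z = diff / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def compare_auc_permutation(scores_a: np.ndarray, scores_b: np.ndarray,
                            labels: np.ndarray, n_perm: int = 2000,
                            seed: int = 0) -> float:
    """Paired permutation test on the AUC difference.

    Randomly swaps the two score vectors case-by-case; suited to contrasts
    where one arm is a binary verdict and the DeLong normal approximation
    is shaky.
    """
    labels = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    rng = np.random.default_rng(seed)
    obs = abs(roc_auc(a, labels)[0] - roc_auc(b, labels)[0])
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(roc_auc(aa, labels)[0] - roc_auc(bb, labels)[0]) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def evaluate_arm(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
                 calls: np.ndarray | None = None, level: float = 0.95,
                 ci_method: str = "exact") -> EvalReport:
    """Full diagnostic report for one arm.

    ``scores`` drive the ROC/AUC; binary calls default to
    ``score >= threshold`` but can be supplied directly (e.g. a reader's
    verdicts, where score and call coincide).
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if calls is None:
        calls = (scores >= threshold).astype(int)
    auc, roc_points = roc_auc(scores, labels)
    bm = binary_metrics(calls, labels, level, ci_method)
    return EvalReport(
        auc=auc,
        roc_points=roc_points,
        sensitivity=bm["sensitivity"],
        specificity=bm["specificity"],
        precision=bm["precision"],
        kappa=cohens_kappa(calls, labels),
        n=len(labels),
    )


# ---------------------------------------------------------------------------
# Cohort descriptive summary
# ---------------------------------------------------------------------------

def cohort_summary(table: pd.DataFrame, group_col: str,
                   normality_alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group comparison in the style of a patient table.

    Continuous variables: Shapiro-Wilk normality in each group gates the
    choice between Welch's t-test (all groups normal) and Mann-Whitney U;
    mean, SD and the test p-value are reported. Categorical (non-numeric
    or few-valued) variables: chi-square on the contingency table.
    """
    groups = [g for g, _ in table.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    if any(len(sub) == 0 for _, sub in table.groupby(group_col)):
        raise ValueError("empty group")
    rows = []
    for col in table.columns:
        if col == group_col:
            continue
        series = table[col]
        parts = [table.loc[table[group_col] == g, col] for g in groups]
        numeric = pd.api.types.is_numeric_dtype(series)
        if numeric and series.nunique() > 5:
            normal = all(
                len(p) >= 3 and stats.shapiro(p).pvalue >= normality_alpha
                for p in parts
            )
            if len(parts) == 2:
                if normal:
                    p = stats.ttest_ind(parts[0], parts[1], equal_var=False).pvalue
                    test = "welch-t"
                else:
                    p = stats.mannwhitneyu(parts[0], parts[1],
                                           alternative="two-sided").pvalue
                    test = "mann-whitney"
            else:
                p = stats.kruskal(*parts).pvalue
                test = "kruskal"
            desc = " / ".join(f"{p_.mean():.2f}±{p_.std():.2f}" for p_ in parts)
        else:
            contingency = pd.crosstab(series, table[group_col])
            if contingency.shape[0] < 2:
                p, test = 1.0, "chi2"
            else:
                p = stats.chi2_contingency(contingency).pvalue
                test = "chi2"
            desc = " / ".join(str(int(n)) for n in
                              series.groupby(table[group_col]).count())
        rows.append({"variable": col, "summary": desc, "test": test,
                     "p_value": float(p)})
    return pd.DataFrame(rows)
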