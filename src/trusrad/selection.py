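"""Four-stage dimensionality reduction of a radiomic feature table.

The chain is fixed: (1) reproducibility filter on the intraclass
correlation coefficient between two segmentation raters, (2) univariate
screen (Welch t-test and Mann-Whitney U), (3) zero-variance filter,
(4) L1-penalised logistic regression with the penalty chosen by repeated
10-fold cross-validation, keeping the features with nonzero coefficients.
Each stage's survivor set is a subset of its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "compute_icc",
    "icc_filter",
    "univariate_screen",
    "variance_filter",
    "lasso_select",
    "spearman_matrix",
    "select_features",
]


@dataclass
class SelectionReport:
    """Everything the selection chain decided and why.

    ``selected`` maps feature name to its (standardised-scale) nonzero
    LASSO coefficient; ``lasso_path`` maps each grid penalty to the fitted
    coefficient vector on the full data.
    """

    icc_per_feature: dict[str, float] = field(default_factory=dict)
    icc_survivors: list[str] = field(default_factory=list)
    screen_survivors: list[str] = field(default_factory=list)
    screen_pvalues: dict[str, tuple[float, float]] = field(default_factory=dict)
    variance_survivors: list[str] = field(default_factory=list)
    lasso_lambda: float = float("nan")
    lambda_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    lasso_path: dict[float, np.ndarray] = field(default_factory=dict)
    cv_deviance: np.ndarray = field(default_factory=lambda: np.array([]))
    selected: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "icc_per_feature": self.icc_per_feature,
            "icc_survivors": self.icc_survivors,
            "screen_survivors": self.screen_survivors,
            "variance_survivors": self.variance_survivors,
            "lasso_lambda": self.lasso_lambda,
            "lambda_grid": [float(x) for x in self.lambda_grid],
            "cv_deviance": [float(x) for x in self.cv_deviance],
            "n_nonzero_path": [
                int((np.abs(self.lasso_path[lam]) > 0).sum())
                for lam in self.lambda_grid
            ] if self.lasso_path else [],
            "selected": self.selected,
        }


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def compute_icc(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict[str, float]:
    """Per-feature ICC(2,1) between two raters' measurements.

    Two-way random effects, absolute agreement, single rater — the variant
    whose expectation is sigma_subject^2 / (sigma_subject^2 + sigma_noise^2)
    under the shared-subject-effect model. Vectorised across features from
    the two-way ANOVA mean squares. Features with zero total variance have
    an undefined ICC and are reported as NaN (they fail the filter).
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("rater tables must share the same feature columns")
    if len(table_a) != len(table_b):
        raise ValueError("rater tables must cover the same subjects")
    n = len(table_a)
    if n < 3:
        raise ValueError("need >= 3 subjects to estimate ICC")
    a = table_a.to_numpy(dtype=float)
    b = table_b.to_numpy(dtype=float)
    k = 2
    grand = (a + b).sum(axis=0) / (n * k)
    row_mean = (a + b) / k                      # per subject
    col_mean = np.stack([a.mean(axis=0), b.mean(axis=0)])   # per rater
    msr = k * ((row_mean - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_mean - grand) ** 2).sum(axis=0) / (k - 1)
    resid_a = a - row_mean - col_mean[0] + grand
    resid_b = b - row_mean - col_mean[1] + grand
    mse = (resid_a**2 + resid_b**2).sum(axis=0) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(denom <= 0, np.nan, icc)
    return {c: float(v) for c, v in zip(table_a.columns, icc)}


def icc_filter(icc_per_feature: dict[str, float], threshold: float = 0.8) -> list[str]:
    """Features with ICC >= threshold (boundary inclusive); NaN fails.

    An empty survivor set raises: nothing downstream can run, and a silent
    empty result would be mistaken for an aggressive-but-valid selection.
    """
    kept = [f for f, v in icc_per_feature.items()
            if np.isfinite(v) and v >= threshold]
    if not kept:
        raise ValueError(
            f"no feature reached ICC >= {threshold}: reproducibility filter "
            "left nothing for downstream selection"
        )
    return kept


# ---------------------------------------------------------------------------
# Univariate screen & variance filter
# ---------------------------------------------------------------------------

def univariate_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    require_both: bool = False,
    label_col: str = "label",
) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Welch t-test + Mann-Whitney U screen of every feature.

    Returns ``(survivors, pvalues)`` where pvalues maps each feature to
    (t-test p, Mann-Whitney p). A feature survives when significant at
    ``alpha`` on at least one test (lenient default), or on both with
    ``require_both=True``. Features constant across all rows are dropped:
    neither test is defined for them.
    """
    labels = table[label_col].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to screen")
    features = [c for c in table.columns if c != label_col]
    g0 = table.loc[labels == 0, features].to_numpy(dtype=float)
    g1 = table.loc[labels == 1, features].to_numpy(dtype=float)
    survivors: list[str] = []
    pvalues: dict[str, tuple[float, float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled below
        t_p = stats.ttest_ind(g0, g1, equal_var=False, axis=0).pvalue
        for j, feat in enumerate(features):
            if np.ptp(np.concatenate([g0[:, j], g1[:, j]])) == 0:
                continue
            u_p = float(stats.mannwhitneyu(g0[:, j], g1[:, j],
                                           alternative="two-sided").pvalue)
            tp = float(t_p[j]) if np.isfinite(t_p[j]) else 1.0
            pvalues[feat] = (tp, u_p)
            hits = (tp < alpha, u_p < alpha)
            if (all(hits) if require_both else any(hits)) or alpha >= 1.0:
                survivors.append(feat)
    return survivors, pvalues


def variance_filter(table: pd.DataFrame, label_col: str = "label",
                    tol: float = 1e-12) -> list[str]:
    """Drop features whose sample variance is (numerically) zero.

    The tolerance is relative to the squared feature scale, so a constant
    column stored with rounding noise is still removed.
    """
    features = [c for c in table.columns if c != label_col]
    x = table[features].to_numpy(dtype=float)
    var = x.var(axis=0)
    scale = np.maximum(1.0, np.abs(x.mean(axis=0)) ** 2)
    kept = [f for f, v, s in zip(features, var, scale) if v > tol * s]
    if not kept:
        raise ValueError("variance filter removed every feature")
    return kept


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def _lambda_grid(x: np.ndarray, y: np.ndarray, n_lambda: int,
                 min_ratio: float) -> np.ndarray:
    """Log-spaced penalty grid from the data-derived lambda_max downward.

    lambda_max = max_j |x_j . (y - ybar)| / n on standardised columns: the
    smallest penalty at which the L1-penalised logistic solution (with an
    unpenalised intercept) is entirely zero.
    """
    n = len(y)
    lam_max = float(np.abs(x.T @ (y - y.mean())).max() / n)
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is 0")
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fit_path(x: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
              loss: str) -> np.ndarray:
    """Coefficients along the penalty grid (decreasing λ), warm-started."""
    n, p = x.shape
    coefs = np.zeros((len(lambdas), p))
    if loss == "logistic":
        # liblinear: fast exact-zero l1 fits on small dense designs; the
        # large intercept_scaling makes the intercept penalty negligible
        model = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", warm_start=True, max_iter=1000,
            tol=1e-6, fit_intercept=True, intercept_scaling=1000.0,
            random_state=0,
        )
        for i, lam in enumerate(lambdas):
            model.C = 1.0 / (n * lam)
            model.fit(x, y)
            coefs[i] = model.coef_[0]
    else:  # squared-error loss on the 0/1 labels
        from sklearn.linear_model import Lasso

        model = Lasso(warm_start=True, max_iter=5000, tol=1e-6)
        for i, lam in enumerate(lambdas):
            model.alpha = lam
            model.fit(x, y)
            coefs[i] = model.coef_
    return coefs


def _cv_deviance(x: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                 n_folds: int, n_repeats: int, seed: int, loss: str) -> np.ndarray:
    """Mean held-out deviance per grid penalty over repeated K-fold CV."""
    dev = np.zeros(len(lambdas))
    count = 0
    for rep in range(n_repeats):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                             random_state=seed + rep)
        for tr, te in cv.split(x, y):
            xtr, xte = _standardize_pair(x[tr], x[te])
            coefs = _fit_path(xtr, y[tr], lambdas, loss)
            for i in range(len(lambdas)):
                dev[i] += _holdout_deviance(xtr, y[tr], xte, y[te], coefs[i], loss)
            count += 1
    return dev / count


def _standardize_pair(xtr: np.ndarray, xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (xtr - mu) / sd, (xte - mu) / sd


def _holdout_deviance(xtr, ytr, xte, yte, coef, loss) -> float:
    # refit the intercept analytically at the fitted slopes
    if loss == "logistic":
        eta_tr = xtr @ coef
        b0 = _intercept_mle(eta_tr, ytr)
        p = 1.0 / (1.0 + np.exp(-(xte @ coef + b0)))
        eps = 1e-12
        p = np.clip(p, eps, 1 - eps)
        return float(-2.0 * np.mean(yte * np.log(p) + (1 - yte) * np.log(1 - p)))
    b0 = float(np.mean(ytr - xtr @ coef))
    resid = yte - (xte @ coef + b0)
    return float(np.mean(resid**2))


def _intercept_mle(eta: np.ndarray, y: np.ndarray, iters: int = 25) -> float:
    """Newton steps for the intercept of a logistic model with fixed slopes."""
    b0 = 0.0
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-(eta + b0)))
        g = float(np.sum(y - p))
        h = float(np.sum(p * (1 - p)))
        if h < 1e-12:
            break
        step = g / h
        b0 += step
        if abs(step) < 1e-10:
            break
    return b0


def lasso_select(
    table: pd.DataFrame,
    n_folds: int = 10,
    n_repeats: int = 50,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    loss: str = "logistic",
    label_col: str = "label",
    report: SelectionReport | None = None,
) -> SelectionReport:
    """Choose the penalty by repeated cross-validated deviance and keep the
    nonzero-coefficient features.

    The penalty grid runs log-spaced from the data-derived lambda_max down
    to ``lambda_max * lambda_min_ratio``. For each of ``n_repeats``
    independent stratified ``n_folds``-fold partitions, the full path is
    fitted on each training fold (features standardised within the fold)
    and held-out deviance accumulated per penalty; lambda* minimises the
    mean. The final model is fitted on all rows at lambda*, and features
    with nonzero coefficients are the selection.

    ``loss`` is ``"logistic"`` (default) or ``"linear"`` (squared error on
    the 0/1 labels).
    """
    if loss not in ("logistic", "linear"):
        raise ValueError("loss must be 'logistic' or 'linear'")
    features = [c for c in table.columns if c != label_col]
    x_raw = table[features].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("label column must contain both classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class count {counts.min()}"
        )
    x = _standardize(x_raw)
    lambdas = _lambda_grid(x, y, n_lambda, lambda_min_ratio)
    dev = _cv_deviance(x_raw, y, lambdas, n_folds, n_repeats, seed, loss)
    best = int(np.argmin(dev))
    lam_star = float(lambdas[best])
    path = _fit_path(x, y, lambdas, loss)
    coef_star = path[best]
    rep = report or SelectionReport()
    rep.lasso_lambda = lam_star
    rep.lambda_grid = lambdas
    rep.cv_deviance = dev
    rep.lasso_path = {float(lam): path[i] for i, lam in enumerate(lambdas)}
    rep.selected = {
        f: float(c) for f, c in zip(features, coef_star) if abs(c) > 0
    }
    if not rep.selected:
        warnings.warn("LASSO selected no features at the CV-optimal penalty")
    return rep


# ---------------------------------------------------------------------------
# Spearman correlation of the selected signature
# ---------------------------------------------------------------------------

def spearman_matrix(table: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Spearman rank-correlation matrix of the (selected) features.

    Constant features get NaN rows/columns; the diagonal is 1 where
    defined.
    """
    features = [c for c in table.columns if c != label_col]
    if len(features) < 2:
        raise ValueError("need >= 2 features")
    if len(table) < 3:
        raise ValueError("need >= 3 rows")
    x = table[features].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    const = x.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return pd.DataFrame(rho, index=features, columns=features)


# ---------------------------------------------------------------------------
# The full chain
# ---------------------------------------------------------------------------

def select_features(
    table: pd.DataFrame,
    rater_a: pd.DataFrame | None = None,
    rater_b: pd.DataFrame | None = None,
    icc_threshold: float = 0.8,
    alpha: float = 0.05,
    require_both: bool = False,
    label_col: str = "label",
    **lasso_kwargs,
) -> SelectionReport:
    """Run the fixed chain ICC -> screen -> variance -> LASSO.

    The ICC stage is skipped (all features retained) when no rater tables
    are supplied — reproducibility data is a separate experiment and not
    every cohort has one.
    """
    report = SelectionReport()
    features = [c for c in table.columns if c != label_col]
    if rater_a is not None and rater_b is not None:
        report.icc_per_feature = compute_icc(rater_a[features], rater_b[features])
        report.icc_survivors = icc_filter(report.icc_per_feature, icc_threshold)
    else:
        report.icc_survivors = list(features)
    t1 = table[report.icc_survivors + [label_col]]
    report.screen_survivors, report.screen_pvalues = univariate_screen(
        t1, alpha=alpha, require_both=require_both, label_col=label_col
    )
    if not report.screen_survivors:
        raise ValueError("univariate screen retained no features")
    t2 = table[report.screen_survivors + [label_col]]
    report.variance_survivors = variance_filter(t2, label_col=label_col)
    t3 = table[report.variance_survivors + [label_col]]
    lasso_select(t3, label_col=label_col, report=report, **lasso_kwargs)
    return report
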