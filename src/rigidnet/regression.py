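"""Predicting clinical rigidity from connection strengths.

The model is Y = X beta + eps, where Y stacks per-subject global rigidity
scores (the sum of the five limb/truncal items of the UPDRS motor exam,
each rated 0-4) and X holds per-subject connection strengths, one column
per network edge.  Because the number of candidate edges far exceeds the
number of subjects, beta is estimated under an L1 (LASSO) sparsity
constraint with the penalty chosen by cross-validated prediction error;
the selected edges are then refit by robust (iteratively reweighted,
bisquare) regression to attach per-edge significance.

The post-selection p-values are the naive refit values, as in the original
procedure they mirror; they are not adjusted for the selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso, lars_path

#: bisquare tuning constant giving 95% Gaussian efficiency
BISQUARE_C = 4.685

RIGIDITY_ITEMS = 5  # four limbs + neck/trunk, each rated 0..4


def global_rigidity_score(item_scores: Sequence[int]) -> int:
    """Sum of the five limb and truncal rigidity items (each ordinal 0-4)."""
    items = list(item_scores)
    if len(items) != RIGIDITY_ITEMS:
        raise ValueError(f"expected {RIGIDITY_ITEMS} items, got {len(items)}")
    for v in items:
        if v not in (0, 1, 2, 3, 4):
            raise ValueError(f"rigidity item {v!r} outside the ordinal range 0-4")
    return int(sum(items))


@dataclass(frozen=True)
class CohortDesign:
    """Subjects x edges strength matrix X aligned with a score vector Y."""

    X: np.ndarray
    Y: np.ndarray
    edge_labels: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "edge_labels", tuple(self.edge_labels))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if X.ndim != 2 or X.shape[0] != len(Y):
            raise ValueError("rows of X must align with Y")
        if len(self.edge_labels) != X.shape[1]:
            raise ValueError("edge_labels must match the columns of X")
        if len(set(self.edge_labels)) != len(self.edge_labels):
            raise ValueError("edge labels must be unique")
        if len(self.subject_ids) != X.shape[0]:
            raise ValueError("subject_ids must match the rows of X")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("missing values in the design")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class LassoSelection:
    """The LASSO path, its cross-validation curve and the chosen support.

    ``coef`` are de-standardized coefficients on the original column scale;
    ``coef_std`` are on the internally standardized scale.  ``fold_ids``
    records the cross-validation partition (with n_folds == n_subjects this
    is exactly leave-one-out).
    """

    lambdas: np.ndarray
    cv_errors: np.ndarray
    chosen_lambda: float
    selected: tuple[int, ...]
    coef: np.ndarray
    coef_std: np.ndarray
    intercept: float
    fold_ids: np.ndarray

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, fit_intercept: bool = True
) -> tuple[np.ndarray, float]:
    """Coordinate-descent LASSO minimizing (1/2n)||y - Xb||^2 + lam*||b||_1."""
    model = Lasso(alpha=lam, fit_intercept=fit_intercept, max_iter=200000, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_) if fit_intercept else 0.0


def _lasso_grid(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact LASSO solutions on a decreasing lambda grid via the LARS path.

    The LASSO solution path is piecewise linear in lambda, so solutions at
    arbitrary grid points are linear interpolations between the LARS knots.
    Returns (coefs of shape L x p, intercepts of shape L); an intercept is
    handled by centering.
    """
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    alphas, _, path_coefs = lars_path(Xc, yc, method="lasso")
    # knots are decreasing; np.interp needs increasing x
    knots = alphas[::-1]
    pc = path_coefs[:, ::-1]
    lam = np.clip(lambdas, knots[0], knots[-1])
    coefs = np.empty((len(lambdas), X.shape[1]))
    for j in range(X.shape[1]):
        coefs[:, j] = np.interp(lam, knots, pc[j])
    coefs[lambdas > knots[-1]] = 0.0  # beyond lambda_max everything is zero
    icpts = y_mean - coefs @ x_mean
    return coefs, icpts


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded balanced partition; degenerates to leave-one-out when n == n_folds."""
    if n_folds == n:
        return np.arange(n)  # deterministic LOO
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(ids)
    return ids


def lasso_cv_select(
    design: CohortDesign,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    rule: str = "min",
) -> LassoSelection:
    """Select predictive edges by LASSO with cross-validated penalty choice.

    Columns are standardized internally; the path runs over a log-spaced
    lambda grid from the smallest penalty that zeroes every coefficient down
    to ``lambda_min_ratio`` times it (default 1e-4, or 1e-2 when the design
    is wider than tall — the glmnet convention).  The chosen lambda
    minimizes the mean squared cross-validation prediction error
    (``rule="min"``); the one-standard-error rule is available as
    ``rule="1se"``.  The returned support is the nonzero set of the
    full-data refit at the chosen lambda.
    """
    n, p = design.X.shape
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown rule {rule!r}")
    y = design.Y
    if np.ptp(y) == 0:
        warnings.warn("constant Y: no edges selected")
        return LassoSelection(
            lambdas=np.array([]),
            cv_errors=np.array([]),
            chosen_lambda=np.nan,
            selected=(),
            coef=np.zeros(p),
            coef_std=np.zeros(p),
            intercept=float(y[0]),
            fold_ids=_fold_assignment(n, n_folds, seed),
        )
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-2 if p >= n else 1e-4
    Xs, col_mean, col_sd = _standardize_columns(design.X)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    fold_ids = _fold_assignment(n, n_folds, seed)

    cv_sq = np.zeros((n, n_lambdas))
    for f in range(n_folds):
        test = fold_ids == f
        train = ~test
        coefs, icpts = _lasso_grid(Xs[train], y[train], lambdas)
        preds = Xs[test] @ coefs.T + icpts  # n_test x L
        cv_sq[test] = (y[test, None] - preds) ** 2
    cv_errors = cv_sq.mean(axis=0)
    best = int(np.argmin(cv_errors))
    if rule == "1se":
        se = cv_sq.std(axis=0, ddof=1)[best] / np.sqrt(n)
        within = np.nonzero(cv_errors <= cv_errors[best] + se)[0]
        best = int(within[0])  # largest lambda within one SE (grid is decreasing)
    chosen = float(lambdas[best])
    path_coefs, path_icpts = _lasso_grid(Xs, y, lambdas[: best + 1])
    coef_std, icpt_std = path_coefs[-1].copy(), float(path_icpts[-1])
    selected = tuple(int(k) for k in np.nonzero(coef_std)[0])
    coef = coef_std / col_sd
    intercept = icpt_std - float(coef @ col_mean) + 0.0
    return LassoSelection(
        lambdas=lambdas,
        cv_errors=cv_errors,
        chosen_lambda=chosen,
        selected=selected,
        coef=coef,
        coef_std=coef_std,
        intercept=intercept,
        fold_ids=fold_ids,
    )


@dataclass(frozen=True)
class RobustFitResult:
    """Bisquare IRLS refit of the selected edges with per-edge significance."""

    edge_indices: tuple[int, ...]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    intercept: float
    intercept_se: float
    df_resid: int


def robust_regress(
    design: CohortDesign, selected: Sequence[int] | None = None
) -> RobustFitResult:
    """Robust regression of Y on the selected strength columns.

    Iteratively reweighted least squares with bisquare weights (tuning
    constant 4.685) and scale estimated by the normalized median absolute
    deviation; an intercept is always included.  p-values come from t
    statistics on n - k - 1 degrees of freedom.  If the residuals of an
    initial exact fit vanish (noiseless data), the exact coefficients are
    returned with zero standard errors and NaN p-values.
    """
    sel = tuple(range(design.n_edges)) if selected is None else tuple(selected)
    X = design.X[:, sel]
    y = design.Y
    n, k = X.shape
    if k >= n:
        raise ValueError(f"{k} regressors with only {n} subjects")
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        labels = [design.edge_labels[j] for j in sel]
        raise ValueError(f"perfectly collinear columns among {labels}")
    df = n - k - 1
    ols_coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ ols_coef
    scale_y = max(np.max(np.abs(y)), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale_y:
        return RobustFitResult(
            edge_indices=sel,
            coefficients=ols_coef[1:],
            std_errors=np.zeros(k),
            p_values=np.full(k, np.nan),
            intercept=float(ols_coef[0]),
            intercept_se=0.0,
            df_resid=df,
        )
    rlm = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    fit = rlm.fit(scale_est="mad")
    tvals = fit.params / fit.bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return RobustFitResult(
        edge_indices=sel,
        coefficients=fit.params[1:],
        std_errors=fit.bse[1:],
        p_values=pvals[1:],
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        df_resid=df,
    )


def compare_strengths_groups(
    values: Sequence[float], labels: Sequence, method: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample comparison of one edge's strengths across groups.

    Default is Welch's t test; ``method="student"`` pools variances.
    Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    a, b = (values[labels == g] for g in uniq)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two observations")
    stat, p = stats.ttest_ind(a, b, equal_var=(method == "student"))
    return float(stat), float(p)
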