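"""Weighted-L1 penalized regression: lasso and adaptive lasso.

The estimator minimizes

    ||y - X beta||^2 + lambda * sum_j w_j |beta_j|

i.e. the residual sum of squares plus a weighted L1 penalty, with *no*
1/(2n) factor in front of the quadratic term.  Lambda values are therefore
not numerically comparable to conventions that normalize by sample size;
:func:`lambda_to_mean_scale` converts.

The adaptive lasso builds the weights from first-stage coefficient
estimates, ``w_j = |beta_j_initial|^(-gamma)``, and tunes the pair
``(gamma, lambda)`` jointly by K-fold cross-validation.  Weight zero marks
an unpenalized column (used for confounders that must stay in the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError

try:  # JIT-compiled inner loop; the pure-Python path is equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=False)
def _cd_sweeps(G, c, diag, beta, gb, thresh, unpenalized, tol, max_sweeps):
    """Cyclic coordinate-descent sweeps on the Gram system (in place).

    Returns (sweeps_used, converged_flag, last_max_delta).
    """
    p = beta.shape[0]
    converged = False
    sweep = 0
    max_delta = 0.0
    while sweep < max_sweeps and not converged:
        sweep += 1
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0.0:
                continue
            b_old = beta[j]
            zj = c[j] - gb[j] + diag[j] * b_old
            if unpenalized[j]:
                b_new = zj / diag[j]
            else:
                az = abs(zj) - thresh[j]
                if az > 0.0:
                    b_new = az / diag[j] if zj > 0.0 else -az / diag[j]
                else:
                    b_new = 0.0
            if b_new != b_old:
                d = b_new - b_old
                for i in range(p):
                    gb[i] += G[i, j] * d
                beta[j] = b_new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            converged = True
    return sweep, converged, max_delta

__all__ = [
    "soft_threshold",
    "objective",
    "fit_weighted_lasso",
    "lambda_max",
    "lambda_to_mean_scale",
    "initial_beta",
    "adaptive_weights",
    "kkt_violation",
    "WeightedLasso",
    "AdaptiveLassoCV",
    "tune_2d_cv",
    "refit_ols_ci",
]

#: Cap applied to adaptive weights so that a zero initial estimate yields a
#: finite (but in practice prohibitive) penalty instead of an infinity.
WEIGHT_CAP = 1e6


def soft_threshold(z, t):
    """Soft-thresholding operator ``sign(z) * max(|z| - t, 0)``.

    Accepts scalars or arrays; ``t`` must be nonnegative.
    """
    z = np.asarray(z, dtype=float)
    if np.any(np.asarray(t) < 0):
        raise ValueError("soft_threshold requires a nonnegative threshold")
    out = np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
    return out.item() if out.ndim == 0 else out


def objective(beta, X, y, lam, weights=None):
    """Penalized objective ``||y - X beta||^2 + lam * sum_j w_j |beta_j|``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    resid = y - X @ beta
    return float(resid @ resid + lam * np.sum(w * np.abs(beta)))


def lambda_to_mean_scale(lam, n):
    """Convert a penalty from the RSS scale used here to the 1/(2n)-RSS
    convention used by e.g. scikit-learn's Lasso (``alpha = lam / (2 n)``)."""
    return lam / (2.0 * n)


def fit_weighted_lasso(
    X,
    y,
    lam,
    weights=None,
    beta0=None,
    tol=1e-9,
    max_sweeps=10_000,
    check_objective=False,
):
    """Cyclic coordinate descent for the weighted-L1 objective.

    Coordinate update: ``beta_j <- S(x_j' r_{-j}, lam*w_j/2) / (x_j'x_j)``
    where ``r_{-j}`` is the partial residual excluding column j and S is
    :func:`soft_threshold`.  Columns with weight 0 receive the plain
    least-squares update.  Uses Gram-matrix bookkeeping, so cost per sweep
    is O(p^2) after a one-time O(n p^2) setup.

    Parameters
    ----------
    beta0 : array, optional
        Warm start (copied).
    check_objective : bool
        Assert the objective is non-increasing across sweeps (debug aid).

    Returns
    -------
    beta : ndarray of shape (p,)
    n_sweeps : int
    converged : bool
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ConfigurationError("lambda must be nonnegative")
    if tol <= 0:
        raise ConfigurationError("tol must be positive")
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (p,) or np.any(w < 0):
        raise ConfigurationError("weights must be nonnegative, one per column")

    G = X.T @ X
    c = X.T @ y
    diag = np.diag(G).copy()
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    gb = G @ beta
    thresh = lam * w / 2.0

    unpenalized = thresh == 0.0
    if check_objective:
        # Sweep-by-sweep monotonicity audit (debug path, pure Python).
        prev_obj = objective(beta, X, y, lam, w)
        converged = False
        sweep = 0
        max_delta = 0.0
        for sweep in range(1, max_sweeps + 1):
            _, _, max_delta = _cd_sweeps(
                G, c, diag, beta, gb, thresh, unpenalized, tol, 1
            )
            obj = objective(beta, X, y, lam, w)
            assert obj <= prev_obj + 1e-9 * (1.0 + abs(prev_obj)), (
                f"objective increased: {prev_obj} -> {obj}"
            )
            prev_obj = obj
            if max_delta < tol:
                converged = True
                break
    else:
        sweep, converged, max_delta = _cd_sweeps(
            G, c, diag, beta, gb, thresh, unpenalized, tol, max_sweeps
        )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(last max coefficient change {max_delta:.3e}); "
            "returning best iterate",
            RuntimeWarning,
        )
    return beta, sweep, converged


def lambda_max(X, y, weights=None):
    """Smallest lambda at which every penalized coefficient is zero.

    ``lambda_max = max_j 2 |x_j' y| / w_j`` over penalized columns.  When
    unpenalized columns are present, y is first residualized on them (they
    remain in the model at any lambda).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    free = w == 0
    r = y
    if free.any():
        Xf = X[:, free]
        coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        r = y - Xf @ coef
    pen = ~free
    if not pen.any():
        return 0.0
    lmax = float(np.max(2.0 * np.abs(X[:, pen].T @ r) / w[pen]))
    # nudge up by one part in 1e10 so the all-zero guarantee survives the
    # rounding of the Gram products inside the solver
    return lmax * (1.0 + 1e-10)


def initial_beta(X, y, method="ols", ridge_lambda=1.0):
    """First-stage coefficient estimates used to build adaptive weights.

    ``method='ols'`` requires a well-conditioned full-rank design; with
    collinearity (or p approaching n) use ``method='ridge'``, which solves
    ``(X'X + ridge_lambda I) beta = X'y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if method == "ols":
        if p >= n:
            raise ConfigurationError(
                "OLS initial estimates need p < n; use method='ridge'"
            )
        cond = np.linalg.cond(X)
        if not np.isfinite(cond) or cond > 1e8:
            raise ConfigurationError(
                f"design is (near-)singular (condition number {cond:.2e}); "
                "use method='ridge' for the initial estimates"
            )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    if method == "ridge":
        if ridge_lambda < 0:
            raise ConfigurationError("ridge_lambda must be nonnegative")
        model = Ridge(alpha=ridge_lambda, fit_intercept=False)
        model.fit(X, y)
        return model.coef_
    raise ConfigurationError(f"unknown initial estimator {method!r}")


def adaptive_weights(beta_initial, gamma, cap=WEIGHT_CAP, penalty_free=None):
    """Adaptive-lasso weights ``w_j = |beta_j_initial|^(-gamma)``, capped.

    A zero initial estimate hits the cap (the variable becomes effectively
    unselectable) rather than producing an infinite weight.  Positions
    listed in ``penalty_free`` are forced to weight 0 (never penalized).
    """
    if gamma <= 0:
        raise ConfigurationError("gamma must be positive")
    if cap <= 0:
        raise ConfigurationError("cap must be positive")
    b = np.abs(np.asarray(beta_initial, dtype=float))
    with np.errstate(divide="ignore"):
        w = np.where(b > 0, b ** (-float(gamma)), np.inf)
    w = np.minimum(w, cap)
    if penalty_free is not None:
        w = w.copy()
        w[np.asarray(penalty_free)] = 0.0
    return w


def kkt_violation(X, y, beta, lam, weights=None):
    """Maximum violation of the first-order optimality (KKT) conditions.

    For active coordinates, ``|2 x_j' r - lam w_j sign(beta_j)|``; for
    inactive ones, ``max(|2 x_j' r| - lam w_j, 0)``.  Returns the largest
    violation over all coordinates; near zero certifies a solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    p = X.shape[1]
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    g = 2.0 * (X.T @ (y - X @ beta))
    active = beta != 0
    viol = np.zeros(p)
    viol[active] = np.abs(g[active] - lam * w[active] * np.sign(beta[active]))
    viol[~active] = np.maximum(np.abs(g[~active]) - lam * w[~active], 0.0)
    return float(viol.max()) if p else 0.0


def _standardize(X, means=None, sds=None):
    """Column standardization (sample sd, ddof=1); zero-variance columns are
    centered only."""
    X = np.asarray(X, dtype=float)
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        sds = np.where(sds < 1e-12, 1.0, sds)
    return (X - means) / sds, means, sds


class WeightedLasso(RegressorMixin, BaseEstimator):
    """Weighted-L1 penalized linear regression at a fixed penalty.

    Minimizes ``||y - X beta||^2 + lam * sum w_j |beta_j|`` by cyclic
    coordinate descent on the columns as given (no internal scaling).
    With unit weights this is the ordinary lasso on the RSS scale.

    Parameters
    ----------
    lam : float
        Nonnegative penalty level.
    weights : array-like or None
        Per-column penalty weights; None means unit weights.  Weight 0
        leaves a column unpenalized.
    fit_intercept : bool
        Fit the intercept by centering X and y before the solve.

    Attributes
    ----------
    coef_ : ndarray
    intercept_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, lam=1.0, weights=None, fit_intercept=True,
                 tol=1e-9, max_sweeps=10_000):
        self.lam = lam
        self.weights = weights
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.fit_intercept:
            x_mean = X.mean(axis=0)
            y_mean = y.mean()
            Xc, yc = X - x_mean, y - y_mean
        else:
            x_mean = np.zeros(X.shape[1])
            y_mean = 0.0
            Xc, yc = X, y
        beta, n_iter, conv = fit_weighted_lasso(
            Xc, yc, self.lam, self.weights, tol=self.tol,
            max_sweeps=self.max_sweeps,
        )
        self.coef_ = beta
        self.intercept_ = float(y_mean - x_mean @ beta)
        self.n_iter_ = n_iter
        self.converged_ = conv
        return self

    def predict(self, X):
        check_is_fitted(self)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


@dataclass
class _GammaPath:
    """Per-gamma bookkeeping of the 2-D cross-validation grid."""

    gamma: float
    lambdas: np.ndarray
    weights_full: np.ndarray
    cv_mse: np.ndarray = field(default=None)


class AdaptiveLassoCV(RegressorMixin, BaseEstimator):
    """Adaptive lasso with joint (gamma, lambda) cross-validation tuning.

    For each gamma in ``gamma_grid``, adaptive weights are built from
    first-stage estimates (OLS, or ridge when multicollinearity is a
    concern) and a log-spaced lambda path is laid out from ``lambda_max``
    down to ``lambda_min_ratio * lambda_max``.  K-fold CV mean squared
    prediction error is evaluated over the whole two-dimensional grid with
    a single shared fold assignment; the final model is refit on all data
    at the CV-minimizing pair.  Ties are broken toward the larger lambda,
    then the smaller gamma (favoring sparsity).

    The design is standardized inside each training fold and the stored
    statistics applied to its held-out fold; the final refit standardizes
    on all data.  ``coef_`` is reported on the original column scale;
    ``coef_std_`` on the standardized scale (hard zeros preserved).

    Parameters
    ----------
    gamma_grid : sequence of float
        Candidate weight exponents (default 0.5, 1, 2).
    n_lambdas : int
        Length of each lambda path.
    cv : int
        Number of folds.
    init : {'auto', 'ols', 'ridge'}
        First-stage estimator.  'auto' picks ridge when the design has
        condition number above 1e3 or p >= n/2, else OLS.
    ridge_lambda : float or 'cv'
        Ridge penalty for the first stage; 'cv' selects it by generalized
        CV over a log grid.
    penalty_free : sequence of int or str, optional
        Columns never penalized (confounders); requires a DataFrame input
        when names are given.
    selection : {'1se', 'min'}
        Pick the sparsest pair (largest lambda, then smallest gamma) whose
        CV error is within one standard error of the minimum ('1se', the
        cost-complexity convention that counters CV-min's known tendency
        to drag in null variables), or the exact CV minimizer ('min');
        exact ties always resolve toward larger lambda then smaller gamma.
    weight_mode : {'full', 'per-fold'}
        Whether the adaptive weights used inside CV come from first-stage
        estimates on the full data (the glmnet penalty-factor convention)
        or are recomputed inside each training fold (no first-stage
        leakage into the held-out fold, at the cost of a noisier CV
        surface).
    random_state : int, optional
        Seeds the fold assignment.

    Attributes
    ----------
    coef_, intercept_ : original-scale coefficients.
    coef_std_ : standardized-scale coefficients (exact zeros define support).
    support_ : list of selected column names/indices (nonzero, excluding
        penalty-free columns).
    chosen_gamma_, chosen_lambda_ : the CV-selected pair.
    cv_surface_ : DataFrame of CV MSE indexed by (gamma, lambda).
    beta_initial_ : first-stage estimates on the full standardized data.
    n_iter_, converged_ : final-refit solver diagnostics.
    """

    def __init__(
        self,
        gamma_grid=(0.5, 1.0, 2.0),
        n_lambdas=100,
        lambda_min_ratio=1e-4,
        cv=10,
        init="auto",
        ridge_lambda="cv",
        weight_cap=WEIGHT_CAP,
        penalty_free=None,
        selection="1se",
        weight_mode="full",
        random_state=None,
        tol=1e-9,
        max_sweeps=10_000,
    ):
        self.gamma_grid = gamma_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.init = init
        self.ridge_lambda = ridge_lambda
        self.weight_cap = weight_cap
        self.penalty_free = penalty_free
        self.selection = selection
        self.weight_mode = weight_mode
        self.random_state = random_state
        self.tol = tol
        self.max_sweeps = max_sweeps

    # -- helpers -----------------------------------------------------------

    def _resolve_penalty_free(self, columns):
        if self.penalty_free is None:
            return np.array([], dtype=int)
        idx = []
        for c in self.penalty_free:
            if isinstance(c, str):
                if columns is None or c not in columns:
                    raise ConfigurationError(
                        f"penalty-free column {c!r} not found in the design"
                    )
                idx.append(list(columns).index(c))
            else:
                idx.append(int(c))
        return np.asarray(sorted(set(idx)), dtype=int)

    def _initial(self, Xs, yc):
        """First-stage estimates on an already standardized design."""
        n, p = Xs.shape
        method = self.init
        if method == "auto":
            cond = np.linalg.cond(Xs) if p < n else np.inf
            method = "ridge" if (p >= n / 2 or cond > 1e3) else "ols"
        if method == "ridge":
            if self.ridge_lambda == "cv":
                rcv = RidgeCV(alphas=np.logspace(-3, 3, 25), fit_intercept=False)
                rcv.fit(Xs, yc)
                return rcv.coef_, method, float(rcv.alpha_)
            return (
                initial_beta(Xs, yc, "ridge", self.ridge_lambda),
                method,
                float(self.ridge_lambda),
            )
        return initial_beta(Xs, yc, "ols"), method, None

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        gammas = list(self.gamma_grid)
        if not gammas:
            raise ConfigurationError("gamma_grid must be nonempty")
        if self.cv < 2:
            raise ConfigurationError("cv must be at least 2")
        free_idx = self._resolve_penalty_free(columns)

        # Shared fold assignment across the whole (gamma, lambda) grid.
        rng = np.random.default_rng(self.random_state)
        folds = np.array_split(rng.permutation(n), self.cv)

        # Full-data standardization, first stage, and lambda paths.
        Xs_full, means, sds = _standardize(X)
        y_mean = y.mean()
        yc_full = y - y_mean
        beta_init_full, init_method, ridge_lam = self._initial(Xs_full, yc_full)
        paths = []
        for g in gammas:
            w_full = adaptive_weights(
                beta_init_full, g, cap=self.weight_cap, penalty_free=free_idx
            )
            lmax = lambda_max(Xs_full, yc_full, w_full)
            if lmax <= 0:
                lmax = 1.0  # degenerate: orthogonal outcome; any path works
            if self.n_lambdas == 1:
                lambdas = np.array([lmax])
            else:
                lambdas = np.geomspace(
                    lmax, self.lambda_min_ratio * lmax, self.n_lambdas
                )
            paths.append(_GammaPath(g, lambdas, w_full))

        # Cross-validated squared error, pooled over held-out folds; the
        # per-fold surfaces feed the 1-SE band.
        sse = np.zeros((len(gammas), self.n_lambdas))
        fold_mse = np.zeros((len(folds), len(gammas), self.n_lambdas))
        for fi, fold in enumerate(folds):
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            Xtr, ytr = X[~mask], y[~mask]
            Xva, yva = X[mask], y[mask]
            Xtr_s, m_tr, s_tr = _standardize(Xtr)
            ytr_mean = ytr.mean()
            ytr_c = ytr - ytr_mean
            Xva_s = (Xva - m_tr) / s_tr
            if self.weight_mode == "per-fold":
                beta_init_tr, _, _ = self._initial(Xtr_s, ytr_c)
            elif self.weight_mode != "full":
                raise ConfigurationError(
                    f"unknown weight_mode {self.weight_mode!r}"
                )
            for gi, path in enumerate(paths):
                if self.weight_mode == "per-fold":
                    w_tr = adaptive_weights(
                        beta_init_tr, path.gamma, cap=self.weight_cap,
                        penalty_free=free_idx,
                    )
                else:
                    w_tr = path.weights_full
                beta = None
                for li, lam in enumerate(path.lambdas):
                    beta, _, _ = fit_weighted_lasso(
                        Xtr_s, ytr_c, lam, w_tr, beta0=beta,
                        tol=self.tol, max_sweeps=self.max_sweeps,
                    )
                    pred = Xva_s @ beta + ytr_mean
                    err = float(np.sum((yva - pred) ** 2))
                    sse[gi, li] += err
                    fold_mse[fi, gi, li] = err / len(yva)
        cv_mse = sse / n

        # Selected pair.  Candidates: the exact minimum ('min') or every
        # pair within one SE of it ('1se'); within the candidate set the
        # sparsest wins -- larger lambda first, then smaller gamma.
        best_flat = int(np.argmin(cv_mse))
        bg, bl = np.unravel_index(best_flat, cv_mse.shape)
        if self.selection == "1se":
            se = float(
                fold_mse[:, bg, bl].std(ddof=1) / np.sqrt(len(folds))
            )
            threshold = cv_mse[bg, bl] + se
        elif self.selection == "min":
            threshold = cv_mse[bg, bl] + 1e-15
        else:
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        cands = np.argwhere(cv_mse <= threshold)
        # lambda paths are descending, so the smallest lambda index is the
        # largest lambda; sort by (lambda index asc, gamma asc).
        cands = sorted(cands.tolist(), key=lambda t: (t[1], t[0]))
        gi, li = cands[0]
        chosen = paths[gi]

        # Final refit on all data at the chosen pair.
        w_full = chosen.weights_full
        beta_warm = None
        for lam in chosen.lambdas[: li + 1]:  # warm-start down the path
            beta_warm, n_iter, conv = fit_weighted_lasso(
                Xs_full, yc_full, lam, w_full, beta0=beta_warm,
                tol=self.tol, max_sweeps=self.max_sweeps,
            )
        beta_std = beta_warm

        self.columns_ = columns
        self.penalty_free_idx_ = free_idx
        self.init_method_ = init_method
        self.ridge_lambda_ = ridge_lam
        self.beta_initial_ = beta_init_full
        self.weights_ = w_full
        self.chosen_gamma_ = float(chosen.gamma)
        self.chosen_lambda_ = float(chosen.lambdas[li])
        self.lambda_paths_ = {pth.gamma: pth.lambdas for pth in paths}
        self.cv_surface_ = pd.DataFrame(
            cv_mse,
            index=pd.Index(gammas, name="gamma"),
            columns=pd.RangeIndex(self.n_lambdas, name="lambda_index"),
        )
        self.coef_std_ = beta_std
        self.scale_means_ = means
        self.scale_sds_ = sds
        self.coef_ = beta_std / sds
        self.intercept_ = float(y_mean - means @ self.coef_)
        names = columns if columns is not None else list(range(p))
        self.support_ = [
            names[j]
            for j in range(p)
            if beta_std[j] != 0.0 and j not in set(free_idx.tolist())
        ]
        self.n_iter_ = n_iter
        self.converged_ = conv
        return self

    def predict(self, X):
        check_is_fitted(self)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def tune_2d_cv(
    X,
    y,
    gamma_grid=(0.5, 1.0, 2.0),
    lambda_grid_size=100,
    K=10,
    seed=None,
    init="auto",
    **kwargs,
):
    """Fit an :class:`AdaptiveLassoCV` (functional form).

    Returns the fitted estimator, whose attributes carry the coefficient
    vector, support, chosen ``(gamma, lambda)``, CV surface and first-stage
    estimates.
    """
    est = AdaptiveLassoCV(
        gamma_grid=gamma_grid,
        n_lambdas=lambda_grid_size,
        cv=K,
        init=init,
        random_state=seed,
        **kwargs,
    )
    return est.fit(X, y)


def refit_ols_ci(X, y, support, forced=(), level=0.95):
    """Naive post-selection OLS refit with Wald t confidence intervals.

    Refits y on the selected columns plus any forced (confounder) columns
    and returns a table of estimates and intervals at the given level.
    Aliased (collinear) columns are dropped with a warning.  No claim of
    post-selection validity is made: the intervals condition on the
    selected support.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    if isinstance(X, pd.DataFrame):
        cols = [c for c in list(forced) + list(support) if c in X.columns]
        missing = [c for c in list(forced) + list(support) if c not in X.columns]
        if missing:
            raise ConfigurationError(f"columns not in design: {missing}")
        Xd = X[cols].to_numpy(dtype=float)
        names = cols
    else:
        X = np.asarray(X, dtype=float)
        idx = list(forced) + list(support)
        Xd = X[:, idx]
        names = [str(i) for i in idx]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Xd.shape[1] >= n:
        raise ConfigurationError("support too large for an OLS refit (p >= n)")

    # Drop aliased columns (rank-deficient after selection).
    keep, dropped = [], []
    for j in range(Xd.shape[1]):
        trial = Xd[:, keep + [j]]
        if np.linalg.matrix_rank(
            np.column_stack([np.ones(n), trial])
        ) == len(keep) + 2:
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping aliased columns from refit: {dropped}")
    Xd = Xd[:, keep]
    names = [names[j] for j in keep]

    A = np.column_stack([np.ones(n), Xd])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = n - A.shape[1]
    rows = []
    if dof > 0 and resid @ resid > 0:
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    else:
        se = np.zeros(A.shape[1])
        tcrit = 0.0
    for i, name in enumerate(["(Intercept)"] + names):
        est = float(coef[i])
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": float(se[i]),
                "ci_low": est - tcrit * se[i],
                "ci_high": est + tcrit * se[i],
            }
        )
    return pd.DataFrame(rows)
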