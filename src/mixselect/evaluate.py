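"""Performance evaluation: R^2, adjusted R^2, MSE, and K-fold
cross-validated training/prediction error.

The cross-validated mean squared prediction error (MSPE) is fold-size
weighted:

    MSPE = sum_k (n_k / n) * sum_{i in C_k} (y_i - yhat_i)^2 / n_k

over the K partitions C_1..C_K, which for any fold sizes equals the
pooled mean of all held-out squared errors.  MSE.CV is reported alongside
as the fold-size-weighted mean of the *training* MSEs of the K fitted
models (an interpretation; see the report metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "CVPlan",
    "PerformanceReport",
    "make_cv_plan",
    "r2_metrics",
    "mspe_kfold",
    "compare_methods",
]


@dataclass
class CVPlan:
    """A fixed K-fold partition: near-equal random folds from a seed."""

    K: int
    assignments: np.ndarray  # sample index -> fold id
    seed: int | None = None

    @property
    def fold_sizes(self):
        return np.bincount(self.assignments, minlength=self.K)

    def folds(self):
        for k in range(self.K):
            yield np.flatnonzero(self.assignments == k)


@dataclass
class PerformanceReport:
    r2: float = np.nan
    adj_r2: float = np.nan
    mse: float = np.nan
    mse_cv: float = np.nan
    mspe_cv: float = np.nan
    p_effective: int = 0
    K: int = 0
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


def make_cv_plan(n, K=10, seed=None):
    """Randomly and equally divide n samples into K folds
    (|max n_k - min n_k| <= 1)."""
    if K < 2:
        raise ConfigurationError("K must be at least 2")
    if K > n:
        raise ConfigurationError(f"K={K} exceeds the sample count n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, K)):
        assignments[chunk] = k
    return CVPlan(K=K, assignments=assignments, seed=seed)


def r2_metrics(y, yhat, p_effective):
    """(R^2, adjusted R^2, MSE) of fitted values against observations.

    ``R^2 = 1 - SSE/SST``; ``adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)``
    with p the number of nonzero estimated coefficients (intercept
    excluded); ``MSE = SSE / n``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ConfigurationError("y and yhat lengths differ")
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateDataError("outcome has zero variance; R^2 undefined")
    sse = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - sse / sst
    if n <= p_effective + 1:
        raise ConfigurationError(
            f"adjusted R^2 needs n > p_effective + 1 (n={n}, p={p_effective})"
        )
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_effective - 1)
    return r2, adj, sse / n


def mspe_kfold(fit_fn, X, y, K=10, seed=None, plan=None):
    """Fold-weighted cross-validated training and prediction error.

    ``fit_fn(X_train, y_train)`` must return an object with a ``predict``
    method and be self-contained (any tuning happens inside the training
    folds).  Returns ``(mse_cv, mspe_cv, plan)``.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(y, dtype=float)
    n = len(y)
    if plan is None:
        plan = make_cv_plan(n, K=K, seed=seed)
    mse_cv = 0.0
    mspe_cv = 0.0
    for fold_idx in plan.folds():
        mask = np.zeros(n, dtype=bool)
        mask[fold_idx] = True
        Xtr = X.loc[~mask] if isinstance(X, pd.DataFrame) else X[~mask]
        Xva = X.loc[mask] if isinstance(X, pd.DataFrame) else X[mask]
        model = fit_fn(Xtr, y[~mask])
        pred_tr = np.asarray(model.predict(Xtr), dtype=float)
        pred_va = np.asarray(model.predict(Xva), dtype=float)
        n_k = int(mask.sum())
        train_mse = float(np.mean((y[~mask] - pred_tr) ** 2))
        fold_mspe = float(np.mean((y[mask] - pred_va) ** 2))
        mse_cv += n_k / n * train_mse
        mspe_cv += n_k / n * fold_mspe
    return mse_cv, mspe_cv, plan


def compare_methods(
    dataset,
    methods=("alasso", "cart_alasso", "rf_alasso"),
    with_interactions=(False, True),
    seed=None,
    K=10,
    confounders=(),
    cv_mode="nested",
    **estimator_kwargs,
):
    """Run the comparison grid (methods x with/without interactions) on one
    dataset, all methods sharing a single CV plan.

    ``dataset`` is a :class:`~mixselect.simulate.SimulatedDataset` or an
    ``(X, y)`` pair.  Returns a tidy DataFrame with one row per
    (method, interactions) cell: R2, adjR2, MSE, MSE.CV, MSPE.CV, support
    size, and the selected support.
    """
    from .pipeline import TwoStepRegressor, evaluate_fit  # late: avoid cycle

    if hasattr(dataset, "X"):
        X, y = dataset.X, np.asarray(dataset.y, dtype=float)
        if dataset.Z is not None:
            X = X.copy()
            X["Z"] = np.asarray(dataset.Z, dtype=float)
            confounders = tuple(confounders) + ("Z",)
    else:
        X, y = dataset
        y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ConfigurationError("compare_methods needs at least 2 predictors")
    plan = make_cv_plan(len(y), K=K, seed=seed)
    if isinstance(with_interactions, bool):
        with_interactions = (with_interactions,)
    rows = []
    for inter in with_interactions:
        for method in methods:
            est = TwoStepRegressor(
                method=method,
                with_interactions=inter,
                confounders=list(confounders),
                random_state=seed,
                cv_mode=cv_mode,
                **estimator_kwargs,
            )
            est.fit(X, y)
            report = evaluate_fit(est, X, y, plan=plan)
            rows.append(
                {
                    "method": method,
                    "with_interactions": inter,
                    "R2": report.r2,
                    "adjR2": report.adj_r2,
                    "MSE": report.mse,
                    "MSE.CV": report.mse_cv,
                    "MSPE.CV": report.mspe_cv,
                    "support_size": len(est.support_),
                    "support": ",".join(map(str, est.support_)),
                }
            )
    return pd.DataFrame(rows)
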