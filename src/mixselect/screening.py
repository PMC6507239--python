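"""First-stage variable screening.

Two screeners are provided for the dimension-reduction step that precedes
the penalized fit:

* a regression random forest with permutation variable importance (VIMP):
  for each variable, the mean increase in a tree's out-of-bag mean squared
  error when that variable's out-of-bag values are permuted.  A positive
  VIMP means the variable predicts better than noise.
* a single CART regression tree, cost-complexity pruned with the one
  standard error rule; the variables appearing in any split of the pruned
  tree are kept.

The forest is a scikit-learn ``RandomForestRegressor``; each tree's
out-of-bag membership is recovered from its recorded bootstrap sample, and
the per-variable permutation streams are reproducible and keyed to the
variable's *name* (so reordering columns reorders the importances with
them).

Confounders never pass through screening: they are force-carried into the
second stage by the pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "ScreenResult",
    "rf_vimp",
    "select_by_vimp",
    "cart_screen",
    "RandomForestVimpScreener",
    "CartScreener",
]


@dataclass
class ScreenResult:
    """Outcome of a screening stage."""

    method: str  # 'rf' | 'cart' | 'none'
    kept: list
    forced: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def empty(self):
        return len(self.kept) == 0


def _as_frame(X):
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(X.shape[1])])


def _name_stream(base_seed, name):
    """Permutation stream keyed to the variable's *name* via a stable CRC32,
    so column order does not change any variable's stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), zlib.crc32(name.encode())])
    )


def rf_vimp(X, y, n_trees=1000, mtry=None, min_node=5, seed=None):
    """Permutation variable importance from a regression random forest.

    Each tree is grown on a bootstrap sample (with replacement, same size
    as the data), choosing among ``mtry`` randomly drawn candidate
    variables at each split (default ``max(m // 3, 1)``, the regression
    convention).  For each variable j,

        vimp_j = mean over trees of
                 [OOB MSE with column j permuted within the OOB rows
                  - OOB MSE unpermuted]

    Variables a tree never splits on contribute exactly zero for that
    tree (permuting them cannot change its predictions).

    Returns a DataFrame with columns ``variable``, ``vimp``, ``rank``
    (rank 1 = largest VIMP; ties broken by column order).
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, m = Xf.shape
    if n < 20:
        raise ConfigurationError("rf_vimp needs at least 20 samples")
    if np.ptp(y) == 0:
        raise DegenerateDataError("outcome is constant; VIMP is undefined")
    if mtry is None:
        mtry = max(m // 3, 1)
    mtry = min(int(mtry), m)

    # Canonical (name-sorted) column order inside the forest: together with
    # name-keyed permutation streams this makes the importances exactly
    # invariant to the order the columns arrive in.
    input_names = list(Xf.columns)
    canon = sorted(range(m), key=lambda j: str(input_names[j]))
    names = [input_names[j] for j in canon]
    Xa = np.ascontiguousarray(Xf.to_numpy(dtype=np.float32)[:, canon])
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node,
        bootstrap=True,
        random_state=None if seed is None else int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(Xa, y)
    samples = list(forest.estimators_samples_)
    perm_rngs = {
        name: _name_stream(0 if seed is None else seed, name) for name in names
    }

    vimp_sum = np.zeros(m)
    vimp_counts = np.zeros(m)  # trees with at least one OOB row
    oob_err_sum = 0.0
    oob_trees = 0
    all_rows = np.arange(n)
    for t, tree in enumerate(forest.estimators_):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[samples[t]] = True
        oob = all_rows[~in_bag]
        if oob.size == 0:
            continue
        X_oob = Xa[oob]
        y_oob = y[oob]
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        # One stacked low-level predict per tree: the unpermuted block plus
        # one permuted block per variable the tree actually splits on
        # (permuting an unused variable cannot change predictions).
        n_oob = oob.size
        stack = np.tile(X_oob, (len(used) + 1, 1))
        for bi, j in enumerate(used, start=1):
            rng_j = perm_rngs[names[j]]
            stack[bi * n_oob:(bi + 1) * n_oob, j] = rng_j.permutation(X_oob[:, j])
        preds = tree.tree_.predict(np.ascontiguousarray(stack))
        preds = np.asarray(preds, dtype=float).reshape(len(used) + 1, n_oob)
        mses = np.mean((y_oob - preds) ** 2, axis=1)
        base_mse = float(mses[0])
        oob_err_sum += base_mse
        oob_trees += 1
        vimp_counts += 1
        vimp_sum[used] += mses[1:] - base_mse
    with np.errstate(invalid="ignore"):
        vimp = np.where(vimp_counts > 0, vimp_sum / np.maximum(vimp_counts, 1), 0.0)
    # back to the caller's column order
    inverse = np.empty(m, dtype=int)
    inverse[canon] = np.arange(m)
    vimp = vimp[inverse]
    order = np.lexsort((np.arange(m), -vimp))  # desc vimp, ties by column order
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    return pd.DataFrame(
        {"variable": input_names, "vimp": vimp, "rank": rank}
    )


def select_by_vimp(vimp_table, rule="positive", k=None, frac=None, forced=()):
    """Turn a VIMP table into a kept-variable set.

    Rules: ``positive`` keeps VIMP > 0 (better than noise); ``top_k``
    keeps the k largest; ``frac_of_max`` keeps VIMP >= frac * max(VIMP).
    Order of ``kept`` follows the input column order.
    """
    names = list(vimp_table["variable"])
    vimp = np.asarray(vimp_table["vimp"], dtype=float)
    m = len(names)
    if rule == "positive":
        keep_mask = vimp > 0
    elif rule == "top_k":
        if k is None:
            raise ConfigurationError("rule='top_k' needs k")
        if k > m:
            import warnings

            warnings.warn(f"top_k k={k} exceeds m={m}; capping at m")
            k = m
        order = np.lexsort((np.arange(m), -vimp))
        keep_mask = np.zeros(m, dtype=bool)
        keep_mask[order[:k]] = True
    elif rule == "frac_of_max":
        if frac is None:
            raise ConfigurationError("rule='frac_of_max' needs frac")
        keep_mask = vimp >= frac * vimp.max()
    else:
        raise ConfigurationError(f"unknown selection rule {rule!r}")
    kept = [names[j] for j in range(m) if keep_mask[j]]
    return ScreenResult(
        method="rf",
        kept=kept,
        forced=list(forced),
        diagnostics={"rule": rule, "k": k, "frac": frac},
    )


def cart_screen(X, y, cv_folds=10, seed=None, min_node=5):
    """Screen with a single cost-complexity-pruned regression tree.

    The pruning strength alpha is chosen by K-fold cross-validation with
    the one-standard-error rule (largest alpha whose CV error is within
    one SE of the minimum), the convention that guards against the
    overfitting a single tree is prone to.  Kept variables are those
    appearing in any split of the pruned tree; a root-only tree keeps
    nothing.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 20:
        raise ConfigurationError("cart_screen needs at least 20 samples")
    if np.ptp(y) == 0:
        raise DegenerateDataError("outcome is constant; CART is undefined")
    Xa = Xf.to_numpy(dtype=float)
    names = list(Xf.columns)

    path = DecisionTreeRegressor(
        min_samples_leaf=min_node, random_state=0
    ).cost_complexity_pruning_path(Xa, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    # Geometric midpoints make each candidate interior to its interval.
    if len(alphas) > 1:
        mids = np.sqrt(np.clip(alphas[:-1], 1e-12, None) * alphas[1:])
        grid = np.concatenate([[0.0], mids, [alphas[-1]]])
    else:
        grid = alphas
    if len(grid) > 40:  # thin a very fine path; endpoints always kept
        keep = np.unique(np.linspace(0, len(grid) - 1, 40).astype(int))
        grid = grid[keep]

    rng = np.random.default_rng(seed)
    fold_ids = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    fold_ids = rng.permutation(fold_ids)
    fold_mse = np.zeros((cv_folds, len(grid)))
    for k in range(cv_folds):
        tr, va = fold_ids != k, fold_ids == k
        for gi, a in enumerate(grid):
            tree = DecisionTreeRegressor(
                min_samples_leaf=min_node, ccp_alpha=a, random_state=0
            )
            tree.fit(Xa[tr], y[tr])
            pred = tree.predict(Xa[va])
            fold_mse[k, gi] = float(np.mean((y[va] - pred) ** 2))
    mean = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    # Largest alpha (strongest pruning) within one SE of the minimum.
    chosen = max(gi for gi in range(len(grid)) if mean[gi] <= threshold)
    final = DecisionTreeRegressor(
        min_samples_leaf=min_node, ccp_alpha=grid[chosen], random_state=0
    )
    final.fit(Xa, y)
    used = np.unique(final.tree_.feature)
    used = used[used >= 0]
    kept = [names[j] for j in sorted(used)]
    return ScreenResult(
        method="cart",
        kept=kept,
        diagnostics={
            "alpha": float(grid[chosen]),
            "cv_mse": float(mean[chosen]),
            "cv_min_mse": float(mean[best]),
            "n_leaves": int(final.get_n_leaves()),
        },
    )


class _BaseScreener(SelectorMixin, BaseEstimator):
    """Shared transformer plumbing for the screeners."""

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def _finalize(self, names, result):
        self.screen_result_ = result
        kept = set(result.kept)
        self.support_mask_ = np.array([c in kept for c in names])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self


class RandomForestVimpScreener(_BaseScreener):
    """Feature selector: keep variables with positive (or top-ranked) random
    forest permutation importance.

    Parameters mirror :func:`rf_vimp` and :func:`select_by_vimp`.  After
    ``fit``, ``vimp_table_`` holds the per-variable importances and
    ``screen_result_`` the kept set.
    """

    def __init__(self, n_trees=1000, mtry=None, min_node=5, rule="positive",
                 k=None, frac=None, random_state=None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node = min_node
        self.rule = rule
        self.k = k
        self.frac = frac
        self.random_state = random_state

    def fit(self, X, y):
        Xf = _as_frame(X)
        self.vimp_table_ = rf_vimp(
            Xf, y, n_trees=self.n_trees, mtry=self.mtry,
            min_node=self.min_node, seed=self.random_state,
        )
        result = select_by_vimp(
            self.vimp_table_, rule=self.rule, k=self.k, frac=self.frac
        )
        result.diagnostics.update(
            n_trees=self.n_trees,
            oob_error=None,
        )
        return self._finalize(list(Xf.columns), result)


class CartScreener(_BaseScreener):
    """Feature selector backed by a 1-SE cost-complexity-pruned CART tree."""

    def __init__(self, cv_folds=10, min_node=5, random_state=None):
        self.cv_folds = cv_folds
        self.min_node = min_node
        self.random_state = random_state

    def fit(self, X, y):
        Xf = _as_frame(X)
        result = cart_screen(
            Xf, y, cv_folds=self.cv_folds, seed=self.random_state,
            min_node=self.min_node,
        )
        return self._finalize(list(Xf.columns), result)
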