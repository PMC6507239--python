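"""End-to-end two-step workflows.

``TwoStepRegressor`` composes the pieces: an optional screening stage
(random-forest VIMP or pruned CART), optional pairwise interaction
expansion *among the screened variables only* (single-step runs expand
over all candidates), and the adaptive lasso with two-dimensional CV,
followed by a naive OLS refit for confidence intervals.  Confounders
bypass screening and enter the penalized stage with weight zero.

Interactions are expanded after screening for the two-step methods: a
variable that fails the screen can contribute neither a main effect nor
any product term.  This ordering is the point of the two-step design —
it shrinks the interaction search space before the penalized fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import __version__
from .alasso import AdaptiveLassoCV, refit_ols_ci
from .errors import ConfigurationError
from .evaluate import PerformanceReport, make_cv_plan, mspe_kfold, r2_metrics
from .screening import CartScreener, RandomForestVimpScreener, ScreenResult

logger = logging.getLogger(__name__)

__all__ = [
    "expand_interactions",
    "TwoStepRegressor",
    "evaluate_fit",
    "AnalysisConfig",
    "RunResult",
    "run_two_step",
]

METHODS = ("alasso", "cart_alasso", "rf_alasso")


def expand_interactions(X, variables=None, meta=None):
    """Append all pairwise products of the listed columns, re-standardized.

    Products are computed from the (already standardized) main-effect
    columns and each product column is itself re-centered and scaled to
    unit sample sd.  Term names are ``A:B`` with A before B in input
    column order; no quadratic (self-product) terms are created.
    Confounders should not be in ``variables``.

    When ``meta`` (from a previous call) is given, its stored means/sds
    are applied instead of refitting — used to transform held-out data.

    Returns ``(expanded, meta)`` where meta is a list of dicts with keys
    name/a/b/mean/sd.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(
            np.asarray(X, float),
            columns=[f"X{j + 1}" for j in range(np.asarray(X).shape[1])],
        )
    if variables is None:
        variables = list(X.columns)
    unknown = [v for v in variables if v not in X.columns]
    if unknown:
        raise ConfigurationError(f"variables not in design: {unknown}")
    if meta is not None:
        cols = {
            m["name"]: (X[m["a"]].to_numpy() * X[m["b"]].to_numpy()
                        - m["mean"]) / m["sd"]
            for m in meta
        }
        return pd.concat(
            [X, pd.DataFrame(cols, index=X.index)], axis=1
        ), meta
    order = [v for v in X.columns if v in set(variables)]
    if len(order) < 2:
        return X.copy(), []
    meta = []
    cols = {}
    for a, b in combinations(order, 2):
        prod = X[a].to_numpy() * X[b].to_numpy()
        mean = float(prod.mean())
        sd = float(prod.std(ddof=1))
        if sd < 1e-12:
            sd = 1.0
        name = f"{a}:{b}"
        cols[name] = (prod - mean) / sd
        meta.append({"name": name, "a": a, "b": b, "mean": mean, "sd": sd})
    out = pd.concat([X, pd.DataFrame(cols, index=X.index)], axis=1)
    return out, meta


class TwoStepRegressor(RegressorMixin, BaseEstimator):
    """Screen-then-shrink mixture regression.

    Parameters
    ----------
    method : {'alasso', 'cart_alasso', 'rf_alasso'}
        'alasso' is the single-step comparator (identity screen); the
        others screen main-effect candidates with a random forest
        (permutation VIMP) or a 1-SE-pruned CART tree first.
    with_interactions : bool
        Expand pairwise products among the retained variables (all
        candidates for the single-step method) before the penalized fit.
    confounders : list of str
        Columns force-carried into the second stage unpenalized; they
        never enter screening or products.
    screen_rule, n_trees, mtry, min_node, cart_cv_folds :
        Screening hyperparameters (see the screening module).
    gamma_grid, n_lambdas, cv, init :
        Adaptive-lasso tuning hyperparameters (see AdaptiveLassoCV).
    hierarchy : bool
        If True, drop selected interactions whose parent main effects are
        not both selected (strong-hierarchy filter; off by default, since
        interaction-only signals are reportable).
    preset_kept : list of str, optional
        Fix the screened set instead of running the screener (used by the
        fixed-screen CV mode).
    cv_mode : {'nested', 'fixed-screen'}
        How performance CV re-runs the procedure (consumed by
        :func:`evaluate_fit`).

    Attributes
    ----------
    screen_result_ : ScreenResult
    fit_ : fitted AdaptiveLassoCV on the stage-two design
    design_columns_ : stage-two design column order
    interaction_meta_ : product-term standardization metadata
    support_ : selected terms (mains and interactions, confounders excluded)
    ci_table_ : naive OLS-refit confidence intervals
    """

    def __init__(
        self,
        method="rf_alasso",
        with_interactions=False,
        confounders=None,
        screen_rule="positive",
        n_trees=1000,
        mtry=None,
        min_node=5,
        cart_cv_folds=10,
        gamma_grid=(0.5, 1.0, 2.0),
        n_lambdas=100,
        cv=10,
        init="auto",
        selection="1se",
        hierarchy=False,
        ci_level=0.95,
        preset_kept=None,
        cv_mode="nested",
        random_state=None,
    ):
        self.method = method
        self.with_interactions = with_interactions
        self.confounders = confounders
        self.screen_rule = screen_rule
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node = min_node
        self.cart_cv_folds = cart_cv_folds
        self.gamma_grid = gamma_grid
        self.n_lambdas = n_lambdas
        self.cv = cv
        self.init = init
        self.selection = selection
        self.hierarchy = hierarchy
        self.ci_level = ci_level
        self.preset_kept = preset_kept
        self.cv_mode = cv_mode
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _screen(self, X_exp, y):
        if self.preset_kept is not None:
            return ScreenResult(
                method="preset", kept=list(self.preset_kept),
                forced=list(self._confounders),
            )
        if self.method == "alasso":
            return ScreenResult(
                method="none", kept=list(X_exp.columns),
                forced=list(self._confounders),
            )
        if self.method == "rf_alasso":
            screener = RandomForestVimpScreener(
                n_trees=self.n_trees, mtry=self.mtry, min_node=self.min_node,
                rule=self.screen_rule, random_state=self.random_state,
            )
        elif self.method == "cart_alasso":
            screener = CartScreener(
                cv_folds=self.cart_cv_folds, min_node=self.min_node,
                random_state=self.random_state,
            )
        else:
            raise ConfigurationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        screener.fit(X_exp, y)
        result = screener.screen_result_
        result.forced = list(self._confounders)
        if isinstance(screener, RandomForestVimpScreener):
            self.vimp_table_ = screener.vimp_table_
        if result.empty:
            logger.warning(
                "screening kept no variables; falling back to the "
                "unscreened single-step analysis"
            )
            result = ScreenResult(
                method=result.method, kept=list(X_exp.columns),
                forced=list(self._confounders),
                diagnostics={**result.diagnostics, "fallback": True},
            )
        return result

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, float),
                columns=[f"X{j + 1}" for j in range(np.asarray(X).shape[1])],
            )
        y = np.asarray(y, dtype=float)
        self._confounders = list(self.confounders or [])
        missing = [c for c in self._confounders if c not in X.columns]
        if missing:
            raise ConfigurationError(f"confounder columns absent: {missing}")
        exp_cols = [c for c in X.columns if c not in self._confounders]
        X_exp = X[exp_cols]

        corr = X_exp.corr().to_numpy()
        hi = np.abs(np.triu(corr, 1)) > 0.8
        if hi.any():
            pairs = [
                (exp_cols[i], exp_cols[j]) for i, j in zip(*np.nonzero(hi))
            ]
            warnings.warn(
                f"highly correlated predictor pairs (|r| > 0.8): {pairs}; "
                "consider removing one of each pair before analysis",
                UserWarning,
            )

        self.screen_result_ = self._screen(X_exp, y)
        kept = list(self.screen_result_.kept)

        design = X[kept + self._confounders]
        self.interaction_meta_ = []
        if self.with_interactions:
            design, self.interaction_meta_ = expand_interactions(
                design, variables=kept
            )
        if design.shape[1] > 0.8 * len(y):
            warnings.warn(
                f"design has {design.shape[1]} columns for {len(y)} samples "
                "after expansion; selection is most reliable for designs "
                "of roughly 10-50 predictors",
                UserWarning,
            )

        self.fit_ = AdaptiveLassoCV(
            gamma_grid=self.gamma_grid,
            n_lambdas=self.n_lambdas,
            cv=self.cv,
            init=self.init,
            selection=self.selection,
            penalty_free=self._confounders or None,
            random_state=self.random_state,
        ).fit(design, y)

        support = list(self.fit_.support_)
        if self.hierarchy and self.interaction_meta_:
            parents = {m["name"]: (m["a"], m["b"]) for m in self.interaction_meta_}
            support = [
                s for s in support
                if s not in parents
                or (parents[s][0] in support and parents[s][1] in support)
            ]
        self.support_ = support
        self.design_columns_ = list(design.columns)
        self.ci_table_ = refit_ols_ci(
            design, y, support, forced=self._confounders, level=self.ci_level
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _build_design(self, X):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, float), columns=list(self.feature_names_in_)
            )
        base = [c for c in self.design_columns_ if ":" not in c]
        design = X[base]
        if self.interaction_meta_:
            design, _ = expand_interactions(
                design, meta=self.interaction_meta_
            )
        return design[self.design_columns_]

    def predict(self, X):
        check_is_fitted(self, "fit_")
        return self.fit_.predict(self._build_design(X))

    @property
    def p_effective_(self):
        """Nonzero coefficients excluding the intercept (selected mains,
        interactions, and forced confounders)."""
        check_is_fitted(self, "fit_")
        return int(np.count_nonzero(self.fit_.coef_std_))


def evaluate_fit(est, X, y, K=10, seed=None, plan=None):
    """Full performance report for a fitted TwoStepRegressor.

    In-sample R^2 / adjusted R^2 / MSE come from the fitted model; the CV
    columns re-run the procedure inside each training fold ('nested'
    mode, the default: screening, tuning and fitting are repeated per
    fold so no selection leaks into the held-out part) or keep the
    full-data screen fixed and re-run only the penalized stage
    ('fixed-screen' mode).
    """
    check_is_fitted(est, "fit_")
    y = np.asarray(y, dtype=float)
    if plan is None:
        plan = make_cv_plan(len(y), K=K, seed=seed)
    r2, adj, mse = r2_metrics(y, est.predict(X), est.p_effective_)

    if est.cv_mode == "fixed-screen":
        refit = clone(est)
        refit.set_params(preset_kept=list(est.screen_result_.kept))
    elif est.cv_mode == "nested":
        refit = clone(est)
    else:
        raise ConfigurationError(f"unknown cv_mode {est.cv_mode!r}")

    def fit_fn(Xtr, ytr):
        return clone(refit).fit(Xtr, ytr)

    mse_cv, mspe_cv, plan = mspe_kfold(fit_fn, X, y, plan=plan)
    return PerformanceReport(
        r2=r2,
        adj_r2=adj,
        mse=mse,
        mse_cv=mse_cv,
        mspe_cv=mspe_cv,
        p_effective=est.p_effective_,
        K=plan.K,
        seed=plan.seed,
        notes={
            "cv_mode": est.cv_mode,
            "mse_cv_definition": "fold-size-weighted mean of training MSEs",
        },
    )


@dataclass
class AnalysisConfig:
    """Fully serializable description of one analysis run."""

    method: str = "rf_alasso"
    with_interactions: bool = False
    confounders: list = field(default_factory=list)
    screen_rule: str = "positive"
    n_trees: int = 1000
    mtry: int | None = None
    min_node: int = 5
    cart_cv_folds: int = 10
    gamma_grid: list = field(default_factory=lambda: [0.5, 1.0, 2.0])
    n_lambdas: int = 100
    K: int = 10
    init: str = "auto"
    selection: str = "1se"
    cv_mode: str = "nested"
    hierarchy: bool = False
    seed: int | None = None

    def to_json(self, **kwargs):
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text):
        return cls(**json.loads(text))

    def estimator(self):
        return TwoStepRegressor(
            method=self.method,
            with_interactions=self.with_interactions,
            confounders=list(self.confounders),
            screen_rule=self.screen_rule,
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node=self.min_node,
            cart_cv_folds=self.cart_cv_folds,
            gamma_grid=tuple(self.gamma_grid),
            n_lambdas=self.n_lambdas,
            cv=self.K,
            init=self.init,
            selection=self.selection,
            cv_mode=self.cv_mode,
            hierarchy=self.hierarchy,
            random_state=self.seed,
        )


@dataclass
class RunResult:
    """Artifacts of one end-to-end run."""

    screen: ScreenResult
    support: list
    coefficients: pd.DataFrame
    ci_table: pd.DataFrame
    performance: PerformanceReport
    provenance: dict
    estimator: TwoStepRegressor = None


def run_two_step(data, config, evaluate=True):
    """Execute the full workflow described by an :class:`AnalysisConfig`.

    ``data`` is a SimulatedDataset or an ``(X, y)`` pair with X a
    DataFrame of standardized exposures (plus confounder columns).
    """
    if hasattr(data, "X"):
        X, y = data.X, np.asarray(data.y, dtype=float)
        if data.Z is not None:
            X = X.copy()
            X["Z"] = np.asarray(data.Z, dtype=float)
            if "Z" not in config.confounders:
                config.confounders = list(config.confounders) + ["Z"]
    else:
        X, y = data
        y = np.asarray(y, dtype=float)

    est = config.estimator()
    est.fit(X, y)
    if evaluate:
        performance = evaluate_fit(est, X, y, K=config.K, seed=config.seed)
    else:
        r2, adj, mse = r2_metrics(y, est.predict(X), est.p_effective_)
        performance = PerformanceReport(
            r2=r2, adj_r2=adj, mse=mse, p_effective=est.p_effective_,
            K=config.K, seed=config.seed,
        )

    coefs = pd.DataFrame(
        {
            "term": est.design_columns_,
            "estimate_std": est.fit_.coef_std_,
            "estimate": est.fit_.coef_,
            "selected": [
                c in set(est.support_) for c in est.design_columns_
            ],
        }
    )
    cfg_json = config.to_json(sort_keys=True)
    provenance = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return RunResult(
        screen=est.screen_result_,
        support=list(est.support_),
        coefficients=coefs,
        ci_table=est.ci_table_,
        performance=performance,
        provenance=provenance,
        estimator=est,
    )
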