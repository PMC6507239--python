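"""Quality control and standardization of biomonitoring exposure tables.

The rules implemented here mirror standard practice for trace-analyte
concentration data:

* concentrations censored below the limit of detection (LOD) are imputed
  as LOD / sqrt(2);
* variables whose combined missing + below-LOD fraction exceeds 40% are
  excluded (strictly "more than" 40%: a variable at exactly the threshold
  is retained);
* surviving exposures are natural-log transformed (concentrations are
  right-skewed and strictly positive after imputation) and z-scored so
  that coefficients are comparable across analytes with very different
  concentration ranges.

Structurally missing (non-LOD) cells that survive the filter are handled
by complete-case row deletion by default; a mean-impute option exists but
is off by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DomainError,
    InputError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureTable",
    "StandardizedMatrix",
    "read_exposure_csv",
    "impute_lod",
    "filter_missing",
    "complete_case",
    "mean_impute",
    "log_zscore",
    "creatinine_correct",
    "LogZScoreScaler",
]

#: Cell strings treated as structurally missing.
MISSING_SENTINELS = ("", "NA", "NaN", "nan")
#: Cell string marking a below-LOD measurement with unrecorded value.
BELOW_LOD_SENTINEL = "<LOD"


@dataclass
class ExposureTable:
    """Raw exposure concentrations with censoring/missingness metadata.

    ``values`` is a samples x variables DataFrame; ``missing_mask`` and
    ``below_lod_mask`` are aligned boolean frames and are disjoint per
    cell.  ``lod`` maps variable name -> detection limit (same units as
    the values).  ``var_meta`` optionally carries a matrix-of-origin tag
    (blood | serum | urine) and a display name per variable.
    """

    values: pd.DataFrame
    lod: dict = field(default_factory=dict)
    missing_mask: pd.DataFrame = None
    below_lod_mask: pd.DataFrame = None
    var_meta: pd.DataFrame = None

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if self.below_lod_mask is None:
            self.below_lod_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if (self.missing_mask & self.below_lod_mask).any().any():
            raise ConfigurationError(
                "missing_mask and below_lod_mask must be disjoint"
            )

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def variables(self):
        return list(self.values.columns)


@dataclass
class StandardizedMatrix:
    """Log/z-scored design with the fitted per-column statistics.

    ``column_means`` and ``column_sds`` are on the log scale; applying
    them to held-out data reproduces the training transformation.
    """

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    transform_log: bool = True

    def transform(self, raw):
        """Apply the stored transformation to new raw concentrations."""
        raw = raw[self.values.columns]
        x = np.log(raw) if self.transform_log else raw
        return (x - self.column_means) / self.column_sds

    def inverse_transform(self, standardized):
        """Back to raw concentrations (exp(mean + sd * z))."""
        x = standardized * self.column_sds + self.column_means
        return np.exp(x) if self.transform_log else x


def read_exposure_csv(
    path,
    outcome_col,
    confounder_cols=(),
    lod_map=None,
    sep=None,
    sample_id_col=None,
):
    """Read a samples x variables delimited table into an ExposureTable.

    Missing cells are empty strings or ``NA``; a cell equal to ``<LOD``,
    or numerically below its variable's detection limit from ``lod_map``,
    is flagged below-LOD.  The outcome column and any confounder columns
    are split off from the exposures.

    Returns ``(table, outcome, confounders)``.
    """
    lod_map = dict(lod_map or {})
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if sample_id_col is not None and sample_id_col in raw.columns:
        raw = raw.set_index(sample_id_col)
    if outcome_col not in raw.columns:
        raise InputError(f"outcome column {outcome_col!r} not found")
    for c in confounder_cols:
        if c not in raw.columns:
            raise InputError(f"confounder column {c!r} not found")

    def numeric(col, allow_sentinels):
        out = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw[col].astype(str).str.strip()):
            if cell in MISSING_SENTINELS:
                continue
            if allow_sentinels and cell == BELOW_LOD_SENTINEL:
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at row {i}, column {col!r}"
                ) from None
        return out

    y = pd.Series(numeric(outcome_col, False), index=raw.index, name=outcome_col)
    if y.isna().any():
        logger.warning("outcome column has missing values")
    conf = pd.DataFrame(
        {c: numeric(c, False) for c in confounder_cols}, index=raw.index
    )

    exp_cols = [
        c for c in raw.columns if c != outcome_col and c not in confounder_cols
    ]
    values = pd.DataFrame(index=raw.index)
    missing = pd.DataFrame(index=raw.index)
    below = pd.DataFrame(index=raw.index)
    for c in exp_cols:
        cells = raw[c].astype(str).str.strip()
        vals = numeric(c, True)
        is_sentinel_lod = (cells == BELOW_LOD_SENTINEL).to_numpy()
        is_missing = np.isnan(vals) & ~is_sentinel_lod
        is_below = is_sentinel_lod.copy()
        if c in lod_map:
            with np.errstate(invalid="ignore"):
                is_below |= vals < lod_map[c]
        values[c] = vals
        missing[c] = is_missing
        below[c] = is_below
    table = ExposureTable(
        values=values,
        lod=lod_map,
        missing_mask=missing,
        below_lod_mask=below,
    )
    return table, y, conf


def impute_lod(table):
    """Replace every below-LOD cell with LOD / sqrt(2); other cells are
    unchanged and the below-LOD mask is preserved for audit."""
    values = table.values.copy()
    for c in table.variables:
        mask = table.below_lod_mask[c]
        if not mask.any():
            continue
        if c not in table.lod:
            raise ConfigurationError(
                f"variable {c!r} has below-LOD cells but no LOD metadata"
            )
        values.loc[mask, c] = table.lod[c] / np.sqrt(2.0)
    return replace(table, values=values)


def filter_missing(table, max_missing_frac=0.40, count_below_lod=True):
    """Drop variables whose missingness exceeds ``max_missing_frac``.

    Missingness counts structurally missing cells plus (by default)
    below-LOD cells; the rule is a strict inequality, so a variable at
    exactly the threshold is retained.  Returns ``(table, drop_report)``
    where the report lists each dropped variable with its fraction.
    """
    if not 0 <= max_missing_frac < 1:
        raise ConfigurationError("max_missing_frac must be in [0, 1)")
    combined = table.missing_mask.copy()
    if count_below_lod:
        combined |= table.below_lod_mask
    frac = combined.mean(axis=0)
    dropped = [
        {"variable": c, "fraction": float(frac[c]), "reason": "missingness"}
        for c in table.variables
        if frac[c] > max_missing_frac
    ]
    keep = [c for c in table.variables if frac[c] <= max_missing_frac]
    if not keep:
        raise DegenerateDataError("all variables exceed the missingness limit")
    out = replace(
        table,
        values=table.values[keep],
        missing_mask=table.missing_mask[keep],
        below_lod_mask=table.below_lod_mask[keep],
        var_meta=None if table.var_meta is None else table.var_meta.loc[keep],
    )
    if dropped:
        logger.info(
            "dropped %d variables over the missingness limit: %s",
            len(dropped),
            ", ".join(d["variable"] for d in dropped),
        )
    return out, dropped


def complete_case(table, *extra_frames):
    """Drop rows with any structurally missing exposure cell; aligned
    extra frames/series are subset to the same rows."""
    keep_rows = ~table.missing_mask.any(axis=1)
    n_drop = int((~keep_rows).sum())
    if n_drop:
        logger.info("complete-case deletion removed %d of %d rows",
                    n_drop, len(keep_rows))
    out = replace(
        table,
        values=table.values.loc[keep_rows],
        missing_mask=table.missing_mask.loc[keep_rows],
        below_lod_mask=table.below_lod_mask.loc[keep_rows],
    )
    extras = tuple(f.loc[keep_rows] for f in extra_frames)
    return (out, *extras) if extras else out


def mean_impute(table):
    """Replace structurally missing cells by the column mean of the
    observed cells (off by default in the pipeline; complete-case is the
    standard route)."""
    values = table.values.copy()
    for c in table.variables:
        mask = table.missing_mask[c]
        if mask.any():
            values.loc[mask, c] = values.loc[~mask, c].mean()
    missing = pd.DataFrame(
        False, index=table.values.index, columns=table.values.columns
    )
    return replace(table, values=values, missing_mask=missing)


def creatinine_correct(table, creatinine, urine_vars=None):
    """Divide urine analyte columns by a per-sample creatinine vector.

    Provided as an optional hook for data not already creatinine-corrected
    upstream; ``urine_vars`` defaults to the variables tagged matrix
    'urine' in ``var_meta`` (all variables if no metadata)."""
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise DomainError("creatinine values must be strictly positive")
    if urine_vars is None:
        if table.var_meta is not None and "matrix" in table.var_meta:
            urine_vars = [
                v for v in table.variables
                if table.var_meta.loc[v, "matrix"] == "urine"
            ]
        else:
            urine_vars = table.variables
    values = table.values.copy()
    for c in urine_vars:
        values[c] = values[c] / creatinine
    return replace(table, values=values)


class LogZScoreScaler(TransformerMixin, BaseEstimator):
    """Natural-log transform followed by per-column z-scoring (sample sd).

    The natural log (rather than log10) is used; after z-scoring the base
    only shifts/scales columns, so downstream fits are base-invariant, but
    fixing it keeps stored statistics reproducible.
    """

    def __init__(self, log=True):
        self.log = log

    def fit(self, X, y=None):
        X = self._validate(X)
        L = np.log(X) if self.log else X
        self.means_ = L.mean(axis=0)
        sds = L.std(axis=0, ddof=1)
        bad = np.flatnonzero(np.asarray(sds) < 1e-12)
        if bad.size:
            names = (
                [X.columns[j] for j in bad]
                if isinstance(X, pd.DataFrame)
                else bad.tolist()
            )
            raise DegenerateDataError(
                f"zero-variance column(s) after log transform: {names}"
            )
        self.sds_ = sds
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = self._validate(X)
        L = np.log(X) if self.log else X
        return (L - self.means_) / self.sds_

    def inverse_transform(self, Z):
        check_is_fitted(self, "means_")
        L = Z * self.sds_ + self.means_
        return np.exp(L) if self.log else L

    def _validate(self, X):
        arr = np.asarray(X, dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise DomainError(
                f"missing cell at row {i}, column {j}; complete-case or "
                "impute before standardizing"
            )
        if self.log and (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise DomainError(
                f"non-positive cell at row {i}, column {j}; the log "
                "transform needs strictly positive concentrations"
            )
        return X if isinstance(X, pd.DataFrame) else arr


def log_zscore(table):
    """Standardize an exposure table: elementwise natural log, then each
    column centered and scaled to unit sample standard deviation.

    Requires all cells positive (run after :func:`impute_lod`) and no
    structurally missing cells (complete-case or impute first).  Returns
    a :class:`StandardizedMatrix` holding the fitted statistics.
    """
    scaler = LogZScoreScaler(log=True)
    vals = table.values
    scaler.fit(vals)
    z = scaler.transform(vals)
    return StandardizedMatrix(
        values=pd.DataFrame(z, index=vals.index, columns=vals.columns),
        column_means=pd.Series(scaler.means_, index=vals.columns),
        column_sds=pd.Series(scaler.sds_, index=vals.columns),
        transform_log=True,
    )


def drop_report_json(dropped, **kwargs):
    """Serialize a filter_missing drop report."""
    return json.dumps(dropped, **kwargs)
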