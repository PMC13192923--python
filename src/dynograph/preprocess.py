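"""Preprocessing chain: median imputation -> standardization -> residualization.

All statistics are fitted on training rows only and applied unchanged to
held-out rows, so no information leaks across the subject-level splits.
Residualization removes covariate-explained variation from every predictor
column: X_res = X - C (C'C)^-1 C' X, computed by QR-based least squares
rather than the explicit inverse.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessState",
    "fit_impute",
    "apply_impute",
    "fit_standardize",
    "apply_standardize",
    "residualize",
    "fit_residualize",
    "apply_residualize",
    "build_covariate_matrix",
    "fit_preprocess",
    "apply_preprocess",
]


@dataclass
class PreprocessState:
    """Frozen training-set statistics for exact out-of-sample reuse.

    ``medians`` are per-feature training medians; ``mean``/``std`` the
    standardization parameters (population convention, divisor n);
    ``dropped`` lists zero-variance features removed at fit time;
    ``residual_coef`` the least-squares covariate coefficient matrix
    (n_covariate_columns x n_features) and ``covariate_columns`` the
    design-matrix column order it expects (intercept first).
    """

    feature_names: list[str]
    medians: dict[str, float]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)
    residual_coef: np.ndarray | None = None
    residual_coef_per_t: dict = field(default_factory=dict)
    site_levels: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [f for f in self.feature_names if f not in set(self.dropped)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "medians": self.medians,
            "mean": self.mean,
            "std": self.std,
            "dropped": self.dropped,
            "covariate_columns": self.covariate_columns,
            "residual_coef": None
            if self.residual_coef is None
            else self.residual_coef.tolist(),
            "residual_coef_per_t": {
                k: np.asarray(v).tolist() for k, v in self.residual_coef_per_t.items()
            },
            "site_levels": self.site_levels,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        payload = json.loads(Path(path).read_text())
        coef = payload.pop("residual_coef")
        per_t = {k: np.asarray(v) for k, v in payload.pop("residual_coef_per_t", {}).items()}
        return cls(
            residual_coef=None if coef is None else np.asarray(coef),
            residual_coef_per_t=per_t,
            **payload,
        )


def fit_impute(train: pd.DataFrame, feature_cols: list[str]) -> PreprocessState:
    """Record the training median of every feature column."""
    medians: dict[str, float] = {}
    for col in feature_cols:
        vals = train[col].to_numpy(dtype=float)
        if np.isnan(vals).all():
            raise ValueError(f"feature column {col!r} is entirely missing in training data")
        medians[col] = float(np.nanmedian(vals))
    return PreprocessState(feature_names=list(feature_cols), medians=medians)


def apply_impute(panel: pd.DataFrame, state: PreprocessState) -> pd.DataFrame:
    """Fill missing feature cells with the stored training medians."""
    out = panel.copy()
    for col in state.feature_names:
        out[col] = out[col].fillna(state.medians[col])
    return out


def fit_standardize(train: pd.DataFrame, state: PreprocessState) -> PreprocessState:
    """Fit per-feature mean/SD (divisor n); zero-variance features are dropped."""
    for col in state.feature_names:
        vals = train[col].to_numpy(dtype=float)
        mu = float(np.mean(vals))
        sigma = float(np.std(vals))
        if sigma == 0.0:
            warnings.warn(
                f"feature {col!r} has zero variance in training data; dropped",
                stacklevel=2,
            )
            logger.warning("dropping zero-variance feature %r", col)
            state.dropped.append(col)
            continue
        state.mean[col] = mu
        state.std[col] = sigma
    return state


def apply_standardize(panel: pd.DataFrame, state: PreprocessState) -> pd.DataFrame:
    """Transform with the stored training mean/SD; dropped columns are removed."""
    out = panel.copy()
    out = out.drop(columns=[c for c in state.dropped if c in out.columns])
    for col in state.retained:
        out[col] = (out[col] - state.mean[col]) / state.std[col]
    return out


def build_covariate_matrix(
    panel: pd.DataFrame,
    covariate_cols: list[str],
    site_levels: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric covariate design matrix with intercept.

    Categorical covariates (object/string dtype, e.g. site) are one-hot
    encoded with the first level dropped as reference so the design stays
    full rank.  ``site_levels`` fixes the level order learned at fit time.
    """
    columns: list[np.ndarray] = [np.ones(len(panel))]
    names = ["intercept"]
    levels_used: list[str] = []
    for col in covariate_cols:
        series = panel[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = site_levels or sorted(series.astype(str).unique())
            levels_used = list(levels)
            for lev in levels[1:]:
                columns.append((series.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}={lev}")
        else:
            columns.append(series.to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(columns), names, levels_used


def _check_full_rank(C: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending columns by sequential rank growth
        bad = []
        kept: list[int] = []
        for j in range(C.shape[1]):
            trial = C[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")


def residualize(X: np.ndarray, C: np.ndarray, add_intercept: bool = True) -> np.ndarray:
    """Least-squares residuals of each column of X against the covariates C.

    Equivalent to X - C (C'C)^-1 C' X but solved via QR for stability.  An
    intercept column is appended unless C already spans the constants.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if C.ndim == 1:
        C = C[:, None]
    if X.shape[0] != C.shape[0]:
        raise ValueError("X and C must have the same number of rows")
    if add_intercept:
        C = np.column_stack([np.ones(C.shape[0]), C])
        names = ["intercept"] + [f"C{j}" for j in range(C.shape[1] - 1)]
    else:
        names = [f"C{j}" for j in range(C.shape[1])]
    _check_full_rank(C, names)
    coef, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ coef


def fit_residualize(
    train: pd.DataFrame,
    state: PreprocessState,
    covariate_cols: list[str],
    per_timepoint: bool = False,
) -> PreprocessState:
    """Fit covariate coefficients on training rows for out-of-sample reuse.

    By default all training rows are pooled into one projection.  With
    ``per_timepoint`` a separate coefficient matrix is fitted per visit
    index, for designs where covariate effects drift across visits.
    """
    C, names, levels = build_covariate_matrix(train, covariate_cols)
    _check_full_rank(C, names)
    X = train[state.retained].to_numpy(dtype=float)
    if per_timepoint:
        coefs: dict[str, list] = {}
        for t, idx in train.groupby("t").indices.items():
            Ct, Xt = C[idx], X[idx]
            _check_full_rank(Ct, names)
            coef_t, *_ = np.linalg.lstsq(Ct, Xt, rcond=None)
            coefs[str(int(t))] = coef_t
        state.residual_coef_per_t = coefs
    else:
        coef, *_ = np.linalg.lstsq(C, X, rcond=None)
        state.residual_coef = coef
    state.covariate_columns = names
    state.site_levels = levels
    return state


def apply_residualize(
    panel: pd.DataFrame, state: PreprocessState, covariate_cols: list[str]
) -> pd.DataFrame:
    """Subtract the training-fitted covariate projection from the features."""
    if state.residual_coef is None and not state.residual_coef_per_t:
        raise ValueError("residualization was not fitted")
    C, names, _ = build_covariate_matrix(
        panel, covariate_cols, site_levels=state.site_levels or None
    )
    if names != state.covariate_columns:
        raise ValueError(
            f"covariate design mismatch: fitted {state.covariate_columns}, got {names}"
        )
    out = panel.copy()
    X = out[state.retained].to_numpy(dtype=float)
    if state.residual_coef_per_t:
        res = np.empty_like(X)
        for t, idx in panel.reset_index(drop=True).groupby("t").indices.items():
            key = str(int(t))
            if key not in state.residual_coef_per_t:
                raise ValueError(f"no per-visit projection fitted for t={t}")
            coef = np.asarray(state.residual_coef_per_t[key])
            res[idx] = X[idx] - C[idx] @ coef
        out[state.retained] = res
    else:
        out[state.retained] = X - C @ state.residual_coef
    return out


def fit_preprocess(
    train: pd.DataFrame,
    feature_cols: list[str],
    covariate_cols: list[str] | None = None,
    per_timepoint: bool = False,
) -> PreprocessState:
    """Fit the full chain (impute -> standardize -> residualize) on training rows."""
    state = fit_impute(train, feature_cols)
    imputed = apply_impute(train, state)
    state = fit_standardize(imputed, state)
    standardized = apply_standardize(imputed, state)
    if covariate_cols:
        state = fit_residualize(standardized, state, covariate_cols, per_timepoint)
    return state


def apply_preprocess(
    panel: pd.DataFrame,
    state: PreprocessState,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Apply a fitted chain to any rows (training or held-out)."""
    out = apply_standardize(apply_impute(panel, state), state)
    if covariate_cols and (state.residual_coef is not None or state.residual_coef_per_t):
        out = apply_residualize(out, state, covariate_cols)
    return out
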