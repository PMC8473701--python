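"""Linear free energy relationship (LFER) models.

The central model form is

    Y = b1 * logP_ow + b2 * S_m + b3 * H_M_HBD + b4 * Flex + c

where Y is a free-energy-determined molecular property (a partition
coefficient, skin permeability, an air/tissue partition coefficient, ...),
logP_ow is an organic-solvent/water partition coefficient (hexadecane/water
logP_16 or octanol/water logP_oct), and the remaining descriptors capture
molecular size, hydrogen-bond-donor capability and conformational
flexibility. Any subset of the four predictors is permitted: each model
records exactly the coefficient set it was built with.

Fitting is ordinary least squares with intercept (statsmodels under the
hood), exposed both as the sklearn-style :class:`LFERRegressor` and as the
functional :func:`fit`. Six ready-to-use literature models ship in
:func:`preset_models`, carrying their published coefficients and statistics
as metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .chemio import CompoundTable
from .descriptors import DescriptorVector
from .errors import BasisMismatch, CollinearDescriptors, LFERKitError, ModelFormatError

SCHEMA_VERSION = "lfer-model/1"

#: Descriptor column names recognised as a logP basis.
BASIS_COLUMNS = {"logP16": "logP16", "logPoct": "logPoct"}


@dataclass(frozen=True)
class FitStatistics:
    """Regression quality summary.

    ``sd`` is the residual standard error sqrt(SSE / (n − p − 1)) and ``f``
    the overall regression F statistic [(SST − SSE)/p] / [SSE/(n − p − 1)],
    matching spreadsheet multiple-regression output conventions. ``q2_loo``
    and ``q2_ext`` are the leave-one-out and external predictive squared
    correlations when available.
    """

    n: int
    r2: float
    sd: float
    f: float
    q2_loo: float | None = None
    q2_ext: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of range: {self.r2}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class LFERModel:
    """A fitted (or literature) LFER model.

    ``coefficients`` maps descriptor column names to slopes; prediction is
    the dot product over exactly that set plus the intercept — descriptors
    absent from the map contribute nothing. ``basis_name`` identifies which
    logP scale (if any) the model uses, and ``provenance`` distinguishes
    models fitted here ("fitted") from published ones ("literature", whose
    statistics are reported verbatim rather than recomputed).
    """

    property_name: str
    coefficients: Mapping[str, float]
    intercept: float
    basis_name: str = "none"
    stats: FitStatistics | None = None
    training_meta: Mapping | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        if self.basis_name not in ("logP16", "logPoct", "none"):
            raise ValueError(f"unknown basis {self.basis_name!r}")
        if self.training_meta is not None:
            cols = set(self.training_meta.get("descriptor_cols", self.coefficients))
            missing = set(self.coefficients) - cols
            if missing:
                raise ValueError(f"coefficients {sorted(missing)} not among training descriptor columns")

    @property
    def descriptor_cols(self) -> list[str]:
        return list(self.coefficients)

    def predict_mapping(self, values: Mapping[str, float]) -> float:
        missing = [c for c in self.coefficients if c not in values]
        if missing:
            raise LFERKitError(f"descriptor value(s) missing for prediction: {', '.join(missing)}")
        return float(sum(b * float(values[c]) for c, b in self.coefficients.items()) + self.intercept)

    def predict_vector(self, v: DescriptorVector) -> float:
        if self.basis_name != "none":
            if v.basis_name != self.basis_name:
                raise BasisMismatch(self.basis_name, v.basis_name)
        return self.predict_mapping(v.as_mapping())

    def predict_frame(self, df: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.coefficients if c not in df.columns]
        if missing:
            raise LFERKitError(f"prediction table lacks column(s): {', '.join(missing)}")
        yhat = pd.Series(np.full(len(df), self.intercept, dtype=float), index=df.index)
        for c, b in self.coefficients.items():
            yhat = yhat + b * df[c].astype(float)
        return yhat.rename(f"{self.property_name}_pred")


def _find_collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Identify columns implicated in rank deficiency via pivoted QR."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    dependent = sorted(piv[rank:])
    if not dependent:
        return list(names)
    return [names[i] for i in dependent]


class LFERRegressor(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares LFER estimator with sklearn semantics.

    Parameters
    ----------
    property_name : str
        Name of the response (e.g. ``"logKp"``); used for labelling only.
    basis_name : {"logP16", "logPoct", "none"}
        Which logP scale, if any, appears among the predictors. Checked at
        prediction time for :class:`DescriptorVector` inputs.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray of slopes, one per descriptor column
    intercept_ : float
    feature_names_in_ : ndarray of descriptor column names
    stats_ : :class:`FitStatistics` of the training fit
    residuals_ : ndarray of training residuals
    model_ : the equivalent immutable :class:`LFERModel`
    """

    def __init__(self, property_name: str = "Y", basis_name: str = "none") -> None:
        self.property_name = property_name
        self.basis_name = basis_name

    def fit(self, X, y, ids: Sequence[str] | None = None) -> "LFERRegressor":
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise ValueError("X must be two-dimensional")
            names = [f"x{i}" for i in range(Xv.shape[1])]
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xv.shape
        if yv.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {yv.shape[0]}")
        if not (np.isfinite(Xv).all() and np.isfinite(yv).all()):
            raise ValueError("X and y must be finite (drop incomplete rows before fitting)")
        if n < p + 2:
            raise LFERKitError(f"need at least {p + 2} complete rows to fit {p} descriptors, got {n}")
        design = sm.add_constant(Xv, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearDescriptors(_find_collinear_columns(Xv, names))
        res = sm.OLS(yv, design).fit()
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.intercept_ = float(res.params[0])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.residuals_ = np.asarray(res.resid, dtype=float)
        sse = float(res.ssr)
        sst = float(res.centered_tss)
        dof = n - p - 1
        sd = math.sqrt(sse / dof) if dof > 0 else float("nan")
        fstat = ((sst - sse) / p) / (sse / dof) if p > 0 and dof > 0 and sse > 0 else float(res.fvalue or 0.0)
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        self.stats_ = FitStatistics(n=n, r2=min(max(r2, 0.0), 1.0), sd=sd, f=float(fstat))
        self.model_ = LFERModel(
            property_name=self.property_name,
            coefficients=dict(zip(names, self.coef_)),
            intercept=self.intercept_,
            basis_name=self.basis_name,
            stats=self.stats_,
            training_meta={
                "n": n,
                "ids": [str(i) for i in ids] if ids is not None else None,
                "descriptor_cols": names,
                "y_mean": float(yv.mean()),
            },
            provenance="fitted",
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            return self.model_.predict_frame(X).to_numpy()
        Xv = np.asarray(X, dtype=float)
        return Xv @ self.coef_ + self.intercept_


def _as_frame(table: CompoundTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, CompoundTable) else table


def fit(
    table: CompoundTable | pd.DataFrame,
    property_col: str,
    descriptor_cols: Sequence[str],
    basis_name: str | None = None,
) -> LFERModel:
    """Fit an LFER by OLS on the complete rows of a compound table.

    Rows with missing values in the response or any descriptor are excluded
    (no imputation). ``basis_name`` is inferred from the descriptor columns
    when not given ("logP16"/"logPoct" if present, else "none").
    """
    df = _as_frame(table)
    cols = list(descriptor_cols)
    needed = cols + [property_col]
    sub = df.dropna(subset=[c for c in needed if c in df.columns])
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise LFERKitError(f"table lacks column(s): {', '.join(missing_cols)}")
    if basis_name is None:
        basis_name = next((b for b in BASIS_COLUMNS if b in cols), "none")
    ids = sub["id"].tolist() if "id" in sub.columns else None
    reg = LFERRegressor(property_name=property_col, basis_name=basis_name)
    reg.fit(sub[cols], sub[property_col], ids=ids)
    return reg.model_


def predict(model: LFERModel, x: DescriptorVector | Mapping[str, float] | pd.DataFrame):
    """Apply a model to a descriptor vector, mapping or table."""
    if isinstance(x, DescriptorVector):
        return model.predict_vector(x)
    if isinstance(x, pd.DataFrame):
        return model.predict_frame(x)
    return model.predict_mapping(x)


# ---------------------------------------------------------------------------
# Preset (literature) models
# ---------------------------------------------------------------------------

def _literature(property_name, basis, coeffs, intercept, **stats) -> LFERModel:
    return LFERModel(
        property_name=property_name,
        coefficients=coeffs,
        intercept=intercept,
        basis_name=basis,
        stats=FitStatistics(**stats),
        provenance="literature",
    )


_PRESETS: dict[str, LFERModel] = {
    # Human skin permeability from octanol/water logP (external validation).
    "logKp/logPoct": _literature(
        "logKp", "logPoct",
        {"logPoct": 0.6157, "Sm": 0.0156, "HM_HBD": -0.0626, "Flex": -0.0988},
        -5.646, n=32, r2=0.953, q2_ext=0.966, sd=0.178, f=136.7,
    ),
    # Air-to-brain partition coefficient from hexadecane/water logP.
    "logKbrain/logP16": _literature(
        "logKbrain", "logP16",
        {"logP16": -0.5129, "Sm": 0.5006, "HM_HBD": 0.1009, "Flex": -0.1893},
        -1.64, n=34, r2=0.964, q2_loo=0.947, sd=0.265, f=195.7,
    ),
    # Air-to-brain partition coefficient from octanol/water logP.
    "logKbrain/logPoct": _literature(
        "logKbrain", "logPoct",
        {"logPoct": -0.7755, "Sm": 0.5473, "HM_HBD": 0.1790, "Flex": -0.0986},
        -1.386, n=31, r2=0.931, q2_loo=0.914, sd=0.368, f=87.4,
    ),
    # Aniline/water partition coefficient: two-descriptor LFER.
    "logPaln/logP16": _literature(
        "logPaln", "logP16",
        {"logP16": 0.4695, "Sm": 0.1506},
        0.010, n=54, r2=0.975, sd=0.208, f=1008.0,
    ),
    # Aniline/water partition coefficient: simple one-variable regression.
    "logPaln/simple": _literature(
        "logPaln", "logP16",
        {"logP16": 0.6416},
        0.726, n=54, r2=0.910, sd=0.394, f=524.9,
    ),
    # Air-to-brain model without the H-bond-donor descriptor.
    "logKbrain/logP16-noHBD": _literature(
        "logKbrain", "logP16",
        {"logP16": -0.6194, "Sm": 0.5446, "Flex": -0.1928},
        -1.637, n=34, r2=0.954, q2_loo=0.938, sd=0.295, f=207.7,
    ),
}


def preset_models() -> list[LFERModel]:
    """The six published LFER models, with literature coefficients and
    statistics carried verbatim as metadata (not recomputed here)."""
    return list(_PRESETS.values())


def preset_names() -> list[str]:
    return list(_PRESETS)


def get_preset(name: str) -> LFERModel:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")
    return _PRESETS[name]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MODEL_FIELDS = {"schema", "property_name", "coefficients", "intercept",
                 "basis_name", "stats", "training_meta", "provenance"}
_STATS_FIELDS = {"n", "r2", "sd", "f", "q2_loo", "q2_ext"}


def serialize_model(model: LFERModel) -> str:
    """Serialize a model to versioned, human-readable JSON text."""
    payload = {
        "schema": SCHEMA_VERSION,
        "property_name": model.property_name,
        "coefficients": dict(model.coefficients),
        "intercept": model.intercept,
        "basis_name": model.basis_name,
        "stats": asdict(model.stats) if model.stats is not None else None,
        "training_meta": dict(model.training_meta) if model.training_meta is not None else None,
        "provenance": model.provenance,
    }
    return json.dumps(payload, indent=2, sort_keys=False)


def deserialize_model(text: str) -> LFERModel:
    """Inverse of :func:`serialize_model`; rejects unknown fields and
    mismatched schema versions."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"malformed model text: {exc}") from exc
    if not isinstance(payload, dict):
        raise ModelFormatError("model text must be a JSON object")
    if payload.get("schema") != SCHEMA_VERSION:
        raise ModelFormatError(f"unsupported schema version {payload.get('schema')!r}; expected {SCHEMA_VERSION!r}")
    unknown = set(payload) - _MODEL_FIELDS
    if unknown:
        raise ModelFormatError(f"unknown field(s) in model text: {', '.join(sorted(unknown))}")
    missing = _MODEL_FIELDS - set(payload)
    if missing:
        raise ModelFormatError(f"missing field(s) in model text: {', '.join(sorted(missing))}")
    stats = payload["stats"]
    if stats is not None:
        unknown_s = set(stats) - _STATS_FIELDS
        if unknown_s:
            raise ModelFormatError(f"unknown stats field(s): {', '.join(sorted(unknown_s))}")
        stats = FitStatistics(**stats)
    return LFERModel(
        property_name=payload["property_name"],
        coefficients=payload["coefficients"],
        intercept=float(payload["intercept"]),
        basis_name=payload["basis_name"],
        stats=stats,
        training_meta=payload["training_meta"],
        provenance=payload["provenance"],
    )
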