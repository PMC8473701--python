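"""Model validation: LOO cross-validation, external test sets, model
comparison, and the hydrogen-bond-acceptor effect analysis.

Q² statistics follow the usual QSPR conventions:

* Q²_LOO = 1 − PRESS/SST, where PRESS sums squared leave-one-out residuals;
  computed via the hat-matrix shortcut e_i/(1 − h_ii), which is exact for
  OLS (the literal refit-per-row oracle lives in the test suite).
* Q²_ext = 1 − Σ(y_test − ŷ)² / Σ(y_test − ȳ_train)², centring the test
  responses on the *training* mean recorded in the model's metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chemio import CompoundTable
from .errors import LFERKitError, TableError
from .lfer import LFERModel, LFERRegressor, _as_frame, fit


@dataclass
class ValidationReport:
    """Predicted-vs-observed summary for one validation run."""

    kind: str  # "loo" or "external"
    model: LFERModel
    q2: float
    predictions: pd.DataFrame  # columns: id, observed, predicted, residual
    obs_vs_pred_slope: float
    obs_vs_pred_intercept: float

    def __post_init__(self) -> None:
        if len(self.predictions) == 0:
            raise ValueError("empty prediction set")


def _obs_vs_pred_line(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    if np.ptp(pred) == 0:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(pred, obs, 1)
    return float(slope), float(intercept)


def loo_q2(
    table: CompoundTable | pd.DataFrame,
    property_col: str,
    descriptor_cols: Sequence[str],
) -> tuple[float, ValidationReport]:
    """Leave-one-out Q² of an OLS LFER fit on a compound table.

    Uses the hat-matrix identity: the prediction for row i from the model
    refit without row i has residual e_i/(1 − h_ii), with e_i the ordinary
    residual and h_ii the leverage. Requires every leverage < 1 (otherwise
    the leave-one-out subproblem is rank deficient).
    """
    df = _as_frame(table)
    cols = list(descriptor_cols)
    sub = df.dropna(subset=cols + [property_col]).reset_index(drop=True)
    n, p = len(sub), len(cols)
    if n < p + 3:
        raise LFERKitError(f"LOO needs at least {p + 3} complete rows, got {n}")
    ids = sub["id"].astype(str).tolist() if "id" in sub.columns else [str(i) for i in range(n)]
    reg = LFERRegressor(property_name=property_col).fit(sub[cols], sub[property_col], ids=ids)
    X = sm.add_constant(sub[cols].to_numpy(dtype=float), has_constant="add")
    y = sub[property_col].to_numpy(dtype=float)
    hat = np.einsum("ij,ji->i", X, np.linalg.solve(X.T @ X, X.T))
    bad = np.flatnonzero(hat >= 1 - 1e-10)
    if bad.size:
        raise LFERKitError(f"leave-one-out refit rank deficient when holding out row(s): {', '.join(ids[i] for i in bad)}")
    loo_resid = reg.residuals_ / (1.0 - hat)
    press = float(np.sum(loo_resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / sst
    pred = y - loo_resid
    slope, intercept = _obs_vs_pred_line(y, pred)
    report = ValidationReport(
        kind="loo",
        model=reg.model_,
        q2=q2,
        predictions=pd.DataFrame({"id": ids, "observed": y, "predicted": pred, "residual": loo_resid}),
        obs_vs_pred_slope=slope,
        obs_vs_pred_intercept=intercept,
    )
    return q2, report


def external_q2(
    model: LFERModel,
    test_table: CompoundTable | pd.DataFrame,
    property_col: str | None = None,
) -> tuple[float, ValidationReport]:
    """External-set Q² of a fitted model on held-out compounds.

    The denominator centres the test responses on the training mean stored
    in the model's ``training_meta``; train/test id overlap is an error.
    """
    df = _as_frame(test_table)
    property_col = property_col or model.property_name
    cols = model.descriptor_cols
    sub = df.dropna(subset=[c for c in cols + [property_col] if c in df.columns]).reset_index(drop=True)
    missing = [c for c in cols + [property_col] if c not in df.columns]
    if missing:
        raise LFERKitError(f"test table lacks column(s): {', '.join(missing)}")
    if len(sub) == 0:
        raise LFERKitError("no complete test rows")
    meta = dict(model.training_meta or {})
    if meta.get("ids") and "id" in sub.columns:
        overlap = sorted(set(map(str, meta["ids"])) & set(sub["id"].astype(str)))
        if overlap:
            raise LFERKitError(f"test set overlaps the training set: {', '.join(overlap)}")
    if "y_mean" not in meta:
        raise LFERKitError("model carries no training mean; refit with lferkit or supply training_meta['y_mean']")
    y = sub[property_col].to_numpy(dtype=float)
    pred = model.predict_frame(sub).to_numpy()
    denom = float(np.sum((y - float(meta["y_mean"])) ** 2))
    if denom == 0:
        raise LFERKitError("degenerate test set: zero variance about the training mean")
    q2 = 1.0 - float(np.sum((y - pred) ** 2)) / denom
    ids = sub["id"].astype(str).tolist() if "id" in sub.columns else [str(i) for i in range(len(sub))]
    slope, intercept = _obs_vs_pred_line(y, pred)
    report = ValidationReport(
        kind="external",
        model=model,
        q2=q2,
        predictions=pd.DataFrame({"id": ids, "observed": y, "predicted": pred, "residual": y - pred}),
        obs_vs_pred_slope=slope,
        obs_vs_pred_intercept=intercept,
    )
    return q2, report


@dataclass(frozen=True)
class ComparisonRow:
    """Simple regression vs full LFER on one compound subset."""

    label: str
    n: int
    r2_simple: float
    sd_simple: float
    r2_lfer: float
    sd_lfer: float


def compare_simple_vs_lfer(
    table: CompoundTable | pd.DataFrame,
    property_col: str,
    basis_col: str,
    full_descriptor_cols: Sequence[str],
    subset_labels: Mapping[str, Sequence[bool]] | str | None = None,
) -> list[ComparisonRow]:
    """Contrast a one-variable regression on the logP basis with the full
    LFER, per compound subset.

    ``subset_labels`` is either a column name holding subset labels (e.g.
    HBA / HBD / apolar class assignments supplied as data), a mapping from
    label to boolean row mask, or None for a single "all" subset. Subsets
    too small to fit the LFER (fewer than p + 2 complete rows) are skipped
    with a warning.
    """
    df = _as_frame(table)
    cols = list(full_descriptor_cols)
    if basis_col not in cols:
        raise LFERKitError(f"basis column {basis_col!r} must be among the LFER descriptors for a nested comparison")
    if subset_labels is None:
        groups = {"all": np.ones(len(df), dtype=bool)}
    elif isinstance(subset_labels, str):
        labels = df[subset_labels].astype(str)
        groups = {lab: (labels == lab).to_numpy() for lab in labels.unique()}
    else:
        groups = {k: np.asarray(v, dtype=bool) for k, v in subset_labels.items()}
    rows: list[ComparisonRow] = []
    for label, mask in groups.items():
        sub = df.loc[mask].dropna(subset=cols + [property_col])
        if len(sub) < len(cols) + 2:
            warnings.warn(f"subset {label!r} has {len(sub)} complete rows; need {len(cols) + 2} — skipped", stacklevel=2)
            continue
        simple = fit(sub, property_col, [basis_col])
        full = fit(sub, property_col, cols)
        rows.append(ComparisonRow(
            label=label, n=len(sub),
            r2_simple=simple.stats.r2, sd_simple=simple.stats.sd,
            r2_lfer=full.stats.r2, sd_lfer=full.stats.sd,
        ))
    return rows


@dataclass
class HBAEffectResult:
    """Per-compound hydrogen-bond-acceptor effects on a partition coefficient."""

    calibration: LFERModel  # logP = a * dG_tr_depol + d on nonpolar solutes
    effects: pd.DataFrame  # columns: id, logp_observed, logp_depolarized, hba_effect


def hba_effect_analysis(
    nonpolar_table: CompoundTable | pd.DataFrame,
    hba_table: CompoundTable | pd.DataFrame,
    logp_col: str,
    dg_depol_col: str = "dG_tr_depol",
) -> HBAEffectResult:
    """Quantify how a solute's H-bond acceptors shift its partition coefficient.

    Nonpolar solutes calibrate the relation logP = a·ΔG_tr_depol + d between
    the experimental partition coefficient and the water→hexadecane transfer
    free energy of the (hypothetically) depolarized solute. For each
    HBA-containing, donor-free solute the calibration then predicts the logP
    its depolarized form would have; the HBA effect is that prediction minus
    the experimental logP. ΔG_tr_depol values are user-supplied data.
    """
    np_df = _as_frame(nonpolar_table)
    hba_df = _as_frame(hba_table)
    for name, frame in (("nonpolar", np_df), ("HBA", hba_df)):
        missing = [c for c in (logp_col, dg_depol_col) if c not in frame.columns]
        if missing:
            raise TableError(f"{name} table lacks column(s): {', '.join(missing)}")
    np_sub = np_df.dropna(subset=[logp_col, dg_depol_col])
    if len(np_sub) < 3:
        raise LFERKitError(f"nonpolar calibration needs at least 3 complete rows, got {len(np_sub)}")
    calibration = fit(np_sub, logp_col, [dg_depol_col], basis_name="none")
    hba_sub = hba_df.dropna(subset=[logp_col, dg_depol_col]).reset_index(drop=True)
    depol = calibration.predict_frame(hba_sub).to_numpy()
    observed = hba_sub[logp_col].to_numpy(dtype=float)
    ids = hba_sub["id"].astype(str).tolist() if "id" in hba_sub.columns else [str(i) for i in range(len(hba_sub))]
    effects = pd.DataFrame({
        "id": ids,
        "logp_observed": observed,
        "logp_depolarized": depol,
        "hba_effect": depol - observed,
    })
    return HBAEffectResult(calibration=calibration, effects=effects)
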