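"""End-to-end NIRS calibration workflow and reporting.

The pipeline mirrors standard chemometric practice for constituent
prediction from ground-tissue FT-NIR scans:

1. restrict spectra to 4000–9000 cm^-1;
2. SNV scatter correction, then first-derivative Savitzky–Golay smoothing
   (25-point window, quadratic);
3. Kennard–Stone partition into calibration and external validation sets;
4. initial PLS fit with full (leave-one-out) cross-validation;
5. one-pass outlier exclusion: calibration samples whose cross-validated
   prediction differs from wet chemistry by more than 2x the initial
   model's RMSECV;
6. refit without outliers, then a single evaluation on the untouched
   validation set.

The report carries counts, component numbers, R2 for calibration /
cross-validation / validation, RMSEC / RMSECV / RMSEP per response, and —
when technical wet-chemistry replicates are supplied — the reference-method
uncertainty (twice the average within-sample standard deviation), which
bounds how well any calibration against that chemistry can do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLSModel, CVResult, cross_validate, fit_pls, predict, rmse
from .spectra import SpectraSet, kennard_stone, restrict_range, savgol_derivative, snv

__all__ = [
    "CalibrationConfig",
    "CalibrationReport",
    "pretreat",
    "detect_outliers",
    "reference_uncertainty",
    "calibrate",
    "calibration_table",
]


@dataclass
class CalibrationConfig:
    """Workflow parameters for one PLS calibration model."""

    responses: tuple[str, ...] = ("TNC",)
    mode: str = "pls1"
    n_components: int = 8
    cal_size: int = 300
    wavenumber_range: tuple[float, float] = (4000.0, 9000.0)
    apply_snv: bool = True       # skip only when no scatter is present
    apply_savgol: bool = True
    savgol_window: int = 25
    savgol_polyorder: int = 2
    savgol_deriv: int = 1
    outlier_multiplier: float = 2.0
    r2_kind: str = "sse"  # "sse" (1 - SSE/SST) or "pearson" (squared correlation)


@dataclass
class CalibrationReport:
    """Calibration summary in the shape of a standard NIR model table."""

    mode: str
    responses: tuple[str, ...]
    n_calibration: int
    n_validation: int
    n_components: int
    outlier_ids: tuple[str, ...]
    r2_calibration: dict[str, float]
    r2_cross_validation: dict[str, float]
    r2_validation: dict[str, float]
    rmsec: dict[str, float]
    rmsecv: dict[str, float]
    rmsep: dict[str, float]
    reference_uncertainty: dict[str, float] = field(default_factory=dict)
    model: PLSModel | None = None
    initial_rmsecv: dict[str, float] = field(default_factory=dict)
    calibration_ids: tuple[str, ...] = ()
    validation_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for d in (self.rmsec, self.rmsecv, self.rmsep):
            if any(v < 0 for v in d.values()):
                raise ValueError("RMSE values must be >= 0")

    def table(self) -> pd.DataFrame:
        """One column per response: the classic calibration summary layout."""
        rows = {
            "Calibration samples": {r: self.n_calibration for r in self.responses},
            "Independent validation samples": {r: self.n_validation for r in self.responses},
            "Outliers removed": {r: len(self.outlier_ids) for r in self.responses},
            "Components in model": {r: self.n_components for r in self.responses},
            "R2 calibration": self.r2_calibration,
            "R2 cross validation": self.r2_cross_validation,
            "R2 independent validation": self.r2_validation,
            "RMSEC": self.rmsec,
            "RMSECV": self.rmsecv,
            "RMSEP validation": self.rmsep,
        }
        if self.reference_uncertainty:
            rows["Reference method uncertainty"] = self.reference_uncertainty
        return pd.DataFrame(rows).T[list(self.responses)]


def pretreat(spectra: SpectraSet, config: CalibrationConfig) -> SpectraSet:
    """Apply the pretreatment chain in fixed order: restrict -> SNV -> SavGol.

    Individual steps can be disabled in the config (e.g. SNV when the
    spectra carry no scatter); the applied chain is recorded on the output
    and later enforced at prediction time.
    """
    out = restrict_range(spectra, *config.wavenumber_range)
    if config.apply_snv:
        out = snv(out)
    if config.apply_savgol:
        out = savgol_derivative(out, window=config.savgol_window,
                                polyorder=config.savgol_polyorder,
                                deriv=config.savgol_deriv)
    return out


def _r2(pred: np.ndarray, ref: np.ndarray, kind: str = "sse") -> float:
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if kind == "pearson":
        return float(np.corrcoef(pred, ref)[0, 1] ** 2)
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((pred - ref) ** 2)) / sst


def detect_outliers(
    cv_predictions: np.ndarray | pd.DataFrame,
    y_reference: np.ndarray | pd.DataFrame,
    rmsecv_initial: np.ndarray | dict | float,
    sample_ids: list[str] | None = None,
    multiplier: float = 2.0,
) -> list:
    """One-pass outlier rule on cross-validated residuals.

    A calibration sample is flagged when |cross-validated prediction -
    reference| exceeds ``multiplier`` x the initial model's RMSECV (strict
    inequality). For multi-response models a sample is flagged if it exceeds
    the rule for *any* response.
    """
    pred = np.asarray(cv_predictions, dtype=float)
    ref = np.asarray(y_reference, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    if ref.ndim == 1:
        ref = ref[:, None]
    if isinstance(rmsecv_initial, dict):
        thr = np.asarray(list(rmsecv_initial.values()), dtype=float)
    else:
        thr = np.atleast_1d(np.asarray(rmsecv_initial, dtype=float))
    resid = np.abs(pred - ref)
    flagged = (resid > multiplier * thr).any(axis=1)
    idx = np.flatnonzero(flagged)
    if sample_ids is not None:
        return [sample_ids[i] for i in idx]
    return idx.tolist()


def reference_uncertainty(triplicates: pd.DataFrame, value_col: str = "value") -> float:
    """Reference-method (wet chemistry) uncertainty from technical replicates.

    Twice the average over samples of the within-sample standard deviation
    (n-1 denominator). Samples with fewer than two replicates are excluded
    with a warning.
    """
    if "sample_id" not in triplicates.columns:
        raise ValueError("triplicates table needs a 'sample_id' column")
    counts = triplicates.groupby("sample_id")[value_col].count()
    bad = counts[counts < 2]
    if len(bad):
        warnings.warn(f"excluding {len(bad)} sample(s) with < 2 technical replicates")
    keep = triplicates[triplicates["sample_id"].isin(counts[counts >= 2].index)]
    if keep.empty:
        raise ValueError("no sample has >= 2 technical replicates")
    sds = keep.groupby("sample_id")[value_col].std(ddof=1)
    return float(2.0 * sds.mean())


def _responses_frame(spectra: SpectraSet, responses: tuple[str, ...]) -> pd.DataFrame:
    cons = spectra.constituents
    if cons is None:
        raise ValueError("spectra carry no paired constituent values")
    out = {}
    for r in responses:
        if r in cons.columns:
            out[r] = cons[r]
        elif r.upper() == "TNC" and {"starch", "sucrose"} <= set(cons.columns):
            out[r] = cons["starch"] + cons["sucrose"]  # TNC = starch + sucrose
        else:
            raise KeyError(f"response {r!r} not found in constituents")
    return pd.DataFrame(out).loc[spectra.sample_ids]


def calibrate(
    spectra: SpectraSet,
    config: CalibrationConfig,
    wetchem_replicates: pd.DataFrame | None = None,
) -> CalibrationReport:
    """Run the full calibration workflow on spectra with paired wet chemistry.

    ``wetchem_replicates`` (optional) is a long table with columns
    ``sample_id``, ``replicate`` and one column per constituent, used only
    for the reference-uncertainty estimate. The validation set is never
    touched before the final evaluation.
    """
    y_all = _responses_frame(spectra, tuple(config.responses))
    pre = pretreat(spectra, config)
    cal_ids, val_ids = kennard_stone(pre, config.cal_size)
    cal, val = pre.subset(cal_ids), pre.subset(val_ids)
    y_cal, y_val = y_all.loc[cal_ids], y_all.loc[val_ids]

    # initial model + full cross-validation on the calibration set
    cv0: CVResult = cross_validate(cal, y_cal, config.n_components, mode=config.mode)
    rmsecv0 = cv0.rmsecv[config.n_components - 1]
    cv0_pred = cv0.predictions[:, :, config.n_components - 1]
    out_ids = detect_outliers(cv0_pred, y_cal.to_numpy(), rmsecv0,
                              sample_ids=cal_ids, multiplier=config.outlier_multiplier)

    clean_ids = [s for s in cal_ids if s not in set(out_ids)]
    clean = cal.subset(clean_ids)
    y_clean = y_cal.loc[clean_ids]

    model = fit_pls(clean, y_clean, config.n_components, mode=config.mode)
    cv1 = cross_validate(clean, y_clean, config.n_components, mode=config.mode)
    cv1_pred = cv1.predictions[:, :, config.n_components - 1]
    fit_pred = predict(model, clean)
    val_pred = predict(model, val)

    resp = tuple(config.responses)
    kind = config.r2_kind
    report = CalibrationReport(
        mode=config.mode,
        responses=resp,
        n_calibration=len(cal_ids),
        n_validation=len(val_ids),
        n_components=config.n_components,
        outlier_ids=tuple(out_ids),
        r2_calibration={r: _r2(fit_pred[r], y_clean[r], kind) for r in resp},
        r2_cross_validation={r: _r2(cv1_pred[:, i], y_clean[r], kind) for i, r in enumerate(resp)},
        r2_validation={r: _r2(val_pred[r], y_val[r], kind) for r in resp},
        rmsec={r: rmse(fit_pred[r], y_clean[r]) for r in resp},
        rmsecv={r: rmse(cv1_pred[:, i], y_clean[r]) for i, r in enumerate(resp)},
        rmsep={r: rmse(val_pred[r], y_val[r]) for r in resp},
        initial_rmsecv={r: float(rmsecv0[i]) for i, r in enumerate(resp)},
        model=model,
        calibration_ids=tuple(cal_ids),
        validation_ids=tuple(val_ids),
    )
    if wetchem_replicates is not None:
        unc = {}
        for r in resp:
            if r in wetchem_replicates.columns:
                tab = wetchem_replicates[["sample_id", r]].rename(columns={r: "value"})
            elif r.upper() == "TNC" and {"starch", "sucrose"} <= set(wetchem_replicates.columns):
                tab = wetchem_replicates[["sample_id"]].copy()
                tab["value"] = wetchem_replicates["starch"] + wetchem_replicates["sucrose"]
            else:
                continue
            unc[r] = reference_uncertainty(tab)
        report.reference_uncertainty = unc
    if report.n_calibration + report.n_validation != spectra.n_samples:
        raise RuntimeError("calibration/validation split lost samples")
    return report


def calibration_table(
    spectra: SpectraSet,
    n_components_pls1: int = 8,
    n_components_pls2: int = 10,
    cal_size: int = 300,
    wetchem_replicates: pd.DataFrame | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, CalibrationReport, CalibrationReport]:
    """Fit the PLS-1 (TNC) and PLS-2 (starch + sucrose) models and combine
    their summaries into one three-column table (TNC, sucrose, starch)."""
    rep1 = calibrate(spectra, CalibrationConfig(
        responses=("TNC",), mode="pls1", n_components=n_components_pls1,
        cal_size=cal_size, **kwargs), wetchem_replicates)
    rep2 = calibrate(spectra, CalibrationConfig(
        responses=("starch", "sucrose"), mode="pls2", n_components=n_components_pls2,
        cal_size=cal_size, **kwargs), wetchem_replicates)
    t1, t2 = rep1.table(), rep2.table()
    combined = pd.concat([t1[["TNC"]], t2[["sucrose", "starch"]]], axis=1)
    return combined, rep1, rep2
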