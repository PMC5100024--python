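"""Partial least-squares regression for NIR calibration.

Thin, typed surface over a mean-centred NIPALS decomposition
(scikit-learn's ``PLSRegression`` with ``scale=False``): PLS-1 predicts a
single response (TNC), PLS-2 predicts starch and sucrose jointly.
Prediction is affine in the pretreated spectrum,

    y_hat = Y_mean + (x - X_mean) . B_k,

and because P'W is upper triangular in NIPALS, the k-component coefficient
matrix is the truncation B_k = R[:, :k] C[:, :k]' of the rotations R and
Y-loadings C fitted once at the largest component count — which makes
leave-one-out cross-validation over a whole component range cheap (one fit
per left-out sample instead of one per sample per component count).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .spectra import SpectraSet

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "cross_validate", "rmse",
           "first_local_minimum"]


@dataclass
class PLSModel:
    """Fitted PLS model with everything needed for affine prediction."""

    mode: str                       # "pls1" | "pls2"
    n_components: int
    x_mean: np.ndarray              # (p,)
    y_mean: np.ndarray              # (q,)
    x_rotations: np.ndarray         # (p, k)
    y_loadings: np.ndarray          # (q, k)
    coef: np.ndarray                # (p, q)
    y_names: tuple[str, ...]
    wavenumbers: np.ndarray | None = None
    treatments: tuple[str, ...] = ()
    training_ids: tuple[str, ...] = ()

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Regression coefficients using the first ``k`` latent components."""
        if k is None or k == self.n_components:
            return self.coef
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must be in [1, {self.n_components}]")
        return self.x_rotations[:, :k] @ self.y_loadings[:, :k].T

    def predict_matrix(self, x: np.ndarray, k: int | None = None) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) @ self.coefficients(k) + self.y_mean

    def save(self, path) -> None:
        """Serialise to a self-describing JSON text file (bit-stable round trip)."""
        payload = {
            "mode": self.mode,
            "n_components": self.n_components,
            "y_names": list(self.y_names),
            "treatments": list(self.treatments),
            "training_ids": list(self.training_ids),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "x_rotations": self.x_rotations.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "wavenumbers": None if self.wavenumbers is None else self.wavenumbers.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mode=d["mode"], n_components=d["n_components"],
            x_mean=np.asarray(d["x_mean"]), y_mean=np.asarray(d["y_mean"]),
            x_rotations=np.asarray(d["x_rotations"]), y_loadings=np.asarray(d["y_loadings"]),
            coef=np.asarray(d["coef"]), y_names=tuple(d["y_names"]),
            wavenumbers=None if d["wavenumbers"] is None else np.asarray(d["wavenumbers"]),
            treatments=tuple(d["treatments"]), training_ids=tuple(d["training_ids"]),
        )


def _as_xy(x, y):
    if isinstance(x, SpectraSet):
        mat = x.absorbance
        meta = (x.wavenumbers, x.treatments, tuple(x.sample_ids))
    else:
        mat = np.asarray(x, dtype=float)
        meta = (None, (), ())
    if isinstance(y, pd.DataFrame):
        ymat, names = y.to_numpy(dtype=float), tuple(y.columns)
    elif isinstance(y, pd.Series):
        ymat, names = y.to_numpy(dtype=float)[:, None], (y.name or "y",)
    else:
        ymat = np.asarray(y, dtype=float)
        if ymat.ndim == 1:
            ymat = ymat[:, None]
        names = tuple(f"y{i + 1}" for i in range(ymat.shape[1]))
    return mat, ymat, names, meta


def fit_pls(x, y, n_components: int, mode: str | None = None,
            check_rank: bool = True) -> PLSModel:
    """Fit a mean-centred PLS model.

    ``x`` may be a pretreated :class:`SpectraSet` (grid and pretreatment are
    then recorded for later enforcement) or a plain matrix; ``y`` one column
    (PLS-1) or several (PLS-2). ``check_rank=False`` skips the exact rank
    validation (an SVD) — used by the cross-validation loop, which validates
    once on the full matrix.
    """
    mat, ymat, names, (wn, treat, ids) = _as_xy(x, y)
    q = ymat.shape[1]
    if mode is None:
        mode = "pls1" if q == 1 else "pls2"
    mode = mode.lower()
    if mode == "pls1" and q != 1:
        raise ValueError("pls1 requires a single response column")
    if mode == "pls2" and q < 2:
        raise ValueError("pls2 requires at least two response columns")
    if check_rank:
        rank = np.linalg.matrix_rank(mat - mat.mean(axis=0))
    else:
        rank = min(mat.shape[0] - 1, mat.shape[1])
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must be in [1, rank(X)={rank}]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg = PLSRegression(n_components=n_components, scale=False).fit(mat, ymat)
    return PLSModel(
        mode=mode, n_components=n_components,
        x_mean=reg._x_mean if hasattr(reg, "_x_mean") else reg.x_mean_,
        y_mean=reg._y_mean if hasattr(reg, "_y_mean") else reg.y_mean_,
        x_rotations=reg.x_rotations_, y_loadings=reg.y_loadings_,
        coef=reg.coef_.T if reg.coef_.shape == (q, mat.shape[1]) else reg.coef_,
        y_names=names, wavenumbers=wn, treatments=treat, training_ids=ids,
    )


def predict(model: PLSModel, x, k: int | None = None) -> pd.DataFrame | np.ndarray:
    """Predict constituents from pretreated spectra.

    When given a :class:`SpectraSet`, the grid and recorded pretreatment
    chain must match the training data exactly; a mismatch raises rather
    than silently predicting from incompatible inputs.
    """
    if isinstance(x, SpectraSet):
        if model.wavenumbers is not None and (
            x.wavenumbers.shape != model.wavenumbers.shape
            or not np.allclose(x.wavenumbers, model.wavenumbers)
        ):
            raise ValueError("wavenumber grid differs from the training grid")
        if model.treatments and tuple(x.treatments) != tuple(model.treatments):
            raise ValueError(
                f"pretreatment {x.treatments} differs from training {model.treatments}"
            )
        out = model.predict_matrix(x.absorbance, k)
        return pd.DataFrame(out, index=x.sample_ids, columns=list(model.y_names))
    return model.predict_matrix(np.asarray(x, dtype=float), k)


@dataclass
class CVResult:
    """Leave-one-out cross-validation curves.

    ``rmsecv`` has one row per component count (1..max_components) and one
    column per response; ``predictions[:, :, k-1]`` are the LOO predictions
    with k components.
    """

    rmsecv: np.ndarray          # (max_components, q)
    predictions: np.ndarray     # (n, q, max_components)
    y_names: tuple[str, ...]

    def curve(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rmsecv, columns=list(self.y_names))
        df.index = pd.RangeIndex(1, self.rmsecv.shape[0] + 1, name="n_components")
        return df


def cross_validate(x, y, max_components: int, mode: str | None = None) -> CVResult:
    """Full (leave-one-out) cross-validation over 1..max_components.

    Each sample is predicted by a model trained on all others; the RMSECV
    curve supports component-count selection. ``max_components`` is capped
    at n - 2 with a warning when necessary.
    """
    mat, ymat, names, _ = _as_xy(x, y)
    n, q = ymat.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if max_components >= n - 1:
        warnings.warn(f"max_components capped at {n - 2} for {n} samples")
        max_components = n - 2
    rank = np.linalg.matrix_rank(mat - mat.mean(axis=0))
    if max_components > rank:
        warnings.warn(f"max_components capped at rank(X)={rank}")
        max_components = int(rank)
    preds = np.empty((n, q, max_components))
    for i in range(n):
        keep = np.arange(n) != i
        sub = fit_pls(mat[keep], ymat[keep], max_components,
                      mode=mode or ("pls1" if q == 1 else "pls2"), check_rank=False)
        for k in range(1, max_components + 1):
            preds[i, :, k - 1] = sub.predict_matrix(mat[i][None, :], k)[0]
    rmsecv = np.sqrt(((preds - ymat[:, :, None]) ** 2).mean(axis=0))
    return CVResult(rmsecv=rmsecv.T, predictions=preds, y_names=names)


def rmse(predicted, reference) -> float:
    """Root-mean-square error sqrt(mean((y_hat - y_ref)^2))."""
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != r.size:
        raise ValueError("predicted and reference must have equal length")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def first_local_minimum(rmsecv_curve: np.ndarray) -> int:
    """Component count (1-based) at the first local minimum of an RMSECV curve.

    A helper for automatic component selection; the calibration workflow
    leaves the final choice to the analyst inspecting the curve.
    """
    c = np.asarray(rmsecv_curve, dtype=float).ravel()
    for k in range(c.size - 1):
        if c[k] <= c[k + 1]:
            return k + 1
    return c.size
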