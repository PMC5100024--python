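"""FT-NIR spectra container and spectral pretreatment.

The calibration workflow pretreats absorbance spectra in a fixed order —
wavenumber range restriction, standard normal variate (SNV) scatter
correction, then a Savitzky–Golay derivative — and partitions samples into
calibration and validation sets with the Kennard–Stone maximin algorithm.
Every pretreatment step is recorded on the :class:`SpectraSet` so a model can
refuse spectra treated differently from its training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraSet",
    "restrict_range",
    "snv",
    "savgol_derivative",
    "kennard_stone",
]


@dataclass
class SpectraSet:
    """A set of absorbance spectra on a common strictly increasing grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly increasing wavenumber grid in cm^-1.
    absorbance : ndarray, shape (n, p)
        One row per sample.
    sample_ids : list of str
    constituents : DataFrame, optional
        Wet-chemistry constituent values (fractions w/w), indexed by
        sample id; e.g. columns ``starch`` and ``sucrose``.
    treatments : tuple of str
        Ordered record of the pretreatment steps already applied.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    constituents: pd.DataFrame | None = None
    treatments: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (samples x grid) matrix")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.wavenumbers.size} points"
            )
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length must match number of spectra")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.constituents is not None:
            missing = [s for s in self.sample_ids if s not in self.constituents.index]
            if missing:
                raise ValueError(f"constituents missing for samples: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, ids: list[str]) -> "SpectraSet":
        """Return the sub-set of spectra for the given sample ids, in order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        cons = None
        if self.constituents is not None:
            cons = self.constituents.loc[ids]
        return SpectraSet(
            self.wavenumbers.copy(),
            self.absorbance[idx].copy(),
            list(ids),
            constituents=cons,
            treatments=self.treatments,
        )


def restrict_range(spectra: SpectraSet, low: float = 4000.0, high: float = 9000.0) -> SpectraSet:
    """Keep only grid points with ``low <= wavenumber <= high``.

    The default window (4000–9000 cm^-1) discards the noisy extremes of an
    FT-NIR scan before model fitting. Idempotent; raises if nothing remains.
    """
    mask = (spectra.wavenumbers >= low) & (spectra.wavenumbers <= high)
    if not mask.any():
        raise ValueError(f"no grid points in [{low}, {high}]")
    tag = f"restrict[{low:g},{high:g}]"
    treatments = spectra.treatments
    if not treatments or treatments[-1] != tag:
        treatments = treatments + (tag,)
    return replace(
        spectra,
        wavenumbers=spectra.wavenumbers[mask],
        absorbance=spectra.absorbance[:, mask],
        treatments=treatments,
    )


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate scatter correction.

    Each spectrum is independently centred to mean 0 and scaled to sample
    standard deviation 1 (n-1 denominator), removing multiplicative scatter
    and additive offsets sample by sample.
    """
    x = spectra.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        bad = spectra.sample_ids[flat[0]]
        raise ValueError(f"constant spectrum for sample {bad!r}: SNV undefined")
    return replace(
        spectra,
        absorbance=(x - mean) / sd,
        treatments=spectra.treatments + ("snv",),
    )


def savgol_derivative(
    spectra: SpectraSet,
    window: int = 25,
    polyorder: int = 2,
    deriv: int = 1,
    spacing_rtol: float = 1e-6,
) -> SpectraSet:
    """Savitzky–Golay smoothed derivative on a uniform grid.

    Fits a local polynomial of order ``polyorder`` over a centred window of
    ``window`` points and evaluates its ``deriv``-th derivative, scaled by the
    grid spacing so the output is per cm^-1. The half-window of points at
    each edge, where no centred window exists, is dropped rather than
    extrapolated.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > spectra.wavenumbers.size:
        raise ValueError("window longer than the grid")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    steps = np.diff(spectra.wavenumbers)
    delta = steps.mean()
    if np.any(np.abs(steps - delta) > spacing_rtol * abs(delta)):
        raise ValueError("grid spacing is not uniform; Savitzky–Golay coefficients assume it")
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, axis=1,
    )
    half = window // 2
    sl = slice(half, spectra.wavenumbers.size - half)
    tag = f"savgol[w={window},p={polyorder},d={deriv}]"
    return replace(
        spectra,
        wavenumbers=spectra.wavenumbers[sl],
        absorbance=out[:, sl],
        treatments=spectra.treatments + (tag,),
    )


def _kennard_stone_indices(x: np.ndarray, n_select: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy maximin selection on the rows of ``x``; ties -> lowest index."""
    n = x.shape[0]
    if not 2 <= n_select < n:
        raise ValueError(f"n_select must be in [2, {n - 1}], got {n_select}")
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    # initial pair at maximum distance; argmax on the flattened upper triangle
    # scans row-major, so the first maximal entry has the lowest (i, j)
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(d2[iu]))
    first, second = int(iu[0][k]), int(iu[1][k])
    selected = [first, second]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[[first, second]] = True
    mind = np.minimum(d2[:, first], d2[:, second])
    while len(selected) < n_select:
        mind_masked = np.where(in_sel, -np.inf, mind)
        nxt = int(np.argmax(mind_masked))  # argmax returns the lowest index on ties
        selected.append(nxt)
        in_sel[nxt] = True
        np.minimum(mind, d2[:, nxt], out=mind)
    remainder = np.flatnonzero(~in_sel)
    return np.asarray(selected, dtype=int), remainder


def kennard_stone(spectra: SpectraSet | np.ndarray, n_select: int):
    """Kennard–Stone calibration/validation split.

    Works in the (pretreated) spectral space with Euclidean distances:
    initialise with the two most distant samples, then repeatedly add the
    candidate whose minimum distance to the selected set is largest.
    Deterministic; ties are broken by the lowest sample index.

    Returns
    -------
    (selected, remainder)
        Lists of sample ids when given a :class:`SpectraSet`, otherwise
        integer index arrays.
    """
    if isinstance(spectra, SpectraSet):
        sel, rem = _kennard_stone_indices(spectra.absorbance, n_select)
        ids = spectra.sample_ids
        return [ids[i] for i in sel], [ids[i] for i in rem]
    return _kennard_stone_indices(np.asarray(spectra, dtype=float), n_select)
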