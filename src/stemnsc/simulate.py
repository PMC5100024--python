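"""Synthetic genotypes, replicated phenotypes, and FT-NIR-like spectra.

These generators define the study conditions for every downstream analysis:
a diversity panel of inbred rice lines genotyped on a SNP array, a
replicated greenhouse phenotyping trial (the default emulates 36 accessions
x 20 replicates), and scatter/baseline-corrupted near-infrared spectra of
ground stem tissue paired with noisy wet-chemistry constituent values.

Phenotypes follow the same hierarchical model the estimation code fits:

    y_ir = mu + a_i + d_i + eps_ir

with additive values ``a_i = sum_j z_ij beta_j`` built from SNP dosages
(infinitesimal scaling so the expected additive variance equals the target),
i.i.d. non-additive line effects ``d_i``, and replicate errors drawn from a
Gaussian or Student-t family with optional line-specific scales. True latent
values are returned alongside the long-format table for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .spectra import SpectraSet

__all__ = [
    "PhenoSimConfig",
    "SpectraSimConfig",
    "SimulatedPhenotypes",
    "SimulatedSpectra",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_spectra",
    "simulate_nsc_concentrations",
    "DEFAULT_TRAITS",
]

#: Trait label vocabulary used across the package (heading/maturity panel).
DEFAULT_TRAITS = (
    "DTH", "STCH_HD", "SUC_HD", "SEN", "TIL", "WT", "GLC_HV", "SUC_HV", "STCH_HV",
)


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw a lines x SNPs dosage matrix under Hardy–Weinberg equilibrium.

    Per-SNP allele frequencies are uniform on ``maf_range`` (a sub-interval
    of (0, 0.5]) and dosages are Binomial(2, p_j), independently across SNPs
    and lines. Deterministic given ``seed``.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_lines, n_snps)).astype(float)
    line_ids = [f"L{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids, dosages)


def _corr_matrix(rho, n_traits: int, what: str) -> np.ndarray:
    """Exchangeable correlation matrix from a scalar, or validate a full one."""
    arr = np.asarray(rho, dtype=float)
    if arr.ndim == 0:
        if abs(float(arr)) > 1:
            raise ValueError(f"|{what}| must be <= 1")
        r = np.full((n_traits, n_traits), float(arr))
        np.fill_diagonal(r, 1.0)
        return r
    if arr.shape != (n_traits, n_traits):
        raise ValueError(f"{what} matrix must be {n_traits}x{n_traits}")
    if np.any(np.abs(arr) > 1) or not np.allclose(arr, arr.T):
        raise ValueError(f"{what} must be symmetric with entries in [-1, 1]")
    return arr


def _chol_psd(r: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of exactly singular correlation matrices."""
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(r)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


@dataclass
class PhenoSimConfig:
    """Study conditions for the replicated phenotype generator.

    Variances are on the trait scale; scalars broadcast across traits.
    ``genetic_corr`` / ``env_corr`` may be scalars (exchangeable) or full
    trait x trait correlation matrices. ``line_cv_spread`` is the log-sd of a
    LogNormal multiplier on each line's error scale (0 = homoscedastic
    lines). ``error_family`` is ``gaussian`` or ``student_t`` (scaled so the
    error variance still equals ``var_error``).
    """

    n_lines: int | None = None  # only needed when no genotypes are supplied
    n_reps: int = 20
    mu: float | tuple = 10.0
    var_additive: float | tuple = 0.6
    var_nonadditive: float | tuple = 0.1
    var_error: float | tuple = 0.3
    genetic_corr: float | np.ndarray = 0.0
    env_corr: float | np.ndarray = 0.0
    line_cv_spread: float = 0.0
    error_family: str = "gaussian"
    t_df: float = 4.0
    traits: tuple[str, ...] | None = None
    seed: int = 0


@dataclass
class SimulatedPhenotypes:
    """Long-format replicated observations plus the latent truth."""

    table: pd.DataFrame  # columns: line, replicate, trait, value
    truth: pd.DataFrame  # per (line, trait): additive, nonadditive, error_sd
    config: PhenoSimConfig

    def trait_truth(self, trait: str, column: str = "additive") -> pd.Series:
        t = self.truth[self.truth["trait"] == trait]
        return t.set_index("line")[column]


def simulate_phenotypes(
    genotypes: GenotypeMatrix | None,
    config: PhenoSimConfig,
) -> SimulatedPhenotypes:
    """Simulate replicated multi-trait phenotypes on a panel of lines.

    SNP effects are Normal(0, var_additive / (2 sum_j p_j(1-p_j))) so the
    expected additive variance matches the target, with correlation
    ``genetic_corr`` across traits (applied to both the additive effects and
    the non-additive line effects). Replicate errors share ``env_corr``
    across traits and, when ``line_cv_spread`` > 0, a line-specific LogNormal
    scale multiplier giving each line a distinct true CV.
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 (dispersion unidentifiable otherwise)")
    va = np.atleast_1d(np.asarray(config.var_additive, dtype=float))
    vd = np.atleast_1d(np.asarray(config.var_nonadditive, dtype=float))
    ve = np.atleast_1d(np.asarray(config.var_error, dtype=float))
    mu = np.atleast_1d(np.asarray(config.mu, dtype=float))
    n_traits = max(va.size, vd.size, ve.size, mu.size,
                   1 if config.traits is None else len(config.traits))
    va, vd, ve, mu = (np.broadcast_to(x, (n_traits,)).astype(float) for x in (va, vd, ve, mu))
    if np.any(va < 0) or np.any(vd < 0) or np.any(ve < 0):
        raise ValueError("variances must be >= 0")
    if config.line_cv_spread < 0:
        raise ValueError("line_cv_spread must be >= 0")
    if config.error_family not in ("gaussian", "student_t"):
        raise ValueError(f"unknown error_family {config.error_family!r}")
    if np.any(va > 0) and genotypes is None:
        raise ValueError("genotypes are required when var_additive > 0")

    traits = config.traits or tuple(DEFAULT_TRAITS[:n_traits])
    if len(traits) != n_traits:
        raise ValueError("traits length inconsistent with variance/mean arrays")

    rng = np.random.default_rng(config.seed)
    if genotypes is not None:
        n_lines = genotypes.n_lines
        line_ids = list(genotypes.line_ids)
    elif config.n_lines is not None and config.n_lines >= 2:
        n_lines = config.n_lines
        line_ids = [f"L{i + 1:03d}" for i in range(n_lines)]
    else:
        raise ValueError("either genotypes or config.n_lines (>= 2) must be provided")

    r_g = _corr_matrix(config.genetic_corr, n_traits, "genetic_corr")
    r_e = _corr_matrix(config.env_corr, n_traits, "env_corr")
    lg, le = _chol_psd(r_g), _chol_psd(r_e)

    # additive values from SNP effects under the infinitesimal scaling
    if genotypes is not None:
        p = genotypes.allele_freqs
        denom = 2.0 * np.sum(p * (1.0 - p))
        z = genotypes.imputed() - 2.0 * p  # centred dosages
        beta = rng.standard_normal((genotypes.n_snps, n_traits)) @ lg.T
        beta *= np.sqrt(va / denom) if denom > 0 else 0.0
        a = z @ beta
        a *= (va > 0)  # exactly zero when no additive variance requested
    else:
        a = np.zeros((n_lines, n_traits))

    d = (rng.standard_normal((n_lines, n_traits)) @ lg.T) * np.sqrt(vd)

    lam = np.exp(rng.normal(0.0, config.line_cv_spread, size=n_lines)) \
        if config.line_cv_spread > 0 else np.ones(n_lines)

    shape = (n_lines, config.n_reps, n_traits)
    if config.error_family == "gaussian":
        eps0 = rng.standard_normal(shape)
    else:
        nu = float(config.t_df)
        if nu <= 2:
            raise ValueError("t_df must be > 2 for finite error variance")
        eps0 = rng.standard_t(nu, size=shape) * np.sqrt((nu - 2.0) / nu)
    eps = (eps0 @ le.T) * np.sqrt(ve) * lam[:, None, None]

    y = mu + a[:, None, :] + d[:, None, :] + eps

    rep_ids = [f"r{r + 1:02d}" for r in range(config.n_reps)]
    table = pd.DataFrame({
        "line": np.repeat(line_ids, config.n_reps * n_traits),
        "replicate": np.tile(np.repeat(rep_ids, n_traits), n_lines),
        "trait": np.tile(list(traits), n_lines * config.n_reps),
        "value": y.ravel(),
    })
    truth = pd.DataFrame({
        "line": np.repeat(line_ids, n_traits),
        "trait": np.tile(list(traits), n_lines),
        "additive": a.ravel(),
        "nonadditive": d.ravel(),
        "error_sd": (np.sqrt(ve)[None, :] * lam[:, None]).ravel(),
    })
    truth["genetic"] = truth["additive"] + truth["nonadditive"]
    return SimulatedPhenotypes(table=table, truth=truth, config=config)


# --- spectra ---------------------------------------------------------------

#: Gaussian absorption bands (centre cm^-1, width cm^-1, height per unit
#: concentration) loosely emulating starch/sucrose overtone features in the
#: 4000–9000 cm^-1 region.
DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "starch": ((4400.0, 150.0, 0.8), (4750.0, 120.0, 0.6),
               (5200.0, 200.0, 1.0), (6900.0, 300.0, 0.5)),
    "sucrose": ((4300.0, 100.0, 0.7), (5000.0, 150.0, 0.9),
                (5600.0, 180.0, 0.6), (8300.0, 400.0, 0.3)),
}

#: Broad bands of the structural-biomass matrix (cell wall, residual water)
#: that dominates ground stem tissue; its mass fraction is 1 minus the
#: analyte fractions, so total composition closes to one.
DEFAULT_MATRIX_BANDS: tuple[tuple[float, float, float], ...] = (
    (4200.0, 300.0, 1.2), (4800.0, 500.0, 1.5), (5800.0, 600.0, 1.0),
    (6800.0, 500.0, 1.2), (8500.0, 700.0, 0.6),
)


@dataclass
class SpectraSimConfig:
    """Study conditions for the FT-NIR-like spectra generator.

    Spectra are linear mixtures of per-constituent pure-component band
    profiles, corrupted by a LogNormal multiplicative scatter factor, an
    additive baseline (offset + slope in the normalised grid coordinate),
    and i.i.d. Gaussian noise. Paired wet-chemistry values add Normal
    measurement error; ``wetchem_reps`` > 1 additionally returns a technical
    replicate table for the reference-uncertainty estimator, and
    ``gross_error_ids`` inject large one-off wet-chemistry blunders of size
    ``gross_error_size`` (alternating sign) for outlier-detection studies.
    """

    wavenumber_start: float = 3300.0
    wavenumber_stop: float = 12000.0
    spacing: float = 4.0
    bands: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    matrix_bands: tuple | None = DEFAULT_MATRIX_BANDS
    scatter_log_sd: float = 0.05
    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 0.02
    noise_sd: float = 1e-3
    wetchem_error_sd: float = 6e-3
    wetchem_reps: int = 1
    gross_error_ids: tuple[int, ...] = ()
    gross_error_size: float = 0.0
    seed: int = 0


@dataclass
class SimulatedSpectra:
    """Spectra plus true and measured constituent values."""

    spectra: SpectraSet                     # constituents = measured wet chemistry
    true_concentrations: pd.DataFrame       # noise-free fractions w/w
    wetchem_replicates: pd.DataFrame | None  # long table when wetchem_reps > 1


def _pure_profiles(grid: np.ndarray, bands: dict[str, tuple]) -> np.ndarray:
    profiles = np.zeros((len(bands), grid.size))
    for c, (name, blist) in enumerate(bands.items()):
        for center, width, height in blist:
            if width <= 0:
                raise ValueError(f"band width must be > 0 for {name}")
            profiles[c] += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return profiles


def simulate_nsc_concentrations(
    n_samples: int,
    seed: int = 0,
    starch_range: tuple[float, float] = (0.02, 0.35),
    sucrose_range: tuple[float, float] = (0.01, 0.12),
) -> pd.DataFrame:
    """Uniform starch/sucrose fractions (w/w) over panel-like ranges.

    Starch spans a wider range than sucrose, mirroring ground stem tissue
    where starch dominates the non-structural pool.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "starch": rng.uniform(*starch_range, size=n_samples),
            "sucrose": rng.uniform(*sucrose_range, size=n_samples),
        },
        index=[f"S{i + 1:04d}" for i in range(n_samples)],
    )


def simulate_spectra(
    concentrations: pd.DataFrame,
    config: SpectraSimConfig,
) -> SimulatedSpectra:
    """Generate absorbance spectra for the given constituent concentrations.

    ``absorbance_s = m_s * (conc_s . pure) + b0_s + b1_s * t + noise`` with
    ``t`` the grid normalised to [0, 1], ``m_s`` LogNormal scatter and
    ``b0/b1`` Gaussian baseline terms. Deterministic given the config seed.
    """
    conc = concentrations.astype(float)
    if list(conc.columns) != list(config.bands.keys()):
        raise ValueError(
            f"concentration columns {list(conc.columns)} do not match band "
            f"constituents {list(config.bands.keys())}"
        )
    if (conc.values < 0).any():
        raise ValueError("concentrations must be non-negative")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = np.arange(config.wavenumber_start, config.wavenumber_stop + 1e-9, config.spacing)
    profiles = _pure_profiles(grid, config.bands)
    rng = np.random.default_rng(config.seed)
    n = conc.shape[0]

    clean = conc.values @ profiles
    if config.matrix_bands is not None:
        matrix_frac = 1.0 - conc.values.sum(axis=1)
        if (matrix_frac < 0).any():
            raise ValueError("analyte fractions exceed 1: no mass left for the matrix")
        matrix_profile = _pure_profiles(grid, {"matrix": config.matrix_bands})[0]
        clean = clean + matrix_frac[:, None] * matrix_profile
    m = np.exp(rng.normal(0.0, config.scatter_log_sd, size=n)) \
        if config.scatter_log_sd > 0 else np.ones(n)
    b0 = rng.normal(0.0, config.baseline_offset_sd, size=n) \
        if config.baseline_offset_sd > 0 else np.zeros(n)
    b1 = rng.normal(0.0, config.baseline_slope_sd, size=n) \
        if config.baseline_slope_sd > 0 else np.zeros(n)
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    absorb = m[:, None] * clean + b0[:, None] + b1[:, None] * t
    if config.noise_sd > 0:
        absorb = absorb + rng.normal(0.0, config.noise_sd, size=absorb.shape)

    measured = conc + rng.normal(0.0, config.wetchem_error_sd, size=conc.shape)
    if config.gross_error_ids:
        ids = np.asarray(config.gross_error_ids, dtype=int)
        if ids.min() < 0 or ids.max() >= n:
            raise ValueError("gross_error_ids out of range")
        signs = np.where(np.arange(ids.size) % 2 == 0, 1.0, -1.0)
        for col in measured.columns:
            measured.iloc[ids, measured.columns.get_loc(col)] += signs * config.gross_error_size

    reps = None
    if config.wetchem_reps > 1:
        rows = []
        for r in range(config.wetchem_reps):
            noisy = conc + rng.normal(0.0, config.wetchem_error_sd, size=conc.shape)
            block = noisy.copy()
            block.insert(0, "replicate", r + 1)
            block.insert(0, "sample_id", conc.index)
            rows.append(block)
        reps = pd.concat(rows, ignore_index=True)

    spectra = SpectraSet(
        wavenumbers=grid,
        absorbance=absorb,
        sample_ids=list(conc.index),
        constituents=measured,
    )
    return SimulatedSpectra(spectra=spectra, true_concentrations=conc, wetchem_replicates=reps)
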