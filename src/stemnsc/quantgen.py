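"""Bayesian hierarchical model for replicated phenotypes with a GRM.

Model for a single trait, observation r of line i:

    y_ir = mu + a_i + d_i + eps_ir
    a ~ MVN(0, sigma2_a K)          additive values, K the GRM
    d ~ MVN(0, sigma2_na I)         non-additive line effects
    eps_ir ~ family(0, sigma_e,i)   Gaussian or Student-t errors with
                                    line-specific scales

The line-specific error variances are shrunk hierarchically towards a common
scale (inverse-gamma with ``line_var_df`` pseudo-replicates), giving each
line its own dispersion and hence a line CV — the study's uncertainty trait.
Narrow- and broad-sense heritability are computed per posterior draw as

    h2 = sigma2_a / (sigma2_a + sigma2_na + mean_i sigma2_e,i)
    H2 = (sigma2_a + sigma2_na) / (same denominator)

so 0 <= h2 <= H2 <= 1 holds for every draw by construction. For Student-t
errors the error variance uses the scale times nu/(nu-2).

All standard deviations carry half-t(3) priors with scale twice the
empirical phenotype SD. The additive and non-additive line effects are
sampled through their sum (whose prior covariance is diagonal in the GRM's
eigenbasis) with a joint Metropolis step for the two variance components —
avoiding the funnel that coordinate-wise conjugate updates hit when one
component sits near zero; the error-variance hierarchy stays conjugate
inverse-gamma. The Student-t degrees of freedom get a shifted-exponential
prior on nu - 2 and a Metropolis-within-Gibbs step. The bivariate fit models the trait pair as additive line values with
a 2x2 genetic covariance tied to K plus residuals sharing a 2x2
environmental covariance (inverse-Wishart priors on both), and reports the
genetic and environmental correlations as (lower, point, upper) credible
triplets. It carries no separate non-additive term: with realised
relationships close to identity that term is nearly aliased with the
additive one and only degrades mixing, so line-level genetic covariance is
absorbed into the additive component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import gammaln
from scipy.stats import invwishart

__all__ = [
    "MCMCSettings",
    "ModelSpec",
    "PosteriorSummary",
    "fit_single_trait",
    "fit_bivariate",
    "summarize",
    "heritability_from_draws",
]

_HALF_T_DF = 3.0  # prior df for all standard-deviation half-t priors


@dataclass
class MCMCSettings:
    n_chains: int = 4
    n_warmup: int = 500
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class ModelSpec:
    """Configuration of the hierarchical model and its sampler."""

    error_family: str = "gaussian"          # gaussian | student_t
    traits: tuple[str, ...] = ()
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    prior_scale_mult: float = 2.0           # half-t scale = mult * empirical SD
    line_var_df: float = 2.0                # shrinkage df for line error variances (light pooling)
    t_df_prior_rate: float = 0.1            # Exp rate on nu - 2
    include_nonadditive: bool = True
    rhat_threshold: float = 1.05
    ci_level: float = 0.9

    def __post_init__(self) -> None:
        if self.error_family not in ("gaussian", "student_t"):
            raise ValueError(f"unknown error_family {self.error_family!r}")
        if len(self.traits) > 2:
            raise ValueError("traits must name at most two traits")


@dataclass
class PosteriorSummary:
    """MCMC draws and derived per-line quantities.

    ``draws`` maps parameter names to arrays of shape (chains, samples) for
    scalars or (chains, samples, n_lines) for line vectors. ``per_line``
    holds posterior means of the GEBV, line mean, and line CV.
    """

    traits: tuple[str, ...]
    line_ids: list[str]
    draws: dict[str, np.ndarray]
    per_line: pd.DataFrame
    warnings: list[str]
    ci_level: float = 0.9

    def summary(self, level: float | None = None) -> pd.DataFrame:
        return summarize(self, level=self.ci_level if level is None else level)

    def scalar_draws(self, name: str) -> np.ndarray:
        """Flattened draws of a scalar parameter across chains."""
        return np.asarray(self.draws[name]).reshape(-1)

    def triplet(self, name: str, level: float | None = None) -> tuple[float, float, float]:
        """(lower, point, upper) equal-tailed credible triplet."""
        level = self.ci_level if level is None else level
        x = self.scalar_draws(name)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
        return float(lo), float(x.mean()), float(hi)


# --------------------------------------------------------------------------
# diagnostics

def _split_halves(x: np.ndarray) -> np.ndarray:
    """Split each chain in half so single-chain runs still yield split-Rhat."""
    c, s = x.shape[0], x.shape[1] - (x.shape[1] % 2)
    return x[:, :s].reshape(c * 2, s // 2)


def split_rhat(x: np.ndarray) -> float:
    """Split-Rhat of (chains, samples) draws via arviz rank-normalised Rhat."""
    import arviz as az
    h = _split_halves(np.asarray(x, dtype=float))
    if h.shape[1] < 4 or np.allclose(h, h.ravel()[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(h[..., None]))["x"].values).ravel()[0])


def effective_sample_size(x: np.ndarray) -> float:
    import arviz as az
    h = _split_halves(np.asarray(x, dtype=float))
    if h.shape[1] < 4 or np.allclose(h, h.ravel()[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(h[..., None]))["x"].values).ravel()[0])


def summarize(posterior: "PosteriorSummary | dict[str, np.ndarray]", level: float = 0.9) -> pd.DataFrame:
    """Posterior mean, equal-tailed credible bounds, split-Rhat and ESS.

    One row per scalar parameter; draws may come from a
    :class:`PosteriorSummary` or a raw ``{name: (chains, samples)}`` dict.
    """
    draws = posterior.draws if isinstance(posterior, PosteriorSummary) else posterior
    if not draws:
        raise ValueError("no draws to summarize")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    rows = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            continue  # line vectors are summarised in per_line
        if arr.size == 0:
            raise ValueError(f"empty draws for {name!r}")
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [alpha, 1.0 - alpha])
        rows[name] = {
            "mean": float(flat.mean()),
            "lower": float(lo),
            "upper": float(hi),
            "rhat": split_rhat(arr),
            "ess": effective_sample_size(arr),
        }
    if not rows:
        raise ValueError("no scalar draws to summarize")
    return pd.DataFrame(rows).T[["mean", "lower", "upper", "rhat", "ess"]]


def heritability_from_draws(
    sigma2_a: np.ndarray, sigma2_na: np.ndarray, sigma2_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw narrow (h2) and broad (H2) sense heritability."""
    total = sigma2_a + sigma2_na + sigma2_e
    return sigma2_a / total, (sigma2_a + sigma2_na) / total


# --------------------------------------------------------------------------
# shared helpers

def _inv_gamma(rng: np.random.Generator, shape: float, rate) -> np.ndarray:
    """Draw from InvGamma(shape, rate) (rate on the inverse scale)."""
    return np.asarray(rate) / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


def _sample_mvn_prec(prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample N(P^-1 b, P^-1) given precision P and linear term b."""
    low = np.linalg.cholesky(prec)
    mean = cho_solve((low, True), lin)
    z = rng.standard_normal(lin.shape[0])
    return mean + solve_triangular(low, z, trans="T", lower=True)


def _align(pheno: pd.DataFrame, grm, trait: str):
    """Extract one trait, map lines to GRM order, validate coverage."""
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    lines = sorted(sub["line"].unique())
    grm_set = set(grm.line_ids)
    missing = [ln for ln in lines if ln not in grm_set]
    if missing:
        raise KeyError(f"line {missing[0]!r} present in phenotypes but absent from the GRM")
    k = grm.subset(lines)
    pos = {s: i for i, s in enumerate(lines)}
    idx = sub["line"].map(pos).to_numpy()
    y = sub["value"].to_numpy(dtype=float)
    counts = np.bincount(idx, minlength=len(lines))
    if not np.any(counts >= 2):
        raise ValueError("at least one line needs >= 2 replicates")
    return y, idx, lines, k


def _k_eig(K: np.ndarray, jitter: float = 1e-8):
    s, u = np.linalg.eigh(0.5 * (K + K.T))
    s = np.clip(s, jitter, None)
    kinv = (u / s) @ u.T
    return s, u, kinv


# --------------------------------------------------------------------------
# single-trait Gibbs sampler

def _halft_log_s2(s2: float, a2: float) -> float:
    """log density of a half-t(3, A) prior on sigma, up to a constant,
    evaluated at sigma^2 and including the log-scale Jacobian (theta = log
    sigma^2), so it can be used directly in a Metropolis step on theta."""
    return -((_HALF_T_DF + 1.0) / 2.0) * np.log1p(s2 / (_HALF_T_DF * a2)) + 0.5 * np.log(s2)


def _update_line_variances(
    resid_bar: np.ndarray, c: np.ndarray, big_k: np.ndarray,
    s2a: float, s2d: float, a2: float, use_d: bool, rng: np.random.Generator,
    prop_chol: np.ndarray, n_sweeps: int = 8,
) -> tuple[float, float, float]:
    """Collapsed Metropolis update of (sigma2_a, sigma2_na).

    The line effects are integrated out analytically: the precision-weighted
    line means satisfy ybar_i - mu ~ MVN(0, sigma2_a K + sigma2_na I +
    diag(1/c_i)), so the two variance components can be sampled from their
    marginal posterior by Metropolis on the log scale. This sidesteps both
    the funnel near sigma2_na = 0 and the slow ridge walk that conditioning
    on the line effects induces. ``prop_chol`` is the Cholesky factor of the
    proposal covariance, adapted during warmup so moves follow the
    (sigma2_a, sigma2_na) ridge. Returns the new values and the acceptance
    fraction of the sweeps.
    """
    n = c.size
    inv_c = 1.0 / c

    def logpost(ta: float, td: float | None) -> float:
        m = np.exp(ta) * big_k
        diag = m.diagonal() + inv_c + (np.exp(td) if td is not None else 0.0)
        m = m.copy()
        np.fill_diagonal(m, diag)
        try:
            low = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            return -np.inf
        alpha = solve_triangular(low, resid_bar, lower=True)
        ll = -np.log(low.diagonal()).sum() - 0.5 * float(alpha @ alpha)
        lp = _halft_log_s2(np.exp(ta), a2)
        if td is not None:
            lp += _halft_log_s2(np.exp(td), a2)
        return ll + lp

    ta, td = np.log(s2a), (np.log(s2d) if use_d else None)
    cur = logpost(ta, td)
    accepted = 0
    for _ in range(n_sweeps):
        if use_d:
            dz = prop_chol @ rng.standard_normal(2)
            ta_new, td_new = ta + dz[0], td + dz[1]
        else:
            ta_new, td_new = ta + prop_chol[0, 0] * rng.standard_normal(), None
        cand = logpost(ta_new, td_new)
        if np.log(rng.uniform()) < cand - cur:
            ta, td, cur = ta_new, td_new, cand
            accepted += 1
    if use_d:
        # swap move: the two components are nearly exchangeable when the
        # realised relationships are close to identity, so proposing
        # (ta, td) -> (td, ta) jumps across the ridge in one step
        cand = logpost(td, ta)
        if np.log(rng.uniform()) < cand - cur:
            ta, td, cur = td, ta, cand
    s2a_new = float(np.exp(ta))
    s2d_new = float(np.exp(td)) if use_d else 0.0
    return s2a_new, s2d_new, accepted / n_sweeps


def _gibbs_single_chain(
    y: np.ndarray,
    idx: np.ndarray,
    n: int,
    s_eig: np.ndarray,
    u_eig: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One chain of the single-trait sampler.

    The additive and non-additive line effects are sampled through their sum
    u = a + d, whose prior covariance sigma2_a K + sigma2_na I is diagonal
    in the eigenbasis of K; (sigma2_a, sigma2_na) then get a joint
    Metropolis update given u, and (a, d) are recovered exactly from their
    Gaussian conditional when a draw is recorded.
    """
    m = np.bincount(idx, minlength=n).astype(float)
    big_n = y.size
    mean_y, sd_y = float(y.mean()), float(y.std(ddof=1))
    a2 = (spec.prior_scale_mult * sd_y) ** 2  # half-t scale squared
    mu_prior_mean, mu_prior_prec = mean_y, 1.0 / (10.0 * sd_y) ** 2
    nu_l = spec.line_var_df
    student = spec.error_family == "student_t"
    use_d = spec.include_nonadditive

    big_k = (u_eig * s_eig) @ u_eig.T  # K rebuilt from its eigendecomposition

    # state
    mu = mean_y
    u = np.zeros(n)  # total line effects a + d
    v0 = sd_y**2
    s2a = v0 / 3.0
    s2d = v0 / 6.0 if use_d else 0.0
    s2e0 = v0 / 3.0
    s2e = np.full(n, s2e0)
    w = np.ones(big_n)
    nu = 8.0
    # adaptive Metropolis bookkeeping for (log s2a, log s2na)
    dim = 2 if use_d else 1
    mh_scale = 1.0
    prop_chol = 0.5 * np.eye(dim)
    th_count, th_mean, th_m2 = 0, np.zeros(dim), np.zeros((dim, dim))

    keep = spec.mcmc.n_samples
    out = {
        "mu": np.empty(keep), "sigma2_a": np.empty(keep), "sigma2_na": np.empty(keep),
        "a": np.empty((keep, n)), "d": np.empty((keep, n)), "sigma2_e": np.empty((keep, n)),
    }
    if student:
        out["nu"] = np.empty(keep)

    for it in range(spec.mcmc.n_warmup + keep):
        prec_obs = w / s2e[idx]
        c = np.bincount(idx, weights=prec_obs, minlength=n)
        t_lin = np.bincount(idx, weights=prec_obs * y, minlength=n)
        # partially collapsed scan: (sigma2_a, sigma2_na) are drawn first
        # from their u-marginalised conditional, and u is redrawn below
        # before anything conditions on it again (Van Dyk-Park ordering)
        resid_bar = t_lin / c - mu
        s2a, s2d, acc = _update_line_variances(
            resid_bar, c, big_k, s2a, s2d, a2, use_d, rng, prop_chol)
        # joint (mu, u) block: mu from its u-marginal (u integrated out via
        # the same Cholesky factor), then u | mu — removes the strong
        # intercept / line-effect posterior coupling
        v = np.clip(s2a * s_eig + s2d, 1e-12, None)
        prec = (u_eig / v) @ u_eig.T
        prec[np.diag_indices(n)] += c
        low = np.linalg.cholesky(prec)
        pinv_c = cho_solve((low, True), c)
        pinv_t = cho_solve((low, True), t_lin)
        p_mu = c.sum() + mu_prior_prec - float(c @ pinv_c)
        l_mu = t_lin.sum() + mu_prior_mean * mu_prior_prec - float(c @ pinv_t)
        mu = rng.normal(l_mu / p_mu, 1.0 / np.sqrt(p_mu))
        mean_u = pinv_t - pinv_c * mu
        z = rng.standard_normal(n)
        u = mean_u + solve_triangular(low, z, trans="T", lower=True)
        if it < spec.mcmc.n_warmup:
            # Welford-style running covariance of theta; proposal = scaled
            # empirical covariance (classic adaptive Metropolis), frozen at
            # the end of warmup so the kept draws target the exact posterior
            theta = np.array([np.log(s2a), np.log(s2d)])[:dim] if use_d \
                else np.array([np.log(s2a)])
            th_count += 1
            delta = theta - th_mean
            th_mean += delta / th_count
            th_m2 += np.outer(delta, theta - th_mean)
            mh_scale = float(np.clip(mh_scale * np.exp(0.15 * (acc - 0.3)), 0.1, 10.0))
            if th_count >= 50 and it % 20 == 0:
                cov = th_m2 / (th_count - 1) * (2.4**2 / dim) * mh_scale
                cov[np.diag_indices(dim)] += 1e-4
                prop_chol = np.linalg.cholesky(cov)
        ut = u_eig.T @ u
        # line-specific error variances around a common scale; the common
        # scale is updated first with the line variances integrated out
        # (inverse-gamma marginal), then the line variances are redrawn
        res = y - mu - u[idx]
        sse = np.bincount(idx, weights=w * res**2, minlength=n)
        s2e0 = _update_error_scale(s2e0, sse, m, nu_l, a2, rng)
        s2e = _inv_gamma(rng, (nu_l + m) / 2.0, (nu_l * s2e0 + sse) / 2.0)
        # Student-t latent weights and degrees of freedom
        if student:
            z2 = res**2 / s2e[idx]
            w = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + z2))
            nu = _update_nu(nu, w, spec.t_df_prior_rate, rng)
        j = it - spec.mcmc.n_warmup
        if j >= 0:
            # exact conditional decomposition of u into (a, d): in the
            # eigenbasis, a~_j | u~_j ~ N(rho_j u~_j, s2a s_j s2d / v_j)
            v = np.clip(s2a * s_eig + s2d, 1e-12, None)
            rho = s2a * s_eig / v
            if use_d and s2d > 0:
                at = rho * ut + np.sqrt(s2a * s_eig * s2d / v) * rng.standard_normal(n)
                a = u_eig @ at
            else:
                a = u
            out["mu"][j] = mu
            out["sigma2_a"][j] = s2a
            out["sigma2_na"][j] = s2d
            out["a"][j] = a
            out["d"][j] = u - a
            out["sigma2_e"][j] = s2e
            if student:
                out["nu"][j] = nu
    return out


def _update_error_scale(
    s2e0: float, sse: np.ndarray, m: np.ndarray, nu_l: float, a2: float,
    rng: np.random.Generator, n_sweeps: int = 4, step: float = 0.4,
) -> float:
    """Metropolis update of the common error scale with the line-specific
    variances integrated out (their inverse-gamma marginal), so the
    hierarchy's coupling does not slow mixing at small replicate counts."""
    n = sse.size

    def logpost(ls: float) -> float:
        s0 = np.exp(ls)
        ll = n * (nu_l / 2.0) * np.log(nu_l * s0) \
            - float(((nu_l + m) / 2.0) @ np.log(nu_l * s0 + sse))
        return ll - s0 / a2 + ls  # Gamma(1, 1/a2) prior + log-scale Jacobian

    ls = np.log(s2e0)
    cur = logpost(ls)
    for _ in range(n_sweeps):
        ls_new = ls + step * rng.standard_normal()
        cand = logpost(ls_new)
        if np.log(rng.uniform()) < cand - cur:
            ls, cur = ls_new, cand
    return float(np.exp(ls))


def _update_nu(nu: float, w: np.ndarray, prior_rate: float, rng: np.random.Generator) -> float:
    """Random-walk Metropolis on log(nu - 2); Exp(prior_rate) prior on nu - 2."""
    sum_log_w, sum_w, big_n = float(np.log(w).sum()), float(w.sum()), w.size

    def logpost(v: float) -> float:
        half = v / 2.0
        ll = big_n * (half * np.log(half) - gammaln(half))
        ll += (half - 1.0) * sum_log_w - half * sum_w
        return ll - prior_rate * (v - 2.0)

    ell = np.log(nu - 2.0)
    ell_new = ell + 0.5 * rng.standard_normal()
    nu_new = 2.0 + np.exp(ell_new)
    log_acc = logpost(nu_new) - logpost(nu) + (ell_new - ell)
    if np.log(rng.uniform()) < log_acc:
        return float(nu_new)
    return nu


def fit_single_trait(
    pheno: pd.DataFrame,
    grm,
    spec: ModelSpec,
    trait: str | None = None,
) -> PosteriorSummary:
    """Fit the hierarchical model to one trait and summarise the posterior.

    ``pheno`` is a long-format table with columns line/replicate/trait/value;
    every line must appear in the GRM. Returns draws for the variance
    components, heritabilities, the per-line GEBV (posterior mean additive
    value), line means and line CVs, plus convergence warnings when any key
    parameter's split-Rhat exceeds the configured threshold.
    """
    if trait is None:
        present = tuple(pd.unique(pheno["trait"]))
        trait = spec.traits[0] if spec.traits else (present[0] if len(present) == 1 else None)
        if trait is None:
            raise ValueError("multiple traits present: specify which to fit")
    y, idx, lines, k = _align(pheno, grm, trait)
    n = len(lines)
    s_eig, u_eig, _ = _k_eig(k.K)
    seeds = np.random.SeedSequence(spec.mcmc.seed).spawn(spec.mcmc.n_chains)
    chains = [
        _gibbs_single_chain(y, idx, n, s_eig, u_eig, spec, np.random.default_rng(s))
        for s in seeds
    ]
    stack = {key: np.stack([c[key] for c in chains]) for key in chains[0]}

    student = spec.error_family == "student_t"
    var_factor = stack["nu"] / (stack["nu"] - 2.0) if student else 1.0
    s2e_line_var = stack["sigma2_e"] * (var_factor[..., None] if student else 1.0)
    s2e_bar = s2e_line_var.mean(axis=2)
    h2, big_h2 = heritability_from_draws(stack["sigma2_a"], stack["sigma2_na"], s2e_bar)

    line_mean_draws = stack["mu"][..., None] + stack["a"] + stack["d"]
    sd_line = np.sqrt(s2e_line_var)
    denom = np.abs(line_mean_draws)
    cv_draws = np.where(denom > 1e-8, sd_line / np.where(denom > 1e-8, denom, 1.0), np.nan)

    warn: list[str] = []
    undefined = np.all(np.isnan(cv_draws), axis=(0, 1))
    for i in np.flatnonzero(undefined):
        warn.append(f"line CV undefined for line {lines[i]} (|line mean| < 1e-8)")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_line = pd.DataFrame(
            {
                "gebv": stack["a"].mean(axis=(0, 1)),
                "line_mean": line_mean_draws.mean(axis=(0, 1)),
                "cv": np.nanmean(cv_draws, axis=(0, 1)),
                "error_sd": sd_line.mean(axis=(0, 1)),
            },
            index=pd.Index(lines, name="line"),
        )

    draws: dict[str, np.ndarray] = {
        "mu": stack["mu"],
        "sigma2_a": stack["sigma2_a"],
        "sigma2_na": stack["sigma2_na"],
        "sigma2_e_mean": s2e_bar,
        "h2": h2,
        "H2": big_h2,
        "a": stack["a"],
        "d": stack["d"],
        "sigma2_e_line": s2e_line_var,
    }
    if student:
        draws["nu"] = stack["nu"]

    # sigma2_na is excluded from the gate: near the zero boundary the half-t
    # mixture mixes slowly without affecting the parameters of interest
    for key in ("mu", "sigma2_a", "sigma2_e_mean", "h2"):
        r = split_rhat(draws[key])
        if np.isfinite(r) and r > spec.rhat_threshold:
            warn.append(f"split-Rhat {r:.3f} > {spec.rhat_threshold} for {key}")

    return PosteriorSummary(
        traits=(trait,), line_ids=lines, draws=draws, per_line=per_line,
        warnings=warn, ci_level=spec.ci_level,
    )


# --------------------------------------------------------------------------
# bivariate fit

def _chol2_solve_sample(p11, p12, p22, l1, l2, rng):
    """Vectorised 2x2 precision solve + Gaussian sample per row."""
    c11 = np.sqrt(p11)
    c21 = p12 / c11
    c22 = np.sqrt(p22 - c21**2)
    u1 = l1 / c11
    u2 = (l2 - c21 * u1) / c22
    x2 = u2 / c22
    x1 = (u1 - c21 * x2) / c11
    z1 = rng.standard_normal(np.shape(p11) or None)
    z2 = rng.standard_normal(np.shape(p11) or None)
    w2 = z2 / c22
    w1 = (z1 - c21 * w2) / c11
    return x1 + w1, x2 + w2


def _biv_theta_unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log g11, log g22, atanh r_g, log e11, log e22, atanh r_e) -> Sg, Se."""
    g11, g22 = np.exp(theta[0]), np.exp(theta[1])
    rg = np.tanh(theta[2])
    e11, e22 = np.exp(theta[3]), np.exp(theta[4])
    re = np.tanh(theta[5])
    sg = np.array([[g11, rg * np.sqrt(g11 * g22)], [rg * np.sqrt(g11 * g22), g22]])
    se = np.array([[e11, re * np.sqrt(e11 * e22)], [re * np.sqrt(e11 * e22), e22]])
    return sg, se


_IW_DF = 4.0  # smallest df giving the inverse-Wishart a finite mean


def _iw_log_prior_2x2(ta1: float, ta2: float, z: float, psi: np.ndarray) -> float:
    """log density of an IW(4, diag(psi)) prior on a 2x2 covariance matrix,
    evaluated in (log-variance, atanh-correlation) coordinates with the
    change-of-variables Jacobian included. The proper inverse-Wishart keeps
    the posterior integrable even when the data make the matrix singular
    (e.g. a trait paired with an exact copy of itself)."""
    r = np.tanh(z)
    one_m_r2 = max(1.0 - r * r, 1e-300)
    logdet = ta1 + ta2 + np.log(one_m_r2)
    g11, g22 = np.exp(ta1), np.exp(ta2)
    # tr(Sigma^-1 Psi) for diagonal Psi via the closed-form 2x2 inverse
    tr_term = (psi[0] / g11 + psi[1] / g22) / one_m_r2
    log_jac = 1.5 * (ta1 + ta2) + np.log(one_m_r2)
    return -(_IW_DF + 3.0) / 2.0 * logdet - 0.5 * tr_term + log_jac


def _biv_log_prior(theta: np.ndarray, psi: np.ndarray) -> float:
    """Independent IW(4, diag(empirical var)/10) priors on the genetic and
    environmental covariance matrices (weakly informative)."""
    return float(_iw_log_prior_2x2(theta[0], theta[1], theta[2], psi)
                 + _iw_log_prior_2x2(theta[3], theta[4], theta[5], psi))


def _c_inverse_parts(sg, se, s_eig, m0):
    """Per-eigenvalue 2x2 covariances C_j = s_j Sg + Se/m and their closed-
    form inverses/determinants, vectorised over j."""
    c11 = s_eig * sg[0, 0] + se[0, 0] / m0
    c12 = s_eig * sg[0, 1] + se[0, 1] / m0
    c22 = s_eig * sg[1, 1] + se[1, 1] / m0
    det = c11 * c22 - c12**2
    return c11, c12, c22, det


def _gibbs_bivariate_chain(m, s_eig, u_eig, kinv, emp_var, spec, rng, y, idx):
    """One chain of the bivariate sampler; ``y`` is (N, 2) complete pairs.

    Balanced designs use a collapsed scheme: the additive values are
    integrated out analytically (the line means are independent 2-vectors in
    the GRM's eigenbasis with covariance s_j Sg + Se/m), and the six
    covariance parameters are updated by adaptive Metropolis on
    (log-variance, atanh-correlation) coordinates; the intercepts come from
    their exact A-marginal conditional, and A is redrawn afterwards for the
    GEBVs. Unbalanced designs fall back to a conditional Gibbs scheme with
    inverse-Wishart updates (slower mixing at very small replicate counts).
    """
    if np.all(m == m[0]):
        return _gibbs_bivariate_balanced(m, s_eig, u_eig, emp_var, spec, rng, y, idx)
    return _gibbs_bivariate_unbalanced(m, s_eig, u_eig, kinv, emp_var, spec, rng, y, idx)


def _gibbs_bivariate_balanced(m, s_eig, u_eig, emp_var, spec, rng, y, idx):
    n = m.size
    m0 = float(m[0])
    big_n = y.shape[0]
    psi = emp_var / 10.0  # IW prior scale: weakly informative
    mu_prior_mean = y.mean(axis=0)
    mu_prior_prec = np.diag(1.0 / (100.0 * emp_var))

    # sufficient statistics: line means (eigenbasis) + within-line scatter
    ybar = np.zeros((n, 2))
    np.add.at(ybar, idx, y)
    ybar /= m[:, None]
    dev = y - ybar[idx]
    ssw = dev.T @ dev
    df_w = big_n - n
    yt = u_eig.T @ ybar           # eigenbasis line means
    u1 = u_eig.T @ np.ones(n)     # eigenbasis image of the intercept direction

    def loglik(theta: np.ndarray, mu: np.ndarray) -> float:
        sg, se = _biv_theta_unpack(theta)
        c11, c12, c22, det = _c_inverse_parts(sg, se, s_eig, m0)
        if np.any(det <= 0):
            return -np.inf
        r1 = yt[:, 0] - u1 * mu[0]
        r2 = yt[:, 1] - u1 * mu[1]
        quad = (c22 * r1**2 - 2 * c12 * r1 * r2 + c11 * r2**2) / det
        ll = -0.5 * float(np.log(det).sum() + quad.sum())
        # within-line residual information about Se
        dete = se[0, 0] * se[1, 1] - se[0, 1] ** 2
        if dete <= 0:
            return -np.inf
        se_inv = np.array([[se[1, 1], -se[0, 1]], [-se[0, 1], se[0, 0]]]) / dete
        ll += -0.5 * (df_w * np.log(dete) + float(np.sum(se_inv * ssw)))
        return ll

    # state
    mu = y.mean(axis=0)
    theta = np.array([np.log(emp_var[0] / 3), np.log(emp_var[1] / 3), 0.0,
                      np.log(emp_var[0] / 2), np.log(emp_var[1] / 2), 0.0])
    dim = 6
    mh_scale = 1.0
    prop_chol = 0.3 * np.eye(dim)
    th_count, th_mean, th_m2 = 0, np.zeros(dim), np.zeros((dim, dim))
    cur = loglik(theta, mu) + _biv_log_prior(theta, psi)

    keep = spec.mcmc.n_samples
    out = {k: np.empty(keep) for k in
           ("mu1", "mu2", "g11", "g12", "g22", "e11", "e12", "e22", "r_g", "r_e")}
    a_accum = np.zeros((n, 2))
    n_sweeps = 8

    for it in range(spec.mcmc.n_warmup + keep):
        acc = 0
        for _ in range(n_sweeps):
            theta_new = theta + prop_chol @ rng.standard_normal(dim)
            cand = loglik(theta_new, mu) + _biv_log_prior(theta_new, psi)
            if np.log(rng.uniform()) < cand - cur:
                theta, cur = theta_new, cand
                acc += 1
        sg, se = _biv_theta_unpack(theta)
        # intercepts from their A-marginal conditional
        c11, c12, c22, det = _c_inverse_parts(sg, se, s_eig, m0)
        i11, i12, i22 = c22 / det, -c12 / det, c11 / det
        p_mu = np.array([
            [float((u1**2 * i11).sum()), float((u1**2 * i12).sum())],
            [float((u1**2 * i12).sum()), float((u1**2 * i22).sum())],
        ]) + mu_prior_prec
        l_mu = np.array([
            float((u1 * (i11 * yt[:, 0] + i12 * yt[:, 1])).sum()),
            float((u1 * (i12 * yt[:, 0] + i22 * yt[:, 1])).sum()),
        ]) + mu_prior_prec @ mu_prior_mean
        mu = _sample_mvn_prec(p_mu, l_mu, rng)
        cur = loglik(theta, mu) + _biv_log_prior(theta, psi)
        if it < spec.mcmc.n_warmup:
            th_count += 1
            delta = theta - th_mean
            th_mean += delta / th_count
            th_m2 += np.outer(delta, theta - th_mean)
            mh_scale = float(np.clip(mh_scale * np.exp(0.15 * (acc / n_sweeps - 0.25)),
                                     0.1, 10.0))
            if th_count >= 80 and it % 20 == 0:
                cov = th_m2 / (th_count - 1) * (2.4**2 / dim) * mh_scale
                cov[np.diag_indices(dim)] += 1e-5
                prop_chol = np.linalg.cholesky(cov)
        j = it - spec.mcmc.n_warmup
        if j >= 0:
            # A | mu, theta for GEBVs (independent 2x2 problems per eigenvalue)
            sg_det = sg[0, 0] * sg[1, 1] - sg[0, 1] ** 2
            sg_det = max(sg_det, 1e-12)
            gi11 = sg[1, 1] / sg_det / s_eig
            gi12 = -sg[0, 1] / sg_det / s_eig
            gi22 = sg[0, 0] / sg_det / s_eig
            dete = se[0, 0] * se[1, 1] - se[0, 1] ** 2
            se_inv = np.array([[se[1, 1], -se[0, 1]], [-se[0, 1], se[0, 0]]]) / dete
            p11 = gi11 + m0 * se_inv[0, 0]
            p12 = gi12 + m0 * se_inv[0, 1]
            p22 = gi22 + m0 * se_inv[1, 1]
            r1 = yt[:, 0] - u1 * mu[0]
            r2 = yt[:, 1] - u1 * mu[1]
            l1 = m0 * (se_inv[0, 0] * r1 + se_inv[0, 1] * r2)
            l2 = m0 * (se_inv[0, 1] * r1 + se_inv[1, 1] * r2)
            x1, x2 = _chol2_solve_sample(p11, p12, p22, l1, l2, rng)
            a_accum += u_eig @ np.column_stack([x1, x2])
            out["mu1"][j], out["mu2"][j] = mu
            out["g11"][j], out["g12"][j], out["g22"][j] = sg[0, 0], sg[0, 1], sg[1, 1]
            out["e11"][j], out["e12"][j], out["e22"][j] = se[0, 0], se[0, 1], se[1, 1]
            out["r_g"][j] = np.tanh(theta[2])
            out["r_e"][j] = np.tanh(theta[5])
    out["a_mean"] = a_accum / keep
    return out


def _gibbs_bivariate_unbalanced(m, s_eig, u_eig, kinv, emp_var, spec, rng, y, idx):
    """Conditional Gibbs fallback (inverse-Wishart updates)."""
    n = m.size
    balanced = np.all(m == m[0])
    nu0 = 4.0  # smallest df giving the inverse-Wishart a finite mean
    psi = np.diag(emp_var) / 10.0  # weakly informative: prior mean well below the data scale
    mu_prior_mean = y.mean(axis=0)
    mu_prior_prec = np.diag(1.0 / (100.0 * emp_var))
    mu = y.mean(axis=0)
    big_a = np.zeros((n, 2))
    sg = np.diag(emp_var) / 3.0
    se = np.diag(emp_var) / 3.0
    keep = spec.mcmc.n_samples
    out = {k: np.empty(keep) for k in
           ("mu1", "mu2", "g11", "g12", "g22", "e11", "e12", "e22", "r_g", "r_e")}
    a_accum = np.zeros((n, 2))

    for it in range(spec.mcmc.n_warmup + keep):
        se_inv = np.linalg.inv(se)
        sg_inv = np.linalg.inv(sg)
        # mu
        r_sum = y.sum(axis=0) - m @ big_a
        p_mu = y.shape[0] * se_inv + mu_prior_prec
        l_mu = se_inv @ r_sum + mu_prior_prec @ mu_prior_mean
        mu = _sample_mvn_prec(p_mu, l_mu, rng)
        # per-line residual sums excluding a
        s_line = np.zeros((n, 2))
        resid0 = y - mu
        np.add.at(s_line, idx, resid0)
        lin = s_line @ se_inv
        if balanced:
            lin_t = u_eig.T @ lin
            p11 = sg_inv[0, 0] / s_eig + m[0] * se_inv[0, 0]
            p12 = sg_inv[0, 1] / s_eig + m[0] * se_inv[0, 1]
            p22 = sg_inv[1, 1] / s_eig + m[0] * se_inv[1, 1]
            x1, x2 = _chol2_solve_sample(p11, p12, p22, lin_t[:, 0], lin_t[:, 1], rng)
            big_a = u_eig @ np.column_stack([x1, x2])
        else:
            prec = np.block([
                [sg_inv[0, 0] * kinv + np.diag(m * se_inv[0, 0]),
                 sg_inv[0, 1] * kinv + np.diag(m * se_inv[0, 1])],
                [sg_inv[0, 1] * kinv + np.diag(m * se_inv[0, 1]),
                 sg_inv[1, 1] * kinv + np.diag(m * se_inv[1, 1])],
            ])
            vec = _sample_mvn_prec(prec, np.concatenate([lin[:, 0], lin[:, 1]]), rng)
            big_a = np.column_stack([vec[:n], vec[n:]])
        # covariance matrices
        at_kinv_a = big_a.T @ kinv @ big_a
        sg = invwishart.rvs(df=nu0 + n, scale=psi + at_kinv_a, random_state=rng)
        res = resid0 - big_a[idx]
        se = invwishart.rvs(df=nu0 + y.shape[0], scale=psi + res.T @ res, random_state=rng)
        j = it - spec.mcmc.n_warmup
        if j >= 0:
            out["mu1"][j], out["mu2"][j] = mu
            out["g11"][j], out["g12"][j], out["g22"][j] = sg[0, 0], sg[0, 1], sg[1, 1]
            out["e11"][j], out["e12"][j], out["e22"][j] = se[0, 0], se[0, 1], se[1, 1]
            out["r_g"][j] = sg[0, 1] / np.sqrt(sg[0, 0] * sg[1, 1])
            out["r_e"][j] = se[0, 1] / np.sqrt(se[0, 0] * se[1, 1])
            a_accum += big_a
    out["a_mean"] = a_accum / keep
    return out


def fit_bivariate(pheno: pd.DataFrame, grm, spec: ModelSpec) -> PosteriorSummary:
    """Fit two traits jointly and estimate genetic/environmental correlations.

    Additive values for the trait pair are MVN with a 2x2 genetic covariance
    tied to the GRM; replicate residuals share a 2x2 environmental
    covariance (Gaussian errors). Observations are paired by (line,
    replicate); replicates missing either trait are dropped with a warning.
    Returns ``r_g`` and ``r_e`` draws; credible triplets come from
    :meth:`PosteriorSummary.triplet`.
    """
    if spec.error_family != "gaussian":
        raise NotImplementedError("fit_bivariate supports Gaussian errors only")
    traits = spec.traits if spec.traits else tuple(sorted(pd.unique(pheno["trait"])))
    if len(traits) != 2:
        raise ValueError("exactly two traits are required for a bivariate fit")
    sub = pheno[pheno["trait"].isin(traits)]
    wide = sub.pivot_table(index=["line", "replicate"], columns="trait",
                           values="value", aggfunc="first").reindex(columns=list(traits))
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    warn: list[str] = []
    if n_dropped:
        warn.append(f"dropped {n_dropped} replicate(s) missing one of the two traits")
    lines = sorted(complete.index.get_level_values("line").unique())
    for t in traits:
        t_lines = set(sub.loc[sub["trait"] == t, "line"].unique())
        if not t_lines & set(lines):
            raise ValueError(f"traits have disjoint line sets: {t!r} shares no lines")
    if not lines:
        raise ValueError("traits have disjoint line sets: no complete (line, replicate) pairs")
    grm_set = set(grm.line_ids)
    missing = [ln for ln in lines if ln not in grm_set]
    if missing:
        raise KeyError(f"line {missing[0]!r} present in phenotypes but absent from the GRM")
    k = grm.subset(lines)
    pos = {s: i for i, s in enumerate(lines)}
    idx = complete.index.get_level_values("line").map(pos).to_numpy()
    y = complete.to_numpy(dtype=float)
    m = np.bincount(idx, minlength=len(lines)).astype(float)
    if not np.any(m >= 2):
        raise ValueError("at least one line needs >= 2 complete replicate pairs")
    s_eig, u_eig, kinv = _k_eig(k.K)
    emp_var = y.var(axis=0, ddof=1)

    seeds = np.random.SeedSequence(spec.mcmc.seed).spawn(spec.mcmc.n_chains)
    chains = [
        _gibbs_bivariate_chain(m, s_eig, u_eig, kinv, emp_var, spec,
                               np.random.default_rng(s), y, idx)
        for s in seeds
    ]
    scalar_keys = [k_ for k_ in chains[0] if k_ != "a_mean"]
    draws = {k_: np.stack([c[k_] for c in chains]) for k_ in scalar_keys}
    a_mean = np.mean([c["a_mean"] for c in chains], axis=0)
    per_line = pd.DataFrame(
        {f"gebv_{traits[0]}": a_mean[:, 0], f"gebv_{traits[1]}": a_mean[:, 1]},
        index=pd.Index(lines, name="line"),
    )
    for key in ("r_g", "r_e", "g11", "e11"):
        r = split_rhat(draws[key])
        if np.isfinite(r) and r > spec.rhat_threshold:
            warn.append(f"split-Rhat {r:.3f} > {spec.rhat_threshold} for {key}")
    return PosteriorSummary(
        traits=tuple(traits), line_ids=lines, draws=draws, per_line=per_line,
        warnings=warn, ci_level=spec.ci_level,
    )
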