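"""Replicate-size subsampling study for experimental-design choice.

Given a highly replicated phenotyping trial, this module re-estimates all
genetic parameters at reduced replicate sizes (RS) by repeatedly drawing,
for each line, an RS-sized subset of its replicates without replacement —
mimicking having run a smaller experiment — and quantifies, per draw:

* accuracy — Pearson correlation between subsample and full-data per-line
  estimates (line means, GEBVs, line CVs) or, across trait pairs, genetic
  correlations;
* relative deviation — (sub - full) / full for scalar parameters (variance
  components and narrow-sense heritability).

The replicate requirement for a dispersion parameter such as the line CV is
defined as the smallest RS at which, for at least half the lines, the
median subsampled estimate over draws lies within a factor band (default
1.5x) of the full-data estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantgen import ModelSpec, PosteriorSummary, fit_bivariate, fit_single_trait

__all__ = [
    "DesignStudyConfig",
    "DesignStudyResult",
    "subsample_replicates",
    "accuracy",
    "relative_deviation",
    "run_design_study",
    "replicate_requirement",
]

#: per-line vector parameters scored by accuracy
_VECTOR_PARAMS = ("line_mean", "gebv", "cv")
#: scalar parameters scored by relative deviation
_SCALAR_PARAMS = ("sigma2_a", "sigma2_na", "sigma2_e", "h2")


@dataclass
class DesignStudyConfig:
    replicate_sizes: tuple[int, ...] = (2, 5, 10, 15)
    n_draws: int = 20
    seed: int = 0
    parameters: tuple[str, ...] = ("line_mean", "gebv", "cv", "r_g", "variance_components", "h2")

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if any(rs < 2 for rs in self.replicate_sizes):
            raise ValueError("every replicate size must be >= 2")


@dataclass
class DesignStudyResult:
    """Tidy per-draw records plus full-data reference estimates."""

    records: pd.DataFrame     # rs, draw, trait, parameter, metric, value, ok
    per_line: pd.DataFrame    # rs, draw, trait, line, parameter, value
    reference: dict           # full-data estimates
    replicate_sizes: tuple[int, ...]
    n_failed: int = 0
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Median and quartiles per (rs, parameter, metric) over clean draws."""
        ok = self.records[self.records["ok"]]
        grp = ok.groupby(["rs", "parameter", "metric"])["value"]
        out = grp.agg(median="median",
                      q1=lambda s: s.quantile(0.25),
                      q3=lambda s: s.quantile(0.75),
                      n="count").reset_index()
        out["iqr"] = out["q3"] - out["q1"]
        return out


def subsample_replicates(pheno: pd.DataFrame, rs: int, seed: int) -> pd.DataFrame:
    """Keep exactly ``rs`` replicates per line, drawn uniformly without
    replacement within each line (the same replicates across all traits,
    since a replicate is one plant). Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    keep_keys = []
    for line, grp in pheno.groupby("line", sort=True):
        reps = np.sort(grp["replicate"].unique())
        if reps.size < rs:
            raise ValueError(f"line {line!r} has {reps.size} replicates, fewer than rs={rs}")
        chosen = rng.choice(reps, size=rs, replace=False)
        keep_keys.extend((line, r) for r in chosen)
    keep = pd.MultiIndex.from_tuples(keep_keys, names=["line", "replicate"])
    out = pheno.set_index(["line", "replicate"])
    out = out.loc[out.index.isin(keep)].reset_index()
    return out


def accuracy(sub_estimates: pd.Series | np.ndarray, full_estimates: pd.Series | np.ndarray) -> float:
    """Pearson correlation between aligned estimate vectors.

    Returns NaN (reported as missing) when either vector has zero variance.
    """
    if isinstance(sub_estimates, pd.Series) and isinstance(full_estimates, pd.Series):
        full_estimates = full_estimates.reindex(sub_estimates.index)
    x = np.asarray(sub_estimates, dtype=float)
    y = np.asarray(full_estimates, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("aligned vectors of length >= 3 are required")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def relative_deviation(sub_value: float, full_value: float) -> float:
    """(sub - full) / full; NaN when the full-data value is zero."""
    if full_value == 0:
        return float("nan")
    return (sub_value - full_value) / full_value


def _fit_all(pheno, grm, spec, traits, pairs, mcmc_seed):
    """Univariate fit per trait and bivariate fit per pair.

    Returns the fits, the pairwise genetic-correlation point estimates,
    per-fit convergence status ({trait_or_pair: bool}), and the failure log.
    """
    fits: dict[str, PosteriorSummary] = {}
    pair_rg: dict[tuple[str, str], float] = {}
    ok: dict = {}
    failed = []
    for i, t in enumerate(traits):
        s = _respec(spec, traits=(t,), seed=mcmc_seed + i)
        fit = fit_single_trait(pheno, grm, s, trait=t)
        fits[t] = fit
        ok[t] = not any("split-Rhat" in w for w in fit.warnings)
        if not ok[t]:
            failed.append(("single", t, fit.warnings))
    for j, (t1, t2) in enumerate(pairs):
        s = _respec(spec, traits=(t1, t2), seed=mcmc_seed + 100 + j)
        fit = fit_bivariate(pheno, grm, s)
        pair_rg[(t1, t2)] = float(fit.scalar_draws("r_g").mean())
        ok[(t1, t2)] = not any("split-Rhat" in w for w in fit.warnings)
        if not ok[(t1, t2)]:
            failed.append(("bivariate", (t1, t2), fit.warnings))
    return fits, pair_rg, ok, failed


def _respec(spec: ModelSpec, traits, seed) -> ModelSpec:
    from dataclasses import replace

    from .quantgen import MCMCSettings
    mcmc = MCMCSettings(n_chains=spec.mcmc.n_chains, n_warmup=spec.mcmc.n_warmup,
                        n_samples=spec.mcmc.n_samples, seed=int(seed) % (2**31 - 1))
    return replace(spec, traits=tuple(traits), mcmc=mcmc)


def run_design_study(
    pheno: pd.DataFrame,
    grm,
    model_spec: ModelSpec,
    config: DesignStudyConfig,
) -> DesignStudyResult:
    """Run the full subsampling experiment.

    The full dataset is fit first (univariate per trait; bivariate per trait
    pair when genetic correlations are requested and at least two traits are
    present). For each replicate size and draw the model is refit on the
    subsample and accuracy / relative-deviation records are emitted. Draws
    whose refit fails the split-Rhat gate are recorded and excluded from
    aggregation.
    """
    traits = tuple(sorted(pd.unique(pheno["trait"])))
    want_rg = "r_g" in config.parameters and len(traits) >= 2
    pairs = tuple(itertools.combinations(traits, 2)) if want_rg else ()
    max_rs = pheno.groupby("line")["replicate"].nunique().min()
    for rs in config.replicate_sizes:
        if rs > max_rs:
            raise ValueError(f"replicate size {rs} exceeds available replicates ({max_rs})")

    root = np.random.SeedSequence(config.seed)
    sub_seeds = root.spawn(len(config.replicate_sizes) * config.n_draws)
    # the full-data fit is the reference for every accuracy/deviation, so it
    # runs with twice the per-chain samples of the subsample refits
    from dataclasses import replace as _dc_replace
    full_mcmc = _dc_replace(model_spec.mcmc, n_samples=2 * model_spec.mcmc.n_samples)
    full_spec = _dc_replace(model_spec, mcmc=full_mcmc)
    full_fits, full_rg, _, full_failed = _fit_all(
        pheno, grm, full_spec, traits, pairs, mcmc_seed=config.seed)
    if full_failed:
        raise RuntimeError(f"full-data fit failed convergence: {full_failed}")

    reference = {
        "per_line": {t: full_fits[t].per_line for t in traits},
        "scalars": {
            t: {
                "sigma2_a": float(full_fits[t].scalar_draws("sigma2_a").mean()),
                "sigma2_na": float(full_fits[t].scalar_draws("sigma2_na").mean()),
                "sigma2_e": float(full_fits[t].scalar_draws("sigma2_e_mean").mean()),
                "h2": float(full_fits[t].scalar_draws("h2").mean()),
            }
            for t in traits
        },
        "r_g": full_rg,
    }

    records = []
    per_line_rows = []
    failures = []
    k = 0
    for rs in config.replicate_sizes:
        for draw in range(config.n_draws):
            sub_seed = sub_seeds[k].generate_state(1)[0] % (2**31 - 1)
            k += 1
            sub = subsample_replicates(pheno, rs, seed=int(sub_seed))
            fits, rg, fit_ok, failed = _fit_all(sub, grm, model_spec, traits, pairs,
                                                mcmc_seed=int(sub_seed))
            if failed:
                failures.append({"rs": rs, "draw": draw, "detail": failed})
            for t in traits:
                ref_pl = reference["per_line"][t]
                for parameter in _VECTOR_PARAMS:
                    if parameter not in config.parameters:
                        continue
                    sub_v = fits[t].per_line[parameter]
                    records.append({
                        "rs": rs, "draw": draw, "trait": t, "parameter": parameter,
                        "metric": "accuracy",
                        "value": accuracy(sub_v, ref_pl[parameter]), "ok": fit_ok[t],
                    })
                    for line, v in sub_v.items():
                        per_line_rows.append({
                            "rs": rs, "draw": draw, "trait": t, "line": line,
                            "parameter": parameter, "value": float(v),
                        })
                if "variance_components" in config.parameters or "h2" in config.parameters:
                    for parameter in _SCALAR_PARAMS:
                        key = "sigma2_e_mean" if parameter == "sigma2_e" else parameter
                        sub_val = float(fits[t].scalar_draws(key).mean())
                        records.append({
                            "rs": rs, "draw": draw, "trait": t, "parameter": parameter,
                            "metric": "relative_deviation",
                            "value": relative_deviation(sub_val, reference["scalars"][t][parameter]),
                            "ok": fit_ok[t],
                        })
            if pairs:
                sub_vec = np.array([rg[p] for p in pairs])
                full_vec = np.array([full_rg[p] for p in pairs])
                if len(pairs) >= 3:
                    records.append({
                        "rs": rs, "draw": draw, "trait": "all_pairs", "parameter": "r_g",
                        "metric": "accuracy", "value": accuracy(sub_vec, full_vec),
                        "ok": all(fit_ok[p] for p in pairs),
                    })
                for p, sv, fv in zip(pairs, sub_vec, full_vec):
                    records.append({
                        "rs": rs, "draw": draw, "trait": f"{p[0]}|{p[1]}", "parameter": "r_g",
                        "metric": "relative_deviation",
                        "value": relative_deviation(sv, fv), "ok": fit_ok[p],
                    })
    return DesignStudyResult(
        records=pd.DataFrame(records),
        per_line=pd.DataFrame(per_line_rows),
        reference=reference,
        replicate_sizes=tuple(config.replicate_sizes),
        n_failed=len(failures),
        failures=failures,
    )


def replicate_requirement(
    result: DesignStudyResult,
    parameter: str = "cv",
    trait: str | None = None,
    band: float = 1.5,
    min_fraction: float = 0.9,
    per_draw: bool = True,
) -> int | None:
    """Smallest RS whose subsampled per-line estimates come within ``band``x
    of the full-data estimates.

    With ``per_draw`` (default), each subsample draw stands for one
    experiment of size RS: a draw's score is the fraction of lines whose
    estimate lies in [full / band, full * band], and an RS qualifies when
    the median draw reaches ``min_fraction`` of lines. With
    ``per_draw=False`` the per-line median over draws is banded instead —
    a laxer reading that averages away the sampling noise the criterion is
    about. Returns None when no RS qualifies.
    """
    pl = result.per_line
    pl = pl[pl["parameter"] == parameter]
    if trait is not None:
        pl = pl[pl["trait"] == trait]
    if pl.empty:
        raise ValueError(f"no per-line records for parameter {parameter!r}")
    for rs in sorted(result.replicate_sizes):
        fractions = []
        for t, tgrp in pl[pl["rs"] == rs].groupby("trait"):
            ref = result.reference["per_line"][t][parameter]
            if per_draw:
                draw_scores = []
                for _, dgrp in tgrp.groupby("draw"):
                    vals = dgrp.set_index("line")["value"]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ratio = vals / ref.reindex(vals.index)
                    draw_scores.append(float(((ratio >= 1.0 / band)
                                              & (ratio <= band)).mean()))
                fractions.append(float(np.median(draw_scores)))
            else:
                med = tgrp.groupby("line")["value"].median()
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = med / ref.reindex(med.index)
                fractions.append(float(((ratio >= 1.0 / band)
                                        & (ratio <= band)).mean()))
        if fractions and np.mean(fractions) >= min_fraction:
            return rs
    return None
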