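"""Configuration-driven pipeline tying the analysis stages together.

A :class:`RunConfig` (usually loaded from YAML) names the stages to run and
their parameters; :func:`run_pipeline` executes them in dependency order,
derives every stage seed from the single global seed, writes all outputs as
CSV, and records a manifest (config echo, seeds, stage outcomes, output
files). Re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as snio
from .calibrate import calibration_table
from .design import DesignStudyConfig, run_design_study
from .grm import compute_grm
from .quantgen import MCMCSettings, ModelSpec, fit_bivariate, fit_single_trait
from .simulate import (
    PhenoSimConfig, SpectraSimConfig, simulate_genotypes,
    simulate_nsc_concentrations, simulate_phenotypes, simulate_spectra,
)
from .traits import select_contrasting

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "quantgen", "design_study", "chemometrics", "traits")


def _strict(cls, block: dict, where: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block {where!r}")
    coerced = {}
    for key, value in block.items():
        coerced[key] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)


@dataclass
class RunConfig:
    """Global seed, output stages, and per-stage parameter blocks."""

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "quantgen")
    genotypes: dict = field(default_factory=lambda: {"n_lines": 36, "n_snps": 400})
    phenotypes: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    n_spectra_samples: int = 120
    quantgen: dict = field(default_factory=dict)
    trait: str | None = None
    trait2: str | None = None
    design_study: dict = field(default_factory=dict)
    chemometrics: dict = field(default_factory=dict)
    traits_selection: dict = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {_STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return _strict(cls, raw, "run")


def _stage_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages and write a manifest. Returns outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    manifest = {"seed": config.seed, "stages": list(config.stages),
                "outputs": [], "outcomes": {}, "stage_seeds": {}}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    state: dict = {}
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                continue
            seed = _stage_seed(root, _STAGES.index(stage))
            manifest["stage_seeds"][stage] = seed
            _run_stage(stage, config, seed, state, emit)
            manifest["outcomes"][stage] = "ok"
    except Exception as exc:
        manifest["outcomes"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name in manifest["outputs"]:
        if not (out / name).exists():  # manifest must list only real files
            raise RuntimeError(f"declared output {name} missing")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _model_spec(config: RunConfig, seed: int, traits: tuple[str, ...]) -> ModelSpec:
    block = dict(config.quantgen)
    mcmc = MCMCSettings(
        n_chains=block.pop("n_chains", 2),
        n_warmup=block.pop("n_warmup", 300),
        n_samples=block.pop("n_samples", 500),
        seed=seed,
    )
    return _strict(ModelSpec, {**block, "mcmc": mcmc, "traits": traits}, "quantgen")


def _run_stage(stage: str, config: RunConfig, seed: int, state: dict, emit) -> None:
    if stage == "simulate":
        geno = simulate_genotypes(seed=seed, **config.genotypes)
        pcfg = _strict(PhenoSimConfig, {**config.phenotypes, "seed": seed + 1}, "phenotypes")
        sim = simulate_phenotypes(geno, pcfg)
        state["geno"], state["pheno"], state["truth"] = geno, sim.table, sim.truth
        emit("genotypes.csv", lambda p: snio.write_genotypes(geno, p))
        emit("phenotypes.csv", lambda p: snio.write_phenotypes(sim.table, p))
        emit("phenotype_truth.csv", lambda p: sim.truth.to_csv(p, index=False))
        if "chemometrics" in config.stages or config.spectra:
            conc = simulate_nsc_concentrations(config.n_spectra_samples, seed=seed + 2)
            scfg = _strict(SpectraSimConfig, {**config.spectra, "seed": seed + 3}, "spectra")
            ss = simulate_spectra(conc, scfg)
            state["spectra"] = ss
            emit("spectra.csv", lambda p: snio.write_spectra(ss.spectra, p))
            emit("wetchem.csv",
                 lambda p: ss.spectra.constituents.rename_axis("sample_id").to_csv(p))
    elif stage == "quantgen":
        pheno, geno = state["pheno"], state["geno"]
        grm = compute_grm(geno)
        state["grm"] = grm
        emit("grm.csv", lambda p: snio.write_grm(grm, p))
        traits = tuple(sorted(pheno["trait"].unique()))
        trait = config.trait or traits[0]
        spec = _model_spec(config, seed, (trait,))
        fit = fit_single_trait(pheno, grm, spec, trait=trait)
        state["fit"] = fit
        emit("posterior_summary.csv", lambda p: fit.summary().to_csv(p))
        emit("per_line.csv", lambda p: fit.per_line.to_csv(p))
        if config.trait2:
            spec2 = _model_spec(config, seed + 7, (trait, config.trait2))
            biv = fit_bivariate(pheno, grm, spec2)
            emit("bivariate_summary.csv", lambda p: biv.summary().to_csv(p))
    elif stage == "design_study":
        pheno, grm = state["pheno"], state["grm"]
        dcfg = _strict(DesignStudyConfig, {**config.design_study, "seed": seed}, "design_study")
        spec = _model_spec(config, seed + 11, ())
        result = run_design_study(pheno, grm, spec, dcfg)
        state["design"] = result
        emit("design_records.csv", lambda p: result.records.to_csv(p, index=False))
        emit("design_summary.csv", lambda p: result.summary().to_csv(p, index=False))
    elif stage == "chemometrics":
        ss = state["spectra"]
        block = dict(config.chemometrics)
        table, rep1, rep2 = calibration_table(
            ss.spectra, wetchem_replicates=ss.wetchem_replicates, **block)
        state["calibration"] = (rep1, rep2)
        emit("calibration_table.csv", lambda p: table.to_csv(p))
    elif stage == "traits":
        pheno = state["pheno"]
        means = pheno.pivot_table(index="line", columns="trait", values="value",
                                  aggfunc="mean")
        block = dict(config.traits_selection)
        selected, diag = select_contrasting(
            means, n_select=block.get("n_select", 6), n_clusters=block.get("n_clusters", 4))
        diag["selected_ids"] = ",".join(selected)
        emit("selection.csv", lambda p: diag.to_csv(p))
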