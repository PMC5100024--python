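import warnings

import numpy as np
import pandas as pd
import pytest

import stemnsc as sn

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_genotypes() -> sn.GenotypeMatrix:
    return sn.simulate_genotypes(n_lines=30, n_snps=200, seed=11)


@pytest.fixture(scope="session")
def small_grm(small_genotypes) -> sn.GRM:
    return sn.compute_grm(small_genotypes)


@pytest.fixture(scope="session")
def small_pheno(small_genotypes) -> sn.SimulatedPhenotypes:
    cfg = sn.PhenoSimConfig(
        n_reps=8, var_additive=0.6, var_nonadditive=0.1, var_error=0.3,
        line_cv_spread=0.2, traits=("STCH_HD",), seed=12,
    )
    return sn.simulate_phenotypes(small_genotypes, cfg)


@pytest.fixture(scope="session")
def quick_mcmc() -> sn.MCMCSettings:
    return sn.MCMCSettings(n_chains=2, n_warmup=200, n_samples=300, seed=7)


@pytest.fixture(scope="session")
def toy_spectra() -> sn.SpectraSet:
    """Tiny deterministic spectra set on a uniform grid."""
    grid = np.arange(4000.0, 4100.0, 4.0)
    rng = np.random.default_rng(3)
    absorb = rng.uniform(0.1, 1.0, size=(6, grid.size))
    return sn.SpectraSet(grid, absorb, [f"S{i}" for i in range(6)])
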