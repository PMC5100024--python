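"""Posterior machinery: summaries, invariants, and model degeneracies."""

import numpy as np
import pandas as pd
import pytest

import stemnsc as sn
from stemnsc.quantgen import heritability_from_draws, summarize


class TestHeritabilityArithmetic:
    def test_fixed_draw(self):
        h2, H2 = heritability_from_draws(np.array(3.0), np.array(1.0), np.array(6.0))
        assert h2 == pytest.approx(0.3)
        assert H2 == pytest.approx(0.4)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(1)
        a, d, e = (rng.gamma(2, size=100) for _ in range(3))
        h2, H2 = heritability_from_draws(a, d, e)
        assert np.all((0 <= h2) & (h2 <= H2) & (H2 <= 1))


class TestSummarize:
    def test_constant_draws(self):
        out = summarize({"x": np.full((1, 3), 0.5)})
        assert out.loc["x", "mean"] == 0.5
        assert out.loc["x", "lower"] == 0.5 and out.loc["x", "upper"] == 0.5

    def test_quantile_oracle(self):
        draws = np.arange(1.0, 101.0)[None, :]
        out = summarize({"x": draws}, level=0.9)
        assert out.loc["x", "lower"] == pytest.approx(np.quantile(draws, 0.05))
        assert out.loc["x", "upper"] == pytest.approx(np.quantile(draws, 0.95))

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(2, 50))
        shuffled = d.copy()
        rng.shuffle(shuffled, axis=1)
        a = summarize({"x": d})[["mean", "lower", "upper"]]
        b = summarize({"x": shuffled})[["mean", "lower", "upper"]]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            summarize({})
        with pytest.raises(ValueError):
            summarize({"x": np.empty((1, 0))})


class TestSingleTraitFit:
    @pytest.fixture(scope="class")
    def fit(self, small_pheno, small_grm, quick_mcmc):
        spec = sn.ModelSpec(traits=("STCH_HD",), mcmc=quick_mcmc)
        return sn.fit_single_trait(small_pheno.table, small_grm, spec)

    def test_draw_invariants(self, fit):
        for name in ("sigma2_a", "sigma2_na", "sigma2_e_mean"):
            assert (fit.scalar_draws(name) >= 0).all()
        h2, H2 = fit.scalar_draws("h2"), fit.scalar_draws("H2")
        assert np.all((0 <= h2) & (h2 <= H2) & (H2 <= 1))

    def test_per_line_outputs(self, fit, small_pheno):
        assert list(fit.per_line.columns[:3]) == ["gebv", "line_mean", "cv"]
        assert len(fit.per_line) == 30
        emp = small_pheno.table.groupby("line")["value"].mean()
        assert np.corrcoef(fit.per_line["line_mean"], emp.loc[fit.line_ids])[0, 1] > 0.95

    def test_deterministic_given_seed(self, fit, small_pheno, small_grm, quick_mcmc):
        spec = sn.ModelSpec(traits=("STCH_HD",), mcmc=quick_mcmc)
        again = sn.fit_single_trait(small_pheno.table, small_grm, spec)
        assert np.array_equal(again.draws["h2"], fit.draws["h2"])

    def test_missing_line_named(self, small_pheno, small_grm, quick_mcmc):
        pheno = small_pheno.table.copy()
        pheno.loc[pheno.index[0], "line"] = "MYSTERY"
        spec = sn.ModelSpec(traits=("STCH_HD",), mcmc=quick_mcmc)
        with pytest.raises(KeyError, match="MYSTERY"):
            sn.fit_single_trait(pheno, small_grm, spec)

    def test_student_t_close_to_gaussian_on_gaussian_data(
        self, small_pheno, small_grm, quick_mcmc, fit
    ):
        spec = sn.ModelSpec(error_family="student_t", traits=("STCH_HD",), mcmc=quick_mcmc)
        fit_t = sn.fit_single_trait(small_pheno.table, small_grm, spec)
        h2_g = fit.scalar_draws("h2").mean()
        h2_t = fit_t.scalar_draws("h2").mean()
        assert abs(h2_g - h2_t) < 0.1


def test_identity_grm_matches_anova_repeatability():
    """With K = I and no separate non-additive term, the model degenerates to
    an exchangeable line-effects model whose repeatability matches a one-way
    ANOVA variance decomposition on a large balanced simulation."""
    cfg = sn.PhenoSimConfig(n_lines=120, n_reps=8, var_additive=0.0,
                            var_nonadditive=0.5, var_error=0.5, seed=21)
    sim = sn.simulate_phenotypes(None, cfg)
    lines = sorted(sim.table["line"].unique())
    grm = sn.GRM.identity(lines)
    spec = sn.ModelSpec(traits=("DTH",), include_nonadditive=False,
                        mcmc=sn.MCMCSettings(n_chains=2, n_warmup=300, n_samples=400, seed=5))
    fit = sn.fit_single_trait(sim.table, grm, spec)
    wide = sim.table.pivot_table(index="line", columns="replicate", values="value")
    r = wide.shape[1]
    msb = r * wide.mean(axis=1).var(ddof=1)
    msw = wide.var(axis=1, ddof=1).mean()
    s2_line = max((msb - msw) / r, 0.0)
    anova_h2 = s2_line / (s2_line + msw)
    assert fit.scalar_draws("h2").mean() == pytest.approx(anova_h2, abs=0.06)


class TestBivariateFit:
    def test_self_correlation_near_one(self, small_pheno, small_grm, quick_mcmc):
        t = small_pheno.table
        dup = pd.concat([t, t.assign(trait="COPY")], ignore_index=True)
        spec = sn.ModelSpec(traits=("COPY", "STCH_HD"), mcmc=quick_mcmc)
        fit = sn.fit_bivariate(dup, small_grm, spec)
        assert fit.triplet("r_g")[1] >= 0.99

    def test_triplet_ordering(self, small_genotypes, small_grm, quick_mcmc):
        cfg = sn.PhenoSimConfig(n_reps=6, var_additive=(0.5, 0.5), var_error=0.4,
                                genetic_corr=0.4, env_corr=0.2,
                                traits=("STCH_HD", "SUC_HD"), seed=31)
        sim = sn.simulate_phenotypes(small_genotypes, cfg)
        spec = sn.ModelSpec(traits=("STCH_HD", "SUC_HD"), mcmc=quick_mcmc)
        fit = sn.fit_bivariate(sim.table, small_grm, spec)
        for name in ("r_g", "r_e"):
            lo, pt, hi = fit.triplet(name)
            assert lo <= pt <= hi
            assert np.all(np.abs(fit.scalar_draws(name)) <= 1)

    def test_disjoint_traits_error(self, small_pheno, small_grm, quick_mcmc):
        t = small_pheno.table
        half = sorted(t["line"].unique())[:15]
        other = t[~t["line"].isin(half)].assign(trait="OTHER")
        dis = pd.concat([t[t["line"].isin(half)], other], ignore_index=True)
        spec = sn.ModelSpec(traits=("OTHER", "STCH_HD"), mcmc=quick_mcmc)
        with pytest.raises(ValueError, match="disjoint"):
            sn.fit_bivariate(dis, small_grm, spec)

    def test_student_t_not_supported(self, small_pheno, small_grm, quick_mcmc):
        spec = sn.ModelSpec(error_family="student_t", traits=("a", "b"), mcmc=quick_mcmc)
        with pytest.raises(NotImplementedError):
            sn.fit_bivariate(small_pheno.table, small_grm, spec)
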