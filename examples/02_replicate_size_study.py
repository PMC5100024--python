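"""How many biological replicates does each genetic parameter need?

Subsamples a highly replicated synthetic trial (36 lines x 20 replicates,
two traits) at replicate sizes 2, 5, 10 and 15, refits the model on each
subsample, and prints how accuracy (correlation with the full-data
estimates) and relative deviation change with replication — the
experimental-design question behind choosing a replicate number.

Scaled for a quick run (two traits, few draws); pass more traits/draws for
smoother distributions.
"""

import warnings

warnings.filterwarnings("ignore")

import stemnsc as sn

geno = sn.simulate_genotypes(36, 400, seed=11)
grm = sn.compute_grm(geno)
sim = sn.simulate_phenotypes(geno, sn.PhenoSimConfig(
    n_reps=20, var_additive=0.6, var_nonadditive=0.1, var_error=0.4,
    genetic_corr=0.5, env_corr=0.2, line_cv_spread=0.5,
    traits=("STCH_HD", "SUC_HD"), seed=12))

spec = sn.ModelSpec(mcmc=sn.MCMCSettings(n_chains=2, n_warmup=250, n_samples=400, seed=13))
cfg = sn.DesignStudyConfig(replicate_sizes=(2, 5, 10), n_draws=4, seed=14)
result = sn.run_design_study(sim.table, grm, spec, cfg)

summary = result.summary()
for parameter, metric in (("line_mean", "accuracy"), ("cv", "accuracy"),
                          ("sigma2_e", "relative_deviation"), ("h2", "relative_deviation")):
    rows = summary[(summary.parameter == parameter) & (summary.metric == metric)]
    print(f"{parameter} ({metric}):")
    print(rows[["rs", "median", "q1", "q3"]].round(3).to_string(index=False))
    print()

print("Reading the output: line-mean accuracy is already high at RS=5 and")
print("gains little beyond it, while line-CV accuracy keeps improving — ")
print("dispersion needs roughly twice the replication of the mean. At RS=2")
print("the error variance is overestimated (positive relative deviation)")
print("and narrow-sense heritability underestimated (negative).")
print(f"Replicate requirement (1.5x band): line mean -> "
      f"{sn.replicate_requirement(result, 'line_mean')}, "
      f"line CV -> {sn.replicate_requirement(result, 'cv')}")
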