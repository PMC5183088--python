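# occudyn

Hierarchical Bayesian analysis of two-season, multi-species presence/absence
resurveys on a quadrat lattice — the study design used to ask how understory
plant communities change between two censuses, and in particular how canopy
gaps (here, gaps opened by mass oak mortality under deer browsing pressure)
affect which species persist and which colonize.

## The model

For species *i* in quadrat *j*, with detection treated as perfect:

```
y1_ij ~ Bernoulli(psi1_ij)        logit(psi1_ij) = beta_o + eps_o_i + r_j
y2_ij ~ Bernoulli(psi2_ij)        psi2_ij = y1_ij * phi_ij + (1 - y1_ij) * gamma_ij

logit(phi_ij)   = beta_s + eps_s_i + (beta_sg + eps_sg_i) * g_j
logit(gamma_ij) = beta_c + eps_c_i + (beta_cg + eps_cg_i) * g_j
```

psi1 is year-1 occurrence, phi survival (persistence of an occupied quadrat),
gamma colonization (of an empty one), and g_j the binary gap covariate.
Species effects `eps_*i ~ Normal(0, sigma_*^2) T(-10, 10)` share a scale per
family ("borrowing strength from the ensemble"); fixed effects get flat
`Normal(0, 10^4) T(-10, 10)` priors; the spatial effect r_j follows an
intrinsic CAR (ICAR) prior on the lattice adjacency, identified by a
sum-to-zero constraint.

The package provides the data model and file readers (long CSV pair and the
BUGS/R-dump dialect with `y1, y2, plot, adj, weights, num`), the exact
likelihood/prior evaluation, an adaptive Metropolis-within-Gibbs sampler,
Gelman-Rubin/ESS diagnostics, posterior summary tables, probability-scale
derived quantities, and a synthetic-data generator that runs the model
forward at the study's dimensions (42 species, 200 quadrats, 20 gap
quadrats) so the entire pipeline is testable — and recoverable against known
truth — without any field data.

## Worked example

```python
import occudyn as od

survey, lattice, truth = od.generate_dataset(od.ScenarioConfig(seed=2))
cfg = od.SamplerConfig(n_chains=4, n_iter=3_000, burn_in=1_000, thin=4, seed=11)
sample = od.run_chains(survey, lattice, cfg)
print(od.summarize(sample, params=["beta_o", "beta_c", "beta_cg", "sigma_r"]).round(2))
print(od.gelman_rubin(sample, params=["beta_o", "beta_c"]).table.round(3))
```

prints (truth: beta_o = -3.25, beta_c = -3.81, beta_cg = 1.51, sigma_r = 0.44)

```
         mean    sd  2.5%    5%   50%   95%  97.5%
beta_o  -2.94  0.31 -3.55 -3.46 -2.94 -2.45  -2.35
beta_c  -3.72  0.32 -4.37 -4.26 -3.72 -3.19  -3.07
beta_cg  1.51  0.31  0.84  0.97  1.54  1.98   2.04
sigma_r  0.44  0.08  0.30  0.31  0.44  0.57   0.60

         rhat       ess  converged
beta_o  1.000  1353.293       True
beta_c  1.000  1040.122       True
```

Every 95% interval above covers its generating value, and R-hat is well
below the conventional 1.1 threshold.  Derived probabilities convert
logit-scale estimates the way such results are reported — plugging posterior
means into the inverse logit:

```python
d = od.derived_probability(-3.81, gap_main=1.51, process="colonization")
print(f"{100 * d.point:.1f}%")   # -> 9.1%  (colonization probability in gaps)
```

The numbered scripts under `analysis/` run the same pipeline as a narrative:
simulate (01), fit (02), diagnose convergence (03), tabulate species effects
and derived probabilities (04), and replicate a parameter-recovery
experiment (05); tables land in `results/`, bulky draws in `scratch/`.

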