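# mrpath

Two-sample Mendelian randomization (MR) and two-step mediation analysis for
GWAS summary statistics, built for causal questions of the form *does an
exposure (e.g. a gut-bacterial taxon's abundance) affect a disease outcome
(e.g. atrial fibrillation), and how much of that effect flows through a
measured mediator (e.g. a circulating inflammatory cytokine)?*

It is aimed at epidemiologists and biostatisticians who work with published
GWAS summary statistics rather than individual-level genotypes. Everything
runs from plain tab-separated summary files, and a seeded synthetic-GWAS
generator with a known causal structure lets the whole pipeline be exercised
and calibrated without downloading any real GWAS.

## The statistical core

Each genetic instrument *j* contributes a Wald ratio
`beta_out_j / beta_exp_j`. The estimators over an instrument set are:

- **IVW** (primary): weighted regression of outcome on exposure betas
  through the origin, weights `1/se_out^2`; switches to multiplicative
  random effects (SE inflated by `sqrt(Q/(k-1))`, floored at 1) when
  Cochran's Q has p < 0.05.
- **MR-Egger**: the same regression with a free intercept; the intercept is
  the directional-pleiotropy test, the slope a pleiotropy-robust estimate
  under the InSIDE assumption.
- **Weighted median** and **weighted mode**: robust estimators consistent
  when at least half the weight, or the largest homogeneous group of
  instruments, is valid; bootstrap SEs are seeded and reproducible.

Instrument selection follows the standard summary-level recipe: association
threshold (default p < 1e-5), greedy LD clumping (1000 kb window,
r² < 0.001), allele harmonization with palindromic-SNP removal, a
user-supplied confounder exclusion list, per-SNP strength metrics
`R² = 2·MAF·(1-MAF)·beta²` and `F = beta²/se²`, and MR-PRESSO outlier
removal.

Mediation uses the product-of-coefficients decomposition on the log-odds
scale: step 1 estimates the exposure→mediator effect `α` by univariable IVW;
step 2 estimates the mediator→outcome effect `b` conditional on the exposure
by multivariable IVW; the indirect effect is `α·b` with first-order
delta-method SE `sqrt(b²·se_α² + α²·se_b²)`, and the proportion mediated is
`α·b / beta_total` (suppressed when the signs disagree or the indirect CI
spans zero).

## Worked example

```python
from mrpath import SimulationConfig, simulate_triplet, two_step_mediation

triplet = simulate_triplet(SimulationConfig(seed=7))
res = two_step_mediation(triplet.exposure, triplet.mediator, triplet.outcome)
print(f"total effect (log-odds):      {res.beta_total:.4f} (se {res.se_total:.4f})")
print(f"step 1, taxon->cytokine:      {res.beta_xm:.4f} (se {res.se_xm:.4f})")
print(f"step 2, cytokine->AF (MVMR):  {res.beta_my:.4f} (se {res.se_my:.4f})")
print(f"indirect OR:                  {res.indirect.or_:.3f} "
      f"({res.indirect.or_ci_low:.3f}-{res.indirect.or_ci_high:.3f})")
print(f"proportion mediated:          {res.proportion.percent:.1f}%")
```

prints

```
total effect (log-odds):      0.1587 (se 0.0039)
step 1, taxon->cytokine:      0.2265 (se 0.0326)
step 2, cytokine->AF (MVMR):  0.2791 (se 0.0110)
indirect OR:                  1.065 (1.046-1.085)
proportion mediated:          39.8%
```

The simulated pathway has a true total effect of 0.160 log-odds units, an
indirect effect of 0.060 (α = 0.2 times b = 0.3) and hence a true mediation
proportion of 37.5%: the pipeline recovers each within sampling error. An
indirect OR of 1.065 means the mediated path alone raises the odds of the
outcome by about 6.5% per SD increase in the exposure.

## Command line

```sh
mrpath simulate --seed 3 --out sim/            # synthetic triplet + LD + truth
mrpath scan --exposure sim/exposure.tsv --rank genus \
            --outcome sim/outcome.tsv --out scan/
mrpath reverse --exposure sim/outcome.tsv --outcome sim/exposure.tsv --out rev/
mrpath mediate --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
               --outcome sim/outcome.tsv --out med/
```

Each run writes its tables plus a `manifest.json` (thresholds, seeds, input
digests); reruns with the same manifest are byte-identical. Per-rank
multiple testing uses p < 0.05/n with n = 9/15/19/30/117 for
phylum/class/order/family/genus by default.

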