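# gsikit

Genetic stock identification (GSI) for SNP-panel genotype data, built around
the mixed-stock analysis workflow used for small pelagic fish such as
Atlantic herring: assemble a genetic baseline of spawning-verified reference
populations, validate it, decompose mixed catches into population
contributions, and summarise where each population is caught relative to
management-area boundaries.

## What it does

* **Genotype data model and I/O** (`gsikit.core`, `gsikit.io`) — diploid
  calls stored as reference-allele dosage g ∈ {0, 1, 2} with a missing
  sentinel; wide-CSV interchange (two allele columns per locus) and optional
  biallelic VCF ingestion; per-individual missing-data filtering (an
  individual is dropped when its missing rate exceeds the threshold, default
  25%); allele-count tallies.
* **Population-structure diagnostics** (`gsikit.popstruct`) — PCA on
  unscaled mean-imputed dosages; pairwise Weir–Cockerham θ (F_ST) with
  permutation significance; observed/unbiased expected heterozygosity and
  F_IS; Benjamini–Hochberg FDR; a two-cluster admixture model fitted by EM
  for splitting spring- vs autumn-spawning ecotypes at an ancestry threshold
  q ≥ 0.70; single-linkage merging of indistinct sampling sites; subsampling
  to balance population sizes.
* **Bayesian assignment** (`gsikit.gsi`) — the conditional GSI model:
  posterior-mean baseline frequencies p̂ = (n_ref + λ)/(n_tot + 2λ),
  Hardy–Weinberg product likelihoods, a Gibbs sampler alternating latent
  origins z_i | π and π | z ~ Dirichlet(1/K + counts), parametric-bootstrap
  bias correction of π̂, leave-one-out self-assignment, and
  simulated-mixture baseline assessment (per-population MSE).
* **Supervised track** (`gsikit.classify`) — LDA, naive Bayes, SVM and
  random-forest classifiers on mean-imputed dosages, Monte-Carlo and
  stratified K-fold cross-validation, mixture prediction, cross-method
  agreement.
* **Reporting** (`gsikit.report`) — composition per 1° × 0.5° statistical
  rectangle, per-stratum summaries north/south of a boundary latitude
  (default 62° N), and the missingness-vs-posterior regression diagnostic.
* **Synthetic data with known truth** (`gsikit.simulate`) — Balding–Nichols
  population frequencies around ancestral frequencies with per-population
  drift F, near-fixed ecotype-diagnostic loci, HWE genotypes, mixtures with
  known proportions, and seasonal samples containing admixed individuals.

## Worked example

```python
import numpy as np
from gsikit.simulate import SimConfig, draw_population_freqs, \
    simulate_baseline_genotypes, simulate_mixture_sample
from gsikit.gsi import baseline_posterior, gibbs_mixture_estimate, \
    bootstrap_bias_correct, loo_self_assign

cfg = SimConfig(seed=1, fst=np.linspace(0.1, 0.3, 12))   # 12 pops, 59 loci
freqs = draw_population_freqs(cfg)
baseline, basedef, truth = simulate_baseline_genotypes(freqs, cfg)

print(loo_self_assign(baseline, basedef).accuracy)       # 97.41

pi_true = np.full(12, 1 / 12)
mixture, _ = simulate_mixture_sample(freqs, pi_true, 100, seed=101, config=cfg)
post = baseline_posterior(baseline, basedef)
est = gibbs_mixture_estimate(mixture, post, seed=201)    # 2000 sweeps, 100 burn-in
corrected = bootstrap_bias_correct(est, post, mixture_size=100, seed=301)
print(np.abs(corrected - pi_true).mean().round(4))       # 0.0262
```

The first number is the leave-one-out self-assignment accuracy of the
synthetic baseline (percent of baseline fish assigned back to their own
population when their alleles are removed from the reference counts).  The
second is the mean absolute error of the bootstrap-corrected mixing
proportions of a 100-fish mixture — about 2.6 percentage points per
population, most of which is the multinomial sampling noise of a 100-fish
catch.

The same pipeline is available from the shell:

```bash
gsikit --seed 5 simulate --config sim.yaml --mixture-proportions 0.5,0.3,0.2 --out run/
gsikit --seed 5 validate --method loo --genotypes run/baseline.csv \
    --panel run/panel.tsv --basedef run/baseline_definition.tsv --out loo.tsv
gsikit --seed 5 assign --method gsi --baseline run/baseline.csv \
    --mixture run/mixture.csv --panel run/panel.tsv \
    --basedef run/baseline_definition.tsv --out assignments.tsv
```

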