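# Methods

## The problem

A mixed-stock fishery catches fish from several reproductively isolated
populations that overlap at sea.  Given a *baseline* — reference individuals
of known (spawning-verified) origin genotyped at a small panel of highly
informative SNPs — genetic stock identification (GSI) estimates, for a catch
of unknown composition, the mixing proportions π over baseline populations
and the origin of each individual fish.  This package implements the full
desk workflow: baseline diagnostics and construction, Bayesian mixture
estimation, a supervised-classification cross-check, and spatial summaries
against management boundaries.

## Data model

Genotypes are reference-allele dosages g ∈ {0, 1, 2} with −1 for missing;
half-called genotypes collapse to missing.  A locus flagged sex-linked stays
in files but is excluded from every statistic and likelihood (such markers
track sex, not population).  Missing-data filtering removes an individual
only when its missing rate strictly exceeds the threshold (default 0.25), so
fish sitting exactly at the acceptance ceiling are retained.

## Conditional Bayesian GSI

Baseline allele frequencies are posterior means under a symmetric per-allele
prior λ (default 0.5, i.e. 1/A for biallelic loci):
p̂\_kl = (n\_ref + λ)/(n\_tot + 2λ), never exactly 0 or 1.  Individual
likelihoods are Hardy–Weinberg products over non-missing informative loci;
missing loci contribute nothing, so a fish with no data is scored by the
mixture prior alone.

Mixing proportions use the latent-origin Gibbs sampler: z\_i | π is
categorical with probability ∝ π\_k L\_ik, and π | z ~ Dirichlet(1/K +
counts).  The prior Dirichlet(1/K) keeps the total prior weight at one fish
regardless of the number of populations.  Defaults are 2000 sweeps with 100
burn-in; posterior means are taken over the kept sweeps, with per-individual
memberships Rao-Blackwellised (average of the conditional membership
probabilities rather than of sampled indicators).  The sampler is batched:
bootstrap replicates and simulated mixtures run as one vectorised chain
update per sweep across all replicates, which changes nothing statistically
but makes the default settings run in seconds.

The parametric-bootstrap bias correction simulates `n_boot` (default 100)
mixtures of the observed size from the baseline posterior at π̂,
re-estimates each with the same Gibbs settings, subtracts the mean bootstrap
bias from π̂, clips at zero and renormalises.  The correction arithmetic
(subtract–clip–renormalise) is this package's own choice; only the existence
of the correction and its replicate counts are prescribed by the workflow it
mirrors.

Leave-one-out self-assignment removes the focal fish's own alleles from its
population's counts *exactly* (count subtraction, no refit) before scoring
it against all populations with equal priors.  This matters: a fish carrying
its population's only copies of an allele can assign home purely through its
own contribution to the reference counts.

The simulated-mixture assessment splits every population in half at random
per replicate, builds the reference from one half, draws intended
proportions from Dirichlet(1.5), draws origins multinomially, resamples
genotypes from the held-out half, and re-estimates.  The reported
per-population MSE compares the estimate with each mixture's **realized**
composition (origin counts / size), not the Dirichlet draw: the estimator
conditions on the fish actually present, so comparing against the intended
proportions would floor the MSE at the multinomial noise E[π(1−π)]/n
(≈ 7 × 10⁻⁴ for 12 populations and n = 100) no matter how good the panel
is.  Against realized composition, a fully diagnostic panel reaches MSE
below 10⁻⁵, and the statistic isolates genuine confusion between
populations — duplicating a population's frequencies inflates the pair's
MSE by well over an order of magnitude.  The Dirichlet concentration 1.5 is
a declared stand-in (the tool this mirrors does not print its value).

## Population-structure diagnostics

* **PCA** operates on centred, *unscaled* dosages with per-locus mean
  imputation of missing calls.  Components with numerically zero variance
  are dropped (their loading vectors are arbitrary), and each retained
  component is oriented so its largest-magnitude loading is positive.
* **Weir–Cockerham θ** uses the variance-component estimator with the
  ratio-of-sums (not mean-of-ratios) multi-locus convention.  Loci where any
  group has no genotyped individual are excluded pairwise.  Permutation
  p-values shuffle pooled individuals between the two groups and use
  (b + 1)/(B + 1) smoothing, so they can never be zero and are slightly
  conservative (super-uniform under the null).  Default 10,000 permutations.
* **Diversity**: per locus, uHe = 2n/(2n − 1) · 2p(1 − p) with n the number
  of genotyped individuals; F_IS = 1 − Ho/uHe averaged over the group's
  polymorphic loci (monomorphic loci are excluded from F_IS but contribute
  zeros to Ho/uHe means).
* **FDR**: Benjamini–Hochberg step-up, input order preserved.
* **Two-cluster admixture** (ecotype splitting): each of a fish's two allele
  copies per locus descends from cluster 1 with probability q_i, so
  g\_ij ~ Binomial(2, q_i f\_1j + (1 − q_i) f\_2j).  Fitting is maximum
  likelihood by allele-level EM (uncorrelated cluster frequencies), best of
  10 random restarts, tolerance 10⁻⁵ on the log-likelihood with a 2000
  iteration cap — the likelihood is monotone per iteration but flattens
  slowly near convergence.  This is a deliberate, documented stand-in for
  the MCMC clustering program usually cited for this step: downstream only
  consumes the decision boundary q̂ vs the threshold, and the threshold rule
  (assign when q ≥ 0.70 or 1 − q ≥ 0.70, otherwise unassigned and excluded
  from baselines) is inclusive at the boundary.
* **Merging**: sampling sites whose BH-adjusted permutation p-value is
  ≥ α (default 0.05) are linked; connected components (single linkage) merge
  into one population, so a chain A≈B, B≈C merges all three even if A and C
  differ.  The exact merge protocol of the workflow this mirrors is not
  public; single linkage on FDR-adjusted p-values is this package's declared
  rule, and the merge audit trail records every linked pair.
* **Balancing** subsamples populations above a cap (default 140) without
  replacement, deterministically under the seed.

## Supervised track

Features are mean-imputed dosage vectors.  Four model kinds are exposed
(LDA, Gaussian naive Bayes, probability-calibrated SVM, random forest with
200 trees); the SVM is the default for mixture prediction.  Monte-Carlo CV
holds a fixed share of *each* population in training (floor(prop · n), at
least one train and one test fish required) for 100 random splits per
proportion; K-fold CV uses stratified folds so every fish is tested exactly
once per K.  Defaults follow the mirrored protocol: proportions 0.5/0.7/0.9
and K ∈ {3, 4, 5, 15}.  Cross-method agreement is the fraction of fish with
identical MAP labels in two assignment tables.

## Spatial reporting

Rectangles are 1° longitude × 0.5° latitude, half-open on the upper edges
(lon\_bin = ⌊lon⌋, lat\_bin = ⌊lat/0.5⌋·0.5).  Stratum membership is
latitude ≥ boundary → north (the boundary case is not specified by the
reporting convention; inclusion in the north is this package's choice).
Stratum means per population are taken over the samples in which the
population occurs — null observations are not included — and the maximum is
over the same samples.  The missingness diagnostic is the OLS slope of the
MAP posterior on the count of missing loci.

## Synthetic data: what it emulates and what it does not

`draw_population_freqs` uses the Balding–Nichols F-model: population
frequencies are Beta-distributed around ancestral frequencies with
Var = F p(1 − p), the standard coalescent-consistent way to induce a target
differentiation.  A designated block of "spawning-time" loci is instead
near-fixed between two ecotype groups of populations (0.95 vs 0.05),
reproducing panels whose first PCA axis separates spring from autumn
spawners.  Defaults mirror the study conditions: 12 populations, 59
informative loci with 9 diagnostic, 90 fish per population, per-population
drift spanning 0.1–0.3, 3% per-call missingness (most real baseline fish
are nearly complete; the acceptance ceiling is rarely approached).
Genotypes are HWE binomial draws; mixtures draw origins multinomially;
seasonal samples give admixed fish q ~ Uniform(0.3, 0.7) so they fall below
the 0.70 threshold by construction.

Not emulated: linkage disequilibrium and inversion haplotypes, genotyping
error, migration or temporal drift, and population-specific missingness
patterns.  Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features.

All generators are deterministic under (config, seed); independent streams
per operation are derived by hashing the operation name into the seed
sequence, so adding a step never perturbs another step's draws.

## Problem sizes used in the test suite and acceptance script

Fixture tallies run on the shipped sample-inventory tables.  Oracle checks
compare θ against an independent ANOVA-mean-squares coding on 100 fuzzed
tables (tolerance 10⁻¹⁰) and the Gibbs sampler against exact enumeration on
all instances with ≤ 4 individuals and 2–3 populations (within 3 Monte-Carlo
SEs by batch means).  Parameter recovery runs 20 seeds at the study-scale
conditions above with 100-fish mixtures and 100 bootstrap replicates.  The
simulated-mixture assessment uses 50 mixtures of 100 (the full protocol's
500 replicates change nothing but runtime).  Null calibration uses 200
identical-frequency datasets with 199 permutations each.

## Known limitations

* The admixture fit is a point estimate; no uncertainty on q is reported.
* Reporting units are the populations themselves; no hierarchical grouping.
* The merge rule and the Dirichlet concentration for simulated proportions
  are declared stand-ins, as noted above.
* VCF ingestion requires records carrying panel locus ids and biallelic
  sites only.
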