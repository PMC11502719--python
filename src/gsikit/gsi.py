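"""Conditional Bayesian genetic stock identification.

The model conditions on posterior-mean baseline allele frequencies: with a
symmetric per-allele prior weight :math:`\\lambda` (default 0.5 for
biallelic loci), population :math:`k`'s reference-allele frequency at locus
:math:`l` is

.. math:: \\hat p_{kl} = (n^{ref}_{kl} + \\lambda) / (n^{tot}_{kl} + 2\\lambda).

Individual likelihoods are Hardy–Weinberg products over non-missing,
non-sex-linked loci.  Mixing proportions of a mixed catch are estimated by a
Gibbs sampler alternating latent origins :math:`z_i \\mid \\pi` and
:math:`\\pi \\mid z \\sim \\mathrm{Dirichlet}(1/K + counts)`, with a
parametric-bootstrap bias correction of the posterior mean.  Baseline quality
is assessed by leave-one-out self-assignment (exact removal of the focal
individual's alleles from its own population's counts) and by re-estimating
simulated mixtures built from held-out baseline splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    BaselineDefinition,
    GenotypeTable,
    allele_counts_by_group,
    population_grouping,
)
from .simulate import derive_rng

# ---------------------------------------------------------------------------
# baseline posterior and likelihoods
# ---------------------------------------------------------------------------


@dataclass
class BaselinePosterior:
    populations: list[str]
    locus_ids: list[str]
    p_hat: np.ndarray  # (K, L) posterior-mean reference-allele frequencies
    n_ref: np.ndarray
    n_total: np.ndarray
    prior: float

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def genotype_logprobs(self) -> np.ndarray:
        """(3, K, L) array of log P(g | p_hat) for g = 0, 1, 2."""
        p = self.p_hat
        return np.stack(
            [2 * np.log1p(-p), math.log(2.0) + np.log(p) + np.log1p(-p), 2 * np.log(p)]
        )


def posterior_allele_freqs(
    n_ref: np.ndarray,
    n_total: np.ndarray,
    populations: Sequence[str],
    locus_ids: Sequence[str],
    prior: float = 0.5,
) -> BaselinePosterior:
    """Posterior-mean allele frequencies from per-population allele counts."""
    n_ref = np.asarray(n_ref, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_ref < 0) or np.any(n_total < 0):
        raise ValueError("allele counts must be non-negative")
    if prior <= 0:
        raise ValueError("prior weight must be positive")
    p_hat = (n_ref + prior) / (n_total + 2 * prior)
    return BaselinePosterior(list(populations), list(locus_ids), p_hat, n_ref, n_total, prior)


def baseline_posterior(
    table: GenotypeTable, basedef: BaselineDefinition, prior: float = 0.5
) -> BaselinePosterior:
    """Counts + posterior over the panel's informative loci, populations in
    baseline-definition order."""
    grouping = population_grouping(table, basedef)
    counts = allele_counts_by_group(table, grouping)
    mask = table.panel.informative
    order = [p for p in basedef.populations if p in counts.groups]
    rows = [counts.groups.index(p) for p in order]
    return posterior_allele_freqs(
        counts.n_ref[rows][:, mask],
        counts.n_total[rows][:, mask],
        order,
        table.panel.informative_ids,
        prior,
    )


def _aligned_dosage(table: GenotypeTable, posterior: BaselinePosterior) -> np.ndarray:
    ids = table.panel.informative_ids
    if ids != posterior.locus_ids:
        if set(ids) != set(posterior.locus_ids):
            raise ValueError("table loci do not match baseline posterior loci")
        order = [ids.index(l) for l in posterior.locus_ids]
        return table.dosage(informative_only=True)[:, order]
    return table.dosage(informative_only=True)


def genotype_log_likelihoods(
    table: GenotypeTable, posterior: BaselinePosterior
) -> np.ndarray:
    """(n, K) log-likelihood of each individual under each population's
    HWE genotype distribution; missing loci contribute zero."""
    X = _aligned_dosage(table, posterior)
    logp = posterior.genotype_logprobs()  # (3, K, L)
    return _loglik_from_dosage(X, logp)


def _loglik_from_dosage(X: np.ndarray, logp: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    K = logp.shape[1]
    ll = np.zeros((n, K))
    for g in (0, 1, 2):
        mask = (X == g).astype(float)  # NaN-safe: NaN != g
        ll += mask @ logp[g].T
    return ll


# ---------------------------------------------------------------------------
# leave-one-out self-assignment
# ---------------------------------------------------------------------------


@dataclass
class SelfAssignmentMatrix:
    populations: list[str]
    matrix: pd.DataFrame  # true x predicted, row percentages
    accuracy: float  # overall %, count-weighted diagonal
    assignments: pd.Series  # predicted population per individual
    n_per_population: dict[str, int]
    mse: pd.Series | None = None  # attached from a simulated-mixture assessment


def loo_self_assign(
    table: GenotypeTable, basedef: BaselineDefinition, prior: float = 0.5
) -> SelfAssignmentMatrix:
    """Leave-one-out self-assignment of every baseline individual.

    Each individual's own alleles are subtracted from its population's
    counts before that population's posterior frequencies are formed; the
    individual is then assigned to the arg-max likelihood population under
    equal population priors.
    """
    grouping = population_grouping(table, basedef)
    post = baseline_posterior(table, basedef, prior)
    pops = post.populations
    pop_sizes = {p: sum(1 for v in grouping.values() if v == p) for p in pops}
    small = [p for p, n in pop_sizes.items() if n < 2]
    if small:
        raise ValueError(f"LOO impossible for populations of size 1: {small}")
    X = _aligned_dosage(table, posterior=post)
    ll = _loglik_from_dosage(X, post.genotype_logprobs())
    pop_index = {p: k for k, p in enumerate(pops)}
    k_of = np.array([pop_index[grouping[ind]] for ind in table.individuals])
    prior_w = post.prior
    for k, pop in enumerate(pops):
        rows = np.where(k_of == k)[0]
        Xk = X[rows]
        nonmiss = ~np.isnan(Xk)
        g = np.where(nonmiss, Xk, 0.0)
        n_ref_adj = post.n_ref[k] - g
        n_tot_adj = post.n_total[k] - 2 * nonmiss
        p_adj = np.clip(
            (n_ref_adj + prior_w) / (n_tot_adj + 2 * prior_w), 1e-12, 1 - 1e-12
        )
        own = (
            g * np.log(p_adj)
            + (2 - g) * np.log1p(-p_adj)
            + (g == 1) * math.log(2.0)
        )
        ll[rows, k] = np.where(nonmiss, own, 0.0).sum(axis=1)
    pred_idx = np.argmax(ll, axis=1)
    pred = pd.Series(
        [pops[i] for i in pred_idx], index=table.individuals, name="predicted"
    )
    K = len(pops)
    mat = np.zeros((K, K))
    for true_k, pk in zip(k_of, pred_idx):
        mat[true_k, pk] += 1
    row_sums = mat.sum(axis=1, keepdims=True)
    pct = 100.0 * mat / np.where(row_sums > 0, row_sums, 1)
    accuracy = 100.0 * float(np.trace(mat)) / float(mat.sum())
    idx = pd.Index(pops)
    return SelfAssignmentMatrix(
        pops,
        pd.DataFrame(pct, index=idx, columns=idx),
        accuracy,
        pred,
        pop_sizes,
    )


# ---------------------------------------------------------------------------
# Gibbs mixture estimation
# ---------------------------------------------------------------------------


@dataclass
class MixtureEstimate:
    populations: list[str]
    pi: np.ndarray
    memberships: np.ndarray  # (n, K) posterior membership per individual
    map_labels: list[str]
    individuals: list[str]
    n_iter: int
    burn_in: int
    seed: int
    pi_corrected: np.ndarray | None = None
    n_bootstraps: int | None = None
    n_missing: np.ndarray | None = None
    pi_draws: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        d = {
            "populations": self.populations,
            "pi": [float(x) for x in self.pi],
            "pi_corrected": None
            if self.pi_corrected is None
            else [float(x) for x in self.pi_corrected],
            "settings": {
                "n_iter": self.n_iter,
                "burn_in": self.burn_in,
                "n_bootstraps": self.n_bootstraps,
            },
            "seed": self.seed,
        }
        return d


def _gibbs_batch(
    logL: np.ndarray,
    alpha: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Gibbs sampler over B independent mixture problems.

    ``logL`` has shape (B, n, K).  Returns posterior means of pi (B, K) and
    Rao-Blackwellised per-individual memberships (B, n, K) from the
    post-burn-in sweeps.
    """
    B, n, K = logL.shape
    if n == 0:
        pi = np.broadcast_to(alpha / alpha.sum(), (B, K)).copy()
        return pi, np.zeros((B, 0, K))
    lik = np.exp(logL - logL.max(axis=2, keepdims=True))
    pi = np.full((B, K), 1.0 / K)
    pi_sum = np.zeros((B, K))
    memb_sum = np.zeros((B, n, K))
    offsets = (np.arange(B) * K)[:, None]
    kept = 0
    for it in range(n_iter):
        w = lik * pi[:, None, :]
        probs = w / w.sum(axis=2, keepdims=True)
        u = rng.random((B, n, 1))
        z = np.minimum((probs.cumsum(axis=2) < u).sum(axis=2), K - 1)
        counts = np.bincount((z + offsets).ravel(), minlength=B * K).reshape(B, K)
        gam = rng.standard_gamma(alpha + counts)
        pi = gam / gam.sum(axis=1, keepdims=True)
        if it >= burn_in:
            pi_sum += pi
            memb_sum += probs
            kept += 1
    return pi_sum / kept, memb_sum / kept


def gibbs_mixture_estimate(
    table: GenotypeTable,
    posterior: BaselinePosterior,
    n_iter: int = 2000,
    burn_in: int = 100,
    seed: int = 0,
    keep_draws: bool = False,
) -> MixtureEstimate:
    """Estimate mixing proportions and per-individual origin posteriors.

    Gibbs sampler: ``z_i | pi`` categorical with probability proportional to
    ``pi_k L_ik``, then ``pi | z ~ Dirichlet(1/K + counts)``.  Posterior
    means are taken over the post-burn-in sweeps (memberships are
    Rao-Blackwellised conditional probabilities).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    K = posterior.n_populations
    if K < 2:
        raise ValueError("need at least two baseline populations")
    rng = derive_rng(seed, "gibbs_mixture_estimate")
    alpha = np.full(K, 1.0 / K)
    n = table.n_individuals
    if n == 0:
        pi = alpha / alpha.sum()
        return MixtureEstimate(
            posterior.populations, pi, np.zeros((0, K)), [], [], n_iter, burn_in, seed
        )
    logL = genotype_log_likelihoods(table, posterior)[None]
    X = _aligned_dosage(table, posterior)
    n_missing = np.isnan(X).sum(axis=1)
    if keep_draws:
        pi_mean, memb, draws = _gibbs_batch_with_draws(logL, alpha, n_iter, burn_in, rng)
    else:
        pi_mean, memb = _gibbs_batch(logL, alpha, n_iter, burn_in, rng)
        draws = None
    memberships = memb[0]
    map_idx = np.argmax(memberships, axis=1)
    return MixtureEstimate(
        populations=posterior.populations,
        pi=pi_mean[0],
        memberships=memberships,
        map_labels=[posterior.populations[i] for i in map_idx],
        individuals=list(table.individuals),
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        n_missing=n_missing,
        pi_draws=draws,
    )


def _gibbs_batch_with_draws(logL, alpha, n_iter, burn_in, rng):
    """Single-problem variant that also returns the kept pi draws (for
    Monte-Carlo error diagnostics)."""
    B, n, K = logL.shape
    assert B == 1
    lik = np.exp(logL - logL.max(axis=2, keepdims=True))
    pi = np.full((1, K), 1.0 / K)
    memb_sum = np.zeros((1, n, K))
    draws = []
    for it in range(n_iter):
        w = lik * pi[:, None, :]
        probs = w / w.sum(axis=2, keepdims=True)
        u = rng.random((1, n, 1))
        z = np.minimum((probs.cumsum(axis=2) < u).sum(axis=2), K - 1)
        counts = np.bincount(z.ravel(), minlength=K).reshape(1, K)
        gam = rng.standard_gamma(alpha + counts)
        pi = gam / gam.sum(axis=1, keepdims=True)
        if it >= burn_in:
            draws.append(pi[0].copy())
            memb_sum += probs
    draws = np.asarray(draws)
    return draws.mean(axis=0)[None], memb_sum / len(draws), draws


# ---------------------------------------------------------------------------
# parametric bootstrap bias correction
# ---------------------------------------------------------------------------


def bootstrap_bias_correct(
    estimate: MixtureEstimate,
    posterior: BaselinePosterior,
    mixture_size: int | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Parametric-bootstrap bias correction of the mixing proportions.

    ``n_boot`` mixtures of ``mixture_size`` individuals are simulated from
    the baseline posterior frequencies at the point estimate, each
    re-estimated with the same Gibbs settings; the mean bootstrap bias is
    subtracted, and the result clipped at zero and renormalised.  Sets and
    returns ``estimate.pi_corrected``.
    """
    if mixture_size is None:
        mixture_size = max(len(estimate.individuals), 1)
    rng = derive_rng(seed, "bootstrap_bias_correct")
    K = posterior.n_populations
    L = posterior.p_hat.shape[1]
    pi_hat = estimate.pi
    origins = rng.choice(K, size=(n_boot, mixture_size), p=pi_hat / pi_hat.sum())
    g = rng.binomial(2, posterior.p_hat[origins])  # (B, n, L)
    logp = posterior.genotype_logprobs()
    logL = np.zeros((n_boot, mixture_size, K))
    for v in (0, 1, 2):
        logL += (g == v).astype(float) @ logp[v].T
    alpha = np.full(K, 1.0 / K)
    pi_boot, _ = _gibbs_batch(logL, alpha, estimate.n_iter, estimate.burn_in, rng)
    bias = pi_boot.mean(axis=0) - pi_hat
    corrected = np.clip(pi_hat - bias, 0.0, None)
    total = corrected.sum()
    corrected = corrected / total if total > 0 else np.full(K, 1.0 / K)
    estimate.pi_corrected = corrected
    estimate.n_bootstraps = n_boot
    return corrected


# ---------------------------------------------------------------------------
# simulated-mixture baseline assessment
# ---------------------------------------------------------------------------


@dataclass
class SimulatedAssessment:
    n_mixtures: int
    mixture_size: int
    mse: pd.Series  # per population
    dirichlet_param: float
    seed: int


def simulate_mixture_assessment(
    table: GenotypeTable,
    basedef: BaselineDefinition,
    n_mixtures: int = 500,
    mixture_size: int = 100,
    dirichlet_param: float = 1.5,
    prior: float = 0.5,
    n_iter: int = 2000,
    burn_in: int = 100,
    seed: int = 0,
) -> SimulatedAssessment:
    """Cross-validation by simulated mixtures.

    For each replicate the baseline is split in half within every
    population; the training half provides the reference frequencies,
    intended proportions are drawn from a symmetric Dirichlet, origins are
    drawn multinomially, mixture genotypes are resampled from the held-out
    half, and the mixture is re-estimated.  The per-population mean squared
    error compares the estimate with the realized composition of each
    simulated mixture (origin counts / size), so it isolates estimation
    error from multinomial sampling noise.
    """
    grouping = population_grouping(table, basedef)
    pops = [p for p in basedef.populations if p in set(grouping.values())]
    K = len(pops)
    rng = derive_rng(seed, "simulate_mixture_assessment")
    members = {p: [i for i, ind in enumerate(table.individuals) if grouping[ind] == p] for p in pops}
    for p, m in members.items():
        if len(m) < 2:
            raise ValueError(f"population {p!r} too small to split: {len(m)}")
    mask = table.panel.informative
    calls = table.calls[:, mask]
    L = calls.shape[1]
    true_pis = rng.dirichlet(np.full(K, dirichlet_param), size=n_mixtures)
    logL = np.empty((n_mixtures, mixture_size, K))
    for b in range(n_mixtures):
        n_ref = np.zeros((K, L))
        n_tot = np.zeros((K, L))
        holdout = []
        for k, p in enumerate(pops):
            m = np.array(members[p])
            perm = rng.permutation(len(m))
            half = len(m) // 2
            train = m[perm[:half]]
            sub = calls[train]
            ok = sub != MISSING
            n_ref[k] = np.where(ok, sub, 0).sum(axis=0)
            n_tot[k] = 2 * ok.sum(axis=0)
            holdout.append(m[perm[half:]])
        p_hat = (n_ref + prior) / (n_tot + 2 * prior)
        logp = np.stack(
            [
                2 * np.log1p(-p_hat),
                math.log(2.0) + np.log(p_hat) + np.log1p(-p_hat),
                2 * np.log(p_hat),
            ]
        )
        origins = rng.choice(K, size=mixture_size, p=true_pis[b])
        true_pis[b] = np.bincount(origins, minlength=K) / mixture_size
        rows = np.array(
            [holdout[k][rng.integers(len(holdout[k]))] for k in origins]
        )
        g = calls[rows].astype(float)
        g[calls[rows] == MISSING] = np.nan
        logL[b] = _loglik_from_dosage(g, logp)
    alpha = np.full(K, 1.0 / K)
    pi_est, _ = _gibbs_batch(logL, alpha, n_iter, burn_in, rng)
    mse = ((pi_est - true_pis) ** 2).mean(axis=0)
    return SimulatedAssessment(
        n_mixtures,
        mixture_size,
        pd.Series(mse, index=pd.Index(pops, name="population"), name="mse"),
        dirichlet_param,
        seed,
    )


# ---------------------------------------------------------------------------
# per-individual assignment table
# ---------------------------------------------------------------------------


def assign_mixture_individuals(
    table: GenotypeTable, estimate: MixtureEstimate
) -> pd.DataFrame:
    """Per-individual MAP population and posterior membership table.

    Ties are broken by population order and flagged; individuals missing all
    loci are flagged uninformative (their posterior equals the estimated
    mixture proportions)."""
    if list(table.individuals) != estimate.individuals:
        raise ValueError("estimate was not computed on this mixture table")
    K = len(estimate.populations)
    memb = estimate.memberships
    map_idx = np.argmax(memb, axis=1)
    ties = (np.isclose(memb, memb.max(axis=1, keepdims=True), rtol=0, atol=1e-12).sum(axis=1) > 1)
    total_loci = int(table.panel.informative.sum())
    n_missing = (
        estimate.n_missing
        if estimate.n_missing is not None
        else np.isnan(table.dosage()).sum(axis=1)
    )
    out = pd.DataFrame(
        {
            "individual": table.individuals,
            "sample_id": table.meta["sample_id"].to_numpy(),
            "map_population": [estimate.populations[i] for i in map_idx],
            "map_posterior": memb[np.arange(len(map_idx)), map_idx],
            "n_missing": n_missing.astype(int),
            "tie": ties,
            "uninformative": n_missing == total_loci,
        }
    )
    for k, p in enumerate(estimate.populations):
        out[f"posterior_{p}"] = memb[:, k]
    return out
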