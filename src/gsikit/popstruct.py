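"""Population-structure diagnostics and baseline construction.

Implements the diagnostics used to vet and assemble a genetic baseline:
principal component analysis on unscaled dosage data, pairwise
Weir–Cockerham :math:`\\theta` (F_ST) with permutation significance,
per-population diversity statistics (Ho, uHe, F_IS), Benjamini–Hochberg FDR
correction, a two-cluster admixture model for splitting spring/autumn
ecotypes, single-linkage merging of indistinct sampling sites, and
per-population subsampling to balance the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MISSING,
    BaselineDefinition,
    GenotypeTable,
    population_grouping,
)
from .simulate import derive_rng

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, C)
    loadings: np.ndarray  # (L_informative, C)
    explained_variance: np.ndarray  # (C,)
    explained_variance_ratio: np.ndarray
    locus_ids: list[str]


def pca_unscaled(table: GenotypeTable) -> PcaResult:
    """PCA of centred (but not variance-scaled) dosage data.

    Missing calls are imputed with the per-locus mean dosage before
    centring.  Components are oriented so the largest-magnitude loading of
    each is positive; sex-linked loci are excluded.
    """
    if table.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    X = table.dosage(informative_only=True)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing locus
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    Xc = X - X.mean(axis=0)
    if not np.any(Xc.std(axis=0) > 0):
        raise ValueError("all loci are monomorphic; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # keep only components with genuinely positive variance (null directions
    # of a rank-deficient matrix have arbitrary loading vectors)
    keep = S > S[0] * 1e-12
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    scores = U * S
    loadings = Vt.T
    n = X.shape[0]
    var = S**2 / (n - 1)
    # sign convention: the largest-|loading| entry of each component is positive
    for c in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    total = var.sum()
    return PcaResult(scores, loadings, var, var / total, table.panel.informative_ids)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-locus Weir–Cockerham (1984) variance components.

    Parameters are arrays of shape ``(r, ..., L)``: per-group sample sizes
    (genotyped individuals), reference-allele frequencies and observed
    heterozygote frequencies.  Returns ``(a, a + b + c, valid)`` of shape
    ``(..., L)``; loci where any group has no genotyped individual (or where
    the components are undefined) are flagged invalid and zeroed.
    """
    r = n.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        nsum = n.sum(axis=0)
        nbar = nsum / r
        valid = (n >= 1).all(axis=0) & (nbar > 1)
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        valid &= nc > 0
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    a = np.where(valid, a, 0.0)
    denom = np.where(valid, a + b + c, 0.0)
    return a, denom, valid


def wc_theta(
    dosage: np.ndarray, group_index: np.ndarray, n_groups: int
) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of summed variance
    components over loci) from a dosage matrix with NaN missing calls."""
    n, p, h = _group_stats(dosage, group_index, n_groups)
    a, denom, _ = _wc_components(n, p, h)
    d = denom.sum()
    if d == 0:
        return math.nan
    return float(a.sum() / d)


def _group_stats(dosage: np.ndarray, group_index: np.ndarray, n_groups: int):
    """Per-group per-locus (n, p, h) from a (N, L) dosage matrix."""
    L = dosage.shape[1]
    nonmiss = ~np.isnan(dosage)
    x = np.where(nonmiss, dosage, 0.0)
    het = np.where(nonmiss, dosage == 1, False).astype(float)
    n = np.zeros((n_groups, L))
    s = np.zeros((n_groups, L))
    hh = np.zeros((n_groups, L))
    np.add.at(n, group_index, nonmiss.astype(float))
    np.add.at(s, group_index, x)
    np.add.at(hh, group_index, het)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, s / (2 * n), 0.0)
        h = np.where(n > 0, hh / n, 0.0)
    return n, p, h


@dataclass
class FstResult:
    populations: list[str]
    theta: pd.DataFrame  # symmetric, NaN diagonal
    pvalues: pd.DataFrame
    n_permutations: int


def pairwise_fst(
    table: GenotypeTable,
    grouping: Mapping[str, str],
    n_permutations: int = 10000,
    seed: int = 0,
) -> FstResult:
    """Pairwise multi-locus Weir–Cockerham theta with permutation p-values.

    For each pair of groups, individuals are pooled and group labels
    shuffled ``n_permutations`` times; the p-value is the smoothed
    proportion ``(#{theta_perm >= theta_obs} + 1) / (B + 1)``.  A pair with
    no locus at which both groups are genotyped and polymorphic gets a NaN
    estimate and p-value.
    """
    groups = list(dict.fromkeys(grouping[i] for i in table.individuals if i in grouping))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    members = {g: [] for g in groups}
    for i, ind in enumerate(table.individuals):
        if ind in grouping:
            members[grouping[ind]].append(i)
    for g, m in members.items():
        if len(m) < 2:
            raise ValueError(f"group {g!r} has fewer than two individuals")
    rng = derive_rng(seed, "pairwise_fst")
    X = table.dosage(informative_only=True)
    K = len(groups)
    theta = np.full((K, K), np.nan)
    pvals = np.full((K, K), np.nan)
    for a in range(K):
        for b in range(a + 1, K):
            rows = members[groups[a]] + members[groups[b]]
            sub = X[rows]
            n1 = len(members[groups[a]])
            gidx = np.array([0] * n1 + [1] * (len(rows) - n1))
            t_obs = wc_theta(sub, gidx, 2)
            theta[a, b] = theta[b, a] = t_obs
            if math.isnan(t_obs) or n_permutations <= 0:
                continue
            t_perm = _permuted_thetas(sub, n1, n_permutations, rng)
            exceed = np.sum(t_perm >= t_obs - 1e-12)
            p = (exceed + 1) / (n_permutations + 1)
            pvals[a, b] = pvals[b, a] = p
    idx = pd.Index(groups)
    return FstResult(
        groups,
        pd.DataFrame(theta, index=idx, columns=idx),
        pd.DataFrame(pvals, index=idx, columns=idx),
        n_permutations,
    )


def _permuted_thetas(
    dosage: np.ndarray, n1: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised two-group theta under B random label permutations."""
    N, L = dosage.shape
    nonmiss = (~np.isnan(dosage)).astype(float)
    x = np.where(np.isnan(dosage), 0.0, dosage)
    het = np.where(np.isnan(dosage), 0.0, (dosage == 1).astype(float))
    order = np.argsort(rng.random((B, N)), axis=1)
    sel = np.zeros((B, N))
    np.put_along_axis(sel, order[:, :n1], 1.0, axis=1)
    tot_n = nonmiss.sum(axis=0)
    tot_x = x.sum(axis=0)
    tot_h = het.sum(axis=0)
    n1m = sel @ nonmiss  # (B, L)
    x1 = sel @ x
    h1 = sel @ het
    n2m = tot_n - n1m
    x2 = tot_x - x1
    h2 = tot_h - h1
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.stack([n1m, n2m])
        p = np.stack(
            [np.where(n1m > 0, x1 / (2 * n1m), 0.0), np.where(n2m > 0, x2 / (2 * n2m), 0.0)]
        )
        h = np.stack(
            [np.where(n1m > 0, h1 / n1m, 0.0), np.where(n2m > 0, h2 / n2m, 0.0)]
        )
    a, denom, _ = _wc_components(n, p, h)
    num = a.sum(axis=-1)
    den = denom.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den != 0, num / den, np.nan)
    return t


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    per_population: pd.DataFrame  # Ho, uHe, Fis, pct_polymorphic


def diversity_stats(table: GenotypeTable, grouping: Mapping[str, str]) -> DiversityStats:
    """Observed (Ho) and unbiased expected heterozygosity (uHe), inbreeding
    coefficient F_IS, and percent polymorphic loci per group.

    Per locus: ``uHe = 2n/(2n - 1) * (1 - p^2 - q^2)`` with ``n`` the number
    of genotyped individuals; ``F_IS = 1 - Ho/uHe`` averaged over the
    group's polymorphic loci.  Monomorphic loci count in Ho and uHe means
    but are excluded from F_IS.
    """
    groups = list(dict.fromkeys(grouping[i] for i in table.individuals if i in grouping))
    X = table.dosage(informative_only=True)
    gidx = {g: k for k, g in enumerate(groups)}
    index = np.array([gidx[grouping[ind]] for ind in table.individuals if ind in grouping])
    rows_used = [i for i, ind in enumerate(table.individuals) if ind in grouping]
    X = X[rows_used]
    n, p, h = _group_stats(X, index, len(groups))
    rows = []
    for k, g in enumerate(groups):
        typed = n[k] > 0
        if not typed.any():
            rows.append({"population": g, "Ho": np.nan, "uHe": np.nan, "Fis": np.nan, "pct_polymorphic": np.nan})
            continue
        ho_l = h[k, typed]
        p_l = p[k, typed]
        n_l = n[k, typed]
        he_l = 2 * p_l * (1 - p_l)
        uhe_l = np.where(n_l > 0.5, (2 * n_l) / (2 * n_l - 1) * he_l, 0.0)
        poly = (p_l > 0) & (p_l < 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fis_l = 1 - ho_l[poly] / uhe_l[poly]
        rows.append(
            {
                "population": g,
                "Ho": float(ho_l.mean()),
                "uHe": float(uhe_l.mean()),
                "Fis": float(fis_l.mean()) if poly.any() else np.nan,
                "pct_polymorphic": 100.0 * float(poly.mean()),
            }
        )
    return DiversityStats(pd.DataFrame(rows).set_index("population"))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# two-cluster admixture model
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    q: np.ndarray  # ancestry fraction to cluster 1, per individual
    cluster_freqs: np.ndarray  # (2, L)
    loglik: float
    n_restarts: int
    converged: bool
    individuals: list[str]
    loglik_path: np.ndarray | None = None


def _admixture_loglik(G: np.ndarray, M: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    mix = np.clip(q[:, None] * f[0] + (1 - q[:, None]) * f[1], 1e-12, 1 - 1e-12)
    g = np.where(M, G, 0)
    ll = g * np.log(mix) + (2 - g) * np.log1p(-mix) + (g == 1) * math.log(2.0)
    return float(np.where(M, ll, 0.0).sum())


def fit_admixture_k2(
    table: GenotypeTable,
    n_restarts: int = 10,
    tol: float = 1e-5,
    max_iter: int = 2000,
    seed: int = 0,
) -> AdmixtureFit:
    """Maximum-likelihood two-cluster admixture fit by allele-level EM.

    Model: each of an individual's two allele copies at a locus descends
    from cluster 1 with probability ``q_i`` and carries the reference allele
    with that cluster's frequency, so
    ``g_ij ~ Binomial(2, q_i f_1j + (1 - q_i) f_2j)``.  Missing calls are
    skipped.  The best of ``n_restarts`` random restarts (by log-likelihood)
    is returned; the likelihood is invariant under the label swap
    ``(q, f1, f2) -> (1 - q, f2, f1)``.
    """
    if table.n_individuals < 2:
        raise ValueError("need at least two individuals")
    Gf = table.dosage(informative_only=True)
    M = ~np.isnan(Gf)
    G = np.where(M, Gf, 0.0)
    n, L = G.shape
    m_i = M.sum(axis=1)
    if np.any(m_i == 0):
        # individuals with no data sit at q = 0.5 and do not move
        pass
    rng = derive_rng(seed, "fit_admixture_k2")
    best = None
    for _ in range(n_restarts):
        q = rng.uniform(0.2, 0.8, size=n)
        f = rng.uniform(0.2, 0.8, size=(2, L))
        prev = -np.inf
        path = []
        converged = False
        for _it in range(max_iter):
            f1, f2 = np.clip(f[0], 1e-9, 1 - 1e-9), np.clip(f[1], 1e-9, 1 - 1e-9)
            qc = q[:, None]
            # responsibilities that a ref / alt allele copy came from cluster 1
            r_ref = qc * f1 / (qc * f1 + (1 - qc) * f2)
            r_alt = qc * (1 - f1) / (qc * (1 - f1) + (1 - qc) * (1 - f2))
            ref_copies = np.where(M, G, 0.0)
            alt_copies = np.where(M, 2.0 - G, 0.0)
            c1 = ref_copies * r_ref + alt_copies * r_alt  # expected copies from cluster 1
            with np.errstate(invalid="ignore"):
                q = np.where(m_i > 0, c1.sum(axis=1) / (2 * m_i), 0.5)
            ref1 = (ref_copies * r_ref).sum(axis=0)
            alt1 = (alt_copies * r_alt).sum(axis=0)
            ref2 = (ref_copies * (1 - r_ref)).sum(axis=0)
            alt2 = (alt_copies * (1 - r_alt)).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.vstack(
                    [
                        np.where(ref1 + alt1 > 0, ref1 / (ref1 + alt1), 0.5),
                        np.where(ref2 + alt2 > 0, ref2 / (ref2 + alt2), 0.5),
                    ]
                )
            ll = _admixture_loglik(G, M, q, f)
            path.append(ll)
            if ll - prev < tol and _it > 0:
                converged = True
                prev = ll
                break
            prev = ll
        fit = AdmixtureFit(
            q=q.copy(),
            cluster_freqs=f.copy(),
            loglik=prev,
            n_restarts=n_restarts,
            converged=converged,
            individuals=list(table.individuals),
            loglik_path=np.asarray(path),
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    best.n_restarts = n_restarts
    return best


@dataclass
class AncestrySplit:
    labels: pd.Series  # cluster_A / cluster_B / unassigned
    counts: dict[str, int]
    threshold: float


def split_by_ancestry(fit: AdmixtureFit, threshold: float = 0.70) -> AncestrySplit:
    """Assign individuals to a cluster when ancestry q (or 1-q) reaches the
    threshold (inclusive); everyone else is left unassigned and should be
    dropped from downstream baselines."""
    labels = np.where(
        fit.q >= threshold,
        "cluster_A",
        np.where(1 - fit.q >= threshold, "cluster_B", "unassigned"),
    )
    s = pd.Series(labels, index=fit.individuals, name="ancestry_cluster")
    counts = {
        "cluster_A": int((labels == "cluster_A").sum()),
        "cluster_B": int((labels == "cluster_B").sum()),
        "unassigned": int((labels == "unassigned").sum()),
    }
    return AncestrySplit(s, counts, threshold)


# ---------------------------------------------------------------------------
# merging and balancing
# ---------------------------------------------------------------------------


@dataclass
class MergeResult:
    partition: list[list[str]]
    label_of: dict[str, str]
    merges: list[tuple[str, str, float]]  # pairs merged, with adjusted p
    adjusted_pvalues: pd.DataFrame


def merge_indistinct_samples(fst: FstResult, alpha: float = 0.05) -> MergeResult:
    """Single-linkage merge of samples that are not significantly
    differentiated after BH-FDR correction of the permutation p-values.

    Every pair whose adjusted p-value is >= ``alpha`` is linked; connected
    components become merged populations.  By single linkage a chain
    A~B, B~C merges all three even if A and C differ.
    """
    samples = fst.populations
    K = len(samples)
    iu = np.triu_indices(K, 1)
    raw = fst.pvalues.to_numpy()[iu]
    adj = np.full(raw.shape, np.nan)
    ok = ~np.isnan(raw)
    if ok.any():
        adj[ok] = bh_fdr(raw[ok])
    adj_mat = np.full((K, K), np.nan)
    adj_mat[iu] = adj
    adj_mat[(iu[1], iu[0])] = adj
    parent = list(range(K))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    merges = []
    for a, b, p in zip(iu[0], iu[1], adj):
        if not np.isnan(p) and p >= alpha:
            merges.append((samples[a], samples[b], float(p)))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    comps: dict[int, list[str]] = {}
    for i, s in enumerate(samples):
        comps.setdefault(find(i), []).append(s)
    partition = list(comps.values())
    label_of = {}
    for group in partition:
        label = "+".join(group)
        for s in group:
            label_of[s] = label
    idx = pd.Index(samples)
    return MergeResult(partition, label_of, merges, pd.DataFrame(adj_mat, index=idx, columns=idx))


def balance_and_trim(
    table: GenotypeTable,
    basedef: BaselineDefinition,
    cap: int = 140,
    seed: int = 0,
) -> GenotypeTable:
    """Subsample overrepresented populations down to ``cap`` individuals
    (without replacement, deterministic under ``seed``); smaller populations
    are untouched and input order is preserved."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    grouping = population_grouping(table, basedef)
    rng = derive_rng(seed, "balance_and_trim")
    keep: set[str] = set()
    for pop in basedef.populations:
        ids = [i for i in table.individuals if grouping[i] == pop]
        if len(ids) > cap:
            ids = list(rng.choice(ids, size=cap, replace=False))
        keep.update(ids)
    kept = [i for i in table.individuals if i in keep]
    return table.subset(kept)
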