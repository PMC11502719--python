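"""Synthetic baselines, seasonal samples and mixed catches with known truth.

Population allele frequencies are drawn from the Balding–Nichols F-model:
given an ancestral frequency :math:`p_l` and a per-population drift
parameter :math:`F_k`, population frequencies follow

.. math:: p_{kl} \\sim \\mathrm{Beta}\\bigl(p_l (1-F_k)/F_k,\\;
          (1-p_l)(1-F_k)/F_k\\bigr),

so that :math:`\\mathrm{Var}(p_{kl}) = F_k\\, p_l (1-p_l)`.  A designated
subset of "spawning-time" loci is instead near-fixed for alternative
alleles between two ecotype groups of populations (default contrast
0.95 / 0.05), mimicking panels whose strongest markers separate spring from
autumn spawners.  Genotypes are Hardy–Weinberg binomial draws; missing calls
are dropped independently per call.

All generators are deterministic under ``(config, seed)``; independent
random streams are derived from the master seed by hashing the operation
name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, BaselineDefinition, GenotypeTable, Locus, SNPPanel


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one named operation under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic baseline.

    Defaults mirror the analysed panel: 12 populations typed at 59
    informative loci of which 9 are strongly ecotype-diagnostic, 90
    individuals per population, drift parameters spanning 0.1–0.3, and a low
    (3%) per-call missing rate.
    """

    n_populations: int = 12
    n_loci: int = 59
    n_diagnostic: int = 9
    ancestral_freqs: np.ndarray | None = None
    fst: np.ndarray | float = 0.2
    sample_sizes: np.ndarray | int = 90
    missing_rate: float = 0.03
    seed: int = 0
    diagnostic_contrast: tuple[float, float] = (0.95, 0.05)
    #: ecotype (0/1) of each population; default splits the populations in half
    ecotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_diagnostic > self.n_loci:
            raise ValueError("n_diagnostic cannot exceed n_loci")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        K = self.n_populations
        self.fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (K,)).copy()
        if np.any(self.fst <= 0.0) or np.any(self.fst >= 1.0):
            raise ValueError("fst values must lie strictly in (0, 1)")
        self.sample_sizes = np.broadcast_to(
            np.asarray(self.sample_sizes, dtype=int), (K,)
        ).copy()
        if self.ancestral_freqs is not None:
            self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
            if self.ancestral_freqs.shape != (self.n_loci,):
                raise ValueError("ancestral_freqs must have length n_loci")
            if np.any(self.ancestral_freqs <= 0) or np.any(self.ancestral_freqs >= 1):
                raise ValueError("ancestral_freqs must lie in (0, 1)")
        if self.ecotypes is None:
            self.ecotypes = (np.arange(K) >= (K + 1) // 2).astype(int)
        else:
            self.ecotypes = np.asarray(self.ecotypes, dtype=int)
            if self.ecotypes.shape != (K,) or not set(np.unique(self.ecotypes)) <= {0, 1}:
                raise ValueError("ecotypes must be a 0/1 vector of length n_populations")

    @property
    def population_labels(self) -> list[str]:
        width = len(str(self.n_populations))
        return [f"pop{k + 1:0{width}d}" for k in range(self.n_populations)]

    def make_panel(self) -> SNPPanel:
        loci = []
        for j in range(self.n_loci):
            loci.append(
                Locus(
                    id=f"snp{j + 1:03d}",
                    chromosome=f"chr{j % 20 + 1}",
                    ref="A",
                    alt="G",
                    spawning_associated=j < self.n_diagnostic,
                )
            )
        return SNPPanel(loci)


@dataclass
class TruthRecord:
    """Ledger of simulation truth: per-individual origin (or admixture
    fraction) and, for mixtures, the true mixing proportions."""

    true_origin: dict[str, str] = field(default_factory=dict)
    true_pi: dict[str, float] | None = None
    true_q: dict[str, float] | None = None
    config: SimConfig | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, origin in self.true_origin.items():
            rows.append(
                {
                    "individual": ind,
                    "true_origin": origin,
                    "true_q": None if self.true_q is None else self.true_q.get(ind),
                }
            )
        return pd.DataFrame(rows)


def draw_population_freqs(config: SimConfig, seed: int | None = None) -> np.ndarray:
    """Draw the (K, L) matrix of per-population reference-allele frequencies.

    Non-diagnostic loci follow the Balding–Nichols model around ancestral
    frequencies; diagnostic loci get the fixed ecotype contrast.
    """
    rng = derive_rng(config.seed if seed is None else seed, "draw_population_freqs")
    K, L = config.n_populations, config.n_loci
    anc = config.ancestral_freqs
    if anc is None:
        anc = rng.uniform(0.1, 0.9, size=L)
    freqs = np.empty((K, L))
    for k in range(K):
        F = config.fst[k]
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        freqs[k] = rng.beta(a, b)
    # keep strictly inside (0, 1) for downstream likelihoods
    np.clip(freqs, 1e-6, 1 - 1e-6, out=freqs)
    hi, lo = config.diagnostic_contrast
    for j in range(config.n_diagnostic):
        freqs[:, j] = np.where(config.ecotypes == 0, hi, lo)
    return freqs


def fully_diagnostic_freqs(
    n_populations: int, n_loci_per_population: int = 5, high: float = 0.95, low: float = 0.05
) -> np.ndarray:
    """Frequency matrix where every population owns a private block of
    near-fixed loci — a baseline with essentially perfect identifiability."""
    L = n_populations * n_loci_per_population
    freqs = np.full((n_populations, L), low)
    for k in range(n_populations):
        freqs[k, k * n_loci_per_population : (k + 1) * n_loci_per_population] = high
    return freqs


def _apply_missing(calls: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        calls[rng.random(calls.shape) < rate] = MISSING


def _hwe_genotypes(freqs_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freqs_rows).astype(np.int8)


def simulate_baseline_genotypes(
    freqs: np.ndarray,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[GenotypeTable, BaselineDefinition, TruthRecord]:
    """Simulate a baseline: HWE genotypes for each population at its own
    frequencies, with independent per-call missingness."""
    rng = derive_rng(config.seed if seed is None else seed, "simulate_baseline_genotypes")
    K, L = freqs.shape
    labels = config.population_labels
    panel = config.make_panel()
    ids, rows, meta_rows, origin = [], [], [], {}
    for k in range(K):
        n_k = int(config.sample_sizes[k])
        g = _hwe_genotypes(np.broadcast_to(freqs[k], (n_k, L)), rng)
        _apply_missing(g, config.missing_rate, rng)
        for i in range(n_k):
            ind = f"{labels[k]}_i{i + 1:03d}"
            ids.append(ind)
            meta_rows.append({"sample_id": labels[k], "source": "baseline"})
            origin[ind] = labels[k]
        rows.append(g)
    calls = np.vstack(rows) if rows else np.empty((0, L), dtype=np.int8)
    table = GenotypeTable(ids, panel, calls, pd.DataFrame(meta_rows))
    basedef = BaselineDefinition({lab: lab for lab in labels}, labels)
    truth = TruthRecord(true_origin=origin, config=config, seed=config.seed if seed is None else seed)
    return table, basedef, truth


def simulate_mixture_sample(
    freqs: np.ndarray,
    proportions: Sequence[float],
    n: int,
    missing_rate: float = 0.03,
    seed: int = 0,
    config: SimConfig | None = None,
    coordinates: tuple[float, float] | None = None,
    sample_id: str = "mix",
) -> tuple[GenotypeTable, TruthRecord]:
    """Simulate one mixed-population catch of ``n`` individuals with origins
    drawn from ``proportions`` (multinomial) and HWE genotypes from the
    origin population's frequencies."""
    pi = np.asarray(proportions, dtype=float)
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("proportions must be non-negative and sum to 1")
    K, L = freqs.shape
    if pi.shape != (K,):
        raise ValueError("proportions length must match number of populations")
    rng = derive_rng(seed, "simulate_mixture_sample")
    if config is None:
        config = SimConfig(n_populations=K, n_loci=L, n_diagnostic=0, seed=seed)
    labels = config.population_labels
    origins = rng.choice(K, size=n, p=pi)
    g = _hwe_genotypes(freqs[origins], rng) if n else np.empty((0, L), dtype=np.int8)
    _apply_missing(g, missing_rate, rng)
    ids = [f"{sample_id}_i{i + 1:04d}" for i in range(n)]
    meta = pd.DataFrame({"sample_id": sample_id, "source": "mixture"}, index=range(n))
    if coordinates is not None and n:
        meta["latitude"] = coordinates[0]
        meta["longitude"] = coordinates[1]
    table = GenotypeTable(ids, config.make_panel(), g, meta)
    truth = TruthRecord(
        true_origin={ind: labels[k] for ind, k in zip(ids, origins)},
        true_pi={labels[k]: float(pi[k]) for k in range(K)},
        config=config,
        seed=seed,
    )
    return table, truth


def simulate_seasonal_sample(
    cluster_freqs: np.ndarray,
    n_pure_a: int,
    n_pure_b: int,
    n_admixed: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    sample_id: str = "seasonal",
) -> tuple[GenotypeTable, TruthRecord]:
    """Simulate a spawning-ground sample containing two ecotype clusters plus
    admixed individuals.

    Pure individuals have ancestry fraction ``q`` of exactly 1 (cluster A)
    or 0 (cluster B); admixed individuals draw ``q ~ Uniform(0.3, 0.7)`` so
    they fall below the 0.70 assignment threshold by construction.  Genotypes
    at each locus are binomial in the mixed frequency
    ``q * p_A + (1 - q) * p_B``.
    """
    if cluster_freqs.shape[0] != 2:
        raise ValueError("cluster_freqs must have exactly two rows")
    rng = derive_rng(seed, "simulate_seasonal_sample")
    L = cluster_freqs.shape[1]
    q = np.concatenate(
        [
            np.ones(n_pure_a),
            np.zeros(n_pure_b),
            rng.uniform(0.3, 0.7, size=n_admixed),
        ]
    )
    mix = q[:, None] * cluster_freqs[0] + (1 - q[:, None]) * cluster_freqs[1]
    g = _hwe_genotypes(mix, rng)
    _apply_missing(g, missing_rate, rng)
    n = len(q)
    ids = [f"{sample_id}_i{i + 1:04d}" for i in range(n)]
    cfg = SimConfig(n_populations=2, n_loci=L, n_diagnostic=0, seed=seed)
    meta = pd.DataFrame({"sample_id": sample_id, "source": "mixture"}, index=range(n))
    table = GenotypeTable(ids, cfg.make_panel(), g, meta)
    kind = (
        ["cluster_A"] * n_pure_a + ["cluster_B"] * n_pure_b + ["admixed"] * n_admixed
    )
    truth = TruthRecord(
        true_origin=dict(zip(ids, kind)),
        true_q={ind: float(v) for ind, v in zip(ids, q)},
        config=cfg,
        seed=seed,
    )
    return table, truth
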