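"""Shared fixtures, table builders, and independent oracles.

The oracles here deliberately re-derive quantities along a different
algebraic route than the package (ANOVA mean squares for theta, explicit
enumeration over latent origins for the mixture posterior) so they can serve
as independent cross-checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from gsikit.core import GenotypeTable, Locus, SNPPanel


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def make_panel(n_loci: int, sex_linked: set[int] | None = None, prefix: str = "snp") -> SNPPanel:
    sex_linked = sex_linked or set()
    return SNPPanel(
        [
            Locus(
                id=f"{prefix}{j + 1:03d}",
                chromosome=f"chr{j % 20 + 1}",
                ref="A",
                alt="G",
                sex_linked=(j in sex_linked),
            )
            for j in range(n_loci)
        ]
    )


def make_table(calls, panel=None, ids=None, meta=None) -> GenotypeTable:
    calls = np.asarray(calls, dtype=np.int8)
    if panel is None:
        panel = make_panel(calls.shape[1])
    if ids is None:
        ids = [f"ind{i + 1:03d}" for i in range(calls.shape[0])]
    return GenotypeTable(list(ids), panel, calls, meta)


def random_table(rng: np.random.Generator, n: int = 12, L: int = 8, missing: float = 0.15):
    calls = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    calls[rng.random(calls.shape) < missing] = -1
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i % 3}" for i in range(n)],
            "latitude": rng.uniform(50, 70, size=n).round(4),
            "longitude": rng.uniform(-10, 25, size=n).round(4),
            "date": ["2021-05-%02d" % (i % 28 + 1) for i in range(n)],
            "maturity": rng.integers(1, 9, size=n).astype(float),
            "source": ["baseline"] * n,
        }
    )
    return make_table(calls, meta=meta)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def anova_theta(dosage: np.ndarray, groups: np.ndarray) -> float:
    """Weir–Cockerham multi-locus theta via the ANOVA mean-squares route
    (MSP / MSI / MSG), an algebraically independent coding of the estimator.
    """
    num = den = 0.0
    labs = np.unique(groups)
    for l in range(dosage.shape[1]):
        col = dosage[:, l]
        data = []
        ok = True
        for g in labs:
            vals = col[(groups == g) & ~np.isnan(col)]
            if len(vals) == 0:
                ok = False
                break
            data.append(vals)
        if not ok:
            continue
        ns = np.array([len(v) for v in data], dtype=float)
        N = ns.sum()
        r = len(data)
        if N <= r:
            continue
        ps = np.array([v.mean() / 2 for v in data])
        pbar = (ns * ps).sum() / N
        ssg = sum(float((v * (2 - v) / 2).sum()) for v in data)
        ssi = sum(float((2 * (v / 2 - p) ** 2).sum()) for v, p in zip(data, ps))
        ssp = sum(2 * n * (p - pbar) ** 2 for n, p in zip(ns, ps))
        msg = ssg / N
        msi = ssi / (N - r)
        msp = ssp / (r - 1)
        nc = (N - (ns**2).sum() / N) / (r - 1)
        if nc <= 0:
            continue
        sigma_a = (msp - msi) / (2 * nc)
        sigma_b = (msi - msg) / 2
        sigma_w = msg
        num += sigma_a
        den += sigma_a + sigma_b + sigma_w
    return num / den if den else float("nan")


def enumeration_pi_posterior(logL: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Exact posterior mean of the mixing proportions by summing over every
    latent-origin configuration (Dirichlet-multinomial weights)."""
    n, K = logL.shape
    a0 = alpha.sum()
    num = np.zeros(K)
    den = 0.0
    for z in product(range(K), repeat=n):
        ll = sum(logL[i, zi] for i, zi in enumerate(z))
        counts = np.bincount(z, minlength=K)
        w = (
            math.lgamma(a0)
            - math.lgamma(a0 + n)
            + sum(math.lgamma(alpha[k] + counts[k]) - math.lgamma(alpha[k]) for k in range(K))
        )
        p = math.exp(ll + w)
        den += p
        num += p * (alpha + counts) / (a0 + n)
    return num / den


def gibbs_mc_se(draws: np.ndarray, n_batches: int = 40) -> np.ndarray:
    """Monte-Carlo standard error of the chain mean by batch means."""
    size = len(draws) // n_batches
    bm = draws[: n_batches * size].reshape(n_batches, size, -1).mean(axis=1)
    return bm.std(axis=0, ddof=1) / math.sqrt(n_batches)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
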