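"""Machine-readable transcriptions of the study's sample-inventory tables.

These fixtures carry metadata only (no genotypes): the baseline sampling
sites with their final population assignments and balanced sizes, the
mixed-catch sample inventory, and the seasonal (spring/autumn ecotype) split
of the candidate baseline samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("gsikit.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_baseline_sites() -> pd.DataFrame:
    """Baseline sampling sites: site metadata, initially genotyped counts
    (``n``), final population label (empty where the site was dropped as
    redundant) and balanced per-population size (``n_pop``, given once per
    population)."""
    return _load("table1_baseline_sites.tsv")


def load_mixture_inventory() -> pd.DataFrame:
    """Mixed-population catch samples by ecoregion, source and year."""
    return _load("table2_mixture_samples.tsv")


def load_seasonal_split() -> pd.DataFrame:
    """Ecotype split of the candidate baseline samples: counts of genetic
    autumn spawners, genetic spring spawners, and unassigned individuals."""
    return _load("table3_seasonal_split.tsv")


@dataclass(frozen=True)
class StudyTallies:
    baseline_individuals: int
    baseline_populations: int
    initially_genotyped: int
    mixture_individuals: int
    total_records: int


def study_tallies() -> StudyTallies:
    """Recompute the study-level sample tallies from the table fixtures."""
    sites = load_baseline_sites()
    mixtures = load_mixture_inventory()
    n_pop = sites["n_pop"].dropna().astype(int)
    pops = sites["population"].dropna()
    pops = pops[pops.astype(str).str.len() > 0]
    baseline_individuals = int(n_pop.sum())
    baseline_populations = int(pops.nunique())
    initially_genotyped = int(sites["n"].sum())
    mixture_individuals = int(mixtures["n"].sum())
    return StudyTallies(
        baseline_individuals=baseline_individuals,
        baseline_populations=baseline_populations,
        initially_genotyped=initially_genotyped,
        mixture_individuals=mixture_individuals,
        total_records=initially_genotyped + mixture_individuals,
    )
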