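"""Data model and tally operations for SNP-panel genotypes.

Genotypes are stored as reference-allele dosage: for each individual and
biallelic locus the call is the number of copies of the reference allele
(0, 1 or 2), with ``-1`` as the missing sentinel.  Half-called or otherwise
unparseable genotypes collapse to missing.  A locus flagged as sex-linked is
retained in files and tables but excluded from every statistic and
likelihood downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: metadata columns a genotype table may carry, in canonical order
META_COLUMNS = ("sample_id", "latitude", "longitude", "date", "maturity", "source")


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP of the panel."""

    id: str
    chromosome: str
    ref: str
    alt: str
    spawning_associated: bool = False
    sex_linked: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref and alt alleles must differ")


@dataclass
class SNPPanel:
    """Ordered collection of panel loci with unique ids."""

    loci: list[Locus]

    def __post_init__(self) -> None:
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids in panel: {dup}")
        self._index = {l.id: j for j, l in enumerate(self.loci)}

    @property
    def ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask over loci: True where the locus enters statistics
        (i.e. it is not sex-linked)."""
        return np.array([not l.sex_linked for l in self.loci], dtype=bool)

    @property
    def informative_ids(self) -> list[str]:
        return [l.id for l in self.loci if not l.sex_linked]

    def index_of(self, locus_id: str) -> int:
        return self._index[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"locus", "chromosome", "ref", "alt"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"panel file missing columns: {sorted(missing_cols)}")
        loci = []
        for _, row in df.iterrows():
            loci.append(
                Locus(
                    id=row["locus"],
                    chromosome=row["chromosome"],
                    ref=row["ref"],
                    alt=row["alt"],
                    spawning_associated=_parse_flag(row.get("spawning_associated", "0")),
                    sex_linked=_parse_flag(row.get("sex_linked", "0")),
                )
            )
        return cls(loci)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "locus": [l.id for l in self.loci],
                "chromosome": [l.chromosome for l in self.loci],
                "ref": [l.ref for l in self.loci],
                "alt": [l.alt for l in self.loci],
                "spawning_associated": [int(l.spawning_associated) for l in self.loci],
                "sex_linked": [int(l.sex_linked) for l in self.loci],
            }
        ).to_csv(path, sep="\t", index=False)


def _parse_flag(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "t"}


@dataclass
class GenotypeTable:
    """Individuals x loci dosage matrix plus per-individual metadata.

    ``calls[i, j]`` is the reference-allele dosage of individual ``i`` at
    panel locus ``j`` (``-1`` = missing).  ``meta`` is indexed by individual
    id and restricted to :data:`META_COLUMNS`.
    """

    individuals: list[str]
    panel: SNPPanel
    calls: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            dup = sorted({i for i in self.individuals if self.individuals.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        expected = (len(self.individuals), self.panel.n_loci)
        if self.calls.shape != expected:
            raise ValueError(f"calls shape {self.calls.shape} != {expected}")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.individuals, name="id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = pd.Index(self.individuals, name="id")
        extra = set(self.meta.columns) - set(META_COLUMNS)
        if extra:
            raise ValueError(f"unknown metadata columns: {sorted(extra)}")
        if "sample_id" not in self.meta.columns:
            self.meta["sample_id"] = list(self.individuals)
        for col in ("latitude", "longitude", "maturity"):
            if col in self.meta.columns:
                self.meta[col] = pd.to_numeric(self.meta[col], errors="raise")
        if "latitude" in self.meta.columns:
            lat = self.meta["latitude"].dropna()
            if ((lat < -90) | (lat > 90)).any():
                raise ValueError("latitude outside [-90, 90]")
        if "longitude" in self.meta.columns:
            lon = self.meta["longitude"].dropna()
            if ((lon < -180) | (lon > 180)).any():
                raise ValueError("longitude outside [-180, 180]")

    # -- convenience -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def dosage(self, informative_only: bool = True) -> np.ndarray:
        """Float dosage matrix with ``NaN`` at missing calls."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        if informative_only:
            x = x[:, self.panel.informative]
        return x

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            rows = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"unknown individual: {e.args[0]}") from None
        return GenotypeTable(
            individuals=list(ids),
            panel=self.panel,
            calls=self.calls[rows],
            meta=self.meta.iloc[rows],
        )

    def equals(self, other: "GenotypeTable") -> bool:
        if self.individuals != other.individuals:
            return False
        if self.panel.ids != other.panel.ids:
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        a, b = self.meta, other.meta
        cols = sorted(set(a.columns) | set(b.columns))
        for col in cols:
            va = a[col] if col in a.columns else pd.Series(np.nan, index=a.index)
            vb = b[col] if col in b.columns else pd.Series(np.nan, index=b.index)
            if not _series_equal(va, vb):
                return False
        return True


def _series_equal(a: pd.Series, b: pd.Series) -> bool:
    na_a, na_b = a.isna().to_numpy(), b.isna().to_numpy()
    if not np.array_equal(na_a, na_b):
        return False
    va, vb = a[~na_a].to_numpy(), b[~na_b].to_numpy()
    if va.dtype.kind == "f" or vb.dtype.kind == "f":
        return np.allclose(va.astype(float), vb.astype(float), rtol=0, atol=1e-12)
    return bool((va.astype(str) == vb.astype(str)).all())


@dataclass
class BaselineDefinition:
    """Mapping of sampling sites (``sample_id``) to baseline populations."""

    site_to_population: dict[str, str]
    populations: list[str]

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population labels")
        unknown = set(self.site_to_population.values()) - set(self.populations)
        if unknown:
            raise ValueError(f"sites map to undeclared populations: {sorted(unknown)}")

    @classmethod
    def from_tsv(cls, path) -> "BaselineDefinition":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if not {"sample_id", "population"} <= set(df.columns):
            raise ValueError("baseline definition needs columns sample_id, population")
        mapping = dict(zip(df["sample_id"], df["population"]))
        if len(mapping) != len(df):
            raise ValueError("duplicate sample_id in baseline definition")
        pops = list(dict.fromkeys(df["population"]))
        return cls(mapping, pops)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.site_to_population), "population": list(self.site_to_population.values())}
        ).to_csv(path, sep="\t", index=False)


def population_grouping(table: GenotypeTable, basedef: BaselineDefinition) -> dict[str, str]:
    """Map every individual of ``table`` to its baseline population via its
    ``sample_id``; raises on unmapped sites."""
    sample_ids = table.meta["sample_id"]
    unmapped = sorted(set(sample_ids) - set(basedef.site_to_population))
    if unmapped:
        raise ValueError(f"sample_id(s) not in baseline definition: {unmapped}")
    return {ind: basedef.site_to_population[sid] for ind, sid in sample_ids.items()}


# ---------------------------------------------------------------------------
# missing-data operations
# ---------------------------------------------------------------------------


def individual_missing_rate(table: GenotypeTable, individual: str) -> float:
    """Fraction of missing calls at non-sex-linked panel loci."""
    if individual not in table.individuals:
        raise KeyError(f"unknown individual: {individual}")
    i = table.individuals.index(individual)
    mask = table.panel.informative
    loci = int(mask.sum())
    if loci == 0:
        raise ValueError("panel has no informative loci")
    return float((table.calls[i, mask] == MISSING).sum()) / loci


@dataclass(frozen=True)
class RemovalRecord:
    individual: str
    missing_rate: float


def filter_by_missing(
    table: GenotypeTable, threshold: float = 0.25
) -> tuple[GenotypeTable, list[RemovalRecord]]:
    """Drop individuals whose missing rate exceeds ``threshold``.

    The comparison is strict (``rate > threshold`` removes): individuals that
    sit exactly at the acceptance ceiling are retained.  Returns the filtered
    table and a removal log; the input table is left untouched.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    mask = table.panel.informative
    n_loci = int(mask.sum())
    rates = (table.calls[:, mask] == MISSING).sum(axis=1) / n_loci
    keep = rates <= threshold
    log = [
        RemovalRecord(ind, float(r))
        for ind, r, k in zip(table.individuals, rates, keep)
        if not k
    ]
    kept_ids = [ind for ind, k in zip(table.individuals, keep) if k]
    return table.subset(kept_ids), log


# ---------------------------------------------------------------------------
# allele counts and tallies
# ---------------------------------------------------------------------------


@dataclass
class GroupAlleleCounts:
    """Per-group, per-locus reference-allele and total allele counts.

    Missing calls contribute zero alleles, so ``n_total`` equals twice the
    number of non-missing calls.  Counts cover *all* panel loci; consumers
    that must ignore sex-linked loci apply ``panel.informative`` themselves.
    """

    groups: list[str]
    locus_ids: list[str]
    n_ref: np.ndarray  # (G, L)
    n_total: np.ndarray  # (G, L)


def allele_counts_by_group(
    table: GenotypeTable, grouping: Mapping[str, str]
) -> GroupAlleleCounts:
    absent = sorted(set(grouping) - set(table.individuals))
    if absent:
        raise ValueError(f"grouped individuals absent from table: {absent}")
    groups = list(dict.fromkeys(grouping[i] for i in table.individuals if i in grouping))
    gi = {g: k for k, g in enumerate(groups)}
    n_ref = np.zeros((len(groups), table.panel.n_loci))
    n_total = np.zeros_like(n_ref)
    for i, ind in enumerate(table.individuals):
        if ind not in grouping:
            continue
        k = gi[grouping[ind]]
        row = table.calls[i]
        ok = row != MISSING
        n_ref[k, ok] += row[ok]
        n_total[k, ok] += 2
    return GroupAlleleCounts(groups, table.panel.ids, n_ref, n_total)


@dataclass
class BaselineTally:
    per_population: dict[str, int]
    n_populations: int
    total: int


def tally_baseline(table: GenotypeTable, basedef: BaselineDefinition) -> BaselineTally:
    """Count individuals per baseline population (populations with zero
    individuals are not counted)."""
    grouping = population_grouping(table, basedef)
    counts: dict[str, int] = {}
    for pop in basedef.populations:
        n = sum(1 for p in grouping.values() if p == pop)
        if n:
            counts[pop] = n
    return BaselineTally(counts, len(counts), sum(counts.values()))
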