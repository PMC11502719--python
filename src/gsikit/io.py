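"""Reading and writing genotype tables.

The native interchange format is a wide CSV: one row per individual, a
leading ``id`` column, optional metadata columns, and two allele columns per
locus named ``<locus>.1`` / ``<locus>.2`` holding single-character allele
codes.  An empty field is a missing allele; a genotype with any missing or
unrecognised allele collapses to missing.  Biallelic VCF ingestion is
available when cyvcf2 is installed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import META_COLUMNS, MISSING, GenotypeTable, SNPPanel


def read_genotype_table(path, panel: SNPPanel, format: str = "wide-csv") -> GenotypeTable:
    """Read a genotype table, coding calls as reference-allele dosage.

    Parameters
    ----------
    path : file path
    panel : SNPPanel
        Loci found in the file must all belong to this panel; panel loci
        absent from the file become all-missing columns.
    format : {"wide-csv", "vcf"}
    """
    if format == "wide-csv":
        return _read_wide_csv(path, panel)
    if format == "vcf":
        return _read_vcf(path, panel)
    raise ValueError(f"unknown format: {format!r}")


def _read_wide_csv(path, panel: SNPPanel) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("wide-csv file must have an 'id' column")
    ids = [s.strip() for s in df["id"].tolist()]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual id(s) in file: {dup}")

    allele_cols = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    file_loci = {c[:-2] for c in allele_cols}
    unknown = sorted(l for l in file_loci if l not in panel)
    if unknown:
        raise ValueError(f"locus in file absent from panel: {unknown}")

    n = len(ids)
    calls = np.full((n, panel.n_loci), MISSING, dtype=np.int8)
    for j, locus in enumerate(panel.loci):
        c1, c2 = f"{locus.id}.1", f"{locus.id}.2"
        if c1 not in df.columns or c2 not in df.columns:
            continue  # locus not genotyped in this file: all missing
        a1 = df[c1].str.strip()
        a2 = df[c2].str.strip()
        valid = a1.isin([locus.ref, locus.alt]) & a2.isin([locus.ref, locus.alt])
        dosage = (a1 == locus.ref).astype(int) + (a2 == locus.ref).astype(int)
        calls[:, j] = np.where(valid, dosage, MISSING)

    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy() if meta_cols else None
    if meta is not None:
        for col in meta.columns:
            meta[col] = meta[col].replace("", np.nan)
    return GenotypeTable(individuals=ids, panel=panel, calls=calls, meta=meta)


def write_genotype_table(table: GenotypeTable, path) -> str:
    """Write a table as wide CSV.  Missing calls serialise as empty allele
    fields; ``read_genotype_table(write_genotype_table(t))`` reproduces ``t``.
    """
    out: dict[str, list] = {"id": list(table.individuals)}
    for col in META_COLUMNS:
        if col in table.meta.columns:
            out[col] = [_cell(v) for v in table.meta[col]]
    for j, locus in enumerate(table.panel.loci):
        col = table.calls[:, j]
        a1, a2 = [], []
        for g in col:
            if g == MISSING:
                a1.append("")
                a2.append("")
            else:
                a1.append(locus.ref if g >= 1 else locus.alt)
                a2.append(locus.ref if g == 2 else locus.alt)
        out[f"{locus.id}.1"] = a1
        out[f"{locus.id}.2"] = a2
    pd.DataFrame(out).to_csv(path, index=False)
    return str(path)


def _cell(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, float) and v == int(v):
        # integral floats (e.g. maturity) round-trip without a trailing .0
        return repr(v)
    return str(v)


def _read_vcf(path, panel: SNPPanel) -> GenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "VCF ingestion requires cyvcf2 (install the 'vcf' extra)"
        ) from e

    reader = VCF(str(path))
    ids = list(reader.samples)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in VCF")
    calls = np.full((len(ids), panel.n_loci), MISSING, dtype=np.int8)
    for var in reader:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic VCF record at {var.CHROM}:{var.POS}")
        locus_id = var.ID
        if locus_id is None or locus_id not in panel:
            raise ValueError(f"locus in file absent from panel: {locus_id}")
        j = panel.index_of(locus_id)
        locus = panel.loci[j]
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        ref_dosage = np.select([gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING)
        if var.REF == locus.ref and var.ALT[0] == locus.alt:
            calls[:, j] = ref_dosage
        elif var.REF == locus.alt and var.ALT[0] == locus.ref:
            flipped = np.where(ref_dosage == MISSING, MISSING, 2 - ref_dosage)
            calls[:, j] = flipped
        else:
            raise ValueError(f"alleles at {locus_id} do not match the panel")
    return GenotypeTable(individuals=ids, panel=panel, calls=calls, meta=None)
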