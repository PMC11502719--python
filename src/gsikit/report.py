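"""Spatial composition summaries of assigned mixed-population catches.

Assigned individuals are aggregated into statistical rectangles (1 degree of
longitude by 0.5 degree of latitude, the ICES reporting grid) and into
strata north/south of a management boundary latitude (default 62 N).  A
simple least-squares diagnostic quantifies how assignment confidence decays
with the number of missing panel loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SpatialComposition:
    rectangles: pd.DataFrame  # lon_bin, lat_bin, n, proportion_<pop>...
    n_excluded: int  # individuals without coordinates
    populations: list[str]


def grid_composition(assignments: pd.DataFrame) -> SpatialComposition:
    """Per-rectangle population proportions.

    ``assignments`` needs columns ``map_population``, ``latitude`` and
    ``longitude``.  Rectangle bins are half-open on their upper edges:
    ``lon_bin = floor(lon)``, ``lat_bin = floor(lat / 0.5) * 0.5``.
    Individuals without coordinates are excluded and counted.
    """
    required = {"map_population", "latitude", "longitude"}
    missing_cols = required - set(assignments.columns)
    if missing_cols:
        raise ValueError(f"assignments missing columns: {sorted(missing_cols)}")
    df = assignments.copy()
    located = df["latitude"].notna() & df["longitude"].notna()
    n_excluded = int((~located).sum())
    df = df[located]
    pops = sorted(df["map_population"].unique())
    df = df.assign(
        lon_bin=np.floor(df["longitude"].astype(float)),
        lat_bin=np.floor(df["latitude"].astype(float) / 0.5) * 0.5,
    )
    rows = []
    for (lon_bin, lat_bin), grp in df.groupby(["lon_bin", "lat_bin"], sort=True):
        row = {"lon_bin": lon_bin, "lat_bin": lat_bin, "n": len(grp)}
        counts = grp["map_population"].value_counts()
        for p in pops:
            row[f"proportion_{p}"] = counts.get(p, 0) / len(grp)
        rows.append(row)
    return SpatialComposition(pd.DataFrame(rows), n_excluded, pops)


def boundary_summary(
    assignments: pd.DataFrame,
    boundary_lat: float = 62.0,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-stratum mean and maximum sample proportions per population.

    Proportions are computed per catch sample first; each sample falls in
    the northern stratum when its representative latitude is >= the
    boundary.  The stratum mean for a population is taken over the samples
    in which the population occurs (null observations are not included,
    matching how mixed-catch compositions are usually reported); the maximum
    is over the same samples.
    """
    required = {"map_population", "latitude", sample_col}
    missing_cols = required - set(assignments.columns)
    if missing_cols:
        raise ValueError(f"assignments missing columns: {sorted(missing_cols)}")
    df = assignments.copy()
    sample_lat = df.groupby(sample_col)["latitude"].first()
    pops = sorted(df["map_population"].unique())
    sample_props = (
        df.groupby(sample_col)["map_population"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=pops, fill_value=0.0)
    )
    strata = np.where(sample_lat.loc[sample_props.index] >= boundary_lat, "north", "south")
    rows = []
    for stratum in ("north", "south"):
        sub = sample_props[strata == stratum]
        for p in pops:
            present = sub[p][sub[p] > 0]
            rows.append(
                {
                    "stratum": stratum,
                    "population": p,
                    "n_samples": int(len(sub)),
                    "n_samples_present": int(len(present)),
                    "mean_pct": 100.0 * float(present.mean()) if len(present) else np.nan,
                    "max_pct": 100.0 * float(present.max()) if len(present) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def missingness_posterior_slope(
    posteriors, n_missing
) -> float:
    """Ordinary least-squares slope of MAP assignment posterior on the
    number of missing panel loci."""
    y = np.asarray(posteriors, dtype=float)
    x = np.asarray(n_missing, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two or more (posterior, n_missing) pairs")
    if np.ptp(x) == 0:
        raise ValueError("missingness values are constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope)
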