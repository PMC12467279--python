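"""Presence-record curation: cleaning, spatial thinning and decade bins.

Occurrence sets hold georeferenced presence records labelled ``native`` or
``invasive``, with an optional observation year used to stratify the invaded
range into decades.  Cleaning removes the classic GBIF failure modes
(zero/invalid coordinates, exact duplicates, points off the climate raster's
land mask); thinning enforces a minimum pairwise great-circle distance to
reduce spatial autocorrelation and sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import haversine_km

__all__ = [
    "OccurrenceSet",
    "RANGE_LABELS",
    "clean",
    "thin",
    "morans_i",
    "stratify_by_decade",
    "DECADE_BINS",
]

RANGE_LABELS = ("native", "invasive")

#: Inclusive year bins for temporal stratification of the invaded range.
DECADE_BINS = {"2000s": (2000, 2009), "2010s": (2010, 2019), "2020s": (2020, 2029)}

_COLUMNS = ["id", "lon", "lat", "range", "year", "source"]


@dataclass
class OccurrenceSet:
    """An ordered collection of presence records with unique ids.

    ``data`` columns: id, lon, lat, range, year (nullable Int64), source.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "id" not in df.columns:
            df.insert(0, "id", [f"r{i}" for i in range(len(df))])
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[_COLUMNS].reset_index(drop=True)
        df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
        df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
        df["year"] = pd.to_numeric(df["year"], errors="coerce").astype("Int64")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate record ids: {dupes[:5]}")
        bad = set(df["range"].dropna()) - set(RANGE_LABELS)
        if bad:
            raise ValueError(f"range labels must be one of {RANGE_LABELS}, got {sorted(bad)}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.data.loc[np.asarray(mask, bool)].reset_index(drop=True),
                             provenance=self.provenance)

    def by_range(self, label: str) -> "OccurrenceSet":
        if label not in RANGE_LABELS:
            raise ValueError(f"unknown range label {label!r}")
        return self.subset((self.data["range"] == label).to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        return cls(df, provenance=provenance or str(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def clean(records: OccurrenceSet, stack) -> tuple[OccurrenceSet, dict[str, int]]:
    """Drop invalid, duplicated and off-raster records.

    Removal rules, applied in order and counted separately:

    - ``zero_coordinates``: (lon, lat) == (0, 0), the classic missing-data sentinel;
    - ``invalid_coordinates``: non-finite or out of [-180, 180] x [-90, 90];
    - ``duplicate``: exact coordinate duplicate (after rounding to 6 decimals,
      GBIF-precision noise) within the same range label — first kept;
    - ``outside_extent``: off the raster bounding box;
    - ``nodata_cell``: on a nodata (e.g. ocean) cell of the stack.

    Returns the cleaned set and the per-rule removal counts.
    """
    if len(records) == 0:
        raise ValueError("cannot clean an empty occurrence set")
    df = records.data
    counts: dict[str, int] = {}
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)

    zero = (lon == 0.0) & (lat == 0.0)
    counts["zero_coordinates"] = int(zero.sum())
    invalid = (~np.isfinite(lon) | ~np.isfinite(lat)
               | (np.abs(lon) > 180.0) | (np.abs(lat) > 90.0)) & ~zero
    counts["invalid_coordinates"] = int(invalid.sum())
    keep = ~(zero | invalid)

    sub = df.loc[keep].copy()
    key = pd.DataFrame({
        "lon": sub["lon"].round(6), "lat": sub["lat"].round(6), "range": sub["range"],
    })
    dup = key.duplicated(keep="first").to_numpy()
    counts["duplicate"] = int(dup.sum())
    sub = sub.loc[~dup]

    t = stack.transform
    lon = sub["lon"].to_numpy(dtype=float)
    lat = sub["lat"].to_numpy(dtype=float)
    inside = ((lon >= t.lon_min) & (lon <= t.lon_max)
              & (lat >= t.lat_min) & (lat <= t.lat_max))
    counts["outside_extent"] = int((~inside).sum())
    sub = sub.loc[inside]

    row, col = t.index_of(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    on_nodata = stack.nodata_mask[row, col]
    counts["nodata_cell"] = int(on_nodata.sum())
    sub = sub.loc[~on_nodata]

    return OccurrenceSet(sub.reset_index(drop=True), provenance=records.provenance), counts


def _greedy_thin_indices(lon: np.ndarray, lat: np.ndarray, min_km: float,
                         order: np.ndarray) -> np.ndarray:
    """Greedy pass over ``order``: keep a point iff >= min_km from all kept."""
    kept: list[int] = []
    kept_lon: list[float] = []
    kept_lat: list[float] = []
    for i in order:
        if kept:
            d = haversine_km(lon[i], lat[i], np.array(kept_lon), np.array(kept_lat))
            if float(np.min(d)) < min_km:
                continue
        kept.append(int(i))
        kept_lon.append(lon[i])
        kept_lat.append(lat[i])
    return np.array(sorted(kept), dtype=int)


def thin(records: OccurrenceSet, min_km: float = 10.0, seed: int = 0) -> OccurrenceSet:
    """Greedy random spatial thinning to a minimum pairwise distance.

    Each range label is thinned independently: records are shuffled with the
    seeded generator, then kept iff at least ``min_km`` (haversine) from every
    already-kept record of the same range.  Deterministic given ``seed``;
    repeated runs with different seeds reproduce the usual robustness check of
    randomized thinning.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    rng = np.random.default_rng(seed)
    keep_mask = np.zeros(len(records), dtype=bool)
    df = records.data
    for label in RANGE_LABELS:
        idx = np.nonzero((df["range"] == label).to_numpy())[0]
        if idx.size == 0:
            continue
        order = idx[rng.permutation(idx.size)]
        lon = df["lon"].to_numpy(dtype=float)
        lat = df["lat"].to_numpy(dtype=float)
        keep_mask[_greedy_thin_indices(lon, lat, min_km, order)] = True
    return records.subset(keep_mask)


def morans_i(records: OccurrenceSet, values, neighbor_km: float = 10.0) -> float:
    """Global Moran's I with binary distance-band weights.

    Neighbors are pairs closer than ``neighbor_km`` (haversine); the statistic
    is I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Provided as a spatial-autocorrelation diagnostic alongside thinning.
    """
    values = np.asarray(values, dtype=float)
    n = len(records)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 records")
    if values.shape != (n,):
        raise ValueError("values must align with records")
    dev = values - values.mean()
    denom = float(np.sum(dev**2))
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for constant values (zero variance)")
    lon = records.data["lon"].to_numpy(dtype=float)
    lat = records.data["lat"].to_numpy(dtype=float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    w = (d < neighbor_km).astype(float)
    np.fill_diagonal(w, 0.0)
    W = float(w.sum())
    if W == 0.0:
        raise ValueError(f"no neighbor pairs within {neighbor_km} km")
    num = float(dev @ w @ dev)
    return (n / W) * num / denom


def stratify_by_decade(records: OccurrenceSet) -> dict[str, OccurrenceSet]:
    """Partition records into 2000s / 2010s / 2020s buckets by year.

    Bins are inclusive: 2000s = [2000, 2009] etc.  Records with a missing
    year or a year outside every bin land in ``"unassigned"`` — never silently
    dropped; the buckets partition the input exactly.
    """
    df = records.data
    year = df["year"]
    assigned = np.zeros(len(df), dtype=bool)
    out: dict[str, OccurrenceSet] = {}
    for name, (lo, hi) in DECADE_BINS.items():
        mask = (year.notna() & (year >= lo) & (year <= hi)).to_numpy()
        out[name] = records.subset(mask)
        assigned |= mask
    out["unassigned"] = records.subset(~assigned)
    return out
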