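"""Gridded climate stacks: containers, text I/O, point extraction and
bioclimatic variable selection.

A :class:`ClimateStack` holds co-registered lon/lat layers (WorldClim-style
``Bio1`` .. ``Bio19`` or any subset) sharing one nodata mask.  Variable
selection follows the common two-step protocol: pairwise Pearson pruning at a
|r| threshold, then an expert (config-driven) pick of 1-2 variables per
thematic group.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridTransform",
    "ClimateStack",
    "EnvMatrix",
    "extract",
    "background_sample",
    "correlation_prune",
    "group_select",
    "BIO_ORDER",
    "DEFAULT_GROUPS",
    "DEFAULT_SELECTION",
    "OutsideExtentError",
]

#: Canonical ordering of the 19 bioclimatic variables; used as tie-break rank.
BIO_ORDER = [f"Bio{i}" for i in range(1, 20)]

#: Thematic variable groups: annual means, extremes, and seasonality.
DEFAULT_GROUPS = {
    "temperature": ["Bio1", "Bio5", "Bio6", "Bio8", "Bio9", "Bio10", "Bio11", "Bio2", "Bio7"],
    "precipitation": ["Bio12", "Bio13", "Bio14", "Bio16", "Bio17", "Bio18", "Bio19"],
    "seasonal": ["Bio3", "Bio4", "Bio15"],
}

#: Default final variable set: annual mean temperature, temperature
#: seasonality, min temperature of the coldest month, annual precipitation,
#: precipitation of the driest month, precipitation seasonality.
DEFAULT_SELECTION = ["Bio1", "Bio4", "Bio6", "Bio12", "Bio14", "Bio15"]


class OutsideExtentError(ValueError):
    """A coordinate falls outside the raster extent."""


def _bio_rank(name: str) -> tuple[int, str]:
    try:
        return (BIO_ORDER.index(name), name)
    except ValueError:
        return (len(BIO_ORDER), name)


@dataclass(frozen=True)
class GridTransform:
    """Affine cell <-> lon/lat mapping for a north-up rectilinear grid.

    Row 0 is the northernmost row; cell (0, 0) spans
    ``[lon_min, lon_min + dlon] x [lat_max - dlat, lat_max]``.
    """

    lon_min: float
    lat_max: float
    dlon: float
    dlat: float
    nrows: int
    ncols: int

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.dlon

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.nrows * self.dlat

    def cell_center(self, row, col):
        """Lon/lat of the center of cell(s) (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + (col + 0.5) * self.dlon
        lat = self.lat_max - (row + 0.5) * self.dlat
        return lon, lat

    def index_of(self, lon, lat):
        """(row, col) of the cell containing each lon/lat point.

        Points exactly on the outer boundary snap to the nearest cell inside;
        points beyond the extent raise :class:`OutsideExtentError`.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        eps = 1e-9
        bad = (
            (lon < self.lon_min - eps)
            | (lon > self.lon_max + eps)
            | (lat < self.lat_min - eps)
            | (lat > self.lat_max + eps)
        )
        if np.any(bad):
            i = int(np.argmax(bad))
            raise OutsideExtentError(
                f"point (lon={lon[i]:.6f}, lat={lat[i]:.6f}) lies outside the raster "
                f"extent [{self.lon_min}, {self.lon_max}] x [{self.lat_min}, {self.lat_max}]"
            )
        col = np.clip(np.floor((lon - self.lon_min) / self.dlon).astype(int), 0, self.ncols - 1)
        row = np.clip(np.floor((self.lat_max - lat) / self.dlat).astype(int), 0, self.nrows - 1)
        return row, col


@dataclass
class ClimateStack:
    """Named, co-registered 2-D climate layers sharing one nodata mask.

    ``data`` has shape (n_layers, nrows, ncols); ``nodata_mask`` is True on
    cells with no valid data in any layer (e.g. ocean).
    """

    names: list[str]
    data: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must have shape (n_layers, nrows, ncols)")
        shape = (self.transform.nrows, self.transform.ncols)
        if self.data.shape[1:] != shape or self.nodata_mask.shape != shape:
            raise ValueError("layers and mask must match the transform's grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    # ---- text serialization: one ASCII grid per layer + JSON sidecar ----

    def to_dir(self, path: str | Path) -> None:
        """Write the stack as ESRI-style ASCII grids plus ``stack.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        t = self.transform
        nodata = -9999.0
        for name, layer in zip(self.names, self.data):
            out = np.where(self.nodata_mask, nodata, layer)
            header = [
                f"ncols {t.ncols}",
                f"nrows {t.nrows}",
                f"xllcorner {float(t.lon_min):.17g}",
                f"yllcorner {float(t.lat_min):.17g}",
                f"dx {float(t.dlon):.17g}",
                f"dy {float(t.dlat):.17g}",
                f"NODATA_value {nodata:.17g}",
            ]
            body = "\n".join(" ".join(f"{float(v):.17g}" for v in row) for row in out)
            (path / f"{name}.asc").write_text("\n".join(header) + "\n" + body + "\n")
        (path / "stack.json").write_text(json.dumps({"layers": self.names}, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClimateStack":
        path = Path(path)
        names = json.loads((path / "stack.json").read_text())["layers"]
        layers, transform, mask = [], None, None
        for name in names:
            header: dict[str, float] = {}
            lines = (path / f"{name}.asc").read_text().splitlines()
            n_header = 0
            for line in lines:
                m = re.match(r"^([A-Za-z_]+)\s+(\S+)$", line.strip())
                if m is None:
                    break
                header[m.group(1).lower()] = float(m.group(2))
                n_header += 1
            grid = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
            dlon = header.get("dx", header.get("cellsize"))
            dlat = header.get("dy", header.get("cellsize"))
            nrows, ncols = int(header["nrows"]), int(header["ncols"])
            t = GridTransform(
                lon_min=header["xllcorner"],
                lat_max=header["yllcorner"] + nrows * dlat,
                dlon=dlon,
                dlat=dlat,
                nrows=nrows,
                ncols=ncols,
            )
            if transform is None:
                transform = t
            elif t != transform:
                raise ValueError(f"layer {name} is not co-registered with the stack")
            layer_mask = grid == header.get("nodata_value", -9999.0)
            mask = layer_mask if mask is None else (mask | layer_mask)
            layers.append(grid)
        return cls(names=names, data=np.stack(layers), transform=transform, nodata_mask=mask)


@dataclass
class EnvMatrix:
    """Rows of climate values for occurrence points or background cells.

    ``data`` columns are climate variables; ``ids`` carries row provenance
    (record ids or ``cell:row,col`` strings); ``range_labels`` tags rows with
    native / invasive where applicable.
    """

    data: pd.DataFrame
    ids: np.ndarray
    range_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        if len(self.ids) != len(self.data):
            raise ValueError("ids must align with data rows")
        if self.range_labels is not None:
            self.range_labels = np.asarray(self.range_labels, dtype=object)
            if len(self.range_labels) != len(self.data):
                raise ValueError("range_labels must align with data rows")
        if self.data.to_numpy(dtype=float, copy=False).size and not np.all(
            np.isfinite(self.data.to_numpy(dtype=float))
        ):
            raise ValueError("EnvMatrix rows must be free of nodata/non-finite values")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def select(self, variables: list[str]) -> "EnvMatrix":
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise KeyError(f"variables not present: {missing}")
        return EnvMatrix(self.data[variables].copy(), self.ids.copy(),
                         None if self.range_labels is None else self.range_labels.copy())

    def subset(self, row_mask: np.ndarray) -> "EnvMatrix":
        row_mask = np.asarray(row_mask, dtype=bool)
        return EnvMatrix(
            self.data.loc[row_mask].reset_index(drop=True),
            self.ids[row_mask],
            None if self.range_labels is None else self.range_labels[row_mask],
        )


def extract(stack: ClimateStack, records) -> EnvMatrix:
    """Climate values of the cell containing each occurrence record.

    Rows align with record order; a record outside the raster extent raises
    :class:`OutsideExtentError`.
    """
    df = records.data
    row, col = stack.transform.index_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    values = stack.data[:, row, col].T  # (n_records, n_layers)
    data = pd.DataFrame(values, columns=stack.names)
    return EnvMatrix(data, ids=df["id"].to_numpy(dtype=object),
                     range_labels=df["range"].to_numpy(dtype=object))


def background_sample(
    stack: ClimateStack,
    region_mask: np.ndarray,
    max_cells: int = 10_000,
    seed: int = 0,
) -> EnvMatrix:
    """All valid (non-nodata) cells of a region, subsampled to ``max_cells``.

    Subsampling is uniform without replacement and deterministic given
    ``seed``.  The returned row ids are ``cell:<row>,<col>`` strings.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    valid = region_mask & ~stack.nodata_mask
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise ValueError("region contains no valid (non-nodata) cells")
    if rows.size > max_cells:
        rng = np.random.default_rng(seed)
        keep = rng.choice(rows.size, size=max_cells, replace=False)
        keep.sort()
        rows, cols = rows[keep], cols[keep]
    values = stack.data[:, rows, cols].T
    ids = np.array([f"cell:{r},{c}" for r, c in zip(rows, cols)], dtype=object)
    return EnvMatrix(pd.DataFrame(values, columns=stack.names), ids=ids)


def correlation_prune(
    env: EnvMatrix, threshold: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop variables until no pair has |Pearson r| > threshold.

    At each step the variable with the highest mean absolute correlation to
    the remaining variables (among those involved in an offending pair) is
    removed; ties keep the lower-numbered Bio variable.  Returns the surviving
    names and the full correlation matrix of the input.
    """
    if len(env.variables) < 2:
        raise ValueError("correlation pruning needs at least 2 variables")
    if len(env.data) < 3:
        raise ValueError("correlation pruning needs at least 3 rows")
    stds = env.data.std(ddof=1)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant variables have undefined correlation: {constant}")
    corr = env.data.corr(method="pearson")
    survivors = list(env.variables)
    while True:
        sub = corr.loc[survivors, survivors].abs()
        np.fill_diagonal(sub.values, 0.0)
        offenders = sorted({v for v in survivors if (sub.loc[v] > threshold).any()})
        if not offenders:
            break
        # mean |r| to all other remaining variables; drop the worst offender
        mean_abs = {v: sub.loc[v].sum() / (len(survivors) - 1) for v in offenders}
        # ties keep the earlier Bio number, i.e. remove the later-ranked one
        drop = max(offenders, key=lambda v: (round(mean_abs[v], 12), _bio_rank(v)))
        survivors.remove(drop)
    survivors = sorted(survivors, key=_bio_rank)
    return survivors, corr


def group_select(
    survivors: list[str],
    groups: dict[str, list[str]] | None = None,
    selection: list[str] | None = None,
    per_group: tuple[int, int] = (1, 2),
) -> list[str]:
    """Config-driven pick of 1-2 variables per thematic group.

    The final list is expert judgment, not an algorithm: ``selection``
    defaults to the standard six (Bio1, Bio4, Bio6, Bio12, Bio14, Bio15).
    Every selected variable must have survived pruning and belong to a group;
    each group must contribute between ``per_group[0]`` and ``per_group[1]``
    picks.
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    selection = DEFAULT_SELECTION if selection is None else selection
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group '{gname}' is empty")
    membership: dict[str, str] = {}
    for gname, members in groups.items():
        for v in members:
            if v in membership:
                raise ValueError(f"variable {v} appears in groups '{membership[v]}' and '{gname}'")
            membership[v] = gname
    counts = {g: 0 for g in groups}
    for v in selection:
        if v not in survivors:
            raise ValueError(
                f"selected variable {v} was pruned (not among survivors {survivors})"
            )
        if v not in membership:
            raise ValueError(f"selected variable {v} belongs to no group")
        counts[membership[v]] += 1
    lo, hi = per_group
    bad = {g: c for g, c in counts.items() if c and not (lo <= c <= hi)}
    if bad:
        raise ValueError(f"groups outside the {lo}-{hi} picks range: {bad}")
    return sorted(selection, key=_bio_rank)
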