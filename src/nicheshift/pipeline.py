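"""End-to-end orchestration: curation -> PCA-env -> overlap -> tests -> report.

``run_full`` executes the whole comparison between a native and an invaded
range — occurrence cleaning and thinning, background construction,
variable selection, the pooled-background PCA, per-stratum density grids,
Schoener's D with its COUE decomposition, and the equivalency/similarity
permutation tests — for the full invasive set ("All") and for each decade
stratum, writing a JSON report plus CSV summary tables.

One master seed drives every stochastic stage through named substreams, so
re-running a config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._utils import substream_seed
from .climate import (ClimateStack, DEFAULT_GROUPS, DEFAULT_SELECTION, EnvMatrix,
                      background_sample, correlation_prune, extract, group_select)
from .env_space import background_surface, density_grid, fit_env_space, project
from .niche_metrics import NicheComparison
from .niche_tests import equivalency_test, similarity_test
from .occurrences import OccurrenceSet, clean, stratify_by_decade, thin

__all__ = ["AnalysisConfig", "AnalysisReport", "wilcoxon_compare", "run_full"]


@dataclass
class AnalysisConfig:
    """All knobs of the analysis, with the conventional defaults.

    Thinning at 10 km, |r| > 0.8 correlation pruning, a 100 x 100 density
    grid, 1000 permutation replicates and a 0.01 significance threshold are
    the standard protocol; every one of them is exposed here.
    """

    occurrences_csv: str | None = None
    stack_dir: str | None = None
    out_dir: str | None = None
    variables: list[str] = field(default_factory=lambda: list(DEFAULT_SELECTION))
    groups: dict[str, list[str]] | None = None
    correlation_threshold: float = 0.8
    thin_km: float = 10.0
    R: int = 100
    bandwidth_multiplier: float = 1.0
    intersection_quantile: float = 0.0
    reps: int = 1000
    alpha: float = 0.01
    background_margin_deg: float = 2.0
    background_max_cells: int = 10_000
    min_stratum_records: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must lie in (0, 1]")
        if self.thin_km <= 0:
            raise ValueError("thin_km must be positive")
        if self.R < 10:
            raise ValueError("R must be at least 10")
        if self.bandwidth_multiplier <= 0:
            raise ValueError("bandwidth_multiplier must be positive")
        if not (0.0 <= self.intersection_quantile < 1.0):
            raise ValueError("intersection_quantile must lie in [0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = self.groups if self.groups is not None else DEFAULT_GROUPS
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class AnalysisReport:
    """The full analysis output; serializable to one JSON document."""

    config: dict
    config_hash: str
    record_counts: dict
    removal_counts: dict
    variables: dict
    pca: dict
    strata: dict
    wilcoxon: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def niche_table(self) -> pd.DataFrame:
        """Per-stratum D / expansion / stability / unfilling table."""
        rows = []
        for name, entry in self.strata.items():
            if entry.get("skipped"):
                continue
            c = entry["comparison"]
            rows.append({"stratum": name, "schoener_d": c["schoener_d"],
                         "expansion": c["expansion"], "stability": c["stability"],
                         "unfilling": c["unfilling"]})
        return pd.DataFrame(rows)


def wilcoxon_compare(native_env: EnvMatrix, invasive_env: EnvMatrix,
                     variable: str) -> dict:
    """Two-sample Wilcoxon rank-sum comparison of one climate variable.

    Mann-Whitney U with tie correction; exact null for small untied samples,
    normal approximation (no continuity correction) otherwise, two-sided.
    Reports group medians and which range sits higher.
    """
    x = native_env.data[variable].to_numpy(dtype=float)
    y = invasive_env.data[variable].to_numpy(dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.unique(np.concatenate([x, y])).size == 1:
        raise ValueError(f"all values of {variable} are tied across both groups")
    res = mannwhitneyu(x, y, alternative="two-sided", use_continuity=False,
                       method="auto")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if med_y > med_x:
        direction = "invasive_higher"
    elif med_y < med_x:
        direction = "invasive_lower"
    else:
        direction = "equal_medians"
    return {
        "variable": variable,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_native": med_x,
        "median_invasive": med_y,
        "direction": direction,
    }


def bbox_region_mask(stack: ClimateStack, records: OccurrenceSet,
                     margin_deg: float = 2.0) -> np.ndarray:
    """Cells whose centers fall in the records' bounding box + margin.

    The minimal-assumption background definition: each range's available
    environment is what surrounds its occurrences.
    """
    df = records.data
    lon_lo, lon_hi = df["lon"].min() - margin_deg, df["lon"].max() + margin_deg
    lat_lo, lat_hi = df["lat"].min() - margin_deg, df["lat"].max() + margin_deg
    t = stack.transform
    rows = np.arange(t.nrows)[:, None]
    cols = np.arange(t.ncols)[None, :]
    lon, lat = t.cell_center(rows, cols)
    return (lon >= lon_lo) & (lon <= lon_hi) & (lat >= lat_lo) & (lat <= lat_hi)


def _analyze_stratum(name, inv_scores, native_grid, space, cfg,
                     nat_scores, bg_nat_scores, bg_inv_scores, z_env_inv):
    grid_inv = density_grid(space, inv_scores, R=cfg.R,
                            bandwidth_multiplier=cfg.bandwidth_multiplier,
                            bg_surface=z_env_inv)
    comparison = NicheComparison.from_grids(native_grid, grid_inv,
                                            cfg.intersection_quantile)
    eq = equivalency_test(nat_scores, inv_scores, bg_nat_scores, bg_inv_scores,
                          reps=cfg.reps,
                          seed=substream_seed(cfg.seed, f"equivalency:{name}"),
                          R=cfg.R, bandwidth_multiplier=cfg.bandwidth_multiplier,
                          space=space)
    sim = similarity_test(native_grid, inv_scores, bg_inv_scores, reps=cfg.reps,
                          seed=substream_seed(cfg.seed, f"similarity:{name}"),
                          bandwidth_multiplier=cfg.bandwidth_multiplier)
    return {
        "n_records": int(len(inv_scores)),
        "skipped": False,
        "comparison": comparison.to_dict(),
        "equivalency_test": {**eq.to_dict(),
                             "significant": bool(eq.p_value < cfg.alpha)},
        "similarity_test": {**sim.to_dict(),
                            "significant": bool(sim.p_value < cfg.alpha)},
    }


def run_full(config: AnalysisConfig, stack: ClimateStack | None = None,
             records: OccurrenceSet | None = None) -> AnalysisReport:
    """Run the complete niche-shift analysis and (optionally) write outputs.

    ``stack`` and ``records`` may be passed in memory; otherwise they are
    read from the paths in ``config``.  Strata with fewer than
    ``min_stratum_records`` invasive records are marked skipped rather than
    analyzed.
    """
    cfg = config
    if records is None:
        if cfg.occurrences_csv is None:
            raise ValueError("no occurrence records: set occurrences_csv or pass records")
        records = OccurrenceSet.from_csv(cfg.occurrences_csv)
    if stack is None:
        if cfg.stack_dir is None:
            raise ValueError("no climate stack: set stack_dir or pass stack")
        stack = ClimateStack.from_dir(cfg.stack_dir)

    n_raw = len(records)
    cleaned, removal_counts = clean(records, stack)
    thinned = thin(cleaned, min_km=cfg.thin_km,
                   seed=substream_seed(cfg.seed, "thin"))
    native = thinned.by_range("native")
    invasive = thinned.by_range("invasive")
    if len(native) == 0 or len(invasive) == 0:
        raise ValueError("both ranges must retain records after curation")

    # --- backgrounds and variable selection ---
    bg_native_all = background_sample(
        stack, bbox_region_mask(stack, native, cfg.background_margin_deg),
        max_cells=cfg.background_max_cells,
        seed=substream_seed(cfg.seed, "bg_native"))
    bg_invasive_all = background_sample(
        stack, bbox_region_mask(stack, invasive, cfg.background_margin_deg),
        max_cells=cfg.background_max_cells,
        seed=substream_seed(cfg.seed, "bg_invasive"))
    pooled_bg = EnvMatrix(
        pd.concat([bg_native_all.data, bg_invasive_all.data], ignore_index=True),
        ids=np.concatenate([
            np.char.add("nat_", bg_native_all.ids.astype(str)),
            np.char.add("inv_", bg_invasive_all.ids.astype(str))]))
    survivors, corr = correlation_prune(pooled_bg, cfg.correlation_threshold)
    variables = group_select(survivors, cfg.groups, cfg.variables)

    # --- PCA-env on pooled backgrounds ---
    bg_native = bg_native_all.select(variables)
    bg_invasive = bg_invasive_all.select(variables)
    space = fit_env_space(bg_native, bg_invasive)
    bg_nat_scores = project(space, bg_native)
    bg_inv_scores = project(space, bg_invasive)
    nat_env = extract(stack, native).select(variables)
    inv_env = extract(stack, invasive).select(variables)
    nat_scores = project(space, nat_env)
    inv_scores = project(space, inv_env)

    z_env_nat = background_surface(space, bg_nat_scores, R=cfg.R,
                                   bandwidth_multiplier=cfg.bandwidth_multiplier)
    z_env_inv = background_surface(space, bg_inv_scores, R=cfg.R,
                                   bandwidth_multiplier=cfg.bandwidth_multiplier)
    native_grid = density_grid(space, nat_scores, R=cfg.R,
                               bandwidth_multiplier=cfg.bandwidth_multiplier,
                               bg_surface=z_env_nat)

    # --- strata: All + decades ---
    strata_scores: dict[str, np.ndarray] = {"All": inv_scores}
    decade_sets = stratify_by_decade(invasive)
    inv_ids = list(invasive.data["id"])
    id_pos = {rid: i for i, rid in enumerate(inv_ids)}
    for decade, subset in decade_sets.items():
        if decade == "unassigned":
            continue
        pos = [id_pos[rid] for rid in subset.data["id"]]
        strata_scores[decade] = inv_scores[pos]

    strata: dict[str, dict] = {}
    for name, scores in strata_scores.items():
        if len(scores) < cfg.min_stratum_records:
            strata[name] = {"n_records": int(len(scores)), "skipped": True}
            continue
        strata[name] = _analyze_stratum(name, scores, native_grid, space, cfg,
                                        nat_scores, bg_nat_scores,
                                        bg_inv_scores, z_env_inv)

    wilcoxon = {v: wilcoxon_compare(nat_env, inv_env, v) for v in variables}

    config_dict = cfg.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()).hexdigest()[:16]
    report = AnalysisReport(
        config=config_dict,
        config_hash=config_hash,
        record_counts={
            "raw": n_raw,
            "after_clean": len(cleaned),
            "after_thin": len(thinned),
            "native": len(native),
            "invasive": len(invasive),
            "unassigned_year": len(decade_sets["unassigned"]),
        },
        removal_counts=removal_counts,
        variables={
            "candidates": list(pooled_bg.data.columns),
            "survivors": survivors,
            "selected": variables,
            "correlation_threshold": cfg.correlation_threshold,
        },
        pca={
            "explained": [float(v) for v in space.explained],
            "pc1_share": float(space.explained[0]),
            "pc2_share": float(space.explained[1]),
            "loadings": {v: [float(space.loadings[i, 0]), float(space.loadings[i, 1])]
                         for i, v in enumerate(space.variables)},
            "axis_ranges": [list(space.axis_ranges[0]), list(space.axis_ranges[1])],
        },
        strata=strata,
        wilcoxon=wilcoxon,
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        report.niche_table().to_csv(out / "niche_table.csv", index=False)
        pd.DataFrame(list(wilcoxon.values())).to_csv(out / "wilcoxon.csv", index=False)
        corr.to_csv(out / "correlation_matrix.csv")
    return report
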