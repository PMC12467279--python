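"""Shared fixtures: small synthetic scenarios and their derived objects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nicheshift import (NicheScenario, OccurrenceSet, generate_climate_stack,
                        generate_occurrences)


def make_records(rows, provenance="test"):
    """OccurrenceSet from a list of (lon, lat, range[, year]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        lon, lat, rng = row[:3]
        year = row[3] if len(row) > 3 else None
        recs.append({"id": f"t{i}", "lon": lon, "lat": lat, "range": rng,
                     "year": year, "source": "test"})
    return OccurrenceSet(pd.DataFrame(recs), provenance=provenance)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast, well-behaved scenario: dense availability, modest counts."""
    return NicheScenario(
        native_centroid=(-1.0, 0.0), invasive_centroid=(1.0, 0.0),
        n_native=150, n_invasive=120, grid_shape=(80, 80),
        nodata_fraction=0.05, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return generate_climate_stack(small_scenario)


@pytest.fixture(scope="session")
def small_records(small_scenario, small_stack):
    return generate_occurrences(small_scenario, small_stack)
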