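"""Shared fixtures: small hand-built panels and generated study panels."""

import numpy as np
import pandas as pd
import pytest

from scmort import GeneratorSpec, MortalityPanel, StudyConfig, generate_panel


def make_panel(series: dict[str, list[float]], start_year: int = 1999,
               population: dict[str, float] | float | None = 1_000_000) -> MortalityPanel:
    """Build a panel from per-unit lists of rates (NaN allowed)."""
    n = len(next(iter(series.values())))
    years = list(range(start_year, start_year + n))
    outcome = pd.DataFrame.from_dict(series, orient="index", columns=years, dtype=float)
    pop = None
    if population is not None:
        if not isinstance(population, dict):
            population = {u: float(population) for u in series}
        pop = pd.DataFrame(
            {y: pd.Series(population, dtype=float) for y in years}
        ).loc[outcome.index]
    return MortalityPanel(outcome=outcome, population=pop)


@pytest.fixture
def cfg() -> StudyConfig:
    return StudyConfig(treated_unit="treated")


@pytest.fixture
def default_panel() -> MortalityPanel:
    return generate_panel(GeneratorSpec(seed=2))


@pytest.fixture
def noise_free_spec() -> GeneratorSpec:
    """Deterministic panel whose donors straddle the treated baseline."""
    return GeneratorSpec(seed=0, noise_sd=0.0)


@pytest.fixture
def spanning_panel() -> MortalityPanel:
    """Noise-free panel with donors placed symmetrically around the treated
    unit's systematic path, so the treated unit lies in the donor convex hull."""
    years = list(range(1999, 2020))
    trend = 0.15
    rows = {}
    offsets = {"treated": 0.0, "lo_a": -0.5, "lo_b": -0.25, "hi_a": 0.25, "hi_b": 0.5}
    for unit, off in offsets.items():
        rows[unit] = [9.0 + off + trend * (y - 1999) for y in years]
    from scmort.simulate import default_effect_path

    path = default_effect_path()
    for y, e in path.items():
        rows["treated"][years.index(y)] += e
    return make_panel(rows, population={u: 1_000_000 for u in offsets})
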