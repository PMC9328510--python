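"""State-by-year mortality panels: the rectangular substrate of every stage.

A :class:`MortalityPanel` holds one outcome (deaths per 100,000 persons) on a
units × years grid, with an optional population grid for translating rate
effects into person counts.  Cells carrying a data source's suppression
sentinel (small counts the vital-statistics system deems unreliable) are kept
as missing values, never imputed: a unit with a missing cell is simply
ineligible — as treated unit or donor — for any analysis window covering the
gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["MortalityPanel", "PanelError", "read_panel", "write_panel", "restrict"]

#: Sentinel strings treated as missing on read (CDC WONDER-style exports).
DEFAULT_SENTINELS = ("Unreliable", "Suppressed", "")


class PanelError(ValueError):
    """Raised for malformed or unusable panel data."""


@dataclass(frozen=True)
class MortalityPanel:
    """Rectangular unit × year outcome panel.

    Parameters
    ----------
    outcome
        DataFrame indexed by unit identifier (str) with integer year columns,
        values in deaths per 100,000.  NaN marks a suppressed/missing cell.
    population
        Optional DataFrame of persons, same shape as ``outcome``.
    outcome_label
        Free-text description of the outcome ("age-adjusted suicide", ...).
    group_label
        Optional demographic stratum tag ("female", "65+", ...).
    """

    outcome: pd.DataFrame
    population: pd.DataFrame | None = None
    outcome_label: str = "age-adjusted suicide"
    group_label: str | None = None

    def __post_init__(self) -> None:
        out = self.outcome
        if out.empty:
            raise PanelError("empty panel")
        if out.index.has_duplicates:
            dups = out.index[out.index.duplicated()].tolist()
            raise PanelError(f"duplicate unit identifiers: {dups}")
        years = list(out.columns)
        if years != sorted(years) or any(
            b - a != 1 for a, b in zip(years, years[1:])
        ):
            raise PanelError(f"years must be contiguous ascending, got {years}")
        vals = out.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise PanelError("negative outcome rate")
        if self.population is not None:
            pop = self.population
            if list(pop.index) != list(out.index) or list(pop.columns) != years:
                raise PanelError("population grid does not match outcome grid")
            if np.nanmin(pop.to_numpy(dtype=float), initial=np.inf) < 1:
                raise PanelError("population must be >= 1 where present")

    # -- basic accessors ---------------------------------------------------

    @property
    def units(self) -> list[str]:
        return list(self.outcome.index)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.outcome.columns]

    def series(self, unit: str) -> pd.Series:
        """Outcome series for one unit, indexed by year."""
        return self.outcome.loc[unit]

    def is_complete(self, unit: str, years: Sequence[int]) -> bool:
        """True if ``unit`` has a finite outcome in every listed year."""
        return bool(np.isfinite(self.outcome.loc[unit, list(years)]).all())

    def complete_units(self, years: Sequence[int]) -> list[str]:
        """Units with no missing cell over the given window."""
        ok = np.isfinite(self.outcome[list(years)]).all(axis=1)
        return list(self.outcome.index[ok])

    def population_series(self, unit: str) -> pd.Series:
        if self.population is None:
            raise PanelError("panel carries no population data")
        return self.population.loc[unit]

    def with_outcome_label(self, label: str) -> "MortalityPanel":
        return replace(self, outcome_label=label)


def _coerce_rate(raw: object, sentinels: tuple[str, ...], row: int) -> float:
    if isinstance(raw, str):
        s = raw.strip()
        if s in sentinels:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise PanelError(f"non-numeric rate {raw!r} at data row {row}") from None
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    return float(raw)


def read_panel(
    path: str | Path,
    *,
    unit_col: str = "state",
    year_col: str = "year",
    rate_col: str = "rate",
    population_col: str | None = None,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
    sep: str | None = None,
    outcome_label: str = "age-adjusted suicide",
    group_label: str | None = None,
) -> MortalityPanel:
    """Read a long-format (one row per unit-year) delimited file.

    Suppression sentinels become missing cells, not zeros.  Duplicate
    (unit, year) rows and non-numeric rates are hard errors.
    """
    sentinels = tuple(sentinels)
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype={unit_col: str},
        keep_default_na=False,
        na_values=[],
    )
    for col in (unit_col, year_col, rate_col):
        if col not in df.columns:
            raise PanelError(f"missing column {col!r} in {path}")
    dup = df.duplicated(subset=[unit_col, year_col])
    if dup.any():
        pair = df.loc[dup.idxmax(), [unit_col, year_col]].tolist()
        raise PanelError(f"duplicate (unit, year) record: {pair}")
    rates = [
        _coerce_rate(v, sentinels, i) for i, v in enumerate(df[rate_col].tolist())
    ]
    long = pd.DataFrame(
        {
            "unit": df[unit_col].astype(str),
            "year": df[year_col].astype(int),
            "rate": rates,
        }
    )
    outcome = long.pivot(index="unit", columns="year", values="rate")
    outcome = outcome.sort_index(axis=0).sort_index(axis=1)
    outcome.columns = [int(c) for c in outcome.columns]
    outcome.index.name = None
    population = None
    if population_col is not None:
        if population_col not in df.columns:
            raise PanelError(f"missing column {population_col!r} in {path}")
        pops = pd.to_numeric(
            df[population_col].replace({s: np.nan for s in sentinels}),
            errors="raise",
        )
        plong = pd.DataFrame(
            {"unit": long["unit"], "year": long["year"], "pop": pops}
        )
        population = plong.pivot(index="unit", columns="year", values="pop")
        population = population.sort_index(axis=0).sort_index(axis=1)
        population.columns = [int(c) for c in population.columns]
        population.index.name = None
    return MortalityPanel(
        outcome=outcome,
        population=population,
        outcome_label=outcome_label,
        group_label=group_label,
    )


def write_panel(panel: MortalityPanel, path: str | Path, *, sep: str = ",") -> None:
    """Write long-format CSV; missing cells become empty fields."""
    rows = panel.outcome.stack(future_stack=True).rename("rate").reset_index()
    rows.columns = ["state", "year", "rate"]
    if panel.population is not None:
        pop = panel.population.stack(future_stack=True).rename("population").reset_index()
        rows["population"] = pop["population"].to_numpy()
    rows.to_csv(path, sep=sep, index=False)


def restrict(
    panel: MortalityPanel,
    years: tuple[int, int] | None = None,
    units: Sequence[str] | None = None,
) -> MortalityPanel:
    """Sub-panel over a year window and/or unit list.

    The result must be rectangular and complete: a requested unit with a
    missing cell inside the window is an error (eligibility-based exclusion is
    the caller's job, upstream of restriction).
    """
    out = panel.outcome
    pop = panel.population
    if units is not None:
        missing = [u for u in units if u not in out.index]
        if missing:
            raise PanelError(f"unknown units: {missing}")
        out = out.loc[list(units)]
        pop = pop.loc[list(units)] if pop is not None else None
    if years is not None:
        lo, hi = years
        want = [y for y in panel.years if lo <= y <= hi]
        if not want or want[0] != lo or want[-1] != hi:
            raise PanelError(
                f"window [{lo}, {hi}] not covered by panel years "
                f"[{panel.years[0]}, {panel.years[-1]}]"
            )
        out = out[want]
        pop = pop[want] if pop is not None else None
    if out.size == 0:
        raise PanelError("restriction yields an empty panel")
    if not np.isfinite(out.to_numpy(dtype=float)).all():
        bad = [
            (u, int(y))
            for u in out.index
            for y in out.columns
            if not np.isfinite(out.loc[u, y])
        ]
        raise PanelError(f"missing cells inside restricted window: {bad[:5]}")
    return MortalityPanel(
        outcome=out,
        population=pop,
        outcome_label=panel.outcome_label,
        group_label=panel.group_label,
    )
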