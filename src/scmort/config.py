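"""Study configuration: treated unit, intervention timing, donor-pool rules."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "star_tier"]


@dataclass(frozen=True)
class StudyConfig:
    """Everything a single synthetic-control study needs beyond the panel.

    The intervention year T0 is the first post-intervention year; the
    pre-intervention window is [pre_start, T0 - 1] and the post window
    [T0, post_end].  ``excluded_units`` are removed before donor selection
    (units with a policy similar to the treated unit's).
    """

    treated_unit: str
    intervention_year: int = 2005
    pre_start: int = 1999
    post_end: int = 2019
    excluded_units: tuple[str, ...] = ()
    donor_k_below: int = 9
    donor_k_above: int = 9
    min_similar_years: int = 4
    closeness_multiplier: float = 2.0
    alpha_tiers: tuple[float, float, float] = (0.10, 0.05, 0.01)
    predictor_mode: str = "all_pre_years"  # or "lag_plus_mean"

    def __post_init__(self) -> None:
        if self.treated_unit in self.excluded_units:
            raise ValueError("treated unit cannot be in excluded_units")
        if len(self.pre_years) < 2:
            raise ValueError("pre-intervention window must span >= 2 years")
        if self.intervention_year > self.post_end:
            raise ValueError("need at least one post-intervention year")
        if self.predictor_mode not in ("all_pre_years", "lag_plus_mean"):
            raise ValueError(f"unknown predictor_mode {self.predictor_mode!r}")
        tiers = self.alpha_tiers
        if list(tiers) != sorted(tiers, reverse=True):
            raise ValueError("alpha_tiers must be in decreasing order")

    @property
    def pre_years(self) -> list[int]:
        return list(range(self.pre_start, self.intervention_year))

    @property
    def post_years(self) -> list[int]:
        return list(range(self.intervention_year, self.post_end + 1))

    @property
    def all_years(self) -> list[int]:
        return list(range(self.pre_start, self.post_end + 1))

    def redated(self, new_t0: int) -> "StudyConfig":
        """Config with the intervention moved to ``new_t0``.

        The similarity floor scales proportionately with the pre-window
        length: ceil(min_similar_years / old_pre_len × new_pre_len).
        """
        old_pre = len(self.pre_years)
        new_pre = new_t0 - self.pre_start
        scaled = math.ceil(self.min_similar_years / old_pre * new_pre)
        return replace(
            self, intervention_year=new_t0, min_similar_years=scaled
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "StudyConfig":
        """Load from a flat key-value YAML file; kwargs override file keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        data = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        for key in ("excluded_units", "alpha_tiers"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def star_tier(p: float, tiers: tuple[float, ...] = (0.10, 0.05, 0.01)) -> str:
    """Map a p-value to its significance stars ('' to '***')."""
    stars = ""
    for i, alpha in enumerate(tiers):
        if p <= alpha:
            stars = "*" * (i + 1)
    return stars
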