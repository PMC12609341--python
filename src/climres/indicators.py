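"""Indicator system for the food-industry supply-chain resilience index.

The composite index is built from 22 province-year indicators organised in
three capability dimensions: resistance (resource base and production
conditions), adaptability (input efficiency and infrastructure buffering)
and innovation (scale, capital and R&D intensity).  Each indicator carries a
direction: "positive" means larger raw values indicate more resilience,
"negative" the opposite (e.g. producer price pressure, pesticide intensity).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "IndicatorSpec",
    "default_indicator_specs",
    "load_indicator_specs",
    "save_indicator_specs",
    "GROUPS",
    "DIRECTIONS",
]

GROUPS = ("resistance", "adaptability", "innovation")
DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator: column name, direction of causality, level-1 group."""

    name: str
    direction: str
    group: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"IndicatorSpec.direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r} for {self.name!r}"
            )
        if self.group not in GROUPS:
            raise ValueError(
                f"IndicatorSpec.group must be one of {GROUPS}, "
                f"got {self.group!r} for {self.name!r}"
            )


# name, direction, group — the standard 22-indicator system.
_DEFAULT_TABLE = [
    # resistance capacity
    ("sown_area", "positive", "resistance"),
    ("irrigated_area", "positive", "resistance"),
    ("gdp_per_capita", "positive", "resistance"),
    ("food_yield_per_area", "positive", "resistance"),
    ("land_productivity", "positive", "resistance"),
    ("labor_productivity", "positive", "resistance"),
    ("producer_price_index", "negative", "resistance"),
    ("primary_sector_share", "positive", "resistance"),
    ("road_area_per_capita", "positive", "resistance"),
    # adaptation capacity
    ("pesticide_rate", "negative", "adaptability"),
    ("fertilizer_rate", "negative", "adaptability"),
    ("plastic_film_rate", "negative", "adaptability"),
    ("rural_electricity", "positive", "adaptability"),
    ("output_growth_index", "positive", "adaptability"),
    ("rural_broadband", "positive", "adaptability"),
    ("disaster_area_ratio", "negative", "adaptability"),
    # innovation capacity
    ("agri_output_value", "positive", "innovation"),
    ("fixed_asset_investment", "positive", "innovation"),
    ("avg_power_level", "positive", "innovation"),
    ("research_investment", "positive", "innovation"),
    ("rd_personnel", "positive", "innovation"),
    ("trade_dependence", "positive", "innovation"),
]


def default_indicator_specs() -> list[IndicatorSpec]:
    """The standard 22-indicator resilience system with directions."""
    return [IndicatorSpec(n, d, g) for n, d, g in _DEFAULT_TABLE]


def load_indicator_specs(path: str | Path) -> list[IndicatorSpec]:
    """Read an indicator spec CSV with columns name,direction,group."""
    specs: list[IndicatorSpec] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            specs.append(
                IndicatorSpec(row["name"].strip(), row["direction"].strip(), row["group"].strip())
            )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("indicator names must be unique")
    return specs


def save_indicator_specs(specs: list[IndicatorSpec], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "direction", "group"])
        for s in specs:
            w.writerow([s.name, s.direction, s.group])
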