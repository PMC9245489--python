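"""Food-frequency-questionnaire (FFQ) intake engine.

A semi-quantitative FFQ records, for each food item, how often it was
consumed (nine ordered frequency categories from "less than once a month"
up to "seven or more times a day") and in what portion (small / medium /
large, meaning 50% smaller than, equal to, or 50% larger than a standard
portion).  Daily nutrient intake is obtained by

    grams/day     = times_per_day(frequency) * standard_portion_g * portion_multiplier
    nutrient/day  = grams/day * nutrient_content_per_100g / 100

summed over items, using a food-composition lookup table.  This module
implements that arithmetic for omega-3 polyunsaturated fatty acids (g/day)
and total energy (kcal/day).

The shipped composition table (``data/composition_synthetic.csv``) is a
small synthetic stand-in — 21 fish/shellfish items plus staples — with
plausible portion masses and contents; it is not a national food
composition database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_LEVELS",
    "PORTION_LEVELS",
    "PORTION_MULTIPLIERS",
    "FrequencyMap",
    "CompositionTable",
    "FFQResponse",
    "item_intake",
    "total_intake",
    "intakes_from_long",
]

#: The nine ordered frequency categories of the instrument.
FREQUENCY_LEVELS = (
    "lt1_per_month",
    "1-3_per_month",
    "1-2_per_week",
    "3-4_per_week",
    "5-6_per_week",
    "daily",
    "2-3_per_day",
    "4-6_per_day",
    "ge7_per_day",
)

#: Portion categories: small = 50% below standard, large = 50% above.
PORTION_LEVELS = ("small", "medium", "large")
PORTION_MULTIPLIERS: Mapping[str, float] = {"small": 0.5, "medium": 1.0, "large": 1.5}

# Interval midpoints, expressed as consumption occasions per day
# (months taken as 30.4 days).
_DEFAULT_TIMES_PER_DAY = {
    "lt1_per_month": 0.5 / 30.4,
    "1-3_per_month": 2.0 / 30.4,
    "1-2_per_week": 1.5 / 7.0,
    "3-4_per_week": 3.5 / 7.0,
    "5-6_per_week": 5.5 / 7.0,
    "daily": 1.0,
    "2-3_per_day": 2.5,
    "4-6_per_day": 5.0,
    "ge7_per_day": 7.0,
}


@dataclass(frozen=True)
class FrequencyMap:
    """Mapping from frequency category to consumption occasions per day.

    The map must be strictly increasing across the nine ordered levels; an
    alternative map (e.g. category lower bounds instead of midpoints) can be
    injected anywhere a ``FrequencyMap`` is accepted.
    """

    times_per_day: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TIMES_PER_DAY)
    )

    def __post_init__(self) -> None:
        missing = set(FREQUENCY_LEVELS) - set(self.times_per_day)
        if missing:
            raise ValueError(f"frequency map missing levels: {sorted(missing)}")
        vals = [self.times_per_day[lvl] for lvl in FREQUENCY_LEVELS]
        if any(v < 0 for v in vals):
            raise ValueError("times per day must be nonnegative")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("times per day must be strictly increasing across levels")

    def __getitem__(self, level: str) -> float:
        try:
            return self.times_per_day[level]
        except KeyError:
            raise KeyError(f"unknown frequency level {level!r}") from None

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.times_per_day[lvl] for lvl in FREQUENCY_LEVELS],
            index=list(FREQUENCY_LEVELS),
            name="times_per_day",
        )


class CompositionTable:
    """Per-item standard portion mass and nutrient contents.

    Wraps a DataFrame indexed by ``item_id`` with columns
    ``standard_portion_g``, ``omega3_g_per_100g`` and
    ``energy_kcal_per_100g``.
    """

    REQUIRED = ("standard_portion_g", "omega3_g_per_100g", "energy_kcal_per_100g")

    def __init__(self, table: pd.DataFrame):
        if "item_id" in table.columns:
            table = table.set_index("item_id")
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"composition table missing column {col!r}")
        if table.index.duplicated().any():
            raise ValueError("duplicate item ids in composition table")
        if (table["standard_portion_g"] <= 0).any():
            raise ValueError("standard portions must be positive")
        if (table[["omega3_g_per_100g", "energy_kcal_per_100g"]] < 0).to_numpy().any():
            raise ValueError("nutrient contents must be nonnegative")
        self.table = table

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "CompositionTable":
        """The synthetic 21-fish/shellfish-item + staples table shipped with the package."""
        with resources.files("omegadose.data").joinpath(
            "composition_synthetic.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    @property
    def item_ids(self) -> list[str]:
        return list(self.table.index)

    def row(self, item_id: str) -> pd.Series:
        try:
            return self.table.loc[item_id]
        except KeyError:
            raise KeyError(f"item {item_id!r} not in composition table") from None

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FFQResponse:
    """One participant's answers: item id -> (frequency level, portion level).

    Unanswered items are simply absent from ``items`` and contribute zero
    intake (documented convention).
    """

    items: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, (freq, portion) in self.items.items():
            if freq not in FREQUENCY_LEVELS:
                raise ValueError(f"item {item!r}: unknown frequency level {freq!r}")
            if portion not in PORTION_LEVELS:
                raise ValueError(f"item {item!r}: unknown portion level {portion!r}")

    def __len__(self) -> int:
        return len(self.items)


def item_intake(
    frequency: str,
    portion: str,
    composition_row: pd.Series,
    frequency_map: FrequencyMap | None = None,
) -> tuple[float, float]:
    """Omega-3 (g/day) and energy (kcal/day) contributed by one answered item."""
    fmap = frequency_map or FrequencyMap()
    if portion not in PORTION_MULTIPLIERS:
        raise ValueError(f"unknown portion level {portion!r}")
    grams_per_day = (
        fmap[frequency]
        * float(composition_row["standard_portion_g"])
        * PORTION_MULTIPLIERS[portion]
    )
    omega3 = grams_per_day * float(composition_row["omega3_g_per_100g"]) / 100.0
    energy = grams_per_day * float(composition_row["energy_kcal_per_100g"]) / 100.0
    return omega3, energy


def total_intake(
    response: FFQResponse,
    table: CompositionTable,
    frequency_map: FrequencyMap | None = None,
) -> tuple[float, float]:
    """Sum item intakes over all answered items -> (omega-3 g/day, energy kcal/day)."""
    fmap = frequency_map or FrequencyMap()
    omega3 = 0.0
    energy = 0.0
    for item_id, (freq, portion) in response.items.items():
        o, e = item_intake(freq, portion, table.row(item_id), fmap)
        omega3 += o
        energy += e
    return omega3, energy


def intakes_from_long(
    responses: pd.DataFrame,
    table: CompositionTable,
    frequency_map: FrequencyMap | None = None,
) -> pd.DataFrame:
    """Vectorised intake computation for long-format responses.

    ``responses`` has one row per answered item with columns
    ``pair_id``, ``item_id``, ``frequency``, ``portion``.  Returns a frame
    indexed by ``pair_id`` with columns ``omega3_g_day`` and
    ``energy_kcal_day``.  Pairs with no answered rows do not appear; callers
    reindex and fill 0 if every pair must be present.
    """
    fmap = frequency_map or FrequencyMap()
    req = {"pair_id", "item_id", "frequency", "portion"}
    if not req.issubset(responses.columns):
        raise ValueError(f"long responses need columns {sorted(req)}")
    bad_freq = set(responses["frequency"].unique()) - set(FREQUENCY_LEVELS)
    if bad_freq:
        raise ValueError(f"unknown frequency levels {sorted(bad_freq)}")
    bad_portion = set(responses["portion"].unique()) - set(PORTION_LEVELS)
    if bad_portion:
        raise ValueError(f"unknown portion levels {sorted(bad_portion)}")
    unknown_items = set(responses["item_id"].unique()) - set(table.item_ids)
    if unknown_items:
        raise KeyError(f"items not in composition table: {sorted(unknown_items)}")

    tpd = responses["frequency"].map(fmap.times_per_day).to_numpy(float)
    mult = responses["portion"].map(PORTION_MULTIPLIERS).to_numpy(float)
    comp = table.table.loc[responses["item_id"]]
    grams = tpd * mult * comp["standard_portion_g"].to_numpy(float)
    out = pd.DataFrame(
        {
            "pair_id": responses["pair_id"].to_numpy(),
            "omega3_g_day": grams * comp["omega3_g_per_100g"].to_numpy(float) / 100.0,
            "energy_kcal_day": grams * comp["energy_kcal_per_100g"].to_numpy(float) / 100.0,
        }
    )
    return out.groupby("pair_id").sum()
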