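"""Per-farm-type calibration constants for the synthetic population generator.

Each farm type carries the empirical structure of its real counterpart:
sample size, flock-size class counts and ranges, per-ewe cost/revenue
means, revenue-composition shares, the efficient-farm count, the TE range
and inefficient-group mean, and category-level best-practice adoption
rates among efficient farms. One annual labor unit (ALU) is taken as
1800 hours/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .farm_records import FarmType

__all__ = ["FarmTypeCalibration", "CALIBRATIONS", "ALU_HOURS"]

ALU_HOURS = 1800.0


@dataclass(frozen=True)
class FarmTypeCalibration:
    n: int
    size_counts: tuple[int, int, int]          # small / medium / large farms
    size_ranges: tuple[tuple[int, int], ...]   # inclusive ewe ranges per class
    efficient_count: int
    te_min: float                              # lowest observed TE
    te_inefficient_mean: float                 # mean TE of the inefficient group
    te_overall_mean: float
    revenue_per_ewe: float                     # EUR/ewe, average farm
    revenue_shares: dict[str, float]           # component -> share of gross revenue
    labor_cost: float                          # EUR/ewe
    feed_cost: float                           # EUR/ewe
    purchased_feed: float                      # EUR/ewe (rest is home-grown)
    variable_capital_cost: float               # EUR/ewe
    fixed_capital_cost: float                  # EUR/ewe
    ewes_per_alu: float
    lambs_per_ewe: float
    feed_kg_dm_per_ewe: float
    practice_rates: dict[str, float] | None    # category -> adoption rate, None = no survey

    @property
    def hours_per_ewe(self) -> float:
        return ALU_HOURS / self.ewes_per_alu

    @property
    def variable_cost_per_ewe(self) -> float:
        return self.feed_cost + self.variable_capital_cost

    @property
    def input_weights(self) -> tuple[float, float, float, float]:
        """Per-ewe weights of the four DEA inputs along the type's input ray:
        (ewes, labor hours, variable cost, fixed capital cost) per ewe."""
        return (1.0, self.hours_per_ewe, self.variable_cost_per_ewe, self.fixed_capital_cost)


CALIBRATIONS: dict[FarmType, FarmTypeCalibration] = {
    FarmType.FRENCH_EXTENSIVE: FarmTypeCalibration(
        n=241,
        size_counts=(80, 45, 116),
        size_ranges=((120, 349), (350, 450), (451, 1079)),
        efficient_count=25,
        te_min=0.31,
        te_inefficient_mean=0.675,
        te_overall_mean=0.709,
        revenue_per_ewe=156.57,
        revenue_shares={
            "lambs_meat": 0.6556, "lambs_breeding": 0.0972, "culls": 0.0443,
            "subsidies": 0.1740, "wool_other": 0.0289,
        },
        labor_cost=66.0, feed_cost=45.0, purchased_feed=34.0,
        variable_capital_cost=26.0, fixed_capital_cost=78.0,
        ewes_per_alu=399.0, lambs_per_ewe=0.87, feed_kg_dm_per_ewe=378.0,
        practice_rates={
            "Feeding": 16 / 25, "Breeding": 15 / 25, "Gadgets and Applications": 13 / 25,
            "Product marketing": 12 / 25, "Information and training": 10 / 25,
            "Reproduction": 12 / 25, "Human resources organization": 10 / 25,
            "Health": 8 / 25, "Product processing": 2 / 25,
        },
    ),
    FarmType.FRENCH_INTENSIVE: FarmTypeCalibration(
        n=61,
        size_counts=(22, 13, 26),
        size_ranges=((120, 349), (350, 450), (451, 989)),
        efficient_count=22,
        te_min=0.576,
        te_inefficient_mean=0.802,
        te_overall_mean=0.873,
        revenue_per_ewe=191.6,
        revenue_shares={
            "lambs_meat": 0.6994, "lambs_breeding": 0.0824, "culls": 0.0548,
            "subsidies": 0.1332, "wool_other": 0.0302,
        },
        labor_cost=51.0, feed_cost=60.0, purchased_feed=45.0,
        variable_capital_cost=27.0, fixed_capital_cost=76.0,
        ewes_per_alu=518.0, lambs_per_ewe=1.07, feed_kg_dm_per_ewe=496.0,
        practice_rates={
            "Feeding": 17 / 22, "Breeding": 14 / 22, "Gadgets and Applications": 18 / 22,
            "Product marketing": 17 / 22, "Information and training": 17 / 22,
            "Reproduction": 13 / 22, "Human resources organization": 6 / 22,
            "Health": 3 / 22, "Product processing": 2 / 22,
        },
    ),
    FarmType.SPANISH_SEMI_INTENSIVE: FarmTypeCalibration(
        n=37,
        size_counts=(13, 13, 11),
        size_ranges=((150, 599), (600, 1000), (1001, 2237)),
        efficient_count=14,
        te_min=0.57,
        te_inefficient_mean=0.798,
        te_overall_mean=0.874,
        revenue_per_ewe=144.4,
        revenue_shares={
            "lambs_meat": 0.6648, "lambs_breeding": 0.0111, "culls": 0.0148,
            "subsidies": 0.2691, "wool_other": 0.0405,
        },
        labor_cost=31.0, feed_cost=59.0, purchased_feed=42.0,
        variable_capital_cost=9.0, fixed_capital_cost=23.0,
        ewes_per_alu=532.0, lambs_per_ewe=1.58, feed_kg_dm_per_ewe=287.0,
        practice_rates={
            "Feeding": 6 / 14, "Breeding": 5 / 14, "Gadgets and Applications": 6 / 14,
            "Product marketing": 6 / 14, "Information and training": 2 / 14,
            "Reproduction": 6 / 14, "Human resources organization": 6 / 14,
            "Health": 2 / 14, "Product processing": 0.0,
        },
    ),
    FarmType.UK_EXTENSIVE: FarmTypeCalibration(
        n=119,
        size_counts=(44, 46, 29),
        size_ranges=((120, 399), (400, 900), (901, 2165)),
        efficient_count=22,
        te_min=0.31,
        te_inefficient_mean=0.722,
        te_overall_mean=0.773,
        revenue_per_ewe=140.04,
        # subsidies unavailable for UK farms; shares over the four components
        revenue_shares={
            "lambs_meat": 0.3874, "lambs_breeding": 0.4374, "culls": 0.1467,
            "wool_other": 0.0285,
        },
        labor_cost=32.0, feed_cost=19.0, purchased_feed=12.0,
        variable_capital_cost=46.0, fixed_capital_cost=64.0,
        ewes_per_alu=922.0, lambs_per_ewe=0.63, feed_kg_dm_per_ewe=86.24,
        practice_rates=None,
    ),
}
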