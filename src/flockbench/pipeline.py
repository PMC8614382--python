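"""Reporting layer: efficiency groups, TE frequency tables, frontier
projection summaries by flock-size class, gross-revenue composition and
per-ewe techno-economic indicators.

All aggregates are computed on unrounded internals; rounding happens only
at presentation. Group means of per-ewe quantities are unweighted means
over farms of each farm's own EUR/ewe ratio (not ratio of sums), which is
robust to flock-size skew; the choice is recorded in the table metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea_core import DEAResult
from .farm_records import (
    REVENUE_COMPONENTS,
    SIZE_CLASSES,
    FarmRecord,
    SizeClassScheme,
    assign_size_class,
)

__all__ = [
    "classify_groups",
    "te_frequency_table",
    "FrequencyTable",
    "projection_summary",
    "ProjectionSummary",
    "percent_increase",
    "revenue_composition",
    "economic_indicators",
    "gross_margin",
    "profit",
    "DEFAULT_TE_BIN_EDGES",
]

#: Interior TE bin edges; bins are [0,.60), [.60,.70), [.70,.80), [.80,.90),
#: [.90, 1-eps), and the efficient bin {TE >= 1-eps}.
DEFAULT_TE_BIN_EDGES = (0.60, 0.70, 0.80, 0.90)


def classify_groups(
    results: Sequence[DEAResult], epsilon: float = 1e-6
) -> tuple[list[int], list[int]]:
    """Partition DMU indices into (efficient, inefficient) by TE >= 1 - eps."""
    if not results:
        raise ValueError("results must be nonempty")
    eff = [r.dmu_index for r in results if r.te >= 1.0 - epsilon]
    ineff = [r.dmu_index for r in results if r.te < 1.0 - epsilon]
    return eff, ineff


@dataclass
class FrequencyTable:
    """TE frequency distribution: one row per bin plus a total row."""

    bins: pd.DataFrame  # columns: label, count, share_pct, mean_te
    total_count: int
    total_mean_te: float

    def to_frame(self) -> pd.DataFrame:
        total = pd.DataFrame(
            [{"label": "Total", "count": self.total_count, "share_pct": 100.0,
              "mean_te": self.total_mean_te}]
        )
        return pd.concat([self.bins, total], ignore_index=True)


def te_frequency_table(
    te_values: Sequence[float] | np.ndarray,
    bin_edges: Sequence[float] = DEFAULT_TE_BIN_EDGES,
    epsilon: float = 1e-6,
) -> FrequencyTable:
    """Bin TE scores into half-open intervals with a closed efficient top bin.

    Bin means come from the unrounded scores. TE outside (0, 1] raises,
    signalling an upstream solver defect.
    """
    te = np.asarray(te_values, dtype=float)
    if te.size == 0:
        raise ValueError("no TE values")
    if np.any(te <= 0) or np.any(te > 1 + 1e-12):
        raise ValueError("TE values must lie in (0, 1]")
    edges = [0.0, *bin_edges, 1.0 - epsilon]
    labels = [f"<{bin_edges[0]:.2f}"]
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        labels.append(f"{lo:.2f}–{hi - 0.01:.2f}")
    labels.append(f"{bin_edges[-1]:.2f}–0.99")
    labels.append("1.00")
    rows = []
    for b in range(len(edges)):
        lo = edges[b]
        hi = edges[b + 1] if b + 1 < len(edges) else None
        if hi is None:
            mask = te >= lo  # efficient bin, closed
        else:
            mask = (te >= lo) & (te < hi)
        count = int(mask.sum())
        rows.append(
            {
                "label": labels[b],
                "count": count,
                "share_pct": 100.0 * count / te.size,
                "mean_te": float(te[mask].mean()) if count else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    if bins["count"].sum() != te.size:
        raise AssertionError("bins do not partition the TE values")
    return FrequencyTable(bins=bins, total_count=int(te.size), total_mean_te=float(te.mean()))


def percent_increase(existing: float, target: float, decimals: int | None = None) -> float:
    """Percent output increase 100*(target/existing - 1); optionally rounded."""
    if existing <= 0:
        raise ValueError("existing output must be positive")
    if target < existing - 1e-6 * existing:
        raise ValueError("target output below existing output")
    pct = 100.0 * (target / existing - 1.0)
    return round(pct, decimals) if decimals is not None else pct


@dataclass
class ProjectionSummary:
    """Mean existing vs efficient-target output per size class and overall."""

    table: pd.DataFrame  # rows small/medium/large/average

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def projection_summary(
    records: Sequence[FarmRecord],
    results: Sequence[DEAResult],
    scheme: SizeClassScheme,
) -> ProjectionSummary:
    """Existing vs slack-adjusted frontier output by flock-size class.

    Uses the phase-2 projected output (theta*y + output slack). Empty
    classes are flagged, not NaN-propagated into percent columns.
    """
    if len(records) != len(results):
        raise ValueError("records and results must align one-to-one")
    y = np.array([r.gross_revenue for r in records])
    ystar = np.array([res.projected_output for res in results])
    classes = np.array([assign_size_class(r, scheme) for r in records])
    rows = []
    for cls in (*SIZE_CLASSES, "average"):
        mask = np.ones(len(records), bool) if cls == "average" else classes == cls
        count = int(mask.sum())
        if count == 0:
            rows.append({"size_class": cls, "count": 0, "existing_output": np.nan,
                         "efficient_target": np.nan, "percent_increase": np.nan,
                         "empty": True})
            continue
        mean_y = float(y[mask].mean())
        mean_ystar = float(ystar[mask].mean())
        rows.append(
            {
                "size_class": cls,
                "count": count,
                "existing_output": mean_y,
                "efficient_target": mean_ystar,
                "percent_increase": percent_increase(mean_y, mean_ystar),
                "empty": False,
            }
        )
    return ProjectionSummary(table=pd.DataFrame(rows))


def _group_frames(
    records: Sequence[FarmRecord], groups: tuple[Sequence[int], Sequence[int]]
) -> list[tuple[str, list[FarmRecord]]]:
    eff_idx, ineff_idx = groups
    eff = [records[i] for i in eff_idx]
    ineff = [records[i] for i in ineff_idx]
    return [("inefficient", ineff), ("efficient", eff), ("average", list(records))]


def revenue_composition(
    records: Sequence[FarmRecord],
    groups: tuple[Sequence[int], Sequence[int]],
) -> pd.DataFrame:
    """Per-ewe gross-revenue composition by efficiency group.

    Rows: inefficient / efficient / average. For each revenue component the
    per-ewe group mean (EUR/ewe) and its share of the group total (%).
    Components absent for every farm (e.g. UK subsidies) are excluded from
    the total and reported as NaN; the excluded names are listed in
    ``frame.attrs['na_components']``.
    """
    out_rows = []
    na_components: set[str] = set()
    for name, members in _group_frames(records, groups):
        if not members:
            continue
        row: dict = {"group": name, "n_farms": len(members)}
        total = 0.0
        any_component = False
        for comp in REVENUE_COMPONENTS:
            per_ewe = [
                getattr(r, comp) / r.ewes for r in members if getattr(r, comp) is not None
            ]
            if not per_ewe:
                row[comp] = np.nan
                na_components.add(comp)
                continue
            any_component = True
            mean = float(np.mean(per_ewe))
            row[comp] = mean
            total += mean
        if not any_component:
            raise ValueError(f"group {name!r}: every revenue component is unavailable")
        row["total"] = total
        for comp in REVENUE_COMPONENTS:
            row[f"{comp}_pct"] = (
                100.0 * row[comp] / total if not np.isnan(row[comp]) else np.nan
            )
        out_rows.append(row)
    frame = pd.DataFrame(out_rows)
    frame.attrs["na_components"] = sorted(na_components)
    frame.attrs["mean_convention"] = "unweighted mean over farms of per-ewe ratios"
    return frame


def gross_margin(gross_revenue: float, feed_cost: float, variable_capital_cost: float) -> float:
    """Gross margin per ewe: gross revenue less the variable cost (feed plus
    variable capital cost)."""
    return gross_revenue - feed_cost - variable_capital_cost


def profit(gross_revenue: float, production_cost: float) -> float:
    """Net profit (or loss) per ewe: gross revenue less total production cost."""
    return gross_revenue - production_cost


_ECON_MEANS = (
    "labor_cost",
    "feed_cost",
    "purchased_feed",
    "homegrown_feed",
    "variable_capital_cost",
    "fixed_capital_cost",
    "feed_kg_dm_per_ewe",
)


def economic_indicators(
    records: Sequence[FarmRecord],
    groups: tuple[Sequence[int], Sequence[int]],
) -> pd.DataFrame:
    """Techno-economic profile by efficiency group (per-ewe group means).

    Derived indicators: production cost = labor + feed + variable capital +
    fixed capital cost; gross margin = gross revenue - feed - variable
    capital; profit = gross revenue - production cost; lambs per ewe; ewes
    per annual labor unit (ALU). An indicator whose components are missing
    for the whole group is reported NaN (unavailable), never zero.
    """
    out_rows = []
    for name, members in _group_frames(records, groups):
        if not members:
            continue
        row: dict = {"group": name, "n_farms": len(members)}
        row["ewes"] = float(np.mean([r.ewes for r in members]))
        row["gross_revenue"] = float(np.mean([r.gross_revenue / r.ewes for r in members]))

        def group_mean(field: str) -> float:
            vals = [getattr(r, field) for r in members if getattr(r, field) is not None]
            return float(np.mean(vals)) if vals else np.nan

        for f in _ECON_MEANS:
            row[f] = group_mean(f)
        lambs = [r.lambs_sold for r in members if r.lambs_sold is not None]
        row["lambs_sold"] = float(np.mean(lambs)) if lambs else np.nan
        lpe = [r.lambs_sold / r.ewes for r in members if r.lambs_sold is not None]
        row["lambs_per_ewe"] = float(np.mean(lpe)) if lpe else np.nan
        epa = [r.ewes / r.alu for r in members if r.alu is not None and r.alu > 0]
        row["ewes_per_alu"] = float(np.mean(epa)) if epa else np.nan
        row["production_cost"] = (
            row["labor_cost"]
            + row["feed_cost"]
            + row["variable_capital_cost"]
            + row["fixed_capital_cost"]
        )
        row["gross_margin"] = gross_margin(
            row["gross_revenue"], row["feed_cost"], row["variable_capital_cost"]
        )
        row["profit"] = profit(row["gross_revenue"], row["production_cost"])
        out_rows.append(row)
    frame = pd.DataFrame(out_rows)
    frame.attrs["mean_convention"] = "unweighted mean over farms of per-ewe ratios"
    return frame
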