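"""Farm accounting records: data model, validation and delimited-text I/O.

One record per farm (decision-making unit). The four DEA inputs are flock
size (ewes), total annual labor (hours), variable cost (EUR) and fixed
capital cost (EUR); the single output is gross revenue (EUR, subsidies
included). Optional columns carry the revenue components and the per-ewe
techno-economic fields used by the reporting layer; an absent optional
value is encoded as an empty field, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FarmType",
    "FarmRecord",
    "SizeClassScheme",
    "DEFAULT_SIZE_SCHEMES",
    "SchemaError",
    "RecordValidationError",
    "REVENUE_COMPONENTS",
    "TECHNICAL_FIELDS",
    "read_farm_table",
    "write_farm_table",
    "assign_size_class",
]


class FarmType(str, Enum):
    """The four farm types, each benchmarked against its own frontier."""

    FRENCH_EXTENSIVE = "french_extensive"
    FRENCH_INTENSIVE = "french_intensive"
    SPANISH_SEMI_INTENSIVE = "spanish_semi_intensive"
    UK_EXTENSIVE = "uk_extensive"


#: Revenue components (EUR/year, farm level). Their sum, when all five are
#: present, must equal gross revenue to 1e-3 relative tolerance.
REVENUE_COMPONENTS = (
    "lambs_meat",
    "lambs_breeding",
    "culls",
    "subsidies",
    "wool_other",
)

#: Optional technical / per-ewe economic fields.
TECHNICAL_FIELDS = (
    "lambs_sold",
    "alu",
    "feed_kg_dm_per_ewe",
    "labor_cost",
    "feed_cost",
    "purchased_feed",
    "homegrown_feed",
    "variable_capital_cost",
    "fixed_capital_cost",
)

MANDATORY_COLUMNS = ("farm_id", "ewes", "labor", "variable_cost", "fixed_cost", "gross_revenue")

_COMPONENT_SUM_RTOL = 1e-3


class SchemaError(ValueError):
    """A farm table is missing a mandatory column."""


class RecordValidationError(ValueError):
    """A single record violates an invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


@dataclass
class FarmRecord:
    """One farm's inputs, output and optional component breakdowns."""

    farm_id: str
    farm_type: FarmType
    ewes: int
    labor: float            # hours/year
    variable_cost: float    # EUR/year
    fixed_cost: float       # EUR/year
    gross_revenue: float    # EUR/year

    # revenue components, EUR/year (None = unavailable, e.g. UK subsidies)
    lambs_meat: float | None = None
    lambs_breeding: float | None = None
    culls: float | None = None
    subsidies: float | None = None
    wool_other: float | None = None

    # technical / per-ewe economic fields
    lambs_sold: float | None = None
    alu: float | None = None                    # annual labor units
    feed_kg_dm_per_ewe: float | None = None
    labor_cost: float | None = None             # EUR/ewe
    feed_cost: float | None = None              # EUR/ewe
    purchased_feed: float | None = None         # EUR/ewe
    homegrown_feed: float | None = None         # EUR/ewe
    variable_capital_cost: float | None = None  # EUR/ewe
    fixed_capital_cost: float | None = None     # EUR/ewe

    def __post_init__(self) -> None:
        self.farm_type = FarmType(self.farm_type)
        if self.ewes < 1:
            raise RecordValidationError(f"ewes must be >= 1, got {self.ewes}")
        if self.gross_revenue <= 0:
            raise RecordValidationError(f"gross_revenue must be > 0, got {self.gross_revenue}")
        for name in ("labor", "variable_cost", "fixed_cost"):
            if getattr(self, name) < 0:
                raise RecordValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        comps = [getattr(self, c) for c in REVENUE_COMPONENTS]
        if all(c is not None for c in comps):
            total = sum(comps)
            if not math.isclose(total, self.gross_revenue, rel_tol=_COMPONENT_SUM_RTOL):
                raise RecordValidationError(
                    f"revenue components sum to {total:.2f}, "
                    f"gross_revenue is {self.gross_revenue:.2f}"
                )

    @property
    def inputs(self) -> tuple[float, float, float, float]:
        """The DEA input bundle (ewes, labor, variable cost, fixed cost)."""
        return (float(self.ewes), self.labor, self.variable_cost, self.fixed_cost)

    def components_available(self) -> tuple[str, ...]:
        return tuple(c for c in REVENUE_COMPONENTS if getattr(self, c) is not None)


@dataclass(frozen=True)
class SizeClassScheme:
    """Flock-size class cuts: small < small_upper, medium = [small_upper,
    large_lower] (boundaries inclusive to medium), large > large_lower."""

    farm_type: FarmType
    small_upper: int
    large_lower: int

    def __post_init__(self) -> None:
        if self.small_upper > self.large_lower:
            raise ValueError("small_upper must be <= large_lower")


DEFAULT_SIZE_SCHEMES: dict[FarmType, SizeClassScheme] = {
    FarmType.FRENCH_EXTENSIVE: SizeClassScheme(FarmType.FRENCH_EXTENSIVE, 350, 450),
    FarmType.FRENCH_INTENSIVE: SizeClassScheme(FarmType.FRENCH_INTENSIVE, 350, 450),
    FarmType.SPANISH_SEMI_INTENSIVE: SizeClassScheme(FarmType.SPANISH_SEMI_INTENSIVE, 600, 1000),
    FarmType.UK_EXTENSIVE: SizeClassScheme(FarmType.UK_EXTENSIVE, 400, 900),
}

SIZE_CLASSES = ("small", "medium", "large")


def assign_size_class(record: FarmRecord, scheme: SizeClassScheme) -> str:
    """Deterministic size class of a farm under a scheme; boundary flocks
    (ewes exactly at a cut) fall to medium, matching the printed interval
    labels, e.g. medium = 350-450 ewes for French farms."""
    if record.ewes < scheme.small_upper:
        return "small"
    if record.ewes <= scheme.large_lower:
        return "medium"
    return "large"


_OPTIONAL_COLUMNS = REVENUE_COMPONENTS + TECHNICAL_FIELDS
_ALL_COLUMNS = MANDATORY_COLUMNS[:1] + ("farm_type",) + MANDATORY_COLUMNS[1:] + _OPTIONAL_COLUMNS


def read_farm_table(path: str | Path, farm_type: FarmType | str | None = None) -> list[FarmRecord]:
    """Read a comma-separated farm table into validated records (file order).

    The table must name at least the four inputs and the output
    (:data:`MANDATORY_COLUMNS`). The farm type comes either from the
    ``farm_type`` argument or from a ``farm_type`` column. Empty optional
    fields are read as absent, not zero.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"farm_id": str}, skipinitialspace=True, float_precision="round_trip"
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    if farm_type is None and "farm_type" not in df.columns:
        raise SchemaError(f"{path.name}: no farm_type column and no farm_type argument")

    records: list[FarmRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        kwargs: dict = {}
        for col in MANDATORY_COLUMNS + ("farm_type",) + _OPTIONAL_COLUMNS:
            if col == "farm_type":
                continue
            if col not in df.columns:
                continue
            raw = getattr(row, col)
            if col == "farm_id":
                kwargs[col] = str(raw)
                continue
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                if col in MANDATORY_COLUMNS:
                    raise RecordValidationError(f"missing value in column '{col}'", row=row_idx)
                continue
            try:
                value = int(raw) if col == "ewes" else float(raw)
            except (TypeError, ValueError) as exc:
                raise RecordValidationError(
                    f"unparseable numeric in column '{col}': {raw!r}", row=row_idx
                ) from exc
            kwargs[col] = value
        ftype = farm_type if farm_type is not None else getattr(row, "farm_type")
        try:
            records.append(FarmRecord(farm_type=FarmType(ftype), **kwargs))
        except RecordValidationError as exc:
            raise RecordValidationError(str(exc), row=row_idx) from exc
    return records


def write_farm_table(records: Iterable[FarmRecord], path: str | Path) -> None:
    """Write records as UTF-8 comma-separated text ('.' decimal mark, header
    row, absent optionals as empty fields). Numeric fields use repr-exact
    serialization so a write/read round trip reproduces them bit for bit."""
    rows = []
    for rec in records:
        row = {}
        for f in dc_fields(FarmRecord):
            val = getattr(rec, f.name)
            if isinstance(val, FarmType):
                val = val.value
            if val is None:
                val = ""
            elif isinstance(val, float):
                val = repr(val)  # shortest round-trip representation
            row[f.name] = val
        rows.append(row)
    df = pd.DataFrame(rows, columns=[f.name for f in dc_fields(FarmRecord)])
    df.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Sequence[FarmRecord]) -> pd.DataFrame:
    """Records as a DataFrame (absent optionals become NaN)."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in dc_fields(FarmRecord)} for r in records]
    )
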