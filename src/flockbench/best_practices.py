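"""Best-practice catalog and adoption tabulations for efficient farms.

The catalog groups named management/production practices into nine
categories (feeding, breeding, gadgets and applications, product
marketing, information and training, reproduction, human resources
organization, health, product processing). Adoption is tabulated two
ways: per category (how many efficient farms selected at least one
practice of the category, and how many distinct practices were selected)
and as a pooled per-practice frequency ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PracticeCatalog",
    "PracticeSelection",
    "default_catalog",
    "category_adoption",
    "practice_frequency_ranking",
    "read_selection_matrix",
    "write_selection_matrix",
]


@dataclass(frozen=True)
class PracticeCatalog:
    """Ordered categories, each holding an ordered list of named practices."""

    categories: tuple[str, ...]
    practices: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category names must be unique")
        for cat in self.categories:
            plist = self.practices.get(cat, ())
            if len(set(plist)) != len(plist):
                raise ValueError(f"duplicate practice names in category {cat!r}")
        extra = set(self.practices) - set(self.categories)
        if extra:
            raise ValueError(f"practices listed for unknown categories: {sorted(extra)}")

    def items(self) -> list[tuple[str, str]]:
        """All (category, practice) pairs in catalog order."""
        return [(c, p) for c in self.categories for p in self.practices.get(c, ())]

    def __contains__(self, item: tuple[str, str]) -> bool:
        cat, prac = item
        return cat in self.categories and prac in self.practices.get(cat, ())


_DEFAULT_ITEMS: dict[str, tuple[str, ...]] = {
    "Feeding": (
        "Understanding of matching animal requirements and supply",
        "Increased forage quality",
        "Innovative grazing practices",
        "Increased pasture quality",
        "Use of by-products to replace conventional feeds",
    ),
    "Breeding": (
        "Use of elite flocks",
        "System/criteria to choose best animals for replacement",
        "Routine data collection",
        "DNA data collection and use in programs",
    ),
    "Gadgets and Applications": (
        "Electronic identification systems",
        "On-farm data collection linked to animal ID for decision making",
    ),
    "Product marketing": (
        "Certification of products",
        "Branding of products for more local and direct markets",
    ),
    "Information and training": (
        "Access to abattoir feedback on carcass quality and health",
        "Computer farm management programs",
    ),
    "Reproduction": (
        "Assisted reproduction techniques",
        "Improved rams and reproduction plans",
    ),
    "Human resources organization": (
        "Staff training courses/regular meetings to get feedback",
        "Monitorization of labour costs/efficiency",
    ),
    "Health": ("Scientific proven use of antibiotic alternatives in feeding",),
    "Product processing": (),
}


def default_catalog() -> PracticeCatalog:
    """The built-in catalog: 9 categories, 20 named practices (the product
    processing category carries no named practice by default); extensible
    by constructing a new :class:`PracticeCatalog`."""
    return PracticeCatalog(
        categories=tuple(_DEFAULT_ITEMS), practices={k: v for k, v in _DEFAULT_ITEMS.items()}
    )


@dataclass
class PracticeSelection:
    """The set of (category, practice) items one farm flagged."""

    farm_id: str
    flags: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def validate(self, catalog: PracticeCatalog) -> None:
        for item in self.flags:
            if item not in catalog:
                raise ValueError(f"farm {self.farm_id}: unknown practice {item!r}")


def category_adoption(
    selections: Sequence[PracticeSelection], catalog: PracticeCatalog
) -> pd.DataFrame:
    """Per-category adoption among the given (efficient) farms.

    Returns one row per category, descending by the number of farms that
    selected at least one practice of the category (stable in catalog
    order on ties), with the number of distinct practices selected.
    """
    for sel in selections:
        sel.validate(catalog)
    rows = []
    for cat in catalog.categories:
        farms = sum(
            1 for sel in selections if any(item[0] == cat for item in sel.flags)
        )
        distinct = len(
            {item[1] for sel in selections for item in sel.flags if item[0] == cat}
        )
        rows.append({"category": cat, "farms_selecting": farms,
                     "distinct_practices": distinct, "n_farms": len(selections)})
    frame = pd.DataFrame(rows)
    return frame.sort_values("farms_selecting", ascending=False, kind="stable").reset_index(
        drop=True
    )


def practice_frequency_ranking(
    selections: Sequence[PracticeSelection],
    catalog: PracticeCatalog,
    total_farms: int | None = None,
) -> pd.DataFrame:
    """Pooled per-practice ranking across efficient farms.

    One row per catalog practice, descending by adopting-farm count; ties
    keep catalog order (stable sort). ``share_pct`` is count / total
    efficient farms (default: number of selections given).
    """
    for sel in selections:
        sel.validate(catalog)
    total = total_farms if total_farms is not None else len(selections)
    rows = []
    for cat, prac in catalog.items():
        count = sum(1 for sel in selections if (cat, prac) in sel.flags)
        rows.append(
            {
                "category": cat,
                "practice": prac,
                "count": count,
                "total_farms": total,
                "share_pct": 100.0 * count / total if total else float("nan"),
            }
        )
    frame = pd.DataFrame(rows, columns=["category", "practice", "count", "total_farms", "share_pct"])
    return frame.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)


def _column_name(cat: str, prac: str) -> str:
    return f"{cat}.{prac}"


def write_selection_matrix(
    selections: Iterable[PracticeSelection], catalog: PracticeCatalog, path: str | Path
) -> None:
    """Write selections as a delimited boolean matrix (rows = farms,
    columns = 'category.practice', values 0/1)."""
    cols = [_column_name(c, p) for c, p in catalog.items()]
    rows = []
    for sel in selections:
        row = {"farm_id": sel.farm_id}
        for (c, p), col in zip(catalog.items(), cols):
            row[col] = int((c, p) in sel.flags)
        rows.append(row)
    pd.DataFrame(rows, columns=["farm_id", *cols]).to_csv(path, index=False)


def read_selection_matrix(path: str | Path, catalog: PracticeCatalog) -> list[PracticeSelection]:
    """Read a boolean selection matrix written by :func:`write_selection_matrix`."""
    df = pd.read_csv(path, dtype={"farm_id": str})
    name_to_item = {_column_name(c, p): (c, p) for c, p in catalog.items()}
    unknown = [c for c in df.columns if c != "farm_id" and c not in name_to_item]
    if unknown:
        raise ValueError(f"selection matrix references unknown practices: {unknown}")
    out = []
    for _, row in df.iterrows():
        flags = frozenset(
            name_to_item[col] for col in df.columns if col != "farm_id" and row[col]
        )
        out.append(PracticeSelection(farm_id=str(row["farm_id"]), flags=flags))
    return out
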