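"""Synthetic farm populations with known-truth technical efficiency.

Construction
------------
All farms of a type share one input-profile ray: the per-ewe bundle
(1 ewe, h hours of labor, v EUR variable cost, f EUR fixed capital cost)
taken from the type's calibration, so a farm of size z ewes uses inputs
z * (1, h, v, f), optionally inflated input-by-input by nonnegative
factors (1 + u_k) with u_ewes = 0. Flock size is therefore always the
binding input and the production frontier lives in the (ewes, revenue)
plane.

Frontier anchors are farms placed exactly on a concave increasing curve
y = c0 + a * z^b (b in (0,1); c0 > 0 gives the variable-returns-to-scale
intercept), sampled at flock sizes spanning the population including both
extremes. The operative frontier is the piecewise-linear interpolation of
the anchor points — exactly the VRS DEA hull of the anchors. Every other
farm's output is TE_true times the hull value at its flock size, with
TE_true drawn from a rescaled Beta distribution on [te_min, 1] and a
calibrated number of farms forced to TE_true = 1 (these get u = 0 so they
are strongly efficient).

Because the estimated and true frontiers coincide whenever the anchors
are in the sample, DEA recovers TE_true exactly (to LP tolerance) — the
recovery property is structural, not statistical. Revenue components are
drawn to match the calibrated composition shares with multiplicative
noise and sum exactly to gross revenue; per-ewe cost fields are derived
from the farm's actual generated inputs so the production-cost identities
hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .best_practices import PracticeCatalog, PracticeSelection, default_catalog
from .calibration import CALIBRATIONS, FarmTypeCalibration
from .farm_records import FarmRecord, FarmType

__all__ = ["SyntheticSpec", "default_spec", "generate_population", "generate_practice_matrix"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything the generator needs; defaults come from the calibration."""

    farm_type: FarmType
    n: int
    seed: int
    frontier_anchor_count: int = 12
    frontier_exponent: float = 0.9       # b in y = c0 + a z^b
    intercept_fraction: float = 0.05     # c0 as fraction of frontier at mean size
    te_min: float = 0.31
    beta_alpha: float = 2.0
    beta_beta: float = 2.0
    efficient_count: int = 25
    size_counts: tuple[int, int, int] = (80, 45, 116)
    size_ranges: tuple[tuple[int, int], ...] = ((120, 349), (350, 450), (451, 1079))
    input_inflation_max: float = 0.25    # u_k upper bound for inefficient farms
    share_noise_sigma: float = 0.15
    technical_noise_sigma: float = 0.10
    calibration: FarmTypeCalibration = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.calibration is None:
            object.__setattr__(self, "calibration", CALIBRATIONS[FarmType(self.farm_type)])
        if not 0 < self.te_min < 1:
            raise ValueError("te_min must be in (0, 1)")
        if not 0 < self.frontier_exponent < 1:
            raise ValueError("frontier exponent must be in (0, 1)")
        if self.frontier_anchor_count < 5:  # m + 1 for the four-input model
            raise ValueError("need at least m+1=5 frontier anchors")
        if self.n < self.frontier_anchor_count:
            raise ValueError("n must be >= frontier_anchor_count")
        if self.efficient_count < self.frontier_anchor_count:
            raise ValueError("efficient_count must cover the anchors")
        if sum(self.size_counts) != self.n:
            raise ValueError("size class counts must sum to n")


def default_spec(farm_type: FarmType | str, seed: int, n: int | None = None) -> SyntheticSpec:
    """The study-condition spec for a farm type: the calibrated sample size,
    size-class counts, TE range and inefficient-group mean.

    ``n`` may override the sample size (class counts are then rescaled
    proportionally and the efficient count likewise).
    """
    cal = CALIBRATIONS[FarmType(farm_type)]
    # Beta mean chosen so the inefficient-group mean TE matches the calibration
    mu = (cal.te_inefficient_mean - cal.te_min) / (1.0 - cal.te_min)
    alpha = 2.0
    beta = alpha * (1.0 - mu) / mu
    counts = cal.size_counts
    eff = cal.efficient_count
    total = cal.n
    if n is not None and n != cal.n:
        scale = n / cal.n
        counts = tuple(max(1, round(c * scale)) for c in cal.size_counts)
        # absorb rounding drift into the largest class
        drift = n - sum(counts)
        big = int(np.argmax(counts))
        counts = tuple(c + drift if i == big else c for i, c in enumerate(counts))
        eff = max(12, round(eff * scale))
        total = n
    return SyntheticSpec(
        farm_type=FarmType(farm_type),
        n=total,
        seed=seed,
        te_min=cal.te_min,
        beta_alpha=alpha,
        beta_beta=beta,
        efficient_count=eff,
        size_counts=counts,  # type: ignore[arg-type]
        size_ranges=cal.size_ranges,
        calibration=cal,
    )


def _frontier_params(spec: SyntheticSpec, z_ref: float) -> tuple[float, float]:
    """(c0, a) such that the smooth frontier at the mean flock size equals the
    calibrated average revenue divided by the calibrated mean TE."""
    cal = spec.calibration
    f_ref = cal.revenue_per_ewe * z_ref / cal.te_overall_mean
    c0 = spec.intercept_fraction * f_ref
    a = (f_ref - c0) / z_ref ** spec.frontier_exponent
    return c0, a


def generate_population(spec: SyntheticSpec) -> tuple[list[FarmRecord], np.ndarray]:
    """Generate one farm type's population and its true efficiencies.

    Returns (records, te_true); records are in generation order and
    deterministic under the spec's seed. The frontier hull is spanned by
    the anchor farms, so a DEA run on the full population recovers
    te_true exactly (up to LP tolerance).
    """
    rng = np.random.default_rng(spec.seed)
    cal = spec.calibration

    # flock sizes per calibrated size class
    ewes = np.concatenate(
        [
            rng.integers(lo, hi + 1, size=cnt)
            for cnt, (lo, hi) in zip(spec.size_counts, spec.size_ranges)
        ]
    ).astype(float)
    rng.shuffle(ewes)
    n = spec.n

    # anchors: farms nearest to evenly spaced size quantiles, extremes included
    order = np.argsort(ewes)
    targets = np.linspace(0, n - 1, spec.frontier_anchor_count).round().astype(int)
    anchor_idx = np.unique(order[targets])
    while anchor_idx.size < spec.frontier_anchor_count:
        extra = rng.integers(0, n)
        if extra not in anchor_idx:
            anchor_idx = np.sort(np.append(anchor_idx, extra))

    c0, a = _frontier_params(spec, float(ewes.mean()))
    z_anchor = np.sort(ewes[anchor_idx])
    f_anchor = c0 + a * z_anchor ** spec.frontier_exponent

    def hull(z: np.ndarray) -> np.ndarray:
        return np.interp(z, z_anchor, f_anchor)

    # efficient farms: all anchors plus randomly chosen extras, TE_true = 1
    te_true = np.empty(n)
    is_eff = np.zeros(n, dtype=bool)
    is_eff[anchor_idx] = True
    pool = np.flatnonzero(~is_eff)
    n_extra = spec.efficient_count - anchor_idx.size
    if n_extra > 0:
        is_eff[rng.choice(pool, size=n_extra, replace=False)] = True
    te_true[is_eff] = 1.0
    n_ineff = int((~is_eff).sum())
    draws = rng.beta(spec.beta_alpha, spec.beta_beta, size=n_ineff)
    te_true[~is_eff] = spec.te_min + (1.0 - spec.te_min) * draws

    gross_revenue = te_true * hull(ewes)

    # inputs along the type ray; inefficient farms get nonnegative inflation
    w = np.asarray(cal.input_weights)
    u = np.zeros((n, 4))
    u[~is_eff, 1:] = rng.uniform(0.0, spec.input_inflation_max, size=(n_ineff, 3))
    X = ewes[:, None] * w[None, :] * (1.0 + u)

    records: list[FarmRecord] = []
    share_names = list(cal.revenue_shares)
    base_shares = np.array([cal.revenue_shares[c] for c in share_names])
    for i in range(n):
        noisy = base_shares * np.exp(
            rng.normal(0.0, spec.share_noise_sigma, size=base_shares.size)
        )
        shares = noisy / noisy.sum()
        comps = shares * gross_revenue[i]
        if np.any(comps < 0):
            raise ValueError("infeasible calibration: negative revenue component")
        comps[-1] = gross_revenue[i] - comps[:-1].sum()  # sum exactly
        comp_map = dict(zip(share_names, comps))

        labor_hours = X[i, 1]
        variable_cost = X[i, 2]
        fixed_cost = X[i, 3]
        wage = cal.labor_cost / cal.hours_per_ewe
        feed_share = cal.feed_cost / cal.variable_cost_per_ewe
        purchased_share = cal.purchased_feed / cal.feed_cost
        var_per_ewe = variable_cost / ewes[i]
        feed_cost = feed_share * var_per_ewe
        purchased = purchased_share * feed_cost
        lpe = cal.lambs_per_ewe * np.exp(rng.normal(0.0, spec.technical_noise_sigma))
        alu = labor_hours / (
            1800.0 * np.exp(rng.normal(0.0, spec.technical_noise_sigma))
        )
        records.append(
            FarmRecord(
                farm_id=f"{spec.farm_type.value}-{i:04d}",
                farm_type=spec.farm_type,
                ewes=int(ewes[i]),
                labor=float(labor_hours),
                variable_cost=float(variable_cost),
                fixed_cost=float(fixed_cost),
                gross_revenue=float(gross_revenue[i]),
                **{k: float(v) for k, v in comp_map.items()},
                lambs_sold=float(np.round(lpe * ewes[i])),
                alu=float(alu),
                feed_kg_dm_per_ewe=float(
                    cal.feed_kg_dm_per_ewe
                    * np.exp(rng.normal(0.0, spec.technical_noise_sigma))
                ),
                labor_cost=float(labor_hours / ewes[i] * wage),
                feed_cost=float(feed_cost),
                purchased_feed=float(purchased),
                homegrown_feed=float(feed_cost - purchased),
                variable_capital_cost=float(var_per_ewe - feed_cost),
                fixed_capital_cost=float(fixed_cost / ewes[i]),
            )
        )
    return records, te_true


def generate_practice_matrix(
    spec: SyntheticSpec,
    efficient_ids: Sequence[str],
    catalog: PracticeCatalog | None = None,
) -> list[PracticeSelection]:
    """Bernoulli practice flags for the efficient farms of one type.

    The per-practice flag probability p within a category with c practices
    and calibrated category-level adoption rate r solves 1-(1-p)^c = r, so
    the chance a farm flags at least one practice of the category is r.
    Deterministic under the spec's seed (independent stream from the
    population draw). Farm types without survey coverage (no calibrated
    rates) yield an empty list.
    """
    catalog = catalog or default_catalog()
    rates = spec.calibration.practice_rates
    if rates is None:
        return []
    for cat, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"adoption rate for {cat!r} outside [0, 1]: {r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))
    selections = []
    for fid in efficient_ids:
        flags = set()
        for cat in catalog.categories:
            practices = catalog.practices.get(cat, ())
            r = rates.get(cat, 0.0)
            if not practices or r <= 0.0:
                continue
            p = 1.0 - (1.0 - r) ** (1.0 / len(practices))
            for prac in practices:
                if rng.random() < p:
                    flags.add((cat, prac))
        selections.append(PracticeSelection(farm_id=str(fid), flags=frozenset(flags)))
    return selections
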