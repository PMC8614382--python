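"""Output-oriented variable-returns-to-scale DEA envelopment solver.

For each decision-making unit (DMU) *i* with inputs x_i (length m) and
single output y_i, the radial phase solves

    max  theta
    s.t. sum_j lambda_j y_j  >= theta * y_i
         sum_j lambda_j x_kj <= x_ki          k = 1..m
         sum_j lambda_j = 1,  lambda_j >= 0

The convexity row (sum of intensity weights = 1) gives variable returns to
scale. Technical efficiency is TE = 1/theta, so TE = 1 on the frontier.

A second phase maximizes the total slack at the optimal theta, so the
frontier projection of a weakly efficient unit moves to the strongly
efficient subset: projected output = theta*y_i + s_out, projected inputs =
x_i - s. Both phases are single LPs solved with HiGHS via scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .farm_records import FarmRecord

__all__ = [
    "DEAProblem",
    "SolverSettings",
    "DEAResult",
    "DEASolverError",
    "solve_theta",
    "maximize_slacks",
    "compute_te",
    "project_to_frontier",
    "solve_all",
    "results_to_frame",
]


class DEASolverError(RuntimeError):
    """LP failure for one DMU; carries the DMU index and solver status."""

    def __init__(self, dmu: int, status: object, message: str):
        self.dmu = dmu
        self.status = status
        super().__init__(f"DMU {dmu}: {message} (solver status: {status})")


@dataclass(frozen=True)
class DEAProblem:
    """An m-input, single-output envelopment problem over n DMUs.

    X is m-by-n (inputs in rows, DMUs in columns), y has length n.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[1] != y.shape[0]:
            raise ValueError(f"X is {X.shape}, y has length {y.shape[0]}: shapes disagree")
        if y.shape[0] < 1:
            raise ValueError("need at least one DMU")
        if np.any(y <= 0):
            raise ValueError("all outputs must be positive")
        if np.any(X < 0):
            raise ValueError("inputs must be nonnegative")
        if np.any(X.max(axis=0) <= 0):
            raise ValueError("every DMU needs at least one positive input")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_records(cls, records: Sequence[FarmRecord]) -> "DEAProblem":
        """Build the four-input problem (ewes, labor, variable cost, fixed
        capital cost -> gross revenue) from farm records of one type."""
        X = np.array([rec.inputs for rec in records], dtype=float).T
        y = np.array([rec.gross_revenue for rec in records], dtype=float)
        return cls(X=X, y=y)


@dataclass(frozen=True)
class SolverSettings:
    feasibility_tolerance: float = 1e-7
    efficiency_epsilon: float = 1e-6
    slack_phase: bool = True
    slack_normalization: str = "raw"  # or "input-mean-scaled"

    def __post_init__(self) -> None:
        for name in ("feasibility_tolerance", "efficiency_epsilon"):
            v = getattr(self, name)
            if not 0 < v < 1e-3:
                raise ValueError(f"{name} must be in (0, 1e-3), got {v}")
        if self.slack_normalization not in ("raw", "input-mean-scaled"):
            raise ValueError(f"unknown slack_normalization {self.slack_normalization!r}")


@dataclass
class DEAResult:
    """Per-DMU scores, peers, slacks and the frontier projection."""

    dmu_index: int
    theta: float
    te: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slack: float
    projected_output: float
    projected_inputs: np.ndarray
    is_efficient: bool

    def reference_set(self, tol: float = 1e-7) -> list[int]:
        """Indices of peer DMUs with intensity weight above tol."""
        return [int(j) for j in np.flatnonzero(self.lambdas > tol)]


def _check_index(problem: DEAProblem, i: int) -> None:
    if not 0 <= i < problem.n:
        raise IndexError(f"DMU index {i} out of range for n={problem.n}")


def solve_theta(
    problem: DEAProblem, i: int, settings: SolverSettings = SolverSettings()
) -> tuple[float, np.ndarray]:
    """Phase 1: the maximal radial output expansion for DMU i.

    Returns (theta, lambdas) attaining it. theta >= 1 always: the DMU
    itself (lambda_i = 1) is feasible.
    """
    _check_index(problem, i)
    X, y, n, m = problem.X, problem.y, problem.n, problem.m
    # variables z = (theta, lambda_1..lambda_n); minimize -theta
    c = np.zeros(n + 1)
    c[0] = -1.0
    A_ub = np.zeros((m + 1, n + 1))
    b_ub = np.zeros(m + 1)
    # theta*y_i - sum lambda_j y_j <= 0
    A_ub[0, 0] = y[i]
    A_ub[0, 1:] = -y
    # sum lambda_j x_kj <= x_ki
    A_ub[1:, 1:] = X
    b_ub[1:] = X[:, i]
    A_eq = np.zeros((1, n + 1))
    A_eq[0, 1:] = 1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0, None)] * (n + 1),
        method="highs",
    )
    if not res.success:
        raise DEASolverError(i, res.status, f"radial phase failed: {res.message}")
    theta = float(res.x[0])
    if theta < 1.0 - settings.feasibility_tolerance:
        raise DEASolverError(i, res.status, f"theta {theta} below 1: self-envelopment violated")
    return max(theta, 1.0), res.x[1:].copy()


def maximize_slacks(
    problem: DEAProblem,
    i: int,
    theta_fixed: float,
    settings: SolverSettings = SolverSettings(),
) -> tuple[np.ndarray, float, np.ndarray]:
    """Phase 2: maximize total slack holding the radial expansion fixed.

    Solves  max  sum_k w_k s_k + w_out s_out
            s.t. sum lambda_j y_j  - s_out = theta_fixed * y_i
                 sum lambda_j x_kj + s_k   = x_ki
                 sum lambda_j = 1, all variables >= 0

    with unit weights by default; 'input-mean-scaled' weights each input
    slack by 1/mean(x_k) so heterogeneous units (head, hours, EUR) are
    commensurable. Returns (input_slacks, output_slack, lambdas).
    """
    _check_index(problem, i)
    X, y, n, m = problem.X, problem.y, problem.n, problem.m
    # variables z = (lambda_1..n, s_1..m, s_out)
    nv = n + m + 1
    if settings.slack_normalization == "input-mean-scaled":
        xbar = X.mean(axis=1)
        w_in = np.where(xbar > 0, 1.0 / np.where(xbar > 0, xbar, 1.0), 1.0)
        w_out = 1.0 / y.mean()
    else:
        w_in = np.ones(m)
        w_out = 1.0
    c = np.zeros(nv)
    c[n : n + m] = -w_in
    c[n + m] = -w_out
    A_eq = np.zeros((m + 2, nv))
    b_eq = np.zeros(m + 2)
    A_eq[0, :n] = y
    A_eq[0, n + m] = -1.0
    b_eq[0] = theta_fixed * y[i]
    for k in range(m):
        A_eq[1 + k, :n] = X[k]
        A_eq[1 + k, n + k] = 1.0
        b_eq[1 + k] = X[k, i]
    A_eq[m + 1, :n] = 1.0
    b_eq[m + 1] = 1.0
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * nv, method="highs")
    if not res.success:
        raise DEASolverError(
            i, res.status, f"slack phase infeasible at theta={theta_fixed}: {res.message}"
        )
    lambdas = res.x[:n].copy()
    slacks = np.maximum(res.x[n : n + m], 0.0) + 0.0  # +0.0 normalizes -0.0
    s_out = float(res.x[n + m])
    s_out = 0.0 if s_out <= 0.0 else s_out
    return slacks, s_out, lambdas


def compute_te(theta: float) -> float:
    """Technical efficiency TE = 1/theta, clamped into (0, 1]."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    return min(1.0 / theta, 1.0)


def project_to_frontier(record_output: float, theta: float, output_slack: float = 0.0) -> float:
    """Frontier (efficient-target) output y* = theta*y + output slack."""
    return theta * record_output + output_slack


def solve_all(
    problem: DEAProblem, settings: SolverSettings = SolverSettings()
) -> list[DEAResult]:
    """Solve both phases for every DMU. Deterministic given problem and
    settings; errors propagate with the DMU index attached."""
    results: list[DEAResult] = []
    for i in range(problem.n):
        theta, lambdas = solve_theta(problem, i, settings)
        if settings.slack_phase:
            slacks, s_out, lambdas = maximize_slacks(problem, i, theta, settings)
        else:
            slacks = np.zeros(problem.m)
            s_out = 0.0
        te = compute_te(theta)
        proj_y = project_to_frontier(problem.y[i], theta, s_out)
        proj_x = np.maximum(problem.X[:, i] - slacks, 0.0)
        scale = np.maximum(np.abs(problem.X[:, i]), 1.0)
        slack_free = bool(
            np.all(slacks <= 1e-5 * scale) and s_out <= 1e-5 * max(problem.y[i], 1.0)
        )
        results.append(
            DEAResult(
                dmu_index=i,
                theta=theta,
                te=te,
                lambdas=lambdas,
                input_slacks=slacks,
                output_slack=s_out,
                projected_output=proj_y,
                projected_inputs=proj_x,
                is_efficient=te >= 1.0 - settings.efficiency_epsilon and slack_free,
            )
        )
    return results


def results_to_frame(results: Sequence[DEAResult]) -> pd.DataFrame:
    """Flatten results to one row per DMU (machine-readable report form)."""
    rows = []
    for r in results:
        row = {
            "dmu_index": r.dmu_index,
            "theta": r.theta,
            "te": r.te,
            "output_slack": r.output_slack,
            "projected_output": r.projected_output,
            "is_efficient": r.is_efficient,
            "reference_set": ";".join(map(str, r.reference_set())),
        }
        for k, s in enumerate(r.input_slacks):
            row[f"input_slack_{k}"] = s
        for k, px in enumerate(r.projected_inputs):
            row[f"projected_input_{k}"] = px
        rows.append(row)
    return pd.DataFrame(rows)
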