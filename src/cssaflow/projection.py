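"""Deterministic projection of per-age recipient proportions.

The population at each age i is split between two states, in-system
(proportion x(i)) and out-of-system (y(i) = 1 - x(i)). Over one year a
non-recipient aged i enters with probability p(i) and a recipient leaves
with probability q(i), while everyone ages one year:

    (x_{t+1}(i+1), y_{t+1}(i+1))' = A(i) (x_t(i), y_t(i))',
    A(i) = [[1 - q(i), p(i)], [q(i), 1 - p(i)]]

A(i) is column-stochastic, so x + y = 1 is conserved exactly. Age 0 at
t+1 is fed by births: newborns to in-system mothers are themselves
in-system, and both states share the same age-specific birth rates b(i),
so the newborn proportion is a b-weighted average of the mothers' x. The
oldest modelled age leaves the window (censoring, not exit). Mortality and
migration are ignored below the age cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .schedules import (
    AgeGrid,
    BirthSchedule,
    PopulationWeights,
    TransitionSchedule,
    ValidationError,
)

__all__ = [
    "StateDistribution",
    "ProjectionResult",
    "transition_matrix",
    "project_scalar",
    "newborn_state",
    "project_step",
    "overall_proportion",
    "project",
]

NewbornMode = Literal["literal", "weighted"]


@dataclass(frozen=True)
class StateDistribution:
    """Per-age recipient proportions x(i) at one time period.

    The non-recipient proportions y(i) = 1 - x(i) are implicit, so the
    two-state split sums to one by construction.
    """

    x: np.ndarray
    grid: AgeGrid = field(default_factory=AgeGrid)
    time_label: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (self.grid.max_age,):
            raise ValidationError(
                f"x must have one value per age (expected length {self.grid.max_age}, got {x.shape})"
            )
        bad = np.flatnonzero(~((x >= 0.0) & (x <= 1.0)))
        if bad.size:
            raise ValidationError(f"x outside [0, 1] at ages {bad.tolist()}")
        object.__setattr__(self, "x", x)

    @property
    def y(self) -> np.ndarray:
        return 1.0 - self.x


@dataclass(frozen=True)
class ProjectionResult:
    """Trajectory of states and overall proportions X over a projection run."""

    states: tuple[StateDistribution, ...]
    overall: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) != len(self.overall):
            raise ValidationError("states and overall must have equal length")

    def to_frame(self):
        """Long-format DataFrame: one row per (period, age), plus overall X."""
        import pandas as pd

        rows = []
        for t, st in enumerate(self.states):
            for i, xi in enumerate(st.x):
                rows.append((t, i, xi, self.overall[t]))
        return pd.DataFrame(rows, columns=["period", "age", "x", "overall_X"])


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)


def transition_matrix(p: float, q: float) -> np.ndarray:
    """One-age annual transition matrix acting on the column (x, y).

    Columns each sum to 1: the first column moves recipients (stay with
    probability 1-q, exit with q), the second moves non-recipients (enter
    with p, stay out with 1-p).
    """
    p = _check_prob("p", p)
    q = _check_prob("q", q)
    return np.array([[1.0 - q, p], [q, 1.0 - p]])


def project_scalar(x0: float, p: float, q: float, steps: int) -> np.ndarray:
    """Iterate the age-homogeneous recursion x' = (1-q) x + p (1-x).

    Returns the trajectory (x0, x1, ..., x_steps); the fixed point is
    p / (p + q) whenever p + q > 0.
    """
    x0 = _check_prob("x0", x0)
    p = _check_prob("p", p)
    q = _check_prob("q", q)
    if steps < 0:
        raise ValidationError(f"steps must be >= 0, got {steps}")
    out = np.empty(steps + 1)
    out[0] = x0
    for t in range(steps):
        out[t + 1] = (1.0 - q) * out[t] + p * (1.0 - out[t])
    return out


def newborn_state(
    x: StateDistribution,
    bs: BirthSchedule,
    pw: PopulationWeights | None = None,
    mode: NewbornMode = "literal",
) -> float:
    """Recipient proportion among newborns entering age 0 next period.

    Newborns inherit their mother's state and both states share the birth
    rates b(i), so the newborn split is a b-weighted average of the
    mothers' split, normalised to a proportion:

    - ``literal``:  sum_i b(i) x(i) / sum_i b(i)
    - ``weighted``: sum_i b(i) w(i) x(i) / sum_i b(i) w(i)  (accounts for
      mothers' cohort sizes via the population weights)
    """
    if x.grid != bs.grid:
        raise ValidationError("state and birth schedule are on different grids")
    if mode == "literal":
        weights = bs.b
    elif mode == "weighted":
        if pw is None:
            raise ValidationError("weighted newborn mode requires population weights")
        if pw.grid != bs.grid:
            raise ValidationError("weights and birth schedule are on different grids")
        weights = bs.b * pw.w
    else:
        raise ValidationError(f"unknown newborn mode {mode!r}")
    denom = weights.sum()
    if denom <= 0.0:
        raise ValidationError("all-zero birth schedule: newborn composition undefined")
    return float(weights @ x.x / denom)


def project_step(
    x: StateDistribution,
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights | None = None,
    newborn_mode: NewbornMode = "literal",
) -> StateDistribution:
    """Advance the per-age state one year.

    Ageing and transition are simultaneous: the state at age i determines
    the state at age i+1 one period later. The oldest age of the input
    exits the modelled window; age 0 of the output is the newborn state.
    """
    for name, grid in (("transition schedule", ts.grid), ("birth schedule", bs.grid)):
        if grid != x.grid:
            raise ValidationError(f"{name} grid does not match the state grid")
    if pw is not None and pw.grid != x.grid:
        raise ValidationError("population weights grid does not match the state grid")
    n = x.grid.max_age
    new_x = np.empty(n)
    new_x[1:] = (1.0 - ts.q[: n - 1]) * x.x[: n - 1] + ts.p[: n - 1] * (1.0 - x.x[: n - 1])
    new_x[0] = newborn_state(x, bs, pw, newborn_mode)
    # results are convex combinations of probabilities; absorb float roundoff only
    np.clip(new_x, 0.0, 1.0, out=new_x)
    return StateDistribution(new_x, x.grid, x.time_label + 1)


def overall_proportion(x: StateDistribution, pw: PopulationWeights) -> float:
    """Population-weighted overall recipient proportion X = sum_i x(i) w(i)."""
    if x.grid != pw.grid:
        raise ValidationError("state and weights are on different grids")
    return float(x.x @ pw.w)


def project(
    x0: StateDistribution,
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    horizon: int,
    newborn_mode: NewbornMode = "literal",
) -> ProjectionResult:
    """Run ``horizon`` annual steps, recording X each period (incl. period 0)."""
    if horizon < 0:
        raise ValidationError(f"horizon must be >= 0, got {horizon}")
    states = [x0]
    for _ in range(horizon):
        states.append(project_step(states[-1], ts, bs, pw, newborn_mode))
    overall = np.array([overall_proportion(st, pw) for st in states])
    return ProjectionResult(tuple(states), overall)
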