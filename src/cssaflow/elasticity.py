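"""Sensitivity of the overall recipient proportion to group transition rates.

Two policy levers exist for every age group: lower its entry probability p
("entering approach") or raise its exit probability q ("leaving approach").
Their leverage on the overall proportion X after a projection horizon is
measured two ways:

- rate of change  dX/dtheta, by central finite difference, with the same
  perturbation applied to every single age in the group;
- elasticity      delta = (dX/dtheta) * theta / X, the percentage change in
  X per 1% change in theta — scale-free, and the fairer comparison because
  a 1% change in a tiny p is feasible where an absolute change of the same
  size as a typical q is not.

Over a single step X is affine in each group parameter, so the finite
difference is exact regardless of step size; longer horizons introduce a
mild nonlinearity through compounding and the newborn feedback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .projection import StateDistribution, project
from .schedules import (
    AgeBand,
    BirthSchedule,
    PopulationWeights,
    TransitionSchedule,
    ValidationError,
)

__all__ = [
    "PerturbationSpec",
    "ElasticityResult",
    "rate_of_change",
    "elasticity",
    "classify_approach",
    "elasticity_table",
]

Target = Literal["entering", "leaving"]
StepMode = Literal["relative", "absolute"]

DEFAULT_STEP = 1e-6


@dataclass(frozen=True)
class PerturbationSpec:
    """One finite-difference probe: which parameter, which ages, how far.

    ``step`` is a relative factor (h = step * group value) in relative mode
    or an additive probability in absolute mode. ``horizon`` is the number
    of projection steps after which X is evaluated.
    """

    target: Target
    group: AgeBand
    mode: StepMode = "relative"
    step: float = DEFAULT_STEP
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.target not in ("entering", "leaving"):
            raise ValidationError(f"target must be 'entering' or 'leaving', got {self.target!r}")
        if self.mode not in ("relative", "absolute"):
            raise ValidationError(f"mode must be 'relative' or 'absolute', got {self.mode!r}")
        if self.step <= 0:
            raise ValidationError(f"step must be > 0, got {self.step}")
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")


@dataclass(frozen=True)
class ElasticityResult:
    """Signed sensitivities for one age group (rendered tables use |.|)."""

    group: AgeBand
    rate_of_change_p: float
    rate_of_change_q: float
    elasticity_p: float
    elasticity_q: float
    recommended_approach: str


def _group_slice(group: AgeBand, ts: TransitionSchedule) -> slice:
    if group.end >= ts.grid.max_age:
        raise ValidationError(
            f"group {group.label} extends beyond the grid (max_age={ts.grid.max_age})"
        )
    return slice(group.start, group.end + 1)


def _group_value(theta: np.ndarray, sl: slice) -> float:
    return float(theta[sl].mean())


def _perturbed_schedule(
    ts: TransitionSchedule, spec: PerturbationSpec, h: float
) -> TransitionSchedule:
    sl = _group_slice(spec.group, ts)
    p, q = ts.p.copy(), ts.q.copy()
    theta = p if spec.target == "entering" else q
    theta[sl] += h
    if np.any(theta[sl] < 0.0) or np.any(theta[sl] > 1.0):
        raise ValidationError(
            f"perturbation {h:+g} pushes {spec.target} probability outside [0, 1] "
            f"in group {spec.group.label}; use a smaller step"
        )
    return TransitionSchedule(p, q, ts.grid)


def _step_size(ts: TransitionSchedule, spec: PerturbationSpec) -> float:
    sl = _group_slice(spec.group, ts)
    theta = ts.p if spec.target == "entering" else ts.q
    if spec.mode == "absolute":
        return spec.step
    base = _group_value(theta, sl)
    if base == 0.0:
        raise ValidationError(
            f"relative step undefined: {spec.target} probability is 0 in group "
            f"{spec.group.label}; use absolute mode"
        )
    return spec.step * base


def _final_X(
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    x0: StateDistribution,
    horizon: int,
) -> float:
    return project(x0, ts, bs, pw, horizon).overall[-1]


def rate_of_change(
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    x0: StateDistribution,
    spec: PerturbationSpec,
) -> float:
    """Central finite difference dX/dtheta for one group parameter.

    X is the overall proportion after ``spec.horizon`` projection steps;
    the same additive perturbation h is applied to every single age in the
    group, and the result is (X(theta + h) - X(theta - h)) / (2 h).
    """
    h = _step_size(ts, spec)
    x_hi = _final_X(_perturbed_schedule(ts, spec, +h), bs, pw, x0, spec.horizon)
    x_lo = _final_X(_perturbed_schedule(ts, spec, -h), bs, pw, x0, spec.horizon)
    return (x_hi - x_lo) / (2.0 * h)


def elasticity(
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    x0: StateDistribution,
    spec: PerturbationSpec,
) -> float:
    """Percentage change in X per 1% change in the group parameter.

    delta = (dX/dtheta) * theta_group / X_baseline, evaluated at the
    baseline schedule; zero when the group parameter itself is zero.
    """
    sl = _group_slice(spec.group, ts)
    theta = ts.p if spec.target == "entering" else ts.q
    base = _group_value(theta, sl)
    x_base = _final_X(ts, bs, pw, x0, spec.horizon)
    if x_base == 0.0:
        raise ValidationError("baseline overall proportion X is 0; elasticity undefined")
    if base == 0.0:
        return 0.0
    return rate_of_change(ts, bs, pw, x0, spec) * base / x_base


def classify_approach(elasticity_p: float, elasticity_q: float) -> str:
    """Which lever moves X more per 1% change: entry (p) or exit (q)?

    Compares elasticity magnitudes; exact equality is a tie.
    """
    for name, v in (("elasticity_p", elasticity_p), ("elasticity_q", elasticity_q)):
        if not np.isfinite(v):
            raise ValidationError(f"{name} is not finite")
    ap, aq = abs(elasticity_p), abs(elasticity_q)
    if ap > aq:
        return "Entering"
    if ap < aq:
        return "Leaving"
    return "Tie"


def elasticity_table(
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    x0: StateDistribution,
    groups: Iterable[AgeBand] | None = None,
    horizon: int = 1,
    step: float = DEFAULT_STEP,
    mode: StepMode = "relative",
    signed: bool = False,
) -> pd.DataFrame:
    """Rates of change and elasticities for every group, with approach labels.

    By default reports absolute values (the conventional presentation);
    pass ``signed=True`` to keep signs (entry rates are >= 0, exit rates
    <= 0 in the interior of the state space). Default groups are decadal
    bands tiling the grid.
    """
    if groups is None:
        n = ts.grid.max_age
        groups = [AgeBand(s, min(s + 9, n - 1)) for s in range(0, n, 10)]
    results = []
    for group in groups:
        row: dict[str, float | str] = {"group": group.label}
        vals = {}
        for target, suffix in (("entering", "p"), ("leaving", "q")):
            spec = PerturbationSpec(target=target, group=group, mode=mode, step=step, horizon=horizon)
            rate = rate_of_change(ts, bs, pw, x0, spec)
            elas = elasticity(ts, bs, pw, x0, spec)
            vals[f"rate_{suffix}"] = rate
            vals[f"elasticity_{suffix}"] = elas
        approach = classify_approach(vals["elasticity_p"], vals["elasticity_q"])
        if not signed:
            vals = {k: abs(v) for k, v in vals.items()}
        row.update(vals)
        row["approach"] = approach
        results.append(row)
    return pd.DataFrame(
        results,
        columns=["group", "rate_p", "rate_q", "elasticity_p", "elasticity_q", "approach"],
    )
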