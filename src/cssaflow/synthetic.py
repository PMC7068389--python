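"""Synthetic model inputs and individual-based Monte-Carlo oracles.

The registry extracts behind published entry/exit schedules are rarely
public, so this module generates statistically plausible stand-ins with
the documented qualitative structure: annual exit probabilities far above
entry probabilities at every age, exit hump-shaped with its peak in the
20s, entry elevated in childhood (children enter through their parents'
means test) and low through adulthood, births confined to mothers aged
15-49, and an age pyramid concentrated in working ages.

It also provides two agent-level simulators that realise the same Markov
process individual by individual. They serve as brute-force oracles: their
empirical frequencies converge to the deterministic formulas, so agreement
within Monte-Carlo error is a strong end-to-end check of both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import StateDistribution
from .schedules import (
    AgeGrid,
    BirthSchedule,
    PopulationWeights,
    TransitionSchedule,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "CohortSample",
    "generate_synthetic_inputs",
    "simulate_cohort",
    "simulate_population",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic input generator.

    ``entry_level`` and ``exit_level`` set the adult baseline scales of the
    annual entry and exit probabilities (entry is raised for children, exit
    follows a hump over age); ``tfr`` scales the birth schedule so that the
    per-age rates sum to roughly that many births per person; the defaults
    mirror a low-fertility, means-tested-assistance setting with a few
    percent of the under-60 population in the system.
    """

    seed: int = 0
    max_age: int = 60
    entry_level: float = 0.003
    child_entry_level: float = 0.03
    exit_level: float = 0.16
    tfr: float = 1.2
    pyramid_shape: float = 0.35
    initial_x_level: float = 0.04
    noise: float = 0.1

    def __post_init__(self) -> None:
        if self.max_age < 2:
            raise ValidationError(f"max_age must be >= 2, got {self.max_age}")
        for name in ("entry_level", "child_entry_level", "exit_level", "initial_x_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.tfr <= 0.0:
            raise ValidationError(
                "tfr must be > 0: an all-zero birth schedule leaves the newborn "
                "composition undefined downstream"
            )
        if self.noise < 0.0:
            raise ValidationError(f"noise must be >= 0, got {self.noise}")


@dataclass(frozen=True)
class CohortSample:
    """Simulated first-exit years for one cohort; 0 encodes censored at cutoff."""

    exit_year: np.ndarray
    n: int
    seed: int
    start_age: int

    @property
    def exit_fraction(self) -> float:
        return float(np.mean(self.exit_year > 0))

    @property
    def mean_time(self) -> float:
        """Empirical mean sojourn with censored individuals counted as 0 years."""
        return float(np.mean(self.exit_year))


def _smooth_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Multiplicative log-normal wiggle, mildly smoothed over adjacent ages."""
    z = rng.normal(size=n)
    kernel = np.array([0.25, 0.5, 0.25])
    z = np.convolve(np.pad(z, 1, mode="edge"), kernel, mode="valid")
    return np.exp(scale * z)


def generate_synthetic_inputs(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[TransitionSchedule, BirthSchedule, PopulationWeights, StateDistribution]:
    """Draw a full, mutually consistent input set.

    Deterministic given the seed; the outputs satisfy every schedule
    invariant by construction, with q(i) > p(i) at every age.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.max_age
    ages = np.arange(n)

    # exit: hump with peak around the mid 20s, declining toward the cutoff
    hump = np.exp(-0.5 * ((ages - 25.0) / 18.0) ** 2)
    q = cfg.exit_level * (0.75 + 0.55 * hump) * _smooth_noise(rng, n, cfg.noise)

    # entry: childhood plateau (children enter through their parents) with a
    # smooth decay to a low adult level
    child = np.exp(-np.maximum(ages - 12.0, 0.0) / 6.0)
    p = (cfg.entry_level + (cfg.child_entry_level - cfg.entry_level) * child)
    p = p * _smooth_noise(rng, n, cfg.noise)

    p = np.clip(p, 0.0, 1.0)
    q = np.clip(q, 0.0, 1.0)
    if np.any(q <= p):
        # keep the documented ordering even under extreme noise draws
        q = np.maximum(q, np.minimum(1.0, p * 1.5 + 1e-3))
    ts = TransitionSchedule(p, q, AgeGrid(n))

    # births on the fertile window, bell-shaped around age 30
    lo, hi = 15, min(49, n - 1)
    if lo > hi:
        raise ValidationError(f"grid with max_age={n} has no fertile ages (15-49)")
    b = np.zeros(n)
    fert_ages = np.arange(lo, hi + 1)
    bell = np.exp(-0.5 * ((fert_ages - 30.0) / 6.5) ** 2)
    bell = bell * _smooth_noise(rng, len(fert_ages), cfg.noise)
    b[lo : hi + 1] = cfg.tfr * bell / bell.sum()
    bs = BirthSchedule(b, ts.grid, fertile_range=(lo, hi))

    # age pyramid: slow geometric taper with extra mass in working ages
    w = (1.0 - cfg.pyramid_shape * ages / n) * _smooth_noise(rng, n, cfg.noise / 2.0)
    pw = PopulationWeights(w / w.sum(), ts.grid)

    # initial recipient proportions near the configured level, higher for
    # children than prime-age adults, mirroring the entry pattern
    x0 = cfg.initial_x_level * (0.8 + 0.8 * child) * _smooth_noise(rng, n, cfg.noise / 2.0)
    x0 = np.clip(x0, 0.0, 1.0)
    state = StateDistribution(x0, ts.grid, time_label=0)

    return ts, bs, pw, state


def simulate_cohort(
    q: np.ndarray,
    start_age: int,
    n: int,
    seed: int,
) -> CohortSample:
    """Simulate n recipients of one age until first exit or the cutoff.

    Each individual faces exit probability q(a) in the year they are aged
    a; ``exit_year`` records the waiting time in years (1 = exited within
    the first year), with 0 for those censored at the cutoff.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0.0) | (q > 1.0)):
        raise ValidationError("q outside [0, 1]")
    if not 0 <= start_age < len(q):
        raise ValidationError(f"start_age {start_age} outside the age grid")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    qq = q[start_age:]
    horizon = len(qq)
    exits = rng.random((n, horizon)) < qq  # independent annual exit draws
    any_exit = exits.any(axis=1)
    first = exits.argmax(axis=1) + 1  # 1-based waiting time
    exit_year = np.where(any_exit, first, 0)
    return CohortSample(exit_year=exit_year, n=n, seed=seed, start_age=start_age)


def simulate_population(
    ts: TransitionSchedule,
    bs: BirthSchedule,
    pw: PopulationWeights,
    x0: StateDistribution,
    n: int,
    horizon: int,
    seed: int,
    newborn_mode: str = "literal",
) -> np.ndarray:
    """Agent-level counterpart of :func:`cssaflow.projection.project`.

    Each age slot carries a fixed-size sample of m = n // max_age agents
    whose in-system indicator represents that age's recipient proportion;
    ageing shifts samples up one slot, the oldest sample leaves the window,
    and newborn agents inherit the state of a random agent at a mother age
    drawn proportional to b (literal mode) or b * w (weighted mode).
    Returns the per-period population-weighted overall proportions
    (length horizon + 1, period 0 included).
    """
    for name, grid in (
        ("transition schedule", ts.grid),
        ("birth schedule", bs.grid),
        ("weights", pw.grid),
    ):
        if grid != x0.grid:
            raise ValidationError(f"{name} grid does not match the state grid")
    if horizon < 0:
        raise ValidationError(f"horizon must be >= 0, got {horizon}")
    n_ages = x0.grid.max_age
    m = n // n_ages
    if m < 1:
        raise ValidationError(f"n={n} leaves no agents per age slot (need >= {n_ages})")
    rng = np.random.default_rng(seed)

    if newborn_mode == "literal":
        mother_w = bs.b.copy()
    elif newborn_mode == "weighted":
        mother_w = bs.b * pw.w
    else:
        raise ValidationError(f"unknown newborn mode {newborn_mode!r}")
    if mother_w.sum() <= 0.0:
        raise ValidationError("all-zero birth schedule: newborn composition undefined")
    mother_w = mother_w / mother_w.sum()

    # state[a, j]: True if agent j of the age-a sample is in the system
    state = rng.random((n_ages, m)) < x0.x[:, None]
    overall = np.empty(horizon + 1)
    overall[0] = float(pw.w @ state.mean(axis=1))
    for t in range(horizon):
        u = rng.random((n_ages, m))
        enter = ~state & (u < ts.p[:, None])
        leave = state & (u < ts.q[:, None])
        new_state = np.empty_like(state)
        new_state[1:] = ((state | enter) & ~leave)[:-1]
        mother_age = rng.choice(n_ages, size=m, p=mother_w)
        mother_idx = rng.integers(0, m, size=m)
        new_state[0] = state[mother_age, mother_idx]
        state = new_state
        overall[t + 1] = float(pw.w @ state.mean(axis=1))
    return overall
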