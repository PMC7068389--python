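"""Sojourn-time analysis: first-exit probability and time in system.

For a recipient aged i, each subsequent year j >= i offers an independent
exit chance q(j) until the age cutoff. The probability of exiting at least
once before the cutoff is

    FirstExit(i) = 1 - prod_{j=i}^{max_age-1} (1 - q(j))

and the waiting time K to first exit (in whole years, K = 1 meaning exit
within the first year) has

    Pr(K = k) = q(i + k - 1) * prod_{m=1}^{k-1} (1 - q(i + m - 1)).

Individuals still in the system when they reach the cutoff are censored;
the remaining probability mass is the censoring probability. The headline
``mean_time`` weights each k by Pr(K = k) with censored individuals
contributing zero years — an unconditional mean over the whole cohort with
censored sojourns truncated to 0, not a mean among leavers. The mean among
leavers is exposed separately as ``conditional_mean_time``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .schedules import ValidationError

__all__ = [
    "SojournResult",
    "first_exit_probability",
    "exit_time_pmf",
    "sojourn_table",
]


@dataclass(frozen=True)
class SojournResult:
    """Exit-time distribution for a recipient of one starting age.

    ``exit_pmf[k-1]`` is the probability of first exit in year k,
    k = 1..(max_age - start_age); ``censor_prob`` is the mass still in the
    system at the age cutoff, so the pmf plus censor mass is a full
    distribution. ``mean_time`` counts censored individuals as zero years.
    """

    start_age: int
    first_exit_prob: float
    exit_pmf: np.ndarray
    censor_prob: float
    mean_time: float

    def __post_init__(self) -> None:
        total = float(self.exit_pmf.sum() + self.censor_prob)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"exit pmf + censor mass = {total}, expected 1")

    @property
    def conditional_mean_time(self) -> float:
        """Mean years to first exit among those who do exit before the cutoff.

        Undefined (nan) when exit is impossible.
        """
        if self.first_exit_prob == 0.0:
            return float("nan")
        return self.mean_time / self.first_exit_prob


def _check_q(q: Sequence[float] | np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    bad = np.flatnonzero(~((q >= 0.0) & (q <= 1.0)))
    if bad.size:
        raise ValidationError(f"q outside [0, 1] at ages {bad.tolist()}")
    return q


def _check_start(q: np.ndarray, start_age: int) -> None:
    if not 0 <= start_age < len(q):
        raise ValidationError(
            f"start_age {start_age} outside the age grid [0, {len(q) - 1}]"
        )


def first_exit_probability(q: Sequence[float] | np.ndarray, start_age: int) -> float:
    """Probability of exiting at least once before the age cutoff."""
    q = _check_q(q)
    _check_start(q, start_age)
    return float(1.0 - np.prod(1.0 - q[start_age:]))


def exit_time_pmf(q: Sequence[float] | np.ndarray, start_age: int) -> SojournResult:
    """Full waiting-time distribution to first exit, with censoring at the cutoff."""
    q = _check_q(q)
    _check_start(q, start_age)
    qq = q[start_age:]
    # survival after k years in-system: prod of (1 - q) over the first k ages
    surv = np.cumprod(1.0 - qq)
    pmf = qq * np.concatenate(([1.0], surv[:-1]))
    censor = float(surv[-1])
    k = np.arange(1, len(qq) + 1)
    mean_time = float(k @ pmf)
    return SojournResult(
        start_age=start_age,
        first_exit_prob=1.0 - censor,
        exit_pmf=pmf,
        censor_prob=censor,
        mean_time=mean_time,
    )


def sojourn_table(
    q: Sequence[float] | np.ndarray,
    ages: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tabulate first-exit probability and mean sojourn time by starting age.

    Default ages are every fifth year from 0 to the last multiple of five
    below the cutoff (0, 5, ..., 55 on the standard 60-year grid).
    """
    q = _check_q(q)
    if ages is None:
        ages = range(0, len(q), 5)
    rows = []
    for age in ages:
        r = exit_time_pmf(q, int(age))
        rows.append(
            (r.start_age, r.first_exit_prob, r.mean_time, r.censor_prob, r.conditional_mean_time)
        )
    return pd.DataFrame(
        rows,
        columns=["age", "first_exit_prob", "mean_time", "censor_prob", "conditional_mean_time"],
    )
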