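"""Age-indexed model inputs: grids, bands, schedules and their validation.

The model works on single years of age over a half-open window [0, max_age);
published transition probabilities usually come in coarser age bands (e.g.
"0-9"), which are expanded piecewise-constant onto the single-age grid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AgeGrid",
    "AgeBand",
    "TransitionSchedule",
    "BirthSchedule",
    "PopulationWeights",
    "ValidationError",
    "ValidationReport",
    "expand_schedule",
    "validate_inputs",
    "parse_band_label",
]

#: tolerance for weight normalisation and other exact-arithmetic checks
WEIGHT_TOL = 1e-12

# both ASCII hyphen and en-dash accepted in band labels such as "0-9" / "0–9"
_BAND_RE = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$")


class ValidationError(ValueError):
    """Raised when a model input violates a structural invariant."""


@dataclass(frozen=True)
class AgeGrid:
    """Consecutive single-year ages 0, 1, ..., max_age - 1.

    ``max_age`` is the exclusive upper bound of the modelled window; reaching
    it means leaving the scope of the model (censoring), not exiting the
    in-system state.
    """

    max_age: int = 60

    def __post_init__(self) -> None:
        if not isinstance(self.max_age, (int, np.integer)) or self.max_age < 2:
            raise ValidationError(f"max_age must be an integer >= 2, got {self.max_age!r}")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.max_age)

    def __len__(self) -> int:
        return int(self.max_age)

    def __contains__(self, age: object) -> bool:
        return isinstance(age, (int, np.integer)) and 0 <= age < self.max_age


def parse_band_label(label: str) -> tuple[int, int]:
    """Parse an inclusive band label like ``"0-9"`` (en-dash accepted) to (start, end)."""
    m = _BAND_RE.match(label)
    if m is None:
        raise ValidationError(f"malformed age-band label {label!r}; expected e.g. '0-9'")
    start, end = int(m.group(1)), int(m.group(2))
    if start > end:
        raise ValidationError(f"age band {label!r} has start > end")
    return start, end


@dataclass(frozen=True)
class AgeBand:
    """An inclusive age range [start, end] carrying one probability or rate.

    Printed tables use inclusive labels ("0-9" means ages 0 through 9);
    internally all range arithmetic is half-open [start, end + 1).
    """

    start: int
    end: int
    value: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValidationError(
                f"invalid age band [{self.start}, {self.end}]: need 0 <= start <= end"
            )
        if self.value is not None and not np.isfinite(self.value):
            raise ValidationError(f"band [{self.start}, {self.end}] value is not finite")

    @classmethod
    def from_label(cls, label: str, value: float | None = None) -> "AgeBand":
        start, end = parse_band_label(label)
        return cls(start, end, value)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def ages(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


def _as_prob_vector(values: Sequence[float] | np.ndarray, grid: AgeGrid, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (grid.max_age,):
        raise ValidationError(
            f"{name} must have one value per age (expected length {grid.max_age}, got {v.shape})"
        )
    return v


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-age annual entry probability p(i) and exit probability q(i).

    p(i): probability that a non-recipient aged i is a recipient one year
    later; q(i): probability that a recipient aged i has exited one year
    later. Both must lie in [0, 1]; out-of-range values are rejected rather
    than clipped so data errors surface.
    """

    p: np.ndarray
    q: np.ndarray
    grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _as_prob_vector(self.p, self.grid, "p"))
        object.__setattr__(self, "q", _as_prob_vector(self.q, self.grid, "q"))
        for name, v in (("p", self.p), ("q", self.q)):
            bad = np.flatnonzero(~((v >= 0.0) & (v <= 1.0)))
            if bad.size:
                raise ValidationError(
                    f"{name} out of [0, 1] at ages {bad.tolist()}: values {v[bad].tolist()}"
                )

    @classmethod
    def unchecked(
        cls, p: Sequence[float], q: Sequence[float], grid: AgeGrid | None = None
    ) -> "TransitionSchedule":
        """Build without invariant checks, for feeding to ``validate_inputs``."""
        p = np.asarray(p, dtype=float)
        grid = grid or AgeGrid(len(p))
        obj = object.__new__(cls)
        object.__setattr__(obj, "p", p)
        object.__setattr__(obj, "q", np.asarray(q, dtype=float))
        object.__setattr__(obj, "grid", grid)
        return obj


@dataclass(frozen=True)
class BirthSchedule:
    """Age-specific birth rates b(i): births to people aged i per person aged i.

    The default fertile window (15, 49) encodes the modelling assumption that
    all births are to mothers aged 15-49; b must vanish outside the declared
    window. Recipients and non-recipients are assumed to share these rates.
    """

    b: np.ndarray
    grid: AgeGrid = field(default_factory=AgeGrid)
    fertile_range: tuple[int, int] = (15, 49)

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", _as_prob_vector(self.b, self.grid, "b"))
        lo, hi = self.fertile_range
        if lo > hi:
            raise ValidationError(f"fertile_range {self.fertile_range} has lo > hi")
        bad = np.flatnonzero(self.b < 0.0)
        if bad.size:
            raise ValidationError(f"negative birth rates at ages {bad.tolist()}")
        ages = self.grid.ages
        outside = (ages < lo) | (ages > hi)
        bad = np.flatnonzero(outside & (self.b > 0.0))
        if bad.size:
            raise ValidationError(
                f"birth rate nonzero outside fertile ages {lo}-{hi} at ages {bad.tolist()}"
            )

    @classmethod
    def unchecked(
        cls,
        b: Sequence[float],
        grid: AgeGrid | None = None,
        fertile_range: tuple[int, int] = (15, 49),
    ) -> "BirthSchedule":
        """Build without invariant checks, for feeding to ``validate_inputs``."""
        b = np.asarray(b, dtype=float)
        grid = grid or AgeGrid(len(b))
        obj = object.__new__(cls)
        object.__setattr__(obj, "b", b)
        object.__setattr__(obj, "grid", grid)
        object.__setattr__(obj, "fertile_range", fertile_range)
        return obj

    @property
    def total(self) -> float:
        """Sum of b(i); roughly a total-fertility proxy on a single-year grid."""
        return float(self.b.sum())


@dataclass(frozen=True)
class PopulationWeights:
    """Age-composition weights w(i): share of age i in the under-max_age population."""

    w: np.ndarray
    grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", _as_prob_vector(self.w, self.grid, "w"))
        bad = np.flatnonzero(self.w < 0.0)
        if bad.size:
            raise ValidationError(f"negative weights at ages {bad.tolist()}")
        s = float(self.w.sum())
        if abs(s - 1.0) > WEIGHT_TOL:
            raise ValidationError(f"weights sum to {s!r}, expected 1 within {WEIGHT_TOL}")

    @classmethod
    def from_counts(cls, counts: Sequence[float], grid: AgeGrid | None = None) -> "PopulationWeights":
        c = np.asarray(counts, dtype=float)
        grid = grid or AgeGrid(len(c))
        total = c.sum()
        if total <= 0:
            raise ValidationError("population counts sum to zero; cannot normalise")
        return cls(c / total, grid)


def expand_schedule(bands: Iterable[AgeBand], grid: AgeGrid) -> np.ndarray:
    """Expand band values piecewise-constant onto the single-age grid.

    The bands must tile the grid exactly: every age 0..max_age-1 covered
    once. Gaps and overlaps are reported with the offending ages.
    """
    bands = sorted(bands, key=lambda b: b.start)
    out = np.full(grid.max_age, np.nan)
    coverage = np.zeros(grid.max_age, dtype=int)
    for band in bands:
        if band.end >= grid.max_age:
            raise ValidationError(
                f"band {band.label} extends beyond the grid (max_age={grid.max_age})"
            )
        if band.value is None:
            raise ValidationError(f"band {band.label} carries no value to expand")
        out[band.start : band.end + 1] = band.value
        coverage[band.start : band.end + 1] += 1
    gaps = np.flatnonzero(coverage == 0)
    if gaps.size:
        raise ValidationError(f"bands leave a gap at ages {gaps.tolist()}")
    overlaps = np.flatnonzero(coverage > 1)
    if overlaps.size:
        raise ValidationError(f"bands overlap at ages {overlaps.tolist()}")
    return out


@dataclass
class ValidationReport:
    """Outcome of cross-validating a set of model inputs.

    Carries one message per detected problem; ``ok`` is True iff none were
    found. Construction of the input types already rejects most structural
    errors, so this reports on inputs assembled from raw arrays.
    """

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def add(self, message: str) -> None:
        self.issues.append(message)

    def summary(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"- {m}" for m in self.issues)


def validate_inputs(
    ts: TransitionSchedule,
    bs: BirthSchedule | None = None,
    pw: PopulationWeights | None = None,
) -> ValidationReport:
    """Cross-check a full input set on a common age grid.

    Returns a report rather than raising, so callers can surface every
    diagnostic at once (e.g. a CLI ``validate`` command).
    """
    report = ValidationReport()
    grid = ts.grid
    for name, v in (("p (entry probability)", ts.p), ("q (exit probability)", ts.q)):
        bad = np.flatnonzero(~((v >= 0.0) & (v <= 1.0) & np.isfinite(v)))
        if bad.size:
            report.add(f"{name} outside [0, 1] at ages {bad.tolist()}")
    if bs is not None:
        if bs.grid != grid:
            report.add(
                f"birth schedule grid (max_age={bs.grid.max_age}) differs from "
                f"transition grid (max_age={grid.max_age})"
            )
        lo, hi = bs.fertile_range
        ages = bs.grid.ages
        bad = np.flatnonzero(((ages < lo) | (ages > hi)) & (bs.b > 0.0))
        if bad.size:
            report.add(f"birth rate nonzero outside fertile ages {lo}-{hi} at ages {bad.tolist()}")
        if np.any(bs.b < 0.0):
            report.add("negative birth rates")
    if pw is not None:
        if pw.grid != grid:
            report.add(
                f"weights grid (max_age={pw.grid.max_age}) differs from "
                f"transition grid (max_age={grid.max_age})"
            )
        s = float(pw.w.sum())
        if abs(s - 1.0) > WEIGHT_TOL:
            report.add(f"weights sum to {s}, expected 1")
        if np.any(pw.w < 0.0):
            report.add("negative population weights")
    return report
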