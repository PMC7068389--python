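"""CSV/JSON readers and writers and report rendering.

File formats (all UTF-8 CSV with headers):

- transition schedule: ``age_band,p_enter,q_leave`` with inclusive band
  labels (``0-9``; en-dash accepted on input, hyphen written on output);
- birth rates: ``age,birth_rate`` per single age;
- population weights: ``age,weight`` per single age;
- initial state: ``age,x`` per single age.

Values are serialised at full float precision; rounding happens only in
rendered report tables (probabilities to 5 decimals, mean times to 2 by
default).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .projection import StateDistribution
from .schedules import (
    AgeBand,
    AgeGrid,
    BirthSchedule,
    PopulationWeights,
    TransitionSchedule,
    ValidationError,
    expand_schedule,
)

__all__ = [
    "RunConfig",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_births_csv",
    "write_births_csv",
    "read_weights_csv",
    "write_weights_csv",
    "read_state_csv",
    "write_state_csv",
    "load_reference_schedule",
    "render_sojourn_report",
    "render_elasticity_report",
    "frame_to_json",
    "ParseError",
]

#: packaged 2014-15 Hong Kong CSSA band schedule (registry estimates)
_REFERENCE_SCHEDULE = "hk_cssa_2014.csv"


class ParseError(ValidationError):
    """Raised when an input file cannot be parsed; carries the line number."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str).rename(columns=lambda c: c.strip())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path | str) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError:
        for line, raw in enumerate(df[col], start=2):  # header is line 1
            try:
                float(raw)
            except (TypeError, ValueError):
                raise ParseError(f"{path}, line {line}: non-numeric {col} value {raw!r}") from None
        raise


def read_schedule_bands(path: str | Path) -> list[tuple[AgeBand, AgeBand]]:
    """Read a band file as (entry band, exit band) pairs, preserving order."""
    df = _read_csv(path, ["age_band", "p_enter", "q_leave"])
    p_vals = _to_float(df, "p_enter", path)
    q_vals = _to_float(df, "q_leave", path)
    pairs = []
    for line, (label, pv, qv) in enumerate(zip(df["age_band"], p_vals, q_vals), start=2):
        try:
            pairs.append((AgeBand.from_label(label, pv), AgeBand.from_label(label, qv)))
        except ValidationError as exc:
            raise ParseError(f"{path}, line {line}: {exc}") from None
    return pairs


def read_schedule_csv(path: str | Path, grid: AgeGrid | None = None) -> TransitionSchedule:
    """Read a band schedule and expand it piecewise-constant to single ages."""
    pairs = read_schedule_bands(path)
    if grid is None:
        grid = AgeGrid(max(b.end for _, b in pairs) + 1)
    p = expand_schedule([pb for pb, _ in pairs], grid)
    q = expand_schedule([qb for _, qb in pairs], grid)
    return TransitionSchedule(p, q, grid)


def write_schedule_csv(path: str | Path, bands: Sequence[tuple[AgeBand, AgeBand]]) -> None:
    rows = [
        {"age_band": pb.label, "p_enter": repr(float(pb.value)), "q_leave": repr(float(qb.value))}
        for pb, qb in bands
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_per_age(
    path: str | Path, value_col: str, grid: AgeGrid | None
) -> tuple[np.ndarray, AgeGrid]:
    df = _read_csv(path, ["age", value_col])
    ages = _to_float(df, "age", path).astype(int)
    values = _to_float(df, value_col, path)
    grid = grid or AgeGrid(int(ages.max()) + 1)
    out = np.zeros(grid.max_age)
    seen = np.zeros(grid.max_age, dtype=bool)
    for a, v in zip(ages, values):
        if not 0 <= a < grid.max_age:
            raise ParseError(f"{path}: age {a} outside grid [0, {grid.max_age - 1}]")
        if seen[a]:
            raise ParseError(f"{path}: duplicate age {a}")
        out[a], seen[a] = v, True
    if not seen.all():
        raise ParseError(f"{path}: missing ages {np.flatnonzero(~seen).tolist()}")
    return out, grid


def read_births_csv(path: str | Path, grid: AgeGrid | None = None) -> BirthSchedule:
    b, grid = _read_per_age(path, "birth_rate", grid)
    return BirthSchedule(b, grid)


def write_births_csv(path: str | Path, bs: BirthSchedule) -> None:
    pd.DataFrame({"age": bs.grid.ages, "birth_rate": [repr(float(v)) for v in bs.b]}).to_csv(
        path, index=False
    )


def read_weights_csv(path: str | Path, grid: AgeGrid | None = None) -> PopulationWeights:
    w, grid = _read_per_age(path, "weight", grid)
    return PopulationWeights(w, grid)


def write_weights_csv(path: str | Path, pw: PopulationWeights) -> None:
    pd.DataFrame({"age": pw.grid.ages, "weight": [repr(float(v)) for v in pw.w]}).to_csv(
        path, index=False
    )


def read_state_csv(path: str | Path, grid: AgeGrid | None = None) -> StateDistribution:
    x, grid = _read_per_age(path, "x", grid)
    return StateDistribution(x, grid)


def write_state_csv(path: str | Path, st: StateDistribution) -> None:
    pd.DataFrame({"age": st.grid.ages, "x": [repr(float(v)) for v in st.x]}).to_csv(
        path, index=False
    )


def load_reference_schedule() -> TransitionSchedule:
    """The packaged 2014-15 Hong Kong CSSA decadal schedule, expanded to ages 0-59."""
    ref = importlib.resources.files("cssaflow.data").joinpath(_REFERENCE_SCHEDULE)
    with importlib.resources.as_file(ref) as path:
        return read_schedule_csv(path, AgeGrid(60))


@dataclass
class RunConfig:
    """File-driven run configuration mirroring the CLI flags."""

    schedule: str | None = None
    births: str | None = None
    weights: str | None = None
    state: str | None = None
    horizon: int = 10
    step: float = 1e-6
    mode: str = "relative"
    precision: int = 5
    mean_precision: int = 2
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _rounded(df: pd.DataFrame, ndigits_by_col: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, ndig in ndigits_by_col.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(ndig)
    return out


def render_sojourn_report(
    table: pd.DataFrame, precision: int = 5, mean_precision: int = 2
) -> str:
    """Fixed-precision text table: probabilities to 5 d.p., means to 2 d.p."""
    ndigits = {
        "first_exit_prob": precision,
        "censor_prob": precision,
        "mean_time": mean_precision,
        "conditional_mean_time": mean_precision,
    }
    return _rounded(table, ndigits).to_string(index=False)


def render_elasticity_report(table: pd.DataFrame, precision: int = 3) -> str:
    ndigits = {c: precision for c in ("rate_p", "rate_q", "elasticity_p", "elasticity_q")}
    return _rounded(table, ndigits).to_string(index=False)


def frame_to_json(df: pd.DataFrame) -> str:
    """Full-precision JSON (records orientation) for any report table."""
    return json.dumps(df.to_dict(orient="records"), indent=2, default=float)
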