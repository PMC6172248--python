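"""Time-dependent nondimensional Earth-system forcings.

The weathering and degassing fluxes are scaled by tabulated, normalized
drivers: land area ``fA``, river runoff ``fD``, carbonate-covered land
fraction ``fL``, chemically-weathering land fraction ``fAW``, seafloor
spreading ``fSR``, a land-plant weathering enhancement, the fraction of
carbonate deposited on shallow platforms, and a normalized seawater calcium
series used by gypsum burial.  All of these equal 1 at the present day.
``GEOG`` is the paleogeographic temperature effect, an additive offset in
kelvin (0 K today, may be negative).

Interpolation between tabulated ages is piecewise linear: the published
forcing tables are coarse, and higher-order interpolation would invent
structure that is not in the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, ParseError, ValidationError

__all__ = [
    "ForcingSet", "ForcingValues", "load_forcing_table",
    "normalize_to_present", "forcing_at", "generate_synthetic_forcings",
    "NORMALIZED_FIELDS", "ADDITIVE_FIELDS",
]

logger = logging.getLogger(__name__)

#: multiplicative drivers, normalized to 1 at 0 Ma
NORMALIZED_FIELDS = ("fA", "fD", "fL", "fAW", "fSR", "plant_weathering",
                     "carb_platform_fraction", "calcium")
#: additive drivers (kelvin offset), 0 at 0 Ma by convention
ADDITIVE_FIELDS = ("GEOG",)
ALL_FIELDS = NORMALIZED_FIELDS + ADDITIVE_FIELDS

_PRESENT_TOL = 1e-9


@dataclass(frozen=True)
class ForcingValues:
    """Scalar forcing values at a single age."""
    fA: float
    fD: float
    fL: float
    fAW: float
    fSR: float
    plant_weathering: float
    carb_platform_fraction: float
    calcium: float
    GEOG: float


@dataclass
class ForcingSet:
    """Tabulated forcings on a common age grid (Ma, stored descending to 0)."""

    age: np.ndarray
    fA: np.ndarray
    fD: np.ndarray
    fL: np.ndarray
    fAW: np.ndarray
    fSR: np.ndarray
    plant_weathering: np.ndarray
    carb_platform_fraction: np.ndarray
    calcium: np.ndarray
    GEOG: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        diffs = np.diff(self.age)
        if self.age.size < 2 or not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("forcing age grid must be strictly monotonic "
                                  "with at least two nodes")
        order = slice(None) if diffs[0] < 0 else slice(None, None, -1)
        self.age = self.age[order]
        for name in ALL_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)[order]
            if arr.shape != self.age.shape:
                raise ValidationError(f"forcing {name!r} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"forcing {name!r} contains non-finite values")
            setattr(self, name, arr)
        if self.age[-1] != 0.0:
            raise ValidationError("forcing grid must include the present (0 Ma)")
        for name in NORMALIZED_FIELDS:
            arr = getattr(self, name)
            if np.any(arr <= 0):
                raise ValidationError(f"normalized forcing {name!r} must be "
                                      "strictly positive")
            if abs(arr[-1] - 1.0) > _PRESENT_TOL:
                raise ValidationError(
                    f"normalized forcing {name!r} is {arr[-1]!r} at 0 Ma; "
                    "must equal 1 (use normalize_to_present or lenient loading)")

    @property
    def start_age(self) -> float:
        return float(self.age[0])

    @classmethod
    def constant(cls, age_grid: np.ndarray) -> "ForcingSet":
        """A no-effect forcing set (all multiplicative 1, GEOG 0)."""
        age_grid = np.asarray(age_grid, dtype=float)
        ones = np.ones_like(age_grid)
        values = {name: ones.copy() for name in NORMALIZED_FIELDS}
        values["GEOG"] = np.zeros_like(age_grid)
        return cls(age=age_grid, **values)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"age_ma": self.age}
        data.update({name: getattr(self, name) for name in ALL_FIELDS})
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def normalize_to_present(age: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Divide a series by its value at 0 Ma so the present value is exactly 1."""
    age = np.asarray(age, dtype=float)
    values = np.asarray(values, dtype=float)
    if 0.0 < age.min() or 0.0 > age.max():
        raise ValidationError("series does not reach 0 Ma; cannot normalize")
    order = np.argsort(age)
    v0 = float(np.interp(0.0, age[order], values[order]))
    if v0 <= 0:
        raise ValidationError(f"present-day value {v0!r} is not positive")
    out = values / v0
    out[age == 0.0] = 1.0
    return out


def load_forcing_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       strict: bool = True) -> ForcingSet:
    """Read a forcing CSV (column ``age_ma`` plus forcing columns).

    ``column_map`` maps nonstandard file headers to canonical forcing names,
    e.g. ``{"spreading": "fSR"}``.  Forcings missing from the file default to
    the constant 1 (GEOG to 0) with a logged warning.  With ``strict=True``
    (default) a normalized forcing whose 0 Ma value differs from 1 is an
    error; with ``strict=False`` it is renormalized to the present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "age_ma" not in df.columns:
        raise ParseError(f"{path}: missing required column 'age_ma'")

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value {df[col].iloc[row]!r} "
                             f"in column {col!r}, row {row}")
        df[col] = numeric

    age = df["age_ma"].to_numpy(dtype=float)
    if np.unique(age).size != age.size:
        raise ValidationError(f"{path}: duplicate ages in 'age_ma'")
    diffs = np.diff(age)
    if age.size >= 2 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValidationError(f"{path}: ages must be strictly monotonic")

    values: dict[str, np.ndarray] = {}
    for name in ALL_FIELDS:
        if name in df.columns:
            series = df[name].to_numpy(dtype=float)
            if name in NORMALIZED_FIELDS:
                present = float(np.interp(0.0, age[np.argsort(age)],
                                          series[np.argsort(age)]))
                if abs(present - 1.0) > _PRESENT_TOL:
                    if strict:
                        raise ValidationError(
                            f"{path}: forcing {name!r} equals {present!r} at 0 Ma "
                            "(strict mode requires 1; pass strict=False to "
                            "renormalize)")
                    series = normalize_to_present(age, series)
            values[name] = series
        else:
            fill = 0.0 if name in ADDITIVE_FIELDS else 1.0
            logger.warning("forcing %r absent from %s; defaulting to %s",
                           name, path, fill)
            values[name] = np.full_like(age, fill)
    return ForcingSet(age=age, **values)


def forcing_at(fs: ForcingSet, t: float) -> ForcingValues:
    """Piecewise-linear forcing values at age ``t`` (Ma); exact on grid nodes."""
    if t < fs.age[-1] - 1e-12 or t > fs.age[0] + 1e-12:
        raise ExtrapolationError(
            f"age {t} Ma outside forcing span [{fs.age[-1]}, {fs.age[0]}] Ma")
    asc = fs.age[::-1]
    out = {}
    for name in ALL_FIELDS:
        out[name] = float(np.interp(t, asc, getattr(fs, name)[::-1]))
    return ForcingValues(**out)


def _random_smooth_unit(rng: np.random.Generator, age: np.ndarray,
                        start_age: float) -> np.ndarray:
    """Smooth curve on the grid, zero at 0 Ma, scaled to unit max amplitude."""
    h = np.zeros_like(age)
    for k in range(1, 5):
        amp = rng.uniform(0.2, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        h += amp * np.sin(2 * np.pi * k * age / (1.3 * start_age) + phase)
    h -= h[age == 0.0]
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def generate_synthetic_forcings(seed: int, start_age: float = 570.0,
                                amplitude: float = 0.2,
                                step: float = 5.0) -> ForcingSet:
    """Deterministic smooth synthetic forcings.

    Each multiplicative series is a low-order sum of sines equal to 1 at
    0 Ma and deviating from 1 by at most ``amplitude``; GEOG is an additive
    curve bounded by ``amplitude`` kelvin.  ``amplitude = 0`` gives the
    degenerate no-effect set.
    """
    if not 0.0 <= amplitude <= 0.5:
        raise ValidationError("amplitude must lie in [0, 0.5]")
    n = int(round(start_age / step))
    age = np.linspace(start_age, 0.0, n + 1)
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for name in NORMALIZED_FIELDS:
        if name == "calcium":
            # seawater calcium enters only gypsum burial; held at 1 by default
            values[name] = np.ones_like(age)
            continue
        sub = rng.uniform(0.3, 1.0)
        values[name] = 1.0 + amplitude * sub * _random_smooth_unit(rng, age,
                                                                   start_age)
    values["GEOG"] = amplitude * rng.uniform(0.3, 1.0) * _random_smooth_unit(
        rng, age, start_age)
    return ForcingSet(age=age, **values)
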