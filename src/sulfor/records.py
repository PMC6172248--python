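"""Seawater isotope records: the d13C driver and the d34S validation series.

An :class:`IsotopeRecord` is an age-indexed permil series with an optional
pointwise standard deviation.  The carbonate d13C record *drives* the model
through the isotope-mass-balance burial calculation; the sulphate d34S
record is used only to validate the synthetic d34S the model outputs, never
to compute fluxes (module boundaries enforce this: no flux routine accepts a
d34S record).

Smoothing is a centred moving average defined over a window in age units
(Myr), not sample counts, so irregular grids are handled consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, ParseError, ValidationError

__all__ = [
    "IsotopeRecord", "load_record", "smooth_record", "perturb_record",
    "record_at", "record_slope_at", "generate_synthetic_delta13c",
    "generate_synthetic_delta34s",
]


@dataclass
class IsotopeRecord:
    """Age-indexed permil record (ages Ma, stored descending to the present)."""

    age: np.ndarray
    delta: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.age.size == 0:
            raise ValidationError("empty isotope record")
        diffs = np.diff(self.age)
        if self.age.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("record ages must be strictly monotonic")
        order = slice(None) if (self.age.size == 1 or diffs[0] < 0) \
            else slice(None, None, -1)
        self.age = self.age[order]
        self.delta = self.delta[order]
        if self.delta.shape != self.age.shape:
            raise ValidationError("delta length mismatch")
        if not np.all(np.isfinite(self.delta)):
            raise ValidationError("delta contains non-finite values")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)[order]
            if self.sd.shape != self.age.shape:
                raise ValidationError("sd length mismatch")
            if np.any(self.sd < 0) or not np.all(np.isfinite(self.sd)):
                raise ValidationError("sd must be finite and non-negative")

    @property
    def start_age(self) -> float:
        return float(self.age[0])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"age_ma": self.age, "delta_permil": self.delta}
        if self.sd is not None:
            data["sd_permil"] = self.sd
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def load_record(path: str | Path) -> IsotopeRecord:
    """Read a record CSV with columns ``age_ma, delta_permil[, sd_permil]``."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("age_ma", "delta_permil"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value in column {col!r}, "
                             f"row {row}")
        df[col] = numeric
    sd = df["sd_permil"].to_numpy(float) if "sd_permil" in df.columns else None
    return IsotopeRecord(age=df["age_ma"].to_numpy(float),
                         delta=df["delta_permil"].to_numpy(float), sd=sd)


def smooth_record(rec: IsotopeRecord, window: float) -> IsotopeRecord:
    """Centred moving average over a ``window``-Myr span of ages.

    Every node within ``window/2`` Myr of a target node (inclusive)
    contributes equally.  A window narrower than the grid spacing returns the
    record unchanged.  The standard deviation, where present, is propagated
    as the window mean of the nodewise sd.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    span = rec.age.max() - rec.age.min()
    if rec.age.size > 1 and span < window:
        raise ValidationError(
            f"record spans {span} Myr, narrower than the {window} Myr window")
    half = window / 2.0
    diffs = np.abs(rec.age[:, None] - rec.age[None, :])
    mask = diffs <= half + 1e-12
    counts = mask.sum(axis=1)
    delta = (mask @ rec.delta) / counts
    sd = (mask @ rec.sd) / counts if rec.sd is not None else None
    return IsotopeRecord(age=rec.age.copy(), delta=delta, sd=sd)


def perturb_record(rec: IsotopeRecord, k: float) -> IsotopeRecord:
    """Shift the record by ``k`` pointwise standard deviations."""
    if rec.sd is None:
        raise ValidationError("perturb_record requires a record with sd")
    return IsotopeRecord(age=rec.age.copy(), delta=rec.delta + k * rec.sd,
                         sd=rec.sd.copy())


def record_at(rec: IsotopeRecord, t: float) -> float:
    """Piecewise-linear record value at age ``t`` (Ma); no extrapolation."""
    if t < rec.age[-1] - 1e-12 or t > rec.age[0] + 1e-12:
        raise ExtrapolationError(
            f"age {t} Ma outside record span [{rec.age[-1]}, {rec.age[0]}] Ma")
    return float(np.interp(t, rec.age[::-1], rec.delta[::-1]))


def record_slope_at(rec: IsotopeRecord, t: float, h: float = 0.5) -> float:
    """d(delta)/dt in permil/Myr of *forward* model time at age ``t``.

    Central difference of the linear interpolant over +/- ``h`` Myr, clipped
    to the record span; forward time runs opposite to age.
    """
    hi = min(t + h, rec.age[0])
    lo = max(t - h, rec.age[-1])
    if hi <= lo:
        return 0.0
    asc = rec.age[::-1]
    v_hi = float(np.interp(hi, asc, rec.delta[::-1]))
    v_lo = float(np.interp(lo, asc, rec.delta[::-1]))
    return (v_lo - v_hi) / (hi - lo)


def _gaussian_bump(age: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((age - center) / width) ** 2)


def _synthetic_record(seed: int, start_age: float, baseline: float,
                      excursion_amp: float, sd_level: float,
                      step: float, n_excursions: int) -> IsotopeRecord:
    if sd_level < 0:
        raise ValidationError("sd_level must be non-negative")
    if excursion_amp < 0:
        raise ValidationError("excursion_amp must be non-negative")
    n = int(round(start_age / step))
    age = np.linspace(start_age, 0.0, n + 1)
    rng = np.random.default_rng(seed)

    # slow drift (zero at present) plus a few localized excursions, jointly
    # bounded by excursion_amp so tests can check the amplitude contract
    drift = np.zeros_like(age)
    for k in range(1, 4):
        drift += (rng.uniform(0.3, 1.0) / k) * np.sin(
            2 * np.pi * k * age / (1.6 * start_age) + rng.uniform(0, 2 * np.pi))
    drift -= drift[age == 0.0]
    peak = np.max(np.abs(drift))
    drift = drift / peak if peak > 0 else drift

    bumps = np.zeros_like(age)
    for _ in range(n_excursions):
        center = rng.uniform(0.25, 0.9) * start_age
        width = rng.uniform(8.0, 20.0)
        sign = rng.choice([-1.0, 1.0])
        bumps += sign * rng.uniform(0.4, 1.0) * _gaussian_bump(age, center, width)
    peak = np.max(np.abs(bumps))
    bumps = bumps / peak if peak > 0 else bumps

    delta = baseline + excursion_amp * (0.3 * drift + 0.7 * bumps)
    delta[age == 0.0] = baseline  # model initializes at isotopic balance
    sd = np.full_like(age, float(sd_level))
    return IsotopeRecord(age=age, delta=delta, sd=sd)


def generate_synthetic_delta13c(seed: int, start_age: float = 570.0,
                                baseline: float = 1.0,
                                excursion_amp: float = 2.0,
                                sd_level: float = 1.0,
                                step: float = 1.0,
                                n_excursions: int = 3) -> IsotopeRecord:
    """Synthetic carbonate d13C record.

    Smooth baseline drift plus a small number of localized excursions; the
    combined deviation from ``baseline`` never exceeds ``excursion_amp``
    permil, the present-day value equals ``baseline`` exactly (so the model
    can initialize at balance), and the pointwise sd is ``sd_level``.
    Deterministic for a fixed seed.
    """
    return _synthetic_record(seed, start_age, baseline, excursion_amp,
                             sd_level, step, n_excursions)


def generate_synthetic_delta34s(seed: int, start_age: float = 570.0,
                                baseline: float = 20.0,
                                excursion_amp: float = 5.0,
                                sd_level: float = 2.0,
                                step: float = 2.0,
                                n_excursions: int = 2) -> IsotopeRecord:
    """Synthetic seawater-sulphate d34S record (validation only)."""
    return _synthetic_record(seed, start_age, baseline, excursion_amp,
                             sd_level, step, n_excursions)
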