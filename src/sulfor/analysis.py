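"""Experiment drivers: baseline run, sensitivity sweeps, diagnostics, validation.

Failures inside sweeps are data, not crashes: a run that collapses (e.g. a
strongly negative d13C shift driving oxygen to zero) is recorded with its
cause and the sweep continues, because failure under perturbation is itself
a scientific result for this class of model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import sulphur
from .config import ModelConfig
from .errors import ValidationError
from .forcings import ForcingSet
from .model import (FailureInfo, Trajectory, integrate, o2mr_from_percent,
                    o2_percent_atm)
from .records import IsotopeRecord, perturb_record

__all__ = [
    "SweepResult", "run_baseline", "j_sweep", "delta13c_envelope",
    "legacy_sulphur_diagnostic", "validate_d34s", "landmarks",
]


@dataclass
class SweepResult:
    """One trajectory (or failure) per swept parameter value."""

    parameter: str
    values: list[float]
    trajectories: dict[float, Trajectory]
    failures: dict[float, FailureInfo | None] = field(default_factory=dict)

    def po2(self, value: float) -> np.ndarray:
        return self.trajectories[value].o2_pct

    def summary_table(self) -> pd.DataFrame:
        """Long-format pO2 per age per parameter value; failed spans absent."""
        frames = []
        for v in self.values:
            traj = self.trajectories[v]
            frames.append(pd.DataFrame({
                "age_ma": traj.ages, "o2_pct": traj.o2_pct,
                self.parameter: v}))
        return pd.concat(frames, ignore_index=True)


def run_baseline(config: ModelConfig, forcings: ForcingSet,
                 record: IsotopeRecord, out: str | Path | None = None,
                 legacy_init: bool = False) -> Trajectory:
    """Full run from the start age to the present; optionally written to CSV."""
    traj = integrate(config, forcings, record, legacy_init=legacy_init)
    if out is not None:
        traj.write_csv(out)
    return traj


def _sweep(parameter: str, values: Sequence[float], run_one) -> SweepResult:
    if len(values) == 0:
        raise ValidationError(f"empty {parameter} sweep")
    values = sorted(float(v) for v in values)
    result = SweepResult(parameter=parameter, values=list(values),
                         trajectories={}, failures={})
    for v in values:
        traj = run_one(v)
        result.trajectories[v] = traj
        result.failures[v] = traj.failure
    return result


def j_sweep(config: ModelConfig, forcings: ForcingSet, record: IsotopeRecord,
            j_values: Sequence[float] = (2.5, 4.0, 5.0, 7.5)) -> SweepResult:
    """Sensitivity of pO2 to the O2-fractionation coupling J."""
    if any(v <= 0 for v in j_values):
        raise ValidationError("J values must be positive")
    return _sweep("J", j_values,
                  lambda v: integrate(config.replace(j=v), forcings, record))


def delta13c_envelope(config: ModelConfig, forcings: ForcingSet,
                      record: IsotopeRecord,
                      k_values: Sequence[float] = (-0.5, 0.5, 1.0),
                      ) -> tuple[SweepResult, pd.DataFrame]:
    """Runs at d13C record shifts of k pointwise standard deviations.

    Returns the sweep plus a per-age envelope table (min/max pO2 across the
    successful perturbed runs, with the unperturbed baseline).  A run that
    fails (as a -1 SD shift does on realistic records) is reported in the
    sweep's ``failures``, and contributes to the envelope only over the ages
    it reached.
    """
    if record.sd is None:
        raise ValidationError("envelope runs need a record with sd")
    baseline = integrate(config, forcings, record)
    sweep = _sweep("k_sd", k_values,
                   lambda v: integrate(config, forcings,
                                       perturb_record(record, v)))
    env = pd.DataFrame({"age_ma": baseline.ages,
                        "o2_pct_baseline": baseline.o2_pct})
    lo = np.full(baseline.ages.size, np.inf)
    hi = np.full(baseline.ages.size, -np.inf)
    for v in sweep.values:
        traj = sweep.trajectories[v]
        if traj.ages.size == 0:
            continue
        interp = np.interp(baseline.ages[::-1], traj.ages[::-1],
                           traj.o2_pct[::-1],
                           left=np.nan, right=np.nan)[::-1]
        reached = baseline.ages >= traj.ages.min() - 1e-9
        valid = reached & np.isfinite(interp)
        lo[valid] = np.minimum(lo[valid], interp[valid])
        hi[valid] = np.maximum(hi[valid], interp[valid])
    env["o2_pct_min"] = np.where(np.isfinite(lo), lo, np.nan)
    env["o2_pct_max"] = np.where(np.isfinite(hi), hi, np.nan)
    sweep.trajectories[0.0] = baseline
    sweep.failures[0.0] = baseline.failure
    return sweep, env


def legacy_sulphur_diagnostic(config: ModelConfig,
                              o2_pct_grid: Sequence[float] | None = None,
                              ) -> pd.DataFrame:
    """Legacy vs forward pyrite burial across an atmospheric-O2 grid.

    Holds the carbon and sulphur background at its present-day reference
    (this is a flux-relationship diagnostic, not a transient run) and
    tabulates, per O2 level: the legacy power-law fractionation alpha_s, the
    pyrite burial flux the legacy isotope inversion would demand, and the
    bounded forward-model burial flux.
    """
    if o2_pct_grid is None:
        o2mr_grid = np.linspace(0.05, 2.0, 79)
        o2_pct_grid = [o2_percent_atm(v) for v in o2mr_grid]
    else:
        o2_pct_grid = [float(p) for p in o2_pct_grid]
        if any(not 0.0 < p < 100.0 for p in o2_pct_grid):
            raise ValidationError("pO2 grid values must lie in (0, 100)% atm")
        o2mr_grid = np.array([o2mr_from_percent(p) for p in o2_pct_grid])

    d_pyrite = config.d34s_sulphate0 - config.alpha_s_forward
    # present-day sulphate inputs: all pyrite-derived weathering + degassing
    pyrite_inputs = [(config.k_bp, d_pyrite)]
    rows = []
    for pct, o2mr in zip(o2_pct_grid, o2mr_grid):
        alpha = sulphur.legacy_alpha_s(o2mr, config.legacy_delta_s0,
                                       config.legacy_n)
        legacy_fbp = sulphur.legacy_pyrite_burial_imb(
            alpha, pyrite_inputs, config.d34s_sulphate0, 0.0, config.oa_s0)
        forward_fbp = sulphur.pyrite_burial(1.0, 1.0, o2mr, config.k_bp,
                                            config.o2mr_floor)
        rows.append((pct, o2mr, alpha, legacy_fbp, forward_fbp))
    return pd.DataFrame(rows, columns=["o2_pct", "o2mr", "alpha_s",
                                       "legacy_pyrite_burial",
                                       "forward_pyrite_burial"])


def validate_d34s(trajectory: Trajectory, observed: IsotopeRecord,
                  band: float) -> dict:
    """Fraction of observed d34S nodes within +/- band of the synthetic output."""
    if band < 0:
        raise ValidationError("band must be non-negative")
    if trajectory.ages.size == 0:
        raise ValidationError("empty trajectory")
    lo, hi = trajectory.ages.min(), trajectory.ages.max()
    mask = (observed.age >= lo - 1e-9) & (observed.age <= hi + 1e-9)
    if not mask.any():
        raise ValidationError("trajectory and observed record spans are disjoint")
    ages = observed.age[mask]
    obs = observed.delta[mask]
    synth = np.interp(ages[::-1], trajectory.ages[::-1],
                      trajectory.d34s_sulphate[::-1])[::-1]
    inside = np.abs(synth - obs) <= band + 1e-12
    table = pd.DataFrame({"age_ma": ages, "observed": obs, "synthetic": synth,
                          "within_band": inside})
    return {"fraction_within": float(inside.mean()), "n": int(inside.size),
            "band": float(band), "table": table}


def landmarks(trajectory: Trajectory) -> dict[str, float]:
    """Summary pO2 landmarks used when comparing against external data.

    Intended for user-supplied digitized d13C/forcing inputs; on synthetic
    fixtures the numbers describe the fixture, not the geological record.
    """
    ages, po2 = trajectory.ages, trajectory.o2_pct

    def window(lo_age: float, hi_age: float) -> np.ndarray:
        return po2[(ages <= hi_age) & (ages >= lo_age)]

    out: dict[str, float] = {}
    early = window(458.0, 541.0)
    if early.size:
        out["early_paleozoic_max_pct"] = float(early.max())
        out["early_paleozoic_min_pct"] = float(early.min())
    dev = (ages <= 420.0) & (ages >= 380.0)
    if dev.any():
        i = np.argmin(np.where(dev, po2, np.inf))
        out["mid_devonian_nadir_pct"] = float(po2[i])
        out["mid_devonian_nadir_age_ma"] = float(ages[i])
    mid_carb = window(320.0, 326.0)
    if mid_carb.size:
        out["bashkirian_dip_pct"] = float(mid_carb.min())
    tri = window(201.0, 252.0)
    if tri.size:
        out["triassic_mean_pct"] = float(tri.mean())
    return out
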