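"""Self-contained synthetic inputs for building and testing the model.

The real driving datasets (the carbonate d13C compilation and the tabulated
Earth-system forcings) are not redistributable, so every test and example in
this package runs on synthetic stand-ins with the statistical structure the
analysis assumes.  Three scenarios are provided:

``steady``
    Exact-balance inputs: unit forcings and a flat d13C record at the
    steady-state value implied by the configured present-day fluxes, so the
    model holds 21% atm O2 indefinitely.  This is the anchor fixture.
``excursion``
    One positive d13C excursion (a Steptoean-style event) on the steady
    background; organic burial and hence O2 rise through it.
``stress``
    A strong, sustained negative d13C excursion near the start; the isotope
    mass balance demands negative organic burial, oxygen collapses, and the
    run ends in a structured failure.  This reproduces the behaviour of a
    -1 SD shift of a realistic record.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .carbon import steady_state_delta13c
from .config import ModelConfig
from .errors import ValidationError
from .forcings import ForcingSet, generate_synthetic_forcings
from .records import IsotopeRecord, _gaussian_bump, generate_synthetic_delta34s

__all__ = ["SCENARIOS", "FixtureSpec", "make_fixture", "write_fixture"]

SCENARIOS = ("steady", "excursion", "stress")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a reproducible synthetic input set."""

    seed: int = 0
    start_age: float = 570.0
    scenario: str = "steady"
    baseline: float | None = None      # permil; None = config steady-state value
    excursion_amp: float = 2.0         # permil, positive-excursion height
    sd: float = 1.0                    # permil, pointwise record sd
    forcing_amplitude: float = 0.0     # 0 = unit forcings (exact balance)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")


def make_fixture(spec: FixtureSpec, config: ModelConfig | None = None,
                 ) -> tuple[ForcingSet, IsotopeRecord, IsotopeRecord, ModelConfig]:
    """Build (forcings, d13C record, d34S record, config) for a scenario.

    The steady d13C value is computed from the configured present fluxes by
    the closed-form steady-state balance, never hard-coded, so a config
    change cannot silently break the anchor.
    """
    config = config if config is not None else ModelConfig(
        start_age=spec.start_age)
    if config.start_age != spec.start_age:
        config = config.replace(start_age=spec.start_age)
    baseline = spec.baseline if spec.baseline is not None \
        else steady_state_delta13c(config)

    forcings = generate_synthetic_forcings(spec.seed, spec.start_age,
                                           spec.forcing_amplitude)
    age = np.linspace(spec.start_age, 0.0, int(round(spec.start_age)) + 1)
    delta = np.full_like(age, baseline)
    if spec.scenario == "excursion":
        # one positive event, late-Cambrian-like placement
        center = min(500.0, 0.88 * spec.start_age)
        delta = delta + spec.excursion_amp * _gaussian_bump(age, center, 10.0)
    elif spec.scenario == "stress":
        # deep sustained negative excursion near model start
        center = 0.95 * spec.start_age
        delta = delta - 4.0 * spec.excursion_amp * _gaussian_bump(age, center,
                                                                  25.0)
    d13c = IsotopeRecord(age=age, delta=delta,
                         sd=np.full_like(age, float(spec.sd)))
    d34s = generate_synthetic_delta34s(
        spec.seed + 1, spec.start_age, baseline=config.d34s_sulphate0,
        excursion_amp=0.0 if spec.scenario == "steady" else 5.0)
    return forcings, d13c, d34s, config


def write_fixture(spec: FixtureSpec, out_dir: str | Path,
                  config: ModelConfig | None = None) -> dict[str, Path]:
    """Write a fixture to CSV/YAML files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    forcings, d13c, d34s, cfg = make_fixture(spec, config)
    paths = {
        "forcings": out / "forcings.csv",
        "delta13c": out / "delta13c.csv",
        "delta34s": out / "delta34s.csv",
        "config": out / "config.yaml",
    }
    forcings.write_csv(paths["forcings"])
    d13c.write_csv(paths["delta13c"])
    d34s.write_csv(paths["delta34s"])
    cfg.to_yaml(paths["config"])
    return paths
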