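"""Model configuration: rate constants, present-day anchors, initial apportionment.

Units
-----
Masses are carried in units of 1e18 mol and fluxes in 1e18 mol/Myr
throughout the package; ages are in Ma (millions of years before present)
and isotope compositions in permil.

The configuration encodes a self-consistent present-day steady state: every
reservoir's input fluxes balance its output fluxes when all forcings equal 1,
RCO2 = 1 and O2 is at its present inventory.  ``validate`` enforces these
closure identities so that a perturbed constant cannot silently break the
steady-state anchor the fixtures and tests rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    # --- time and reporting ---
    start_age: float = 570.0      # Ma, model start
    report_step: float = 1.0      # Myr, trajectory output resolution

    # --- carbon isotope system ---
    j: float = 4.0                # O2 sensitivity of carbon fractionation
    delta0: float = 25.0          # permil, present carbonate-organic fractionation
    beta: float = 0.5             # oxidative-weathering O2 exponent
    d13c_carb0: float = 1.0       # permil, initial/present crustal carbonate d13C
    d13c_org0: float = -24.0      # permil, initial/present crustal organic d13C

    # --- climate / weathering feedback ---
    gcm: float = 4.0              # K temperature rise per e-fold of RCO2
    act_coeff: float = 0.09       # 1/K, kinetic (Arrhenius-like) weathering term
    runoff_coeff: float = 0.045   # 1/K, runoff response to warming
    runoff_exp: float = 0.65      # exponent on the runoff term
    erosion_area_exp: float = 0.5     # exponent on land area fA in erosion term
    erosion_runoff_exp: float = 0.65  # exponent on runoff fD in erosion term

    # --- carbon reservoirs (1e18 mol) ---
    oa_c0: float = 3.193          # ocean-atmosphere carbon
    corg_y0: float = 250.0        # young crustal organic carbon
    corg_a0: float = 1000.0       # ancient crustal organic carbon
    ccarb_y0: float = 1000.0      # young crustal carbonate
    ccarb_a0: float = 4000.0      # ancient crustal carbonate

    # --- carbon fluxes at present (1e18 mol/Myr) ---
    fws0: float = 6.65            # silicate weathering
    fwc_y0: float = 8.0           # young carbonate weathering
    fwc_a0: float = 5.35          # ancient carbonate weathering
    fbg0: float = 4.5             # organic carbon burial
    fwg_y0: float = 2.0           # young organic weathering
    fwg_a0: float = 1.75          # ancient organic weathering
    degas_org_y0: float = 0.5
    degas_org_a0: float = 0.25
    degas_carb_y0: float = 1.0
    degas_carb_a0: float = 5.65
    t_org0: float = 2.0           # young->ancient organic transfer
    t_carb0: float = 11.0         # young->ancient carbonate transfer

    # carbonate degassing platform/deep-ocean weighting
    platform_frac0: float = 0.5       # present fraction of carbonate on platforms
    shallow_degas_rel: float = 0.5    # platform degassing efficiency vs deep ocean

    # --- sulphur initialization (1e18 mol) ---
    total_s: float = 418.0
    oa_s_init: float = 38.0
    pyr_total_init: float = 280.0
    gyp_total_init: float = 100.0
    young_frac_pyr: float = 0.25
    young_frac_gyp: float = 0.4

    # --- sulphur present-day anchors and rate constants ---
    oa_s0: float = 38.0           # present ocean sulphate (1e18 mol)
    new_kwp: float = 0.35         # young pyrite weathering constant (flux at anchor)
    new_kwgyp: float = 0.6        # young gypsum weathering constant
    k_bp: float = 0.53            # pyrite burial constant (present flux)
    k_bgyp: float = 1.0           # gypsum burial constant (present flux)
    fwp_a0: float = 0.15          # ancient pyrite weathering at present
    fwgyp_a0: float = 0.3         # ancient gypsum weathering at present
    degas_pyr_y0: float = 0.01
    degas_pyr_a0: float = 0.02
    degas_gyp_y0: float = 0.05
    degas_gyp_a0: float = 0.05
    t_pyr0: float = 0.17          # young->ancient pyrite transfer
    t_gyp0: float = 0.35          # young->ancient gypsum transfer
    alpha_s_forward: float = 35.0  # permil, burial fractionation (d34S output only)
    d34s_sulphate0: float = 20.0   # permil, initial/present seawater sulphate d34S

    # --- legacy (isotope-inversion) sulphur scheme ---
    legacy_delta_s0: float = 35.0  # permil, fractionation at present O2
    legacy_n: float = 1.5          # power-law exponent on O2mr
    legacy_total_s: float = 638.0
    legacy_oa_s_init: float = 38.0
    legacy_pyr_total_init: float = 300.0
    legacy_gyp_total_init: float = 300.0

    # --- oxygen ---
    o2_0: float = 38.0            # present ocean-atmosphere O2 (1e18 mol)
    o2mr_floor: float = 1e-3      # guards the 1/O2mr singularity in pyrite burial

    # --- solver ---
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = 5.0         # Myr; keeps short isotope excursions resolved

    def __post_init__(self) -> None:
        self.validate()

    # ----- derived anchors -----

    @property
    def pyr_y0(self) -> float:
        """Present-day young pyrite reservoir (Pyr_0 in the burial equations)."""
        return self.young_frac_pyr * self.pyr_total_init

    @property
    def pyr_a0(self) -> float:
        return (1.0 - self.young_frac_pyr) * self.pyr_total_init

    @property
    def gyp_y0(self) -> float:
        return self.young_frac_gyp * self.gyp_total_init

    @property
    def gyp_a0(self) -> float:
        return (1.0 - self.young_frac_gyp) * self.gyp_total_init

    @property
    def fbc0(self) -> float:
        """Present carbonate burial: carbonate + silicate weathering supply."""
        return self.fwc_y0 + self.fwc_a0 + self.fws0

    # ----- validation -----

    def validate(self) -> None:
        """Check positivity and the present-day steady-state closure identities."""
        for name in ("start_age", "delta0", "gcm", "oa_c0", "corg_y0", "corg_a0",
                     "ccarb_y0", "ccarb_a0", "fws0", "fwc_y0", "fbg0", "oa_s0",
                     "o2_0", "k_bp", "k_bgyp", "new_kwp", "new_kwgyp", "rtol",
                     "atol", "max_step", "alpha_s_forward", "legacy_delta_s0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"config field {name!r} must be positive")
        if not (0.0 < self.young_frac_pyr < 1.0 and 0.0 < self.young_frac_gyp < 1.0):
            raise ConfigError("young fractions must lie strictly in (0, 1)")

        identities = {
            "organic burial balances organic oxidation":
                (self.fbg0,
                 self.fwg_y0 + self.fwg_a0 + self.degas_org_y0 + self.degas_org_a0),
            "ancient organic reservoir closure":
                (self.t_org0, self.fwg_a0 + self.degas_org_a0),
            "ancient carbonate reservoir closure":
                (self.t_carb0, self.fwc_a0 + self.degas_carb_a0),
            "young carbonate reservoir closure":
                (self.fws0 + self.fwc_a0, self.degas_carb_y0 + self.t_carb0),
            "young pyrite reservoir closure":
                (self.k_bp, self.new_kwp + self.degas_pyr_y0 + self.t_pyr0),
            "ancient pyrite reservoir closure":
                (self.t_pyr0, self.fwp_a0 + self.degas_pyr_a0),
            "young gypsum reservoir closure":
                (self.k_bgyp, self.new_kwgyp + self.degas_gyp_y0 + self.t_gyp0),
            "ancient gypsum reservoir closure":
                (self.t_gyp0, self.fwgyp_a0 + self.degas_gyp_a0),
            "sulphur apportionment sums to total":
                (self.total_s,
                 self.oa_s_init + self.pyr_total_init + self.gyp_total_init),
            "legacy sulphur apportionment sums to total":
                (self.legacy_total_s,
                 self.legacy_oa_s_init + self.legacy_pyr_total_init
                 + self.legacy_gyp_total_init),
        }
        bad = [
            f"{name}: {lhs!r} != {rhs!r}"
            for name, (lhs, rhs) in identities.items()
            if abs(lhs - rhs) > 1e-9 * max(1.0, abs(lhs), abs(rhs))
        ]
        if bad:
            raise ConfigError(
                "steady-state closure violated:\n  " + "\n  ".join(bad))

    # ----- (de)serialization -----

    _SECTIONS = {
        "time": ("start_age", "report_step"),
        "carbon": ("j", "delta0", "beta", "d13c_carb0", "d13c_org0",
                   "oa_c0", "corg_y0", "corg_a0", "ccarb_y0", "ccarb_a0",
                   "fws0", "fwc_y0", "fwc_a0", "fbg0", "fwg_y0", "fwg_a0",
                   "degas_org_y0", "degas_org_a0", "degas_carb_y0",
                   "degas_carb_a0", "t_org0", "t_carb0",
                   "platform_frac0", "shallow_degas_rel"),
        "climate": ("gcm", "act_coeff", "runoff_coeff", "runoff_exp",
                    "erosion_area_exp", "erosion_runoff_exp"),
        "sulphur": ("total_s", "oa_s_init", "pyr_total_init", "gyp_total_init",
                    "young_frac_pyr", "young_frac_gyp", "oa_s0",
                    "new_kwp", "new_kwgyp", "k_bp", "k_bgyp",
                    "fwp_a0", "fwgyp_a0", "degas_pyr_y0", "degas_pyr_a0",
                    "degas_gyp_y0", "degas_gyp_a0", "t_pyr0", "t_gyp0",
                    "alpha_s_forward", "d34s_sulphate0",
                    "legacy_delta_s0", "legacy_n", "legacy_total_s",
                    "legacy_oa_s_init", "legacy_pyr_total_init",
                    "legacy_gyp_total_init"),
        "oxygen": ("o2_0", "o2mr_floor"),
        "solver": ("rtol", "atol", "max_step"),
    }

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {section: {name: getattr(self, name) for name in names}
                for section, names in self._SECTIONS.items()}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelConfig":
        """Build from a flat mapping or one nested by section."""
        flat: dict[str, Any] = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if isinstance(value, Mapping):
                flat.update(value)
            else:
                flat[key] = value
        unknown = sorted(set(flat) - valid)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**{k: float(v) for k, v in flat.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def replace(self, **changes: Any) -> "ModelConfig":
        return dataclasses.replace(self, **changes)
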