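"""Assembly and stiff integration of the coupled C-S-O2 reservoir system.

State vector (units 1e18 mol; isotope compositions in permil):

* masses - ocean-atmosphere carbon, young/ancient crustal organic carbon and
  carbonate, young/ancient pyrite and gypsum, ocean sulphate, and
  ocean-atmosphere O2;
* compositions - d13C of the four crustal carbon reservoirs and d34S of
  sulphate and the four crustal sulphur reservoirs.

The seawater d13C itself is prescribed by the driving record (that is the
point of the isotope-mass-balance inversion), so it is not a free state.

CO2 closure
-----------
Carbonate burial is set by alkalinity supply, F_bc = F_wc + F_ws, so the
ocean-atmosphere carbon balance reduces to

    F_ws = (degassing + organic weathering) - F_bg ,

the classical quasi-equilibrium between silicate weathering drawdown and net
CO2 sources.  Because the organic burial flux from IMB is *linear* in the
climate multiplier m (through young carbonate weathering), m has a closed
form each step and RCO2 is recovered diagnostically by inverting the climate
function.  This keeps the right-hand side root-free and fast.

Time convention: the internal ODE time runs forward in Myr from the start
age; all I/O is in Ma before present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import json
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import carbon, sulphur
from .config import ModelConfig
from .errors import ConfigError, ModelFailureError, ValidationError
from .forcings import ALL_FIELDS, ForcingSet, ForcingValues
from .records import IsotopeRecord

__all__ = [
    "STATE_FIELDS", "ReservoirState", "FailureInfo", "Trajectory",
    "initialize", "derivatives", "compute_fluxes", "integrate",
    "o2_percent_atm", "o2mr_from_percent",
]

logger = logging.getLogger(__name__)

STATE_FIELDS = (
    "oa_c", "corg_y", "corg_a", "ccarb_y", "ccarb_a",
    "pyr_y", "pyr_a", "gyp_y", "gyp_a", "oa_s", "o2",
    "d13c_corg_y", "d13c_corg_a", "d13c_ccarb_y", "d13c_ccarb_a",
    "d34s_oa", "d34s_pyr_y", "d34s_pyr_a", "d34s_gyp_y", "d34s_gyp_a",
)
_IDX = {name: i for i, name in enumerate(STATE_FIELDS)}
_MASS_FIELDS = STATE_FIELDS[:11]

#: mol O2 released per mol pyrite S buried (8 SO4 -> 4 FeS2 frees 15 O2)
PYRITE_O2_STOICH = 15.0 / 8.0

FLUX_FIELDS = (
    "f_bg", "f_bc", "f_ws", "f_wc_y", "f_wc_a", "f_wg_y", "f_wg_a",
    "degas_org_y", "degas_org_a", "degas_carb_y", "degas_carb_a",
    "t_org", "t_carb",
    "f_wp_y", "f_wp_a", "f_wgyp_y", "f_wgyp_a", "f_bp", "f_bgyp",
    "degas_pyr_y", "degas_pyr_a", "degas_gyp_y", "degas_gyp_a",
    "t_pyr", "t_gyp",
)


@dataclass
class ReservoirState:
    """Named view of the 20-component state vector."""

    oa_c: float
    corg_y: float
    corg_a: float
    ccarb_y: float
    ccarb_a: float
    pyr_y: float
    pyr_a: float
    gyp_y: float
    gyp_a: float
    oa_s: float
    o2: float
    d13c_corg_y: float
    d13c_corg_a: float
    d13c_ccarb_y: float
    d13c_ccarb_a: float
    d34s_oa: float
    d34s_pyr_y: float
    d34s_pyr_a: float
    d34s_gyp_y: float
    d34s_gyp_a: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ReservoirState":
        return cls(**{name: float(y[i]) for i, name in enumerate(STATE_FIELDS)})

    @property
    def total_carbon(self) -> float:
        return self.oa_c + self.corg_y + self.corg_a + self.ccarb_y + self.ccarb_a

    @property
    def total_sulphur(self) -> float:
        return self.oa_s + self.pyr_y + self.pyr_a + self.gyp_y + self.gyp_a


@dataclass
class FailureInfo:
    """Structured model failure: when and why a run left the physical domain."""
    age: float          # Ma at which the run stopped
    cause: str          # machine-readable cause (e.g. 'o2_floor')
    detail: str = ""


def o2_percent_atm(o2mr: float | np.ndarray) -> float | np.ndarray:
    """Atmospheric O2 mixing ratio (% atm) at a fixed non-O2 inventory.

    21% at present (O2mr = 1); monotone in O2mr.
    """
    o2mr = np.asarray(o2mr, dtype=float)
    if np.any(o2mr <= 0):
        raise ValidationError("o2mr must be positive")
    out = 100.0 * o2mr / (o2mr + 79.0 / 21.0)
    return float(out) if out.ndim == 0 else out


def o2mr_from_percent(pct: float) -> float:
    """Inverse of :func:`o2_percent_atm`."""
    if not 0.0 < pct < 100.0:
        raise ValidationError("percent O2 must lie in (0, 100)")
    return (79.0 / 21.0) * pct / (100.0 - pct)


# ---------------------------------------------------------------------------
# run context: precomputed interpolation tables and derived constants
# ---------------------------------------------------------------------------

class _RunContext:
    """Everything the right-hand side needs, precomputed once per run."""

    def __init__(self, config: ModelConfig, forcings: ForcingSet,
                 record: IsotopeRecord, start_age: float):
        if forcings.age[0] < start_age - 1e-9 or forcings.age[-1] > 1e-9:
            raise ValidationError("forcings do not span [0, start_age]")
        if record.age[0] < start_age - 1e-9 or record.age[-1] > 1e-9:
            raise ValidationError("record does not span [0, start_age]")

        self.config = config
        self.start_age = start_age
        # ascending-age copies for np.interp
        self._f_age = forcings.age[::-1].copy()
        self._f_vals = {name: getattr(forcings, name)[::-1].copy()
                        for name in ALL_FIELDS}
        self._r_age = record.age[::-1].copy()
        self._r_delta = record.delta[::-1].copy()
        self.slope_h = 0.5  # Myr half-width for the record slope stencil
        self.diagnostics = {"fbg_clipped": 0, "o2mr_floored": 0}

    def forcings_at(self, age: float) -> ForcingValues:
        return ForcingValues(**{name: float(np.interp(age, self._f_age, vals))
                                for name, vals in self._f_vals.items()})

    def record_value(self, age: float) -> float:
        return float(np.interp(age, self._r_age, self._r_delta))

    def record_slope(self, age: float) -> float:
        """d(delta)/dt in forward time, central difference over the span."""
        hi = min(age + self.slope_h, self._r_age[-1])
        lo = max(age - self.slope_h, self._r_age[0])
        if hi <= lo:
            return 0.0
        v_hi = float(np.interp(hi, self._r_age, self._r_delta))
        v_lo = float(np.interp(lo, self._r_age, self._r_delta))
        return (v_lo - v_hi) / (hi - lo)


def compute_fluxes(age: float, y: np.ndarray,
                   ctx: _RunContext) -> tuple[dict[str, float], dict[str, Any]]:
    """All fluxes (1e18 mol/Myr) and diagnostics at one (age, state) point.

    Raises :class:`ModelFailureError` when the state leaves the domain in a
    way the flux laws cannot represent (fractionation collapse, silicate
    weathering closure failure).
    """
    cfg = ctx.config
    fv = ctx.forcings_at(age)
    rec_d = ctx.record_value(age)
    rec_slope = ctx.record_slope(age)

    m_ = {name: max(float(y[_IDX[name]]), 0.0) for name in _MASS_FIELDS}
    d13c_cy = float(y[_IDX["d13c_ccarb_y"]])
    d13c_ca = float(y[_IDX["d13c_ccarb_a"]])
    d13c_oy = float(y[_IDX["d13c_corg_y"]])
    d13c_oa_ = float(y[_IDX["d13c_corg_a"]])

    o2mr_raw = m_["o2"] / cfg.o2_0
    o2mr = max(o2mr_raw, cfg.o2mr_floor)
    if o2mr_raw < cfg.o2mr_floor:
        ctx.diagnostics["o2mr_floored"] += 1

    frac = carbon.carbon_fractionation(o2mr, cfg.j, cfg.delta0)
    erosion = carbon.erosion_factor(fv.fA, fv.fD, cfg.erosion_area_exp,
                                    cfg.erosion_runoff_exp)

    # --- climate-independent carbon fluxes ---
    f_wg_y, f_wg_a = carbon.organic_weathering_flux(
        m_["corg_y"], m_["corg_a"], erosion, o2mr,
        fwg_y0=cfg.fwg_y0, fwg_a0=cfg.fwg_a0,
        corg_y0=cfg.corg_y0, corg_a0=cfg.corg_a0, beta=cfg.beta)
    f_wc_a = cfg.fwc_a0 * (m_["ccarb_a"] / cfg.ccarb_a0) * erosion
    pw = carbon.carbonate_degassing_weight(fv.carb_platform_fraction,
                                           cfg.platform_frac0,
                                           cfg.shallow_degas_rel)
    degas_carb_y = carbon.degassing_flux(
        m_["ccarb_y"], cfg.degas_carb_y0 / cfg.ccarb_y0, fv.fSR, pw)
    degas_carb_a = carbon.degassing_flux(
        m_["ccarb_a"], cfg.degas_carb_a0 / cfg.ccarb_a0, fv.fSR, pw)
    degas_org_y = carbon.degassing_flux(
        m_["corg_y"], cfg.degas_org_y0 / cfg.corg_y0, fv.fSR)
    degas_org_a = carbon.degassing_flux(
        m_["corg_a"], cfg.degas_org_a0 / cfg.corg_a0, fv.fSR)

    # --- closed-form climate multiplier (see module docstring) ---
    ws_base = carbon.silicate_weathering_base(cfg.fws0, erosion, fv.fAW,
                                              fv.plant_weathering)
    wc_y_base = cfg.fwc_y0 * fv.fL * erosion * (m_["ccarb_y"] / cfg.ccarb_y0)

    inputs_fixed = (
        (f_wc_a, d13c_ca), (degas_carb_y, d13c_cy), (degas_carb_a, d13c_ca),
        (f_wg_y, d13c_oy), (f_wg_a, d13c_oa_),
        (degas_org_y, d13c_oy), (degas_org_a, d13c_oa_),
    )
    a_term = (m_["oa_c"] * rec_slope
              + sum(f * (rec_d - d) for f, d in inputs_fixed)) / frac
    b_term = wc_y_base * (rec_d - d13c_cy) / frac
    co2_sources = (degas_carb_y + degas_carb_a + degas_org_y + degas_org_a
                   + f_wg_y + f_wg_a)
    denom = ws_base + b_term
    if denom <= 0 or ws_base <= 0:
        raise ModelFailureError("silicate weathering closure degenerate",
                                age=age, cause="weathering_closure")
    m_clim = (co2_sources - a_term) / denom
    fbg_clipped = False
    if a_term + b_term * m_clim < 0.0:
        # IMB demands negative organic burial: clip and rebalance CO2
        fbg_clipped = True
        ctx.diagnostics["fbg_clipped"] += 1
        f_bg = 0.0
        m_clim = co2_sources / ws_base
    else:
        f_bg = a_term + b_term * m_clim
    if m_clim <= 1e-6:
        raise ModelFailureError(
            "climate multiplier collapsed: silicate weathering cannot "
            "balance the IMB burial demand", age=age, cause="co2_collapse")

    f_ws = ws_base * m_clim
    f_wc_y = wc_y_base * m_clim
    f_bc = f_wc_y + f_wc_a + f_ws

    t_org = (cfg.t_org0 / cfg.corg_y0) * m_["corg_y"]
    t_carb = (cfg.t_carb0 / cfg.ccarb_y0) * m_["ccarb_y"]

    # --- sulphur ---
    f_wp_y = sulphur.young_pyrite_weathering(
        f_ws / cfg.fws0, m_["pyr_y"] / cfg.pyr_y0, o2mr, cfg.new_kwp)
    f_wgyp_y = sulphur.young_gypsum_weathering(
        f_wc_y / cfg.fwc_y0, m_["gyp_y"] / cfg.gyp_y0, cfg.new_kwgyp)
    f_wp_a, f_wgyp_a = sulphur.ancient_sulphur_weathering(
        m_["pyr_a"], m_["gyp_a"], erosion, o2mr,
        fwp_a0=cfg.fwp_a0, fwgyp_a0=cfg.fwgyp_a0,
        pyr_a0=cfg.pyr_a0, gyp_a0=cfg.gyp_a0)
    f_bp = sulphur.pyrite_burial(m_["oa_s"] / cfg.oa_s0, f_bg / cfg.fbg0,
                                 o2mr, cfg.k_bp, cfg.o2mr_floor)
    f_bgyp = sulphur.gypsum_burial(m_["oa_s"] / cfg.oa_s0, fv.calcium,
                                   cfg.k_bgyp)
    s_aux = sulphur.sulphur_degassing_and_transfer(
        m_["pyr_y"], m_["pyr_a"], m_["gyp_y"], m_["gyp_a"], fv.fSR,
        k_degas_pyr_y=cfg.degas_pyr_y0 / cfg.pyr_y0,
        k_degas_pyr_a=cfg.degas_pyr_a0 / cfg.pyr_a0,
        k_degas_gyp_y=cfg.degas_gyp_y0 / cfg.gyp_y0,
        k_degas_gyp_a=cfg.degas_gyp_a0 / cfg.gyp_a0,
        k_t_pyr=cfg.t_pyr0 / cfg.pyr_y0, k_t_gyp=cfg.t_gyp0 / cfg.gyp_y0)

    fluxes = {
        "f_bg": f_bg, "f_bc": f_bc, "f_ws": f_ws,
        "f_wc_y": f_wc_y, "f_wc_a": f_wc_a,
        "f_wg_y": f_wg_y, "f_wg_a": f_wg_a,
        "degas_org_y": degas_org_y, "degas_org_a": degas_org_a,
        "degas_carb_y": degas_carb_y, "degas_carb_a": degas_carb_a,
        "t_org": t_org, "t_carb": t_carb,
        "f_wp_y": f_wp_y, "f_wp_a": f_wp_a,
        "f_wgyp_y": f_wgyp_y, "f_wgyp_a": f_wgyp_a,
        "f_bp": f_bp, "f_bgyp": f_bgyp,
        "t_pyr": s_aux["t_pyr"], "t_gyp": s_aux["t_gyp"],
        "degas_pyr_y": s_aux["degas_pyr_y"], "degas_pyr_a": s_aux["degas_pyr_a"],
        "degas_gyp_y": s_aux["degas_gyp_y"], "degas_gyp_a": s_aux["degas_gyp_a"],
    }
    for name, value in fluxes.items():
        if not np.isfinite(value) or value < 0:
            raise ModelFailureError(f"flux {name!r} = {value!r} is invalid",
                                    age=age, cause="flux_assembly")
    diag = {"m_climate": m_clim, "frac": frac, "o2mr": o2mr,
            "rec_delta": rec_d, "rec_slope": rec_slope,
            "fbg_clipped": fbg_clipped,
            "o2mr_floored": o2mr_raw < cfg.o2mr_floor, "geog": fv.GEOG}
    return fluxes, diag


def assemble_derivatives(y: np.ndarray, fluxes: dict[str, float],
                         diag: dict[str, Any], cfg: ModelConfig) -> np.ndarray:
    """Derivative vector from a flux set; fluxes only move mass internally."""
    f = fluxes
    dy = np.zeros(len(STATE_FIELDS))
    carbon_inputs = (f["f_wc_y"] + f["f_wc_a"] + f["degas_carb_y"]
                     + f["degas_carb_a"] + f["f_wg_y"] + f["f_wg_a"]
                     + f["degas_org_y"] + f["degas_org_a"])
    dy[_IDX["oa_c"]] = carbon_inputs - f["f_bg"] - f["f_bc"]
    dy[_IDX["corg_y"]] = f["f_bg"] - f["f_wg_y"] - f["degas_org_y"] - f["t_org"]
    dy[_IDX["corg_a"]] = f["t_org"] - f["f_wg_a"] - f["degas_org_a"]
    dy[_IDX["ccarb_y"]] = (f["f_bc"] - f["f_wc_y"] - f["degas_carb_y"]
                           - f["t_carb"])
    dy[_IDX["ccarb_a"]] = f["t_carb"] - f["f_wc_a"] - f["degas_carb_a"]

    dy[_IDX["pyr_y"]] = (f["f_bp"] - f["f_wp_y"] - f["degas_pyr_y"]
                         - f["t_pyr"])
    dy[_IDX["pyr_a"]] = f["t_pyr"] - f["f_wp_a"] - f["degas_pyr_a"]
    dy[_IDX["gyp_y"]] = (f["f_bgyp"] - f["f_wgyp_y"] - f["degas_gyp_y"]
                         - f["t_gyp"])
    dy[_IDX["gyp_a"]] = f["t_gyp"] - f["f_wgyp_a"] - f["degas_gyp_a"]
    s_inputs = (f["f_wp_y"] + f["f_wp_a"] + f["f_wgyp_y"] + f["f_wgyp_a"]
                + f["degas_pyr_y"] + f["degas_pyr_a"] + f["degas_gyp_y"]
                + f["degas_gyp_a"])
    dy[_IDX["oa_s"]] = s_inputs - f["f_bp"] - f["f_bgyp"]

    pyr_net = (f["f_bp"] - f["f_wp_y"] - f["f_wp_a"]
               - f["degas_pyr_y"] - f["degas_pyr_a"])
    dy[_IDX["o2"]] = (f["f_bg"] - f["f_wg_y"] - f["f_wg_a"]
                      - f["degas_org_y"] - f["degas_org_a"]
                      + PYRITE_O2_STOICH * pyr_net)

    # crustal carbon isotope budgets (inputs mix in; outputs leave at own d13C)
    eps = 1e-12
    rec_d = diag["rec_delta"]
    d_bury_org = rec_d - diag["frac"]
    dy[_IDX["d13c_corg_y"]] = f["f_bg"] * (d_bury_org - y[_IDX["d13c_corg_y"]]) \
        / max(y[_IDX["corg_y"]], eps)
    dy[_IDX["d13c_corg_a"]] = f["t_org"] * (y[_IDX["d13c_corg_y"]]
                                            - y[_IDX["d13c_corg_a"]]) \
        / max(y[_IDX["corg_a"]], eps)
    dy[_IDX["d13c_ccarb_y"]] = f["f_bc"] * (rec_d - y[_IDX["d13c_ccarb_y"]]) \
        / max(y[_IDX["ccarb_y"]], eps)
    dy[_IDX["d13c_ccarb_a"]] = f["t_carb"] * (y[_IDX["d13c_ccarb_y"]]
                                              - y[_IDX["d13c_ccarb_a"]]) \
        / max(y[_IDX["ccarb_a"]], eps)

    s_masses = {k: float(y[_IDX[k]]) for k in
                ("oa_s", "pyr_y", "pyr_a", "gyp_y", "gyp_a")}
    s_deltas = {"oa_s": float(y[_IDX["d34s_oa"]]),
                "pyr_y": float(y[_IDX["d34s_pyr_y"]]),
                "pyr_a": float(y[_IDX["d34s_pyr_a"]]),
                "gyp_y": float(y[_IDX["d34s_gyp_y"]]),
                "gyp_a": float(y[_IDX["d34s_gyp_a"]])}
    ds = sulphur.update_delta34s(s_masses, s_deltas, f, cfg.alpha_s_forward)
    dy[_IDX["d34s_oa"]] = ds["oa_s"]
    dy[_IDX["d34s_pyr_y"]] = ds["pyr_y"]
    dy[_IDX["d34s_pyr_a"]] = ds["pyr_a"]
    dy[_IDX["d34s_gyp_y"]] = ds["gyp_y"]
    dy[_IDX["d34s_gyp_a"]] = ds["gyp_a"]
    return dy


def derivatives(state: ReservoirState | np.ndarray, age: float,
                config: ModelConfig, forcings: ForcingSet,
                record: IsotopeRecord) -> np.ndarray:
    """Full derivative field d(state)/dt (per Myr of forward time) at ``age``."""
    y = state.to_array() if isinstance(state, ReservoirState) else \
        np.asarray(state, dtype=float)
    ctx = _RunContext(config, forcings, record,
                      min(forcings.age[0], record.age[0]))
    fluxes, diag = compute_fluxes(age, y, ctx)
    return assemble_derivatives(y, fluxes, diag, config)


def initialize(config: ModelConfig, legacy: bool = False) -> ReservoirState:
    """State at the start age.

    Sulphur is apportioned from the configured totals (default: 418e18 mol
    total, 38 ocean sulphate, 280 pyrite, 100 gypsum - a 2.8:1
    pyrite:gypsum ratio; ``legacy=True`` restores the 638e18 mol, 1:1
    apportionment).  Carbon reservoirs and all compositions start at their
    configured near-steady values.
    """
    if legacy:
        total, oas = config.legacy_total_s, config.legacy_oa_s_init
        pyr, gyp = config.legacy_pyr_total_init, config.legacy_gyp_total_init
    else:
        total, oas = config.total_s, config.oa_s_init
        pyr, gyp = config.pyr_total_init, config.gyp_total_init
    if abs(oas + pyr + gyp - total) > 1e-9 * max(1.0, total):
        raise ConfigError("sulphur apportionment does not sum to the total")
    return ReservoirState(
        oa_c=config.oa_c0,
        corg_y=config.corg_y0, corg_a=config.corg_a0,
        ccarb_y=config.ccarb_y0, ccarb_a=config.ccarb_a0,
        pyr_y=config.young_frac_pyr * pyr,
        pyr_a=(1 - config.young_frac_pyr) * pyr,
        gyp_y=config.young_frac_gyp * gyp,
        gyp_a=(1 - config.young_frac_gyp) * gyp,
        oa_s=oas, o2=config.o2_0,
        d13c_corg_y=config.d13c_org0, d13c_corg_a=config.d13c_org0,
        d13c_ccarb_y=config.d13c_carb0, d13c_ccarb_a=config.d13c_carb0,
        d34s_oa=config.d34s_sulphate0,
        d34s_pyr_y=config.d34s_sulphate0 - config.alpha_s_forward,
        d34s_pyr_a=config.d34s_sulphate0 - config.alpha_s_forward,
        d34s_gyp_y=config.d34s_sulphate0, d34s_gyp_a=config.d34s_sulphate0,
    )


@dataclass
class Trajectory:
    """Reported time series of a model run.

    ``ages`` descends from the start age toward 0 Ma (it stops early when a
    run fails); states are row-per-age.  Fluxes, RCO2 and pO2 are
    recomputed on the reporting grid from the integrated state.
    """

    ages: np.ndarray
    states: np.ndarray                  # (n_ages, n_state)
    o2mr: np.ndarray
    o2_pct: np.ndarray
    rco2: np.ndarray
    fluxes: dict[str, np.ndarray]
    d34s_sulphate: np.ndarray
    d13c_input: np.ndarray
    fbg_clipped: np.ndarray             # bool per reported age
    o2mr_floored: np.ndarray
    config: ModelConfig
    failure: FailureInfo | None = None
    solver_diagnostics: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.failure is None

    def state_series(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    @property
    def total_carbon(self) -> np.ndarray:
        return sum(self.state_series(n) for n in
                   ("oa_c", "corg_y", "corg_a", "ccarb_y", "ccarb_a"))

    @property
    def total_sulphur(self) -> np.ndarray:
        return sum(self.state_series(n) for n in
                   ("oa_s", "pyr_y", "pyr_a", "gyp_y", "gyp_a"))

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {
            "age_ma": self.ages, "o2_pct": self.o2_pct, "o2mr": self.o2mr,
            "rco2": self.rco2,
        }
        for name in STATE_FIELDS:
            data[name] = self.state_series(name)
        for name in FLUX_FIELDS:
            data[name] = self.fluxes[name]
        data["d34s_sulphate"] = self.d34s_sulphate
        data["d13c_input"] = self.d13c_input
        data["flag_fbg_clipped"] = self.fbg_clipped.astype(int)
        data["flag_o2mr_floored"] = self.o2mr_floored.astype(int)
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        """Write the trajectory plus a config/failure sidecar for provenance."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "failure": None if self.failure is None else {
                "age": self.failure.age, "cause": self.failure.cause,
                "detail": self.failure.detail},
            "solver_diagnostics": self.solver_diagnostics,
        }
        path.with_suffix(path.suffix + ".config.json").write_text(
            json.dumps(sidecar, indent=2))


def integrate(config: ModelConfig, forcings: ForcingSet,
              record: IsotopeRecord, *, legacy_init: bool = False,
              initial_state: ReservoirState | None = None,
              start_age: float | None = None,
              rtol: float | None = None, atol: float | None = None,
              ) -> Trajectory:
    """Integrate from the start age to 0 Ma with an adaptive implicit solver.

    Failures (oxygen or sulphate floor breach, CO2 collapse, solver
    non-convergence) terminate the run and are reported in
    ``Trajectory.failure``; the trajectory holds the portion completed.
    """
    start = float(start_age if start_age is not None else config.start_age)
    if start <= 0:
        raise ValidationError("start age must be positive")
    ctx = _RunContext(config, forcings, record, start)
    state0 = initial_state if initial_state is not None else \
        initialize(config, legacy=legacy_init)
    y0 = state0.to_array()

    o2_floor = config.o2mr_floor * config.o2_0
    oa_s_floor = 1e-3 * config.oa_s0

    def rhs(tau: float, y: np.ndarray) -> np.ndarray:
        age = start - tau
        fluxes, diag = compute_fluxes(age, y, ctx)
        return assemble_derivatives(y, fluxes, diag, config)

    def o2_event(tau: float, y: np.ndarray) -> float:
        return y[_IDX["o2"]] - o2_floor

    def sulphate_event(tau: float, y: np.ndarray) -> float:
        return y[_IDX["oa_s"]] - oa_s_floor

    o2_event.terminal = True          # type: ignore[attr-defined]
    o2_event.direction = -1           # type: ignore[attr-defined]
    sulphate_event.terminal = True    # type: ignore[attr-defined]
    sulphate_event.direction = -1     # type: ignore[attr-defined]

    n_report = int(round(start / config.report_step))
    t_eval = np.linspace(0.0, start, n_report + 1)

    failure: FailureInfo | None = None
    try:
        sol = solve_ivp(rhs, (0.0, start), y0, method="Radau", t_eval=t_eval,
                        events=(o2_event, sulphate_event),
                        rtol=rtol if rtol is not None else config.rtol,
                        atol=atol if atol is not None else config.atol,
                        max_step=config.max_step, dense_output=False)
    except ModelFailureError as exc:
        logger.warning("model failure during integration: %s", exc)
        failure = FailureInfo(age=exc.age if exc.age is not None else np.nan,
                              cause=exc.cause, detail=str(exc))
        return _empty_trajectory(config, ctx, start, failure)

    times = sol.t
    ys = sol.y
    if sol.status == 1:  # terminated on an event
        causes = ("o2_floor", "sulphate_floor")
        which = next(i for i, te in enumerate(sol.t_events) if te.size)
        tau_ev = float(sol.t_events[which][0])
        failure = FailureInfo(age=start - tau_ev, cause=causes[which],
                              detail=f"state floor reached at {start - tau_ev:.2f} Ma")
        times = np.append(times, tau_ev)
        ys = np.hstack([ys, sol.y_events[which][0][:, None]])
    elif sol.status < 0:
        failure = FailureInfo(age=start - float(sol.t[-1]) if sol.t.size else start,
                              cause="solver_failure", detail=sol.message)

    return _build_trajectory(config, ctx, start, times, ys, failure)


def _empty_trajectory(config: ModelConfig, ctx: _RunContext, start: float,
                      failure: FailureInfo) -> Trajectory:
    empty = np.array([])
    return Trajectory(ages=empty, states=np.empty((0, len(STATE_FIELDS))),
                      o2mr=empty, o2_pct=empty, rco2=empty,
                      fluxes={name: empty for name in FLUX_FIELDS},
                      d34s_sulphate=empty, d13c_input=empty,
                      fbg_clipped=np.array([], dtype=bool),
                      o2mr_floored=np.array([], dtype=bool),
                      config=config, failure=failure,
                      solver_diagnostics=dict(ctx.diagnostics))


def _build_trajectory(config: ModelConfig, ctx: _RunContext, start: float,
                      times: np.ndarray, ys: np.ndarray,
                      failure: FailureInfo | None) -> Trajectory:
    n = times.size
    ages = start - times
    fluxes = {name: np.empty(n) for name in FLUX_FIELDS}
    rco2 = np.empty(n)
    clipped = np.zeros(n, dtype=bool)
    floored = np.zeros(n, dtype=bool)
    d13c_in = np.empty(n)
    for i in range(n):
        try:
            fl, diag = compute_fluxes(float(ages[i]), ys[:, i], ctx)
        except ModelFailureError:
            for name in FLUX_FIELDS:
                fluxes[name][i] = np.nan
            rco2[i] = np.nan
            d13c_in[i] = ctx.record_value(float(ages[i]))
            continue
        for name in FLUX_FIELDS:
            fluxes[name][i] = fl[name]
        rco2[i] = carbon.invert_climate_multiplier(
            diag["m_climate"], config.gcm, diag["geog"], config.act_coeff,
            config.runoff_coeff, config.runoff_exp)
        clipped[i] = diag["fbg_clipped"]
        floored[i] = diag["o2mr_floored"]
        d13c_in[i] = diag["rec_delta"]

    o2mr = np.maximum(ys[_IDX["o2"], :] / config.o2_0, config.o2mr_floor * 1e-3)
    return Trajectory(
        ages=ages, states=ys.T.copy(), o2mr=o2mr,
        o2_pct=o2_percent_atm(o2mr), rco2=rco2, fluxes=fluxes,
        d34s_sulphate=ys[_IDX["d34s_oa"], :].copy(), d13c_input=d13c_in,
        fbg_clipped=clipped, o2mr_floored=floored, config=config,
        failure=failure, solver_diagnostics=dict(ctx.diagnostics))
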