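"""Carbon-side fluxes: IMB organic burial, weathering, degassing, climate feedback.

Organic carbon burial is not computed from productivity but *inverted* from
the carbonate d13C record by isotope mass balance (IMB): given the isotopic
compositions of the carbon inputs to the ocean-atmosphere reservoir and the
carbonate-organic fractionation, the burial flux is whatever is needed to
hold the seawater composition on the record,

    F_bg = [ M_oa * d(delta_rec)/dt + sum_i F_i (delta_rec - delta_i) ] / DELTA

with DELTA the fractionation.  DELTA itself depends on oxygen,
DELTA = delta0 + J (O2mr - 1): higher O2 means larger fractionation, so less
burial is needed for the same isotopic shift - the stabilizing feedback.

Weathering fluxes follow the GEOCARB-family multiplicative structure: a
present-day anchor flux times normalized forcings, a reservoir-size ratio,
an erosion term in land area and runoff, and (for silicate and young
carbonate) a climate multiplier in RCO2 and paleogeography.  Oxidative
weathering of organic carbon scales as O2mr**beta.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

from scipy.optimize import brentq

from .errors import ModelFailureError, ValidationError

__all__ = [
    "carbon_fractionation", "organic_burial_imb", "climate_multiplier",
    "invert_climate_multiplier", "erosion_factor", "silicate_weathering_base",
    "silicate_weathering_flux", "carbonate_weathering_flux",
    "organic_weathering_flux", "degassing_flux", "carbonate_degassing_weight",
    "steady_state_delta13c",
]

logger = logging.getLogger(__name__)


def carbon_fractionation(o2mr: float, j: float, delta0: float = 25.0) -> float:
    """Carbonate-organic fractionation DELTA13C (permil) at normalized O2.

    Linear in O2mr with slope ``j``; equals ``delta0`` at present O2.
    A non-positive result means the inversion is ill-posed and is raised as
    a model failure.
    """
    if o2mr <= 0:
        raise ValidationError("o2mr must be positive")
    frac = delta0 + j * (o2mr - 1.0)
    if frac <= 0:
        raise ModelFailureError(
            f"carbon fractionation {frac:.3f} permil is non-positive at "
            f"O2mr={o2mr:.4f}", cause="fractionation_collapse")
    return frac


def organic_burial_imb(oa_c: float, rec_value: float, rec_slope: float,
                       inputs: Sequence[tuple[float, float]],
                       frac: float) -> tuple[float, bool]:
    """Organic burial flux from the d13C mass balance of the surface reservoir.

    Parameters
    ----------
    oa_c
        Ocean-atmosphere carbon mass (1e18 mol).
    rec_value, rec_slope
        Record d13C (permil) and its forward-time derivative (permil/Myr).
    inputs
        ``(flux, delta)`` pairs for every carbon input (weathering and
        degassing), fluxes in 1e18 mol/Myr.
    frac
        Carbonate-organic fractionation (permil), must be positive.

    Returns
    -------
    (F_bg, clipped)
        Burial flux and whether a negative demand was clipped to zero.
    """
    if frac <= 0:
        raise ModelFailureError("non-positive fractionation in IMB",
                                cause="fractionation_collapse")
    demand = oa_c * rec_slope
    for flux, delta in inputs:
        demand += flux * (rec_value - delta)
    fbg = demand / frac
    if fbg < 0:
        logger.warning("IMB demands negative organic burial (%.4g); clipped "
                       "to zero", fbg)
        return 0.0, True
    return fbg, False


# ---------------------------------------------------------------------------
# climate / weathering machinery
# ---------------------------------------------------------------------------

def climate_multiplier(rco2: float, gcm: float, geog: float = 0.0,
                       act_coeff: float = 0.09, runoff_coeff: float = 0.045,
                       runoff_exp: float = 0.65) -> float:
    """Weathering multiplier from CO2-driven warming plus paleogeography.

    Temperature offset dT = gcm * ln(RCO2) + GEOG feeds a kinetic
    (exponential) term and a runoff term; equals 1 at RCO2 = 1, GEOG = 0 and
    is strictly increasing in RCO2 for gcm > 0.
    """
    if rco2 <= 0:
        raise ValidationError("RCO2 must be positive")
    dt = gcm * math.log(rco2) + geog
    runoff = 1.0 + runoff_coeff * dt
    if runoff <= 0:
        return 0.0
    return math.exp(act_coeff * dt) * runoff ** runoff_exp


def invert_climate_multiplier(m: float, gcm: float, geog: float = 0.0,
                              act_coeff: float = 0.09,
                              runoff_coeff: float = 0.045,
                              runoff_exp: float = 0.65) -> float:
    """RCO2 at which :func:`climate_multiplier` equals ``m`` (diagnostic)."""
    if m <= 0:
        raise ValidationError("climate multiplier must be positive")

    def g(dt: float) -> float:
        runoff = max(1.0 + runoff_coeff * dt, 0.0)
        return math.exp(act_coeff * dt) * runoff ** runoff_exp - m

    lo = -1.0 / runoff_coeff + 1e-9  # multiplier -> 0 here
    hi = 100.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e5:
            raise ModelFailureError("climate multiplier inversion diverged",
                                    cause="rco2_inversion")
    dt = brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
    return math.exp((dt - geog) / gcm)


def erosion_factor(fA: float, fD: float, area_exp: float = 0.5,
                   runoff_exp: float = 0.65) -> float:
    """Erosion/runoff forcing term shared by the weathering fluxes."""
    if fA <= 0 or fD <= 0:
        raise ValidationError("fA and fD must be positive")
    return fA ** area_exp * fD ** runoff_exp


def silicate_weathering_base(fws0: float, erosion: float, fAW: float,
                             plant: float) -> float:
    """Silicate weathering with the climate multiplier factored out."""
    if fAW <= 0 or plant <= 0:
        raise ValidationError("fAW and plant_weathering must be positive")
    return fws0 * erosion * fAW * plant


def silicate_weathering_flux(rco2: float, erosion: float, fAW: float,
                             plant: float, geog: float, *, fws0: float,
                             gcm: float, act_coeff: float = 0.09,
                             runoff_coeff: float = 0.045,
                             runoff_exp: float = 0.65) -> float:
    """Silicate weathering flux (1e18 mol/Myr); equals ``fws0`` at present."""
    base = silicate_weathering_base(fws0, erosion, fAW, plant)
    return base * climate_multiplier(rco2, gcm, geog, act_coeff,
                                     runoff_coeff, runoff_exp)


def carbonate_weathering_flux(ccarb_y: float, ccarb_a: float, fL: float,
                              erosion: float, climate: float, *,
                              fwc_y0: float, fwc_a0: float, ccarb_y0: float,
                              ccarb_a0: float) -> tuple[float, float]:
    """Young and ancient carbonate weathering (1e18 mol/Myr).

    The young flux carries the carbonate land fraction and the climate
    multiplier; the ancient flux is a rate constant times the ancient
    reservoir times erosion only.
    """
    if ccarb_y < 0 or ccarb_a < 0:
        raise ValidationError("carbonate reservoirs must be non-negative")
    f_y = fwc_y0 * fL * erosion * climate * (ccarb_y / ccarb_y0)
    f_a = fwc_a0 * (ccarb_a / ccarb_a0) * erosion
    return f_y, f_a


def organic_weathering_flux(corg_y: float, corg_a: float, erosion: float,
                            o2mr: float, *, fwg_y0: float, fwg_a0: float,
                            corg_y0: float, corg_a0: float,
                            beta: float = 0.5) -> tuple[float, float]:
    """Oxidative weathering of young and ancient organic carbon.

    Scales with the reservoir, the erosion forcing and O2mr**beta, so it
    vanishes without free oxygen.
    """
    if o2mr < 0:
        raise ValidationError("o2mr must be non-negative")
    ox = o2mr ** beta
    f_y = fwg_y0 * (corg_y / corg_y0) * erosion * ox
    f_a = fwg_a0 * (corg_a / corg_a0) * erosion * ox
    return f_y, f_a


def carbonate_degassing_weight(platform_forcing: float,
                               platform_frac0: float = 0.5,
                               shallow_rel: float = 0.5) -> float:
    """Platform/deep-ocean weighting on carbonate degassing; 1 at present.

    Deep-ocean carbonate is recycled more efficiently than platform
    carbonate (``shallow_rel`` < 1), so shifting deposition onto platforms
    lowers the degassing flux.
    """
    frac = min(max(platform_frac0 * platform_forcing, 0.0), 1.0)
    present = shallow_rel * platform_frac0 + (1.0 - platform_frac0)
    return (shallow_rel * frac + (1.0 - frac)) / present


def degassing_flux(mass: float, k_degas: float, fsr: float,
                   weight: float = 1.0) -> float:
    """Metamorphic/volcanic degassing: rate constant x reservoir x spreading."""
    if mass < 0 or k_degas < 0 or fsr < 0:
        raise ValidationError("degassing inputs must be non-negative")
    return k_degas * mass * fsr * weight


def steady_state_delta13c(config) -> float:
    """Record d13C at which IMB returns the configured present burial flux.

    Closed form of the steady-state mass balance with all reservoirs at
    their configured compositions; the synthetic steady fixture uses this so
    a config change cannot silently break the balance anchor.
    """
    inputs = [
        (config.fwc_y0 + config.fwc_a0 + config.degas_carb_y0
         + config.degas_carb_a0, config.d13c_carb0),
        (config.fwg_y0 + config.fwg_a0 + config.degas_org_y0
         + config.degas_org_a0, config.d13c_org0),
    ]
    total = sum(f for f, _ in inputs)
    weighted = sum(f * d for f, d in inputs)
    return (config.fbg0 * config.delta0 + weighted) / total
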