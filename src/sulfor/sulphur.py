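"""Forward sulphur cycle, plus the legacy isotope-inversion scheme as diagnostic.

The defining structural choice of this model: pyrite and gypsum burial are
computed *forwards* from model state - ocean sulphate, the organic burial
flux, oxygen - instead of being inverted from the d34S record.  Young pyrite
weathers with silicate rocks and young gypsum with carbonate rocks, so those
fluxes ride on the respective weathering functions:

    F_wp_y   = (F_ws / F_ws_0)   * new_kwp   * (Pyr_y / Pyr_0) * O2mr**0.5
    F_wgyp_y = (F_wc_y / F_wc_y0) * new_kwgyp * (Gyp_y / Gyp_0)
    F_bp     = k_bp   * (OA_S / OA_S_0) * (F_bg / F_bg_0) * (1 / O2mr)
    F_bgyp   = k_bgyp * (OA_S / OA_S_0) * Calc

The 1/O2mr term in pyrite burial is the retained oxygen feedback (more
anoxia, more pyrite); it is singular at zero oxygen, so callers guard O2mr
with a configurable floor.  The d34S record plays no role in any flux here -
it is reserved for validation of the synthetic d34S output.

The legacy scheme (fractionation alpha_s = delta_s0 * O2mr**n feeding an IMB
inversion for pyrite burial) is exposed purely as a diagnostic of its own
low-oxygen pathology: as O2 drops, alpha_s collapses and the inverted burial
flux diverges.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import ModelFailureError, ValidationError

__all__ = [
    "young_pyrite_weathering", "young_gypsum_weathering", "pyrite_burial",
    "gypsum_burial", "ancient_sulphur_weathering",
    "sulphur_degassing_and_transfer", "update_delta34s",
    "legacy_alpha_s", "legacy_pyrite_burial_imb",
]


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValidationError(f"{name} must be non-negative, got {value!r}")


def young_pyrite_weathering(f_ws_ratio: float, pyr_y_ratio: float,
                            o2mr: float, new_kwp: float = 0.35) -> float:
    """Young pyrite weathering; rides on silicate weathering, O2mr**0.5."""
    _check_nonneg(f_ws_ratio=f_ws_ratio, pyr_y_ratio=pyr_y_ratio, o2mr=o2mr)
    return f_ws_ratio * new_kwp * pyr_y_ratio * o2mr ** 0.5


def young_gypsum_weathering(f_wc_y_ratio: float, gyp_y_ratio: float,
                            new_kwgyp: float = 0.6) -> float:
    """Young gypsum weathering; rides on young carbonate weathering."""
    _check_nonneg(f_wc_y_ratio=f_wc_y_ratio, gyp_y_ratio=gyp_y_ratio)
    return f_wc_y_ratio * new_kwgyp * gyp_y_ratio


def pyrite_burial(oa_s_ratio: float, f_bg_ratio: float, o2mr: float,
                  k_bp: float = 0.53, o2mr_floor: float = 1e-3) -> float:
    """Pyrite burial: sulphate supply x organic delivery x inverse oxygen.

    Strictly decreasing in O2mr.  O2mr below ``o2mr_floor`` is clamped to
    the floor (the singular limit is a model-failure condition handled by
    the integrator's state floors).
    """
    _check_nonneg(oa_s_ratio=oa_s_ratio, f_bg_ratio=f_bg_ratio)
    if o2mr <= 0:
        raise ModelFailureError("pyrite burial is singular at zero O2",
                                cause="o2_floor")
    return k_bp * oa_s_ratio * f_bg_ratio / max(o2mr, o2mr_floor)


def gypsum_burial(oa_s_ratio: float, calc: float,
                  k_bgyp: float = 1.0) -> float:
    """Gypsum burial: sulphate supply times the normalized calcium reservoir."""
    _check_nonneg(oa_s_ratio=oa_s_ratio, calc=calc)
    return k_bgyp * oa_s_ratio * calc


def ancient_sulphur_weathering(pyr_a: float, gyp_a: float, erosion: float,
                               o2mr: float, *, fwp_a0: float = 0.15,
                               fwgyp_a0: float = 0.3, pyr_a0: float = 210.0,
                               gyp_a0: float = 60.0) -> tuple[float, float]:
    """Ancient pyrite (O2-sensitive) and gypsum (O2-insensitive) weathering."""
    _check_nonneg(pyr_a=pyr_a, gyp_a=gyp_a, erosion=erosion, o2mr=o2mr)
    f_wp_a = fwp_a0 * (pyr_a / pyr_a0) * erosion * o2mr ** 0.5
    f_wgyp_a = fwgyp_a0 * (gyp_a / gyp_a0) * erosion
    return f_wp_a, f_wgyp_a


def sulphur_degassing_and_transfer(
        pyr_y: float, pyr_a: float, gyp_y: float, gyp_a: float, fsr: float, *,
        k_degas_pyr_y: float, k_degas_pyr_a: float, k_degas_gyp_y: float,
        k_degas_gyp_a: float, k_t_pyr: float, k_t_gyp: float,
) -> dict[str, float]:
    """Degassing (linear in mass and spreading rate) and young->ancient transfer.

    Transfers depend only on the young reservoir mass.  Degassed sulphur is
    routed to ocean sulphate (emitted oxidized), keeping the system closed.
    """
    _check_nonneg(pyr_y=pyr_y, pyr_a=pyr_a, gyp_y=gyp_y, gyp_a=gyp_a, fsr=fsr)
    return {
        "degas_pyr_y": k_degas_pyr_y * pyr_y * fsr,
        "degas_pyr_a": k_degas_pyr_a * pyr_a * fsr,
        "degas_gyp_y": k_degas_gyp_y * gyp_y * fsr,
        "degas_gyp_a": k_degas_gyp_a * gyp_a * fsr,
        "t_pyr": k_t_pyr * pyr_y,
        "t_gyp": k_t_gyp * gyp_y,
    }


def update_delta34s(masses: Mapping[str, float], deltas: Mapping[str, float],
                    fluxes: Mapping[str, float],
                    alpha_s_forward: float = 35.0,
                    oa_s_floor: float = 1e-6) -> dict[str, float]:
    """Time derivatives of the five d34S compositions (permil/Myr).

    Pyrite is buried at sulphate d34S minus ``alpha_s_forward``; gypsum at
    sulphate d34S unfractionated; weathering and degassing return each
    crustal reservoir's own composition.  Total 34S-weighted mass is
    conserved by construction.

    ``masses``/``deltas`` keys: ``oa_s, pyr_y, pyr_a, gyp_y, gyp_a``;
    ``fluxes`` keys as produced by the flux routines
    (``f_wp_y, f_wp_a, f_wgyp_y, f_wgyp_a, f_bp, f_bgyp, degas_*, t_pyr,
    t_gyp``).
    """
    oa_s = masses["oa_s"]
    if oa_s <= oa_s_floor:
        raise ModelFailureError("ocean sulphate below isotope-budget floor",
                                cause="sulphate_floor")
    d_s = deltas["oa_s"]
    inputs = (
        (fluxes["f_wp_y"] + fluxes["degas_pyr_y"], deltas["pyr_y"]),
        (fluxes["f_wp_a"] + fluxes["degas_pyr_a"], deltas["pyr_a"]),
        (fluxes["f_wgyp_y"] + fluxes["degas_gyp_y"], deltas["gyp_y"]),
        (fluxes["f_wgyp_a"] + fluxes["degas_gyp_a"], deltas["gyp_a"]),
    )
    budget = sum(f * (d - d_s) for f, d in inputs)
    budget += fluxes["f_bp"] * alpha_s_forward  # burial removes light S
    out = {"oa_s": budget / oa_s}

    d_bury_pyr = d_s - alpha_s_forward
    eps = 1e-12
    out["pyr_y"] = fluxes["f_bp"] * (d_bury_pyr - deltas["pyr_y"]) \
        / max(masses["pyr_y"], eps)
    out["gyp_y"] = fluxes["f_bgyp"] * (d_s - deltas["gyp_y"]) \
        / max(masses["gyp_y"], eps)
    out["pyr_a"] = fluxes["t_pyr"] * (deltas["pyr_y"] - deltas["pyr_a"]) \
        / max(masses["pyr_a"], eps)
    out["gyp_a"] = fluxes["t_gyp"] * (deltas["gyp_y"] - deltas["gyp_a"]) \
        / max(masses["gyp_a"], eps)
    return out


def legacy_alpha_s(o2mr: float, delta_s0: float = 35.0,
                   n: float = 1.5) -> float:
    """Legacy power-law sulphur fractionation alpha_s = delta_s0 * O2mr**n."""
    if o2mr < 0:
        raise ValidationError("o2mr must be non-negative")
    return delta_s0 * o2mr ** n


def legacy_pyrite_burial_imb(alpha_s: float,
                             inputs: Sequence[tuple[float, float]],
                             rec_value: float, rec_slope: float,
                             oa_s: float) -> float:
    """Pyrite burial inverted from a d34S record (legacy scheme).

    Mirrors the organic-carbon IMB with alpha_s in the denominator, hence
    the documented divergence as alpha_s -> 0 at low oxygen.
    """
    if alpha_s <= 0:
        raise ModelFailureError("legacy inversion requires alpha_s > 0",
                                cause="alpha_s_collapse")
    demand = oa_s * rec_slope
    for flux, delta in inputs:
        demand += flux * (rec_value - delta)
    return demand / alpha_s
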