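import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sulfor import ModelFailureError
from sulfor.sulphur import (ancient_sulphur_weathering, gypsum_burial,
                            legacy_alpha_s, legacy_pyrite_burial_imb,
                            pyrite_burial, sulphur_degassing_and_transfer,
                            update_delta34s, young_gypsum_weathering,
                            young_pyrite_weathering)

KWP, KWGYP, KBP, KBGYP = 0.35, 0.6, 0.53, 1.0


class TestForwardFluxEquations:
    def test_young_pyrite_weathering_scalings(self):
        assert young_pyrite_weathering(1, 1, 1, KWP) == pytest.approx(KWP)
        assert young_pyrite_weathering(1, 1, 0.25, KWP) == pytest.approx(0.5 * KWP)
        assert young_pyrite_weathering(2, 0.5, 1, KWP) == pytest.approx(KWP)

    def test_young_gypsum_weathering_scalings(self):
        assert young_gypsum_weathering(1, 1, KWGYP) == pytest.approx(KWGYP)
        assert young_gypsum_weathering(2, 0.5, KWGYP) == pytest.approx(KWGYP)
        assert young_gypsum_weathering(3.0, 0.0, KWGYP) == 0.0

    def test_pyrite_burial_inverse_oxygen(self):
        assert pyrite_burial(1, 1, 1, KBP) == pytest.approx(KBP)
        assert pyrite_burial(1, 1, 0.5, KBP) == pytest.approx(2 * KBP)
        assert pyrite_burial(0.5, 2, 1, KBP) == pytest.approx(KBP)
        with pytest.raises(ModelFailureError):
            pyrite_burial(1, 1, 0.0, KBP)

    def test_pyrite_burial_floor_caps_the_singularity(self):
        capped = pyrite_burial(1, 1, 1e-9, KBP, o2mr_floor=1e-3)
        assert capped == pytest.approx(KBP / 1e-3)

    def test_gypsum_burial_calcium_scaling(self):
        assert gypsum_burial(1, 1, KBGYP) == pytest.approx(KBGYP)
        assert gypsum_burial(1, 0.5, KBGYP) == pytest.approx(0.5 * KBGYP)
        assert gypsum_burial(0, 1, KBGYP) == 0.0

    def test_ancient_weathering_oxygen_feedback_on_pyrite_only(self):
        kw = dict(fwp_a0=0.15, fwgyp_a0=0.3, pyr_a0=210.0, gyp_a0=60.0)
        anchor = ancient_sulphur_weathering(210.0, 60.0, 1.0, 1.0, **kw)
        assert anchor == (pytest.approx(0.15), pytest.approx(0.3))
        low = ancient_sulphur_weathering(210.0, 60.0, 1.0, 0.25, **kw)
        assert low[0] == pytest.approx(0.075)
        assert low[1] == pytest.approx(0.3)
        zero_pyr = ancient_sulphur_weathering(0.0, 60.0, 1.0, 1.0, **kw)
        assert zero_pyr == (0.0, pytest.approx(0.3))

    def test_degassing_and_transfer_linearity(self):
        kw = dict(k_degas_pyr_y=0.01 / 70, k_degas_pyr_a=0.02 / 210,
                  k_degas_gyp_y=0.05 / 40, k_degas_gyp_a=0.05 / 60,
                  k_t_pyr=0.17 / 70, k_t_gyp=0.35 / 40)
        present = sulphur_degassing_and_transfer(70, 210, 40, 60, 1.0, **kw)
        assert present["degas_pyr_y"] == pytest.approx(0.01)
        assert present["t_gyp"] == pytest.approx(0.35)
        no_spread = sulphur_degassing_and_transfer(70, 210, 40, 60, 0.0, **kw)
        assert no_spread["degas_gyp_a"] == 0.0
        assert no_spread["t_pyr"] == pytest.approx(present["t_pyr"])
        doubled = sulphur_degassing_and_transfer(140, 210, 40, 60, 1.0, **kw)
        assert doubled["t_pyr"] == pytest.approx(2 * present["t_pyr"])

    def test_negative_feedback_directions(self):
        # more oxygen: less pyrite burial, more pyrite weathering -
        # both push O2 back down
        assert pyrite_burial(1, 1, 1.5, KBP) < pyrite_burial(1, 1, 1.0, KBP)
        assert young_pyrite_weathering(1, 1, 1.5, KWP) > \
            young_pyrite_weathering(1, 1, 1.0, KWP)


def _balanced_fluxes(scale=1.0):
    return {k: v * scale for k, v in {
        "f_wp_y": 0.35, "f_wp_a": 0.15, "f_wgyp_y": 0.6, "f_wgyp_a": 0.3,
        "f_bp": 0.53, "f_bgyp": 1.0, "degas_pyr_y": 0.01, "degas_pyr_a": 0.02,
        "degas_gyp_y": 0.05, "degas_gyp_a": 0.05, "t_pyr": 0.17,
        "t_gyp": 0.35}.items()}


_MASSES = {"oa_s": 38.0, "pyr_y": 70.0, "pyr_a": 210.0,
           "gyp_y": 40.0, "gyp_a": 60.0}


class TestDelta34SBudget:
    def test_uniform_composition_without_fractionation_is_fixed_point(self):
        deltas = {k: 12.0 for k in _MASSES}
        out = update_delta34s(_MASSES, deltas, _balanced_fluxes(),
                              alpha_s_forward=0.0)
        assert all(abs(v) < 1e-14 for v in out.values())

    def test_steady_reference_composition_is_fixed_point(self):
        deltas = {"oa_s": 20.0, "pyr_y": -15.0, "pyr_a": -15.0,
                  "gyp_y": 20.0, "gyp_a": 20.0}
        out = update_delta34s(_MASSES, deltas, _balanced_fluxes(),
                              alpha_s_forward=35.0)
        assert all(abs(v) < 1e-12 for v in out.values())

    def test_pyrite_burial_alone_drives_sulphate_heavy(self):
        deltas = {k: 20.0 for k in _MASSES}
        fluxes = {k: 0.0 for k in _balanced_fluxes()}
        fluxes["f_bp"] = 0.5
        out = update_delta34s(_MASSES, deltas, fluxes, alpha_s_forward=35.0)
        assert out["oa_s"] > 0

    def test_doubling_fluxes_doubles_sulphate_tendency(self):
        deltas = {"oa_s": 20.0, "pyr_y": -10.0, "pyr_a": -18.0,
                  "gyp_y": 22.0, "gyp_a": 17.0}
        one = update_delta34s(_MASSES, deltas, _balanced_fluxes(1.0))
        two = update_delta34s(_MASSES, deltas, _balanced_fluxes(2.0))
        for key in one:
            assert two[key] == pytest.approx(2 * one[key], abs=1e-14)

    def test_empty_sulphate_reservoir_rejected(self):
        masses = dict(_MASSES, oa_s=0.0)
        with pytest.raises(ModelFailureError):
            update_delta34s(masses, {k: 0.0 for k in _MASSES},
                            _balanced_fluxes())

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_total_isotope_mass_conserved(self, seed):
        """sum(M_i * delta_i) must be invariant under the isotope budget."""
        rng = np.random.default_rng(seed)
        deltas = {k: float(rng.uniform(-30, 30)) for k in _MASSES}
        fluxes = {k: float(rng.uniform(0, 2)) for k in _balanced_fluxes()}
        out = update_delta34s(_MASSES, deltas, fluxes, alpha_s_forward=35.0)
        # mass derivatives implied by the same fluxes
        dm = {
            "oa_s": sum(fluxes[k] for k in ("f_wp_y", "f_wp_a", "f_wgyp_y",
                                            "f_wgyp_a", "degas_pyr_y",
                                            "degas_pyr_a", "degas_gyp_y",
                                            "degas_gyp_a"))
            - fluxes["f_bp"] - fluxes["f_bgyp"],
            "pyr_y": fluxes["f_bp"] - fluxes["f_wp_y"]
            - fluxes["degas_pyr_y"] - fluxes["t_pyr"],
            "pyr_a": fluxes["t_pyr"] - fluxes["f_wp_a"] - fluxes["degas_pyr_a"],
            "gyp_y": fluxes["f_bgyp"] - fluxes["f_wgyp_y"]
            - fluxes["degas_gyp_y"] - fluxes["t_gyp"],
            "gyp_a": fluxes["t_gyp"] - fluxes["f_wgyp_a"]
            - fluxes["degas_gyp_a"],
        }
        total = sum(_MASSES[k] * out[k] + deltas[k] * dm[k] for k in _MASSES)
        assert total == pytest.approx(0.0, abs=1e-9)


class TestLegacyScheme:
    def test_alpha_s_power_law(self):
        assert legacy_alpha_s(1.0) == 35.0
        assert legacy_alpha_s(0.25, 35.0, 1.5) == pytest.approx(4.375)
        assert legacy_alpha_s(0.0) == 0.0

    def test_imb_inversion_steady_fraction(self):
        # input 15 permil lighter than the record, 30 permil fractionation:
        # half the sulphate input is buried as pyrite
        fbp = legacy_pyrite_burial_imb(30.0, [(1.0, -15.0)], 0.0, 0.0, 38.0)
        assert fbp == pytest.approx(0.5)

    def test_halving_fractionation_doubles_burial(self):
        a = legacy_pyrite_burial_imb(30.0, [(1.0, -15.0)], 0.0, 0.0, 38.0)
        b = legacy_pyrite_burial_imb(15.0, [(1.0, -15.0)], 0.0, 0.0, 38.0)
        assert b == pytest.approx(2 * a)

    def test_no_isotopic_demand_means_no_burial(self):
        assert legacy_pyrite_burial_imb(30.0, [(1.0, 5.0)], 5.0, 0.0, 38.0) == 0.0

    def test_nonpositive_fractionation_rejected(self):
        with pytest.raises(ModelFailureError):
            legacy_pyrite_burial_imb(0.0, [(1.0, -15.0)], 0.0, 0.0, 38.0)
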