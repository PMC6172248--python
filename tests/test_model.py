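import dataclasses

import numpy as np
import pytest

import sulfor
from sulfor import (ConfigError, ModelConfig, ValidationError, initialize,
                    integrate, o2_percent_atm, o2mr_from_percent)
from sulfor.model import (PYRITE_O2_STOICH, STATE_FIELDS, _IDX, _RunContext,
                          assemble_derivatives, compute_fluxes)


class TestInitialize:
    def test_default_apportionment(self, config):
        st = initialize(config)
        assert st.total_sulphur == pytest.approx(418.0)
        assert st.oa_s == 38.0
        pyr, gyp = st.pyr_y + st.pyr_a, st.gyp_y + st.gyp_a
        assert pyr == pytest.approx(280.0) and gyp == pytest.approx(100.0)
        assert pyr / gyp == pytest.approx(2.8)

    def test_legacy_apportionment(self, config):
        st = initialize(config, legacy=True)
        assert st.total_sulphur == pytest.approx(638.0)
        assert st.pyr_y + st.pyr_a == pytest.approx(300.0)
        assert st.gyp_y + st.gyp_a == pytest.approx(300.0)

    def test_inconsistent_apportionment_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(total_s=500.0)  # no longer sums with 38+280+100


class TestO2Conversion:
    @pytest.mark.parametrize("o2mr,pct", [
        (1.0, 21.0), (0.5, 11.7318), (2.0, 34.7107)])
    def test_percent_examples(self, o2mr, pct):
        assert o2_percent_atm(o2mr) == pytest.approx(pct, abs=1e-3)

    def test_roundtrip_and_monotonicity(self):
        grid = np.linspace(0.05, 3.0, 40)
        pct = o2_percent_atm(grid)
        assert np.all(np.diff(pct) > 0)
        back = np.array([o2mr_from_percent(p) for p in pct])
        assert np.allclose(back, grid)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            o2_percent_atm(0.0)
        with pytest.raises(ValidationError):
            o2mr_from_percent(100.0)


class TestDerivativeField:
    def test_anchor_state_is_steady(self, steady_fixture):
        forcings, d13c, _, cfg = steady_fixture
        st = initialize(cfg)
        dy = sulfor.derivatives(st, cfg.start_age, cfg, forcings, d13c)
        assert np.max(np.abs(dy)) < 1e-10

    def test_excess_oxygen_is_drawn_down(self, steady_fixture):
        forcings, d13c, _, cfg = steady_fixture
        st = dataclasses.replace(initialize(cfg), o2=cfg.o2_0 * 1.1)
        dy = sulfor.derivatives(st, 300.0, cfg, forcings, d13c)
        assert dy[_IDX["o2"]] < 0

    def test_pyrite_burial_oxygen_stoichiometry(self, steady_fixture):
        # a unit of pyrite burial must add 15/8 mol O2 per mol S
        forcings, d13c, _, cfg = steady_fixture
        st = initialize(cfg)
        ctx = _RunContext(cfg, forcings, d13c, cfg.start_age)
        y = st.to_array()
        fluxes, diag = compute_fluxes(cfg.start_age, y, ctx)
        base = assemble_derivatives(y, fluxes, diag, cfg)
        bumped = dict(fluxes, f_bp=fluxes["f_bp"] + 1.0)
        out = assemble_derivatives(y, bumped, diag, cfg)
        assert out[_IDX["o2"]] - base[_IDX["o2"]] == pytest.approx(
            PYRITE_O2_STOICH)
        assert PYRITE_O2_STOICH == pytest.approx(15.0 / 8.0)


class TestIntegration:
    def test_steady_fixture_holds_present_oxygen(self, steady_traj):
        assert steady_traj.ok
        assert steady_traj.ages[0] == 570.0 and steady_traj.ages[-1] == 0.0
        assert np.max(np.abs(steady_traj.o2_pct - 21.0)) < 0.1

    def test_mass_conservation_over_full_run(self, excursion_traj):
        s = excursion_traj.total_sulphur
        c = excursion_traj.total_carbon
        assert np.max(np.abs(s - s[0])) / s[0] < 1e-6
        assert np.max(np.abs(c - c[0])) / c[0] < 1e-6

    def test_isotope_weighted_sulphur_mass_conserved(self, excursion_traj):
        traj = excursion_traj
        pairs = [("oa_s", "d34s_oa"), ("pyr_y", "d34s_pyr_y"),
                 ("pyr_a", "d34s_pyr_a"), ("gyp_y", "d34s_gyp_y"),
                 ("gyp_a", "d34s_gyp_a")]
        weighted = sum(traj.state_series(m) * traj.state_series(d)
                       for m, d in pairs)
        scale = sum(traj.state_series(m) * np.abs(traj.state_series(d))
                    for m, d in pairs)[0]
        assert np.max(np.abs(weighted - weighted[0])) / scale < 1e-5

    def test_tolerance_halving_self_convergence(self, excursion_fixture,
                                                excursion_traj):
        forcings, d13c, _, cfg = excursion_fixture
        finer = integrate(cfg, forcings, d13c, rtol=cfg.rtol / 2,
                          atol=cfg.atol / 2)
        rel = np.abs(finer.o2_pct - excursion_traj.o2_pct) \
            / excursion_traj.o2_pct
        assert np.max(rel) < 1e-3

    def test_explicit_euler_oracle_on_subinterval(self, excursion_fixture,
                                                  excursion_traj):
        """Brute-force explicit Euler at 1-kyr steps across the excursion
        must match the stiff solver in every state variable."""
        forcings, d13c, _, cfg = excursion_fixture
        ctx = _RunContext(cfg, forcings, d13c, cfg.start_age)
        i0 = int(np.argmin(np.abs(excursion_traj.ages - 505.0)))
        y = excursion_traj.states[i0].copy()
        age, h = float(excursion_traj.ages[i0]), 1e-3
        for k in range(int(round(10.0 / h))):
            fluxes, diag = compute_fluxes(age, y, ctx)
            y = y + h * assemble_derivatives(y, fluxes, diag, cfg)
            age -= h
        i1 = int(np.argmin(np.abs(excursion_traj.ages - age)))
        ref = excursion_traj.states[i1]
        rel = np.abs(y - ref) / np.maximum(np.abs(ref), 1e-6)
        assert np.max(rel) < 5e-3

    def test_oxygen_perturbation_relaxes_back(self, steady_fixture):
        forcings, d13c, _, cfg = steady_fixture
        st = dataclasses.replace(initialize(cfg), o2=cfg.o2_0 * 1.1)
        traj = integrate(cfg, forcings, d13c, initial_state=st,
                         start_age=300.0)
        assert traj.ok
        marks = [float(np.abs(traj.o2_pct - 21.0)[
            np.argmin(np.abs(traj.ages - a))]) for a in
            (300, 290, 280, 270, 260, 250)]
        assert all(a > b for a, b in zip(marks, marks[1:]))
        assert marks[-1] < 0.3 * marks[0]  # mostly recovered within 50 Myr

    def test_stress_fixture_fails_structurally(self, stress_fixture):
        forcings, d13c, _, cfg = stress_fixture
        traj = integrate(cfg, forcings, d13c)
        assert not traj.ok
        assert traj.failure.cause == "o2_floor"
        assert 0.0 < traj.failure.age < cfg.start_age
        # the reported portion of the run is finite, never NaN garbage
        assert np.all(np.isfinite(traj.states))

    def test_trajectory_csv_roundtrip_with_config_sidecar(self, tmp_path,
                                                          steady_traj):
        out = tmp_path / "traj.csv"
        steady_traj.write_csv(out)
        assert out.exists()
        sidecar = out.with_suffix(".csv.config.json")
        assert sidecar.exists()
        import json
        meta = json.loads(sidecar.read_text())
        assert meta["config"]["sulphur"]["total_s"] == 418.0
        import pandas as pd
        df = pd.read_csv(out)
        assert set(STATE_FIELDS) <= set(df.columns)
        assert {"age_ma", "o2_pct", "rco2", "d34s_sulphate",
                "d13c_input"} <= set(df.columns)
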