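"""Solver verification against analytic oracles and basic invariants.

The expensive full pulsatile runs live in the acceptance tests; here the
solver is exercised on small steady/short-transient problems with known
answers.
"""

import numpy as np
import pytest

from stenoflow import (CarreauParams, FluidParams, InletWaveform,
                       SimulationConfig, StenosisGeometry, ConfigurationError,
                       run_simulation)
from stenoflow.solver import _Simple, _build_operator, step
from stenoflow.waveform import build_waveform


def small_operator(outlet_pressure=0.0, waveform=None):
    geom = StenosisGeometry(r_s=1.4e-3, l_c=1e-3, l_s=1e-3, l_d=1e-3,
                            L_prox=4e-3, L_dist=4e-3)
    cfg = SimulationConfig(outlet_mode="PL", outlet_pressure=outlet_pressure,
                           nz_per_mm=2, nr=12)
    wf = waveform or InletWaveform.constant(0.0)
    return _build_operator(geom, CarreauParams.newtonian(0.00345),
                           FluidParams(), None, wf, cfg), cfg


class TestRestState:
    def test_rest_is_a_fixed_point(self):
        op, cfg = small_operator()
        sim = _Simple(op)
        info = sim.advance(cfg.dt)
        assert np.abs(sim.uz).max() == 0.0
        assert np.abs(sim.ur).max() == 0.0
        assert np.ptp(sim.p) == 0.0
        assert info["mass_balance"] == 0.0

    def test_step_wrapper_preserves_rest(self):
        op, cfg = small_operator()
        sim = _Simple(op)
        st = sim.state()
        st2 = step(st, sim, cfg, cfg.dt)
        assert np.abs(st2.uz).max() == 0.0
        assert st2.t == cfg.dt


class TestAnalyticOracles:
    def test_poiseuille_gradient(self, poiseuille_check):
        # steady Newtonian tube flow vs 8*mu*v/R^2
        assert abs(poiseuille_check.rel_err) < 0.02, str(poiseuille_check)

    def test_porous_slug_gradient(self, slug_check):
        # steady seepage vs phi*mu*u/k
        assert abs(slug_check.rel_err) < 0.01, str(slug_check)


class TestTransient:
    def test_mass_balance_short_pulsatile_run(self):
        geom = StenosisGeometry(L_prox=6e-3, L_dist=6e-3)
        cfg = SimulationConfig(outlet_mode="PL", nz_per_mm=2, nr=16,
                               n_cycles=1, steps_per_cycle=10,
                               probe_planes=(3e-3, 12e-3))
        h = run_simulation(geom, CarreauParams(), FluidParams(), None,
                           build_waveform(), cfg)
        assert np.all(h.mass_error <= 1e-3)
        assert h.times.shape == (10,)
        assert np.all(np.isfinite(h.p_mean))

    def test_determinism_bit_identical(self):
        geom = StenosisGeometry(L_prox=6e-3, L_dist=6e-3)
        cfg = SimulationConfig(outlet_mode="PL", nz_per_mm=2, nr=12,
                               n_cycles=1, steps_per_cycle=4,
                               probe_planes=(3e-3, 12e-3))
        args = (geom, CarreauParams(), FluidParams(), None)
        h1 = run_simulation(*args, build_waveform(), cfg)
        h2 = run_simulation(*args, build_waveform(), cfg)
        assert np.array_equal(h1.p_mean, h2.p_mean)
        assert np.array_equal(h1.uz_mean, h2.uz_mean)

    def test_bdf2_runs_and_conserves_mass(self):
        geom = StenosisGeometry(L_prox=6e-3, L_dist=6e-3)
        cfg = SimulationConfig(outlet_mode="PL", nz_per_mm=2, nr=12,
                               n_cycles=1, steps_per_cycle=4,
                               time_scheme="bdf2", probe_planes=(3e-3, 12e-3))
        h = run_simulation(geom, CarreauParams(), FluidParams(), None,
                           build_waveform(), cfg)
        assert np.all(h.mass_error <= 1e-3)


class TestPorousLoad:
    def test_steady_ffr_increases_with_bed_length(self):
        # a longer porous bed adds Darcy resistance, raising the whole
        # pressure level and pushing FFR toward 1
        from stenoflow.constitutive import PorousParams
        from stenoflow.solver import (run_steady, _probe_indices,
                                      _probe_sample, default_probe_planes)
        ffrs = []
        for L in (0.1e-3, 0.2e-3, 0.4e-3):
            geom = StenosisGeometry(L_porous=L)
            cfg = SimulationConfig(outlet_mode="ML")
            sim, op = run_steady(geom, CarreauParams(), FluidParams(),
                                 PorousParams(), 0.28, cfg)
            ia, idx = _probe_indices(op.grid, default_probe_planes(geom))
            ffrs.append(_probe_sample(sim, idx)[0] / _probe_sample(sim, ia)[0])
        assert ffrs[0] < ffrs[1] < ffrs[2]


class TestConfigConsistency:
    def test_pl_with_porous_geometry_rejected(self):
        geom = StenosisGeometry(L_porous=1e-3)
        cfg = SimulationConfig(outlet_mode="PL")
        with pytest.raises(ConfigurationError):
            run_simulation(geom, CarreauParams(), FluidParams(), None,
                           build_waveform(), cfg)

    def test_ml_without_porous_geometry_rejected(self):
        geom = StenosisGeometry()
        cfg = SimulationConfig(outlet_mode="ML")
        with pytest.raises(ConfigurationError):
            run_simulation(geom, CarreauParams(), FluidParams(), None,
                           build_waveform(), cfg)
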