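"""Cycle statistics, FFR and report assembly tests.

The printed-table consistency harness checks that the fluctuation
definition (range / peak * 100) reproduces every percent cell of the
reference results table from its own peak/low cells.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow import (ConfigurationError, ContractViolation, DomainError,
                       SimulationConfig, StenosisGeometry, compute_ffr,
                       fluctuation_stats, make_report, report_from_traces,
                       time_average)
from stenoflow.solver import FieldHistory

# reference results table: per outlet mode, (peak_a, peak_d, low_a, low_d,
# range_a, pct_a, range_d, pct_d, FFR)
TABLE = {
    "ML": (7170, 5480, 1980, 1760, 5190, 72.4, 3720, 67.9, 0.813),
    "PL": (4540, 2870, 2960, 2740, 1580, 34.8, 130, 4.53, 0.776),
}


class TestTimeAverage:
    def test_constant(self):
        assert time_average(np.full(100, 42.0)) == pytest.approx(42.0)

    def test_sinusoid_about_mean(self):
        t = np.linspace(0, 0.8, 2001)
        y = 5.0 + 3.0 * np.sin(2 * np.pi * t / 0.8)
        assert time_average(y, t) == pytest.approx(5.0, abs=1e-6)

    def test_two_level_equal_time(self):
        n = 4000
        t = np.linspace(0, 1, 2 * n)
        y = np.where(t < 0.5, 100.0, 200.0)
        assert time_average(y, t) == pytest.approx(150.0, abs=0.1)

    def test_rejects_degenerate(self):
        with pytest.raises(ContractViolation):
            time_average([1.0])


class TestFluctuationStats:
    @pytest.mark.parametrize("peak,low,rng,pct", [
        (7170, 1980, 5190, 72.4),   # ML proximal
        (5480, 1760, 3720, 67.9),   # ML distal
        (4540, 2960, 1580, 34.8),   # PL proximal
        (2870, 2740, 130, 4.53),    # PL distal
    ])
    def test_reference_table_cells(self, peak, low, rng, pct):
        trace = np.linspace(low, peak, 50)
        p, lo, r, c = fluctuation_stats(trace)
        assert (p, lo) == (peak, low)
        assert r == pytest.approx(rng, abs=0.5)
        assert c == pytest.approx(pct, abs=0.05)

    def test_constant_trace(self):
        p, lo, r, c = fluctuation_stats(np.full(10, 7.0))
        assert r == 0.0 and c == 0.0

    def test_nonpositive_peak_percent_missing(self):
        _, _, _, c = fluctuation_stats(np.array([-3.0, -1.0]))
        assert c is None


class TestComputeFFR:
    def test_reference_ml(self):
        assert round(compute_ffr(3522.0, 4331.0, 0.0), 3) == 0.813

    def test_reference_pl(self):
        # the printed whole-Pa means give 0.77679; consistent with the
        # printed 0.776 to one unit in the last printed digit
        assert compute_ffr(2805.0, 3611.0, 0.0) == pytest.approx(0.776,
                                                                 abs=1e-3)

    def test_no_pressure_loss(self):
        assert compute_ffr(1234.0, 1234.0, 100.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_driving_pressure(self):
        with pytest.raises(DomainError):
            compute_ffr(100.0, 50.0, 50.0)

    @given(scale=st.floats(0.1, 10), pv=st.floats(0, 500))
    @settings(deadline=None, max_examples=40)
    def test_invariant_under_common_rescaling(self, scale, pv):
        pa, pd_ = 4000.0, 3300.0
        base = compute_ffr(pd_, pa, pv)
        scaled = compute_ffr(pv + scale * (pd_ - pv), pv + scale * (pa - pv), pv)
        assert scaled == pytest.approx(base, rel=1e-10)


def synthetic_history(pa_trace, pd_trace, mode="ML", n_cycles=1):
    """Wrap two single-cycle traces in a FieldHistory."""
    spc = len(pa_trace)
    times = np.arange(1, spc * n_cycles + 1) * 0.0032
    p = np.tile(np.column_stack([pa_trace, pd_trace]), (n_cycles, 1))
    geom = StenosisGeometry(L_porous=0.2e-3 if mode == "ML" else 0.0)
    cfg = SimulationConfig(outlet_mode=mode, steps_per_cycle=spc,
                           n_cycles=n_cycles)
    z = np.array([11e-3, 22.7e-3])
    return FieldHistory(times=times, probe_z=z, p_mean=p,
                        uz_mean=np.zeros_like(p), uz_center=np.zeros_like(p),
                        mass_error=np.zeros(spc * n_cycles),
                        steps_per_cycle=spc, n_cycles=n_cycles,
                        config=cfg, geom=geom)


class TestMakeReport:
    def trace(self, low, peak, n=247):
        x = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return low + (peak - low) * 0.5 * (1 - np.cos(x))

    @pytest.mark.parametrize("mode", ["ML", "PL"])
    def test_reproduces_table_cells_from_extrema(self, mode):
        pa_pk, pd_pk, pa_lo, pd_lo, rng_a, pct_a, rng_d, pct_d, _ = TABLE[mode]
        h = synthetic_history(self.trace(pa_lo, pa_pk),
                              self.trace(pd_lo, pd_pk), mode)
        rep = make_report(h)
        assert rep.p_a_peak == pytest.approx(pa_pk, rel=1e-3)
        assert rep.p_d_peak == pytest.approx(pd_pk, rel=1e-3)
        assert rep.p_a_low == pytest.approx(pa_lo, rel=1e-3)
        assert rep.p_d_low == pytest.approx(pd_lo, rel=1e-3)
        assert rep.p_a_range == pytest.approx(rng_a, rel=1e-3)
        assert rep.p_d_range == pytest.approx(rng_d, rel=1e-3)
        # percent cells at their printed precision (1 d.p.; the small PL
        # distal cell is printed with 2 d.p.)
        assert rep.p_a_range_pct == pytest.approx(pct_a, abs=0.05)
        tol = 0.005 if pct_d < 10 else 0.05
        assert rep.p_d_range_pct == pytest.approx(pct_d, abs=tol)
        assert rep.area_stenosis_pct == pytest.approx(75.0)

    def test_identical_traces_give_unit_ffr(self):
        tr = self.trace(2000, 5000)
        rep = make_report(synthetic_history(tr, tr.copy()))
        assert rep.ffr == pytest.approx(1.0, abs=1e-12)
        assert rep.p_a_avg == rep.p_d_avg

    def test_ffr_identity_holds(self):
        rep = make_report(synthetic_history(self.trace(2000, 5000),
                                            self.trace(1500, 4200)))
        alt = 1.0 - (rep.p_a_avg - rep.p_d_avg) / rep.p_a_avg
        assert rep.ffr == pytest.approx(alt, abs=1e-13)

    def test_missing_plane_rejected(self):
        h = synthetic_history(self.trace(2000, 5000), self.trace(1500, 4200))
        h.probe_z = h.probe_z[:1]
        with pytest.raises(ConfigurationError):
            make_report(h)

    def test_statistics_use_final_cycle(self):
        # first cycle wildly different; report must reflect the last one
        pa = self.trace(3000, 6000)
        pd_ = self.trace(2500, 5000)
        h = synthetic_history(pa, pd_, n_cycles=2)
        h.p_mean[:247, :] *= 10.0
        rep = make_report(h)
        assert rep.p_a_peak == pytest.approx(6000, rel=1e-3)


class TestReportFromTraces:
    def test_round_trip_from_csv_frame(self):
        x = np.linspace(0, 2 * np.pi, 247, endpoint=False)
        pa = 4000 + 1500 * np.sin(x)
        pd_ = 3300 + 1200 * np.sin(x)
        t = np.arange(247) * 0.0032
        df = pd.concat([
            pd.DataFrame({"time_s": t, "plane": 0, "p_mean_Pa": pa}),
            pd.DataFrame({"time_s": t, "plane": 1, "p_mean_Pa": pd_}),
        ])
        rep = report_from_traces(df, 247)
        assert rep.p_a_peak == pytest.approx(pa.max())
        assert rep.ffr == pytest.approx(np.trapezoid(pd_, t)
                                        / np.trapezoid(pa, t), rel=1e-3)
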