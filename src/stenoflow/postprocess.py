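"""Cycle statistics and fractional flow reserve (FFR) from probe traces.

FFR is the clinical index of stenosis severity:

    FFR = (P̃_d - P_v) / (P̃_a - P_v)

with P̃_a / P̃_d the time-averaged pressures proximal/distal to the stenosis
over one cardiac cycle and P_v the venous pressure (taken as 0, the usual
convention).  A Table-style report also carries each probe's peak pressure,
trough ("low") pressure, fluctuation range (peak - low) and fluctuation
percent (range / peak * 100).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ContractViolation, ConfigurationError, DomainError
from .geometry import area_stenosis
from .solver import FieldHistory

__all__ = ["HemoReport", "time_average", "fluctuation_stats", "compute_ffr",
           "make_report"]


def time_average(trace, times=None) -> float:
    """Time-weighted mean of a pressure trace over exactly one cycle
    (trapezoidal quadrature; uniform spacing assumed when ``times`` absent)."""
    y = np.asarray(trace, dtype=float)
    if y.size < 2:
        raise ContractViolation("time_average needs a full-cycle trace")
    if times is None:
        return float(y.mean())
    t = np.asarray(times, dtype=float)
    if t.shape != y.shape:
        raise ContractViolation("trace and times must have matching shapes")
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def fluctuation_stats(trace) -> tuple[float, float, float, float | None]:
    """(peak, low, range, percent) of a cycle trace.

    range = peak - low; percent = range / peak * 100, or None when the peak
    is non-positive (percent undefined).
    """
    y = np.asarray(trace, dtype=float)
    if y.size == 0:
        raise ContractViolation("fluctuation_stats needs a non-empty trace")
    peak, low = float(y.max()), float(y.min())
    rng = peak - low
    pct = rng / peak * 100.0 if peak > 0.0 else None
    return peak, low, rng, pct


def compute_ffr(p_d_avg: float, p_a_avg: float, p_v: float = 0.0) -> float:
    """FFR = (P̃_d - P_v) / (P̃_a - P_v); requires P̃_a > P_v."""
    if p_a_avg <= p_v:
        raise DomainError(
            f"FFR undefined: averaged proximal pressure {p_a_avg} must exceed "
            f"venous pressure {p_v}")
    return (p_d_avg - p_v) / (p_a_avg - p_v)


@dataclass
class HemoReport:
    """Table-style per-run summary: cycle pressure statistics and FFR."""

    outlet_mode: str
    area_stenosis_pct: float
    p_a_peak: float
    p_d_peak: float
    p_a_low: float
    p_d_low: float
    p_a_range: float
    p_d_range: float
    p_a_range_pct: float | None
    p_d_range_pct: float | None
    p_a_avg: float
    p_d_avg: float
    ffr: float
    p_v: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """One-row table mirroring the peak/low/fluctuation/FFR layout."""
        return pd.DataFrame([{
            "outlet": ("Microcirculation Seepage Load"
                       if self.outlet_mode == "ML" else "Pressure Load"),
            "peak_Pa_a": round(self.p_a_peak), "peak_Pa_d": round(self.p_d_peak),
            "low_Pa_a": round(self.p_a_low), "low_Pa_d": round(self.p_d_low),
            "fluct_Pa_a": round(self.p_a_range),
            "fluct_pct_a": None if self.p_a_range_pct is None
            else round(self.p_a_range_pct, 1),
            "fluct_Pa_d": round(self.p_d_range),
            "fluct_pct_d": None if self.p_d_range_pct is None
            else round(self.p_d_range_pct, 2),
            "FFR": round(self.ffr, 3),
            "AS_pct": (round(self.area_stenosis_pct)
                       if np.isfinite(self.area_stenosis_pct) else None),
        }])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)


def report_from_traces(df: pd.DataFrame, steps_per_cycle: int = 247,
                       outlet_mode: str = "?", as_pct: float = float("nan"),
                       p_v: float = 0.0) -> HemoReport:
    """Build a report from a traces table (columns ``time_s``, ``plane``,
    ``p_mean_Pa``) using the final ``steps_per_cycle`` rows of each plane."""
    planes = sorted(df["plane"].unique())
    if len(planes) < 2:
        raise ConfigurationError("traces must contain at least two probe planes")
    stats = {}
    for pl in planes[:2]:
        sub = df[df["plane"] == pl].sort_values("time_s").tail(steps_per_cycle)
        if len(sub) < steps_per_cycle:
            raise ContractViolation("traces shorter than one full cycle")
        peak, low, rng, pct = fluctuation_stats(sub["p_mean_Pa"])
        avg = time_average(sub["p_mean_Pa"].to_numpy(),
                           sub["time_s"].to_numpy())
        stats[pl] = (peak, low, rng, pct, avg)
    (pa_peak, pa_low, pa_rng, pa_pct, pa_avg) = stats[planes[0]]
    (pd_peak, pd_low, pd_rng, pd_pct, pd_avg) = stats[planes[1]]
    return HemoReport(
        outlet_mode=outlet_mode, area_stenosis_pct=as_pct,
        p_a_peak=pa_peak, p_d_peak=pd_peak, p_a_low=pa_low, p_d_low=pd_low,
        p_a_range=pa_rng, p_d_range=pd_rng,
        p_a_range_pct=pa_pct, p_d_range_pct=pd_pct,
        p_a_avg=pa_avg, p_d_avg=pd_avg,
        ffr=compute_ffr(pd_avg, pa_avg, p_v), p_v=p_v)


def make_report(history: FieldHistory, p_v: float = 0.0) -> HemoReport:
    """Assemble the cycle report from the statistics-ready (final) cycle.

    Verifies internally that the two equivalent FFR forms, P̃_d/P̃_a and
    1 - ΔP̃/P̃_a, agree to machine precision (12 decimals) when P_v = 0.
    """
    if history.probe_z.size < 2:
        raise ConfigurationError(
            "report needs both proximal and distal probe planes")
    sl = history.stats_cycle
    t = history.times[sl]
    pa = history.p_mean[sl, 0]
    pd_ = history.p_mean[sl, 1]
    if pa.size != history.steps_per_cycle:
        raise ContractViolation("statistics cycle is incomplete")

    pa_peak, pa_low, pa_rng, pa_pct = fluctuation_stats(pa)
    pd_peak, pd_low, pd_rng, pd_pct = fluctuation_stats(pd_)
    pa_avg = time_average(pa, t)
    pd_avg = time_average(pd_, t)
    ffr = compute_ffr(pd_avg, pa_avg, p_v)
    if p_v == 0.0:
        alt = 1.0 - (pa_avg - pd_avg) / pa_avg
        if abs(ffr - alt) > 1e-12:
            raise ContractViolation(
                f"FFR identity violated: {ffr} vs 1-dP/Pa {alt}")

    return HemoReport(
        outlet_mode=history.config.outlet_mode,
        area_stenosis_pct=area_stenosis(history.geom),
        p_a_peak=pa_peak, p_d_peak=pd_peak, p_a_low=pa_low, p_d_low=pd_low,
        p_a_range=pa_rng, p_d_range=pd_rng,
        p_a_range_pct=pa_pct, p_d_range_pct=pd_pct,
        p_a_avg=pa_avg, p_d_avg=pd_avg, ffr=ffr, p_v=p_v)
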