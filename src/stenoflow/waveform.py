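"""Synthesis of the periodic pulsatile coronary inlet velocity signal.

Only four statistics of the inlet waveform are prescribed: peak velocity,
cycle-mean velocity, trough velocity, and period (equivalently heart rate).
The synthesized signal is periodic, C1-continuous, bounded by the trough and
peak values, and diastolic-dominant (the global maximum falls in the second
half of the cycle, as coronary flow does).

Two templates are provided:

``piecewise-cosine`` (default)
    Two raised-cosine half-waves — a systolic dip to the trough followed by a
    diastolic hump to the peak — joined with zero slope.  The junction level
    follows from the mean constraint in closed form, so all three statistics
    are attained exactly for every admissible (v_min < v_mean < v_max)
    triple.  The systolic fraction defaults to 0.35 of the cycle and is moved
    inside its feasibility interval automatically when the requested
    asymmetry demands it.

``fourier2``
    A two-harmonic Fourier series whose amplitudes/phase are fitted
    numerically to the peak and trough (the mean is the zeroth coefficient),
    then time-shifted so the peak is diastolic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError

__all__ = [
    "InletWaveform",
    "build_waveform",
    "inlet_profile",
    "inlet_face_flux",
    "period_from_heart_rate",
]


@dataclass(frozen=True)
class InletWaveform:
    """Periodic inlet velocity signal: statistics plus a sampler t -> v (m/s)."""

    v_max: float
    v_mean: float
    v_min: float
    period: float
    sampler: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if self.period <= 0.0:
            raise ConfigurationError(f"period must be > 0, got {self.period}")
        if not (self.v_min <= self.v_mean <= self.v_max):
            raise ConfigurationError(
                f"require v_min <= v_mean <= v_max, got "
                f"({self.v_min}, {self.v_mean}, {self.v_max})"
            )

    def __call__(self, t) -> np.ndarray | float:
        out = self.sampler(np.asarray(t, dtype=float))
        return float(out) if np.isscalar(t) else out

    @classmethod
    def constant(cls, v: float, period: float = 0.8) -> "InletWaveform":
        """Degenerate steady 'waveform' (used for steady analytic benchmarks)."""
        return cls(v_max=v, v_mean=v, v_min=v, period=period,
                   sampler=lambda t: np.full_like(np.asarray(t, dtype=float), v))


def period_from_heart_rate(hr: float) -> float:
    """Cycle period in seconds from heart rate in beats/min."""
    if hr <= 0.0:
        raise ConfigurationError(f"heart rate must be > 0, got {hr}")
    return 60.0 / hr


def _systolic_fraction(beta: float, preferred: float = 0.35) -> float:
    """Pick the systolic fraction f_s inside its feasibility interval.

    Attaining both extrema with an interior junction level requires
    1 - 2*beta < f_s < 2 - 2*beta where beta = (v_mean - v_min)/(v_max - v_min).
    """
    lo = max(0.05, 1.0 - 2.0 * beta)
    hi = min(0.95, 2.0 - 2.0 * beta)
    if lo >= hi:  # cannot happen for beta in (0, 1), kept as a guard
        raise ConfigurationError(f"no feasible systolic fraction for beta={beta}")
    if lo < preferred < hi:
        return preferred
    # nudge just inside the interval, keeping a 10% margin
    m = 0.1 * (hi - lo)
    return float(np.clip(preferred, lo + m, hi - m))


def _build_piecewise_cosine(v_max, v_mean, v_min, period) -> Callable:
    beta = (v_mean - v_min) / (v_max - v_min)
    f_s = _systolic_fraction(beta)
    t_s = f_s * period
    # junction level from the exact mean of the two cosine half-waves
    v_j = 2.0 * v_mean - f_s * v_min - (1.0 - f_s) * v_max
    if not (v_min < v_j < v_max):
        raise ConfigurationError(
            f"infeasible waveform statistics: junction level {v_j:.4g} outside "
            f"({v_min}, {v_max})"
        )

    def sampler(t):
        th = np.mod(np.asarray(t, dtype=float), period)
        sys = th < t_s
        out = np.empty_like(th)
        out[sys] = v_j + (v_min - v_j) * 0.5 * (1.0 - np.cos(2.0 * np.pi * th[sys] / t_s))
        td = th[~sys] - t_s
        out[~sys] = v_j + (v_max - v_j) * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * td / (period - t_s))
        )
        return out

    return sampler


def _build_fourier2(v_max, v_mean, v_min, period) -> Callable:
    x = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)

    def extrema(a1, a2, phi2):
        v = v_mean + a1 * np.cos(x) + a2 * np.cos(2.0 * x - phi2)
        return v.max(), v.min()

    # amplitudes fitted for each candidate second-harmonic phase; the best
    # phase wins (the 2x2 problem is well-posed for LM)
    amp = 0.5 * (v_max - v_min)
    best = None
    for phi2 in np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False):
        def resid(p):
            vmax, vmin = extrema(p[0], p[1], phi2)
            return [vmax - v_max, vmin - v_min]

        sol = least_squares(resid, x0=[0.9 * amp, 0.15 * amp], method="lm")
        err = float(np.abs(sol.fun).max())
        if best is None or err < best[0]:
            best = (err, sol.x[0], sol.x[1], phi2)
    err, a1, a2, phi2 = best
    if err > 1e-3:
        raise ConfigurationError(
            "two-harmonic fit failed to attain the requested extrema; "
            "use the piecewise-cosine template"
        )
    # place the peak at 0.675 of the cycle (diastolic)
    v_grid = v_mean + a1 * np.cos(x) + a2 * np.cos(2.0 * x - phi2)
    x_peak = x[np.argmax(v_grid)]
    shift = 0.675 * 2.0 * np.pi - x_peak

    def sampler(t):
        th = 2.0 * np.pi * np.mod(np.asarray(t, dtype=float), period) / period - shift
        return v_mean + a1 * np.cos(th) + a2 * np.cos(2.0 * th - phi2)

    return sampler


def build_waveform(
    v_max: float = 0.46,
    v_mean: float = 0.28,
    v_min: float = 0.13,
    period: float = 0.8,
    shape: str = "piecewise-cosine",
) -> InletWaveform:
    """Synthesize a periodic inlet waveform attaining the three velocity
    statistics (each to within 1e-3 m/s; the default template is exact)."""
    if not (v_min < v_mean < v_max):
        raise ConfigurationError(
            f"require v_min < v_mean < v_max, got ({v_min}, {v_mean}, {v_max})"
        )
    if period <= 0.0:
        raise ConfigurationError(f"period must be > 0, got {period}")
    if shape == "piecewise-cosine":
        sampler = _build_piecewise_cosine(v_max, v_mean, v_min, period)
    elif shape == "fourier2":
        sampler = _build_fourier2(v_max, v_mean, v_min, period)
    else:
        raise ConfigurationError(f"unknown waveform shape {shape!r}")
    return InletWaveform(v_max=v_max, v_mean=v_mean, v_min=v_min,
                         period=period, sampler=sampler)


def inlet_profile(waveform: InletWaveform, t, r, R, profile: str = "parabolic"):
    """Axial inlet velocity at radius ``r`` and time ``t``.

    The radial shape is normalized so its cross-section average equals the
    sampler value: plug flow returns the sampler value everywhere; the
    parabolic (fully developed) shape is 2*v*(1 - (r/R)^2).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0.0) or np.any(r_arr > R * (1.0 + 1e-12)):
        raise DomainError(f"radial position outside [0, R={R}]")
    v = waveform(t)
    if profile == "flat":
        out = np.broadcast_to(np.asarray(v, dtype=float), r_arr.shape).copy() \
            if r_arr.ndim else v
        return out
    if profile == "parabolic":
        out = 2.0 * v * (1.0 - (r_arr / R) ** 2)
        return float(out) if np.ndim(out) == 0 else out
    raise ConfigurationError(f"unknown radial profile {profile!r}")


def inlet_face_flux(v: float, r0, r1, R: float, profile: str = "parabolic"):
    """Exact per-radian volume flux of the inlet profile through the annulus
    r in [r0, r1]:  integral of u(r) * r dr.  Summed over all inlet faces it
    equals v * R^2 / 2 (the per-radian flux of a uniform stream v)."""
    r0 = np.asarray(r0, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if profile == "flat":
        return v * 0.5 * (r1**2 - r0**2)
    if profile == "parabolic":
        return 2.0 * v * (0.5 * (r1**2 - r0**2) - (r1**4 - r0**4) / (4.0 * R**2))
    raise ConfigurationError(f"unknown radial profile {profile!r}")
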