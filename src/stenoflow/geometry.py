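"""Parametric axisymmetric stenosis geometry and body-fitted structured grid.

The vessel is a solid of revolution around the z axis.  Its radius profile is
piecewise linear ("trapezoidal" stenosis): a straight proximal segment at
radius ``r_p``, a linear taper over ``l_c`` down to the throat radius ``r_s``,
a straight throat of length ``l_s``, a linear expansion over ``l_d`` back to
the distal radius ``r_d``, a straight distal segment, and (optionally) a
porous segment of the same radius representing the downstream
microcirculation bed.

All quantities are SI (metres).  The grid is body-fitted: at every axial
station the radial coordinate is a fixed set of fractions of the local wall
radius, mildly clustered toward the wall.  Cell volumes and face areas are
per-radian measures of the ring cells (the factor 2*pi cancels everywhere it
would appear on both sides of a balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "StenosisGeometry",
    "StructuredGrid",
    "radius_profile",
    "area_stenosis",
    "build_grid",
]


@dataclass(frozen=True)
class StenosisGeometry:
    """Axisymmetric trapezoidal stenosis geometry (SI units, metres).

    Defaults are the reference coronary case: 1.4 mm proximal/distal radius,
    0.7 mm throat (75% area stenosis), 1.5/1.2/3 mm converging/throat/
    diverging lengths.  ``L_porous = 0`` means no microcirculation segment.
    """

    r_p: float = 1.4e-3
    r_s: float = 0.7e-3
    r_d: float = 1.4e-3
    l_c: float = 1.5e-3
    l_s: float = 1.2e-3
    l_d: float = 3.0e-3
    L_prox: float = 14.0e-3
    L_dist: float = 14.0e-3
    L_porous: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_p", "r_s", "r_d", "l_c", "l_s", "l_d", "L_prox", "L_dist"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.L_porous < 0.0:
            raise ConfigurationError(f"L_porous must be >= 0, got {self.L_porous}")
        if not (0.0 < self.r_s <= min(self.r_p, self.r_d)):
            raise ConfigurationError(
                f"throat radius r_s={self.r_s} must satisfy 0 < r_s <= min(r_p, r_d)"
            )

    # ---- segment bookkeeping -------------------------------------------------
    @property
    def segment_lengths(self) -> tuple[float, ...]:
        """(proximal, converging, throat, diverging, distal, porous) lengths."""
        return (self.L_prox, self.l_c, self.l_s, self.l_d, self.L_dist, self.L_porous)

    @property
    def breakpoints(self) -> np.ndarray:
        """Axial positions of segment junctions, starting at z = 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def z_converging_start(self) -> float:
        return self.L_prox

    @property
    def z_diverging_end(self) -> float:
        return self.L_prox + self.l_c + self.l_s + self.l_d

    @property
    def z_porous_start(self) -> float:
        return self.z_diverging_end + self.L_dist

    def analytic_volume(self) -> float:
        """Exact per-radian solid-of-revolution volume, sum of frusta."""
        bp = self.breakpoints
        radii = self._breakpoint_radii()
        vol = 0.0
        for a, b, ra, rb in zip(bp[:-1], bp[1:], radii[:-1], radii[1:]):
            # per-radian frustum volume: (1/2) * integral of r(z)^2
            vol += (b - a) * (ra * ra + ra * rb + rb * rb) / 6.0
        return vol

    def _breakpoint_radii(self) -> np.ndarray:
        return np.array([self.r_p, self.r_p, self.r_s, self.r_s, self.r_d, self.r_d, self.r_d])


def radius_profile(geom: StenosisGeometry, z) -> np.ndarray | float:
    """Wall radius R(z) of the piecewise-linear (trapezoidal) profile.

    Accepts a scalar or array axial position; raises :class:`DomainError`
    outside ``[0, total_length]`` (with a small floating tolerance).
    """
    z_arr = np.asarray(z, dtype=float)
    tol = 1e-12 + 1e-9 * geom.total_length
    if np.any(z_arr < -tol) or np.any(z_arr > geom.total_length + tol):
        raise DomainError(
            f"axial position outside [0, {geom.total_length:.6g}] m: {z!r}"
        )
    r = np.interp(np.clip(z_arr, 0.0, geom.total_length), geom.breakpoints, geom._breakpoint_radii())
    return float(r) if np.isscalar(z) else r


def area_stenosis(geom: StenosisGeometry) -> float:
    """Area stenosis percentage, (r_p^2 - r_s^2) / r_p^2 * 100."""
    return (geom.r_p**2 - geom.r_s**2) / geom.r_p**2 * 100.0


@dataclass
class StructuredGrid:
    """Body-fitted structured grid of the axisymmetric vessel.

    ``z`` are axial node coordinates (ni+1), ``s`` radial fractions (nj+1,
    0 = axis, 1 = wall), ``r[i, j] = s[j] * R(z[i])``.  Cells are indexed
    ``(i, j)``; per-radian volumes/face areas carry the cylindrical metric.
    """

    geom: StenosisGeometry
    z: np.ndarray            # (ni+1,) axial node coordinates
    s: np.ndarray            # (nj+1,) radial fractions
    r: np.ndarray            # (ni+1, nj+1) radial node coordinates
    porous: np.ndarray       # (ni, nj) bool, True in microcirculation cells
    vol: np.ndarray          # (ni, nj) per-radian cell volume, m^3/rad
    area_rz: np.ndarray      # (ni, nj) planar (z,r) cross-section area of cell
    zc: np.ndarray           # (ni, nj) volume centroid, axial
    rc: np.ndarray           # (ni, nj) volume centroid, radial
    Se: np.ndarray           # (ni+1, nj) per-radian area of constant-z faces (normal +z)
    Sn_z: np.ndarray = field(repr=False, default=None)  # (ni, nj+1) revolved area vec, z comp
    Sn_r: np.ndarray = field(repr=False, default=None)  # (ni, nj+1) revolved area vec, r comp

    @property
    def ni(self) -> int:
        return self.z.size - 1

    @property
    def nj(self) -> int:
        return self.s.size - 1

    @property
    def n_cells(self) -> int:
        return self.ni * self.nj

    def total_volume(self) -> float:
        return float(self.vol.sum())


def _segment_cells(length: float, nz_per_mm: float, refine: float, min_cells: int) -> int:
    return max(min_cells, int(round(length * 1e3 * nz_per_mm * refine)))


def _graded_nodes(a: float, b: float, h_fine: float, fine_at_end: bool,
                  ratio: float = 1.15, growth_cap: float = 4.0) -> np.ndarray:
    """Nodes over [a, b] with spacing h_fine at one end, growing geometrically
    (capped at growth_cap * h_fine) toward the other.  Spacings are rescaled
    so they tile the segment exactly."""
    L = b - a
    sizes = []
    h = h_fine
    while sum(sizes) < L:
        sizes.append(min(h, growth_cap * h_fine))
        h *= ratio
    sizes = np.asarray(sizes) * (L / sum(sizes))
    if fine_at_end:
        sizes = sizes[::-1]
    return a + np.concatenate([[0.0], np.cumsum(sizes)])


def _graded_nodes_two_sided(a: float, b: float, h_start: float, h_end: float,
                            ratio: float = 1.2, h_cap: float = 1.0e-3,
                            ) -> np.ndarray:
    """Nodes over [a, b] with spacings h_start / h_end at the two ends, each
    growing geometrically toward a mid-segment cap, rescaled to tile [a, b]."""
    L = b - a
    left, right = [], []
    h0, h1 = h_start, h_end
    while sum(left) + sum(right) < L:
        if h0 <= h1:
            left.append(min(h0, h_cap))
            h0 *= ratio
        else:
            right.append(min(h1, h_cap))
            h1 *= ratio
    sizes = np.asarray(left + right[::-1])
    sizes = sizes * (L / sizes.sum())
    return a + np.concatenate([[0.0], np.cumsum(sizes)])


def _radial_fractions(nr: int, stretch: float) -> np.ndarray:
    """Radial fractions with cell widths geometrically shrinking toward the wall."""
    w = stretch ** (-np.arange(nr, dtype=float))
    s = np.concatenate([[0.0], np.cumsum(w)])
    return s / s[-1]


def build_grid(
    geom: StenosisGeometry,
    nz_per_mm: float = 4.0,
    nr: int = 32,
    *,
    stretch: float = 1.08,
    refine_stenosis: float = 2.0,
    min_cells_porous: int = 4,
) -> StructuredGrid:
    """Build the body-fitted grid.

    ``nz_per_mm`` sets the base axial resolution; the converging/throat/
    diverging block is refined by ``refine_stenosis``.  A porous segment, if
    present, gets at least ``min_cells_porous`` axial cells however short it
    is.  Radial cells are clustered toward the wall with ratio ``stretch``.
    """
    if nz_per_mm < 2:
        raise ConfigurationError(f"nz_per_mm must be >= 2, got {nz_per_mm}")
    if nr < 8:
        raise ConfigurationError(f"nr must be >= 8, got {nr}")
    if not (1.0 <= stretch <= 1.1):
        raise ConfigurationError(f"radial stretch ratio must be in [1, 1.1], got {stretch}")

    # stenotic block refined; long straight feeds graded coarse away from it
    refines = (1.0, refine_stenosis, refine_stenosis, refine_stenosis, 1.0, 1.0)
    h_base = 1e-3 / nz_per_mm
    z_parts = []
    bp = geom.breakpoints
    for k, (a, b, ref) in enumerate(zip(bp[:-1], bp[1:], refines)):
        if b - a <= 0.0:
            continue
        if k == 0:                       # proximal: fine toward the stenosis
            nodes = _graded_nodes(a, b, h_base, fine_at_end=True)
        elif k == 4:                     # distal: fine toward the stenosis and,
            # when a porous bed follows, matched to its cell size at the far
            # end (large spacing jumps at the porous interface are avoided)
            if geom.L_porous > 0.0:
                h_end = min(h_base, geom.L_porous / min_cells_porous)
                nodes = _graded_nodes_two_sided(a, b, h_base, h_end)
            else:
                nodes = _graded_nodes(a, b, h_base, fine_at_end=False)
        else:
            min_cells = min_cells_porous if k == 5 else 2
            n = _segment_cells(b - a, nz_per_mm, ref, min_cells)
            nodes = np.linspace(a, b, n + 1)
        z_parts.append(nodes[:-1])
    z = np.concatenate(z_parts + [[geom.total_length]])

    s = _radial_fractions(nr, stretch)
    R = np.asarray(radius_profile(geom, z))
    r = s[None, :] * R[:, None]

    ni, nj = z.size - 1, nr

    # zone tags: cell is porous when its axial midpoint lies in the porous segment
    zmid = 0.5 * (z[:-1] + z[1:])
    porous_col = (geom.L_porous > 0.0) & (zmid >= geom.z_porous_start - 1e-15)
    porous = np.repeat(porous_col[:, None], nj, axis=1)

    # --- metric terms (all exact for the piecewise-linear wall) --------------
    dz = np.diff(z)[:, None]                      # (ni, 1)
    rb0, rb1 = r[:-1, :-1], r[1:, :-1]            # bottom edge radii at z_i, z_{i+1}
    rt0, rt1 = r[:-1, 1:], r[1:, 1:]              # top edge radii
    rbm, rtm = 0.5 * (rb0 + rb1), 0.5 * (rt0 + rt1)

    def g(rt, rb):                                # (r_top^2 - r_bot^2) / 2, quadratic in z
        return 0.5 * (rt * rt - rb * rb)

    g0, gm, g1 = g(rt0, rb0), g(rtm, rbm), g(rt1, rb1)
    vol = dz / 6.0 * (g0 + 4.0 * gm + g1)         # Simpson: exact for quadratics

    z0, z1 = z[:-1][:, None], z[1:][:, None]
    zm = 0.5 * (z0 + z1)
    zc = dz / 6.0 * (z0 * g0 + 4.0 * zm * gm + z1 * g1) / vol

    def h(rt, rb):                                # (r_top^3 - r_bot^3) / 3, cubic in z
        return (rt**3 - rb**3) / 3.0

    rc = dz / 6.0 * (h(rt0, rb0) + 4.0 * h(rtm, rbm) + h(rt1, rb1)) / vol

    # planar cross-section (trapezoid with vertical sides)
    area_rz = dz * 0.5 * ((rt0 - rb0) + (rt1 - rb1))

    # constant-z ("east") faces at every i-line: per-radian annulus area
    Se = 0.5 * (r[:, 1:] ** 2 - r[:, :-1] ** 2)   # (ni+1, nj)

    # constant-j ("north") faces: cone frusta along each j-line
    dr_line = r[1:, :] - r[:-1, :]                # (ni, nj+1)
    rbar = 0.5 * (r[1:, :] + r[:-1, :])
    Sn_z = -dr_line * rbar                        # outward-"up" normal (−Δr, Δz) * r̄
    Sn_r = (z[1:] - z[:-1])[:, None] * rbar

    grid = StructuredGrid(
        geom=geom, z=z, s=s, r=r, porous=porous, vol=vol, area_rz=area_rz,
        zc=zc, rc=rc, Se=Se, Sn_z=Sn_z, Sn_r=Sn_r,
    )

    if np.any(vol <= 0.0):
        raise ConfigurationError("grid produced non-positive cell volumes")
    rel = abs(grid.total_volume() - geom.analytic_volume()) / geom.analytic_volume()
    if rel > 5e-3:
        raise ConfigurationError(
            f"grid volume deviates from analytic solid of revolution by {rel:.2e}"
        )
    return grid
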