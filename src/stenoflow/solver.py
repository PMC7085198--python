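"""Transient axisymmetric incompressible generalized-Newtonian flow solver.

Finite-volume discretization on the body-fitted structured (z, r) grid of
:mod:`stenoflow.geometry`: collocated variables with Rhie–Chow face
velocities, SIMPLE pressure–velocity coupling iterated to a residual target
inside each implicit (backward-Euler) time step, first-order upwind
convection with a deferred central correction, over-relaxed non-orthogonal
diffusion, and the full deviatoric stress of a variable-viscosity fluid
(transpose and hoop terms included).  Cells tagged as microcirculation carry
the Darcy momentum sink of the porous (seepage) balance; dividing that
balance by the constant porosity of the zone leaves the standard equations
plus a sink (phi*eta/k) u per unit volume, which is what is assembled.

Boundary conditions: prescribed velocity profile at the inlet, fixed static
pressure with zero-gradient velocity at the outlet, no-slip (or free-slip,
for analytic benchmarks) walls, symmetry at the axis.  The scheme is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as law
from .errors import ConfigurationError, ConvergenceError, DivergenceError
from .geometry import StenosisGeometry, StructuredGrid, build_grid
from .waveform import InletWaveform, inlet_face_flux

log = logging.getLogger("stenoflow.solver")

__all__ = ["SimulationConfig", "FlowState", "FieldHistory", "AxisymFV",
           "run_simulation", "run_steady", "default_probe_planes"]


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical and boundary-condition settings for a run.

    ``outlet_mode`` selects the constant-pressure load ("PL", fixed static
    pressure, no porous segment) or the microcirculation load ("ML", porous
    segment present, zero pressure behind it).  ``outlet_pressure=None``
    resolves to 3333 Pa for PL and 0 Pa for ML.
    """

    dt: float = 0.0032
    steps_per_cycle: int = 247
    n_cycles: int = 3
    residual_tol: float = 1e-5
    outlet_mode: str = "ML"
    outlet_pressure: float | None = None
    probe_planes: tuple[float, ...] | None = None
    nz_per_mm: float = 4.0
    nr: int = 32
    radial_profile: str = "parabolic"
    porous_eta: str | float = "mu_inf"   # "mu_inf" | "carreau" | constant Pa*s
    wall_bc: str = "noslip"              # "noslip" | "slip"
    cds_blend: float = 0.9               # deferred central-correction weight
    alpha_u: float = 0.9
    alpha_p: float = 0.7
    max_outer: int = 600
    min_outer: int = 2
    time_scheme: str = "backward-euler"  # | "bdf2"
    snapshot_every: int = 0              # full-field snapshot every N steps (0 = off)

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or self.residual_tol <= 0.0:
            raise ConfigurationError("dt and residual_tol must be > 0")
        if self.outlet_mode not in ("ML", "PL"):
            raise ConfigurationError(f"outlet_mode must be ML or PL, got {self.outlet_mode}")
        if self.time_scheme not in ("backward-euler", "bdf2"):
            raise ConfigurationError(f"unknown time_scheme {self.time_scheme}")
        if self.wall_bc not in ("noslip", "slip"):
            raise ConfigurationError(f"unknown wall_bc {self.wall_bc}")

    @property
    def resolved_outlet_pressure(self) -> float:
        if self.outlet_pressure is not None:
            return self.outlet_pressure
        return 3333.0 if self.outlet_mode == "PL" else 0.0


def default_probe_planes(geom: StenosisGeometry) -> tuple[float, float]:
    """Default probe planes: 3 mm upstream of the converging-section start
    (pre-stenotic, 'aortic') and 3 mm downstream of the diverging-section end
    (post-stenotic, 'distal')."""
    return (geom.z_converging_start - 3.0e-3, geom.z_diverging_end + 3.0e-3)


@dataclass
class FlowState:
    """Velocity/pressure fields on the grid at time ``t`` (cell-centred)."""

    uz: np.ndarray
    ur: np.ndarray
    p: np.ndarray
    t: float
    mu: np.ndarray | None = None


@dataclass
class FieldHistory:
    """Probe traces per time step plus optional full-field snapshots."""

    times: np.ndarray
    probe_z: np.ndarray
    p_mean: np.ndarray          # (nsteps, nplanes) area-averaged pressure, Pa
    uz_mean: np.ndarray         # (nsteps, nplanes) area-averaged axial velocity
    uz_center: np.ndarray       # (nsteps, nplanes) centerline axial velocity
    mass_error: np.ndarray      # (nsteps,) |inflow - outflow| / inflow
    steps_per_cycle: int
    n_cycles: int
    config: SimulationConfig
    geom: StenosisGeometry
    snapshots: list = field(default_factory=list)

    @property
    def stats_cycle(self) -> slice:
        """Index slice of the statistics-ready (final) cycle."""
        return slice((self.n_cycles - 1) * self.steps_per_cycle,
                     self.n_cycles * self.steps_per_cycle)


# =========================================================================
class AxisymFV:
    """Finite-volume operator on one grid; holds all geometric factors."""

    def __init__(self, grid: StructuredGrid, fluid: law.FluidParams,
                 carreau: law.CarreauParams, porous: law.PorousParams | None,
                 waveform: InletWaveform, config: SimulationConfig):
        self.grid = grid
        self.fluid = fluid
        self.carreau = carreau
        self.porous = porous
        self.waveform = waveform
        self.cfg = config
        self.rho = fluid.density

        g = grid
        self.ni, self.nj = g.ni, g.nj
        nc = self.ni * self.nj
        self.nc = nc
        self.vol = g.vol
        self.area_rz = g.area_rz
        self.rbar = g.vol / g.area_rz
        self.zc, self.rc = g.zc, g.rc

        self._geometry_factors()
        self._sparse_pattern()
        self._porous_coefficients()
        self._interface_faces()
        self._scales()

    # ---- precomputation --------------------------------------------------
    def _geometry_factors(self) -> None:
        g = self.grid
        zc, rc = self.zc, self.rc

        # internal constant-z faces between (i,j) and (i+1,j)
        self.eS = g.Se[1:-1, :]                       # (ni-1, nj), z-component only
        e_dz = zc[1:, :] - zc[:-1, :]
        e_dr = rc[1:, :] - rc[:-1, :]
        sdote = self.eS * e_dz
        self.eDf = self.eS**2 / sdote
        self.e_kz = self.eS - self.eDf * e_dz
        self.e_kr = -self.eDf * e_dr
        self.e_dz, self.e_dr = e_dz, e_dr
        zf = g.z[1:-1][:, None]
        self.e_w = (zc[1:, :] - zf) / (zc[1:, :] - zc[:-1, :])   # weight of owner (i,j)
        # face-centroid offsets from owner/neighbor centroids (for
        # gradient-corrected face pressures)
        re = g.r[1:-1, :]
        rfc = np.where(re[:, 1:] > re[:, :-1] + 1e-30,
                       2.0 / 3.0 * (re[:, 1:] ** 3 - re[:, :-1] ** 3)
                       / np.maximum(re[:, 1:] ** 2 - re[:, :-1] ** 2, 1e-30),
                       0.5 * (re[:, 1:] + re[:, :-1]))
        self.e_dPz, self.e_dPr = zf - zc[:-1, :], rfc - rc[:-1, :]
        self.e_dNz, self.e_dNr = zf - zc[1:, :], rfc - rc[1:, :]

        # internal constant-s faces between (i,j) and (i,j+1)
        self.nSz = g.Sn_z[:, 1:-1]                    # (ni, nj-1)
        self.nSr = g.Sn_r[:, 1:-1]
        n_dz = zc[:, 1:] - zc[:, :-1]
        n_dr = rc[:, 1:] - rc[:, :-1]
        sdotn = self.nSz * n_dz + self.nSr * n_dr
        S2 = self.nSz**2 + self.nSr**2
        self.nDf = S2 / sdotn
        self.n_kz = self.nSz - self.nDf * n_dz
        self.n_kr = self.nSr - self.nDf * n_dr
        self.n_dz, self.n_dr = n_dz, n_dr
        zfm = 0.5 * (g.z[:-1] + g.z[1:])[:, None]
        rfm = 0.5 * (g.r[:-1, 1:-1] + g.r[1:, 1:-1])
        dP = np.hypot(zfm - zc[:, :-1], rfm - rc[:, :-1])
        dN = np.hypot(zfm - zc[:, 1:], rfm - rc[:, 1:])
        self.n_w = dN / (dP + dN)                     # weight of owner (i,j)
        self.n_dPz, self.n_dPr = zfm - zc[:, :-1], rfm - rc[:, :-1]
        self.n_dNz, self.n_dNr = zfm - zc[:, 1:], rfm - rc[:, 1:]

        # inlet faces (i = 0, outward normal -z)
        self.inS = g.Se[0, :]
        self.in_d = zc[0, :] - g.z[0]
        self.inDf = self.inS / self.in_d
        # exact per-face mean inlet velocity shape: flux / area at unit v
        r_edges = g.r[0, :]
        self.in_shape = (inlet_face_flux(1.0, r_edges[:-1], r_edges[1:],
                                         g.r[0, -1], self.cfg.radial_profile)
                         / self.inS)

        # outlet faces (i = ni, outward normal +z)
        self.outS = g.Se[-1, :]
        self.out_d = g.z[-1] - zc[-1, :]
        self.outDf = self.outS / self.out_d

        # wall faces (top of cells (i, nj-1))
        self.wSz = g.Sn_z[:, -1]
        self.wSr = g.Sn_r[:, -1]
        zfw = 0.5 * (g.z[:-1] + g.z[1:])
        rfw = 0.5 * (g.r[:-1, -1] + g.r[1:, -1])
        dwz = zfw - zc[:, -1]
        dwr = rfw - rc[:, -1]
        sdotw = self.wSz * dwz + self.wSr * dwr
        self.wDf = (self.wSz**2 + self.wSr**2) / sdotw
        self.w_dz, self.w_dr = dwz, dwr

        # planar edge normals for Green-Gauss gradients
        # vertical edges at every i-line: planar normal (+z) * edge length (dr)
        self.pe_len = g.r[:, 1:] - g.r[:, :-1]        # (ni+1, nj)
        # slanted edges at every j-line: planar normal (-dr, dz)
        self.pn_nz = -(g.r[1:, :] - g.r[:-1, :])      # (ni, nj+1)
        self.pn_nr = (g.z[1:] - g.z[:-1])[:, None] * np.ones_like(g.r[:-1, :])

    def _sparse_pattern(self) -> None:
        ni, nj, nc = self.ni, self.nj, self.nc
        idx = np.arange(nc).reshape(ni, nj)
        self.idx = idx
        pe, ne = idx[:-1, :].ravel(), idx[1:, :].ravel()     # E-family owner/neigh
        pn, nn = idx[:, :-1].ravel(), idx[:, 1:].ravel()     # N-family
        diag = np.arange(nc)
        self._rows = np.concatenate([diag, pe, ne, pn, nn])
        self._cols = np.concatenate([diag, ne, pe, nn, pn])

    def _interface_faces(self) -> None:
        """Constant-z internal faces across which the porous tag jumps.

        The Darcy sink makes the pressure gradient discontinuous there;
        face pressures and Rhie-Chow terms at these faces use one-sided
        axial gradients from each zone (exact for piecewise-linear p)."""
        col = self.grid.porous.any(axis=1)
        self.iface_idx = np.nonzero(col[:-1] != col[1:])[0]
        wide = set()
        cols = set()
        for i_f in self.iface_idx:
            wide.update(i for i in (i_f - 1, i_f, i_f + 1) if 0 <= i < self.ni - 1)
            cols.update(i for i in (i_f, i_f + 1) if 0 <= i < self.ni)
        self.iface_wide = np.asarray(sorted(wide), dtype=int)
        self.iface_cols = np.asarray(sorted(cols), dtype=int)

    def _one_sided_axial(self, p: np.ndarray, i_f: int):
        """One-sided axial dp/dz on the owner (i_f) and neighbor (i_f+1)
        sides of an internal constant-z face, avoiding the face itself."""
        zc = self.zc
        if i_f >= 1:
            gP = (p[i_f, :] - p[i_f - 1, :]) / (zc[i_f, :] - zc[i_f - 1, :])
        else:
            gP = np.zeros(self.nj)
        if i_f + 2 <= self.ni - 1:
            gN = (p[i_f + 2, :] - p[i_f + 1, :]) / (zc[i_f + 2, :] - zc[i_f + 1, :])
        else:
            gN = np.zeros(self.nj)
        return gP, gN

    def _porous_coefficients(self) -> None:
        cfg, porous = self.cfg, self.porous
        self.sink = np.zeros((self.ni, self.nj))
        self.porous_mask = self.grid.porous
        if porous is None or not self.porous_mask.any():
            self.eta_mode = None
            return
        if isinstance(cfg.porous_eta, (int, float)):
            eta = float(cfg.porous_eta)
            self.eta_mode = "const"
        elif cfg.porous_eta == "mu_inf":
            eta = self.carreau.mu_inf
            self.eta_mode = "const"
        elif cfg.porous_eta == "carreau":
            eta = np.nan   # filled each iteration from the viscosity field
            self.eta_mode = "carreau"
        else:
            raise ConfigurationError(f"unknown porous_eta {cfg.porous_eta!r}")
        # sink of the phi-divided balance: (phi * eta / k) * u per unit volume
        self._sink_base = porous.porosity / porous.k
        if self.eta_mode == "const":
            self.sink = np.where(self.porous_mask, self._sink_base * eta, 0.0)

    def _scales(self) -> None:
        v_ref = max(abs(self.waveform.v_max), 1e-12)
        self.mdot_ref = self.rho * max(abs(self.waveform.v_mean), 0.1 * v_ref) \
            * self.inS.sum()
        self.mom_ref = self.mdot_ref * v_ref

    # ---- field operators -------------------------------------------------
    def grad_planar(self, phi: np.ndarray, inlet, outlet, wall, axis,
                    eface_over: dict | None = None):
        """Planar Green-Gauss gradient of a cell field.

        Boundary treatments: each of inlet/outlet/wall/axis is either the
        string "zero_grad" or an array/scalar of face values.  ``eface_over``
        optionally overrides internal constant-z face values (by face index).
        """
        ni, nj = self.ni, self.nj
        fz = np.zeros((ni, nj))
        fr = np.zeros((ni, nj))

        # internal vertical edges
        pf = self.e_w * phi[:-1, :] + (1.0 - self.e_w) * phi[1:, :]
        if eface_over:
            for i_f, val in eface_over.items():
                pf[i_f, :] = val
        c = pf * self.pe_len[1:-1, :]
        fz[:-1, :] += c
        fz[1:, :] -= c
        # inlet edge
        pin = phi[0, :] if isinstance(inlet, str) else inlet
        fz[0, :] -= pin * self.pe_len[0, :]
        # outlet edge
        pout = phi[-1, :] if isinstance(outlet, str) else outlet
        fz[-1, :] += pout * self.pe_len[-1, :]

        # internal slanted edges
        pf = self.n_w * phi[:, :-1] + (1.0 - self.n_w) * phi[:, 1:]
        cz = pf * self.pn_nz[:, 1:-1]
        cr = pf * self.pn_nr[:, 1:-1]
        fz[:, :-1] += cz
        fr[:, :-1] += cr
        fz[:, 1:] -= cz
        fr[:, 1:] -= cr
        # wall edge
        pw = phi[:, -1] if isinstance(wall, str) else wall
        fz[:, -1] += pw * self.pn_nz[:, -1]
        fr[:, -1] += pw * self.pn_nr[:, -1]
        # axis edge (outward planar normal (0, -1) * dz)
        pa = phi[:, 0] if isinstance(axis, str) else axis
        fr[:, 0] -= pa * self.pn_nr[:, 0]

        return fz / self.area_rz, fr / self.area_rz

    def iface_pressures(self, p: np.ndarray) -> dict:
        """One-sided reconstructed face pressures at porous-interface faces."""
        over = {}
        for i_f in self.iface_idx:
            gP, gN = self._one_sided_axial(p, i_f)
            over[i_f] = 0.5 * ((p[i_f, :] + gP * self.e_dPz[i_f, :])
                               + (p[i_f + 1, :] + gN * self.e_dNz[i_f, :]))
        return over

    def pressure_gradient(self, p: np.ndarray, p_out: float):
        """Cell pressure gradient with interface-aware face pressures."""
        return self.grad_planar(p, "zero_grad", np.full(self.nj, p_out),
                                "zero_grad", "zero_grad",
                                eface_over=self.iface_pressures(p))

    def velocity_gradients(self, uz, ur, t):
        noslip = self.cfg.wall_bc == "noslip"
        uz_wall = np.zeros(self.ni) if noslip else "zero_grad"
        ur_wall = np.zeros(self.ni) if noslip else "zero_grad"
        uz_in = self.inlet_values(t)
        duz_dz, duz_dr = self.grad_planar(uz, uz_in, "zero_grad", uz_wall, "zero_grad")
        dur_dz, dur_dr = self.grad_planar(ur, np.zeros(self.nj), "zero_grad",
                                          ur_wall, np.zeros(self.ni))
        return duz_dz, duz_dr, dur_dz, dur_dr

    def viscosity(self, uz, ur, t):
        duz_dz, duz_dr, dur_dz, dur_dr = self.velocity_gradients(uz, ur, t)
        d_tt = ur / self.rc
        gamma = law.shear_rate(duz_dz, dur_dr, d_tt, 0.5 * (duz_dr + dur_dz))
        mu = law.carreau_viscosity(self.carreau, gamma)
        if self.eta_mode == "carreau":
            self.sink = np.where(self.porous_mask, self._sink_base * mu, 0.0)
        return np.asarray(mu), (duz_dz, duz_dr, dur_dz, dur_dr)

    def inlet_values(self, t) -> np.ndarray:
        """Face-mean inlet axial velocity per inlet face at time t."""
        return self.waveform(t) * self.in_shape

    def inlet_mdot(self, t) -> np.ndarray:
        """Per-face inlet mass flux (positive = entering the domain)."""
        return self.rho * self.inlet_values(t) * self.inS

    # ---- face interpolation helpers -------------------------------------
    def face_e(self, phi):
        return self.e_w * phi[:-1, :] + (1.0 - self.e_w) * phi[1:, :]

    def face_n(self, phi):
        return self.n_w * phi[:, :-1] + (1.0 - self.n_w) * phi[:, 1:]


# =========================================================================
class _Simple:
    """One transient SIMPLE solve driven by :class:`AxisymFV`."""

    def __init__(self, op: AxisymFV):
        self.op = op
        self.cfg = op.cfg
        nc = op.nc
        self.uz = np.zeros((op.ni, op.nj))
        self.ur = np.zeros((op.ni, op.nj))
        self.p = np.full((op.ni, op.nj), self.cfg.resolved_outlet_pressure)
        self.mdot_e = np.zeros((op.ni - 1, op.nj))   # internal E-face fluxes
        self.mdot_n = np.zeros((op.ni, op.nj - 1))   # internal N-face fluxes
        self.mdot_out = np.zeros(op.nj)
        self.mdot_in = np.zeros(op.nj)
        self.t = 0.0
        self._uz_old = self.uz.copy()
        self._ur_old = self.ur.copy()
        self._uz_old2 = None
        self._ur_old2 = None
        self._lu = {}                 # cached factorizations per component
        self._pfrozen = None          # frozen p'-equation (per time step)

    # -- assembly of one momentum component --------------------------------
    def _momentum(self, comp, mu, grads, p_grad, dt_coefs, t_next):
        op, cfg = self.op, self.cfg
        rho = op.rho
        ni, nj = op.ni, op.nj
        u = self.uz if comp == "z" else self.ur
        duz_dz, duz_dr, dur_dz, dur_dr = grads

        aP = np.zeros((ni, nj))
        aE = np.zeros((ni - 1, nj))   # coefficient linking owner row -> east neigh
        aW = np.zeros((ni - 1, nj))   # east-neigh row -> owner
        aN = np.zeros((ni, nj - 1))
        aS = np.zeros((ni, nj - 1))
        b = np.zeros((ni, nj))

        c0, c1, c2 = dt_coefs          # u_t ~ (c0 u - c1 u_old - c2 u_old2)/dt
        tr = rho * op.vol / cfg.dt
        aP += c0 * tr
        u_old = self._uz_old if comp == "z" else self._ur_old
        b += tr * c1 * u_old
        if c2:
            u_old2 = self._uz_old2 if comp == "z" else self._ur_old2
            b += tr * c2 * u_old2

        mu_e = op.face_e(mu)
        mu_n = op.face_n(mu)

        # diffusion, implicit orthogonal part
        dE = mu_e * op.eDf
        aP[:-1, :] += dE
        aP[1:, :] += dE
        aE -= dE
        aW -= dE
        dN = mu_n * op.nDf
        aP[:, :-1] += dN
        aP[:, 1:] += dN
        aN -= dN
        aS -= dN

        # convection, implicit upwind
        me, mn = self.mdot_e, self.mdot_n
        aP[:-1, :] += np.maximum(me, 0.0)
        aP[1:, :] += np.maximum(-me, 0.0)
        aE -= np.maximum(-me, 0.0)
        aW -= np.maximum(me, 0.0)
        aP[:, :-1] += np.maximum(mn, 0.0)
        aP[:, 1:] += np.maximum(-mn, 0.0)
        aN -= np.maximum(-mn, 0.0)
        aS -= np.maximum(mn, 0.0)

        # deferred central correction for convection
        if cfg.cds_blend > 0.0:
            fc = op.face_e(u)
            fu = np.where(me >= 0.0, u[:-1, :], u[1:, :])
            corr = cfg.cds_blend * me * (fc - fu)
            corr[op.iface_wide, :] = 0.0   # pure upwind near the porous interface
            b[:-1, :] -= corr
            b[1:, :] += corr
            fc = op.face_n(u)
            fu = np.where(mn >= 0.0, u[:, :-1], u[:, 1:])
            corr = cfg.cds_blend * mn * (fc - fu)
            corr[op.iface_cols, :] = 0.0
            b[:, :-1] -= corr
            b[:, 1:] += corr

        # explicit viscous terms: cross-diffusion + transpose-stress
        if comp == "z":
            g_dz, g_dr = duz_dz, duz_dr          # grad of this component
            tz_e = op.face_e(duz_dz)             # transpose flux uses d(u)/dz
            tr_e = op.face_e(dur_dz)
            tz_n = op.face_n(duz_dz)
            tr_n = op.face_n(dur_dz)
        else:
            g_dz, g_dr = dur_dz, dur_dr
            tz_e = op.face_e(duz_dr)
            tr_e = op.face_e(dur_dr)
            tz_n = op.face_n(duz_dr)
            tr_n = op.face_n(dur_dr)
        gfz_e = op.face_e(g_dz)
        gfr_e = op.face_e(g_dr)
        flux_e = mu_e * (gfz_e * op.e_kz + gfr_e * op.e_kr
                         + tz_e * op.eS)          # E faces: S_r = 0
        b[:-1, :] += flux_e
        b[1:, :] -= flux_e
        gfz_n = op.face_n(g_dz)
        gfr_n = op.face_n(g_dr)
        flux_n = mu_n * (gfz_n * op.n_kz + gfr_n * op.n_kr
                         + tz_n * op.nSz + tr_n * op.nSr)
        b[:, :-1] += flux_n
        b[:, 1:] -= flux_n

        # pressure force (revolved Green-Gauss; includes the hoop p-term).
        # Face pressures are gradient-corrected from both sides: this is a
        # skewness correction in smooth regions and recovers the one-sided
        # face value where the pressure gradient has a kink (porous interface).
        gpz, gpr = p_grad
        pf_e = (op.e_w * (self.p[:-1, :] + gpz[:-1, :] * op.e_dPz
                          + gpr[:-1, :] * op.e_dPr)
                + (1.0 - op.e_w) * (self.p[1:, :] + gpz[1:, :] * op.e_dNz
                                    + gpr[1:, :] * op.e_dNr))
        for i_f, val in op.iface_pressures(self.p).items():
            pf_e[i_f, :] = val             # porous-interface faces: one-sided
        fz = np.zeros((ni, nj))
        fr = np.zeros((ni, nj))
        c = pf_e * op.eS
        fz[:-1, :] += c
        fz[1:, :] -= c
        fz[0, :] -= self.p[0, :] * op.inS                 # inlet: zero-gradient p
        fz[-1, :] += cfg.resolved_outlet_pressure * op.outS
        pf_n = (op.n_w * (self.p[:, :-1] + gpz[:, :-1] * op.n_dPz
                          + gpr[:, :-1] * op.n_dPr)
                + (1.0 - op.n_w) * (self.p[:, 1:] + gpz[:, 1:] * op.n_dNz
                                    + gpr[:, 1:] * op.n_dNr))
        cz = pf_n * op.nSz
        cr = pf_n * op.nSr
        fz[:, :-1] += cz
        fr[:, :-1] += cr
        fz[:, 1:] -= cz
        fr[:, 1:] -= cr
        pw = self.p[:, -1] + gpz[:, -1] * op.w_dz + gpr[:, -1] * op.w_dr
        fz[:, -1] += pw * op.wSz
        fr[:, -1] += pw * op.wSr
        if comp == "z":
            b -= fz
        else:
            b -= fr - self.p * op.area_rz                 # wedge faces: + p A_rz

        # boundary faces -----------------------------------------------------
        mu_in = mu[0, :]
        mu_w = mu[:, -1]
        # inlet: Dirichlet velocity (value per face)
        uin = op.inlet_values(t_next) if comp == "z" else np.zeros(nj)
        dco = mu_in * op.inDf
        aP[0, :] += dco
        b[0, :] += dco * uin
        b[0, :] += self.mdot_in * uin                     # convective inflow
        # outlet: zero-gradient velocity -> upwinded convection on diagonal
        aP[-1, :] += np.maximum(self.mdot_out, 0.0)
        # wall
        if cfg.wall_bc == "noslip":
            dco = mu_w * op.wDf
            aP[:, -1] += dco                              # u_wall = 0
            # (cross-diffusion at the wall is dropped; first-order wall layer)
        # slip wall: zero viscous flux, zero mass flux -> nothing to add

        # porous Darcy sink and (for u_r) the hoop viscous term
        aP += op.sink * op.vol
        if comp == "r":
            aP += 2.0 * mu * op.vol / op.rbar**2

        return aP, aE, aW, aN, aS, b

    def _solve_comp(self, comp, mu, grads, p_grad, dt_coefs, t_next, refactor):
        op, cfg = self.op, self.cfg
        u = self.uz if comp == "z" else self.ur
        aP, aE, aW, aN, aS, b = self._momentum(comp, mu, grads, p_grad, dt_coefs, t_next)

        # residual of the unrelaxed system at the current iterate
        data = np.concatenate([aP.ravel(), aE.ravel(), aW.ravel(),
                               aN.ravel(), aS.ravel()])
        A = sp.csr_matrix((data, (op._rows, op._cols)), shape=(op.nc, op.nc))
        # scaled residual (standard CFD normalization by sum |a_P u_P|,
        # floored by a global momentum-flux scale for start-up/rest states)
        denom = max(np.abs(aP * u).sum(), op.mom_ref)
        res = np.abs(A @ u.ravel() - b.ravel()).sum() / denom

        # implicit under-relaxation
        alpha = cfg.alpha_u
        aP_rel = aP / alpha
        b_rel = b + (1.0 - alpha) * aP_rel * u
        # a direct factorization is computed at step start; afterwards it
        # serves as a preconditioner for BiCGStab on the fresh system
        data[: op.nc] = aP_rel.ravel()
        A = sp.csc_matrix((data, (op._rows, op._cols)), shape=(op.nc, op.nc))
        if refactor or comp not in self._lu:
            self._lu[comp] = spla.splu(A)
            unew = self._lu[comp].solve(b_rel.ravel())
        else:
            M = spla.LinearOperator((op.nc, op.nc), matvec=self._lu[comp].solve)
            unew, ok = spla.bicgstab(A, b_rel.ravel(), x0=u.ravel(), M=M,
                                     rtol=1e-6, atol=0.0, maxiter=40)
            if ok != 0:                      # stale preconditioner: refactor
                self._lu[comp] = spla.splu(A)
                unew = self._lu[comp].solve(b_rel.ravel())
        unew = unew.reshape(op.ni, op.nj)
        if not np.all(np.isfinite(unew)):
            raise DivergenceError(f"non-finite {comp}-velocity at t={t_next}")
        if comp == "z":
            self.uz = unew
        else:
            self.ur = unew

        # SIMPLEC denominator a_P - sum(a_nb) for the pressure-correction
        # coupling (off-diagonals are negative, so add them back)
        nbsum = np.zeros_like(aP)
        nbsum[:-1, :] += aE
        nbsum[1:, :] += aW
        nbsum[:, :-1] += aN
        nbsum[:, 1:] += aS
        return res, aP_rel + nbsum

    # -- Rhie-Chow fluxes and pressure correction ---------------------------
    def _pressure_step(self, aPz, aPr, t_next, refactor, n_corr=1):
        """Rhie-Chow face fluxes + pressure correction.

        ``n_corr`` correctors are applied per call (the second, PISO-like
        pass reuses the same coefficient matrix and costs one back-solve);
        the returned mass residual is the continuity defect of the incoming
        velocity/pressure fields.
        """
        mass0 = None
        for corr in range(n_corr):
            mass_res = self._one_corrector(aPz, aPr, t_next,
                                           refactor and corr == 0)
            if mass0 is None:
                mass0 = mass_res
        return mass0

    def _one_corrector(self, aPz, aPr, t_next, refactor):
        op, cfg = self.op, self.cfg
        rho = op.rho
        ni, nj = op.ni, op.nj

        D = op.vol / (0.5 * (aPz + aPr))
        dpz, dpr = op.pressure_gradient(self.p, cfg.resolved_outlet_pressure)

        # inlet flux (exact, prescribed)
        self.mdot_in = op.inlet_mdot(t_next)

        # internal E faces
        uf = op.face_e(self.uz)
        Df = op.face_e(D)
        gpd = (op.face_e(dpz) * op.e_dz + op.face_e(dpr) * op.e_dr)
        for i_f in op.iface_idx:
            gP, gN = op._one_sided_axial(self.p, i_f)
            gpd[i_f, :] = gP * op.e_dPz[i_f, :] - gN * op.e_dNz[i_f, :]
        self.mdot_e = rho * (uf * op.eS
                             - Df * op.eDf * ((self.p[1:, :] - self.p[:-1, :]) - gpd))
        self.eC = rho * Df * op.eDf          # p'-equation coefficient

        # internal N faces
        ufz = op.face_n(self.uz)
        ufr = op.face_n(self.ur)
        Df = op.face_n(D)
        gpd = (op.face_n(dpz) * op.n_dz + op.face_n(dpr) * op.n_dr)
        self.mdot_n = rho * (ufz * op.nSz + ufr * op.nSr
                             - Df * op.nDf * ((self.p[:, 1:] - self.p[:, :-1]) - gpd))
        self.nC = rho * Df * op.nDf

        # outlet faces
        p_out = cfg.resolved_outlet_pressure
        gpd = dpz[-1, :] * (op.grid.z[-1] - op.zc[-1, :])
        self.mdot_out = rho * (self.uz[-1, :] * op.outS
                               - D[-1, :] * op.outDf * ((p_out - self.p[-1, :]) - gpd))
        self.outC = rho * D[-1, :] * op.outDf

        # continuity defect
        div = np.zeros((ni, nj))
        div[:-1, :] += self.mdot_e
        div[1:, :] -= self.mdot_e
        div[:, :-1] += self.mdot_n
        div[:, 1:] -= self.mdot_n
        div[0, :] -= self.mdot_in
        div[-1, :] += self.mdot_out
        mass_res = np.abs(div).sum() / op.mdot_ref

        # pressure-correction equation: sum_f C_f (p'_P - p'_N) = -div
        aP = np.zeros((ni, nj))
        aP[:-1, :] += self.eC
        aP[1:, :] += self.eC
        aP[:, :-1] += self.nC
        aP[:, 1:] += self.nC
        aP[-1, :] += self.outC
        data = np.concatenate([aP.ravel(), -self.eC.ravel(), -self.eC.ravel(),
                               -self.nC.ravel(), -self.nC.ravel()])
        A = sp.csc_matrix((data, (op._rows, op._cols)), shape=(op.nc, op.nc))
        if refactor or self._pfrozen is None:
            self._pfrozen = spla.splu(A)
            pc = self._pfrozen.solve(-div.ravel())
        else:
            M = spla.LinearOperator((op.nc, op.nc), matvec=self._pfrozen.solve)
            pc, ok = spla.bicgstab(A, -div.ravel(), M=M, rtol=1e-7, atol=0.0,
                                   maxiter=60)
            if ok != 0:
                self._pfrozen = spla.splu(A)
                pc = self._pfrozen.solve(-div.ravel())
        pc = pc.reshape(ni, nj)
        if not np.all(np.isfinite(pc)):
            raise DivergenceError(f"non-finite pressure correction at t={t_next}")

        # corrections
        self.mdot_e += self.eC * (pc[:-1, :] - pc[1:, :])
        self.mdot_n += self.nC * (pc[:, :-1] - pc[:, 1:])
        self.mdot_out += self.outC * pc[-1, :]
        self.p += cfg.alpha_p * pc
        gz, gr = op.pressure_gradient(pc, 0.0)
        self.uz -= D * gz
        self.ur -= D * gr
        return mass_res

    # -- one implicit time step --------------------------------------------
    def advance(self, t_next: float, dt_coefs=(1.0, 1.0, 0.0)) -> dict:
        op, cfg = self.op, self.cfg
        # time-extrapolated initial guess (cheap; cuts outer iterations)
        if self._uz_old2 is not None:
            self.uz = self.uz + (self._uz_old - self._uz_old2)
            self.ur = self.ur + (self._ur_old - self._ur_old2)
        worst = np.inf
        prev = np.inf
        info = {}
        for it in range(cfg.max_outer):
            refactor = it == 0
            mu, grads = op.viscosity(self.uz, self.ur, t_next)
            p_grad = op.pressure_gradient(self.p, cfg.resolved_outlet_pressure)
            res_z, aPz = self._solve_comp("z", mu, grads, p_grad, dt_coefs,
                                          t_next, refactor)
            res_r, aPr = self._solve_comp("r", mu, grads, p_grad, dt_coefs,
                                          t_next, refactor)
            mass_res = self._pressure_step(aPz, aPr, t_next, it == 0)
            prev = worst
            worst = max(res_z, res_r, mass_res)
            if it + 1 >= cfg.min_outer and worst < cfg.residual_tol:
                info = {"outer": it + 1, "res_uz": res_z, "res_ur": res_r,
                        "res_mass": mass_res}
                break
        else:
            raise ConvergenceError(
                f"time step to t={t_next:.5f} s did not reach residual "
                f"{cfg.residual_tol:g}; worst residual {worst:.3e}",
                worst_residual=worst)
        self._uz_old2, self._ur_old2 = self._uz_old, self._ur_old
        self._uz_old, self._ur_old = self.uz.copy(), self.ur.copy()
        self.t = t_next
        info["mass_balance"] = self.global_mass_error()
        return info

    def global_mass_error(self) -> float:
        inflow = self.mdot_in.sum()
        outflow = self.mdot_out.sum()
        if abs(inflow) < 1e-30:
            return abs(outflow)
        return abs(inflow - outflow) / abs(inflow)

    def state(self) -> FlowState:
        return FlowState(uz=self.uz.copy(), ur=self.ur.copy(),
                         p=self.p.copy(), t=self.t)


# =========================================================================
def _probe_indices(grid: StructuredGrid, planes) -> np.ndarray:
    """Nearest interior constant-z face index for each probe plane."""
    z = grid.z
    out = []
    for zp in planes:
        if not (z[0] <= zp <= z[-1]):
            raise ConfigurationError(f"probe plane z={zp} outside the domain")
        out.append(int(np.clip(np.argmin(np.abs(z - zp)), 1, grid.ni - 1)))
    return np.asarray(out)


def _probe_sample(sim: _Simple, iface: int):
    """Area-averaged pressure/axial velocity and centreline velocity at an
    interior constant-z face line."""
    op = sim.op
    i = iface - 1                       # owner cell column of internal E-face i
    w = op.e_w[i, :]
    S = op.eS[i, :]
    pf = w * sim.p[i, :] + (1.0 - w) * sim.p[i + 1, :]
    uf = w * sim.uz[i, :] + (1.0 - w) * sim.uz[i + 1, :]
    A = S.sum()
    return (pf * S).sum() / A, (uf * S).sum() / A, uf[0]


def _build_operator(geom, carreau, fluid, porous, waveform, config):
    grid = build_grid(geom, config.nz_per_mm, config.nr)
    return AxisymFV(grid, fluid, carreau, porous, waveform, config)


def _check_consistency(geom: StenosisGeometry, config: SimulationConfig):
    if config.outlet_mode == "PL" and geom.L_porous > 0.0:
        raise ConfigurationError(
            "outlet_mode=PL requires a geometry without porous segment "
            f"(L_porous={geom.L_porous})")
    if config.outlet_mode == "ML" and geom.L_porous <= 0.0:
        raise ConfigurationError("outlet_mode=ML requires L_porous > 0")


def step(state: FlowState, sim: _Simple, config: SimulationConfig,
         t_next: float) -> FlowState:
    """Advance a flow state by one implicit time step (functional wrapper
    around the SIMPLE driver; ``sim`` carries grid/operator context)."""
    sim.uz, sim.ur, sim.p = state.uz.copy(), state.ur.copy(), state.p.copy()
    sim._uz_old, sim._ur_old = state.uz.copy(), state.ur.copy()
    sim.t = state.t
    sim.advance(t_next)
    return sim.state()


def run_simulation(geom: StenosisGeometry, carreau: law.CarreauParams,
                   fluid: law.FluidParams, porous: law.PorousParams | None,
                   waveform: InletWaveform, config: SimulationConfig,
                   ) -> FieldHistory:
    """Run ``n_cycles`` full cardiac cycles and record probe traces each step.

    The final cycle is the statistics-ready one (see
    :attr:`FieldHistory.stats_cycle`).  Initial condition: fluid at rest at
    the outlet pressure.
    """
    _check_consistency(geom, config)
    op = _build_operator(geom, carreau, fluid, porous, waveform, config)
    sim = _Simple(op)

    planes = config.probe_planes or default_probe_planes(geom)
    ifaces = _probe_indices(op.grid, planes)

    nsteps = config.n_cycles * config.steps_per_cycle
    times = np.zeros(nsteps)
    p_mean = np.zeros((nsteps, len(planes)))
    uz_mean = np.zeros((nsteps, len(planes)))
    uz_center = np.zeros((nsteps, len(planes)))
    mass_err = np.zeros(nsteps)
    snapshots = []

    bdf2 = config.time_scheme == "bdf2"
    for n in range(nsteps):
        t_next = (n + 1) * config.dt
        coefs = (1.5, 2.0, -0.5) if (bdf2 and n > 0) else (1.0, 1.0, 0.0)
        info = sim.advance(t_next, coefs)
        times[n] = t_next
        for kp, i in enumerate(ifaces):
            p_mean[n, kp], uz_mean[n, kp], uz_center[n, kp] = _probe_sample(sim, i)
        mass_err[n] = info["mass_balance"]
        log.debug("step %d t=%.4f outer=%d res=(%.2e,%.2e,%.2e) mass=%.2e",
                  n + 1, t_next, info["outer"], info["res_uz"], info["res_ur"],
                  info["res_mass"], info["mass_balance"])
        if config.snapshot_every and (n + 1) % config.snapshot_every == 0:
            st = sim.state()
            st.mu, _ = op.viscosity(st.uz, st.ur, t_next)
            snapshots.append(st)
        if (n + 1) % config.steps_per_cycle == 0:
            cyc = (n + 1) // config.steps_per_cycle
            sl = slice(n + 1 - config.steps_per_cycle, n + 1)
            log.info("cycle %d done: mean probe pressures %s Pa, max mass err %.2e",
                     cyc, np.round(p_mean[sl].mean(axis=0), 1), mass_err[sl].max())

    return FieldHistory(times=times, probe_z=np.asarray(planes), p_mean=p_mean,
                        uz_mean=uz_mean, uz_center=uz_center, mass_error=mass_err,
                        steps_per_cycle=config.steps_per_cycle,
                        n_cycles=config.n_cycles, config=config, geom=geom,
                        snapshots=snapshots)


def run_steady(geom: StenosisGeometry, carreau: law.CarreauParams,
               fluid: law.FluidParams, porous: law.PorousParams | None,
               v_inlet: float, config: SimulationConfig, *,
               dt_pseudo: float = 0.01, max_steps: int = 400,
               steady_tol: float = 1e-4):
    """March to a steady state with a constant inlet velocity.

    Returns the converged :class:`_Simple` driver (fields accessible as
    ``.uz/.ur/.p``) plus the operator, for probing.  Convergence is declared
    when the per-step relative change of the velocity field drops below
    ``steady_tol``.
    """
    _check_consistency(geom, config)
    wf = InletWaveform.constant(v_inlet)
    cfg = replace(config, dt=dt_pseudo)
    op = _build_operator(geom, carreau, fluid, porous, wf, cfg)
    sim = _Simple(op)
    scale = max(abs(v_inlet), 1e-12)
    for n in range(max_steps):
        uz_prev = sim.uz.copy()
        sim.advance((n + 1) * dt_pseudo)
        change = np.abs(sim.uz - uz_prev).max() / scale
        if change < steady_tol:
            log.info("steady state after %d pseudo-steps (change %.2e)", n + 1, change)
            return sim, op
    raise ConvergenceError(
        f"steady march did not settle within {max_steps} steps "
        f"(last change {change:.3e})", worst_residual=change)
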