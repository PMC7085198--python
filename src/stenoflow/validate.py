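"""Built-in analytic verification suite.

Each check exercises the solver against a closed-form oracle:

* Carreau limits — mu(0) = mu0 and mu(inf) = mu_inf;
* Hagen–Poiseuille — steady Newtonian flow in a straight tube with a
  fully-developed (parabolic) inlet must reproduce the axial pressure
  gradient 8 mu v / R^2;
* porous slug — steady uniform Newtonian flow through a porous tube with
  free-slip walls must reproduce the seepage gradient phi mu u / k.

Used by the ``validate`` CLI subcommand and by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import CarreauParams, FluidParams, PorousParams, carreau_viscosity
from .geometry import StenosisGeometry
from .solver import SimulationConfig, run_steady, _probe_indices, _probe_sample

__all__ = ["ValidationResult", "check_carreau_limits", "check_poiseuille",
           "check_porous_slug", "run_all"]


@dataclass
class ValidationResult:
    name: str
    value: float
    expected: float
    rel_err: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.rel_err) <= self.tol

    def __str__(self) -> str:
        mark = "PASS" if self.passed else "FAIL"
        return (f"[{mark}] {self.name}: got {self.value:.6g}, expected "
                f"{self.expected:.6g} (rel err {self.rel_err:+.2e}, tol {self.tol:g})")


def check_carreau_limits() -> list[ValidationResult]:
    p = CarreauParams()
    lo = carreau_viscosity(p, 0.0)
    hi = carreau_viscosity(p, 1e9)
    return [
        ValidationResult("Carreau zero-shear limit", lo, p.mu0,
                         lo / p.mu0 - 1.0, 1e-12),
        ValidationResult("Carreau infinite-shear limit", hi, p.mu_inf,
                         hi / p.mu_inf - 1.0, 1e-2),
    ]


def check_poiseuille(mu: float = 0.00345, v_mean: float = 0.28,
                     radius: float = 1.4e-3) -> ValidationResult:
    """Steady Newtonian straight tube vs the analytic 8*mu*v/R^2 gradient."""
    geom = StenosisGeometry(r_p=radius, r_s=radius, r_d=radius,
                            l_c=1e-3, l_s=1e-3, l_d=1e-3,
                            L_prox=8e-3, L_dist=8e-3)
    cfg = SimulationConfig(outlet_mode="PL", outlet_pressure=0.0)
    sim, op = run_steady(geom, CarreauParams.newtonian(mu), FluidParams(),
                         None, v_mean, cfg)
    i1, i2 = _probe_indices(op.grid, [5e-3, 15e-3])
    p1 = _probe_sample(sim, i1)[0]
    p2 = _probe_sample(sim, i2)[0]
    grad = (p1 - p2) / (op.grid.z[i2] - op.grid.z[i1])
    exact = 8.0 * mu * v_mean / radius**2
    return ValidationResult("Poiseuille pressure gradient", grad, exact,
                            grad / exact - 1.0, 0.02)


def check_porous_slug(mu: float = 0.00345, u: float = 0.28) -> ValidationResult:
    """Steady uniform flow through a porous tube vs the phi*mu*u/k gradient."""
    pp = PorousParams()
    geom = StenosisGeometry(r_s=1.4e-3, l_c=0.5e-3, l_s=0.5e-3, l_d=0.5e-3,
                            L_prox=2e-3, L_dist=0.5e-3, L_porous=20e-3)
    cfg = SimulationConfig(outlet_mode="ML", outlet_pressure=0.0, nr=16,
                           wall_bc="slip", radial_profile="flat")
    sim, op = run_steady(geom, CarreauParams.newtonian(mu), FluidParams(),
                         pp, u, cfg)
    z0 = geom.z_porous_start
    i1, i2 = _probe_indices(op.grid, [z0 + 5e-3, z0 + 15e-3])
    p1 = _probe_sample(sim, i1)[0]
    p2 = _probe_sample(sim, i2)[0]
    grad = (p1 - p2) / (op.grid.z[i2] - op.grid.z[i1])
    exact = pp.porosity * mu * u / pp.k
    return ValidationResult("porous-slug seepage gradient", grad, exact,
                            grad / exact - 1.0, 0.01)


def run_all() -> list[ValidationResult]:
    out = check_carreau_limits()
    out.append(check_poiseuille())
    out.append(check_porous_slug())
    return out
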