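"""Blood rheology and microcirculation porous-medium closure.

Blood is a homogeneous shear-thinning generalized-Newtonian fluid following
the Carreau law

    mu(gamma) = mu_inf + (mu0 - mu_inf) * [1 + (lambda*gamma)^2]^((n-1)/2)

with the scalar shear rate gamma = sqrt(2 D:D) built from the second
invariant of the strain-rate tensor D (the standard choice for generalized
Newtonian CFD).  The microcirculation bed is a porous medium of porosity phi
whose permeability follows a Kozeny–Carman-type relation in the
representative microvessel diameter d,

    k = d^2 phi^3 / (180 (1 - phi)^2),

and whose momentum sink (Darcy drag, per unit volume of the phi-weighted
balance) is (phi^2 eta / k) u.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractViolation, DomainError

__all__ = [
    "CarreauParams",
    "PorousParams",
    "FluidParams",
    "carreau_viscosity",
    "shear_rate",
    "permeability",
    "porous_sink",
]


@dataclass(frozen=True)
class CarreauParams:
    """Carreau viscosity parameters.  Defaults are literature values for blood."""

    mu0: float = 0.0560       # zero-shear viscosity, Pa*s
    mu_inf: float = 0.00345   # infinite-shear viscosity, Pa*s
    lambda_t: float = 3.313   # time constant, s
    n_index: float = 0.3568   # power-law index

    def __post_init__(self) -> None:
        if not (self.mu0 >= self.mu_inf > 0.0):
            raise ConfigurationError(
                f"require mu0 >= mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if self.lambda_t <= 0.0:
            raise ConfigurationError(f"lambda_t must be > 0, got {self.lambda_t}")
        if not (0.0 < self.n_index <= 1.0):
            raise ConfigurationError(
                f"n_index must be in (0, 1] (shear-thinning), got {self.n_index}"
            )

    @classmethod
    def newtonian(cls, mu: float) -> "CarreauParams":
        """Constant-viscosity (Newtonian) degenerate case, mu0 = mu_inf = mu."""
        return cls(mu0=mu, mu_inf=mu, lambda_t=1.0, n_index=1.0)


@dataclass(frozen=True)
class FluidParams:
    """Bulk fluid parameters; density of whole blood by default."""

    density: float = 1060.0   # kg/m^3

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise ConfigurationError(f"density must be > 0, got {self.density}")


@dataclass(frozen=True)
class PorousParams:
    """Microcirculation porous-zone parameters.

    ``porosity`` is the void fraction phi; ``d_micro`` the representative
    microvessel diameter.  Permeability is always derived (property ``k``),
    never user-set.
    """

    porosity: float = 0.5
    d_micro: float = 100e-6   # m

    def __post_init__(self) -> None:
        if not (0.0 < self.porosity < 1.0):
            raise DomainError(f"porosity must be in (0, 1), got {self.porosity}")
        if self.d_micro <= 0.0:
            raise ConfigurationError(f"d_micro must be > 0, got {self.d_micro}")

    @property
    def k(self) -> float:
        return permeability(self)


def carreau_viscosity(params: CarreauParams, gamma) -> np.ndarray | float:
    """Dynamic viscosity mu(gamma), bounded in [mu_inf, mu0] for gamma >= 0."""
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0.0):
        raise DomainError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lambda_t * g) ** 2
    ) ** ((params.n_index - 1.0) / 2.0)
    return float(mu) if np.isscalar(gamma) else mu


def shear_rate(d_zz, d_rr, d_tt, d_zr) -> np.ndarray | float:
    """Scalar shear rate gamma = sqrt(2 D:D) from the axisymmetric strain-rate
    tensor components (D_zz, D_rr, D_thetatheta = u_r/r, D_zr).

    Depends only on the symmetric velocity gradient; a rigid-body rotation
    contributes nothing.
    """
    g2 = 2.0 * (np.asarray(d_zz) ** 2 + np.asarray(d_rr) ** 2 + np.asarray(d_tt) ** 2
                + 2.0 * np.asarray(d_zr) ** 2)
    out = np.sqrt(g2)
    return float(out) if np.ndim(out) == 0 else out


def permeability(params: PorousParams) -> float:
    """Kozeny–Carman permeability k = d^2 phi^3 / (180 (1 - phi)^2), m^2."""
    phi, d = params.porosity, params.d_micro
    return d * d * phi**3 / (180.0 * (1.0 - phi) ** 2)


def porous_sink(u, mu, params: PorousParams, *, is_porous=True) -> np.ndarray | float:
    """Darcy momentum sink (phi^2 * mu / k) * u of the phi-weighted balance, Pa/m.

    Must only be evaluated in porous-tagged cells; lumen cells have no sink.
    """
    if not np.all(is_porous):
        raise ContractViolation("porous_sink called on a lumen cell")
    coeff = params.porosity**2 * np.asarray(mu, dtype=float) / params.k
    out = coeff * np.asarray(u, dtype=float)
    return float(out) if np.ndim(out) == 0 else out
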