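"""Rheology and porous-closure tests against closed-form values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow import (CarreauParams, ContractViolation, DomainError,
                       PorousParams, carreau_viscosity, permeability,
                       porous_sink, shear_rate)


class TestCarreau:
    def test_zero_shear_limit(self):
        assert carreau_viscosity(CarreauParams(), 0.0) == pytest.approx(0.0560)

    def test_infinite_shear_limit(self):
        assert carreau_viscosity(CarreauParams(), 1e9) == pytest.approx(
            0.00345, abs=1e-5)

    def test_value_at_inverse_time_constant(self):
        # mu_inf + (mu0-mu_inf) * 2^((n-1)/2) at gamma = 1/lambda
        p = CarreauParams()
        expected = p.mu_inf + (p.mu0 - p.mu_inf) * 2.0 ** ((p.n_index - 1) / 2)
        got = carreau_viscosity(p, 1.0 / p.lambda_t)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.04550, abs=1e-5)

    def test_negative_shear_rejected(self):
        with pytest.raises(DomainError):
            carreau_viscosity(CarreauParams(), -1.0)

    @given(g=st.lists(st.floats(0, 1e7), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=40)
    def test_bounded_and_monotone(self, g):
        p = CarreauParams()
        gam = np.sort(np.asarray(g))
        mu = carreau_viscosity(p, gam)
        assert np.all(mu <= p.mu0 + 1e-15) and np.all(mu >= p.mu_inf - 1e-15)
        assert np.all(np.diff(mu) <= 1e-15)    # non-increasing (shear-thinning)

    @given(g=st.floats(0, 1e6))
    @settings(deadline=None, max_examples=30)
    def test_newtonian_limit(self, g):
        p = CarreauParams.newtonian(0.004)
        assert carreau_viscosity(p, g) == pytest.approx(0.004, rel=1e-12)


class TestShearRate:
    def test_simple_shear_recovers_gradient(self):
        # duz/dr = g, everything else zero -> D_zr = g/2, gamma = |g|
        g = 123.4
        assert shear_rate(0.0, 0.0, 0.0, g / 2) == pytest.approx(abs(g))

    def test_zero_tensor(self):
        assert shear_rate(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_uniaxial_extension(self):
        # D = diag(e, -e/2, -e/2) -> gamma = sqrt(2*(e^2 + e^2/4 + e^2/4))
        e = 10.0
        expected = np.sqrt(3.0) * e
        assert shear_rate(e, -e / 2, -e / 2, 0.0) == pytest.approx(expected)


class TestPermeability:
    def test_reference_value(self):
        assert permeability(PorousParams()) == pytest.approx(2.7778e-11,
                                                             rel=1e-4)

    def test_impermeable_limit(self):
        assert permeability(PorousParams(porosity=1e-6)) < 1e-23

    def test_quadratic_in_diameter(self):
        k1 = permeability(PorousParams(d_micro=100e-6))
        k2 = permeability(PorousParams(d_micro=200e-6))
        assert k2 == pytest.approx(4.0 * k1, rel=1e-12)

    @given(phi=st.floats(0.05, 0.95), d=st.floats(10e-6, 500e-6))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_both_arguments(self, phi, d):
        k = permeability(PorousParams(porosity=phi, d_micro=d))
        assert permeability(PorousParams(porosity=min(phi + 0.01, 0.99),
                                         d_micro=d)) > k
        assert permeability(PorousParams(porosity=phi, d_micro=d * 1.1)) > k

    def test_porosity_domain(self):
        with pytest.raises(DomainError):
            PorousParams(porosity=1.5)


class TestPorousSink:
    def test_zero_velocity(self):
        assert porous_sink(0.0, 0.00345, PorousParams()) == 0.0

    def test_reference_drag(self):
        # phi^2 * mu / k * u at u = 1 cm/s
        got = porous_sink(0.01, 0.00345, PorousParams())
        assert got == pytest.approx(3.105e5, rel=1e-3)

    @given(u=st.floats(-1, 1), mu=st.floats(1e-3, 0.06), s=st.floats(0.1, 5))
    @settings(deadline=None, max_examples=40)
    def test_linear_in_velocity_and_viscosity(self, u, mu, s):
        p = PorousParams()
        base = porous_sink(u, mu, p)
        assert porous_sink(s * u, mu, p) == pytest.approx(s * base, rel=1e-12,
                                                          abs=1e-12)
        assert porous_sink(u, s * mu, p) == pytest.approx(s * base, rel=1e-12,
                                                          abs=1e-12)

    def test_lumen_cell_rejected(self):
        with pytest.raises(ContractViolation):
            porous_sink(0.1, 0.00345, PorousParams(), is_porous=False)
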