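"""Geometry and grid metric tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow import (ConfigurationError, DomainError, StenosisGeometry,
                       area_stenosis, build_grid, radius_profile)


@pytest.fixture
def ref_geom():
    return StenosisGeometry()


class TestRadiusProfile:
    @pytest.mark.parametrize("where,expected", [
        ("throat_mid", 0.7e-3),        # throat radius
        ("converging_mid", 1.05e-3),   # linear taper midpoint of 1.4 and 0.7
        ("proximal", 1.4e-3),          # reference lumen
        ("porous", 1.4e-3),            # porous bed keeps the distal radius
    ])
    def test_reference_stations(self, where, expected):
        g = StenosisGeometry(L_porous=5e-3)
        z = {"throat_mid": g.L_prox + g.l_c + g.l_s / 2,
             "converging_mid": g.L_prox + g.l_c / 2,
             "proximal": g.L_prox / 2,
             "porous": g.z_porous_start + 2e-3}[where]
        assert radius_profile(g, z) == pytest.approx(expected, rel=1e-12)

    def test_out_of_domain_raises(self, ref_geom):
        with pytest.raises(DomainError):
            radius_profile(ref_geom, -1e-3)
        with pytest.raises(DomainError):
            radius_profile(ref_geom, ref_geom.total_length + 1e-3)

    @given(rs=st.floats(0.2, 1.4), lc=st.floats(0.5, 5), ld=st.floats(0.5, 5))
    @settings(deadline=None, max_examples=30)
    def test_continuous_at_junctions(self, rs, lc, ld):
        g = StenosisGeometry(r_s=rs * 1e-3, l_c=lc * 1e-3, l_d=ld * 1e-3,
                             L_porous=1e-3)
        eps = 1e-10
        for zb in g.breakpoints[1:-1]:
            left = radius_profile(g, zb - eps)
            right = radius_profile(g, zb + eps)
            assert left == pytest.approx(right, abs=1e-8)


class TestAreaStenosis:
    def test_reference_case_is_75(self, ref_geom):
        assert area_stenosis(ref_geom) == pytest.approx(75.0, abs=1e-12)

    def test_no_stenosis_is_zero(self):
        g = StenosisGeometry(r_s=1.4e-3)
        assert area_stenosis(g) == pytest.approx(0.0, abs=1e-12)

    def test_same_ratio_other_radii(self):
        g = StenosisGeometry(r_p=2e-3, r_s=1e-3, r_d=2e-3)
        assert area_stenosis(g) == pytest.approx(75.0, abs=1e-12)

    @given(scale=st.floats(0.25, 4.0))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_radial_scaling(self, scale):
        g0 = StenosisGeometry()
        g1 = StenosisGeometry(r_p=g0.r_p * scale, r_s=g0.r_s * scale,
                              r_d=g0.r_d * scale)
        assert area_stenosis(g1) == pytest.approx(area_stenosis(g0), rel=1e-12)


class TestInvariants:
    def test_rejects_bad_throat(self):
        with pytest.raises(ConfigurationError):
            StenosisGeometry(r_s=2.0e-3)   # throat wider than lumen
        with pytest.raises(ConfigurationError):
            StenosisGeometry(l_c=-1e-3)
        with pytest.raises(ConfigurationError):
            StenosisGeometry(L_porous=-1e-3)


class TestGrid:
    def test_total_length_sums_segments(self):
        g = StenosisGeometry(L_porous=10e-3)
        expected = (14 + 1.5 + 1.2 + 3 + 14 + 10) * 1e-3
        assert g.total_length == pytest.approx(expected, rel=1e-12)
        grid = build_grid(g, 4, 32)
        assert grid.z[-1] == pytest.approx(expected, rel=1e-12)

    def test_volumes_positive_and_match_analytic(self):
        g = StenosisGeometry(L_porous=0.2e-3)
        grid = build_grid(g, 4, 32)
        assert np.all(grid.vol > 0.0)
        rel = abs(grid.total_volume() - g.analytic_volume()) / g.analytic_volume()
        assert rel < 5e-3
        assert grid.n_cells == grid.ni * grid.nj

    def test_metric_exact_at_two_resolutions(self):
        # the wall is piecewise linear, so the per-cell quadrature is exact
        # at any resolution (grid volume converges trivially)
        g = StenosisGeometry(L_porous=1e-3)
        for nz, nr in [(2, 8), (6, 48)]:
            grid = build_grid(g, nz, nr)
            rel = abs(grid.total_volume() - g.analytic_volume()) / g.analytic_volume()
            assert rel < 1e-12

    def test_porous_tagging(self):
        g = StenosisGeometry(L_porous=2e-3)
        grid = build_grid(g, 4, 16)
        zmid_cols = 0.5 * (grid.z[:-1] + grid.z[1:])
        inside = zmid_cols >= g.z_porous_start
        assert np.array_equal(grid.porous.any(axis=1), inside)
        assert np.array_equal(grid.porous.all(axis=1), inside)

    def test_no_porous_segment_no_tags(self):
        grid = build_grid(StenosisGeometry(), 4, 16)
        assert grid.porous.sum() == 0

    def test_wall_follows_radius_profile(self):
        g = StenosisGeometry(L_porous=0.5e-3)
        grid = build_grid(g, 4, 16)
        R = np.asarray(radius_profile(g, grid.z))
        np.testing.assert_allclose(grid.r[:, -1], R, rtol=1e-12)
        np.testing.assert_allclose(grid.r[:, 0], 0.0, atol=1e-15)

    def test_resolution_floor_enforced(self):
        with pytest.raises(ConfigurationError):
            build_grid(StenosisGeometry(), 1, 32)
        with pytest.raises(ConfigurationError):
            build_grid(StenosisGeometry(), 4, 4)
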