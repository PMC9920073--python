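import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afm3d.contact_models import (
    ElasticParams,
    IndenterGeometry,
    SneddonSeriesCorrection,
    force_conical,
    force_cylindrical,
    force_paraboloid,
    force_sneddon_sphere,
    force_sphere_series,
    shape_function,
    sneddon_contact_radius,
    unit_force_basis,
)
from afm3d.errors import (
    ConfigurationError,
    DomainError,
    GeometryMismatchError,
    ParameterError,
)
from afm3d.units import KPA, NM, NN


class TestGeometryValidation:
    def test_cone_requires_half_angle(self):
        with pytest.raises(ParameterError):
            IndenterGeometry("cone")

    def test_cone_rejects_radius(self):
        with pytest.raises(ParameterError):
            IndenterGeometry("cone", radius=1e-6, half_angle=0.4)

    @pytest.mark.parametrize("kind", ["cylinder", "paraboloid", "sphere"])
    def test_radius_kinds_require_positive_radius(self, kind):
        with pytest.raises(ParameterError):
            IndenterGeometry(kind)
        with pytest.raises(ParameterError):
            IndenterGeometry(kind, radius=-1e-6)

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            IndenterGeometry("pyramid", radius=1e-6)

    def test_half_angle_range(self):
        with pytest.raises(ParameterError):
            IndenterGeometry.cone(math.pi / 2)

    def test_poisson_range(self):
        with pytest.raises(ParameterError):
            ElasticParams(1e3, poisson_ratio=0.6)
        ElasticParams(1e3, poisson_ratio=0.5)  # inclusive upper bound

    def test_negative_modulus(self):
        with pytest.raises(ParameterError):
            ElasticParams(-1.0)


class TestCylindrical:
    def test_zero_modulus(self, cylinder_1um):
        assert force_cylindrical(ElasticParams(0.0), cylinder_1um, 1e-7) == 0.0

    def test_zero_depth(self, cylinder_1um):
        assert force_cylindrical(ElasticParams(154 * KPA), cylinder_1um, 0.0) == 0.0

    def test_hand_evaluated_value(self, cylinder_1um):
        # 2 * 154e3 * 1e-6 * 150e-9 / (1 - 0.25) = 6.16e-8 N
        f = force_cylindrical(ElasticParams(154 * KPA, 0.5), cylinder_1um, 150 * NM)
        assert f == pytest.approx(6.16e-8, rel=1e-12)

    def test_geometry_mismatch(self, cone25):
        with pytest.raises(GeometryMismatchError):
            force_cylindrical(ElasticParams(1e3), cone25, 1e-7)

    def test_negative_depth(self, cylinder_1um):
        with pytest.raises(DomainError):
            force_cylindrical(ElasticParams(1e3), cylinder_1um, -1e-9)


class TestConical:
    def test_zero_depth(self, cone25):
        assert force_conical(ElasticParams(10 * KPA), cone25, 0.0) == 0.0

    def test_linearity_in_modulus(self, cone25):
        f1 = force_conical(ElasticParams(5 * KPA), cone25, 3e-7)
        f2 = force_conical(ElasticParams(10 * KPA), cone25, 3e-7)
        assert f2 == pytest.approx(2 * f1, rel=1e-14)

    def test_hand_evaluated_value(self, cone25):
        # (2 * tan(25 deg) / (pi * 0.75)) * 10e3 * (500e-9)**2 = 9.8954e-10 N
        f = force_conical(ElasticParams(10 * KPA, 0.5), cone25, 500 * NM)
        expected = 2 * math.tan(math.radians(25)) / (math.pi * 0.75) * 10e3 * (500e-9) ** 2
        assert f == pytest.approx(expected, rel=1e-14)
        assert f == pytest.approx(9.9e-10, rel=1e-2)

    def test_quadratic_scaling(self, cone25):
        p = ElasticParams(7 * KPA)
        assert force_conical(p, cone25, 2e-7) == pytest.approx(
            4 * force_conical(p, cone25, 1e-7), rel=1e-13
        )


class TestParaboloid:
    def test_zero_depth(self, paraboloid_1um):
        assert force_paraboloid(ElasticParams(20 * KPA), paraboloid_1um, 0.0) == 0.0

    def test_hand_evaluated_value(self, paraboloid_1um):
        # 4 * sqrt(1e-6) * 20e3 / (3 * 0.75) * (100e-9)**1.5 = 1.1244e-9 N
        f = force_paraboloid(ElasticParams(20 * KPA, 0.5), paraboloid_1um, 100 * NM)
        assert f == pytest.approx(1.12e-9, rel=5e-3)
        assert f == pytest.approx(4 * 1e-3 * 20e3 / 2.25 * (1e-7) ** 1.5, rel=1e-14)

    def test_three_halves_scaling(self, paraboloid_1um):
        p = ElasticParams(20 * KPA)
        assert force_paraboloid(p, paraboloid_1um, 4e-7) == pytest.approx(
            8 * force_paraboloid(p, paraboloid_1um, 1e-7), rel=1e-13
        )


def _bisect_contact_radius(R, h, iters=200):
    """Independent bisection oracle for ln((R+rc)/(R-rc)) = 2h/rc."""
    lo, hi = 1e-18 * R, R * (1 - 1e-15)
    f = lambda rc: math.log((R + rc) / (R - rc)) - 2 * h / rc  # noqa: E731
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSneddonSphere:
    def test_zero_depth_radius(self, sphere_1um):
        assert sneddon_contact_radius(sphere_1um, 0.0) == 0.0
        assert force_sneddon_sphere(ElasticParams(20 * KPA), sphere_1um, 0.0) == 0.0

    def test_hertz_limit_contact_radius(self, sphere_1um):
        rc = sneddon_contact_radius(sphere_1um, 10 * NM)
        assert rc == pytest.approx(math.sqrt(1e-6 * 10e-9), rel=0.01)

    def test_bisection_oracle(self, sphere_1um):
        for h in [1e-9, 1e-8, 1e-7, 4e-7]:
            rc = sneddon_contact_radius(sphere_1um, h)
            assert rc == pytest.approx(_bisect_contact_radius(1e-6, h), rel=1e-10)

    @given(
        R=st.floats(1e-8, 1e-5),
        ratio=st.floats(1e-6, 0.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_contact_radius_residual(self, R, ratio):
        h = ratio * R
        rc = sneddon_contact_radius(IndenterGeometry.sphere(R), h)
        resid = math.log((R + rc) / (R - rc)) - 2 * h / rc
        assert abs(resid) < 1e-9

    def test_hertz_limit_force(self, sphere_1um, paraboloid_1um):
        p = ElasticParams(20 * KPA, 0.5)
        h = 1e-3 * 1e-6  # h/R = 1e-3
        fs = force_sneddon_sphere(p, sphere_1um, h)
        fp = force_paraboloid(p, paraboloid_1um, h)
        assert abs(fs - fp) / fp < 0.01

    def test_monotone_in_depth(self, sphere_1um):
        h = np.linspace(0, 0.5e-6, 40)
        f = force_sneddon_sphere(ElasticParams(20 * KPA), sphere_1um, h)
        assert np.all(np.diff(f) > 0)

    def test_wrong_geometry(self, cone25):
        with pytest.raises(GeometryMismatchError):
            sneddon_contact_radius(cone25, 1e-8)


class TestSphereSeries:
    def test_c1_only_reduces_to_paraboloid(self, sphere_1um, paraboloid_1um):
        p = ElasticParams(20 * KPA, 0.5)
        corr = SneddonSeriesCorrection((1.0,))
        for h in [1e-8, 1e-7, 3e-7]:
            assert force_sphere_series(p, sphere_1um, h, corr) == pytest.approx(
                force_paraboloid(p, paraboloid_1um, h), rel=1e-14
            )

    def test_zero_depth(self, sphere_1um):
        corr = SneddonSeriesCorrection((1.0, -0.2))
        assert force_sphere_series(ElasticParams(20 * KPA), sphere_1um, 0.0, corr) == 0.0

    def test_term_by_term_sum_oracle(self, sphere_1um, paraboloid_1um):
        p = ElasticParams(20 * KPA, 0.5)
        coeffs = (1.0, -0.3, 0.05, -0.01)
        R, h = 1e-6, 2e-7
        # independent term-by-term evaluation of the correction series
        z = coeffs[0]
        for m in range(2, len(coeffs) + 1):
            z += 3.0 / (2 * m) * coeffs[m - 1] * R ** (1.5 - m) * h ** (m - 1.5)
        expected = force_paraboloid(p, paraboloid_1um, h) * z
        got = force_sphere_series(p, sphere_1um, h, SneddonSeriesCorrection(coeffs))
        assert got == pytest.approx(expected, rel=1e-13)

    def test_empty_coefficients_rejected(self):
        with pytest.raises(ConfigurationError):
            SneddonSeriesCorrection(())

    def test_z_above_one_warns(self, sphere_1um):
        corr = SneddonSeriesCorrection((1.0, 0.5))  # pushes Z above 1
        with pytest.warns(UserWarning, match="Z"):
            force_sphere_series(ElasticParams(20 * KPA), sphere_1um, 3e-7, corr)


class TestShapeFunction:
    def test_definition_consistency(self, cone25):
        rng = np.random.default_rng(42)
        for h in rng.uniform(1e-9, 1e-6, 10):
            f = force_conical(ElasticParams(7 * KPA, 0.5), cone25, h)
            assert f == pytest.approx(7 * KPA * shape_function(cone25, 0.5, h), rel=1e-14)

    def test_zero_depth(self, paraboloid_1um):
        assert shape_function(paraboloid_1um, 0.5, 0.0) == 0.0

    def test_unit_modulus_equivalence(self, paraboloid_1um):
        g = shape_function(paraboloid_1um, 0.5, 100 * NM)
        assert g == pytest.approx(
            force_paraboloid(ElasticParams(1.0, 0.5), paraboloid_1um, 100 * NM), rel=1e-15
        )

    def test_sphere_unsupported(self, sphere_1um):
        with pytest.raises(GeometryMismatchError):
            shape_function(sphere_1um, 0.5, 1e-8)

    def test_unit_force_basis_sphere(self, sphere_1um):
        basis = unit_force_basis(sphere_1um, 0.5, 2e-7)
        full = force_sneddon_sphere(ElasticParams(20 * KPA, 0.5), sphere_1um, 2e-7)
        assert full == pytest.approx(20 * KPA * basis, rel=1e-14)


class TestInvariants:
    @pytest.mark.parametrize("maker,kind", [
        (lambda: IndenterGeometry.cylinder(1e-6), "cylinder"),
        (lambda: IndenterGeometry.cone(math.radians(25)), "cone"),
        (lambda: IndenterGeometry.paraboloid(1e-6), "paraboloid"),
        (lambda: IndenterGeometry.sphere(1e-6), "sphere"),
    ])
    def test_zero_at_origin_and_monotone(self, maker, kind):
        geom = maker()
        h = np.linspace(0, 4e-7, 25)
        f = np.asarray(unit_force_basis(geom, 0.5, h)) * 20 * KPA
        assert f[0] == 0.0
        assert np.all(np.diff(f) > 0)

    @given(k=st.floats(0.0, 50.0), e=st.floats(1.0, 1e6), ratio=st.floats(1e-4, 0.4))
    @settings(max_examples=60, deadline=None)
    def test_homogeneity_in_modulus(self, k, e, ratio):
        geom = IndenterGeometry.sphere(1e-6)
        h = ratio * 1e-6
        f1 = force_sneddon_sphere(ElasticParams(e, 0.3), geom, h)
        f2 = force_sneddon_sphere(ElasticParams(k * e, 0.3), geom, h)
        assert f2 == pytest.approx(k * f1, rel=1e-12, abs=1e-300)

    def test_unit_round_trip(self, cone25):
        f_si = force_conical(ElasticParams(10 * KPA, 0.5), cone25, 500 * NM)
        f_nn = f_si / NN
        assert f_nn * NN == pytest.approx(f_si, rel=1e-12)
        h_nm = 500 * NM / NM
        assert h_nm * NM == pytest.approx(500 * NM, rel=1e-12)
        e_kpa = 10 * KPA / KPA
        assert e_kpa * KPA == pytest.approx(10 * KPA, rel=1e-12)
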