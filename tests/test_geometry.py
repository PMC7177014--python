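"""Thinning-field definition: zone scaling, direction constant, force."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memthin import (
    ThinningFieldParams,
    ZoneGeometry,
    direction_constant,
    thinning_force,
    zone_scaling,
)
from memthin.geometry import (
    ConfigurationError,
    thinning_force_array,
    zone_scaling_array,
)

GEOM = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)


class TestZoneScaling:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (27.5, 1.0),  # thin-zone center
            (27.5 + 5.0, 1.0),  # thin-zone edge
            (27.5 - 5.0, 1.0),
            (27.5 + 10.0, 0.5),  # linear ramp midpoint: 5 nm into buffer
            (27.5 + 7.5, 0.75),
            (27.5 + 15.0, 0.0),  # buffer/normal boundary
            (27.5 - 15.0, 0.0),
            (0.0, 0.0),  # normal zone across the periodic boundary
            (55.0, 0.0),
        ],
    )
    def test_reference_values(self, x, expected):
        assert zone_scaling(x, GEOM) == pytest.approx(expected, abs=1e-12)

    def test_spec_example_geometry(self):
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
        assert zone_scaling(27.5 + 7.5, geom) == pytest.approx(0.75)
        # midpoint of the ramp is half-way through the buffer
        mid = 27.5 + 5.0 + 5.0
        assert zone_scaling(mid, geom) == pytest.approx(0.5)

    def test_continuity_on_grid(self):
        x = np.linspace(-5, 60, 20001)
        c = zone_scaling_array(x, GEOM)
        dx = x[1] - x[0]
        # slope bounded by 1/A_buffer => continuous within float tolerance
        assert np.abs(np.diff(c)).max() <= dx / GEOM.A_buffer + 1e-12

    def test_periodic_wrap(self):
        x = np.array([3.0, 3.0 + 55.0, 3.0 - 55.0])
        c = zone_scaling_array(x, GEOM)
        assert np.allclose(c, c[0])

    def test_array_matches_scalar(self):
        xs = np.linspace(0, 55, 777)
        arr = zone_scaling_array(xs, GEOM)
        scalars = np.array([zone_scaling(float(x), GEOM) for x in xs])
        np.testing.assert_allclose(arr, scalars, atol=1e-14)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            ZoneGeometry(X_box=20.0, A_thin=10.0, A_buffer=10.0)
        with pytest.raises(ConfigurationError):
            ZoneGeometry(X_box=20.0, A_thin=-1.0, A_buffer=5.0)
        with pytest.raises(ConfigurationError):
            ThinningFieldParams(k=-1.0)
        with pytest.raises(ConfigurationError):
            ThinningFieldParams(D=0.0)

    def test_zone_partition_tiles_box(self):
        """thin + 2*buffer + normal lengths add up to the whole box."""
        t0, t1 = GEOM.thin_range()
        normal = sum(hi - lo for lo, hi in GEOM.normal_ranges())
        total = (t1 - t0) + 2 * GEOM.A_buffer + normal
        assert total == pytest.approx(GEOM.X_box, abs=1e-12)


class TestDirectionConstant:
    @pytest.mark.parametrize(
        "z,d", [(1.5, 1), (0.3, 0), (-1.5, -1), (0.51, 1), (-0.51, -1), (0.5, 0)]
    )
    def test_cases(self, z, d):
        assert direction_constant(z, D=1.0) == d


class TestThinningForce:
    def test_hand_evaluated_magnitudes(self):
        p = ThinningFieldParams(k=20.0, D=1.0)
        # tail bead 1.5 nm above the midplane, full zone scale
        assert thinning_force(1.5, 1.0, p) == pytest.approx(-20.0)
        assert thinning_force(-1.5, 1.0, p) == pytest.approx(20.0)

    def test_head_beads_feel_nothing(self):
        p = ThinningFieldParams(k=20.0, D=1.0)
        assert thinning_force(2.0, 1.0, p, is_tail=False) == 0.0

    def test_non_finite_coordinates_error(self):
        p = ThinningFieldParams()
        with pytest.raises(RuntimeError):
            thinning_force(float("nan"), 1.0, p)

    @given(
        z=st.floats(-4, 4),
        c=st.floats(0, 1),
        k=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_restoring_and_antisymmetric(self, z, c, k):
        p = ThinningFieldParams(k=k, D=1.0)
        f = thinning_force(z, c, p)
        # antisymmetry
        assert thinning_force(-z, c, p) == pytest.approx(-f, abs=1e-9)
        # restoring: force points toward the midplane wherever nonzero
        if f != 0.0:
            assert np.sign(f) == -np.sign(z)
        # dead zone
        if abs(z) <= p.D / 2 or c == 0.0:
            assert f == 0.0
        # linear in k and C
        assert thinning_force(z, c, ThinningFieldParams(k=2 * k, D=1.0)) == (
            pytest.approx(2 * f, rel=1e-12, abs=1e-12)
        )

    def test_grid_invariants(self):
        """Antisymmetry, dead zone, continuity, k-linearity on an (x,z) grid."""
        xs = np.linspace(0, GEOM.X_box, 221, endpoint=False)
        zs = np.linspace(-3, 3, 241)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        tails = np.ones(X.size, dtype=bool)
        p1 = ThinningFieldParams(k=20.0, D=1.0)
        f1 = thinning_force_array(X.ravel(), Z.ravel(), GEOM, p1, tails).reshape(X.shape)
        # antisymmetry in z
        np.testing.assert_allclose(f1, -f1[:, ::-1], atol=1e-12)
        # dead zone
        dead = np.abs(Z) <= 0.5
        assert np.all(f1[dead] == 0.0)
        c = zone_scaling_array(xs, GEOM)
        assert np.all(f1[c == 0.0, :] == 0.0)
        # linearity in k
        f2 = thinning_force_array(
            X.ravel(), Z.ravel(), GEOM, ThinningFieldParams(k=40.0, D=1.0), tails
        ).reshape(X.shape)
        np.testing.assert_allclose(f2, 2 * f1, atol=1e-12)
        # continuity: bounded discrete gradient in x and z
        dfdx = np.abs(np.diff(f1, axis=0)).max()
        # |dF/dx| <= k * (D/2 - |z|)_max / A_buffer
        assert dfdx <= 20.0 * 2.5 / GEOM.A_buffer * (xs[1] - xs[0]) + 1e-9
        dfdz = np.abs(np.diff(f1, axis=1)).max()
        assert dfdz <= 20.0 * (zs[1] - zs[0]) + 1e-9

    def test_disabled_field_is_zero(self):
        p = ThinningFieldParams(k=20.0, D=1.0, enabled=False)
        x = np.array([27.5]); z = np.array([2.0])
        f = thinning_force_array(x, z, GEOM, p, np.array([True]))
        assert f[0] == 0.0
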