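"""Trajectory-model tests: auxiliary functions, sector rules, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arcuate import (
    BundleModelParams,
    PointDeg,
    ScanGeometry,
    b_inf,
    b_sup,
    beta_grid,
    c_inf,
    c_sup,
    phi_of_r,
    region_of_phi0,
    sample_trajectory,
)
from arcuate.errors import DegenerateTrajectoryError
from arcuate.geometry import rotate_about


class TestAuxiliaryFunctions:
    def test_curvature_location_at_tanh_centers(self):
        # the tanh term vanishes at its center, leaving the constant
        assert c_sup(121.0) == 1.9
        assert c_inf(-90.0) == 1.0

    def test_scalar_oracle_values(self):
        # independent high-precision evaluation via math.tanh / math.exp
        assert c_sup(135.0) == pytest.approx(1.9 + 1.4 * math.tanh(1.0), abs=1e-14)
        assert b_sup(121.0, -1.9) == pytest.approx(math.exp(-1.9), abs=1e-14)
        assert b_inf(-90.0, 0.7) == pytest.approx(-math.exp(0.7), abs=1e-14)

    def test_sector_violations_rejected(self):
        with pytest.raises(ValueError):
            c_sup(59.9)
        with pytest.raises(ValueError):
            c_inf(-59.9)
        with pytest.raises(ValueError):
            b_sup(30.0, -1.9)

    def test_beta_range_enforced_unless_overridden(self):
        with pytest.raises(ValueError):
            b_sup(121.0, -3.0)
        assert b_sup(121.0, -3.0, allow_outside=True) == pytest.approx(
            math.exp(-3.0)
        )

    @given(
        st.floats(60, 180, allow_nan=False),
        st.floats(-2.5, -1.3, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_b_sup_positive(self, phi0, beta):
        assert b_sup(phi0, beta) > 0

    @given(
        st.floats(-180, -60, allow_nan=False).filter(lambda p: p > -180),
        st.floats(0.1, 1.3, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_b_inf_negative(self, phi0, beta):
        assert b_inf(phi0, beta) < 0

    def test_curvature_location_monotone(self):
        sup = c_sup(np.linspace(60, 180, 500))
        assert np.all(np.diff(sup) > 0)
        inf = c_inf(np.linspace(-60, -179.9, 500))  # increasing in -phi0
        assert np.all(np.diff(inf) > 0)


class TestTrajectoryEquation:
    def test_boundary_identity_random_draws(self, rng):
        # phi(phi0, r0) = phi0 exactly, over both sectors
        for _ in range(1000):
            if rng.random() < 0.5:
                phi0 = rng.uniform(60, 180)
                beta, region = rng.uniform(-2.5, -1.3), "superior"
            else:
                phi0 = rng.uniform(-179.99, -60)
                beta, region = rng.uniform(0.1, 1.3), "inferior"
            r0 = rng.uniform(2, 8)
            assert phi_of_r(phi0, r0, r0, beta, region) == pytest.approx(
                phi0, abs=1e-12
            )

    def test_scalar_oracle(self):
        # phi = 121 + exp(-1.9) * 5 ** 1.9, by direct evaluation
        expected = 121 + math.exp(-1.9) * 5 ** 1.9
        assert phi_of_r(121, 9, 4, -1.9, "superior") == pytest.approx(
            expected, abs=1e-12
        )

    def test_r_below_r0_rejected(self):
        with pytest.raises(ValueError):
            phi_of_r(121, 3.9, 4, -1.9, "superior")

    def test_monotone_in_r_by_sector(self):
        r = np.linspace(4, 20, 200)
        sup = phi_of_r(100.0, r, 4, -1.9, "superior")
        assert np.all(np.diff(sup) >= 0)
        inf = phi_of_r(-100.0, r, 4, 0.7, "inferior")
        assert np.all(np.diff(inf) <= 0)


class TestSectorRule:
    @pytest.mark.parametrize(
        "phi0, region",
        [
            (60, "superior"),   # boundary inclusive
            (-60, "inferior"),  # boundary inclusive
            (0, "nasal"),
            (180, "superior"),
            (59.9, "nasal"),
            (-59.9, "nasal"),
            (-179.9, "inferior"),
        ],
    )
    def test_boundaries(self, phi0, region):
        assert region_of_phi0(phi0) == region


class TestBetaGrid:
    def test_superior_grid_printed_values(self):
        g = beta_grid("superior")
        assert len(g) == 11
        assert g[0] == -1.3 and g[-1] == -2.5
        assert g[5] == pytest.approx(-1.90, abs=1e-12)
        assert g[4] == pytest.approx(-1.78, abs=1e-12)

    def test_inferior_grid_printed_values(self):
        g = beta_grid("inferior")
        assert g[0] == 1.3 and g[-1] == pytest.approx(0.1)
        assert g[5] == pytest.approx(0.70, abs=1e-12)
        assert g[4] == pytest.approx(0.82, abs=1e-12)

    def test_even_spacing(self):
        g = beta_grid("inferior")
        assert np.allclose(np.diff(g), -(1.3 - 0.1) / 10)


class TestSampleTrajectory:
    def test_zero_relative_fd_matches_model_frame(self, geometry):
        # recorded FD equals the assumed one and the BMO sits at the
        # assumed ONH position: the output is the untransformed model path
        t = sample_trajectory(geometry, 121.0, -1.9)
        r_c = geometry.r_c_deg
        assert t.polyline[0] == pytest.approx(
            [15 + r_c * math.cos(math.radians(121)),
             2 + r_c * math.sin(math.radians(121))],
            abs=1e-12,
        )
        assert t.phi[0] == pytest.approx(121.0)

    def test_starts_on_circle_and_radii_nondecreasing(self, geometry):
        for phi0, beta in [(80.0, -1.3), (170.0, -2.5), (-70.0, 0.1), (0.0, None)]:
            t = sample_trajectory(geometry, phi0, beta)
            bx, by = geometry.bmo_center
            d0 = math.hypot(t.polyline[0, 0] - bx, t.polyline[0, 1] - by)
            assert d0 == pytest.approx(geometry.r_c_deg, abs=1e-9)
            assert np.all(np.diff(t.r) >= -1e-12)

    def test_nasal_ray_is_straight_radial(self, geometry):
        t = sample_trajectory(geometry, 0.0, None)
        # collinear with the ray from the BMO center through the circle point
        assert np.allclose(t.polyline[:, 1], 2.0)
        assert np.all(np.diff(t.polyline[:, 0]) > 0)

    def test_raphe_clipping_keeps_one_side(self, geometry):
        t = sample_trajectory(geometry, 170.0, -1.9)
        assert t.clip_reason in ("raphe", "fd_line")
        # fovea latitude is y = 0 in this zero-rotation frame
        assert np.all(t.polyline[:, 1] >= -1e-9)
        assert t.polyline[-1, 1] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_translation_equivariance(self, geometry):
        rotated = ScanGeometry(
            bmo_center=PointDeg(14.5, 2.5), fd_angle_deg=-2.59, r_c_deg=6.0
        )
        base = sample_trajectory(geometry, 121.0, -1.9)
        moved = sample_trajectory(rotated, 121.0, -1.9)
        delta = rotated.fd_angle_deg - (-7.59)
        onh = PointDeg(15.0, 2.0)
        onh_rot = rotate_about(onh, PointDeg(0, 0), delta)
        off = (rotated.bmo_center.x - onh_rot.x, rotated.bmo_center.y - onh_rot.y)
        n = min(len(base.r), len(moved.r))
        for k in (0, n // 2, n - 1):
            p = rotate_about(
                PointDeg(*base.polyline[k]), PointDeg(0, 0), delta
            )
            assert moved.polyline[k] == pytest.approx(
                [p.x + off[0], p.y + off[1]], abs=1e-9
            )
        # the polar radius about the BMO center is transform-invariant
        assert np.allclose(base.r[:n], moved.r[:n])

    def test_same_sector_trajectories_never_cross(self, geometry):
        a = sample_trajectory(geometry, 100.0, -1.9)
        b = sample_trajectory(geometry, 130.0, -1.9)
        n = min(len(a.r), len(b.r))
        assert np.all(b.phi[:n] - a.phi[:n] > 0)

    def test_r_c_at_or_above_r_max_rejected(self):
        g = ScanGeometry(r_c_deg=26.0)
        with pytest.raises(ValueError):
            sample_trajectory(g, 121.0, -1.9)

    def test_degenerate_start_on_boundary(self):
        # a start point exactly on the fovea-latitude line: y = 2 + 6 sin(phi0) = 0
        g = ScanGeometry(r_c_deg=6.0)
        phi0 = math.degrees(math.asin(-1.0 / 3.0))  # nasal-sector ray
        with pytest.raises(DegenerateTrajectoryError):
            sample_trajectory(g, phi0, None)

    def test_field_box_truncation(self, geometry):
        params = BundleModelParams(field_extent_deg=(30.0, 25.0))
        t = sample_trajectory(geometry, 100.0, -1.9, params)
        assert t.clip_reason == "field_edge"
        assert np.all(np.abs(t.polyline[-1]) <= [15 + 1e-6, 12.5 + 1e-6])
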