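"""Border-extraction tests: binarization, component selection, perimeter,
and the upper/lower split, against brute-force raster oracles."""

import numpy as np
import pytest

from arcuate import (
    PMap,
    PointDeg,
    ScanGeometry,
    binarize_pmap,
    extract_arcuate_borders,
    extract_perimeter,
    generate_arcuate_borders,
    generate_arcuate_pmap,
    mirror_pmap,
    select_arcuate_component,
    split_borders,
    wrap_phi,
)
from arcuate.borders import CAT_NORMAL, CAT_P1, CAT_P5, BinaryMask
from arcuate.errors import DegenerateBorderError, NoArcuateError


def make_pmap(grid, pixel_size=0.25, origin=None, geometry=None):
    grid = np.asarray(grid, dtype=np.uint8)
    h, w = grid.shape
    if origin is None:
        origin = PointDeg(-(w - 1) / 2 * pixel_size + 15, (h - 1) / 2 * pixel_size + 2)
    return PMap(grid, pixel_size, origin, geometry or ScanGeometry())


class TestBinarize:
    def test_all_normal_gives_empty_mask(self):
        pm = make_pmap(np.zeros((9, 9)))
        assert binarize_pmap(pm).grid.sum() == 0

    def test_single_p1_pixel(self):
        g = np.zeros((9, 9))
        g[4, 4] = CAT_P1
        mask = binarize_pmap(make_pmap(g))
        assert mask.grid.sum() == 1 and mask.grid[4, 4] == 1

    def test_p5_and_outside_threshold_to_zero(self):
        g = np.zeros((9, 9))
        g[1, 1] = CAT_P5
        g[2, 2] = 255  # outside-field
        assert binarize_pmap(make_pmap(g)).grid.sum() == 0


class TestSelectComponent:
    def test_single_component_no_seed(self):
        # one arc-shaped component: selection must return it unchanged
        geom = ScanGeometry()
        ps = 0.25
        h = w = 81
        origin = PointDeg(15 - 10, 2 + 10)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        x = origin.x + jj * ps
        y = origin.y - ii * ps
        r = np.hypot(x - 15, y - 2)
        phi = np.degrees(np.arctan2(y - 2, x - 15))
        g = ((r > 6) & (r < 8) & (phi > 80) & (phi < 120)).astype(np.uint8)
        pm = PMap(g * CAT_P1, ps, origin, geom)
        mask = binarize_pmap(pm)
        comp = select_arcuate_component(mask)
        assert np.array_equal(comp.grid, mask.grid)

    def test_seed_selects_containing_component(self):
        g = np.zeros((40, 40))
        g[5:25, 5:8] = CAT_P1   # large blob
        g[30:32, 30:32] = CAT_P1  # small blob
        pm = make_pmap(g)
        x, y = pm.pixel_center(30, 30)
        comp = select_arcuate_component(binarize_pmap(pm), PointDeg(float(x), float(y)))
        assert comp.grid.sum() == 4  # the small one was seeded

    def test_angular_extent_rule(self):
        # two arcs about the BMO center: ~40 deg extent vs ~5 deg extent;
        # brute-force construction by angle test per pixel
        geom = ScanGeometry()
        ps = 0.25
        h = w = 81
        origin = PointDeg(15 - 10, 2 + 10)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        x = origin.x + jj * ps
        y = origin.y - ii * ps
        r = np.hypot(x - 15, y - 2)
        phi = np.degrees(np.arctan2(y - 2, x - 15))
        g = np.zeros((h, w))
        g[(r > 6) & (r < 8) & (phi > 80) & (phi < 120)] = CAT_P1   # 40 deg
        g[(r > 6) & (r < 8) & (phi > -100) & (phi < -95)] = CAT_P1  # 5 deg
        pm = PMap(g.astype(np.uint8), ps, origin, geom)
        comp = select_arcuate_component(binarize_pmap(pm), min_angular_extent=20.0)
        ii2, jj2 = np.nonzero(comp.grid)
        x2, y2 = pm.pixel_center(ii2, jj2)
        phi2 = np.degrees(np.arctan2(y2 - 2, x2 - 15))
        assert phi2.min() > 70 and phi2.max() < 130  # the wide arc won

    def test_empty_mask_rejected(self):
        pm = make_pmap(np.zeros((9, 9)))
        with pytest.raises(NoArcuateError):
            select_arcuate_component(binarize_pmap(pm))


class TestPerimeter:
    def brute_force_perimeter(self, grid):
        h, w = grid.shape
        out = np.zeros_like(grid)
        for i in range(h):
            for j in range(w):
                if not grid[i, j]:
                    continue
                edge = i in (0, h - 1) or j in (0, w - 1)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and not grid[ni, nj]:
                        edge = True
                out[i, j] = edge
        return out

    def test_single_pixel_is_its_own_perimeter(self):
        g = np.zeros((9, 9))
        g[4, 4] = CAT_P1
        pm = make_pmap(g)
        per = extract_perimeter(binarize_pmap(pm))
        assert per.grid.sum() == 1 and per.grid[4, 4] == 1

    def test_filled_square_keeps_8_border_pixels(self):
        g = np.zeros((9, 9))
        g[3:6, 3:6] = CAT_P1
        per = extract_perimeter(binarize_pmap(make_pmap(g)))
        assert per.grid.sum() == 8
        assert per.grid[4, 4] == 0

    def test_disc_matches_brute_force_oracle(self):
        h = w = 31
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        mask = ((ii - 15) ** 2 + (jj - 15) ** 2 <= 100).astype(np.uint8)
        pm = make_pmap(mask * CAT_P1)
        per = extract_perimeter(BinaryMask(mask, pm))
        assert np.array_equal(per.grid, self.brute_force_perimeter(mask))


class TestSplitBorders:
    def test_band_between_trajectories(self, spec_superior):
        # rasterized band bounded by the phi0=100 and phi0=130 trajectories:
        # extracted borders must lie within one pixel of the generators
        pm = generate_arcuate_pmap(spec_superior)
        upper, lower = extract_arcuate_borders(pm)
        exact_up, exact_lo = generate_arcuate_borders(spec_superior)
        for got, ref in ((upper, exact_up), (lower, exact_lo)):
            gx = got.r * np.cos(np.radians(got.phi))
            gy = got.r * np.sin(np.radians(got.phi))
            rx = ref.r * np.cos(np.radians(ref.phi))
            ry = ref.r * np.sin(np.radians(ref.phi))
            d = np.hypot(gx[:, None] - rx, gy[:, None] - ry).min(axis=1)
            assert d.max() < pm.pixel_size  # directed Hausdorff < 1 px

    def test_annulus_sector_constant_angles(self):
        geom = ScanGeometry()
        ps = 0.25
        h = w = 81
        origin = PointDeg(15 - 10, 2 + 10)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        x = origin.x + jj * ps
        y = origin.y - ii * ps
        r = np.hypot(x - 15, y - 2)
        phi = np.degrees(np.arctan2(y - 2, x - 15))
        g = ((r > 5) & (r < 9) & (phi > 95) & (phi < 125)).astype(np.uint8) * CAT_P1
        pm = PMap(g, ps, origin, geom)
        upper, lower = extract_arcuate_borders(pm, min_angular_extent=20.0)
        # interior bins follow the two constant angles (1 px tolerance
        # translates to ~atan(ps / r) degrees at these radii)
        tol = np.degrees(ps / 5) + 1e-9
        assert np.median(np.abs(upper.phi - 125)) < tol
        assert np.median(np.abs(lower.phi - 95)) < tol

    def test_single_pixel_wide_arc_degenerate(self):
        geom = ScanGeometry()
        ps = 0.25
        h = w = 81
        origin = PointDeg(15 - 10, 2 + 10)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        x = origin.x + jj * ps
        y = origin.y - ii * ps
        r = np.hypot(x - 15, y - 2)
        phi = np.degrees(np.arctan2(y - 2, x - 15))
        g = ((np.abs(r - 7) < ps / 2) & (phi > 80) & (phi < 120)).astype(np.uint8)
        pm = PMap(g * CAT_P1, ps, origin, geom)
        with pytest.raises((DegenerateBorderError, NoArcuateError)):
            extract_arcuate_borders(pm, min_angular_extent=20.0)

    def test_border_points_lie_on_perimeter(self, spec_superior):
        pm = generate_arcuate_pmap(spec_superior)
        mask = select_arcuate_component(binarize_pmap(pm))
        per = extract_perimeter(mask)
        upper, lower = split_borders(per)
        ii, jj = np.nonzero(per.grid)
        px, py = pm.pixel_center(ii, jj)
        bx, by = pm.geometry.bmo_center
        for b in (upper, lower):
            x = bx + b.r * np.cos(np.radians(b.phi))
            y = by + b.r * np.sin(np.radians(b.phi))
            d = np.hypot(x[:, None] - px, y[:, None] - py).min(axis=1)
            assert d.max() < 1e-9

    def test_idempotent_on_rasterized_component(self, spec_superior):
        pm = generate_arcuate_pmap(spec_superior)
        comp = select_arcuate_component(binarize_pmap(pm))
        upper1, lower1 = split_borders(extract_perimeter(comp))
        # re-rasterize the selected component as a fresh p-map and re-run
        pm2 = PMap(comp.grid * CAT_P1, pm.pixel_size, pm.origin, pm.geometry)
        upper2, lower2 = extract_arcuate_borders(pm2)
        assert np.array_equal(upper1.r, upper2.r)
        assert np.array_equal(upper1.phi, upper2.phi)
        assert np.array_equal(lower1.phi, lower2.phi)

    def test_extraction_commutes_with_mirroring(self, spec_superior):
        pm = generate_arcuate_pmap(spec_superior)
        upper, lower = extract_arcuate_borders(pm)
        m_upper, m_lower = extract_arcuate_borders(mirror_pmap(pm))
        # mirroring maps phi -> 180 - phi and swaps the angular extremes,
        # so the mirrored upper border is the mirror of the lower border
        assert np.allclose(np.sort(m_upper.r), np.sort(lower.r))
        got = np.sort(wrap_phi(180.0 - m_upper.phi))
        assert np.allclose(got, np.sort(lower.phi), atol=1e-9)
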