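"""Geometry: rasterization, dilation, shape statistics and distances."""

import math

import numpy as np
import pytest

from arcdose import geometry as geo
from arcdose.grids import ContourSet, ContourSlice, DoseGrid, StructureMask
from conftest import sphere_mask


def _grid(shape, spacing=1.0, origin=None):
    if origin is None:
        origin = tuple(-spacing * (s - 1) / 2 for s in shape)
    return DoseGrid(np.zeros(shape), spacing=(spacing,) * 3, origin=origin)


class TestRasterize:
    def test_square_voxel_count(self):
        """10x10 mm square on a 1 mm grid covers 100 voxel centres per slice."""
        grid = DoseGrid(np.zeros((3, 20, 20)), spacing=(1, 1, 1), origin=(0, 0.5, 0.5))
        square = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], dtype=float)
        contours = ContourSet("sq", [ContourSlice(z=float(z), polygons=[square])
                                     for z in range(3)])
        mask = geo.rasterize(contours, grid)
        assert mask.values.sum(axis=(1, 2)).tolist() == [100, 100, 100]

    def test_empty_contour_set(self):
        mask = geo.rasterize(ContourSet("none", []), _grid((3, 4, 4)))
        assert mask.is_empty()

    def test_circle_area_within_one_percent(self):
        """Voxel area of a radius-10 mm circle at 0.5 mm approximates pi r^2."""
        n = 50
        grid = DoseGrid(np.zeros((1, n, n)), spacing=(1, 0.5, 0.5),
                        origin=(0, -(n - 1) * 0.25, -(n - 1) * 0.25))
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = np.column_stack([10 * np.sin(theta), 10 * np.cos(theta)])
        mask = geo.rasterize(ContourSet("circle", [ContourSlice(0.0, [circle])]), grid)
        area_mm2 = mask.values.sum() * 0.25
        assert area_mm2 == pytest.approx(np.pi * 100, rel=0.01)

    def test_contour_outside_grid_raises(self):
        grid = _grid((3, 10, 10))
        far = np.array([[100, 100], [100, 110], [110, 110]], dtype=float)
        contours = ContourSet("far", [ContourSlice(0.0, [far])])
        with pytest.raises(ValueError, match="outside the grid"):
            geo.rasterize(contours, grid)


class TestExpandMargin:
    def test_zero_margin_is_identity(self, small_sphere):
        out = geo.expand_margin(small_sphere, 0.0)
        np.testing.assert_array_equal(out.values, small_sphere.values)

    def test_single_voxel_becomes_digital_ball(self):
        values = np.zeros((13, 13, 13), dtype=bool)
        values[6, 6, 6] = True
        mask = StructureMask(values, spacing=(1, 1, 1))
        out = geo.expand_margin(mask, 5.0)
        ax = np.arange(13) - 6
        Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
        expected = Z ** 2 + Y ** 2 + X ** 2 <= 25.0 + 1e-9
        np.testing.assert_array_equal(out.values, expected)

    def test_sphere_expansion_matches_analytic_volume(self):
        # 0.5 mm grid: voxel-centre dilation carries a half-voxel inward bias,
        # so the grid must be fine enough for a 2% volume agreement
        mask = sphere_mask(20.0, 0.5, margin_vox=12)
        out = geo.expand_margin(mask, 5.0)
        expected = 4 / 3 * math.pi * 25.0 ** 3 / 1000
        assert out.volume_cm3 == pytest.approx(expected, rel=0.02)

    def test_extensive_and_monotone(self, small_sphere):
        a = geo.expand_margin(small_sphere, 2.0)
        b = geo.expand_margin(small_sphere, 4.0)
        assert np.all(a.values | ~small_sphere.values)  # output contains input
        assert np.all(b.values | ~a.values)             # monotone in the margin

    def test_anisotropic_margin(self):
        values = np.zeros((21, 21, 21), dtype=bool)
        values[10, 10, 10] = True
        mask = StructureMask(values, spacing=(1, 1, 1))
        out = geo.expand_margin(mask, (8.0, 5.0, 5.0))
        assert out.values[18, 10, 10] and not out.values[19, 10, 10]
        assert out.values[10, 15, 10] and not out.values[10, 16, 10]


class TestSurfaceAndVolume:
    def test_digitized_sphere(self):
        mask = sphere_mask(20.0, 1.0)
        area, volume = geo.surface_and_volume(mask)
        assert volume == pytest.approx(4 / 3 * math.pi * 8.0, rel=0.01)
        assert area == pytest.approx(4 * math.pi * 4.0, rel=0.03)

    def test_aligned_cube_volume_exact(self):
        values = np.zeros((16, 16, 16), dtype=bool)
        values[3:13, 3:13, 3:13] = True  # 10 mm cube on a 1 mm grid
        mask = StructureMask(values, spacing=(1, 1, 1))
        _, volume = geo.surface_and_volume(mask)
        assert volume == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_spheres_additive(self):
        single = sphere_mask(8.0, 1.0)
        a1, v1 = geo.surface_and_volume(single)
        values = np.zeros((25, 25, 60), dtype=bool)
        ax = np.arange(25) - 12.0
        Z, Y, X = np.meshgrid(ax, ax, np.arange(60, dtype=float), indexing="ij")
        values |= Z ** 2 + Y ** 2 + (X - 12) ** 2 <= 64.0
        values |= Z ** 2 + Y ** 2 + (X - 46) ** 2 <= 64.0
        pair = StructureMask(values, spacing=(1, 1, 1))
        a2, v2 = geo.surface_and_volume(pair)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)
        assert a2 == pytest.approx(2 * a1, rel=0.01)

    def test_empty_mask_raises(self):
        mask = StructureMask(np.zeros((3, 3, 3), bool), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            geo.surface_and_volume(mask)


class TestSphericity:
    def test_exact_sphere_is_one(self):
        for r in (1.0, 10.0, 87.3):
            area = 4 * math.pi * r ** 2
            volume = 4 / 3 * math.pi * r ** 3
            assert geo.sphericity(area, volume) == pytest.approx(1.0, abs=1e-12)

    def test_unit_cube_closed_form(self):
        assert geo.sphericity(6.0, 1.0) == pytest.approx((math.pi / 6) ** (1 / 3), abs=1e-12)

    def test_inverse_linear_in_area(self):
        assert geo.sphericity(3.0, 1.0) == pytest.approx(2 * geo.sphericity(6.0, 1.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            geo.sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            geo.sphericity(1.0, -1.0)


class TestSphericityLike:
    v20 = 4 / 3 * math.pi * 20.0 ** 3 / 1000  # cm^3
    v25 = 4 / 3 * math.pi * 25.0 ** 3 / 1000

    def test_concentric_spheres_exceed_one(self):
        psi = geo.sphericity_like(self.v20, self.v25, 5.0)
        assert psi == pytest.approx(1.0203, abs=2e-4)
        assert psi > 1.0

    def test_thin_shell_limit_approaches_one(self):
        d = 0.1
        v_out = 4 / 3 * math.pi * 20.1 ** 3 / 1000
        assert abs(geo.sphericity_like(self.v20, v_out, d) - 1.0) < 1e-3

    def test_linear_in_margin(self):
        one = geo.sphericity_like(self.v20, self.v25, 5.0)
        two = geo.sphericity_like(self.v20, self.v25, 10.0)
        assert two == pytest.approx(2 * one)

    def test_degenerate_shell_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            geo.sphericity_like(self.v25, self.v20, 5.0)


class TestMinDistance:
    def test_separated_spheres(self):
        values = np.zeros((25, 25, 60), dtype=bool)
        ax = np.arange(25) - 12.0
        Z, Y, X = np.meshgrid(ax, ax, np.arange(60, dtype=float), indexing="ij")
        a = StructureMask(Z ** 2 + Y ** 2 + (X - 12) ** 2 <= 100.0, spacing=(1, 1, 1))
        b = StructureMask(Z ** 2 + Y ** 2 + (X - 42) ** 2 <= 100.0, spacing=(1, 1, 1))
        d = geo.min_distance(a, b)
        assert d == pytest.approx(10.0, abs=math.sqrt(3))

    def test_overlap_gives_zero(self, small_sphere):
        assert geo.min_distance(small_sphere, small_sphere) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (8, 9, 10)
        spacing = (2.0, 1.0, 1.5)
        a = rng.random(shape) < 0.08
        b = rng.random(shape) < 0.08
        if not (a.any() and b.any()):
            pytest.skip("degenerate draw")
        ma = StructureMask(a, spacing=spacing)
        mb = StructureMask(b, spacing=spacing)
        pa = np.argwhere(a) * spacing
        pb = np.argwhere(b) * spacing
        brute = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1))
        assert geo.min_distance(ma, mb) == pytest.approx(brute, abs=1e-9)
        assert geo.min_distance(mb, ma) == pytest.approx(brute, abs=1e-9)

    def test_per_slice_at_least_3d(self):
        rng = np.random.default_rng(3)
        a = StructureMask(rng.random((6, 8, 8)) < 0.15, spacing=(2, 1, 1))
        b = StructureMask(rng.random((6, 8, 8)) < 0.15, spacing=(2, 1, 1))
        assert geo.min_distance(a, b, per_slice=True) >= geo.min_distance(a, b)

    def test_empty_mask_raises(self, small_sphere):
        empty = StructureMask(np.zeros_like(small_sphere.values),
                              spacing=small_sphere.spacing, origin=small_sphere.origin)
        with pytest.raises(ValueError):
            geo.min_distance(small_sphere, empty)


class TestIsocentreDisplacement:
    @pytest.mark.parametrize("ml,ap,expected", [(0, 0, 0), (3, 4, 5), (-3, 4, 5), (3, -4, 5)])
    def test_pythagorean(self, ml, ap, expected):
        assert geo.isocentre_displacement(ml, ap) == pytest.approx(expected)


class TestOverlap:
    def test_identical_masks(self, small_sphere):
        cm3, pct = geo.overlap(small_sphere, small_sphere)
        assert cm3 == pytest.approx(small_sphere.volume_cm3)
        assert pct == pytest.approx(100.0)

    def test_disjoint_masks(self, small_sphere):
        other = StructureMask(np.zeros_like(small_sphere.values),
                              spacing=small_sphere.spacing, origin=small_sphere.origin)
        other.values[0, 0, 0] = True
        cm3, pct = geo.overlap(small_sphere, other)
        assert cm3 == 0.0 and pct == 0.0

    def test_half_embedded_cube(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        a[2:8, 2:8, 2:8] = True
        b = np.zeros_like(a)
        b[2:8, 2:8, 5:] = True  # right half of the cube (and beyond)
        cm3, pct = geo.overlap(StructureMask(a, spacing=(1, 1, 1)),
                               StructureMask(b, spacing=(1, 1, 1)))
        assert pct == pytest.approx(50.0, abs=100 / 6)  # within one voxel layer
        assert cm3 == pytest.approx(6 * 6 * 3 / 1000)


class TestSphericityConvergence:
    def test_monotone_convergence_to_one(self):
        """Mask-derived sphericity error shrinks monotonically with refinement."""
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            mask = sphere_mask(20.0, spacing)
            area, volume = geo.surface_and_volume(mask)
            errors.append(abs(geo.sphericity(area, volume) - 1.0))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.03
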