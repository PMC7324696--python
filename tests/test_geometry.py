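"""Geometry operations against closed-form solids and brute-force oracles."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from spacerselect.geometry import (
    ContourSlice,
    ContourStack,
    InvalidStructureError,
    MarginSpec,
    StructureRecipeConfig,
    expand_margin,
    height_limit,
    make_wall,
    mean_slice_hausdorff,
    overlap_volume,
    slice_geometry,
    slice_hausdorff,
    volume,
)

from conftest import (
    box_stack,
    circle,
    cylinder_stack,
    sphere_stack,
    sphere_volume_cc,
    square,
)


class TestContourStack:
    def test_rejects_nonuniform_z(self):
        slices = [(0.0, [circle(0, 0, 5)]), (2.0, [circle(0, 0, 5)]),
                  (5.0, [circle(0, 0, 5)])]
        with pytest.raises(InvalidStructureError):
            ContourStack("bad", slices, 2.0)

    def test_rejects_degenerate_polygon(self):
        with pytest.raises(InvalidStructureError):
            ContourStack("bad", [(0.0, [np.array([[0, 0], [1, 1]])])], 1.0)

    def test_rejects_self_intersecting_polygon(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(InvalidStructureError):
            ContourStack("bad", [(0.0, [bowtie])], 1.0)

    def test_explicit_closure_normalized(self):
        sq = square(0, 0, 5)
        closed = np.vstack([sq, sq[:1]])
        s = ContourStack("sq", [(0.0, [closed])], 1.0)
        assert len(s.slices[0].polygons[0]) == 4


class TestVolume:
    def test_unit_cube(self):
        assert volume(box_stack(10.0, 10.0, spacing=1.0)) == pytest.approx(1.0)

    def test_empty_stack(self):
        assert volume(ContourStack("empty", [], 1.0)) == 0.0

    def test_sphere_against_closed_form(self):
        # cohort-mean-scale rectum volume (~79.7 cc at r = 26.7 mm)
        r = 26.7
        v = volume(sphere_stack(r, spacing=2.0))
        assert v == pytest.approx(sphere_volume_cc(r), rel=0.02)

    def test_holes_subtracted(self):
        annulus = ContourStack(
            "ring", [(0.5, [circle(0, 0, 20), circle(0, 0, 10)])], 1.0
        )
        assert volume(annulus) == pytest.approx(math.pi * (400 - 100) / 1000, rel=0.01)

    def test_raster_refinement_reduces_error(self):
        # volume here is vector (shoelace), so check the raster-dependent op:
        # margin expansion error decreases as the raster is refined
        truth = sphere_volume_cc(27.0)
        errs = []
        for res in (2.0, 1.0, 0.5):
            cfg = StructureRecipeConfig(raster_resolution=res)
            v = volume(expand_margin(sphere_stack(20.0, spacing=2.0),
                                     MarginSpec(7, 7, 7, 7, 7, 7), cfg))
            errs.append(abs(v - truth) / truth)
        assert errs[2] < errs[0]
        assert errs[1] < 0.03


class TestExpandMargin:
    def test_isotropic_sphere_margin(self):
        ptv = expand_margin(sphere_stack(20.0, spacing=2.0),
                            MarginSpec(7, 7, 7, 7, 7, 7))
        assert volume(ptv) == pytest.approx(sphere_volume_cc(27.0), rel=0.02)

    def test_zero_margin_is_identity(self):
        s = sphere_stack(20.0, spacing=2.0)
        out = expand_margin(s, MarginSpec(0, 0, 0, 0, 0, 0))
        assert volume(out) == pytest.approx(volume(s), rel=0.02)
        assert out.z_positions.min() == pytest.approx(s.z_positions.min())
        assert out.z_positions.max() == pytest.approx(s.z_positions.max())

    def test_superset_of_input(self):
        s = sphere_stack(20.0, spacing=2.0)
        out = expand_margin(s, MarginSpec())
        tol = StructureRecipeConfig().raster_resolution
        for sl in s.slices:
            osl = out.slice_at(sl.z)
            assert osl is not None
            g_in = slice_geometry(sl.polygons)
            g_out = slice_geometry(osl.polygons)
            # input contained in output up to raster tolerance
            assert g_in.difference(g_out.buffer(tol)).area < 1e-6

    def test_anisotropic_posterior_margin(self):
        # posterior (+y) 5 mm, all else 7 mm: bounding box grows accordingly
        s = sphere_stack(20.0, spacing=2.0)
        out = expand_margin(s, MarginSpec(anterior=7, posterior=5, left=7,
                                          right=7, superior=7, inferior=7))
        (_, ymin_in, _), (_, ymax_in, _) = s.bounding_box()
        (_, ymin_out, _), (_, ymax_out, _) = out.bounding_box()
        assert ymax_out - ymax_in == pytest.approx(5.0, abs=0.75)
        assert ymin_in - ymin_out == pytest.approx(7.0, abs=0.75)

    def test_empty_input_raises(self):
        with pytest.raises(InvalidStructureError):
            expand_margin(ContourStack("empty", [], 2.0), MarginSpec())


class TestMakeWall:
    def test_spherical_shell_volume(self):
        wall = make_wall(sphere_stack(20.0, spacing=1.0))
        truth = sphere_volume_cc(20.0) - sphere_volume_cc(17.0)
        assert volume(wall) == pytest.approx(truth, rel=0.03)

    def test_wall_is_subset_with_smaller_volume(self):
        organ = cylinder_stack(15.0, 100.0, spacing=2.0)
        wall = make_wall(organ)
        assert volume(wall) < volume(organ)
        for sl in wall.slices:
            osl = organ.slice_at(sl.z)
            g_w, g_o = slice_geometry(sl.polygons), slice_geometry(osl.polygons)
            assert g_w.difference(g_o.buffer(1e-6)).area < 1e-9

    def test_cylinder_annulus_area(self):
        wall = make_wall(cylinder_stack(15.0, 100.0, spacing=2.0))
        mid = wall.slice_at(50.0, tol=1.1)
        area = slice_geometry(mid.polygons).area
        assert area == pytest.approx(math.pi * (15**2 - 12**2), rel=0.03)

    def test_zero_thickness_gives_empty_wall(self):
        wall = make_wall(sphere_stack(20.0), StructureRecipeConfig(wall_thickness=0.0))
        assert wall.is_empty

    def test_thin_slice_keeps_whole_polygon(self):
        thin = cylinder_stack(2.0, 10.0, spacing=2.0)  # radius < thickness
        wall = make_wall(thin)
        assert volume(wall) == pytest.approx(volume(thin), rel=0.01)


class TestHeightLimit:
    def test_interval_arithmetic(self):
        wall = cylinder_stack(15.0, 200.0, spacing=2.5, z0=-1.25)
        ptv = cylinder_stack(20.0, 40.0, spacing=2.5, z0=78.75)
        out = height_limit(wall, ptv)
        assert out.z_positions.min() >= 80.0 - 17.5 - 1e-9
        assert out.z_positions.max() <= 120.0 + 17.5 + 1e-9
        # retained slices are unchanged
        for sl in out.slices:
            src = wall.slice_at(sl.z)
            assert all(
                np.allclose(a, b) for a, b in zip(sl.polygons, src.polygons)
            )

    def test_noop_when_ptv_covers_wall(self):
        wall = cylinder_stack(15.0, 40.0, spacing=2.0)
        ptv = cylinder_stack(20.0, 100.0, spacing=2.0, z0=-30.0)
        out = height_limit(wall, ptv)
        assert len(out.slices) == len(wall.slices)

    def test_zero_extent_spans_ptv_range(self):
        wall = cylinder_stack(15.0, 100.0, spacing=2.0)
        ptv = cylinder_stack(20.0, 20.0, spacing=2.0, z0=40.0)
        out = height_limit(wall, ptv, StructureRecipeConfig(height_limit_extent=0.0))
        assert out.z_positions.min() >= ptv.z_positions.min() - 1e-9
        assert out.z_positions.max() <= ptv.z_positions.max() + 1e-9

    def test_idempotent(self):
        wall = cylinder_stack(15.0, 200.0, spacing=2.0)
        ptv = cylinder_stack(20.0, 40.0, spacing=2.0, z0=80.0)
        once = height_limit(wall, ptv)
        twice = height_limit(once, ptv)
        assert np.allclose(once.z_positions, twice.z_positions)

    def test_disjoint_ranges_empty(self):
        wall = cylinder_stack(15.0, 20.0, spacing=2.0, z0=0.0)
        ptv = cylinder_stack(20.0, 20.0, spacing=2.0, z0=100.0)
        out = height_limit(wall, ptv)
        assert len(out.slices) == 0


class TestOverlapVolume:
    def test_sphere_lens_closed_form(self):
        a = sphere_stack(20.0, spacing=2.0)
        b = sphere_stack(20.0, spacing=2.0, center=(30.0, 0.0, 0.0))
        r, d = 20.0, 30.0
        lens = math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12 / 1000
        assert overlap_volume(a, b) == pytest.approx(lens, rel=0.03)

    def test_commutative(self):
        a = sphere_stack(20.0, spacing=2.0)
        b = sphere_stack(15.0, spacing=2.0, center=(10.0, 5.0, 2.0))
        assert overlap_volume(a, b) == pytest.approx(overlap_volume(b, a), rel=1e-9)

    def test_self_overlap_is_volume(self):
        a = sphere_stack(20.0, spacing=2.0)
        assert overlap_volume(a, a) == pytest.approx(volume(a), rel=1e-9)

    def test_containment(self):
        small = sphere_stack(10.0, spacing=2.0)
        big = sphere_stack(25.0, spacing=2.0)
        assert overlap_volume(small, big) == pytest.approx(volume(small), rel=1e-6)

    def test_disjoint_is_zero(self):
        a = sphere_stack(10.0, spacing=2.0)
        b = sphere_stack(10.0, spacing=2.0, center=(50.0, 0.0, 0.0))
        assert overlap_volume(a, b) == 0.0


def brute_force_hausdorff_cm(p, q, step=0.1):
    """Independent oracle: max-min over densely sampled boundary points."""
    def sample(poly):
        ring = Polygon(poly).exterior
        n = max(int(ring.length / step), 8)
        return np.array([ring.interpolate(i / n, normalized=True).coords[0]
                         for i in range(n)])

    pa, pb = sample(p), sample(q)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
    d_ab = np.sqrt(d2.min(axis=1)).max()
    d_ba = np.sqrt(d2.min(axis=0)).max()
    return max(d_ab, d_ba) / 10.0


class TestSliceHausdorff:
    def test_concentric_circles(self):
        assert slice_hausdorff(circle(0, 0, 10), circle(0, 0, 25)) == pytest.approx(
            1.5, abs=0.01
        )

    def test_identical_polygons(self):
        sq = square(0, 0, 5)
        assert slice_hausdorff(sq, sq) == pytest.approx(0.0, abs=1e-12)

    def test_offset_unit_squares(self):
        a = square(0, 0, 5)
        b = square(3, 4, 5)
        expected = brute_force_hausdorff_cm(a, b, step=0.1)
        assert slice_hausdorff(a, b) == pytest.approx(0.5, abs=0.02)
        assert slice_hausdorff(a, b) == pytest.approx(expected, abs=0.02)

    def test_degenerate_raises(self):
        with pytest.raises(InvalidStructureError):
            slice_hausdorff(np.array([[0, 0], [1, 0], [2, 0]]), square(0, 0, 5))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = _random_convexish(rng)
            b = _random_convexish(rng)
            ours = slice_hausdorff(a, b)
            oracle = brute_force_hausdorff_cm(a, b, step=0.1)
            assert ours == pytest.approx(oracle, abs=0.02)  # 0.2 mm

    def test_directed_is_asymmetric(self):
        small, big = circle(0, 0, 5), circle(0, 0, 20)
        d_sb = slice_hausdorff(small, big, directed=True)
        d_bs = slice_hausdorff(big, small, directed=True)
        assert d_sb == pytest.approx(1.5, abs=0.01)
        assert d_bs == pytest.approx(1.5, abs=0.01)
        sq_in = square(10, 0, 2)
        assert slice_hausdorff(sq_in, big, directed=True) < slice_hausdorff(
            big, sq_in, directed=True
        )


def _random_convexish(rng):
    n = rng.integers(6, 16)
    th = np.sort(rng.uniform(0, 2 * math.pi, n))
    r = rng.uniform(5, 25, n)
    c = rng.uniform(-10, 10, 2)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])


class TestMeanSliceHausdorff:
    def test_parallel_cylinders_constant(self):
        # equal radii: the curve Hausdorff per slice equals the axis gap,
        # constant over all shared slices, so the mean equals it too
        a = cylinder_stack(10.0, 20.0, spacing=2.0)
        b = cylinder_stack(10.0, 20.0, spacing=2.0, center_xy=(31.8, 0.0))
        per_slice = slice_hausdorff(circle(0, 0, 10), circle(31.8, 0, 10))
        got = mean_slice_hausdorff(a, b)
        assert got == pytest.approx(per_slice, abs=0.005)
        assert got == pytest.approx(3.18, abs=0.01)  # axis gap in cm

    def test_single_shared_slice(self):
        a = cylinder_stack(10.0, 2.0, spacing=2.0)
        b = cylinder_stack(12.0, 20.0, spacing=2.0, z0=-10.0)
        expected = slice_hausdorff(a.slices[0].polygons[0], circle(0, 0, 12))
        assert mean_slice_hausdorff(a, b) == pytest.approx(expected, abs=0.005)

    def test_identical_stacks_zero(self):
        a = cylinder_stack(10.0, 20.0, spacing=2.0)
        assert mean_slice_hausdorff(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_no_common_slices_raises(self):
        a = cylinder_stack(10.0, 10.0, spacing=2.0, z0=0.0)
        b = cylinder_stack(10.0, 10.0, spacing=2.0, z0=100.0)
        with pytest.raises(InvalidStructureError):
            mean_slice_hausdorff(a, b)
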