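"""Peripheral band, sampling windows, displacement and translocation."""

import numpy as np
import pytest
import shapely

from conftest import circle_contour, circle_with_exact_perimeter
from fretrack.errors import ConfigError, GeometryError
from fretrack.levelset import CorrespondenceMap, signed_distance
from fretrack.sampling import (
    build_band,
    integrate_translocation,
    map_interval_edges,
    partition_windows,
    sample_ratio,
    window_displacement,
    windows_from_intervals,
)

GRID = dict(shape=(160, 160), grid_spacing=0.5)


def _circle_with_field(radius=20.0, n=800):
    c = circle_contour(radius, n=n)
    return c, signed_distance(c, **GRID)


# -- band ------------------------------------------------------------------

def test_band_area_matches_annulus():
    c, f = _circle_with_field(radius=20.0)
    band = build_band(c, f, depth=2.0)
    area = band.sum() * 0.5**2
    expected = np.pi * (20.0**2 - 18.0**2)
    assert abs(area - expected) / expected < 0.10


def test_band_rejects_nonpositive_depth():
    c, f = _circle_with_field()
    with pytest.raises(ConfigError):
        build_band(c, f, depth=0.0)


def test_band_pixels_are_inside_and_near_the_edge():
    c, f = _circle_with_field(radius=15.0)
    depth = 1.5
    band = build_band(c, f, depth=depth)
    ring = shapely.linearrings(np.vstack([c.points, c.points[:1]]))
    poly = shapely.polygons(ring)
    iy, ix = np.nonzero(band)
    pts = shapely.points(np.column_stack([ix * 0.5, iy * 0.5]))
    assert shapely.contains(poly, pts).all()
    assert (shapely.distance(ring, pts) <= depth + 1e-9).all()


# -- windows ---------------------------------------------------------------

def test_circle_of_125um_circumference_gives_100_windows():
    c = circle_with_exact_perimeter(125.0)
    f = signed_distance(c, **GRID)
    band = build_band(c, f, depth=1.0)
    windows = partition_windows(c, band, width=1.25, grid_spacing=0.5)
    assert len(windows) == 100
    widths = np.array([w.arc_width for w in windows])
    np.testing.assert_allclose(widths, 1.25, rtol=1e-9)


def test_floor_rule_for_window_count():
    c = circle_with_exact_perimeter(10.0, n=400)
    f = signed_distance(c, **GRID)
    band = build_band(c, f, depth=0.5)
    windows = partition_windows(c, band, width=3.0, grid_spacing=0.5, min_windows=3)
    assert len(windows) == 3
    assert windows[0].arc_width == pytest.approx(10.0 / 3)


def test_too_few_windows_is_a_geometry_error():
    c = circle_with_exact_perimeter(10.0, n=400)
    f = signed_distance(c, **GRID)
    band = build_band(c, f, depth=0.5)
    with pytest.raises(GeometryError):
        partition_windows(c, band, width=3.0, grid_spacing=0.5)  # only 3 < 8 fit


def test_windows_partition_the_band_exactly():
    rng = np.random.default_rng(5)
    th = np.sort(rng.uniform(0, 2 * np.pi, 48))
    r = rng.uniform(14, 20, 48)
    from fretrack.boundary import Contour

    c = Contour(np.column_stack([40 + r * np.cos(th), 40 + r * np.sin(th)]))
    f = signed_distance(c, **GRID)
    band = build_band(c, f, depth=1.5)
    windows = partition_windows(c, band, width=2.0, grid_spacing=0.5)
    union = np.zeros_like(band)
    total = 0
    for w in windows:
        assert not (union & w.mask).any()  # pairwise disjoint
        union |= w.mask
        total += w.n_pixels
    assert (union == band).all()


# -- ratio sampling --------------------------------------------------------

def test_uniform_ratio_gives_uniform_window_means():
    c, f = _circle_with_field()
    band = build_band(c, f, depth=1.5)
    windows = partition_windows(c, band, width=2.0, grid_spacing=0.5)
    frame = np.full(f.shape, 1.7)
    vals = sample_ratio(windows, frame)
    np.testing.assert_allclose(vals, 1.7)


def test_sector_ratio_pattern_is_recovered():
    c, f = _circle_with_field()
    band = build_band(c, f, depth=1.5)
    windows = partition_windows(c, band, width=2.0, grid_spacing=0.5)
    yy, xx = np.indices(f.shape)
    ang = np.arctan2(yy * 0.5 - 40, xx * 0.5 - 40)
    frame = np.where(np.abs(ang) < 0.8, 0.8, 1.0)
    vals = sample_ratio(windows, frame)
    centroids = np.array([w.centroid for w in windows])
    cang = np.arctan2(centroids[:, 1] - 40, centroids[:, 0] - 40)
    in_sector = np.abs(cang) < 0.6
    out_sector = np.abs(cang) > 1.0
    assert np.nanmax(np.abs(vals[in_sector] - 0.8)) < 0.05
    assert np.nanmax(np.abs(vals[out_sector] - 1.0)) < 0.05


def test_fully_invalid_window_is_missing_not_zero():
    c, f = _circle_with_field()
    band = build_band(c, f, depth=1.5)
    windows = partition_windows(c, band, width=2.0, grid_spacing=0.5)
    frame = np.full(f.shape, 2.0)
    valid = np.ones(f.shape, bool)
    valid[windows[3].mask] = False
    vals = sample_ratio(windows, frame, valid)
    assert np.isnan(vals[3])
    assert vals[0] == pytest.approx(2.0)


# -- window displacement ---------------------------------------------------

def _radial_corr(contour, dr):
    """Correspondence of a uniformly expanding circle (outward by dr)."""
    n = 200
    src = np.arange(n) / n
    pts = contour.point_at(src)
    radial = (pts - 40) / np.hypot(*(pts - 40).T)[:, None]
    return CorrespondenceMap(src, src.copy(), dr * radial, source_points=pts)


def test_uniform_expansion_gives_uniform_positive_displacement():
    c = circle_contour(20.0, n=800)
    edges = np.arange(25) / 25
    d, flagged = window_displacement(edges, _radial_corr(c, 2.0), c)
    assert not flagged.any()
    np.testing.assert_allclose(d, 2.0, atol=0.01)


def test_static_boundary_gives_zero_displacement():
    c = circle_contour(20.0, n=800)
    edges = np.arange(25) / 25
    d, _ = window_displacement(edges, _radial_corr(c, 0.0), c)
    np.testing.assert_allclose(d, 0.0, atol=1e-9)


def test_sector_advance_is_localized():
    c = circle_contour(20.0, n=800)
    n = 200
    src = np.arange(n) / n
    pts = c.point_at(src)
    radial = (pts - 40) / np.hypot(*(pts - 40).T)[:, None]
    amp = np.where((src > 0.2) & (src < 0.4), 3.0, 0.0)
    corr = CorrespondenceMap(src, src.copy(), amp[:, None] * radial, source_points=pts)
    edges = np.arange(20) / 20
    d, _ = window_displacement(edges, corr, c)
    mids = edges + 0.025
    inside = (mids > 0.23) & (mids < 0.37)
    outside = (mids < 0.15) | (mids > 0.45)
    assert np.all(d[inside] > 2.5)
    assert np.all(np.abs(d[outside]) < 0.5)


def test_retraction_is_negative():
    c = circle_contour(20.0, n=800)
    edges = np.arange(25) / 25
    d, _ = window_displacement(edges, _radial_corr(c, -1.5), c)
    np.testing.assert_allclose(d, -1.5, atol=0.01)


# -- translocation ---------------------------------------------------------

def test_constant_displacement_integrates_linearly():
    disp = np.ones((3, 4))  # 5 frames, release at 0
    b = integrate_translocation(disp, 0).values
    np.testing.assert_allclose(b, np.tile([0, 1, 2, 3, 4], (3, 1)))


def test_zero_displacement_integrates_to_zero():
    b = integrate_translocation(np.zeros((4, 6)), 3).values
    assert (b == 0).all()


def test_translocation_matches_prefix_sum_oracle():
    rng = np.random.default_rng(11)
    disp = rng.normal(0, 1, (6, 9))  # 10 frames
    release = 4
    b = integrate_translocation(disp, release).values
    for w in range(6):
        for t in range(10):
            if t >= release:
                expected = disp[w, release:t].sum()
            else:
                expected = -disp[w, t:release].sum()
            assert b[w, t] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(b[:, release], 0.0)


def test_translocation_is_additive_over_frame_ranges():
    rng = np.random.default_rng(2)
    disp = rng.normal(0, 1, (3, 8))
    b = integrate_translocation(disp, 0).values
    k = 4
    partial = integrate_translocation(disp[:, :k], 0).values
    rest = integrate_translocation(disp[:, k:], 0).values
    np.testing.assert_allclose(b[:, k:], partial[:, -1:] + rest)


def test_interval_edges_propagate_through_correspondence():
    src = np.arange(100) / 100
    tgt = (src + 0.1) % 1.0  # rigid circular shift
    corr = CorrespondenceMap(src, tgt, np.zeros((100, 2)))
    edges = np.arange(10) / 10
    mapped = map_interval_edges(edges, corr)
    np.testing.assert_allclose((mapped - edges) % 1.0, 0.1, atol=1e-6)
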