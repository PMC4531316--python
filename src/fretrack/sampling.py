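"""Peripheral band construction, sampling windows, and translocation.

Ratio signal and edge motion are quantified in small windows tiling a thin
band just inside the cell edge: the band is the set of pixels whose signed
distance lies in [-depth, 0) (default depth 0.5 um), and it is divided
into windows of fixed arc width (default 1.25 um) along the boundary.
Window displacement is the mean of the correspondence displacement vectors
falling inside the window's arc interval, projected on the outward normal
(protrusion positive).  Displacements are integrated over time from the
release frame to give the boundary *translocation* B(w, t): the location
change of each edge window since the moment the constraint was removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .boundary import Contour
from .errors import ConfigError, GeometryError
from .levelset import CorrespondenceMap, LevelSetField
from .stmap import SpatioTemporalMap

__all__ = [
    "SamplingWindow",
    "WindowTimeCourse",
    "build_band",
    "partition_windows",
    "windows_from_intervals",
    "sample_ratio",
    "window_displacement",
    "map_interval_edges",
    "integrate_translocation",
]


@dataclass
class SamplingWindow:
    """One sampling window: an arc interval of the peripheral band.

    ``mask`` is a boolean image selecting the band pixels whose nearest
    boundary point falls inside [arc_start, arc_end) (arc positions in
    micrometers along the contour).
    """

    window_index: int
    arc_start: float
    arc_end: float
    mask: np.ndarray
    centroid: tuple[float, float]

    @property
    def arc_width(self) -> float:
        return self.arc_end - self.arc_start

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class WindowTimeCourse:
    """Per-window time series of ratio, displacement and translocation."""

    ratio_series: np.ndarray         # (T,) dimensionless, NaN = missing
    displacement_series: np.ndarray  # (T-1,) um per frame pair
    translocation_series: np.ndarray  # (T,) um, 0 at release


def build_band(contour: Contour, field: LevelSetField, depth: float) -> np.ndarray:
    """Boolean mask of pixels inside the cell within ``depth`` of the edge.

    Selects grid points with ``-depth <= phi < 0`` — the distance-map band
    hugging the boundary from the inside.
    """
    if depth <= 0:
        raise ConfigError("band depth must be positive")
    band = (field.phi >= -depth) & (field.phi < 0)
    if not band.any():
        raise GeometryError("peripheral band is empty")
    return band


def _pixel_arc_params(contour: Contour, band: np.ndarray, grid_spacing: float) -> np.ndarray:
    """Arc parameter of the nearest boundary point for each band pixel."""
    iy, ix = np.nonzero(band)
    pix = np.column_stack([ix, iy]) * grid_spacing
    fine_n = max(64, int(np.ceil(contour.perimeter / (0.1 * grid_spacing))))
    fine_n = min(fine_n, 200_000)
    params = np.arange(fine_n) / fine_n
    tree = cKDTree(contour.point_at(params))
    _, nearest = tree.query(pix, workers=-1)
    return params[nearest]


def windows_from_intervals(
    contour: Contour,
    band: np.ndarray,
    interval_edges: np.ndarray,
    grid_spacing: float,
) -> list[SamplingWindow]:
    """Build windows from explicit arc-interval edges (normalized params).

    ``interval_edges`` are n circularly increasing parameters in [0, 1);
    window i spans [edges[i], edges[i+1]) with wrap-around for the last.
    Every band pixel is assigned to exactly one window.
    """
    edges = np.asarray(interval_edges, float) % 1.0
    n = len(edges)
    pix_params = _pixel_arc_params(contour, band, grid_spacing)
    # rotate so edges[0] is the origin, then bin
    rel = (pix_params - edges[0]) % 1.0
    rel_edges = (edges - edges[0]) % 1.0
    rel_edges[0] = 0.0
    order = np.argsort(rel_edges)
    bins = np.searchsorted(rel_edges[order], rel, side="right") - 1
    win_of_pixel = order[np.clip(bins, 0, n - 1)]

    iy, ix = np.nonzero(band)
    perim = contour.perimeter
    windows = []
    for w in range(n):
        mask = np.zeros_like(band)
        sel = win_of_pixel == w
        mask[iy[sel], ix[sel]] = True
        start = edges[w]
        end = edges[(w + 1) % n]
        width = (end - start) % 1.0
        if width == 0.0:
            width = 1.0 / n
        if sel.any():
            centroid = (float(np.mean(ix[sel]) * grid_spacing), float(np.mean(iy[sel]) * grid_spacing))
        else:
            mid = (start + width / 2) % 1.0
            centroid = tuple(contour.point_at(mid)[0])
        windows.append(
            SamplingWindow(
                window_index=w,
                arc_start=start * perim,
                arc_end=(start + width) * perim,
                mask=mask,
                centroid=centroid,
            )
        )
    return windows


def partition_windows(
    contour: Contour,
    band: np.ndarray,
    width: float,
    *,
    grid_spacing: float = 0.5,
    min_windows: int = 8,
) -> list[SamplingWindow]:
    """Divide the band into ``floor(perimeter / width)`` equal arc windows."""
    if width <= 0:
        raise ConfigError("window width must be positive")
    if not band.any():
        raise GeometryError("band is empty")
    n = int(np.floor(contour.perimeter / width))
    if n < min_windows:
        raise GeometryError(f"only {n} windows fit — cell too small for windowing")
    edges = np.arange(n) / n
    return windows_from_intervals(contour, band, edges, grid_spacing)


def sample_ratio(
    windows: list[SamplingWindow],
    ratio_frame: np.ndarray,
    valid_mask: np.ndarray | None = None,
    *,
    min_valid_pixels: int = 3,
) -> np.ndarray:
    """Mean ratio inside each window over valid pixels.

    Windows with fewer than ``min_valid_pixels`` valid pixels are reported
    as NaN (missing), never as zero.
    """
    if valid_mask is None:
        valid_mask = np.isfinite(ratio_frame)
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        sel = w.mask & valid_mask
        if sel.sum() >= min_valid_pixels:
            out[i] = float(np.nanmean(ratio_frame[sel]))
    return out


def window_displacement(
    interval_edges: np.ndarray,
    corr: CorrespondenceMap,
    contour: Contour,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window normal displacement from correspondence vectors.

    For each arc interval on Gamma(t), the displacement vectors of the
    reference points whose source parameter lies inside the interval are
    averaged and projected on the window's outward normal (protrusion
    positive, retraction negative).  Windows containing no reference point
    are filled by circular linear interpolation from their neighbors and
    flagged.

    Returns ``(displacements_um, interpolated_flags)``.
    """
    edges = np.asarray(interval_edges, float) % 1.0
    n = len(edges)
    widths = (np.roll(edges, -1) - edges) % 1.0
    widths[widths == 0.0] = 1.0 / n
    mids = (edges + widths / 2) % 1.0
    normals = contour.normal_at(mids)

    src = corr.source_indices % 1.0
    rel = (src - edges[0]) % 1.0
    rel_edges = (edges - edges[0]) % 1.0
    rel_edges[0] = 0.0
    order = np.argsort(rel_edges)
    bins = np.searchsorted(rel_edges[order], rel, side="right") - 1
    win_of_ref = order[np.clip(bins, 0, n - 1)]

    disp = np.full(n, np.nan)
    for w in range(n):
        sel = win_of_ref == w
        if sel.any():
            mean_vec = corr.displacement_vectors[sel].mean(axis=0)
            disp[w] = float(mean_vec @ normals[w])
    interpolated = ~np.isfinite(disp)
    if interpolated.any():
        if interpolated.all():
            raise GeometryError("no window contains any reference point")
        idx = np.arange(n, dtype=float)
        good = np.flatnonzero(~interpolated)
        x = np.concatenate([good - n, good, good + n]).astype(float)
        y = np.tile(disp[good], 3)
        disp[interpolated] = np.interp(idx[interpolated], x, y)
    return disp, interpolated


def map_interval_edges(edges: np.ndarray, corr: CorrespondenceMap) -> np.ndarray:
    """Propagate window-interval edges through a correspondence map.

    Each edge parameter on Gamma(t) is mapped to its target parameter on
    Gamma(t+1) by circular interpolation of the correspondence, preserving
    window (material) identity across frames.  Widths drift slightly and
    are deliberately not re-equalized.
    """
    src = np.asarray(corr.source_indices, float)
    tgt = np.asarray(corr.target_indices, float)
    order = np.argsort(src)
    s = src[order]
    # lift targets so they increase monotonically along the sorted sources
    d = np.diff(tgt[order])
    d = (d + 0.5) % 1.0 - 0.5
    t_lift = tgt[order][0] + np.concatenate([[0.0], np.cumsum(np.maximum(d, 0.0))])
    xs = np.concatenate([s - 1.0, s, s + 1.0])
    ys = np.concatenate([t_lift - 1.0, t_lift, t_lift + 1.0])
    return np.interp(np.asarray(edges, float) % 1.0, xs, ys) % 1.0


def integrate_translocation(
    displacement_map: np.ndarray,
    release_index: int,
    *,
    arc_positions: np.ndarray | None = None,
    frame_times: np.ndarray | None = None,
) -> SpatioTemporalMap:
    """Cumulative translocation B(w, t) from per-frame-pair displacements.

    ``displacement_map`` has shape (windows, T-1), column j holding the
    displacement from frame j to j+1.  The translocation at frame t is the
    signed sum of displacements since the release frame, so B(:, release)
    is exactly zero and pre-release frames carry the negative backward
    partial sums.
    """
    d = np.asarray(displacement_map, float)
    n_w, n_pairs = d.shape
    n_frames = n_pairs + 1
    if not 0 <= release_index < n_frames:
        raise ConfigError("release_index out of range")
    b = np.zeros((n_w, n_frames))
    for t in range(release_index + 1, n_frames):
        b[:, t] = b[:, t - 1] + d[:, t - 1]
    for t in range(release_index - 1, -1, -1):
        b[:, t] = b[:, t + 1] - d[:, t]
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float) - release_index
    if arc_positions is None:
        arc_positions = np.arange(n_w, dtype=float)
    return SpatioTemporalMap(values=b, arc_positions=np.asarray(arc_positions, float),
                             frame_times=np.asarray(frame_times, float), kind="translocation")
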