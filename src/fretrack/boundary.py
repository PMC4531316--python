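"""Cell boundary detection and closed-contour geometry.

The cell outline in each frame is represented as a :class:`Contour`: an
ordered, closed, simple polyline with sub-pixel vertices in micrometers.
Contours are always stored with positive signed (shoelace) area, i.e.
counter-clockwise traversal in the numeric (x, y) coordinate frame with the
cell interior on the left of the direction of travel.  Points along the
contour are addressed by a normalized arc-length parameter in [0, 1), the
"spline index" used throughout the tracking and windowing stages.

Detection segments the fluorescence frame into ``k`` intensity layers by
1-D k-means (background, dim periphery, bright body), keeps the largest
connected non-background component and extracts its outer boundary with
marching squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage as ndi
from scipy.cluster.vq import kmeans2
from skimage import measure, morphology

from .errors import ConfigError, DetectionError, GeometryError

__all__ = ["Contour", "detect_boundary", "resample_contour"]


@dataclass
class Contour:
    """Closed cell-boundary polyline for one frame.

    Parameters
    ----------
    points : (n, 2) ndarray
        Vertex coordinates ``(x, y)`` in micrometers.  The closing edge from
        the last vertex back to the first is implicit.
    frame_index : int
        Index of the movie frame this contour belongs to.
    """

    points: np.ndarray
    frame_index: int = 0
    _cum: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise GeometryError("contour needs an (n>=3, 2) point array")
        # drop an explicit closing vertex if present
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts
        self._cum = None

    # -- basic geometry ----------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    def _closed(self) -> np.ndarray:
        return np.vstack([self.points, self.points[:1]])

    @property
    def cumlen(self) -> np.ndarray:
        """Cumulative arc length at each vertex plus the closing vertex."""
        if self._cum is None:
            seg = np.diff(self._closed(), axis=0)
            self._cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        return self._cum

    @property
    def perimeter(self) -> float:
        return float(self.cumlen[-1])

    @property
    def signed_area(self) -> float:
        p = self._closed()
        x, y = p[:, 0], p[:, 1]
        return float(0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    def ensure_positive_orientation(self) -> "Contour":
        """Return a contour with positive shoelace area (interior on the left)."""
        if self.signed_area < 0:
            return Contour(self.points[::-1].copy(), self.frame_index)
        return self

    @property
    def vertex_params(self) -> np.ndarray:
        """Normalized arc-length parameter in [0, 1) of each vertex."""
        return self.cumlen[:-1] / self.perimeter

    # -- parameterized access ----------------------------------------------

    def point_at(self, params) -> np.ndarray:
        """Interpolate boundary points at normalized arc parameters.

        ``params`` may be any array of values; they are wrapped into [0, 1).
        """
        s = (np.atleast_1d(np.asarray(params, float)) % 1.0) * self.perimeter
        cum = self.cumlen
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, self.n_points - 1)
        p = self._closed()
        seg = p[idx + 1] - p[idx]
        seglen = np.maximum(cum[idx + 1] - cum[idx], 1e-300)
        frac = (s - cum[idx]) / seglen
        return p[idx] + frac[:, None] * seg

    def normal_at(self, params) -> np.ndarray:
        """Outward unit normal at arc parameters (positive-orientation contour)."""
        params = np.atleast_1d(np.asarray(params, float))
        eps = 0.25 / max(self.perimeter, 1e-9)  # ~0.25 um smoothing window
        p_fwd = self.point_at(params + eps)
        p_bwd = self.point_at(params - eps)
        t = p_fwd - p_bwd
        t /= np.maximum(np.hypot(t[:, 0], t[:, 1]), 1e-300)[:, None]
        # interior on the left => outward normal is the right-hand rotation
        return np.column_stack([t[:, 1], -t[:, 0]])

    def nearest_param(self, points) -> np.ndarray:
        """Arc parameter of the boundary point nearest to each query point."""
        ring = shapely.linestrings(self._closed())
        pts = shapely.points(np.atleast_2d(np.asarray(points, float)))
        d = shapely.line_locate_point(ring, pts)
        return np.asarray(d, float) / self.perimeter % 1.0

    def is_simple(self) -> bool:
        return bool(shapely.is_simple(shapely.linearrings(self._closed())))

    def roll_to(self, origin_point) -> "Contour":
        """Re-anchor the parameter origin at the vertex nearest ``origin_point``."""
        d = np.hypot(*(self.points - np.asarray(origin_point, float)).T)
        i = int(np.argmin(d))
        return Contour(np.roll(self.points, -i, axis=0), self.frame_index)

    def roll_to_top(self) -> "Contour":
        """Anchor the origin at the topmost (min y), then leftmost vertex."""
        order = np.lexsort((self.points[:, 0], self.points[:, 1]))
        return Contour(np.roll(self.points, -int(order[0]), axis=0), self.frame_index)


def _kmeans_labels(values: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means with evenly spaced quantile initialization (deterministic)."""
    v = values.reshape(-1, 1).astype(float)
    init = np.quantile(v, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-cluster warnings on degenerate frames
        centroids, labels = kmeans2(v, init, minit="matrix", seed=seed)
    return centroids.ravel(), labels


def detect_boundary(
    intensity_frame: np.ndarray,
    k: int = 3,
    seed: int = 0,
    *,
    pixel_size: float = 1.0,
    min_area: int = 100,
    closing_radius: int = 1,
    frame_index: int = 0,
) -> Contour:
    """Detect the closed cell outline in a fluorescence frame.

    Pixels are clustered into ``k`` intensity layers; everything brighter
    than the darkest (background) layer forms the cell mask.  The mask is
    morphologically closed, hole-filled, reduced to its largest connected
    component and its outer boundary extracted at sub-pixel resolution.

    Returns a positively oriented :class:`Contour` in micrometers
    (``pixel_size`` micrometers per pixel, pixel centers on integer
    coordinates, x rightward, y downward).
    """
    frame = np.asarray(intensity_frame, float)
    if frame.ndim != 2:
        raise ConfigError("intensity frame must be 2-D")
    if k < 2:
        raise ConfigError("need k >= 2 intensity layers")

    centroids, labels = _kmeans_labels(frame, k, seed)
    background = int(np.argmin(centroids))
    # Foreground classes must clear the background centroid by 3 background
    # SDs *and* by 10% of the dynamic range: plain "brighter than the darkest
    # class" percolates through noise when k-means splits a unimodal
    # background into several levels, while a genuine dim-periphery layer
    # clears both margins comfortably.
    bg_values = frame.ravel()[labels == background]
    bg_sd = float(bg_values.std()) if bg_values.size else 0.0
    c_bg = centroids[background]
    margin = max(3.0 * bg_sd, 0.1 * (float(np.max(centroids)) - c_bg))
    foreground = np.flatnonzero(centroids > c_bg + margin)
    mask = np.isin(labels, foreground).reshape(frame.shape)
    if not mask.any():
        raise DetectionError("no pixel class brighter than the background layer")

    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    lab, n = ndi.label(mask)
    if n == 0:
        raise DetectionError("empty mask after morphology")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area:
        raise DetectionError(
            f"largest component has {int(sizes[biggest - 1])} px < min_area={min_area}"
        )
    mask = lab == biggest

    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DetectionError("no boundary found")
    longest = max(contours, key=len)
    rc = longest - 1.0  # undo padding
    pts = np.column_stack([rc[:, 1], rc[:, 0]]) * pixel_size  # (x, y) um
    c = Contour(pts, frame_index).ensure_positive_orientation()
    if c.n_points < 16:
        raise DetectionError("boundary too short (< 16 points)")
    return c


def resample_contour(contour: Contour, spacing: float) -> Contour:
    """Redistribute contour vertices at uniform arc-length spacing.

    The number of points is ``round(perimeter / spacing)`` (minimum 16); the
    parameter origin (first point) is preserved.
    """
    if spacing <= 0:
        raise ConfigError("spacing must be positive")
    perim = contour.perimeter
    if spacing > perim / 16:
        raise ConfigError(f"spacing {spacing} too coarse for perimeter {perim:.3g}")
    n = max(16, int(round(perim / spacing)))
    pts = contour.point_at(np.arange(n) / n)
    return Contour(pts, contour.frame_index)
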