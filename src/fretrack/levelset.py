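"""Level-set boundary evolution and point correspondence.

The boundary of the cell at time t, Gamma(t), is embedded as the zero level
of a signed-distance field phi(x, y) (negative inside the cell).  To
connect the outlines detected in two consecutive frames, phi is evolved
under the Hamilton-Jacobi equation

    d(phi)/dt + V |grad phi| = 0,

with normal speed ``V = -phi_next`` — the signed distance to the *target*
frame's boundary — so the front moves toward the target zero level and
stalls on it.  The intermediate zero-level contours produced along the way
let each reference point on Gamma(t) be chased by repeated nearest-point
projection onto the next intermediate, yielding a 1-D arc-length ("spline
index") correspondence between Gamma(t) and Gamma(t+1).

Raw matches can conflict geometrically (missing matches, crossing vector
pairs, vectors pointing against the local motion, worst at sharp corners);
:func:`correct_conflicts` repairs them deterministically by circular
interpolation, circular isotonic projection and neighbor-consistent
re-assignment, flagging every touched point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import isotonic_regression
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from skimage import measure

from .boundary import Contour, resample_contour
from .errors import GeometryError, TrackingError

__all__ = [
    "LevelSetField",
    "CorrespondenceMap",
    "signed_distance",
    "evolve",
    "correspond",
    "correct_conflicts",
]

FLAG_NORMAL = "normal"
FLAG_MISSING = "corrected-missing"
FLAG_CROSSING = "corrected-crossing"
FLAG_DIRECTION = "corrected-direction"


@dataclass
class LevelSetField:
    """Signed-distance embedding of a closed contour on a regular grid.

    ``phi[iy, ix]`` is the signed Euclidean distance (micrometers) from the
    grid point ``(x, y) = (ix, iy) * grid_spacing`` to the contour; negative
    inside the cell.
    """

    phi: np.ndarray
    grid_spacing: float

    @property
    def shape(self):
        return self.phi.shape


@dataclass
class CorrespondenceMap:
    """Per-reference-point match between Gamma(t) and Gamma(t+1).

    Parameters are normalized arc lengths in [0, 1) on the respective
    contours; ``displacement_vectors`` connect each source point to its
    matched point on the next contour.  ``flags`` records which correction,
    if any, produced each match.
    """

    source_indices: np.ndarray        # (n,) params on Gamma(t)
    target_indices: np.ndarray        # (n,) params on Gamma(t+1); NaN = missing
    displacement_vectors: np.ndarray  # (n, 2) um
    flags: np.ndarray = field(default=None)
    source_points: np.ndarray = field(default=None)  # (n, 2) um on Gamma(t)

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.full(len(self.source_indices), FLAG_NORMAL, dtype=object)

    @property
    def n_points(self) -> int:
        return len(self.source_indices)


# ---------------------------------------------------------------------------
# signed distance
# ---------------------------------------------------------------------------

def signed_distance(
    contour: Contour,
    shape: tuple[int, int],
    grid_spacing: float,
    *,
    fine_spacing_factor: float = 0.1,
) -> LevelSetField:
    """Exact signed Euclidean distance from every grid point to the contour.

    The contour is densified to ``fine_spacing_factor * grid_spacing``
    vertex spacing and queried through a KD-tree, giving sub-grid accuracy;
    the sign comes from a point-in-polygon test.

    Raises :class:`GeometryError` if the contour comes within 3 grid cells
    of the grid edge (the narrow band must fit inside the domain).
    """
    ny, nx = shape
    h = float(grid_spacing)
    lo = contour.points.min(axis=0)
    hi = contour.points.max(axis=0)
    margin = 3 * h
    if lo[0] < margin or lo[1] < margin or hi[0] > (nx - 1) * h - margin or hi[1] > (ny - 1) * h - margin:
        raise GeometryError("contour too close to the grid edge (need >= 3-cell margin)")

    fine = max(16, int(np.ceil(contour.perimeter / (fine_spacing_factor * h))))
    fine = min(fine, 400_000)
    dense = contour.point_at(np.arange(fine) / fine)
    tree = cKDTree(dense)

    xs = np.arange(nx) * h
    ys = np.arange(ny) * h
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, _ = tree.query(pts, workers=-1)

    poly = shapely.polygons(np.vstack([contour.points, contour.points[:1]]))
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    phi = np.where(inside, -dist, dist).reshape(ny, nx)
    return LevelSetField(phi, h)


def extract_zero_contour(field: LevelSetField, frame_index: int = 0) -> Contour:
    """Longest closed zero-level contour of phi, in micrometers."""
    found = measure.find_contours(field.phi, 0.0)
    if not found:
        raise TrackingError("level set has no zero contour")
    longest = max(found, key=len)
    pts = np.column_stack([longest[:, 1], longest[:, 0]]) * field.grid_spacing
    return Contour(pts, frame_index).ensure_positive_orientation()


# ---------------------------------------------------------------------------
# Hamilton-Jacobi evolution
# ---------------------------------------------------------------------------

def _upwind_step(phi: np.ndarray, V: np.ndarray, dt: float, h: float) -> np.ndarray:
    """One forward-Euler step of d(phi)/dt = -V |grad phi| (Godunov upwind)."""
    pad = np.pad(phi, 1, mode="edge")
    dmx = (phi - pad[1:-1, :-2]) / h
    dpx = (pad[1:-1, 2:] - phi) / h
    dmy = (phi - pad[:-2, 1:-1]) / h
    dpy = (pad[2:, 1:-1] - phi) / h
    gp = np.sqrt(
        np.maximum(dmx, 0) ** 2 + np.minimum(dpx, 0) ** 2
        + np.maximum(dmy, 0) ** 2 + np.minimum(dpy, 0) ** 2
    )
    gm = np.sqrt(
        np.minimum(dmx, 0) ** 2 + np.maximum(dpx, 0) ** 2
        + np.minimum(dmy, 0) ** 2 + np.maximum(dpy, 0) ** 2
    )
    return phi - dt * (np.maximum(V, 0) * gp + np.minimum(V, 0) * gm)


def _front_residual(field: LevelSetField, interp) -> tuple[float, Contour]:
    """Max |phi_next| sampled on the current zero contour."""
    c = extract_zero_contour(field)
    vals = interp(np.column_stack([c.points[:, 1], c.points[:, 0]]))
    return float(np.max(np.abs(vals))), c


def evolve(
    contour_t: Contour,
    contour_next: Contour,
    n_intermediate: int = 10,
    *,
    shape: tuple[int, int] | None = None,
    grid_spacing: float = 0.5,
    max_steps: int = 500,
    speed_clip_cells: float = 5.0,
    reinit_every: int = 25,
    check_every: int = 5,
    tol_cells: float = 0.5,
    cfl: float = 0.5,
) -> list[Contour]:
    """Morph Gamma(t) onto Gamma(t+1), returning intermediate contours.

    The normal speed is ``V = -phi_next`` (clipped to ``speed_clip_cells``
    grid cells, which leaves the zero-level dynamics unchanged but keeps
    the CFL step useful far from the target).  Time stepping is
    forward-Euler with the Godunov upwind gradient and CFL number 0.5; phi
    is reinitialized to signed distance every ``reinit_every`` steps.

    Returns ``n_intermediate`` contours sampled along the evolution; the
    last one lies within one grid cell (Hausdorff) of ``contour_next``.
    Raises :class:`TrackingError` with the final residual if the front has
    not stalled on the target within ``max_steps``.
    """
    if n_intermediate < 1:
        raise TrackingError("n_intermediate must be >= 1")
    h = float(grid_spacing)
    if shape is None:
        hi = np.vstack([contour_t.points, contour_next.points]).max(axis=0)
        nx = int(np.ceil(hi[0] / h)) + 6
        ny = int(np.ceil(hi[1] / h)) + 6
        shape = (ny, nx)

    field = signed_distance(contour_t, shape, h)
    target = signed_distance(contour_next, shape, h)
    ny, nx = shape
    interp = RegularGridInterpolator(
        (np.arange(ny) * h, np.arange(nx) * h), target.phi,
        bounds_error=False, fill_value=None,
    )
    vclip = speed_clip_cells * h
    V = -np.clip(target.phi, -vclip, vclip)
    dt = cfl * h / vclip
    tol = tol_cells * h

    snapshots: list[Contour] = []
    phi = field.phi
    converged = False
    for step in range(1, max_steps + 1):
        phi = _upwind_step(phi, V, dt, h)
        if step % reinit_every == 0:
            c = extract_zero_contour(LevelSetField(phi, h))
            phi = signed_distance(c, shape, h).phi
        if step % check_every == 0 or step == max_steps:
            res, c = _front_residual(LevelSetField(phi, h), interp)
            snapshots.append(Contour(c.points, contour_next.frame_index))
            if res < tol:
                converged = True
                break
    if not converged:
        res, _ = _front_residual(LevelSetField(phi, h), interp)
        raise TrackingError(
            f"level-set front did not stall on the target within {max_steps} steps "
            f"(max residual |phi_next| = {res:.3g} um)"
        )

    idx = np.round(np.linspace(0, len(snapshots) - 1, n_intermediate)).astype(int)
    return [snapshots[i] for i in idx]


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------

def _project_points(points: np.ndarray, contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """Nearest points on a contour and their arc parameters (vectorized)."""
    closed = np.vstack([contour.points, contour.points[:1]])
    ring = shapely.linestrings(closed)
    geoms = shapely.points(points)
    d = np.asarray(shapely.line_locate_point(ring, geoms), float)
    proj = shapely.line_interpolate_point(ring, d)
    coords = shapely.get_coordinates(proj)
    return coords, (d / contour.perimeter) % 1.0


def correspond(
    contour_t: Contour,
    intermediates: list[Contour],
    contour_next: Contour,
    *,
    ref_spacing: float = 0.5,
    apply_corrections: bool = True,
) -> CorrespondenceMap:
    """Chase reference points through the intermediate contours.

    Reference points are placed on ``contour_t`` at ~``ref_spacing``
    micrometer spacing; each is projected to its nearest point on every
    successive intermediate and finally onto ``contour_next``, whose arc
    parameter is recorded.  The raw matches are then passed through
    :func:`correct_conflicts` (unless ``apply_corrections`` is False).
    """
    refs = resample_contour(contour_t, ref_spacing)
    pts = refs.points
    source_params = refs.vertex_params  # params on the resampled contour == on contour_t
    current = pts.copy()
    for inter in intermediates:
        current, _ = _project_points(current, inter)
    current, target_params = _project_points(current, contour_next)
    disp = current - pts
    raw = CorrespondenceMap(
        source_indices=source_params,
        target_indices=target_params,
        displacement_vectors=disp,
        source_points=pts,
    )
    if apply_corrections:
        return correct_conflicts(raw, contour_next)
    return raw


def _circular_unwrap(t: np.ndarray) -> np.ndarray:
    """Lift circular parameters to the line with minimal-magnitude increments."""
    d = np.diff(t)
    d = (d + 0.5) % 1.0 - 0.5
    return t[0] + np.concatenate([[0.0], np.cumsum(d)])


def _circular_interp(params: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Fill ``bad`` entries by circular-linear interpolation from good neighbors."""
    n = len(params)
    good = ~bad
    if good.sum() == 0:
        raise TrackingError("no trusted matches left to interpolate from")
    out = params.copy()
    gi = np.flatnonzero(good)
    lifted = _circular_unwrap(params[good])
    # periodic extension of the good samples for interpolation over the circle
    x = np.concatenate([gi - n, gi, gi + n]).astype(float)
    y = np.concatenate([lifted - 1.0, lifted, lifted + 1.0])
    bi = np.flatnonzero(bad).astype(float)
    out[bad] = np.interp(bi, x, y) % 1.0
    return out


def correct_conflicts(
    raw_map: CorrespondenceMap,
    contour_next: Contour | None = None,
    *,
    max_flag_fraction: float = 0.5,
    neighbor_window: int = 5,
    min_motion: float = 0.25,
) -> CorrespondenceMap:
    """Repair geometric conflicts in a raw correspondence map.

    Three corrections are applied in order:

    1. *missing* — NaN target parameters are filled by circular linear
       interpolation of the neighboring targets;
    2. *crossing* — locally inverted target order is replaced by the
       circular isotonic (PAV) projection of the unwrapped target sequence,
       the nearest circularly non-decreasing sequence in least squares;
    3. *direction* — displacement vectors projecting opposite the local
       mean motion (dot product < 0, i.e. more than 90 degrees off) are
       re-assigned to the neighbor-interpolated target parameter.

    Every touched point is flagged.  If more than ``max_flag_fraction`` of
    points end up flagged, a :class:`TrackingError` reports poor tracking
    quality.
    """
    t = np.asarray(raw_map.target_indices, float).copy()
    flags = raw_map.flags.copy()
    n = len(t)

    # (a) missing matches
    missing = ~np.isfinite(t)
    if missing.any():
        t = _circular_interp(t, missing)
        flags[missing] = FLAG_MISSING

    # (b) crossings: circular isotonic projection
    lifted = _circular_unwrap(t)
    iso = isotonic_regression(lifted).x
    crossing = np.abs(iso - lifted) > 1e-9
    if crossing.any():
        t = iso % 1.0
        newly = crossing & (flags == FLAG_NORMAL)
        flags[newly] = FLAG_CROSSING

    disp = raw_map.displacement_vectors.copy()
    if contour_next is not None and raw_map.source_points is not None:
        disp = contour_next.point_at(t) - raw_map.source_points

    # (c) direction conflicts against the local mean motion
    if raw_map.source_points is not None:
        kernel = np.ones(2 * neighbor_window + 1)
        kernel /= kernel.sum()
        mean_dx = np.convolve(np.tile(disp[:, 0], 3), kernel, "same")[n:2 * n]
        mean_dy = np.convolve(np.tile(disp[:, 1], 3), kernel, "same")[n:2 * n]
        # only vectors of appreciable length against an appreciable local
        # trend count as direction conflicts; sub-resolution jitter is noise
        dot = disp[:, 0] * mean_dx + disp[:, 1] * mean_dy
        significant = (np.hypot(mean_dx, mean_dy) > min_motion) & (
            np.hypot(disp[:, 0], disp[:, 1]) > min_motion
        )
        wrong = (dot < 0) & significant
        if wrong.any():
            t = _circular_interp(t, wrong)
            # re-impose monotonicity after re-assignment
            t = isotonic_regression(_circular_unwrap(t)).x % 1.0
            flags[wrong & (flags == FLAG_NORMAL)] = FLAG_DIRECTION
            if contour_next is not None:
                disp = contour_next.point_at(t) - raw_map.source_points

    n_flagged = int(np.sum(flags != FLAG_NORMAL))
    if n_flagged > max_flag_fraction * n:
        raise TrackingError(
            f"{n_flagged}/{n} correspondence points needed correction — tracking quality too low"
        )
    return CorrespondenceMap(
        source_indices=raw_map.source_indices.copy(),
        target_indices=t,
        displacement_vectors=disp,
        flags=flags,
        source_points=None if raw_map.source_points is None else raw_map.source_points.copy(),
    )


def is_circularly_monotone(params: np.ndarray, tol: float = 1e-9) -> bool:
    """True if the circular sequence of parameters is non-decreasing
    (total winding one turn, no backward increments)."""
    lifted = _circular_unwrap(np.asarray(params, float))
    return bool(np.all(np.diff(lifted) >= -tol))
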