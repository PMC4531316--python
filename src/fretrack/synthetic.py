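"""Ground-truthed synthetic data: edge maps and two-channel movies.

Emulates a single endothelial cell confined in an elliptic micro-well
(20 um x 80 um footprint) and released at a known frame, after which one
or more angular sectors of the edge protrude outward while the biosensor
ratio in the same sectors drops, with a programmable temporal lead
tau between signal drop and motion.

Two levels of realism are generated:

* *map level* — windows-by-frames ratio and translocation matrices built
  directly from the same logistic time profile g, with the ratio drop a
  time-shifted copy of the translocation rise.  Because both share one
  shape, the cross-correlation-recoverable lag equals the programmed lead
  tau by construction, which makes lag-recovery tests well-posed.
* *image level* — rendered donor/acceptor TIFF-ready stacks: the initial
  ellipse grows outward along local normals inside the protruding
  sector(s), channels are drawn with area-fraction anti-aliasing at the
  boundary, and Poisson shot noise plus Gaussian read noise are added.
  Analytic truth contours and truth window maps accompany the movie.

What the generator deliberately does *not* emulate: actin/membrane
mechanics, photobleaching, intracellular texture beyond uniform levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon2mask
from skimage.measure import block_reduce

from .boundary import Contour
from .errors import ConfigError, GeometryError
from .io_ratio import TwoChannelMovie
from .stmap import SpatioTemporalMap

__all__ = ["Sector", "Scenario", "SCENARIOS", "generate_maps", "generate_ensemble", "generate_movie"]


@dataclass(frozen=True)
class Sector:
    """A protruding region of the edge.

    At map level ``start``/``stop`` are inclusive window indices; at image
    level they are elliptic-parameter angles in radians (the sector gets a
    cosine-squared taper toward its ends).
    """

    start: float
    stop: float
    max_advance: float  # um


@dataclass(frozen=True)
class Scenario:
    """Registered study conditions for one synthetic cell (or ensemble)."""

    name: str
    level: str                      # "map" | "image"
    n_frames: int
    frame_interval: float           # min
    release_index: int
    sectors: tuple[Sector, ...]
    advance_midpoint: float         # min post-release
    steepness: float                # min (logistic time constant)
    lead_time: float                # tau, min; ratio drop leads motion by tau
    ratio_floor: float = 0.85       # sector ratio at full drop (baseline 1.0)
    noise_sd: float = 0.05          # fraction of each signal's dynamic range
    n_windows: int = 64             # map level
    n_cells: int = 1                # >1 = ensemble (map level)
    advance_jitter: float = 0.0     # fractional per-cell jitter on max_advance
    # image level
    shape_px: tuple[int, int] = (256, 320)   # (rows, cols)
    pixel_size: float = 0.5                  # um / px
    ellipse_axes: tuple[float, float] = (40.0, 10.0)  # semi-axes um (x, y)
    center: tuple[float, float] = (80.0, 64.0)        # um (x, y)
    fret_inside: float = 1000.0
    fret_outside: float = 50.0
    read_noise_sd: float = 10.0
    poisson_noise: bool = True               # shot noise on both channels
    advance_duration: float | None = None    # min; image-level sigmoid completes here

    def validate(self) -> None:
        if self.n_frames < 2 or not 0 <= self.release_index < self.n_frames:
            raise ConfigError("bad frame count / release index")
        if self.lead_time < 0 or self.noise_sd < 0:
            raise ConfigError("lead_time and noise_sd must be non-negative")
        if self.level not in ("map", "image"):
            raise ConfigError(f"unknown scenario level {self.level!r}")
        if self.level == "map":
            spans = []
            for s in self.sectors:
                a, b = int(s.start), int(s.stop)
                if not (0 <= a <= b < self.n_windows):
                    raise ConfigError("sector window range out of bounds")
                spans.append((a, b))
            for (a1, b1), (a2, b2) in zip(sorted(spans), sorted(spans)[1:]):
                if a2 <= b1:
                    raise ConfigError("sectors overlap")

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) - self.release_index) * self.frame_interval


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _grid_profile(times: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Logistic profile affinely normalized to [0, 1] on the frame grid."""
    g = _logistic((times - midpoint) / steepness)
    lo, hi = g[0], g[-1]
    if hi - lo < 1e-12:
        raise ConfigError("sigmoid is flat on the frame grid")
    return (g - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# registered scenarios
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, Scenario] = {}


def _register(s: Scenario) -> Scenario:
    s.validate()
    SCENARIOS[s.name] = s
    return s


POL_A = _register(
    Scenario(
        name="POL-A", level="map", n_windows=64, n_frames=50, frame_interval=1.0,
        release_index=10, sectors=(Sector(20, 31, 25.0),),
        advance_midpoint=20.0, steepness=0.4, lead_time=10.0,
        ratio_floor=0.85, noise_sd=0.05,
    )
)

POL_B = _register(
    Scenario(
        name="POL-B", level="map", n_windows=40, n_frames=50, frame_interval=1.0,
        release_index=10, sectors=(Sector(12, 19, 25.0),),
        advance_midpoint=22.0, steepness=0.4, lead_time=15.0,
        ratio_floor=0.85, noise_sd=0.05, n_cells=3, advance_jitter=0.10,
    )
)

NP_A = _register(
    Scenario(
        name="NP-A", level="map", n_windows=64, n_frames=50, frame_interval=1.0,
        release_index=10,
        sectors=(Sector(4, 11, 30.0), Sector(26, 33, 30.0), Sector(48, 55, 30.0)),
        advance_midpoint=20.0, steepness=0.4, lead_time=0.0,
        ratio_floor=0.85, noise_sd=0.05,
    )
)

POL_C = _register(
    Scenario(
        name="POL-C", level="image", n_frames=25, frame_interval=2.0, release_index=3,
        sectors=(Sector(-0.55, 0.55, 30.0),),  # right-end angular sector, radians
        advance_midpoint=5.0, steepness=1.5, lead_time=10.0,
        ratio_floor=0.85, noise_sd=0.05,
        shape_px=(256, 320), pixel_size=0.5,
        ellipse_axes=(40.0, 10.0), center=(80.0, 64.0),
        fret_inside=1000.0, fret_outside=50.0, read_noise_sd=10.0,
        advance_duration=10.0,
    )
)


# ---------------------------------------------------------------------------
# map-level generation
# ---------------------------------------------------------------------------

def generate_maps(
    scenario: Scenario | str,
    seed: int,
) -> tuple[SpatioTemporalMap, SpatioTemporalMap, dict]:
    """Window-level ratio and translocation maps plus the truth record.

    Sector windows follow ``B(w, t) = A * h(t)`` and
    ``S(w, t) = 1 - drop * h(t + tau)`` with one shared normalized
    logistic profile h, so the programmed lead tau is exactly the
    CC-recoverable lag.  I.i.d. Gaussian noise scaled by each signal's
    dynamic range is added everywhere.
    """
    sc = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    sc.validate()
    if sc.level != "map":
        raise ConfigError(f"scenario {sc.name} is not map-level")
    if sc.n_cells != 1:
        raise ConfigError("use generate_ensemble for multi-cell scenarios")
    return _one_cell_maps(sc, seed)


def _one_cell_maps(sc: Scenario, seed: int) -> tuple[SpatioTemporalMap, SpatioTemporalMap, dict]:
    rng = np.random.default_rng(seed)
    t = sc.frame_times
    drop = 1.0 - sc.ratio_floor
    h_move = _grid_profile(t, sc.advance_midpoint, sc.steepness)
    h_drop = _grid_profile(t, sc.advance_midpoint - sc.lead_time, sc.steepness)

    b = np.zeros((sc.n_windows, sc.n_frames))
    s = np.ones((sc.n_windows, sc.n_frames))
    sector_windows = []
    max_adv = max(sec.max_advance for sec in sc.sectors)
    for sec in sc.sectors:
        w = np.arange(int(sec.start), int(sec.stop) + 1)
        sector_windows.extend(w.tolist())
        b[w] = sec.max_advance * h_move
        s[w] = 1.0 - drop * h_drop
    if sc.noise_sd > 0:
        b += rng.normal(0, sc.noise_sd * max_adv, b.shape)
        s += rng.normal(0, sc.noise_sd * drop, s.shape)

    arc = np.arange(sc.n_windows) * 1.25  # nominal 1.25-um window spacing
    ratio_map = SpatioTemporalMap(s, arc, t, kind="ratio")
    transloc_map = SpatioTemporalMap(b, arc, t, kind="translocation")
    truth = {
        "tau_min": sc.lead_time,
        "sector_windows": sorted(sector_windows),
        "max_advance_um": max_adv,
        "ratio_floor": sc.ratio_floor,
        "seed": seed,
    }
    return ratio_map, transloc_map, truth


def generate_ensemble(
    scenario: Scenario | str,
    seed: int,
) -> list[tuple[SpatioTemporalMap, SpatioTemporalMap, dict]]:
    """Per-cell maps for an ensemble scenario with jittered advance.

    Cell c uses an independent child seed and a max advance scaled by
    ``1 + U(-jitter, +jitter)``.
    """
    sc = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    sc.validate()
    if sc.level != "map":
        raise ConfigError(f"scenario {sc.name} is not map-level")
    seeds = np.random.SeedSequence(seed).spawn(sc.n_cells)
    out = []
    for c, ss in enumerate(seeds):
        child = int(ss.generate_state(1)[0] % (2**31 - 1))
        jit_rng = np.random.default_rng(child)
        factor = 1.0 + jit_rng.uniform(-sc.advance_jitter, sc.advance_jitter)
        cell_sc = replace(
            sc,
            n_cells=1,
            name=f"{sc.name}-cell{c}",
            sectors=tuple(replace(s, max_advance=s.max_advance * factor) for s in sc.sectors),
        )
        ratio_map, transloc_map, truth = _one_cell_maps(cell_sc, child)
        truth["cell"] = c
        out.append((ratio_map, transloc_map, truth))
    return out


# ---------------------------------------------------------------------------
# image-level generation
# ---------------------------------------------------------------------------

def _angle_taper(
    theta: np.ndarray, sectors: tuple[Sector, ...], flat_fraction: float = 0.6
) -> np.ndarray:
    """Flat-topped angular weight: 1 over the central ``flat_fraction`` of
    each sector (a broad, uniform protrusion front, as in a lamellipodium),
    rolling off as cosine-squared toward the sector ends, 0 outside."""
    th = (theta + np.pi) % (2 * np.pi) - np.pi
    w = np.zeros_like(th, dtype=float)
    for sec in sectors:
        c = (sec.start + sec.stop) / 2
        half = (sec.stop - sec.start) / 2
        rel = np.abs((th - c + np.pi) % (2 * np.pi) - np.pi)
        flat = flat_fraction * half
        ramp = np.cos(np.pi * (rel - flat) / (2 * (half - flat))) ** 2
        w_sec = np.where(rel <= flat, 1.0, np.where(rel <= half, ramp, 0.0))
        w = np.maximum(w, w_sec)
    return w


def _duration_profile(t: float, sc: Scenario) -> float:
    """Sigmoid reaching exactly 0 at release and 1 at release + duration."""
    dur = sc.advance_duration if sc.advance_duration is not None else 10.0
    g0 = _logistic((0.0 - sc.advance_midpoint) / sc.steepness)
    g1 = _logistic((dur - sc.advance_midpoint) / sc.steepness)
    g = _logistic((t - sc.advance_midpoint) / sc.steepness)
    return float(np.clip((g - g0) / (g1 - g0), 0.0, 1.0))


def truth_contour(sc: Scenario, t: float, n_theta: int = 1024, frame_index: int = 0) -> Contour:
    """Analytic cell outline at time t (minutes relative to release)."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    a, bax = sc.ellipse_axes
    cx, cy = sc.center
    ex = cx + a * np.cos(theta)
    ey = cy + bax * np.sin(theta)
    nx = bax * np.cos(theta)
    ny = a * np.sin(theta)
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    taper = _angle_taper(theta, sc.sectors)
    amp = max(s.max_advance for s in sc.sectors)
    adv = amp * taper * _duration_profile(t, sc)
    pts = np.column_stack([ex + adv * nx, ey + adv * ny])
    return Contour(pts, frame_index).ensure_positive_orientation()


def truth_advance(sc: Scenario, theta: np.ndarray, t: float) -> np.ndarray:
    """Programmed normal advance (um) at elliptic angles theta, time t."""
    amp = max(s.max_advance for s in sc.sectors)
    return amp * _angle_taper(np.asarray(theta, float), sc.sectors) * _duration_profile(t, sc)


def _ratio_profile(sc: Scenario, t: float) -> float:
    return _duration_profile(t + sc.lead_time, sc)


def generate_movie(
    scenario: Scenario | str,
    seed: int,
    *,
    supersample: int = 3,
) -> tuple[TwoChannelMovie, list[Contour], dict]:
    """Render a two-channel movie with analytic truth contours.

    The acceptor (FRET) channel is ``fret_outside`` plus
    ``fret_inside - fret_outside`` times the per-pixel cell area fraction
    (computed by ``supersample x supersample`` sub-pixel rasterization of
    the truth polygon); the donor channel is the acceptor times the local
    ratio field (1.0 in the body, dropping to ``ratio_floor`` in the
    protruding sector with lead ``tau``).  Poisson shot noise and Gaussian
    read noise are then applied per channel.
    """
    sc = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    sc.validate()
    if sc.level != "image":
        raise ConfigError(f"scenario {sc.name} is not image-level")
    rng = np.random.default_rng(seed)
    ny, nx = sc.shape_px
    h = sc.pixel_size
    times = sc.frame_times

    # check the fully protruded footprint stays inside the frame
    final = truth_contour(sc, float(times[-1]))
    hi = final.points.max(axis=0)
    lo = final.points.min(axis=0)
    if lo.min() < 2 * h or hi[0] > (nx - 3) * h or hi[1] > (ny - 3) * h:
        raise GeometryError("protrusion pushes the boundary off the image")

    # sub-pixel grid for area-fraction anti-aliasing
    ss = supersample
    cx, cy = sc.center
    a, bax = sc.ellipse_axes
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    # elliptic angle of each pixel, for the ratio field
    theta_pix = np.arctan2((yy * h - cy) / bax, (xx * h - cx) / a)

    donor = np.empty((sc.n_frames, ny, nx))
    acceptor = np.empty((sc.n_frames, ny, nx))
    contours = []
    drop = 1.0 - sc.ratio_floor
    for i, t in enumerate(times):
        c = truth_contour(sc, float(t), frame_index=i)
        contours.append(c)
        # polygon vertices in supersampled (row, col) pixel units
        poly_rc = np.column_stack([c.points[:, 1], c.points[:, 0]]) / h * ss + (ss - 1) / 2
        mask_ss = polygon2mask((ny * ss, nx * ss), poly_rc)
        frac = block_reduce(mask_ss.astype(float), (ss, ss), np.mean)
        ratio_field = 1.0 - drop * _angle_taper(theta_pix, sc.sectors) * _ratio_profile(sc, float(t))
        fret_clean = sc.fret_outside + (sc.fret_inside - sc.fret_outside) * frac
        ecfp_clean = fret_clean * np.where(frac > 0, ratio_field, 1.0)
        fret = rng.poisson(fret_clean).astype(float) if sc.poisson_noise else fret_clean
        ecfp = rng.poisson(ecfp_clean).astype(float) if sc.poisson_noise else ecfp_clean
        if sc.read_noise_sd > 0:
            fret = fret + rng.normal(0, sc.read_noise_sd, fret_clean.shape)
            ecfp = ecfp + rng.normal(0, sc.read_noise_sd, ecfp_clean.shape)
        acceptor[i] = fret
        donor[i] = ecfp

    # float32 so a TIFF round trip is bit-identical
    movie = TwoChannelMovie(
        donor.astype(np.float32), acceptor.astype(np.float32), h, times, sc.release_index
    )
    truth = {
        "tau_min": sc.lead_time,
        "max_advance_um": max(s.max_advance for s in sc.sectors),
        "ratio_floor": sc.ratio_floor,
        "advance_duration_min": sc.advance_duration,
        "seed": seed,
    }
    return movie, contours, truth


def truth_window_maps(
    sc: Scenario,
    arc_params: np.ndarray,
) -> tuple[SpatioTemporalMap, SpatioTemporalMap]:
    """Truth ratio/translocation maps sampled at given initial arc params.

    ``arc_params`` are normalized arc positions on the *initial* ellipse;
    they are converted to elliptic angles and the programmed advance and
    ratio drop evaluated there for every frame time.
    """
    c0 = truth_contour(sc, sc.frame_times[0] - 1e9)  # pre-release ellipse
    pts = c0.point_at(np.asarray(arc_params, float))
    a, bax = sc.ellipse_axes
    cx, cy = sc.center
    theta = np.arctan2((pts[:, 1] - cy) / bax, (pts[:, 0] - cx) / a)
    times = sc.frame_times
    taper = _angle_taper(theta, sc.sectors)
    amp = max(s.max_advance for s in sc.sectors)
    b = np.column_stack([amp * taper * _duration_profile(float(t), sc) for t in times])
    drop = 1.0 - sc.ratio_floor
    s = np.column_stack([1.0 - drop * taper * _ratio_profile(sc, float(t)) for t in times])
    arc = np.asarray(arc_params, float) * c0.perimeter
    return (
        SpatioTemporalMap(s, arc, times, kind="ratio"),
        SpatioTemporalMap(b, arc, times, kind="translocation"),
    )
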