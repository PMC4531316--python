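"""Globally normalized temporal and spatial cross-correlation.

For a window with ratio time course S(t) and translocation time course
B(t), the temporal cross-correlation at lag tau is

    rho(tau) = Cov(S(t), B(t + tau)) / (sigma_S_max * sigma_B_max),

where the covariance runs over the overlapping samples after centering
each series by its full-length mean, and sigma_S_max / sigma_B_max are the
*maximal* standard deviations of the centered time courses over all
windows of the map.  This global normalization down-weights windows with
little change, highlighting the regions with significant signal and
motion; it never increases a coefficient's magnitude relative to the
window's own (Pearson) normalization.

Sign convention (documented prominently because results depend on it):
a *positive* lag at the correlation minimum means the ratio change
precedes the translocation change in time.

The spatial analog correlates circular line scans across windows at one
time step, normalized by the maximal spatial standard deviations over all
time steps; the shift at the minimum locates the spatial offset between
signal change and motion (zero = co-located).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, StatsError
from .stmap import SpatioTemporalMap

__all__ = [
    "CCResult",
    "GlobalNorms",
    "global_sigmas",
    "spatial_sigmas",
    "temporal_cc",
    "spatial_cc",
    "cc_map",
    "spatial_cc_map",
    "extract_minimum",
]


@dataclass
class CCResult:
    """A cross-correlation curve plus its most negative point.

    ``offsets`` is the lag axis (minutes for temporal, windows for
    spatial), symmetric about zero; omitted lags carry NaN values.
    """

    offsets: np.ndarray
    values: np.ndarray
    min_value: float
    min_offset: float
    no_negative_minimum: bool = False


@dataclass
class GlobalNorms:
    """Map-wide normalization constants of the centered time courses."""

    sigma_s_max: float
    sigma_b_max: float
    mu_s: np.ndarray
    mu_b: np.ndarray


def _row_sds(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = np.nanmean(values, axis=1)
    sd = np.nanstd(values - mu[:, None], axis=1)
    return mu, sd


def global_sigmas(ratio_map: SpatioTemporalMap, transloc_map: SpatioTemporalMap) -> GlobalNorms:
    """Maximal per-window standard deviations of both maps' time courses."""
    if ratio_map.values.shape != transloc_map.values.shape:
        raise StatsError("ratio and translocation maps must share axes")
    mu_s, sd_s = _row_sds(ratio_map.values)
    mu_b, sd_b = _row_sds(transloc_map.values)
    s_max = float(np.nanmax(sd_s)) if np.any(np.isfinite(sd_s)) else 0.0
    b_max = float(np.nanmax(sd_b)) if np.any(np.isfinite(sd_b)) else 0.0
    if s_max <= 0 and b_max <= 0:
        raise StatsError("both maps are constant — normalization degenerate")
    return GlobalNorms(s_max, b_max, mu_s, mu_b)


def spatial_sigmas(ratio_map: SpatioTemporalMap, transloc_map: SpatioTemporalMap) -> GlobalNorms:
    """Maximal per-time-step *spatial* standard deviations of the line scans."""
    mu_s, sd_s = _row_sds(ratio_map.values.T)
    mu_b, sd_b = _row_sds(transloc_map.values.T)
    s_max = float(np.nanmax(sd_s)) if np.any(np.isfinite(sd_s)) else 0.0
    b_max = float(np.nanmax(sd_b)) if np.any(np.isfinite(sd_b)) else 0.0
    if s_max <= 0 and b_max <= 0:
        raise StatsError("both maps are spatially constant — normalization degenerate")
    return GlobalNorms(s_max, b_max, mu_s, mu_b)


def temporal_cc(
    s: np.ndarray,
    b: np.ndarray,
    norms: GlobalNorms,
    max_lag: float,
    *,
    frame_interval: float = 1.0,
    min_overlap: int = 5,
) -> CCResult:
    """Temporal cross-correlation of one window's S and B series.

    ``max_lag`` is in minutes and is rounded down to the frame grid.  Lags
    whose overlap (after pairwise deletion of missing samples) is shorter
    than ``min_overlap`` are omitted (NaN).
    """
    s = np.asarray(s, float)
    b = np.asarray(b, float)
    if s.shape != b.shape or s.ndim != 1:
        raise StatsError("series must be 1-D and equally long")
    n = len(s)
    max_lag_frames = int(np.floor(max_lag / frame_interval))
    max_lag_frames = min(max_lag_frames, n - 1)
    sc = s - np.nanmean(s)
    bc = b - np.nanmean(b)
    denom = norms.sigma_s_max * norms.sigma_b_max
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    vals = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = sc[: n - lag], bc[lag:]
        else:
            x, y = sc[-lag:], bc[: n + lag]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_overlap:
            continue
        vals[i] = np.mean(x[ok] * y[ok]) / denom if denom > 0 else np.nan
    offsets = lags * frame_interval
    return _finalize(offsets.astype(float), vals)


def spatial_cc(
    ratio_line: np.ndarray,
    transloc_line: np.ndarray,
    norms_spatial: GlobalNorms,
    max_shift: int,
) -> CCResult:
    """Circular spatial cross-correlation of one time step's line scans.

    Lines are treated as circular (window n-1 adjacent to window 0); shift
    s correlates the ratio at window w with the translocation at window
    w + s.  Normalization uses the maximal spatial standard deviations
    over all time steps (``norms_spatial``).
    """
    s = np.asarray(ratio_line, float)
    b = np.asarray(transloc_line, float)
    if s.shape != b.shape or s.ndim != 1:
        raise StatsError("line scans must be 1-D and equally long")
    n = len(s)
    if n < 8:
        raise GeometryError("need at least 8 windows for spatial correlation")
    max_shift = int(min(max_shift, n // 2))
    sc = s - np.nanmean(s)
    bc = b - np.nanmean(b)
    denom = norms_spatial.sigma_s_max * norms_spatial.sigma_b_max
    shifts = np.arange(-max_shift, max_shift + 1)
    vals = np.full(len(shifts), np.nan)
    for i, sh in enumerate(shifts):
        y = np.roll(bc, -sh)  # y[w] = bc[w + sh]
        ok = np.isfinite(sc) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        vals[i] = np.mean(sc[ok] * y[ok]) / denom if denom > 0 else np.nan
    return _finalize(shifts.astype(float), vals)


def _finalize(offsets: np.ndarray, vals: np.ndarray) -> CCResult:
    finite = np.isfinite(vals)
    if not finite.any():
        return CCResult(offsets, vals, np.nan, np.nan, no_negative_minimum=True)
    vmin = np.nanmin(vals)
    # ties: smallest |offset| first, then positive offset
    cand = np.flatnonzero(finite & (vals == vmin))
    key = sorted(cand, key=lambda i: (abs(offsets[i]), -np.sign(offsets[i])))
    imin = key[0]
    return CCResult(
        offsets=offsets,
        values=vals,
        min_value=float(vmin),
        min_offset=float(offsets[imin]),
        no_negative_minimum=bool(vmin >= 0),
    )


def extract_minimum(cc: CCResult) -> tuple[float, float]:
    """Most negative coefficient and its offset (ties: smallest |offset|,
    then positive).  A curve with no negative values is flagged on the
    result (``no_negative_minimum``) but still returns its minimum."""
    if len(cc.offsets) < 3:
        raise StatsError("need at least 3 offsets to extract a minimum")
    return cc.min_value, cc.min_offset


def cc_map(
    ratio_map: SpatioTemporalMap,
    transloc_map: SpatioTemporalMap,
    norms: GlobalNorms,
    max_lag: float,
) -> tuple[np.ndarray, np.ndarray, list[CCResult]]:
    """Temporal CC per window, stacked along the edge.

    Returns ``(lag_axis_minutes, matrix windows x lags, per-window results)``.
    All-missing windows give all-NaN rows.
    """
    interval = float(np.median(np.diff(ratio_map.frame_times)))
    results = []
    rows = []
    lag_axis = None
    for w in range(ratio_map.n_windows):
        s = ratio_map.values[w]
        b = transloc_map.values[w]
        if not (np.isfinite(s).sum() >= 5 and np.isfinite(b).sum() >= 5):
            res = None
        else:
            res = temporal_cc(s, b, norms, max_lag, frame_interval=interval)
            lag_axis = res.offsets
        results.append(res)
        rows.append(None if res is None else res.values)
    if lag_axis is None:
        raise StatsError("no window had enough data for cross-correlation")
    mat = np.vstack([np.full(len(lag_axis), np.nan) if r is None else r for r in rows])
    return lag_axis, mat, results


def spatial_cc_map(
    ratio_map: SpatioTemporalMap,
    transloc_map: SpatioTemporalMap,
    norms_spatial: GlobalNorms,
    max_shift: int,
) -> tuple[np.ndarray, np.ndarray, list[CCResult]]:
    """Spatial CC per time step, stacked along time (rows = time steps)."""
    results = []
    rows = []
    axis = None
    for t in range(ratio_map.n_frames):
        s = ratio_map.values[:, t]
        b = transloc_map.values[:, t]
        if np.isfinite(s).sum() < 8 or np.isfinite(b).sum() < 8:
            res = None
        else:
            res = spatial_cc(s, b, norms_spatial, max_shift)
            axis = res.offsets
        results.append(res)
        rows.append(None if res is None else res.values)
    if axis is None:
        raise StatsError("no time step had enough data for spatial correlation")
    mat = np.vstack([np.full(len(axis), np.nan) if r is None else r for r in rows])
    return axis, mat, results
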