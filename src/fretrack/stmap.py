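"""Spatiotemporal maps and protrusive-region / cell-polarity classification.

A :class:`SpatioTemporalMap` is a windows-by-frames matrix of either the
edge ratio signal (dimensionless) or the boundary translocation
(micrometers), with explicit arc positions and frame times.  The edge of a
cell is split into protrusive (P) and non-protrusive (NP) regions: windows
whose post-release peak translocation reaches at least 75% of the cell's
maximal translocation are P.  A cell with a single circularly contiguous
P-region has a unique protrusion front and is classified as polarized;
cells with several P-regions are non-polarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassificationError, ShapeError

__all__ = [
    "SpatioTemporalMap",
    "RegionLabeling",
    "assemble_map",
    "classify_regions",
    "classify_cell",
]


@dataclass
class SpatioTemporalMap:
    """Windows x frames matrix of an edge quantity.

    ``kind`` is ``"ratio"`` or ``"translocation"``; missing entries are NaN.
    """

    values: np.ndarray        # (n_windows, n_frames)
    arc_positions: np.ndarray  # (n_windows,) um along the edge
    frame_times: np.ndarray    # (n_frames,) minutes, release at 0
    kind: str = "ratio"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ShapeError("map values must be 2-D (windows x frames)")
        if len(self.arc_positions) != v.shape[0] or len(self.frame_times) != v.shape[1]:
            raise ShapeError("axis metadata inconsistent with value matrix")
        self.values = v
        self.arc_positions = np.asarray(self.arc_positions, float)
        self.frame_times = np.asarray(self.frame_times, float)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: rows = windows (arc position), columns = times."""
        df = pd.DataFrame(self.values, columns=[f"{t:g}" for t in self.frame_times])
        df.insert(0, "arc_um", self.arc_positions)
        return df


@dataclass
class RegionLabeling:
    """P/NP labels per window plus the maximal circular P-runs."""

    window_labels: np.ndarray                 # (n,) of "P" | "NP"
    regions: list[tuple[int, int]] = field(default_factory=list)  # (start, end) inclusive, circular
    cell_class: str = ""

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def assemble_map(
    per_frame_samples: list[np.ndarray],
    frame_times: np.ndarray,
    arc_positions: np.ndarray,
    kind: str = "ratio",
) -> SpatioTemporalMap:
    """Column-stack per-frame sample vectors into a spatiotemporal map.

    Isolated missing samples (a single-frame gap in a window's time course)
    are filled by linear interpolation in time; runs of two or more missing
    frames are left missing.
    """
    lengths = {len(v) for v in per_frame_samples}
    if len(lengths) != 1:
        raise ShapeError(f"per-frame sample vectors have differing lengths: {sorted(lengths)}")
    values = np.column_stack([np.asarray(v, float) for v in per_frame_samples])
    times = np.asarray(frame_times, float)
    for w in range(values.shape[0]):
        row = values[w]
        bad = ~np.isfinite(row)
        for j in np.flatnonzero(bad):
            if 0 < j < len(row) - 1 and np.isfinite(row[j - 1]) and np.isfinite(row[j + 1]):
                f = (times[j] - times[j - 1]) / (times[j + 1] - times[j - 1])
                values[w, j] = row[j - 1] + f * (row[j + 1] - row[j - 1])
    return SpatioTemporalMap(values, arc_positions, times, kind=kind)


def _circular_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, end) inclusive index pairs."""
    n = len(labels)
    if labels.all():
        return [(0, n - 1)]
    if not labels.any():
        return []
    # rotate so position 0 is False, find linear runs, rotate back
    shift = int(np.flatnonzero(~labels)[0])
    rolled = np.roll(labels, -shift)
    runs = []
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(rolled) - 1))
    return [((a + shift) % n, (b + shift) % n) for a, b in runs]


def _run_length(run: tuple[int, int], n: int) -> int:
    a, b = run
    return (b - a) % n + 1


def classify_regions(
    transloc_map: SpatioTemporalMap,
    threshold_fraction: float = 0.75,
    min_region_windows: int = 3,
    merge_gap: int = 1,
) -> RegionLabeling:
    """Label windows P/NP by the 75%-of-maximal-translocation rule.

    Per window the peak translocation over post-release frames is taken;
    windows whose peak reaches ``threshold_fraction`` of the cell maximum
    (inclusive) are P.  Circular P-runs shorter than ``min_region_windows``
    are suppressed, and runs separated by at most ``merge_gap`` NP windows
    are merged; the surviving runs are the P-regions.
    """
    if transloc_map.kind != "translocation":
        raise ClassificationError("region classification needs a translocation map")
    post = transloc_map.frame_times >= 0
    vals = transloc_map.values[:, post]
    peaks = np.nanmax(vals, axis=1)
    peaks = np.where(np.isfinite(peaks), peaks, -np.inf)
    m = np.max(peaks)
    if not np.isfinite(m) or m <= 0:
        raise ClassificationError("no positive translocation — no protrusion to classify")
    n = transloc_map.n_windows
    p = peaks >= threshold_fraction * m

    # suppress noise runs shorter than the minimum region size
    for run in _circular_runs(p):
        if _run_length(run, n) < min_region_windows:
            a, b = run
            idx = [(a + i) % n for i in range(_run_length(run, n))]
            p[idx] = False

    # merge runs separated by small NP gaps
    if p.any() and not p.all() and merge_gap > 0:
        for run in _circular_runs(~p):
            if _run_length(run, n) <= merge_gap:
                a, b = run
                idx = [(a + i) % n for i in range(_run_length(run, n))]
                # only bridge gaps that sit between two P windows
                before = (a - 1) % n
                after = (b + 1) % n
                if p[before] and p[after]:
                    p[idx] = True

    regions = _circular_runs(p)
    labels = np.where(p, "P", "NP").astype(object)
    labeling = RegionLabeling(window_labels=labels, regions=regions)
    labeling.cell_class = classify_cell(labeling)
    return labeling


def classify_cell(labeling: RegionLabeling) -> str:
    """Polarized iff the cell has exactly one P-region."""
    if labeling.n_regions == 0:
        raise ClassificationError("no P-region found — cannot classify cell")
    return "polarized" if labeling.n_regions == 1 else "non-polarized"


def labeling_to_frame(labeling: RegionLabeling, arc_positions: np.ndarray) -> pd.DataFrame:
    """Export labels as a table (window_index, arc_um, label, region_id)."""
    n = len(labeling.window_labels)
    region_id = np.full(n, -1)
    for rid, (a, b) in enumerate(labeling.regions):
        for i in range(_run_length((a, b), n)):
            region_id[(a + i) % n] = rid
    return pd.DataFrame(
        {
            "window_index": np.arange(n),
            "arc_um": np.asarray(arc_positions, float),
            "label": labeling.window_labels,
            "region_id": region_id,
        }
    )
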