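"""End-to-end orchestration: movie -> maps -> classification -> correlation.

Stages mirror the analysis flow: load and background-correct the two
channels, compute the masked ratio movie, detect the boundary in every
frame, morph each boundary onto the next with the level-set evolver and
establish point correspondence, build the peripheral sampling windows on
the first frame and propagate them materially through the correspondence,
sample ratio and normal displacement per window, integrate translocation
from the release frame, classify P/NP regions and cell polarity, and
compute the globally normalized temporal and spatial cross-correlation
maps with their minima.

Every run produces a manifest (effective config, seeds) so results can be
reproduced exactly; intermediate tables are written to the output
directory when one is given, and cached contours are reused on resume.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boundary import Contour, detect_boundary
from .crosscorr import cc_map, extract_minimum, global_sigmas, spatial_cc_map, spatial_sigmas
from .errors import ConfigError, FretrackError
from .io_ratio import RatioMovie, TwoChannelMovie, compute_ratio, load_stack, save_stack, subtract_background
from .levelset import CorrespondenceMap, correspond, evolve, signed_distance
from .sampling import (
    build_band,
    integrate_translocation,
    map_interval_edges,
    sample_ratio,
    window_displacement,
    windows_from_intervals,
)
from .stmap import SpatioTemporalMap, assemble_map, classify_regions, labeling_to_frame
from .stats import bootstrap_mean
from . import synthetic

log = logging.getLogger("fretrack")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_movie", "run_synthetic"]


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with field defaults.

    Units: spatial parameters in micrometers, times in minutes.
    """

    pixel_size: float = 0.5
    frame_interval: float = 2.0
    release_index: int = 0
    background_percentile: float = 0.05
    min_intensity: float | None = None
    median_radius: int = 0            # optional ratio smoothing, px (0 = off)
    detect_channel: str = "acceptor"  # "acceptor" | "donor" | "sum"
    k: int = 3
    min_area: int = 100
    depth: float = 0.5
    width: float = 1.25
    n_intermediate: int = 10
    ref_spacing: float = 0.5
    max_evolve_steps: int = 500
    threshold_fraction: float = 0.75
    min_region_windows: int = 3
    max_lag: float | None = None      # default: half the post-release duration
    max_shift: int | None = None      # default: quarter of the window count
    n_boot: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigError("pixel_size and frame_interval must be positive")
        if self.depth <= 0 or self.width <= 0:
            raise ConfigError("window depth and width must be positive")
        if self.detect_channel not in ("acceptor", "donor", "sum"):
            raise ConfigError(f"unknown detection channel {self.detect_channel!r}")
        if not 0 < self.background_percentile < 0.5:
            raise ConfigError("background percentile must lie in (0, 0.5)")


@dataclass
class PipelineResult:
    """Bundle of all per-stage outputs of one analysis run."""

    config: RunConfig
    contours: list[Contour]
    correspondences: list[CorrespondenceMap]
    ratio_map: SpatioTemporalMap
    transloc_map: SpatioTemporalMap
    labeling: object
    cell_class: str
    temporal_lags: np.ndarray          # (n_lags,) minutes
    temporal_cc_matrix: np.ndarray     # windows x lags
    cc_minima: pd.DataFrame            # per-window min value / lag / flag
    spatial_shifts: np.ndarray
    spatial_cc_matrix: np.ndarray      # time steps x shifts
    summary: dict
    manifest: dict = field(default_factory=dict)

    def export(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _contours_frame(self.contours).to_csv(out / "contours.csv", index=False)
        _corr_frame(self.correspondences).to_csv(out / "correspondence.csv", index=False)
        self.ratio_map.to_frame().to_csv(out / "ratio_map.csv", index=False)
        self.transloc_map.to_frame().to_csv(out / "translocation_map.csv", index=False)
        lab = labeling_to_frame(self.labeling, self.ratio_map.arc_positions)
        lab.to_csv(out / "labeling.csv", index=False)
        cc = pd.DataFrame(self.temporal_cc_matrix, columns=[f"{t:g}" for t in self.temporal_lags])
        cc.insert(0, "window", np.arange(len(cc)))
        cc.to_csv(out / "temporal_cc_map.csv", index=False)
        scc = pd.DataFrame(self.spatial_cc_matrix, columns=[f"{s:g}" for s in self.spatial_shifts])
        scc.insert(0, "time_step", np.arange(len(scc)))
        scc.to_csv(out / "spatial_cc_map.csv", index=False)
        self.cc_minima.to_csv(out / "cc_minima.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _contours_frame(contours: list[Contour]) -> pd.DataFrame:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.frame_index, i, x, y))
    return pd.DataFrame(rows, columns=["frame_index", "point_index", "x_um", "y_um"])


def _corr_frame(corrs: list[CorrespondenceMap]) -> pd.DataFrame:
    rows = []
    for t, m in enumerate(corrs):
        for i in range(m.n_points):
            dx, dy = m.displacement_vectors[i]
            rows.append((t, m.source_indices[i], m.target_indices[i], dx, dy, m.flags[i]))
    return pd.DataFrame(
        rows, columns=["frame_index", "source_param", "target_param", "dx_um", "dy_um", "flag"]
    )


def _detect_all(movie: TwoChannelMovie, config: RunConfig) -> list[Contour]:
    if config.detect_channel == "acceptor":
        stacks = movie.acceptor_frames
    elif config.detect_channel == "donor":
        stacks = movie.donor_frames
    else:
        stacks = movie.acceptor_frames + movie.donor_frames
    contours = []
    for i, frame in enumerate(stacks):
        c = detect_boundary(
            frame, k=config.k, seed=config.seed, pixel_size=movie.pixel_size,
            min_area=config.min_area, frame_index=i,
        )
        c = c.roll_to_top() if i == 0 else c.roll_to(contours[-1].points[0])
        contours.append(c)
    return contours


def _load_cached_contours(outdir) -> list[Contour] | None:
    path = Path(outdir) / "contours.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    contours = []
    for idx, sub in df.groupby("frame_index", sort=True):
        contours.append(Contour(sub[["x_um", "y_um"]].to_numpy(float), int(idx)))
    return contours or None


def analyze_movie(
    movie: TwoChannelMovie, config: RunConfig, outdir=None, resume: bool = False
) -> PipelineResult:
    """Run the full analysis on an in-memory two-channel movie.

    With ``resume=True`` and an ``outdir`` containing a previous run's
    ``contours.csv``, detection is skipped and the cached contours reused.
    """
    config.validate()
    t0 = time.time()
    stage = "ratio"
    try:
        corrected = subtract_background(movie, config.background_percentile)
        ratio = compute_ratio(corrected, config.min_intensity)
        if config.median_radius > 0:
            from scipy.ndimage import median_filter

            sm = np.empty_like(ratio.ratio_frames)
            r = config.median_radius
            for i, fr in enumerate(ratio.ratio_frames):
                sm[i] = median_filter(np.nan_to_num(fr, nan=0.0), size=2 * r + 1)
                sm[i][~ratio.valid_mask[i]] = np.nan
            ratio = RatioMovie(sm, ratio.valid_mask)
        log.info("ratio stage done in %.1fs", time.time() - t0)

        stage = "detect"
        contours = _load_cached_contours(outdir) if (resume and outdir) else None
        if contours is not None and len(contours) != movie.n_frames:
            contours = None
        if contours is None:
            # detection runs on the raw channel: clipping during background
            # subtraction distorts the intensity layers the clustering relies on
            contours = _detect_all(movie, config)
        log.info("detected %d contours", len(contours))

        stage = "track"
        shape = movie.donor_frames.shape[1:]
        h = movie.pixel_size
        correspondences = []
        n_flagged = 0
        for t in range(len(contours) - 1):
            inter = evolve(
                contours[t], contours[t + 1], config.n_intermediate,
                shape=shape, grid_spacing=h, max_steps=config.max_evolve_steps,
            )
            m = correspond(contours[t], inter, contours[t + 1], ref_spacing=config.ref_spacing)
            n_flagged += int(np.sum(m.flags != "normal"))
            correspondences.append(m)
        log.info("tracking done in %.1fs (%d corrected matches)", time.time() - t0, n_flagged)

        stage = "sample"
        perim0 = contours[0].perimeter
        n_win = int(np.floor(perim0 / config.width))
        edges = np.arange(n_win) / n_win
        arc_positions = (edges + 0.5 / n_win) * perim0
        ratio_samples = []
        disp_cols = []
        interval_list = []
        for t, c in enumerate(contours):
            interval_list.append(edges)
            field_t = signed_distance(c, shape, h)
            band = build_band(c, field_t, config.depth)
            windows = windows_from_intervals(c, band, edges, h)
            ratio_samples.append(
                sample_ratio(windows, ratio.ratio_frames[t], ratio.valid_mask[t])
            )
            if t < len(correspondences):
                d, _ = window_displacement(edges, correspondences[t], c)
                disp_cols.append(d)
                edges = map_interval_edges(edges, correspondences[t])
        disp = np.column_stack(disp_cols)
        transloc_map = integrate_translocation(
            disp, movie.release_index, arc_positions=arc_positions, frame_times=movie.frame_times
        )
        ratio_map = assemble_map(ratio_samples, movie.frame_times, arc_positions, kind="ratio")
        log.info("sampling done in %.1fs (%d windows)", time.time() - t0, n_win)

        stage = "classify"
        labeling = classify_regions(
            transloc_map, config.threshold_fraction, config.min_region_windows
        )
        cell_class = labeling.cell_class

        stage = "correlate"
        post = movie.frame_times[movie.frame_times >= 0]
        max_lag = config.max_lag if config.max_lag is not None else float(post[-1] - post[0]) / 2
        norms = global_sigmas(ratio_map, transloc_map)
        lag_axis, cc_matrix, cc_results = cc_map(ratio_map, transloc_map, norms, max_lag)
        minima_rows = []
        for w, res in enumerate(cc_results):
            if res is None:
                minima_rows.append((w, labeling.window_labels[w], np.nan, np.nan, True))
            else:
                mv, mo = extract_minimum(res)
                minima_rows.append((w, labeling.window_labels[w], mv, mo, res.no_negative_minimum))
        cc_minima = pd.DataFrame(
            minima_rows, columns=["window", "label", "min_value", "min_lag_min", "no_negative_minimum"]
        )
        max_shift = config.max_shift if config.max_shift is not None else max(4, n_win // 4)
        s_norms = spatial_sigmas(ratio_map, transloc_map)
        shift_axis, s_matrix, _ = spatial_cc_map(ratio_map, transloc_map, s_norms, max_shift)

        stage = "stats"
        p_lags = cc_minima.loc[
            (cc_minima.label == "P") & ~cc_minima.no_negative_minimum, "min_lag_min"
        ].to_numpy()
        summary = {
            "cell_class": cell_class,
            "n_windows": int(n_win),
            "n_regions": labeling.n_regions,
            "peak_translocation_um": float(np.nanmax(transloc_map.values)),
            "n_corrected_matches": int(n_flagged),
        }
        if len(p_lags) >= 2:
            m, lo, hi = bootstrap_mean(p_lags, config.n_boot, config.seed)
            summary["p_region_lag_mean_min"] = m
            summary["p_region_lag_ci95"] = [lo, hi]
        result = PipelineResult(
            config=config,
            contours=contours,
            correspondences=correspondences,
            ratio_map=ratio_map,
            transloc_map=transloc_map,
            labeling=labeling,
            cell_class=cell_class,
            temporal_lags=lag_axis,
            temporal_cc_matrix=cc_matrix,
            cc_minima=cc_minima,
            spatial_shifts=shift_axis,
            spatial_cc_matrix=s_matrix,
            summary=summary,
            manifest={
                "version": __version__,
                "config": {k: (v if not isinstance(v, np.generic) else v.item())
                           for k, v in asdict(config).items()},
                "runtime_s": round(time.time() - t0, 2),
            },
        )
        if outdir is not None:
            result.export(outdir)
        return result
    except FretrackError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def run_pipeline(config: RunConfig, donor_path, acceptor_path, outdir=None) -> PipelineResult:
    """Load a two-channel TIFF pair and run :func:`analyze_movie`."""
    movie = load_stack(
        donor_path, acceptor_path, config.pixel_size, config.frame_interval, config.release_index
    )
    return analyze_movie(movie, config, outdir=outdir)


def run_synthetic(scenario_name: str, seed: int, outdir) -> dict:
    """Generate a registered scenario and write movie/maps + truth files."""
    if scenario_name not in synthetic.SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario_name!r}")
    sc = synthetic.SCENARIOS[scenario_name]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    if sc.level == "map":
        if sc.n_cells == 1:
            cells = [synthetic.generate_maps(sc, seed)]
        else:
            cells = synthetic.generate_ensemble(sc, seed)
        for c, (ratio_map, transloc_map, truth) in enumerate(cells):
            tag = f"_cell{c}" if len(cells) > 1 else ""
            ratio_map.to_frame().to_csv(out / f"ratio_map{tag}.csv", index=False)
            transloc_map.to_frame().to_csv(out / f"translocation_map{tag}.csv", index=False)
            (out / f"truth{tag}.json").write_text(json.dumps(truth, indent=2))
        written["cells"] = len(cells)
    else:
        movie, contours, truth = synthetic.generate_movie(sc, seed)
        save_stack(movie, out / "donor.tif", out / "acceptor.tif")
        _contours_frame(contours).to_csv(out / "truth_contours.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        (out / "config.yaml").write_text(
            yaml.safe_dump(
                {
                    "pixel_size_um": sc.pixel_size,
                    "frame_interval_min": sc.frame_interval,
                    "release_index": sc.release_index,
                }
            )
        )
        written["frames"] = sc.n_frames
    (out / "manifest.json").write_text(
        json.dumps({"scenario": scenario_name, "seed": seed, "version": __version__}, indent=2)
    )
    written["outdir"] = str(out)
    return written
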