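"""Two-channel stack I/O, background correction and ratio computation.

The FRET readout is the donor/acceptor (ECFP/FRET) emission ratio computed
pixelwise after per-frame background subtraction.  Low-signal pixels, where
the quotient would be dominated by noise, are masked out rather than set to
zero: :class:`RatioMovie` carries NaN at invalid pixels plus an explicit
boolean validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

from .errors import ConfigError, FormatError

__all__ = [
    "TwoChannelMovie",
    "RatioMovie",
    "load_stack",
    "save_stack",
    "subtract_background",
    "estimate_background_sd",
    "compute_ratio",
]


@dataclass
class TwoChannelMovie:
    """Donor (ECFP) and acceptor (FRET) intensity stacks with timing metadata.

    ``frame_times`` are minutes relative to constraint release (release at
    t = 0); ``release_index`` is the frame at which the confining membrane
    was peeled off.
    """

    donor_frames: np.ndarray      # (T, H, W) arbitrary units
    acceptor_frames: np.ndarray   # (T, H, W)
    pixel_size: float             # um / pixel
    frame_times: np.ndarray       # minutes, release at 0
    release_index: int

    def __post_init__(self):
        d = np.asarray(self.donor_frames, float)
        a = np.asarray(self.acceptor_frames, float)
        if d.shape != a.shape or d.ndim != 3:
            raise FormatError(f"channel shapes differ: {d.shape} vs {a.shape}")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        t = np.asarray(self.frame_times, float)
        if len(t) != len(d) or np.any(np.diff(t) <= 0):
            raise ConfigError("frame_times must be strictly increasing, one per frame")
        if not 0 <= self.release_index < len(d):
            raise ConfigError("release_index out of range")
        self.donor_frames, self.acceptor_frames, self.frame_times = d, a, t

    @property
    def n_frames(self) -> int:
        return len(self.donor_frames)

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass
class RatioMovie:
    """Dimensionless donor/acceptor ratio stack with per-pixel validity.

    Invalid pixels hold NaN (never a silent zero) and ``valid_mask`` is
    False there.
    """

    ratio_frames: np.ndarray  # (T, H, W), NaN where invalid
    valid_mask: np.ndarray    # (T, H, W) bool


def load_stack(
    donor_path,
    acceptor_path,
    pixel_size: float,
    frame_interval: float,
    release_index: int,
) -> TwoChannelMovie:
    """Read two multi-page TIFFs into a :class:`TwoChannelMovie`.

    Frame times are reconstructed as ``(index - release_index) * frame_interval``.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ConfigError("pixel_size and frame_interval must be positive")
    try:
        donor = np.asarray(tifffile.imread(donor_path), float)
        acceptor = np.asarray(tifffile.imread(acceptor_path), float)
    except (OSError, ValueError) as exc:
        raise FormatError(f"could not decode TIFF stacks: {exc}") from exc
    if donor.ndim == 2:
        donor = donor[None]
    if acceptor.ndim == 2:
        acceptor = acceptor[None]
    if donor.shape != acceptor.shape:
        raise FormatError(f"stack shapes differ: {donor.shape} vs {acceptor.shape}")
    times = (np.arange(len(donor)) - release_index) * frame_interval
    return TwoChannelMovie(donor, acceptor, pixel_size, times, release_index)


def save_stack(movie: TwoChannelMovie, donor_path, acceptor_path) -> None:
    """Write both channels as 32-bit float multi-page TIFFs (lossless)."""
    tifffile.imwrite(donor_path, movie.donor_frames.astype(np.float32))
    tifffile.imwrite(acceptor_path, movie.acceptor_frames.astype(np.float32))


def subtract_background(movie: TwoChannelMovie, percentile: float = 0.05) -> TwoChannelMovie:
    """Subtract a per-frame, per-channel low-percentile background.

    The cell occupies a minority of the field of view, so a low percentile
    (default 5th) of the whole frame tracks the camera/medium background
    without requiring a prior segmentation.  Negative residuals are clipped
    to zero.
    """
    if not 0 < percentile < 0.5:
        raise ConfigError("background percentile must lie in (0, 0.5)")

    def _sub(frames):
        bg = np.quantile(frames, percentile, axis=(1, 2), keepdims=True)
        return np.clip(frames - bg, 0.0, None)

    return replace(
        movie,
        donor_frames=_sub(movie.donor_frames),
        acceptor_frames=_sub(movie.acceptor_frames),
    )


def estimate_background_sd(movie: TwoChannelMovie, fraction: float = 0.2) -> float:
    """Spread of the dim (background) pixels of the acceptor channel.

    Per frame, the standard deviation of the dimmest ``fraction`` of pixels
    is computed; the median over frames is returned.  Used to derive the
    default ratio intensity threshold (3 x background SD).
    """
    sds = []
    for frame in movie.acceptor_frames:
        cut = np.quantile(frame, fraction)
        low = frame[frame <= cut]
        sds.append(np.std(low) if low.size else 0.0)
    return float(np.median(sds))


def compute_ratio(movie: TwoChannelMovie, min_intensity: float | None = None) -> RatioMovie:
    """Pixelwise donor/acceptor ratio, masked where the acceptor is dim.

    Pixels with acceptor intensity below ``min_intensity`` (default: three
    times the post-subtraction background standard deviation) are marked
    invalid — low-signal quotients are unstable, and only
    biosensor-expressing regions should be quantified.
    """
    if min_intensity is None:
        min_intensity = 3.0 * estimate_background_sd(movie)
        min_intensity = max(min_intensity, np.finfo(float).tiny)
    if min_intensity <= 0:
        raise ConfigError("min_intensity must be positive")
    acc = movie.acceptor_frames
    valid = acc >= min_intensity
    ratio = np.full(acc.shape, np.nan)
    np.divide(movie.donor_frames, acc, out=ratio, where=valid)
    valid &= np.isfinite(ratio) & (ratio > 0)
    ratio[~valid] = np.nan
    return RatioMovie(ratio, valid)


def save_ratio(ratio: RatioMovie, ratio_path, mask_path) -> None:
    """Write the ratio stack (float32) and validity mask (uint8) as TIFFs."""
    tifffile.imwrite(ratio_path, ratio.ratio_frames.astype(np.float32))
    tifffile.imwrite(mask_path, ratio.valid_mask.astype(np.uint8))
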