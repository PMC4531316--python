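"""Group statistics: bootstrap means, Welch t-tests, baseline normalization.

Window time courses pooled across cells by region type (P vs NP) and phase
(pre- vs post-release) are compared with bootstrap confidence intervals of
the mean (percentile method, 5000 resamples by default) and Welch
unequal-variance t-tests.  Windows are the sampling unit; per-cell
pseudo-replication is not corrected (a caveat documented in the methods
note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import StatsError

__all__ = ["GroupSample", "bootstrap_mean", "compare_groups", "normalize_timecourse"]


@dataclass
class GroupSample:
    """A pooled sample of per-window scalars with provenance."""

    values: np.ndarray
    group: str = ""          # "P" | "NP"
    phase: str = ""          # "pre-release" | "post-release"
    cell_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, float).ravel()
        if v.size == 0:
            raise StatsError("empty group sample")
        self.values = v
        if self.cell_ids is None:
            self.cell_ids = np.zeros(v.size, dtype=int)


def bootstrap_mean(
    sample: GroupSample | np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, float, float]:
    """Mean with a percentile bootstrap confidence interval.

    Resamples the values with replacement ``n_boot`` times (deterministic
    given ``seed``) and returns ``(mean, lower, upper)``.
    """
    values = sample.values if isinstance(sample, GroupSample) else np.asarray(sample, float)
    n = len(values)
    if n < 2:
        raise StatsError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (100.0 - ci) / 2
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def compare_groups(
    a: GroupSample | np.ndarray,
    b: GroupSample | np.ndarray,
    tails: str = "two",
) -> float:
    """Welch unequal-variance t-test p-value between two samples.

    ``tails="one"`` tests the directional hypothesis mean(a) > mean(b);
    ``tails="two"`` is two-sided.  Two zero-variance samples with equal
    means return p = 1 (no evidence of difference).
    """
    va = a.values if isinstance(a, GroupSample) else np.asarray(a, float)
    vb = b.values if isinstance(b, GroupSample) else np.asarray(b, float)
    if len(va) < 2 or len(vb) < 2:
        raise StatsError("both samples need n >= 2")
    if va.std() == 0 and vb.std() == 0:
        return 1.0 if va.mean() == vb.mean() else 0.0
    alternative = {"two": "two-sided", "one": "greater"}.get(tails)
    if alternative is None:
        raise StatsError(f"tails must be 'one' or 'two', got {tails!r}")
    res = sps.ttest_ind(va, vb, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def normalize_timecourse(series: np.ndarray, baseline_frames) -> np.ndarray:
    """Divide a time course by its pre-release baseline mean.

    ``baseline_frames`` is an index range (anything ``series[...]``
    accepts).  The normalized baseline is ~1 by construction.
    """
    series = np.asarray(series, float)
    base = series[baseline_frames]
    if np.asarray(base).size == 0:
        raise StatsError("baseline range is empty")
    m = np.nanmean(base)
    if not np.isfinite(m) or m <= 0:
        raise StatsError(f"baseline mean must be positive, got {m}")
    return series / m
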