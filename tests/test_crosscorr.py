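"""Globally normalized temporal and spatial cross-correlation."""

import numpy as np
import pytest

from fretrack.crosscorr import (
    CCResult,
    GlobalNorms,
    cc_map,
    extract_minimum,
    global_sigmas,
    spatial_cc,
    spatial_cc_map,
    spatial_sigmas,
    temporal_cc,
)
from fretrack.errors import StatsError
from fretrack.stmap import SpatioTemporalMap


def _own_norms(s, b):
    return GlobalNorms(
        float(np.std(s - np.mean(s))), float(np.std(b - np.mean(b))),
        np.array([np.mean(s)]), np.array([np.mean(b)]),
    )


def _maps(svals, bvals, release=0):
    n_w, n_t = svals.shape
    times = np.arange(n_t, dtype=float) - release
    arc = np.arange(n_w, dtype=float)
    return (
        SpatioTemporalMap(svals, arc, times, kind="ratio"),
        SpatioTemporalMap(bvals, arc, times, kind="translocation"),
    )


def _sigmoid_series(n=30, mid=12.0, k=1.0):
    t = np.arange(n, dtype=float)
    return 1.0 / (1.0 + np.exp(-(t - mid) / k))


# -- norms -----------------------------------------------------------------

def test_global_sigmas_take_the_maximum_row_sd():
    s = np.vstack([np.linspace(0, 0.1, 10), np.linspace(0, 0.3, 10)])
    b = np.vstack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
    norms = global_sigmas(*_maps(s, b))
    assert norms.sigma_s_max == pytest.approx(np.std(s[1] - s[1].mean()))
    assert norms.sigma_b_max == pytest.approx(np.std(b[1] - b[1].mean()))


def test_global_sigmas_match_brute_force_over_rows():
    rng = np.random.default_rng(8)
    s = rng.normal(1, 0.2, (12, 25))
    b = rng.normal(0, 3, (12, 25))
    norms = global_sigmas(*_maps(s, b))
    assert norms.sigma_s_max == pytest.approx(max(np.std(r - r.mean()) for r in s))
    assert norms.sigma_b_max == pytest.approx(max(np.std(r - r.mean()) for r in b))


def test_all_constant_maps_are_degenerate():
    with pytest.raises(StatsError):
        global_sigmas(*_maps(np.ones((4, 10)), np.full((4, 10), 2.0)))


# -- temporal CC -----------------------------------------------------------

def test_perfect_anticorrelation_at_zero_lag():
    s = _sigmoid_series()
    b = -s
    res = temporal_cc(s, b, _own_norms(s, b), max_lag=10)
    assert res.min_offset == 0.0
    assert res.min_value == pytest.approx(-1.0, abs=1e-9)


def test_programmed_shift_is_recovered():
    delta = 4
    s = _sigmoid_series(n=40, mid=10.0, k=0.5)
    b = -np.concatenate([np.full(delta, s[0]), s[:-delta]])  # b(t) = -s(t - delta)
    res = temporal_cc(s, b, _own_norms(s, b), max_lag=10)
    # brute-force over all lags as the oracle
    sc, bc = s - s.mean(), b - b.mean()
    n = len(s)
    brute = {}
    for lag in range(-10, 11):
        if lag >= 0:
            x, y = sc[: n - lag], bc[lag:]
        else:
            x, y = sc[-lag:], bc[: n + lag]
        brute[lag] = np.mean(x * y)
    assert res.min_offset == min(brute, key=brute.get)
    assert res.min_offset == delta


def test_global_normalization_scales_coefficients_linearly():
    s = _sigmoid_series()
    b = -s + 0.1 * np.sin(np.arange(30))
    own = _own_norms(s, b)
    doubled = GlobalNorms(own.sigma_s_max * 2, own.sigma_b_max, own.mu_s, own.mu_b)
    r_own = temporal_cc(s, b, own, max_lag=8)
    r_glob = temporal_cc(s, b, doubled, max_lag=8)
    np.testing.assert_allclose(r_glob.values, r_own.values / 2)


def test_temporal_cc_matches_double_loop_oracle():
    rng = np.random.default_rng(17)
    s = rng.normal(0, 1, 20)
    b = rng.normal(0, 1, 20)
    norms = _own_norms(s, b)
    res = temporal_cc(s, b, norms, max_lag=7, min_overlap=5)
    mu_s, mu_b = s.mean(), b.mean()
    for lag, val in zip(res.offsets, res.values):
        lag = int(lag)
        acc, cnt = 0.0, 0
        for t in range(20):
            if 0 <= t + lag < 20:
                acc += (s[t] - mu_s) * (b[t + lag] - mu_b)
                cnt += 1
        expected = acc / cnt / (norms.sigma_s_max * norms.sigma_b_max)
        assert val == pytest.approx(expected, rel=1e-10)


def test_transpose_symmetry():
    rng = np.random.default_rng(3)
    s = rng.normal(0, 1, 24)
    b = rng.normal(0, 1, 24)
    norms = _own_norms(s, b)
    r1 = temporal_cc(s, b, norms, max_lag=8)
    r2 = temporal_cc(b, s, norms, max_lag=8)
    np.testing.assert_allclose(r1.values, r2.values[::-1], atol=1e-12)


def test_global_normalization_never_increases_magnitude():
    rng = np.random.default_rng(5)
    s_map = rng.normal(1, 0.2, (8, 30))
    b_map = rng.normal(0, 2, (8, 30))
    ratio_map, transloc_map = _maps(s_map, b_map)
    norms = global_sigmas(ratio_map, transloc_map)
    for w in range(8):
        own = _own_norms(s_map[w], b_map[w])
        r_own = temporal_cc(s_map[w], b_map[w], own, max_lag=6)
        r_glob = temporal_cc(s_map[w], b_map[w], norms, max_lag=6)
        assert np.all(np.abs(r_glob.values) <= np.abs(r_own.values) + 1e-12)


def test_short_overlap_lags_are_omitted():
    s = np.arange(12, dtype=float)
    b = -s
    res = temporal_cc(s, b, _own_norms(s, b), max_lag=11, min_overlap=5)
    far = np.abs(res.offsets) > 7
    assert np.isnan(res.values[far]).all()


# -- spatial CC ------------------------------------------------------------

def _spatial_norms(line_s, line_b):
    return GlobalNorms(
        float(np.std(line_s - line_s.mean())), float(np.std(line_b - line_b.mean())),
        np.array([line_s.mean()]), np.array([line_b.mean()]),
    )


def test_colocated_patterns_minimize_at_zero_shift():
    w = np.arange(32)
    s = 1.0 - 0.2 * np.exp(-((w - 16) ** 2) / 18)
    b = -s
    res = spatial_cc(s, b, _spatial_norms(s, b), max_shift=10)
    assert res.min_offset == 0.0


@pytest.mark.parametrize("k", range(1, 8))
def test_rotated_pattern_minimizes_at_the_rotation(k):
    w = np.arange(32)
    s = 1.0 - 0.2 * np.exp(-((w - 16) ** 2) / 18)
    b = -np.roll(s, -k)  # b(w) = -s(w + k) ... pattern rotated by -k
    res = spatial_cc(s, b, _spatial_norms(s, b), max_shift=10)
    # brute force over circular shifts
    sc, bc = s - s.mean(), b - b.mean()
    brute = {sh: np.mean(sc * np.roll(bc, -sh)) for sh in range(-10, 11)}
    assert res.min_offset == min(brute, key=brute.get)


def test_constant_line_gives_zero_coefficients():
    s = np.full(20, 1.3)
    b = np.sin(np.arange(20))
    norms = GlobalNorms(0.5, float(np.std(b - b.mean())), np.zeros(1), np.zeros(1))
    res = spatial_cc(s, b, norms, max_shift=6)
    np.testing.assert_allclose(res.values, 0.0, atol=1e-12)


# -- maps and minima -------------------------------------------------------

def test_cc_map_is_uniformly_most_negative_at_zero_lag_for_mirror_maps():
    s_map = np.tile(_sigmoid_series(), (6, 1))
    b_map = -s_map
    ratio_map, transloc_map = _maps(s_map + 0.001 * np.random.default_rng(0).normal(size=s_map.shape), b_map)
    norms = global_sigmas(ratio_map, transloc_map)
    lags, mat, _ = cc_map(ratio_map, transloc_map, norms, max_lag=8)
    zero_col = int(np.flatnonzero(lags == 0)[0])
    assert np.all(np.nanargmin(mat, axis=1) == zero_col)


def test_lagged_sector_confined_to_its_rows():
    n_t, delta = 40, 3
    base = _sigmoid_series(n=n_t, mid=15.0, k=1.0)
    lagged = np.concatenate([np.full(delta, base[0]), base[:-delta]])
    s_map = np.tile(base, (10, 1))
    b_map = np.vstack([-lagged if 3 <= w <= 6 else -base for w in range(10)])
    ratio_map, transloc_map = _maps(s_map, b_map)
    norms = global_sigmas(ratio_map, transloc_map)
    lags, mat, results = cc_map(ratio_map, transloc_map, norms, max_lag=10)
    for w, res in enumerate(results):
        expected = delta if 3 <= w <= 6 else 0
        assert res.min_offset == expected


def test_all_missing_row_stays_missing():
    s_map = np.tile(_sigmoid_series(), (4, 1))
    s_map[2] = np.nan
    b_map = -np.tile(_sigmoid_series(), (4, 1))
    ratio_map, transloc_map = _maps(s_map, b_map)
    norms = global_sigmas(ratio_map, transloc_map)
    lags, mat, results = cc_map(ratio_map, transloc_map, norms, max_lag=8)
    assert np.isnan(mat[2]).all()
    assert results[2] is None


def test_extract_minimum_basic_and_ties():
    r = CCResult(np.array([-2.0, 0, 2]), np.array([-0.2, -0.9, -0.4]), -0.9, 0.0)
    assert extract_minimum(r) == (-0.9, 0.0)
    from fretrack.crosscorr import _finalize

    tied = _finalize(np.array([-3.0, 0.0, 3.0]), np.array([-0.9, -0.5, -0.9]))
    assert tied.min_offset == 3.0  # positive offset wins the tie
    allpos = _finalize(np.array([-1.0, 0.0, 1.0]), np.array([0.2, 0.5, 0.3]))
    assert allpos.no_negative_minimum


def test_spatial_cc_map_stacks_time_steps():
    rng = np.random.default_rng(1)
    s_map = rng.normal(1, 0.1, (12, 6))
    b_map = rng.normal(0, 1, (12, 6))
    ratio_map, transloc_map = _maps(s_map, b_map)
    norms = spatial_sigmas(ratio_map, transloc_map)
    shifts, mat, results = spatial_cc_map(ratio_map, transloc_map, norms, max_shift=4)
    assert mat.shape == (6, 9)
    assert len(results) == 6
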