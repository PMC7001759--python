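"""Rate maps, Skaggs information, sparsity, coherence, fields, gridness,
border and gradient analyses."""

import numpy as np
import pytest

from spikespatial import spatial_maps as sm
from spikespatial import synthetic as syn
from spikespatial.errors import (InsufficientDataError,
                                 UndefinedStatisticError)
from spikespatial.io_session import SpatialTrack, SpikeTrain

from conftest import GRID_GT, PLACE_GT


def make_map(rate, occupancy=None):
    """RateMap from explicit arrays (analytic and random-map oracles)."""
    rate = np.asarray(rate, dtype=float)
    occ = (np.ones_like(rate) if occupancy is None
           else np.asarray(occupancy, dtype=float))
    return sm.RateMap(occupancy=occ, bin_size=3.0, origin=(0.0, 0.0),
                      rate=rate, rate_unsmoothed=rate, visited=occ > 0)


def brute_force_skaggs(rate, occ):
    """Independent direct-summation oracle."""
    p = occ / occ.sum()
    mean = (p * rate).sum()
    total = 0.0
    for pi, li in zip(p.ravel(), rate.ravel()):
        if li > 0:
            total += pi * (li / mean) * np.log2(li / mean)
    return total


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_occupancy_stationary_animal():
    t = np.arange(0, 60, 0.02)
    track = SpatialTrack(t, np.full(t.size, 1.0), np.full(t.size, 1.0),
                         np.zeros(t.size))
    occ = sm.occupancy_map(track, bin_size=3.0)
    assert occ.occupancy.max() == pytest.approx(60.0, abs=track.dt)
    assert occ.occupancy.sum() == pytest.approx(60.0, abs=track.dt)


def test_occupancy_conserves_duration(track600):
    occ = sm.occupancy_map(track600)
    assert occ.occupancy.sum() == pytest.approx(track600.duration,
                                                abs=track600.dt)


def test_occupancy_uniform_sweep():
    """Uniform sweep across 4 bins: equal dwell to within one sample."""
    t = np.arange(0, 48, 0.02)
    x = np.linspace(0, 11.999, t.size)
    track = SpatialTrack(t, x, np.zeros(t.size), np.zeros(t.size))
    occ = sm.occupancy_map(track, bin_size=3.0)
    col = occ.occupancy[:, 0]
    oracle, _ = np.histogram(x, bins=np.arange(0, 15, 3.0))
    np.testing.assert_allclose(col[:4], oracle[:4] * track.dt)
    assert col[:4].max() - col[:4].min() <= 2 * track.dt


# ---------------------------------------------------------------------------
# rate map
# ---------------------------------------------------------------------------

def test_rate_map_uniform_unit(track600, uniform_train):
    rmap = sm.rate_map(uniform_train, track600)
    rates = rmap.rate[rmap.visited]
    true = uniform_train.n_spikes / track600.duration
    # smoothed estimate: the large majority of visited bins within +/-20%
    assert np.mean(np.abs(rates - true) / true < 0.2) > 0.85
    assert np.nanmean(rates) == pytest.approx(true, rel=0.05)


def test_rate_map_zero_spikes(track600):
    train = SpikeTrain(np.empty(0), track600.duration)
    rmap = sm.rate_map(train, track600)
    assert np.nanmax(rmap.rate) == 0.0


def test_rate_map_place_cell_peak_location(track600, place_train):
    rmap = sm.rate_map(place_train, track600)
    pk = np.unravel_index(np.nanargmax(np.nan_to_num(rmap.rate)),
                          rmap.shape)
    cx, cy = rmap.bin_centres()
    err = np.hypot(cx[pk[0]] - PLACE_GT.centre[0],
                   cy[pk[1]] - PLACE_GT.centre[1])
    assert err <= 2 * rmap.bin_size


def test_rate_map_conserves_spike_count(track600, place_train):
    rmap = sm.rate_map(place_train, track600)
    in_period = np.sum((place_train.timestamps >= track600.t[0])
                       & (place_train.timestamps <= track600.t[-1]))
    assert int(rmap.counts.sum()) == in_period


# ---------------------------------------------------------------------------
# Skaggs information and sparsity
# ---------------------------------------------------------------------------

def test_skaggs_uniform_is_zero():
    assert sm.skaggs_information(make_map(np.full((8, 8), 3.0))) \
        == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n", [2, 4, 16])
def test_skaggs_single_bin_log2n(n):
    rate = np.zeros((n, 1))
    rate[0, 0] = 5.0
    assert sm.skaggs_information(make_map(rate)) == pytest.approx(
        np.log2(n), abs=1e-12)


def test_skaggs_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        rate = rng.gamma(2.0, 2.0, size=(12, 12))
        occ = rng.uniform(0.5, 3.0, size=(12, 12))
        m = make_map(rate, occ)
        assert sm.skaggs_information(m) == pytest.approx(
            brute_force_skaggs(rate, occ), abs=1e-12)


def test_skaggs_nonnegative_property():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = make_map(rng.gamma(1.5, 2.0, size=(10, 10)))
        assert sm.skaggs_information(m) >= -1e-12


def test_skaggs_zero_rate_undefined():
    with pytest.raises(UndefinedStatisticError):
        sm.skaggs_information(make_map(np.zeros((4, 4))))


def test_sparsity_uniform_is_one():
    assert sm.sparsity(make_map(np.full((6, 6), 2.0))) == pytest.approx(1.0)


def test_sparsity_single_active_bin():
    rate = np.zeros((4, 4))
    rate[2, 2] = 8.0
    assert sm.sparsity(make_map(rate)) == pytest.approx(1.0 / 16)


def test_sparsity_matches_brute_force():
    rng = np.random.default_rng(11)
    rate = rng.gamma(2.0, 2.0, size=(10, 10))
    occ = rng.uniform(0.5, 3.0, size=(10, 10))
    p = occ / occ.sum()
    oracle = (p * rate).sum() ** 2 / (p * rate ** 2).sum()
    assert sm.sparsity(make_map(rate, occ)) == pytest.approx(oracle,
                                                             abs=1e-12)


# ---------------------------------------------------------------------------
# spatial coherence
# ---------------------------------------------------------------------------

def test_coherence_smooth_gradient_high():
    gx, gy = np.meshgrid(np.arange(20.0), np.arange(20.0), indexing="ij")
    m = make_map(gx + gy)
    assert sm.spatial_coherence(m) > 0.9


def test_coherence_iid_noise_low():
    rng = np.random.default_rng(5)
    rs = [sm.spatial_coherence(make_map(rng.uniform(0, 10, (40, 40))))
          for _ in range(10)]
    assert np.all(np.abs(rs) < 0.1)


def test_coherence_constant_map_undefined():
    with pytest.raises(UndefinedStatisticError):
        sm.spatial_coherence(make_map(np.full((5, 5), 2.0)))


# ---------------------------------------------------------------------------
# place field
# ---------------------------------------------------------------------------

def test_place_field_centroid_recovery(track600, place_train):
    rmap = sm.rate_map(place_train, track600)
    f = sm.detect_place_field(rmap, threshold_frac=0.2)
    assert f is not None
    err = np.hypot(f.centroid[0] - PLACE_GT.centre[0],
                   f.centroid[1] - PLACE_GT.centre[1])
    assert err <= rmap.bin_size


def test_place_field_keeps_higher_peak_only():
    rate = np.zeros((20, 20))
    rate[3:6, 3:6] = 10.0   # higher, left
    rate[14:17, 14:17] = 6.0
    f = sm.detect_place_field(make_map(rate), threshold_frac=0.2, min_bins=4)
    assert np.all(f.bins[:, 0] < 10)
    assert f.peak_rate == 10.0


def test_place_field_flat_map_none():
    assert sm.detect_place_field(make_map(np.zeros((8, 8)))) is None


# ---------------------------------------------------------------------------
# spatial autocorrelation and gridness
# ---------------------------------------------------------------------------

def test_autocorr_unity_at_zero_offset(track600, place_train):
    ac = sm.spatial_autocorrelation(sm.rate_map(place_train, track600))
    ci, cj = ac.centre
    assert ac.values[ci, cj] == pytest.approx(1.0, abs=1e-9)


def test_autocorr_striped_map_period():
    gx = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")[0]
    rate = (gx % 6 == 0).astype(float) * 5.0
    ac = sm.spatial_autocorrelation(make_map(rate))
    ci, cj = ac.centre
    row = ac.values[:, cj]
    off = np.arange(row.size) - ci
    assert row[off == 6][0] == pytest.approx(1.0, abs=1e-9)
    assert row[off == -6][0] == pytest.approx(1.0, abs=1e-9)
    between = row[(np.abs(off) > 0) & (np.abs(off) < 6)]
    assert np.nanmax(between) < 0.5


def test_autocorr_symmetric_under_negation(track600, grid_train):
    ac = sm.spatial_autocorrelation(sm.rate_map(grid_train, track600))
    v = ac.values
    flipped = v[::-1, ::-1]
    both = np.isfinite(v) & np.isfinite(flipped)
    np.testing.assert_allclose(v[both], flipped[both], atol=1e-9)


@pytest.fixture(scope="module")
def grid_autocorr(track600, grid_train):
    return sm.spatial_autocorrelation(sm.rate_map(grid_train, track600))


def test_grid_cell_six_peaks_at_spacing(grid_autocorr):
    g = sm.grid_score(grid_autocorr)
    assert not g.low_confidence
    assert len(g.peak_radii) == 6
    np.testing.assert_allclose(np.median(g.peak_radii), GRID_GT.spacing,
                               rtol=0.1)


def test_gridness_recovery_and_contrast(track600, grid_train, place_train):
    g_grid = sm.grid_score(sm.spatial_autocorrelation(
        sm.rate_map(grid_train, track600)))
    g_place = sm.grid_score(sm.spatial_autocorrelation(
        sm.rate_map(place_train, track600)))
    assert g_grid.gridness > 0.4
    assert g_grid.spacing == pytest.approx(GRID_GT.spacing, rel=0.1)
    assert g_place.gridness < 0.2
    assert g_grid.gridness > g_place.gridness


def test_ideal_hexagon_sixty_degree_symmetry(grid_autocorr):
    """Rotating the grid autocorrelogram by 60 deg nearly reproduces it."""
    g = sm.grid_score(grid_autocorr)
    assert g.rotation_correlations[60] > 0.9
    assert g.rotation_correlations[120] > 0.9
    assert g.rotation_correlations[60] > g.rotation_correlations[30]


# ---------------------------------------------------------------------------
# border and gradient
# ---------------------------------------------------------------------------

def test_hull_area_close_to_arena(track600):
    boundary = sm.estimate_border(track600)
    assert sm.polygon_area(boundary) == pytest.approx(100.0 ** 2, rel=0.05)


def test_border_cell_negative_correlation(track600, border_train):
    rmap = sm.rate_map(border_train, track600)
    model = sm.border_analysis(rmap, sm.estimate_border(track600))
    assert model.correlation < -0.8


def test_uniform_unit_no_border_correlation(track600, uniform_train):
    rmap = sm.rate_map(uniform_train, track600)
    model = sm.border_analysis(rmap, sm.estimate_border(track600))
    assert abs(model.correlation) < 0.2


def test_gompertz_noiseless_recovery():
    d = np.arange(0.0, 50.0, 2.0)
    rates = 10.0 * np.exp(-5.0 * np.exp(-0.3 * d))
    model = sm.BorderModel(boundary=np.zeros((4, 2)),
                           bin_distance=np.zeros((2, 2)),
                           distance_centres=d, distance_rates=rates,
                           distance_occupancy=np.ones(d.size),
                           correlation=0.0)
    fit = sm.gradient_fit(model)
    assert fit["a"] == pytest.approx(10.0, rel=1e-6)
    assert fit["b"] == pytest.approx(5.0, rel=1e-6)
    assert fit["c"] == pytest.approx(0.3, rel=1e-6)
    assert fit["inflection_cm"] == pytest.approx(np.log(5.0) / 0.3, rel=1e-6)


def test_gompertz_constant_curve_flagged():
    d = np.arange(0.0, 30.0, 2.0)
    model = sm.BorderModel(boundary=np.zeros((4, 2)),
                           bin_distance=np.zeros((2, 2)),
                           distance_centres=d,
                           distance_rates=np.full(d.size, 4.0),
                           distance_occupancy=np.ones(d.size),
                           correlation=0.0)
    fit = sm.gradient_fit(model)
    assert not fit["is_gradient"]


def test_gradient_cell_good_fit(track600):
    """A unit whose rate rises away from the wall is well fit by Gompertz."""
    gt_curve = lambda dist: 12.0 * np.exp(-4.0 * np.exp(-0.25 * dist))

    def rate_fn(track):
        return gt_curve(track.channel("border_distance"))
    rate_fn.max_rate = 12.0
    train = syn.simulate_from_rate(track600, rate_fn, seed=31)
    rmap = sm.rate_map(train, track600)
    model = sm.border_analysis(rmap, sm.estimate_border(track600))
    fit = sm.gradient_fit(model)
    assert fit["r_squared"] > 0.9
    assert fit["is_gradient"]
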