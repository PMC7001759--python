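"""Head-direction/speed/AHV tuning, circular statistics, distributive
prediction, weighted linear fits."""

import numpy as np
import pytest

from spikespatial import spatial_maps as sm
from spikespatial import synthetic as syn
from spikespatial import tuning_1d as t1
from spikespatial.errors import (InsufficientDataError, InvalidArgumentError,
                                 UndefinedStatisticError)
from spikespatial.io_session import SpikeTrain

from conftest import HD_GT, PLACE_GT, SPEED_GT


def make_hd_curve(rate):
    rate = np.asarray(rate, dtype=float)
    nb = rate.size
    width = 360.0 / nb
    return t1.TuningCurve(centres=(np.arange(nb) + 0.5) * width, rate=rate,
                          occupancy=np.ones(nb), counts=rate.copy(),
                          variable="hd", bin_width=width, circular=True,
                          spike_count=int(rate.sum()))


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def test_hd_curve_peak_near_preferred(track600, hd_train):
    curve = t1.tuning_curve(hd_train, track600, "hd")
    stats = t1.circular_stats(curve)
    err = abs((stats.mean_direction - HD_GT.preferred_direction + 180)
              % 360 - 180)
    assert err <= 5.0
    peak_err = abs((stats.preferred_direction - HD_GT.preferred_direction
                    + 180) % 360 - 180)
    assert peak_err <= 4 * curve.bin_width  # broad kappa=2 curve: noisy peak


def test_uniform_unit_flat_hd_curve(track600, uniform_train):
    curve = t1.tuning_curve(uniform_train, track600, "hd")
    mean = curve.mean_rate
    ok = curve.occupancy > 1.0
    dev = np.abs(curve.rate[ok] - mean) / mean
    assert np.mean(dev < 0.25) > 0.95  # Poisson scatter only


def test_no_spikes_zero_curve(track600):
    train = SpikeTrain(np.empty(0), track600.duration)
    curve = t1.tuning_curve(train, track600, "hd")
    assert np.nansum(curve.rate) == 0.0


def test_unknown_variable_rejected(track600, hd_train):
    with pytest.raises(InvalidArgumentError):
        t1.tuning_curve(hd_train, track600, "altitude")


def test_occupancy_bounded_by_duration(track600, hd_train):
    for var in ("hd", "speed", "ahv"):
        curve = t1.tuning_curve(hd_train, track600, var)
        assert curve.occupancy.sum() <= track600.duration + 1e-6


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def test_all_mass_one_direction():
    rate = np.zeros(72)
    rate[10] = 50.0
    stats = t1.circular_stats(make_hd_curve(rate))
    assert stats.resultant_length == pytest.approx(1.0)
    assert stats.rayleigh_z == pytest.approx(stats.resultant_length ** 2 * 50)
    assert stats.mean_direction == pytest.approx(52.5)


def test_rotation_invariance(track600, hd_train):
    """Rotating all directions by 90 deg rotates the mean direction and
    leaves R, Z and kappa unchanged."""
    curve = t1.tuning_curve(hd_train, track600, "hd")
    stats = t1.circular_stats(curve)
    rotated = make_hd_curve(np.roll(np.nan_to_num(curve.rate), 18))
    rotated.spike_count = curve.spike_count
    stats_rot = t1.circular_stats(rotated)
    assert stats_rot.resultant_length == pytest.approx(
        stats.resultant_length, abs=1e-9)
    assert stats_rot.kappa == pytest.approx(stats.kappa, abs=1e-9)
    assert (stats_rot.mean_direction - stats.mean_direction) % 360 \
        == pytest.approx(90.0, abs=1e-6)


def test_curve_resultant_matches_spike_resultant(track600, hd_train):
    """R from the rate-weighted curve agrees with R computed directly from
    per-spike directions within a bin-discretisation tolerance."""
    curve = t1.tuning_curve(hd_train, track600, "hd")
    R_curve = t1.circular_stats(curve).resultant_length
    ts = hd_train.timestamps
    spike_dirs = np.radians(t1.interp_channel(track600, ts, "hd"))
    R_spikes = np.abs(np.mean(np.exp(1j * spike_dirs)))
    assert R_curve == pytest.approx(R_spikes, abs=0.05)


def test_uniform_directions_rayleigh_size():
    """n = 2000 uniform directions: p > 0.01 in >= 95% of seeds."""
    ok = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        dirs = rng.uniform(0, 360, 2000)
        counts, _ = np.histogram(dirs, bins=np.arange(0, 361, 5.0))
        curve = make_hd_curve(counts.astype(float))
        ok += t1.circular_stats(curve).rayleigh_p > 0.01
    assert ok >= int(0.95 * n_seeds)


def test_kappa_recovery_from_von_mises_sample():
    """kappa = 2 sample of 2000 directions: estimate within 15%."""
    errs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        dirs = np.degrees(rng.vonmises(np.pi / 2, 2.0, size=2000)) % 360.0
        counts, _ = np.histogram(dirs, bins=np.arange(0, 361, 5.0))
        stats = t1.circular_stats(make_hd_curve(counts.astype(float)))
        errs.append(abs(stats.kappa - 2.0) / 2.0)
    assert np.median(errs) < 0.15
    assert np.all(np.array(errs) < 0.25)


def test_half_width_of_von_mises_curve():
    """Half-width (zero baseline) of an analytic von Mises curve matches the
    closed-form crossing of exp(kappa (cos d - 1)) = 1/2."""
    kappa = 4.0
    centres = (np.arange(72) + 0.5) * 5.0
    rate = 10 * np.exp(kappa * (np.cos(np.radians(centres - 180.0)) - 1.0))
    stats = t1.circular_stats(make_hd_curve(rate))
    expected = 2 * np.degrees(np.arccos(1 + np.log(0.5) / kappa))
    assert stats.half_width == pytest.approx(expected, abs=5.0)


def test_zero_rate_curve_undefined():
    with pytest.raises(UndefinedStatisticError):
        t1.circular_stats(make_hd_curve(np.zeros(72)))


# ---------------------------------------------------------------------------
# turning-direction split
# ---------------------------------------------------------------------------

def test_hd_split_symmetric_preference(track600, hd_train):
    split = t1.hd_by_rotation(hd_train, track600, ahv_threshold=30.0)
    assert split["cw"] is not None and split["ccw"] is not None
    p_cw = t1.circular_stats(split["cw"]).mean_direction
    p_ccw = t1.circular_stats(split["ccw"]).mean_direction
    delta = abs((p_cw - p_ccw + 180) % 360 - 180)
    assert delta <= 2 * split["cw"].bin_width


def test_hd_split_threshold_beyond_range(track600, hd_train):
    ahv_max = np.max(np.abs(track600.angular_velocity))
    split = t1.hd_by_rotation(hd_train, track600, ahv_threshold=ahv_max + 1)
    assert split["cw"] is None and split["ccw"] is None
    assert len(split["flags"]) == 2


def test_hd_split_dwell_conservation(track600, hd_train):
    thr = 30.0
    split = t1.hd_by_rotation(hd_train, track600, ahv_threshold=thr)
    dwell_cw = split["cw"].occupancy.sum()
    dwell_ccw = split["ccw"].occupancy.sum()
    excluded = np.sum(np.abs(track600.angular_velocity) <= thr) * track600.dt
    assert dwell_cw + dwell_ccw + excluded \
        == pytest.approx(track600.duration, abs=2 * track600.dt)


# ---------------------------------------------------------------------------
# distributive prediction
# ---------------------------------------------------------------------------

def test_uniform_map_predicts_constant(track600):
    nx = int(np.floor((track600.x.max() - track600.x.min()) / 3.0)) + 1
    ny = int(np.floor((track600.y.max() - track600.y.min()) / 3.0)) + 1
    rate = np.full((nx, ny), 4.0)
    rmap = sm.RateMap(occupancy=np.ones((nx, ny)), bin_size=3.0,
                      origin=(track600.x.min(), track600.y.min()),
                      rate=rate, rate_unsmoothed=rate,
                      visited=np.ones((nx, ny), bool))
    pred, _ = t1.expected_rate_from_place(rmap, track600, "hd")
    ok = np.isfinite(pred.rate)
    np.testing.assert_allclose(pred.rate[ok], 4.0, atol=1e-9)


def test_distributive_ratio_separates_place_from_hd(track600, place_train,
                                                    hd_train):
    """A place cell's apparent HD tuning is explained by the locational map
    (small ratio, positively correlated prediction); a genuine HD cell's is
    not (large ratio)."""
    rm_p = sm.rate_map(place_train, track600)
    obs_p = t1.tuning_curve(place_train, track600, "hd")
    pred_p, ratio_p = t1.expected_rate_from_place(rm_p, track600, "hd",
                                                  observed=obs_p)
    rm_h = sm.rate_map(hd_train, track600)
    obs_h = t1.tuning_curve(hd_train, track600, "hd")
    _, ratio_h = t1.expected_rate_from_place(rm_h, track600, "hd",
                                             observed=obs_h)
    assert ratio_p < 0.15
    assert ratio_h > 2 * ratio_p
    both = np.isfinite(pred_p.rate) & np.isfinite(obs_p.rate)
    assert np.corrcoef(pred_p.rate[both], obs_p.rate[both])[0, 1] > 0.2


# ---------------------------------------------------------------------------
# linear tuning
# ---------------------------------------------------------------------------

def test_speed_slope_recovery(track600, speed_train):
    curve = t1.tuning_curve(speed_train, track600, "speed")
    fit = t1.linear_rate_correlation(curve)
    assert fit["slope"] == pytest.approx(SPEED_GT.slope, rel=0.15)
    assert fit["r"] > 0.8
    assert fit["p"] < 0.001


def test_two_bins_exact_line():
    curve = t1.TuningCurve(centres=np.array([1.0, 3.0]),
                           rate=np.array([2.0, 6.0]),
                           occupancy=np.array([1.0, 1.0]),
                           counts=np.array([2.0, 6.0]), variable="speed",
                           bin_width=2.0, spike_count=8)
    fit = t1.linear_rate_correlation(curve)
    assert fit["slope"] == pytest.approx(2.0)
    assert fit["intercept"] == pytest.approx(0.0, abs=1e-9)


def test_uniform_unit_no_significant_speed_slope(track600):
    """Monte-Carlo size check: untuned units yield a non-significant speed
    slope (the calibrated quantity at 16 curve bins) in >= 95% of seeds."""
    gt = syn.GroundTruth(kind="uniform", peak_rate=8.0)
    ok = 0
    n_seeds = 20
    for seed in range(100, 100 + n_seeds):
        train = syn.simulate_from_rate(track600, syn.uniform_rate(gt),
                                       seed=seed)
        fit = t1.linear_rate_correlation(
            t1.tuning_curve(train, track600, "speed"))
        ok += fit["p"] > 0.01
    assert ok >= int(0.95 * n_seeds)
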