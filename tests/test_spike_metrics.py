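"""Waveform summaries, ISI statistics, bursts, theta indices, PSTH."""

import numpy as np
import pytest
from scipy import stats

from spikespatial import spike_metrics as sk
from spikespatial import synthetic as syn
from spikespatial.errors import (InsufficientDataError, InvalidArgumentError,
                                 MissingDataError)
from spikespatial.io_session import SpikeTrain


def _template_train(n_copies=100, noise_sd=0.0, seed=0):
    """Biphasic template: peak at 200 us, trough at 500 us, 48 kHz."""
    rate = 48000.0
    s = np.arange(50) / rate * 1e6
    tpl = 100 * (np.exp(-0.5 * ((s - 200) / 40) ** 2)
                 - 0.8 * np.exp(-0.5 * ((s - 500) / 60) ** 2))
    rng = np.random.default_rng(seed)
    wf = tpl[None, None, :] + rng.normal(0, noise_sd, (n_copies, 1, 50))
    ts = np.arange(n_copies) * 0.1 + 0.05
    return SpikeTrain(ts, n_copies * 0.1 + 0.1, waveforms=wf,
                      waveform_rate=rate), tpl


def test_waveform_identical_copies():
    train, tpl = _template_train()
    s = sk.waveform_properties(train)
    np.testing.assert_allclose(s.sd, 0.0, atol=1e-9)
    assert s.amplitude[0] == pytest.approx(tpl.max() - tpl.min())


def test_waveform_noise_mean_recovers_template():
    train, tpl = _template_train(n_copies=400, noise_sd=10.0, seed=1)
    s = sk.waveform_properties(train)
    se = 10.0 / np.sqrt(400)
    assert np.all(np.abs(s.mean[0] - tpl) < 4 * se)


def test_waveform_width_peak_to_trough():
    """Oracle: argmax at 200 us, subsequent argmin at 500 us -> 300 us."""
    train, tpl = _template_train()
    s = sk.waveform_properties(train)
    rate = 48000.0
    ipk, = np.where(tpl == tpl.max())
    itr = ipk[0] + np.argmin(tpl[ipk[0]:])
    expected = (itr - ipk[0]) / rate * 1e6
    assert s.width_us[0] == pytest.approx(expected)
    assert abs(s.width_us[0] - 300.0) <= 1e6 / rate  # within one sample


def test_waveform_missing_raises():
    with pytest.raises(MissingDataError):
        sk.waveform_properties(SpikeTrain([0.1], 1.0))


# ---------------------------------------------------------------------------
# ISI histogram
# ---------------------------------------------------------------------------

def test_isi_periodic_train_single_bin():
    train = SpikeTrain(np.arange(0, 100, 0.125), 100.0)
    corr, viol = sk.isi_histogram(train, bin=0.002, max_lag=0.5)
    assert viol == 0
    peak_bin = np.argmax(corr.counts)
    assert corr.edges[peak_bin] <= 0.125 < corr.edges[peak_bin + 1]
    assert corr.counts[peak_bin] == train.n_spikes - 1


def test_isi_two_spikes():
    corr, _ = sk.isi_histogram(SpikeTrain([0.0, 1.0], 2.0), bin=0.1,
                               max_lag=2.0)
    assert corr.counts.sum() == 1
    assert corr.counts[10] == 1  # the [1.0, 1.1) bin


def test_isi_poisson_matches_exponential():
    """KS test of the empirical ISI distribution against Exp(5 Hz)."""
    rng = np.random.default_rng(3)
    ts = np.cumsum(rng.exponential(1 / 5.0, size=3000))
    train = SpikeTrain(ts, ts[-1] + 1)
    isi = np.diff(train.timestamps)
    d, p = stats.kstest(isi, "expon", args=(0, 1 / 5.0))
    assert p > 0.01


def test_isi_needs_two_spikes():
    with pytest.raises(InsufficientDataError):
        sk.isi_histogram(SpikeTrain([0.5], 1.0))


# ---------------------------------------------------------------------------
# ISI before/after
# ---------------------------------------------------------------------------

def test_before_after_hand_example():
    pairs = sk.isi_before_after(SpikeTrain([0.0, 0.1, 0.3, 0.35], 1.0))
    np.testing.assert_allclose(pairs, [[0.1, 0.2], [0.2, 0.05]])


def test_before_after_periodic_identical():
    pairs = sk.isi_before_after(SpikeTrain(np.arange(0, 10, 0.125), 10.0))
    np.testing.assert_allclose(pairs, 0.125)


def test_before_after_theta_burst_density(theta_pair):
    """Theta-locked firing replicates ~125 ms intervals: the density near
    (125, 125) ms exceeds a rate-matched Poisson control."""
    train, _ = theta_pair
    rng = np.random.default_rng(0)
    ctrl_ts = np.sort(rng.uniform(0, train.duration, train.n_spikes))
    ctrl = SpikeTrain(np.unique(ctrl_ts), train.duration)

    def density(tr):
        p = sk.isi_before_after(tr)
        box = ((np.abs(p[:, 0] - 0.125) < 0.03)
               & (np.abs(p[:, 1] - 0.125) < 0.03))
        return box.mean()

    assert density(train) > 2 * density(ctrl)


# ---------------------------------------------------------------------------
# autocorrelogram
# ---------------------------------------------------------------------------

def test_acg_periodic_peaks():
    train = SpikeTrain(np.arange(0, 60, 0.125), 60.0)
    acg = sk.isi_autocorrelation(train, bin=0.005, window=0.5)
    centre = acg.counts.size // 2
    pos = acg.counts[centre:]
    lags = acg.centres[centre:]
    top = np.argsort(pos)[::-1][:3]
    peak_lags = np.sort(lags[top])
    np.testing.assert_allclose(peak_lags, [0.125, 0.250, 0.375], atol=0.005)


def test_acg_symmetric(theta_pair):
    acg = sk.isi_autocorrelation(theta_pair[0])
    np.testing.assert_array_equal(acg.counts, acg.counts[::-1])


def test_acg_single_spike_empty():
    acg = sk.isi_autocorrelation(SpikeTrain([0.5], 1.0))
    assert acg.counts.sum() == 0


def test_acg_poisson_flat():
    """Monte-Carlo envelope: no bin of a Poisson train's ACG exceeds the
    across-seed mean by more than 5 SD."""
    counts = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        ts = np.unique(np.sort(rng.uniform(0, 300, 1500)))
        acg = sk.isi_autocorrelation(SpikeTrain(ts, 300.0), bin=0.01,
                                     window=0.5)
        counts.append(acg.counts.astype(float))
    counts = np.array(counts)
    mean, sd = counts.mean(), counts.std()
    assert np.all(counts.max(axis=1) < mean + 5 * sd)


def test_acg_rejects_bin_ge_window():
    with pytest.raises(InvalidArgumentError):
        sk.isi_autocorrelation(SpikeTrain([0.1, 0.2], 1.0), bin=0.5,
                               window=0.5)


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

def test_burst_hand_example():
    train = SpikeTrain([0.0, 0.005, 0.010, 1.0, 2.0], 3.0)
    b = sk.burst_properties(train, intra_burst_max=0.010, min_spikes=2)
    assert b["n_bursts"] == 1
    assert b["mean_burst_length"] == 3
    assert b["propensity"] == pytest.approx(0.6)


def test_burst_regular_train_none():
    b = sk.burst_properties(SpikeTrain(np.arange(0, 60, 1.0), 60.0))
    assert b["n_bursts"] == 0
    assert b["propensity"] == 0.0


def test_burst_propensity_recovers_design():
    train, designed = syn.simulate_bursty_train(
        duration=600.0, event_rate=2.0, burst_fraction=0.4, seed=5)
    b = sk.burst_properties(train, intra_burst_max=0.010, min_spikes=2)
    assert b["propensity"] == pytest.approx(designed, abs=0.05)


# ---------------------------------------------------------------------------
# theta indices
# ---------------------------------------------------------------------------

def _model_acg(f=8.0, a=1.0, d=0.15, c=0.3, bin=0.005, window=0.5):
    n_bins = int(round(window / bin))
    edges = np.linspace(-n_bins * bin, n_bins * bin, 2 * n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts = (a * np.cos(2 * np.pi * f * centres)
              * np.exp(-np.abs(centres) / d) + c)
    return sk.Correlogram(edges, 1000 * counts, bin, (-window, window))


def test_theta_fit_recovers_model():
    acg = _model_acg(f=8.0, a=1.0, c=0.3)
    fit = sk.theta_indices(acg)
    assert fit.frequency == pytest.approx(8.0, abs=0.1)
    assert fit.modulation_index == pytest.approx(1.0 / 1.3, abs=0.02)
    assert fit.r_squared > 0.99


def test_theta_fit_flat_acg():
    acg = _model_acg(a=0.0, c=0.5)
    fit = sk.theta_indices(acg)
    assert fit.modulation_index <= 0.05


def test_theta_fit_scale_invariant():
    acg = _model_acg()
    fit1 = sk.theta_indices(acg)
    scaled = sk.Correlogram(acg.edges, acg.counts * 7.3, acg.bin_width,
                            acg.window)
    fit2 = sk.theta_indices(scaled)
    assert fit2.modulation_index == pytest.approx(fit1.modulation_index,
                                                  abs=1e-6)
    assert fit2.skipping_index == pytest.approx(fit1.skipping_index,
                                                abs=1e-6)


def test_theta_skipping_contrast():
    """Alternate-cycle peaks (a half-frequency component) raise the skipping
    index above a non-skipping control."""
    bin, window = 0.005, 0.5
    n_bins = int(round(window / bin))
    edges = np.linspace(-n_bins * bin, n_bins * bin, 2 * n_bins + 1)
    tau = 0.5 * (edges[:-1] + edges[1:])
    env = np.exp(-np.abs(tau) / 0.2)
    base = np.cos(2 * np.pi * 8.0 * tau)
    skip = base + 0.6 * np.cos(np.pi * 8.0 * tau)
    mk = lambda y: sk.Correlogram(edges, 1000 * (y * env + 1.5), bin,
                                  (-window, window))
    fit_skip = sk.theta_indices(mk(skip))
    fit_ctrl = sk.theta_indices(mk(base))
    assert fit_skip.skipping_index > fit_ctrl.skipping_index + 0.1


def test_theta_fit_requires_half_second_window():
    acg = _model_acg(window=0.3)
    with pytest.raises(InvalidArgumentError):
        sk.theta_indices(acg)


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def test_psth_peak_at_zero():
    ts = np.arange(0.5, 60.0, 0.5)
    train = SpikeTrain(ts, 60.0)
    p = sk.psth(train, ts[::5], window=(-0.1, 0.1), bin=0.01)
    assert np.argmax(p.counts) == 10  # bin containing lag 0


def test_psth_poisson_flat():
    rng = np.random.default_rng(2)
    ts = np.unique(np.sort(rng.uniform(0, 600, 6000)))  # ~10 Hz
    train = SpikeTrain(ts, 600.0)
    events = np.arange(5.0, 595.0, 2.0)
    p = sk.psth(train, events, window=(-0.5, 0.5), bin=0.05)
    sd = np.sqrt(10.0 / (events.size * 0.05))
    assert np.all(np.abs(p.counts - 10.0) < 4 * sd)


def test_psth_empty_windows_zero():
    train = SpikeTrain([50.0], 100.0)
    p = sk.psth(train, [10.0, 20.0], window=(-0.1, 0.1), bin=0.01)
    assert p.counts.sum() == 0


def test_psth_needs_events():
    with pytest.raises(InsufficientDataError):
        sk.psth(SpikeTrain([0.1], 1.0), [])
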