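"""Waveform and spike-train characterisation.

Covers the single-unit firing-property analyses: mean waveform shape,
inter-spike-interval (ISI) histogram with refractory-violation count, the
ISI before/after scatter, the spike-train autocorrelogram, burst detection,
theta-rhythmicity indices fitted to the autocorrelogram, and the
peri-stimulus time histogram (PSTH) for event-aligned data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import (FitError, InsufficientDataError, InvalidArgumentError,
                     MissingDataError)
from .io_session import SpikeTrain

REFRACTORY_S = 0.002  #: refractory threshold for violation counting


@dataclass
class WaveformSummary:
    """Per-channel mean waveform shape statistics."""

    mean: np.ndarray          # [n_channels, n_samples] uV
    sd: np.ndarray            # [n_channels, n_samples] uV
    peak_amplitude: np.ndarray    # per channel, uV
    trough_amplitude: np.ndarray  # per channel, uV (signed)
    amplitude: np.ndarray         # per channel, max - min of mean, uV
    width_us: np.ndarray          # per channel, peak-to-trough time, us
    rate: float


@dataclass
class Correlogram:
    """Binned lag histogram (ISI, autocorrelation or PSTH)."""

    edges: np.ndarray   # bin edges, s
    counts: np.ndarray  # per bin (counts, or Hz for a PSTH)
    bin_width: float
    window: tuple

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class ThetaFit:
    """Damped-cosine fit to the spike-train autocorrelogram."""

    frequency: float          # Hz, within the fitted band
    decay: float              # s
    modulation_index: float   # in [0, 1]
    skipping_index: float     # in [0, 1]
    r_squared: float
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def waveform_properties(train: SpikeTrain) -> WaveformSummary:
    """Mean/SD waveform per channel with amplitude and peak-to-trough width.

    Width is measured on the mean waveform (peak sample to the subsequent
    trough sample) rather than per spike, which keeps the estimate stable at
    realistic noise levels.
    """
    if train.waveforms is None:
        raise MissingDataError("spike train carries no waveforms")
    if train.waveform_rate is None or train.waveform_rate <= 0:
        raise MissingDataError("waveform sampling rate missing")
    mean = train.waveforms.mean(axis=0)
    sd = train.waveforms.std(axis=0)
    n_chan = mean.shape[0]
    peak = mean.max(axis=1)
    trough = mean.min(axis=1)
    width = np.full(n_chan, np.nan)
    dt_us = 1e6 / train.waveform_rate
    for c in range(n_chan):
        ipk = int(np.argmax(mean[c]))
        after = mean[c, ipk:]
        if after.size > 1:
            itr = ipk + int(np.argmin(after))
            if itr > ipk:
                width[c] = (itr - ipk) * dt_us
    return WaveformSummary(mean=mean, sd=sd, peak_amplitude=peak,
                           trough_amplitude=trough, amplitude=peak - trough,
                           width_us=width, rate=train.waveform_rate)


# ---------------------------------------------------------------------------
# ISI statistics
# ---------------------------------------------------------------------------

def isi_histogram(train: SpikeTrain, bin: float = 0.002,
                  max_lag: float = 0.5) -> tuple[Correlogram, int]:
    """Histogram of successive inter-spike intervals on [0, max_lag).

    Returns the correlogram and the count of refractory violations
    (intervals below 2 ms).
    """
    if train.n_spikes < 2:
        raise InsufficientDataError("need at least 2 spikes for ISIs")
    isi = np.diff(train.timestamps)
    edges = np.arange(0.0, max_lag + bin * 0.5, bin)
    counts, _ = np.histogram(isi, bins=edges)
    violations = int(np.sum(isi < REFRACTORY_S))
    return Correlogram(edges, counts, bin, (0.0, max_lag)), violations


def isi_before_after(train: SpikeTrain) -> np.ndarray:
    """Paired (ISI before, ISI after) for every interior spike.

    Returns an ``(n_spikes - 2, 2)`` array in spike order; the scatter of
    these pairs makes ISI replication (rhythmic firing) visible as patches.
    """
    if train.n_spikes < 3:
        raise InsufficientDataError("need at least 3 spikes for ISI pairs")
    isi = np.diff(train.timestamps)
    return np.column_stack([isi[:-1], isi[1:]])


def isi_autocorrelation(train: SpikeTrain, bin: float = 0.005,
                        window: float = 0.5) -> Correlogram:
    """Spike-train autocorrelogram: all ordered pair lags in (0, window].

    Positive lags are mirrored to negative ones; the zero-lag (self-pair)
    count is excluded, so the histogram is exactly symmetric.
    """
    if bin >= window:
        raise InvalidArgumentError("bin must be smaller than window")
    if train.n_spikes < 2:
        counts = np.zeros(2 * max(1, int(round(window / bin))), dtype=int)
        nb = counts.size // 2
        edges = np.linspace(-nb * bin, nb * bin, counts.size + 1)
        return Correlogram(edges, counts, bin, (-window, window))
    ts = train.timestamps
    n_bins = int(round(window / bin))
    pos = np.zeros(n_bins, dtype=np.int64)
    # two-pointer sweep over the sorted train
    j0 = np.searchsorted(ts, ts + 1e-12, side="left")
    j1 = np.searchsorted(ts, ts + window, side="right")
    for i in range(ts.size):
        lags = ts[i + 1:j1[i]] - ts[i]
        if lags.size:
            idx = np.minimum((lags / bin).astype(int), n_bins - 1)
            np.add.at(pos, idx, 1)
    counts = np.concatenate([pos[::-1], pos])
    edges = np.linspace(-n_bins * bin, n_bins * bin, 2 * n_bins + 1)
    return Correlogram(edges, counts, bin, (-window, window))


def burst_properties(train: SpikeTrain, intra_burst_max: float = 0.010,
                     min_spikes: int = 2) -> dict:
    """Detect bursts as maximal runs of short ISIs.

    A burst is a maximal run of consecutive ISIs all <= ``intra_burst_max``
    containing at least ``min_spikes`` spikes.  Returns burst count, mean
    burst length (spikes), bursting propensity (fraction of all spikes that
    are inside bursts) and mean inter-burst interval (onset-to-onset).
    """
    if train.n_spikes < 2:
        raise InsufficientDataError("need at least 2 spikes")
    isi = np.diff(train.timestamps)
    short = isi <= intra_burst_max
    bursts = []
    i = 0
    while i < short.size:
        if short[i]:
            j = i
            while j < short.size and short[j]:
                j += 1
            n_in_run = j - i + 1  # spikes spanned by the run of short ISIs
            if n_in_run >= min_spikes:
                bursts.append((i, n_in_run))
            i = j
        else:
            i += 1
    n_burst_spikes = sum(n for _, n in bursts)
    onsets = train.timestamps[[i for i, _ in bursts]]
    return {
        "n_bursts": len(bursts),
        "mean_burst_length": float(np.mean([n for _, n in bursts])) if bursts else 0.0,
        "propensity": n_burst_spikes / train.n_spikes,
        "mean_interburst_interval": float(np.mean(np.diff(onsets))) if len(bursts) > 1 else np.nan,
    }


# ---------------------------------------------------------------------------
# theta rhythmicity
# ---------------------------------------------------------------------------

def _theta_model(tau, a, f, d, c):
    return a * np.cos(2 * np.pi * f * tau) * np.exp(-np.abs(tau) / d) + c


def _skip_model(tau, a, s, f, d, c):
    return ((a * np.cos(2 * np.pi * f * tau)
             + s * np.cos(np.pi * f * tau)) * np.exp(-np.abs(tau) / d) + c)


def theta_indices(acg: Correlogram, band: tuple = (4.0, 14.0),
                  n_restarts: int = 8, restart_seed: int = 0) -> ThetaFit:
    """Theta-modulation and theta-skipping indices from the autocorrelogram.

    A damped cosine ``a cos(2 pi f tau) exp(-|tau|/d) + c`` is fitted by
    least squares to the positive-lag autocorrelogram over the 4-14 Hz
    band with multiple random restarts.  The modulation index is
    ``a / (a + c)`` clipped to [0, 1].  The skipping index refits with an
    added component at half the fitted frequency and reports the relative
    amplitude of that half-frequency component, ``s / (|a| + |s|)``: firing
    on alternate theta cycles inflates every second autocorrelogram peak,
    which only the half-frequency term can absorb.  Both indices are ratios
    of fitted amplitudes, hence invariant to rescaling the counts.
    """
    if acg.window[1] < 0.5 - 1e-9:
        raise InvalidArgumentError("autocorrelogram window must be >= 0.5 s")
    tau = acg.centres
    keep = tau > 0
    tau = tau[keep]
    y = acg.counts[keep].astype(float)
    if not np.any(y > 0):
        return ThetaFit(np.nan, np.nan, 0.0, 0.0, 0.0)
    scale = y.max()
    yn = y / scale
    rng = np.random.default_rng(restart_seed)
    best = None
    c0 = float(np.median(yn))
    a0 = max(float(yn.max() - c0), 1e-3)
    freqs = np.concatenate([[8.0], rng.uniform(band[0], band[1],
                                               size=n_restarts - 1)])
    bounds = ([0.0, band[0], 1e-3, 0.0], [10.0, band[1], 10.0, 10.0])
    for f0 in freqs:
        try:
            popt, _ = curve_fit(_theta_model, tau, yn,
                                p0=[a0, f0, 0.2, c0], bounds=bounds,
                                maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        resid = yn - _theta_model(tau, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("theta fit did not converge in any restart")
    sse, (a, f, d, c) = best
    sst = float(np.sum((yn - yn.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    mod_index = float(np.clip(a / (a + c), 0.0, 1.0)) if (a + c) > 0 else 0.0
    # skipping: allow a half-frequency component, frequency fixed at the fit
    try:
        sk_bounds = ([0.0, -10.0, 1e-3, 0.0], [10.0, 10.0, 10.0, 10.0])

        def skip_fixed_f(tau_, a_, s_, d_, c_):
            return _skip_model(tau_, a_, s_, f, d_, c_)

        popt2, _ = curve_fit(skip_fixed_f, tau, yn, p0=[a, 0.0, d, c],
                             bounds=sk_bounds, maxfev=5000)
        a2, s2, _, _ = popt2
        denom = abs(a2) + abs(s2)
        skip_index = float(np.clip(abs(s2) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    except (RuntimeError, ValueError):
        skip_index = np.nan
    return ThetaFit(frequency=float(f), decay=float(d),
                    modulation_index=mod_index, skipping_index=skip_index,
                    r_squared=r2,
                    params={"a": a * scale, "c": c * scale, "f": f, "d": d})


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def psth(train: SpikeTrain, event_times, window: tuple = (-0.5, 0.5),
         bin: float = 0.010) -> Correlogram:
    """Peri-stimulus time histogram in Hz, averaged over events."""
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise InsufficientDataError("need at least one event")
    lo, hi = window
    edges = np.arange(lo, hi + bin * 0.5, bin)
    counts = np.zeros(edges.size - 1)
    ts = train.timestamps
    for ev in event_times:
        rel = ts[(ts >= ev + lo) & (ts < ev + hi)] - ev
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rate = counts / (event_times.size * bin)
    return Correlogram(edges, rate, bin, window)
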