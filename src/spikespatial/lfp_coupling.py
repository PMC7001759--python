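"""LFP spectra and spike-LFP coupling.

Raw-signal analyses: Welch band power and the short-time spectrogram.
Spike-coupled analyses: the spike-triggered average (STA) of the LFP and its
spectrum, spike-field coherence (SFC, the per-frequency ratio of STA power
to the mean power of the spike-centred segments, in percent), the
phase-locking value (PLV, modulus of the mean unit phasor of per-spike
Fourier phases), time-resolved variants of all three on a grid of lags
around the spike, and the distribution of band-passed LFP phases at spike
times via the Hilbert transform.

Phase convention: 0 degrees at the peak of the (band-passed) oscillation,
increasing through the cycle, so a unit firing at the trough has mean phase
180.  Spikes whose analysis window crosses the recording boundary are
dropped, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidArgumentError
from .io_session import LfpSignal, SpikeTrain
from .tuning_1d import _rayleigh_p

#: band name -> (f_lo, f_hi) Hz
DEFAULT_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 12.0),
                 "beta": (12.0, 30.0), "gamma": (30.0, 80.0)}
DEFAULT_FREQS = np.arange(1.0, 41.0, 1.0)
DEFAULT_WINDOW_S = 0.5
MIN_SPIKES = 10


@dataclass
class Spectrum:
    frequencies: np.ndarray
    power: np.ndarray          # uV^2/Hz
    bands: dict                # name -> {f_lo, f_hi, power, relative}
    total_power: float


@dataclass
class Spectrogram:
    frequencies: np.ndarray
    times: np.ndarray
    power: np.ndarray          # [n_freq, n_time]


@dataclass
class STAResult:
    lags: np.ndarray           # s, symmetric about 0
    sta: np.ndarray            # uV
    frequencies: np.ndarray
    power: np.ndarray          # spectrum of the STA
    n_spikes: int


@dataclass
class CouplingProfile:
    frequencies: np.ndarray
    sfc: Optional[np.ndarray] = None    # percent, [0, 100]
    plv: Optional[np.ndarray] = None    # [0, 1]
    lags: Optional[np.ndarray] = None
    sta_power_matrix: Optional[np.ndarray] = None  # [n_lag, n_freq]
    sfc_matrix: Optional[np.ndarray] = None
    plv_matrix: Optional[np.ndarray] = None
    peak_lag: Optional[dict] = None


@dataclass
class PhaseSample:
    phases: np.ndarray         # deg in [0, 360), one per retained spike
    band: tuple
    mean_phase: float          # deg
    resultant_length: float
    rayleigh_p: float


# ---------------------------------------------------------------------------
# raw LFP
# ---------------------------------------------------------------------------

def welch_spectrum(lfp: LfpSignal, segment: float = 2.0,
                   overlap: float = 0.5,
                   bands: dict = None) -> Spectrum:
    """Welch periodogram with per-band absolute and relative power.

    Band power is the integral of the density over [f_lo, f_hi); relative
    power is the share of the total integrated power.
    """
    if segment > lfp.duration:
        raise InvalidArgumentError("segment must not exceed the duration")
    bands = DEFAULT_BANDS if bands is None else bands
    nperseg = int(round(segment * lfp.rate))
    f, p = sps.welch(lfp.samples, fs=lfp.rate, nperseg=nperseg,
                     noverlap=int(nperseg * overlap))
    total = float(np.trapezoid(p, f))
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        bp = float(np.trapezoid(p[sel], f[sel])) if sel.sum() > 1 else 0.0
        out[name] = {"f_lo": lo, "f_hi": hi, "power": bp,
                     "relative": bp / total if total > 0 else np.nan}
    return Spectrum(frequencies=f, power=p, bands=out, total_power=total)


def spectrogram(lfp: LfpSignal, window: float = 1.0,
                overlap: float = 0.5) -> Spectrogram:
    """Short-time Fourier power of the LFP."""
    if window > lfp.duration:
        raise InvalidArgumentError("window must not exceed the duration")
    nperseg = int(round(window * lfp.rate))
    f, t, s = sps.spectrogram(lfp.samples, fs=lfp.rate, nperseg=nperseg,
                              noverlap=int(nperseg * overlap))
    return Spectrogram(frequencies=f, times=t, power=s)


# ---------------------------------------------------------------------------
# spike-centred segments
# ---------------------------------------------------------------------------

def _segments(lfp: LfpSignal, times: np.ndarray, half_n: int) -> np.ndarray:
    """Matrix of LFP segments centred on ``times``; edge windows dropped."""
    centres = np.round(times * lfp.rate).astype(int)
    ok = (centres - half_n >= 0) & (centres + half_n < lfp.n)
    centres = centres[ok]
    if centres.size == 0:
        return np.empty((0, 2 * half_n + 1))
    offs = np.arange(-half_n, half_n + 1)
    return lfp.samples[centres[:, None] + offs[None, :]]


def spike_triggered_average(lfp: LfpSignal, train: SpikeTrain,
                            window: float = DEFAULT_WINDOW_S) -> STAResult:
    """Mean LFP around spike times and the spectrum of that mean."""
    half_n = int(round(window * lfp.rate))
    segs = _segments(lfp, train.timestamps, half_n)
    if segs.shape[0] < MIN_SPIKES:
        raise InsufficientDataError(
            f"need >= {MIN_SPIKES} spikes fully inside the recording")
    sta = segs.mean(axis=0)
    lags = np.arange(-half_n, half_n + 1) / lfp.rate
    f, p = sps.periodogram(sta, fs=lfp.rate, window="hann")
    return STAResult(lags=lags, sta=sta, frequencies=f, power=p,
                     n_spikes=segs.shape[0])


def _seg_power(segs: np.ndarray, rate: float):
    win = np.hanning(segs.shape[1])
    f = np.fft.rfftfreq(segs.shape[1], d=1.0 / rate)
    spec = np.fft.rfft(segs * win[None, :], axis=1)
    return f, np.abs(spec) ** 2


def spike_field_coherence(lfp: LfpSignal, train: SpikeTrain,
                          window: float = DEFAULT_WINDOW_S,
                          freqs: np.ndarray = None) -> CouplingProfile:
    """SFC(f) = 100 x power(STA)(f) / mean over spikes of power(segment)(f).

    Identical tapering for numerator and denominator bounds the ratio in
    [0, 100] (the power of a mean never exceeds the mean power).
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    half_n = int(round(window * lfp.rate))
    segs = _segments(lfp, train.timestamps, half_n)
    if segs.shape[0] < MIN_SPIKES:
        raise InsufficientDataError(
            f"need >= {MIN_SPIKES} spikes fully inside the recording")
    f, pseg = _seg_power(segs, lfp.rate)
    _, psta = _seg_power(segs.mean(axis=0)[None, :], lfp.rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        sfc_native = 100.0 * psta[0] / pseg.mean(axis=0)
    sfc = np.interp(freqs, f, np.nan_to_num(sfc_native))
    return CouplingProfile(frequencies=freqs, sfc=np.clip(sfc, 0.0, 100.0))


def phase_locking_value(lfp: LfpSignal, train: SpikeTrain,
                        freqs: np.ndarray = None,
                        window: float = DEFAULT_WINDOW_S) -> CouplingProfile:
    """PLV(f): modulus of the mean unit phasor of per-spike windowed
    Fourier coefficients.  1 for perfectly repeatable spike-LFP phase,
    O(1/sqrt(n)) for unrelated spikes."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    half_n = int(round(window * lfp.rate))
    segs = _segments(lfp, train.timestamps, half_n)
    if segs.shape[0] < MIN_SPIKES:
        raise InsufficientDataError(
            f"need >= {MIN_SPIKES} spikes fully inside the recording")
    plv = _plv_from_segments(segs, lfp.rate, freqs)
    return CouplingProfile(frequencies=freqs, plv=plv)


def _plv_from_segments(segs: np.ndarray, rate: float,
                       freqs: np.ndarray) -> np.ndarray:
    win = np.hanning(segs.shape[1])
    t = (np.arange(segs.shape[1]) - segs.shape[1] // 2) / rate
    basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :]) * win[None, :]
    coefs = segs @ basis.T  # [n_spikes, n_freqs]
    mag = np.abs(coefs)
    mag[mag == 0] = 1.0
    return np.abs((coefs / mag).mean(axis=0))


def time_resolved_coupling(lfp: LfpSignal, train: SpikeTrain,
                           lags: np.ndarray = None,
                           freqs: np.ndarray = None,
                           window: float = DEFAULT_WINDOW_S,
                           band: tuple = (4.0, 12.0)) -> CouplingProfile:
    """STA power, SFC and PLV recomputed in windows centred at spike + lag.

    A unit locked to the *next* oscillation cycle rather than the current
    one shows all three metrics maximal at a positive lag of about one
    period.  ``peak_lag`` reports, per metric, the lag maximising the mean
    value inside ``band``.
    """
    lags = (np.arange(-0.2, 0.2 + 1e-9, 0.025) if lags is None
            else np.asarray(lags, float))
    if np.any(np.abs(lags) > 1.0):
        raise InvalidArgumentError("lags must be within +/- 1 s")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    half_n = int(round(window * lfp.rate))
    sta_m = np.full((lags.size, freqs.size), np.nan)
    sfc_m = np.full((lags.size, freqs.size), np.nan)
    plv_m = np.full((lags.size, freqs.size), np.nan)
    for i, lag in enumerate(lags):
        segs = _segments(lfp, train.timestamps + lag, half_n)
        if segs.shape[0] < MIN_SPIKES:
            raise InsufficientDataError("too few spikes at some lag")
        f, pseg = _seg_power(segs, lfp.rate)
        _, psta = _seg_power(segs.mean(axis=0)[None, :], lfp.rate)
        sta_m[i] = np.interp(freqs, f, psta[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            sfc_nat = 100.0 * psta[0] / pseg.mean(axis=0)
        sfc_m[i] = np.clip(np.interp(freqs, f, np.nan_to_num(sfc_nat)),
                           0.0, 100.0)
        plv_m[i] = _plv_from_segments(segs, lfp.rate, freqs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    peak_lag = {name: float(lags[int(np.argmax(m[:, sel].mean(axis=1)))])
                for name, m in (("sta", sta_m), ("sfc", sfc_m),
                                ("plv", plv_m))}
    return CouplingProfile(frequencies=freqs, lags=lags,
                           sta_power_matrix=sta_m, sfc_matrix=sfc_m,
                           plv_matrix=plv_m, peak_lag=peak_lag)


# ---------------------------------------------------------------------------
# phase distribution
# ---------------------------------------------------------------------------

def bandpass_phase(lfp: LfpSignal, band: tuple) -> np.ndarray:
    """Instantaneous phase (deg, 0 at the peak) of the band-passed signal.

    4th-order Butterworth applied forward and backward (zero phase
    distortion), then the analytic-signal angle via the Hilbert transform.
    """
    lo, hi = band
    nyq = lfp.rate / 2.0
    if not (0 < lo < hi < nyq):
        raise InvalidArgumentError("band must lie inside (0, Nyquist)")
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    filt = sps.sosfiltfilt(sos, lfp.samples)
    analytic = sps.hilbert(filt)
    return np.degrees(np.angle(analytic)) % 360.0


def spike_phase_distribution(lfp: LfpSignal, train: SpikeTrain,
                             band: tuple = (4.0, 12.0)) -> PhaseSample:
    """Band-passed LFP phase at each spike time with circular summary."""
    phase = bandpass_phase(lfp, band)
    idx = np.round(train.timestamps * lfp.rate).astype(int)
    idx = idx[(idx >= 0) & (idx < lfp.n)]
    if idx.size < 2:
        raise InsufficientDataError("need at least 2 spikes in the recording")
    phases = phase[idx]
    rad = np.radians(phases)
    C, S = np.cos(rad).mean(), np.sin(rad).mean()
    R = float(np.hypot(C, S))
    mean_phase = float(np.degrees(np.arctan2(S, C)) % 360.0)
    n = phases.size
    p = _rayleigh_p(n * R ** 2, n)
    return PhaseSample(phases=phases, band=band, mean_phase=mean_phase,
                       resultant_length=R, rayleigh_p=p)
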