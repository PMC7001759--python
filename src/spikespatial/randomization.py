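"""Spike-time randomization: shuffling nulls, time-shift profiles, time-lapse.

The shuffle mechanism is a circular time shift of the whole spike train by a
uniform random offset (at least ``min_shift`` seconds away from zero), which
decouples spikes from the animal's path while preserving spike count and the
inter-spike-interval structure up to the single wrapped interval.  An
i.i.d.-replacement mode (spike times redrawn uniformly) is available for
comparison.  The observed statistic is compared to the 95th percentile of
the null by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .io_session import SpatialTrack, SpikeTrain
from . import spatial_maps

DEFAULT_N_SHUFFLES = 500
DEFAULT_MIN_SHIFT_S = 20.0
DEFAULT_PERCENTILES = (95.0,)
#: default time-shift grid, s
DEFAULT_SHIFTS = np.arange(-0.2, 0.4 + 1e-9, 0.025)


@dataclass
class NullDistribution:
    statistic: str
    n_shuffles: int
    values: np.ndarray
    percentile_levels: tuple
    cutoffs: np.ndarray
    observed: float
    exceeds: bool          # observed beyond the first (95th) cutoff
    n_dropped: int
    seed: int


@dataclass
class ShiftProfile:
    shifts: np.ndarray
    values: np.ndarray
    argmax_shift: float


# ---------------------------------------------------------------------------
# canned statistics
# ---------------------------------------------------------------------------

def skaggs_statistic(bin_size: float = spatial_maps.DEFAULT_BIN_CM,
                     smooth_bins: int = spatial_maps.DEFAULT_SMOOTH_BINS
                     ) -> Callable:
    """Statistic function: Skaggs information of the locational rate map."""

    def fn(train: SpikeTrain, track: SpatialTrack) -> float:
        rmap = spatial_maps.rate_map(train, track, bin_size=bin_size,
                                     smooth_bins=smooth_bins)
        return spatial_maps.skaggs_information(rmap)

    fn.__name__ = "skaggs_information"
    return fn


def coherence_statistic(bin_size: float = spatial_maps.DEFAULT_BIN_CM
                        ) -> Callable:
    """Statistic function: spatial coherence of the unsmoothed rate map."""

    def fn(train: SpikeTrain, track: SpatialTrack) -> float:
        rmap = spatial_maps.rate_map(train, track, bin_size=bin_size)
        return spatial_maps.spatial_coherence(rmap)

    fn.__name__ = "spatial_coherence"
    return fn


# ---------------------------------------------------------------------------
# shuffling
# ---------------------------------------------------------------------------

def _surrogate(train: SpikeTrain, track: SpatialTrack, rng, mode: str,
               min_shift: float) -> SpikeTrain:
    if mode == "shift":
        shift = rng.uniform(min_shift, train.duration - min_shift)
        return train.shifted(shift)
    if mode == "redraw":
        ts = np.sort(rng.uniform(0.0, train.duration, size=train.n_spikes))
        return SpikeTrain(np.unique(ts), train.duration, train.tetrode_no,
                          train.unit_no)
    raise InvalidArgumentError("shuffle mode must be 'shift' or 'redraw'")


def shuffle_null(train: SpikeTrain, track: SpatialTrack,
                 statistic_fn: Callable, n: int = DEFAULT_N_SHUFFLES,
                 min_shift: float = DEFAULT_MIN_SHIFT_S, seed: int = 0,
                 mode: str = "shift",
                 percentiles: tuple = DEFAULT_PERCENTILES) -> NullDistribution:
    """Null distribution of ``statistic_fn`` under spike-time randomization.

    Each surrogate circularly shifts all spike times by a uniform offset in
    ``[min_shift, duration - min_shift)`` and recomputes the statistic.
    Surrogates on which the statistic fails are dropped and counted; more
    than 5% failures raises.  ``exceeds`` reports whether the observed
    statistic lies beyond the first percentile cutoff (95th by default).
    """
    if n < 100:
        raise InvalidArgumentError("need at least 100 shuffles")
    if min_shift >= train.duration - min_shift:
        raise InvalidArgumentError("min_shift too large for this duration")
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(train, track))
    values = []
    dropped = 0
    for _ in range(n):
        surro = _surrogate(train, track, rng, mode, min_shift)
        try:
            values.append(float(statistic_fn(surro, track)))
        except Exception:
            dropped += 1
    if dropped > 0.05 * n:
        raise InsufficientDataError(
            f"statistic failed on {dropped}/{n} surrogates")
    values = np.asarray(values)
    cutoffs = np.percentile(values, percentiles)
    name = getattr(statistic_fn, "__name__", "statistic")
    return NullDistribution(statistic=name, n_shuffles=len(values),
                            values=values, percentile_levels=tuple(percentiles),
                            cutoffs=cutoffs, observed=observed,
                            exceeds=bool(observed > cutoffs[0]),
                            n_dropped=dropped, seed=seed)


# ---------------------------------------------------------------------------
# time shift
# ---------------------------------------------------------------------------

def time_shift_profile(train: SpikeTrain, track: SpatialTrack,
                       statistic_fn: Callable,
                       shifts: Sequence = None) -> ShiftProfile:
    """Statistic as a function of a circular shift of the whole spike train.

    A unit whose firing genuinely follows the tracked variable shows a
    smooth profile peaking near the (negative of the) response latency; a
    random association gives a flat profile.  Default grid -0.2 s to +0.4 s
    in 25 ms steps.
    """
    shifts = np.asarray(DEFAULT_SHIFTS if shifts is None else shifts,
                        dtype=float)
    if np.any(np.diff(shifts) <= 0):
        raise InvalidArgumentError("shifts must be strictly increasing")
    if np.any(np.abs(shifts) > train.duration / 4):
        raise InvalidArgumentError("shifts must be within +/- duration/4")
    values = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        shifted = train if s == 0 else train.shifted(s)
        values[i] = float(statistic_fn(shifted, track))
    return ShiftProfile(shifts=shifts, values=values,
                        argmax_shift=float(shifts[int(np.argmax(values))]))


# ---------------------------------------------------------------------------
# time lapse
# ---------------------------------------------------------------------------

def time_lapse(train: SpikeTrain, track: SpatialTrack, window: float,
               mode: str = "cumulative", analysis: Callable = None) -> list:
    """Recompute an analysis on successive time windows.

    ``mode="cumulative"`` analyses [0, k*window) with the final element
    covering the whole session exactly; ``mode="disjoint"`` analyses
    non-overlapping windows that partition the session.  ``analysis`` is a
    callable ``(train, track) -> result`` and defaults to the locational
    rate map.
    """
    if window > track.duration:
        raise InvalidArgumentError("window must not exceed the duration")
    if mode not in ("cumulative", "disjoint"):
        raise InvalidArgumentError("mode must be 'cumulative' or 'disjoint'")
    if analysis is None:
        # bin on the whole-session grid so windowed maps are comparable
        geom = spatial_maps._bin_geometry(track, spatial_maps.DEFAULT_BIN_CM)
        analysis = lambda tr, tk: spatial_maps.rate_map(tr, tk,
                                                        geometry=geom)
    duration = track.duration
    n_win = int(np.ceil(duration / window - 1e-9))
    results = []
    for k in range(1, n_win + 1):
        if mode == "cumulative":
            t0, t1 = 0.0, min(k * window, duration)
            if k == n_win:
                t1 = duration  # final element = whole session exactly
        else:
            t0, t1 = (k - 1) * window, min(k * window, duration)
        sub_train = train.restricted(t0, t1)
        sub_track = track.restricted(t0, t1)
        results.append(analysis(sub_train, sub_track))
    return results
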