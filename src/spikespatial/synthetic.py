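"""Synthetic sessions with known ground truth.

Every analysis in the package has a parameter-recovery test built on this
module: a correlated random-walk trajectory in a square or circular arena,
inhomogeneous-Poisson spike trains driven by closed-form tuning functions
(Gaussian place field, von Mises head-direction tuning, hexagonal grid,
border-distance decay, linear speed tuning), theta-rhythmic units locked to
a synthetic LFP, and Gaussian waveform-feature clusters for cluster-quality
metrics.

All generators are pure functions of (parameters, seed): identical calls
give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import i0

from .errors import InvalidArgumentError
from .io_session import LfpSignal, SpatialTrack, SpikeTrain, derive_kinematics


@dataclass
class ArenaSpec:
    """Geometry and sampling of a simulated arena.

    ``extent`` is the side length (square) or diameter (circle) in cm; the
    arena is centred on the origin.  ``rate`` is the position-sampling rate.
    """

    shape: str = "square"
    extent: float = 100.0
    rate: float = 50.0
    duration: float = 600.0

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circle"):
            raise InvalidArgumentError("shape must be 'square' or 'circle'")
        if self.extent <= 0 or self.duration <= 0:
            raise InvalidArgumentError("extent and duration must be positive")
        if self.rate < 10:
            raise InvalidArgumentError("position rate must be >= 10 Hz")


@dataclass
class GroundTruth:
    """Parameters of one simulated unit, by kind.

    Only the parameters relevant to ``kind`` are read; the rest keep their
    defaults.  Rates are Hz, lengths cm, angles degrees.
    """

    kind: str = "place"
    peak_rate: float = 10.0
    baseline: float = 0.5
    centre: tuple = (0.0, 0.0)      # place: field centre
    width: float = 10.0             # place: Gaussian sigma
    preferred_direction: float = 0.0  # hd
    kappa: float = 4.0              # hd: von Mises concentration
    spacing: float = 40.0           # grid
    orientation: float = 0.0        # grid
    decay: float = 10.0             # border: exponential length constant
    slope: float = 0.2              # speed: Hz per cm/s
    theta_frequency: float = 8.0
    locking_phase: float = 0.0
    locking_kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = ("place", "hd", "grid", "border", "speed", "theta", "uniform")
        if self.kind not in kinds:
            raise InvalidArgumentError(f"kind must be one of {kinds}")
        if not (self.peak_rate > self.baseline >= 0):
            raise InvalidArgumentError("need peak_rate > baseline >= 0")
        if self.kappa < 0 or self.locking_kappa < 0:
            raise InvalidArgumentError("kappa must be >= 0")
        if self.spacing <= 0:
            raise InvalidArgumentError("spacing must be positive")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _inside(shape: str, half: float, x: float, y: float) -> bool:
    if shape == "square":
        return -half <= x <= half and -half <= y <= half
    return x * x + y * y <= half * half


def simulate_trajectory(arena: ArenaSpec, step_sd: float = 0.35,
                        turn_sd: float = 12.0, hd_jitter_kappa: float = 20.0,
                        seed: int = 0) -> SpatialTrack:
    """Correlated random walk reflected at the arena walls.

    The heading performs a wrapped random walk (``turn_sd`` degrees per
    step); step lengths are folded normal with scale ``step_sd`` cm, giving a
    mean running speed of roughly ``step_sd * rate * 0.8`` cm/s.  Head
    direction is the movement heading plus von Mises jitter with
    concentration ``hd_jitter_kappa``, so heading and locomotion direction
    are correlated but not identical — the sampling bias a real rodent shows.
    Derived kinematic channels (speed, angular velocity, border distance) are
    attached, with border distance measured to the true arena wall.
    """
    if step_sd <= 0:
        raise InvalidArgumentError("step_sd must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(arena.duration * arena.rate))
    half = arena.extent / 2.0
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    x[0] = y[0] = 0.0
    heading[0] = rng.uniform(0, 360)
    turns = rng.normal(0.0, turn_sd, size=n)
    steps = np.abs(rng.normal(step_sd, step_sd / 2.0, size=n))
    for i in range(1, n):
        h = heading[i - 1] + turns[i]
        rad = math.radians(h)
        nx = x[i - 1] + steps[i] * math.cos(rad)
        ny = y[i - 1] + steps[i] * math.sin(rad)
        if not _inside(arena.shape, half, nx, ny):
            # reflect: bounce the heading and retry from the old position
            if arena.shape == "square":
                if not -half <= nx <= half:
                    h = 180.0 - h
                if not -half <= ny <= half:
                    h = -h
            else:
                h = h + 180.0 + rng.normal(0, 30.0)
            rad = math.radians(h)
            nx = x[i - 1] + steps[i] * math.cos(rad)
            ny = y[i - 1] + steps[i] * math.sin(rad)
            nx = min(max(nx, -half), half)
            ny = min(max(ny, -half), half)
            if arena.shape == "circle":
                r = math.hypot(nx, ny)
                if r > half:
                    nx *= half / r
                    ny *= half / r
        x[i] = nx
        y[i] = ny
        heading[i] = h % 360.0
    jitter = np.degrees(rng.vonmises(0.0, hd_jitter_kappa, size=n))
    hd = np.mod(heading + jitter, 360.0)
    t = np.arange(n) / arena.rate
    track = SpatialTrack(t, x, y, hd)
    boundary = arena_boundary(arena)
    return derive_kinematics(track, boundary=boundary)


def arena_boundary(arena: ArenaSpec) -> np.ndarray:
    """Closed polyline of the true arena wall (used by the simulator)."""
    half = arena.extent / 2.0
    if arena.shape == "square":
        pts = [(-half, -half), (half, -half), (half, half), (-half, half),
               (-half, -half)]
        return np.array(pts)
    ang = np.linspace(0, 2 * np.pi, 101)
    return np.column_stack([half * np.cos(ang), half * np.sin(ang)])


# ---------------------------------------------------------------------------
# tuning functions -> rate along the track
# ---------------------------------------------------------------------------

def place_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Gaussian place field: baseline + (peak-baseline) exp(-d^2 / 2 sigma^2)."""
    if gt.kind != "place":
        raise InvalidArgumentError("ground truth kind must be 'place'")

    def fn(track: SpatialTrack) -> np.ndarray:
        d2 = (track.x - gt.centre[0]) ** 2 + (track.y - gt.centre[1]) ** 2
        return gt.baseline + (gt.peak_rate - gt.baseline) * np.exp(
            -d2 / (2.0 * gt.width ** 2))
    fn.max_rate = gt.peak_rate
    return fn


def hd_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Von Mises head-direction tuning, peak at the preferred direction."""
    if gt.kind != "hd":
        raise InvalidArgumentError("ground truth kind must be 'hd'")

    def fn(track: SpatialTrack) -> np.ndarray:
        ang = np.radians(track.head_direction - gt.preferred_direction)
        shape = np.exp(gt.kappa * (np.cos(ang) - 1.0))  # 1 at peak, e^-2k opposite
        return gt.baseline + (gt.peak_rate - gt.baseline) * shape
    fn.max_rate = gt.peak_rate
    return fn


def grid_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Hexagonal grid built from three plane cosines 60 degrees apart.

    With wave number 4*pi / (sqrt(3) * spacing) the maxima of the cosine sum
    form a triangular lattice with the stated spacing.  The sum is rescaled
    to [-1/2, 1] and clipped at zero before scaling between baseline and
    peak, yielding sharp fields separated by silent troughs.
    """
    if gt.kind != "grid":
        raise InvalidArgumentError("ground truth kind must be 'grid'")
    k = 4.0 * np.pi / (np.sqrt(3.0) * gt.spacing)
    angles = np.radians(gt.orientation + np.array([0.0, 60.0, 120.0]))

    def fn(track: SpatialTrack) -> np.ndarray:
        g = np.zeros(track.n)
        for a in angles:
            g += np.cos(k * (track.x * np.cos(a) + track.y * np.sin(a)))
        g /= 3.0  # in [-1/2, 1], max 1 on the lattice
        return gt.baseline + (gt.peak_rate - gt.baseline) * np.clip(g, 0.0, 1.0)
    fn.max_rate = gt.peak_rate
    return fn


def border_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Rate decaying exponentially with distance from the arena border."""
    if gt.kind != "border":
        raise InvalidArgumentError("ground truth kind must be 'border'")

    def fn(track: SpatialTrack) -> np.ndarray:
        d = track.channel("border_distance")
        return gt.baseline + (gt.peak_rate - gt.baseline) * np.exp(-d / gt.decay)
    fn.max_rate = gt.peak_rate
    return fn


def speed_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Linear speed tuning, clipped at zero and at the stated peak."""
    if gt.kind != "speed":
        raise InvalidArgumentError("ground truth kind must be 'speed'")

    def fn(track: SpatialTrack) -> np.ndarray:
        return np.clip(gt.baseline + gt.slope * track.channel("speed"),
                       0.0, gt.peak_rate)
    fn.max_rate = gt.peak_rate
    return fn


def uniform_rate(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Spatially untuned unit at the ground-truth peak rate."""

    def fn(track: SpatialTrack) -> np.ndarray:
        return np.full(track.n, gt.peak_rate)
    fn.max_rate = gt.peak_rate
    return fn


_RATE_FACTORIES = {"place": place_rate, "hd": hd_rate, "grid": grid_rate,
                   "border": border_rate, "speed": speed_rate,
                   "uniform": uniform_rate}


def rate_function(gt: GroundTruth) -> Callable[[SpatialTrack], np.ndarray]:
    """Dispatch to the tuning function for ``gt.kind``."""
    try:
        return _RATE_FACTORIES[gt.kind](gt)
    except KeyError:
        raise InvalidArgumentError(f"no rate function for kind {gt.kind!r}")


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def simulate_from_rate(track: SpatialTrack, rate_fn, seed: int = 0,
                       max_rate: Optional[float] = None,
                       tetrode_no: int = 1, unit_no: int = 1) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by Lewis-Shedler thinning.

    Candidate spikes are drawn as a homogeneous Poisson process at
    ``max_rate`` (taken from ``rate_fn.max_rate`` when not given) and
    retained with probability rate(t)/max_rate, where the rate is evaluated
    at the nearest track sample.  The expected spike count is the integral
    of the rate along the track.
    """
    lam = np.asarray(rate_fn(track), dtype=float)
    if np.any(lam < 0):
        raise InvalidArgumentError("rate function returned a negative rate")
    if max_rate is None:
        max_rate = getattr(rate_fn, "max_rate", None)
        if max_rate is None:
            max_rate = float(lam.max())
    if np.any(lam > max_rate * (1 + 1e-9)):
        raise InvalidArgumentError("rate exceeds stated max_rate")
    rng = np.random.default_rng(seed)
    duration = track.duration
    if max_rate <= 0:
        return SpikeTrain(np.empty(0), duration, tetrode_no, unit_no)
    n_cand = rng.poisson(max_rate * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.clip(np.round(cand * track.rate).astype(int), 0, track.n - 1)
    keep = rng.uniform(size=n_cand) < lam[idx] / max_rate
    ts = cand[keep]
    # enforce strict ascent (duplicate uniform draws are measure-zero but
    # finite precision can collide)
    ts = np.unique(ts)
    return SpikeTrain(ts, duration, tetrode_no, unit_no)


def simulate_theta_unit_and_lfp(duration: float = 300.0, theta_f: float = 8.0,
                                lfp_rate: float = 250.0,
                                locking_phase: float = 0.0,
                                locking_kappa: float = 4.0,
                                mean_rate: float = 10.0,
                                noise_sd: float = 50.0,
                                amplitude: float = 100.0,
                                seed: int = 0):
    """Theta LFP plus a spike train phase-locked to it.

    The LFP is ``amplitude * cos(2 pi f t)`` plus white noise.  Phase 0 is at
    the oscillation peak and increases through the cycle (the package-wide
    phase convention).  Spikes are an inhomogeneous Poisson process with rate
    ``mean_rate * vonmises_pdf(phase - locking_phase, kappa) * 2 pi``, so the
    time-averaged rate equals ``mean_rate`` and kappa controls the locking
    strength (kappa = 0 gives no locking).

    Returns ``(SpikeTrain, LfpSignal)``.
    """
    if locking_kappa < 0:
        raise InvalidArgumentError("locking kappa must be >= 0")
    if theta_f >= lfp_rate / 2:
        raise InvalidArgumentError("theta_f must be below the LFP Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration * lfp_rate))
    t = np.arange(n) / lfp_rate
    phase = 2.0 * np.pi * theta_f * t
    lfp = amplitude * np.cos(phase) + rng.normal(0.0, noise_sd, size=n)
    phi0 = math.radians(locking_phase)
    max_mod = mean_rate * math.exp(locking_kappa) / i0(locking_kappa)
    n_cand = rng.poisson(max_mod * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    cphase = 2.0 * np.pi * theta_f * cand
    lam = mean_rate * np.exp(locking_kappa * np.cos(cphase - phi0)) / i0(locking_kappa)
    keep = rng.uniform(size=n_cand) < lam / max_mod
    ts = np.unique(cand[keep])
    return SpikeTrain(ts, duration), LfpSignal(lfp, lfp_rate)


def simulate_lagged_theta_events(duration: float = 120.0,
                                 theta_f: float = 8.0,
                                 lfp_rate: float = 250.0,
                                 lag: float = 0.125, n_cycles: float = 3.0,
                                 amplitude: float = 100.0,
                                 noise_sd: float = 60.0,
                                 event_rate: float = 1.5,
                                 seed: int = 0):
    """Spikes followed (or preceded) by a transient theta burst.

    Each spike deposits a Gaussian-windowed theta wavelet into the LFP,
    centred ``lag`` seconds after the spike with its peak phase at the
    centre.  Because the oscillation is transient rather than continuous,
    time-resolved coupling metrics are maximal at ``lag`` — the ground
    truth for lag-recovery tests (a unit locked to the *next* theta cycle
    corresponds to ``lag`` of one period).

    Returns ``(SpikeTrain, LfpSignal)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * lfp_rate))
    t = np.arange(n) / lfp_rate
    lfp = rng.normal(0.0, noise_sd, size=n)
    margin = abs(lag) + n_cycles / theta_f
    n_ev = rng.poisson(event_rate * duration)
    ts = np.sort(rng.uniform(margin, duration - margin, size=n_ev))
    # keep events separated so wavelets do not overlap
    keep = np.concatenate([[True], np.diff(ts) > 2 * n_cycles / theta_f])
    ts = np.unique(ts[keep])
    env_sd = n_cycles / (4.0 * theta_f)
    for ev in ts:
        centre = ev + lag
        sel = np.abs(t - centre) < 4 * env_sd
        tau = t[sel] - centre
        lfp[sel] += (amplitude * np.cos(2 * np.pi * theta_f * tau)
                     * np.exp(-0.5 * (tau / env_sd) ** 2))
    return SpikeTrain(ts, duration), LfpSignal(lfp, lfp_rate)


def simulate_bursty_train(duration: float, event_rate: float,
                          burst_fraction: float, burst_size: int = 3,
                          intra_isi: float = 0.005, seed: int = 0) -> tuple:
    """Poisson event train where a fraction of events become short bursts.

    Returns ``(SpikeTrain, designed_propensity)`` where the designed
    propensity is the expected fraction of spikes that fall inside bursts.
    Used as bookkeeping ground truth for burst-detection tests.
    """
    rng = np.random.default_rng(seed)
    n_ev = rng.poisson(event_rate * duration)
    events = np.sort(rng.uniform(0, duration - burst_size * intra_isi, size=n_ev))
    # keep events separated so bursts never merge
    keep = np.concatenate([[True], np.diff(events) > 20 * intra_isi])
    events = events[keep]
    is_burst = rng.uniform(size=events.size) < burst_fraction
    ts = []
    for ev, b in zip(events, is_burst):
        if b:
            ts.extend(ev + intra_isi * np.arange(burst_size))
        else:
            ts.append(ev)
    ts = np.unique(np.asarray(ts))
    n_burst_ev = int(is_burst.sum())
    n_spikes = n_burst_ev * burst_size + (events.size - n_burst_ev)
    designed = n_burst_ev * burst_size / n_spikes if n_spikes else 0.0
    return SpikeTrain(ts, duration), designed


# ---------------------------------------------------------------------------
# waveform clusters
# ---------------------------------------------------------------------------

def simulate_waveform_clusters(n_per_cluster, means, covariances, seed: int = 0):
    """Gaussian feature clouds with stated moments, one per cluster.

    ``means`` is a sequence of feature vectors, ``covariances`` a matching
    sequence of covariance matrices; ``n_per_cluster`` an int or sequence.
    Returns a list of (n_i x d) sample arrays.
    """
    rng = np.random.default_rng(seed)
    means = [np.asarray(m, dtype=float) for m in means]
    covs = [np.asarray(c, dtype=float) for c in covariances]
    if len(means) != len(covs):
        raise InvalidArgumentError("means and covariances must match in length")
    if np.isscalar(n_per_cluster):
        ns = [int(n_per_cluster)] * len(means)
    else:
        ns = [int(v) for v in n_per_cluster]
    clouds = []
    for n, m, c in zip(ns, means, covs):
        if c.shape != (m.size, m.size):
            raise InvalidArgumentError("covariance dimensions must match mean")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise InvalidArgumentError("covariance must be positive definite")
        clouds.append(rng.multivariate_normal(m, c, size=n,
                                              method="cholesky"))
    return clouds


def make_waveforms(train: SpikeTrain, n_channels: int = 4,
                   n_samples: int = 50, rate: float = 48000.0,
                   peak_uv: float = 150.0, noise_sd: float = 5.0,
                   seed: int = 0) -> SpikeTrain:
    """Attach synthetic biphasic tetrode waveforms to a spike train.

    The template is a positive Gaussian peak followed by a slower negative
    trough, scaled per channel so that cluster-quality features vary across
    the tetrode; white noise is added per spike.
    """
    rng = np.random.default_rng(seed)
    s = np.arange(n_samples) / rate * 1e6  # microseconds
    template = (np.exp(-0.5 * ((s - 200.0) / 60.0) ** 2)
                - 0.6 * np.exp(-0.5 * ((s - 500.0) / 120.0) ** 2))
    chan_gain = np.linspace(1.0, 0.4, n_channels)
    wf = (peak_uv * template[None, None, :] * chan_gain[None, :, None]
          + rng.normal(0.0, noise_sd,
                       size=(train.n_spikes, n_channels, n_samples)))
    return SpikeTrain(train.timestamps, train.duration, train.tetrode_no,
                      train.unit_no, wf, rate)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def simulate_session(record_id: str, ground_truths, arena: ArenaSpec = None,
                     seed: int = 0, with_lfp: bool = True,
                     with_waveforms: bool = False):
    """Build a full synthetic :class:`~spikespatial.io_session.Session`.

    One trajectory is shared by all units; each :class:`GroundTruth` becomes
    one spike train on its own tetrode (numbered from 1).  A theta LFP named
    ``"eeg"`` is attached when ``with_lfp``.  Returns ``(Session, track)``
    ground truth list unchanged; all randomness derives from ``seed``.
    """
    from .io_session import Session
    arena = arena or ArenaSpec()
    rng = np.random.default_rng(seed)
    track = simulate_trajectory(arena, seed=int(rng.integers(2 ** 31)))
    units = []
    for i, gt in enumerate(ground_truths):
        sub_seed = int(rng.integers(2 ** 31))
        if gt.kind == "theta":
            train, _ = simulate_theta_unit_and_lfp(
                duration=arena.duration, theta_f=gt.theta_frequency,
                locking_phase=gt.locking_phase,
                locking_kappa=gt.locking_kappa, mean_rate=gt.peak_rate,
                seed=sub_seed)
            train = SpikeTrain(train.timestamps, track.duration,
                               tetrode_no=i + 1, unit_no=1)
        else:
            train = simulate_from_rate(track, rate_function(gt),
                                       seed=sub_seed, tetrode_no=i + 1,
                                       unit_no=1)
        if with_waveforms:
            train = make_waveforms(train, seed=sub_seed)
        units.append(train)
    lfps = {}
    if with_lfp:
        _, lfp = simulate_theta_unit_and_lfp(duration=arena.duration,
                                             seed=int(rng.integers(2 ** 31)))
        lfps["eeg"] = lfp
    return Session(record_id, track, units, lfps)
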