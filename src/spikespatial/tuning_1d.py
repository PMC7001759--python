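"""Single-variable tuning: head direction, speed, angular velocity, border
distance.

Builds 1D tuning curves (rate vs an independent variable), computes circular
statistics for angular variables (resultant length, Rayleigh test, von Mises
concentration, tuning half-width), splits head-direction tuning by turning
direction, fits a weighted line for speed/angular-velocity tuning, and
implements the distributive-hypothesis check: the directional tuning curve
*predicted* purely from the locational rate map and the joint dwell of
(location, direction), used to unmask apparent directional tuning that is
really a sampling artefact of a place field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .errors import (InsufficientDataError, InvalidArgumentError,
                     UndefinedStatisticError)
from .io_session import SpatialTrack, SpikeTrain
from .spatial_maps import RateMap, _bin_indices

#: per-variable (bin width, range) defaults; angles deg, speed cm/s, ahv deg/s
VARIABLE_DEFAULTS = {
    "hd": (5.0, (0.0, 360.0)),
    "speed": (2.5, (0.0, 40.0)),
    "ahv": (10.0, (-200.0, 200.0)),
    "border_distance": (3.0, None),  # range from data
}


@dataclass
class TuningCurve:
    """Binned firing rate against one independent variable."""

    centres: np.ndarray
    rate: np.ndarray        # Hz, NaN on unoccupied bins
    occupancy: np.ndarray   # s per bin
    counts: np.ndarray      # spikes per bin
    variable: str
    bin_width: float
    circular: bool = False
    spike_count: int = 0
    #: dwell-weighted mean of the variable per bin (NaN where unoccupied);
    #: used instead of bin centres in linear fits to avoid attenuation from
    #: skewed within-bin dwell
    bin_means: Optional[np.ndarray] = None

    @property
    def mean_rate(self) -> float:
        occ = self.occupancy
        ok = occ > 0
        return float(np.sum(occ[ok] * self.rate[ok]) / occ[ok].sum())


@dataclass
class CircularStats:
    resultant_length: float   # R in [0, 1]
    mean_direction: float     # deg
    rayleigh_z: float
    rayleigh_p: float
    kappa: float
    peak_rate: float
    preferred_direction: float  # deg, bin-resolved peak
    half_width: float           # deg


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def interp_channel(track: SpatialTrack, times: np.ndarray,
                   variable: str) -> np.ndarray:
    """Track channel value at arbitrary times by linear interpolation;
    angular channels are interpolated on the unwrapped angle."""
    ch = track.channel(variable)
    if variable in ("hd", "head_direction"):
        unwrapped = np.unwrap(ch, period=360.0)
        return np.mod(np.interp(times, track.t, unwrapped), 360.0)
    return np.interp(times, track.t, ch)


def _build_curve(spike_vals, sample_vals, dt, variable, bin_width, rng,
                 circular):
    lo, hi = rng
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    occ_counts, _ = np.histogram(sample_vals, bins=edges)
    occupancy = occ_counts * dt
    counts, _ = np.histogram(spike_vals, bins=edges)
    if not np.any(occupancy > 0):
        raise InsufficientDataError("no occupied bins for this variable")
    val_sums, _ = np.histogram(sample_vals, bins=edges, weights=sample_vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, counts / np.where(occupancy > 0,
                                                         occupancy, 1.0),
                        np.nan)
        bin_means = np.where(occ_counts > 0,
                             val_sums / np.where(occ_counts > 0, occ_counts,
                                                 1.0), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return TuningCurve(centres=centres, rate=rate, occupancy=occupancy,
                       counts=counts.astype(float), variable=variable,
                       bin_width=bin_width, circular=circular,
                       spike_count=int(counts.sum()), bin_means=bin_means)


def tuning_curve(train: SpikeTrain, track: SpatialTrack, variable: str,
                 bin_width: Optional[float] = None,
                 value_range: Optional[tuple] = None) -> TuningCurve:
    """Firing rate vs one track variable (``hd``, ``speed``, ``ahv`` or
    ``border_distance``).

    Rate per bin is (spikes whose interpolated variable value falls in the
    bin) / (dwell in the bin).  Out-of-range samples and spikes (e.g. speeds
    above the cap) are excluded from both numerator and denominator.
    """
    if variable not in VARIABLE_DEFAULTS:
        raise InvalidArgumentError(
            f"variable must be one of {sorted(VARIABLE_DEFAULTS)}")
    default_bin, default_range = VARIABLE_DEFAULTS[variable]
    bin_width = bin_width or default_bin
    sample_vals = track.channel(variable)
    ts = train.timestamps
    keep = (ts >= track.t[0]) & (ts <= track.t[-1])
    spike_vals = interp_channel(track, ts[keep], variable)
    rng = value_range or default_range
    if rng is None:
        hi = float(sample_vals.max())
        hi = np.ceil(hi / bin_width) * bin_width
        rng = (0.0, max(hi, bin_width))
    circular = variable == "hd"
    return _build_curve(spike_vals, sample_vals, track.dt, variable,
                        bin_width, rng, circular)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def _kappa_from_r(r: float) -> float:
    # standard piecewise approximation of the von Mises MLE
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def _rayleigh_p(z: float, n: float) -> float:
    # Zar's approximation, accurate for n >= ~10
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - n * z)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def circular_stats(curve: TuningCurve) -> CircularStats:
    """Directional statistics of a circular tuning curve.

    The resultant vector is computed from the rate-weighted bin directions;
    the Rayleigh Z uses the spike count as n.  The von Mises concentration
    is recovered from R by the standard piecewise approximation.  Half-width
    is the angular width of the curve at half the peak rate (zero baseline),
    linearly interpolated at the crossings.
    """
    if not curve.circular:
        raise InvalidArgumentError("circular statistics need an angular curve")
    w = np.nan_to_num(curve.rate)
    total = w.sum()
    if total <= 0:
        raise UndefinedStatisticError("zero total rate")
    theta = np.radians(curve.centres)
    C = float(np.sum(w * np.cos(theta)) / total)
    S = float(np.sum(w * np.sin(theta)) / total)
    R = float(np.hypot(C, S))
    mean_dir = float(np.degrees(np.arctan2(S, C)) % 360.0)
    n = max(curve.spike_count, 1)
    Z = n * R ** 2
    p = _rayleigh_p(Z, n)
    kappa = _kappa_from_r(min(R, 1.0 - 1e-12))
    ipk = int(np.nanargmax(curve.rate))
    peak = float(curve.rate[ipk])
    preferred = float(curve.centres[ipk])
    half_width = _half_width(curve, ipk, peak)
    return CircularStats(resultant_length=R, mean_direction=mean_dir,
                         rayleigh_z=float(Z), rayleigh_p=p,
                         kappa=float(kappa), peak_rate=peak,
                         preferred_direction=preferred,
                         half_width=half_width)


def _half_width(curve: TuningCurve, ipk: int, peak: float) -> float:
    """Angular width at half the peak rate (baseline zero), interpolated."""
    rate = np.nan_to_num(curve.rate)
    nb = rate.size
    half = peak / 2.0
    b = curve.bin_width

    def walk(direction):
        # distance (deg) from the peak centre to the half-rate crossing
        for step in range(1, nb):
            j = (ipk + direction * step) % nb
            j_prev = (ipk + direction * (step - 1)) % nb
            if rate[j] < half:
                r0, r1 = rate[j_prev], rate[j]
                frac = (r0 - half) / (r0 - r1) if r0 > r1 else 0.0
                return (step - 1 + frac) * b
        return 180.0  # never crosses: half the circle per side

    return float(min(walk(+1) + walk(-1), 360.0))


# ---------------------------------------------------------------------------
# turning-direction split
# ---------------------------------------------------------------------------

def hd_by_rotation(train: SpikeTrain, track: SpatialTrack,
                   ahv_threshold: float = 30.0) -> dict:
    """Head-direction tuning split by turning direction.

    Track samples (and spikes, via their interpolated angular velocity) are
    partitioned into clockwise (ahv < -threshold) and counter-clockwise
    (ahv > +threshold) sets; slow-turning epochs are excluded.  Returns
    ``{"cw": curve|None, "ccw": curve|None, "flags": [...]}`` with a flag
    naming any empty partition.
    """
    ahv = track.channel("ahv")
    ts = train.timestamps
    keep = (ts >= track.t[0]) & (ts <= track.t[-1])
    spike_ahv = interp_channel(track, ts[keep], "ahv")
    spike_hd = interp_channel(track, ts[keep], "hd")
    hd = track.channel("hd")
    out = {"cw": None, "ccw": None, "flags": []}
    for name, sample_mask, spike_mask in (
            ("cw", ahv < -ahv_threshold, spike_ahv < -ahv_threshold),
            ("ccw", ahv > ahv_threshold, spike_ahv > ahv_threshold)):
        if not np.any(sample_mask):
            out["flags"].append(f"{name} partition empty")
            continue
        try:
            out[name] = _build_curve(spike_hd[spike_mask], hd[sample_mask],
                                     track.dt, "hd", 5.0, (0.0, 360.0), True)
        except InsufficientDataError:
            out["flags"].append(f"{name} partition empty")
    return out


# ---------------------------------------------------------------------------
# distributive-hypothesis prediction
# ---------------------------------------------------------------------------

def expected_rate_from_place(rmap: RateMap, track: SpatialTrack,
                             variable: str,
                             bin_width: Optional[float] = None,
                             observed: Optional[TuningCurve] = None):
    """Tuning curve predicted from the locational rate map alone.

    For every variable bin v the prediction is the joint-dwell-weighted mean
    of the locational rates the animal experienced while the variable was in
    v: ``sum_loc lambda(loc) T(loc, v) / sum_loc T(loc, v)``.  If the unit's
    firing depends on location only, this reproduces the observed curve and
    any apparent directional tuning is a sampling artefact.

    Returns ``(predicted_curve, distributive_ratio)``; the ratio
    ``mean_bins |ln((1 + obs) / (1 + pred))|`` is NaN when no observed curve
    is supplied (small for genuinely location-driven units).
    """
    default_bin, default_range = VARIABLE_DEFAULTS[variable]
    bin_width = bin_width or default_bin
    vals = track.channel(variable)
    rng = default_range
    if rng is None:
        hi = np.ceil(float(vals.max()) / bin_width) * bin_width
        rng = (0.0, max(hi, bin_width))
    ix, iy, ok = _bin_indices(track.x, track.y, rmap.origin, rmap.bin_size,
                              *rmap.shape)
    lam = np.full(track.n, np.nan)
    lam[ok] = rmap.rate[ix[ok], iy[ok]]
    good = np.isfinite(lam) & (vals >= rng[0]) & (vals < rng[1])
    if not np.any(good):
        raise InsufficientDataError("no joint occupancy of map and variable")
    edges = np.arange(rng[0], rng[1] + bin_width * 0.5, bin_width)
    n_bins = edges.size - 1
    idx = np.minimum(((vals[good] - rng[0]) / bin_width).astype(int),
                     n_bins - 1)
    wsum = np.bincount(idx, weights=lam[good], minlength=n_bins)
    w = np.bincount(idx, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(w > 0, wsum / np.where(w > 0, w, 1.0), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    curve = TuningCurve(centres=centres, rate=pred, occupancy=w * track.dt,
                        counts=np.zeros(n_bins), variable=variable,
                        bin_width=bin_width, circular=variable == "hd",
                        spike_count=0)
    ratio = np.nan
    if observed is not None:
        both = np.isfinite(pred) & np.isfinite(observed.rate)
        if np.any(both):
            ratio = float(np.mean(np.abs(np.log(
                (1.0 + observed.rate[both]) / (1.0 + pred[both])))))
    return curve, ratio


# ---------------------------------------------------------------------------
# linear tuning
# ---------------------------------------------------------------------------

def linear_rate_correlation(curve: TuningCurve) -> dict:
    """Occupancy-weighted least-squares line through the tuning curve.

    The abscissa is the dwell-weighted mean of the variable within each bin
    (falling back to bin centres when unavailable): regressing on raw bin
    centres systematically attenuates the slope whenever dwell is skewed
    within bins, as it is in the tails of a speed distribution.  Returns
    slope, intercept, the weighted product-moment correlation and the
    p-value of the slope.
    """
    ok = (curve.occupancy > 0) & np.isfinite(curve.rate)
    if int(ok.sum()) < 3 and int(ok.sum()) != 2:
        if int(ok.sum()) < 2:
            raise InsufficientDataError("need at least 2 occupied bins")
    x = (curve.bin_means[ok] if curve.bin_means is not None
         else curve.centres[ok])
    y = curve.rate[ok]
    w = curve.occupancy[ok]
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero variance in the variable")
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    intercept, slope = fit.params
    # weighted correlation coefficient
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    r = float(cov / np.sqrt(vx * vy)) if vx > 0 and vy > 0 else np.nan
    p = float(fit.pvalues[1]) if x.size > 2 else np.nan
    return {"slope": float(slope), "intercept": float(intercept), "r": r,
            "p": p, "n_bins": int(ok.sum())}
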