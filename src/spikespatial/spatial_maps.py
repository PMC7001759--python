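"""Locational firing analyses.

From a tracked path and a spike train this module builds dwell-normalised
firing-rate maps and derives the standard single-unit spatial statistics:
Skaggs information content (bits/spike), sparsity, spatial coherence, place
field detection, the 2D spatial autocorrelogram with its hexagonal
"gridness" score, and border/gradient analyses based on the distance to the
arena boundary estimated from the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LinearRing

from .errors import (FitError, InsufficientDataError, InvalidArgumentError,
                     UndefinedStatisticError)
from .io_session import SpatialTrack, SpikeTrain

DEFAULT_BIN_CM = 3.0
DEFAULT_SMOOTH_BINS = 5      # boxcar kernel side, bins
OCCUPANCY_FLOOR_S = 0.1      # bins with less dwell are masked


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RateMap:
    """Binned occupancy and firing rate with bin geometry.

    Arrays are indexed ``[ix, iy]`` with bin ``i`` covering
    ``[origin + i*bin_size, origin + (i+1)*bin_size)``.  ``rate`` is the
    smoothed estimate and is NaN on unvisited bins; ``rate_unsmoothed`` and
    raw spike ``counts`` are kept for statistics that must not see the
    smoothing kernel (spatial coherence, spike-count conservation).
    """

    occupancy: np.ndarray
    bin_size: float
    origin: tuple
    counts: Optional[np.ndarray] = None
    rate: Optional[np.ndarray] = None
    rate_unsmoothed: Optional[np.ndarray] = None
    visited: Optional[np.ndarray] = None
    smoothing: str = "none"

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if self.rate is not None else np.nan

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate over visited bins."""
        occ = self.occupancy[self.visited]
        lam = self.rate[self.visited]
        return float(np.sum(occ * lam) / np.sum(occ))

    def bin_centres(self):
        nx, ny = self.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return cx, cy


@dataclass
class PlaceField:
    """Connected high-rate region containing the map's peak."""

    bins: np.ndarray       # [n, 2] integer bin indices
    centroid: tuple        # cm
    size_cm2: float
    peak_rate: float
    mean_rate: float


@dataclass
class SpatialAutocorr:
    """Pearson correlation of the rate map with itself at integer offsets."""

    values: np.ndarray     # [2nx-1, 2ny-1], NaN where overlap < min_overlap
    bin_size: float

    @property
    def centre(self) -> tuple:
        return ((self.values.shape[0] - 1) // 2,
                (self.values.shape[1] - 1) // 2)


@dataclass
class GridScore:
    gridness: float
    spacing: float          # cm
    orientation: float      # deg in [0, 60)
    peak_radii: np.ndarray  # cm, the peripheral peaks used
    rotation_correlations: dict
    low_confidence: bool = False


@dataclass
class BorderModel:
    """Firing rate as a function of distance to the arena boundary."""

    boundary: np.ndarray        # closed polyline [n, 2] cm
    bin_distance: np.ndarray    # per map bin, cm
    distance_centres: np.ndarray
    distance_rates: np.ndarray
    distance_occupancy: np.ndarray
    correlation: float          # Pearson r between bin rate and bin distance
    gompertz: Optional[dict] = None


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def _bin_geometry(track: SpatialTrack, bin_size: float, geometry=None):
    if geometry is not None:
        return geometry
    x0, y0 = float(track.x.min()), float(track.y.min())
    nx = int(np.floor((track.x.max() - x0) / bin_size)) + 1
    ny = int(np.floor((track.y.max() - y0) / bin_size)) + 1
    return (x0, y0), nx, ny


def _bin_indices(x, y, origin, bin_size, nx, ny):
    ix = np.floor((x - origin[0]) / bin_size).astype(int)
    iy = np.floor((y - origin[1]) / bin_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    return ix, iy, ok


def occupancy_map(track: SpatialTrack, bin_size: float = DEFAULT_BIN_CM,
                  speed_filter: Optional[tuple] = None,
                  geometry=None) -> RateMap:
    """Dwell time (s) per spatial bin, half-open binning.

    ``speed_filter = (lo, hi)`` keeps only samples with speed in [lo, hi);
    total occupancy then equals the filtered tracked time.  ``geometry``
    fixes ``(origin, nx, ny)`` explicitly so maps of track subsets share a
    common grid.
    """
    if bin_size <= 0:
        raise InvalidArgumentError("bin size must be positive")
    origin, nx, ny = _bin_geometry(track, bin_size, geometry)
    x, y = track.x, track.y
    if speed_filter is not None:
        sp = track.channel("speed")
        keep = (sp >= speed_filter[0]) & (sp < speed_filter[1])
        x, y = x[keep], y[keep]
    occ = np.zeros((nx, ny))
    ix, iy, ok = _bin_indices(x, y, origin, bin_size, nx, ny)
    np.add.at(occ, (ix[ok], iy[ok]), track.dt)
    return RateMap(occupancy=occ, bin_size=bin_size, origin=origin,
                   visited=occ >= OCCUPANCY_FLOOR_S)


def spike_positions(train: SpikeTrain, track: SpatialTrack):
    """Interpolate the track at spike times; spikes outside the tracked
    period are dropped."""
    ts = train.timestamps
    keep = (ts >= track.t[0]) & (ts <= track.t[-1])
    ts = ts[keep]
    return np.interp(ts, track.t, track.x), np.interp(ts, track.t, track.y)


def rate_map(train: SpikeTrain, track: SpatialTrack,
             bin_size: float = DEFAULT_BIN_CM,
             smooth_bins: int = DEFAULT_SMOOTH_BINS,
             smooth_order: str = "pre",
             occupancy_floor: float = OCCUPANCY_FLOOR_S,
             geometry=None) -> RateMap:
    """Dwell-normalised locational firing-rate map.

    Spike counts and occupancy are binned on the same grid; with
    ``smooth_order="pre"`` (default) both are smoothed with a
    ``smooth_bins`` x ``smooth_bins`` boxcar *before* division, with
    ``"post"`` the raw-rate map is smoothed after division (a visited-bin
    aware mean).  Bins with raw dwell below ``occupancy_floor`` seconds are
    masked to NaN — rate estimates there would be dominated by noise.
    """
    if bin_size <= 0:
        raise InvalidArgumentError("bin size must be positive")
    occ_map = occupancy_map(track, bin_size, geometry=geometry)
    occ = occ_map.occupancy
    sx, sy = spike_positions(train, track)
    if sx.size == 0 and train.n_spikes > 0:
        raise InsufficientDataError("no spikes within the tracked period")
    counts = np.zeros_like(occ)
    ix, iy, ok = _bin_indices(sx, sy, occ_map.origin, bin_size,
                              *occ.shape)
    np.add.at(counts, (ix[ok], iy[ok]), 1.0)
    visited = occ >= occupancy_floor
    if not np.any(visited):
        raise InsufficientDataError("no bins exceed the occupancy floor")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_rate = np.where(visited, counts / np.where(occ > 0, occ, np.nan),
                            np.nan)
    if smooth_bins and smooth_bins > 1:
        if smooth_order == "pre":
            sc = ndimage.uniform_filter(counts, smooth_bins, mode="constant")
            so = ndimage.uniform_filter(occ, smooth_bins, mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(visited & (so > 0), sc / so, np.nan)
        elif smooth_order == "post":
            filled = np.where(visited, raw_rate, 0.0)
            num = ndimage.uniform_filter(filled, smooth_bins, mode="constant")
            den = ndimage.uniform_filter(visited.astype(float), smooth_bins,
                                         mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(visited & (den > 0), num / den, np.nan)
        else:
            raise InvalidArgumentError("smooth_order must be 'pre' or 'post'")
        smoothing = f"boxcar{smooth_bins}-{smooth_order}"
    else:
        rate, smoothing = raw_rate, "none"
    return RateMap(occupancy=occ, bin_size=bin_size, origin=occ_map.origin,
                   counts=counts, rate=rate, rate_unsmoothed=raw_rate,
                   visited=visited, smoothing=smoothing)


# ---------------------------------------------------------------------------
# scalar map statistics
# ---------------------------------------------------------------------------

def _visited_p_lambda(rmap: RateMap):
    occ = rmap.occupancy[rmap.visited]
    lam = rmap.rate[rmap.visited]
    ok = np.isfinite(lam)
    occ, lam = occ[ok], lam[ok]
    if occ.size == 0 or occ.sum() <= 0:
        raise UndefinedStatisticError("no visited bins with finite rate")
    return occ / occ.sum(), lam


def skaggs_information(rmap: RateMap) -> float:
    """Skaggs spatial information content in bits per spike.

    ``sum_i p_i (lambda_i / mean) log2(lambda_i / mean)`` with ``p_i`` the
    occupancy share of bin i and ``mean`` the occupancy-weighted mean rate;
    zero-rate bins contribute zero.  Always >= 0, and 0 only for a map that
    is uniform over the visited bins.
    """
    p, lam = _visited_p_lambda(rmap)
    mean = float(np.sum(p * lam))
    if mean <= 0:
        raise UndefinedStatisticError("mean rate is zero")
    pos = lam > 0
    ratio = lam[pos] / mean
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def sparsity(rmap: RateMap) -> float:
    """Occupancy-weighted sparsity ``(sum p lam)^2 / sum p lam^2`` in (0, 1];
    1 for a uniform map, 1/N when all firing sits in one of N equal bins."""
    p, lam = _visited_p_lambda(rmap)
    mean = float(np.sum(p * lam))
    denom = float(np.sum(p * lam ** 2))
    if mean <= 0 or denom <= 0:
        raise UndefinedStatisticError("mean rate is zero")
    return mean ** 2 / denom


def spatial_coherence(rmap: RateMap) -> float:
    """Correlation between each visited bin's (unsmoothed) rate and the mean
    rate of its visited 8-neighbours; a smoothness measure of the raw map."""
    rate = rmap.rate_unsmoothed if rmap.rate_unsmoothed is not None else rmap.rate
    visited = rmap.visited
    if int(visited.sum()) < 9:
        raise InsufficientDataError("need at least 9 visited bins")
    filled = np.where(visited, rate, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(filled, kernel, mode="constant")
    nb_n = ndimage.convolve(visited.astype(float), kernel, mode="constant")
    ok = visited & (nb_n > 0)
    a = rate[ok]
    b = nb_sum[ok] / nb_n[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("degenerate variance in coherence")
    return float(np.corrcoef(a, b)[0, 1])


def detect_place_field(rmap: RateMap, threshold_frac: float = 0.2,
                       min_bins: int = 9) -> Optional[PlaceField]:
    """4-connected region of bins above ``threshold_frac * peak`` that
    contains the global peak; ``None`` when no region qualifies."""
    rate = rmap.rate
    if not np.any(np.nan_to_num(rate) > 0):
        return None
    peak = np.nanmax(rate)
    mask = np.nan_to_num(rate) >= threshold_frac * peak
    labels, _ = ndimage.label(mask)  # default structure = 4-connectivity
    pk_idx = np.unravel_index(np.nanargmax(np.nan_to_num(rate)), rate.shape)
    lab = labels[pk_idx]
    member = np.argwhere(labels == lab)
    if lab == 0 or member.shape[0] < min_bins:
        return None
    cx, cy = rmap.bin_centres()
    occ = rmap.occupancy[member[:, 0], member[:, 1]]
    w = occ if occ.sum() > 0 else np.ones(member.shape[0])
    centroid = (float(np.sum(w * cx[member[:, 0]]) / w.sum()),
                float(np.sum(w * cy[member[:, 1]]) / w.sum()))
    rates = rate[member[:, 0], member[:, 1]]
    return PlaceField(bins=member, centroid=centroid,
                      size_cm2=member.shape[0] * rmap.bin_size ** 2,
                      peak_rate=float(peak),
                      mean_rate=float(np.nanmean(rates)))


# ---------------------------------------------------------------------------
# spatial autocorrelation and gridness
# ---------------------------------------------------------------------------

def spatial_autocorrelation(rmap: RateMap,
                            min_overlap: int = 20) -> SpatialAutocorr:
    """Pearson correlation of the map with itself at every integer bin
    offset, using pairwise-complete visited bins; offsets with fewer than
    ``min_overlap`` overlapping bins are NaN.  Symmetric under offset
    negation; exactly 1 at zero offset."""
    rate = np.where(rmap.visited, rmap.rate, np.nan)
    nx, ny = rate.shape
    if int(rmap.visited.sum()) < 4:
        raise InsufficientDataError("need at least 2x2 visited bins")
    out = np.full((2 * nx - 1, 2 * ny - 1), np.nan)
    for dx in range(-(nx - 1), nx):
        ax0, ax1 = max(0, dx), min(nx, nx + dx)
        bx0, bx1 = max(0, -dx), min(nx, nx - dx)
        for dy in range(-(ny - 1), ny):
            ay0, ay1 = max(0, dy), min(ny, ny + dy)
            by0, by1 = max(0, -dy), min(ny, ny - dy)
            a = rate[ax0:ax1, ay0:ay1]
            b = rate[bx0:bx1, by0:by1]
            ok = np.isfinite(a) & np.isfinite(b)
            n = int(ok.sum())
            if n < min_overlap:
                continue
            av, bv = a[ok], b[ok]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
            out[dx + nx - 1, dy + ny - 1] = r
    return SpatialAutocorr(values=out, bin_size=rmap.bin_size)


def _rotated_annulus_correlation(values, mask, angle):
    """Pearson correlation between the annulus and its rotation by ``angle``
    degrees about the centre."""
    filled = np.nan_to_num(values)
    valid = np.isfinite(values).astype(float)
    rot = ndimage.rotate(filled, angle, reshape=False, order=1, mode="constant")
    rot_valid = ndimage.rotate(valid, angle, reshape=False, order=1,
                               mode="constant")
    ok = mask & np.isfinite(values) & (rot_valid > 0.99)
    a, b = values[ok], rot[ok]
    if a.size < 20 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def grid_score(autocorr: SpatialAutocorr) -> GridScore:
    """Hexagonal regularity of the spatial autocorrelogram.

    The six peripheral peaks nearest the centre define the grid spacing
    (median peak distance) and orientation (angle of the nearest peak,
    mod 60).  Gridness is computed on an annulus that excludes the central
    peak and extends to 1.2x the median peak radius:
    ``min(corr at 60, 120) - max(corr at 30, 90, 150)`` of the annulus with
    its own rotation.  With fewer than six detectable peaks a fallback outer
    radius (80% of the map half-width) is used and the result flagged
    low-confidence.
    """
    v = autocorr.values
    cxi, cyi = autocorr.centre
    nx, ny = v.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rad = np.hypot(ii - cxi, jj - cyi)
    # central peak extent: connected region > 0.3 around the centre
    core = np.nan_to_num(v) > 0.3
    labels, _ = ndimage.label(core)
    central_lab = labels[cxi, cyi]
    if central_lab > 0:
        r_central = float(rad[labels == central_lab].max()) + 1.0
    else:
        r_central = 2.0
    # peripheral local maxima
    filled = np.nan_to_num(v, nan=-1.0)
    is_max = (ndimage.maximum_filter(filled, size=3) == filled) & (filled > 0.1)
    is_max &= rad > r_central
    peaks = np.argwhere(is_max)
    low_confidence = False
    if peaks.shape[0] >= 6:
        d = np.hypot(peaks[:, 0] - cxi, peaks[:, 1] - cyi)
        order = np.argsort(d)[:6]
        six = peaks[order]
        radii = d[order]
        r_outer = 1.2 * float(np.median(radii))
        spacing = float(np.median(radii)) * autocorr.bin_size
        ang = np.degrees(np.arctan2(six[:, 1] - cyi, six[:, 0] - cxi)) % 60.0
        nearest = int(np.argmin(radii))
        orientation = float(np.degrees(np.arctan2(
            six[nearest, 1] - cyi, six[nearest, 0] - cxi)) % 60.0)
        peak_radii = radii * autocorr.bin_size
    else:
        low_confidence = True
        r_outer = 0.8 * min(cxi, cyi)
        spacing = np.nan
        orientation = np.nan
        peak_radii = np.empty(0)
    r_outer = min(r_outer, min(cxi, cyi) - 0.5)
    if r_outer <= r_central + 1:
        r_outer = r_central + 2
        low_confidence = True
    mask = (rad >= r_central) & (rad <= r_outer)
    corrs = {a: _rotated_annulus_correlation(v, mask, a)
             for a in (30, 60, 90, 120, 150)}
    on = [corrs[60], corrs[120]]
    off = [corrs[30], corrs[90], corrs[150]]
    gridness = float(np.nanmin(on) - np.nanmax(off))
    return GridScore(gridness=gridness, spacing=spacing,
                     orientation=orientation, peak_radii=peak_radii,
                     rotation_correlations=corrs,
                     low_confidence=low_confidence)


# ---------------------------------------------------------------------------
# border and gradient analyses
# ---------------------------------------------------------------------------

def estimate_border(track: SpatialTrack) -> np.ndarray:
    """Arena boundary estimated as the convex hull of the traversed path.

    Returns a closed polyline ``[n+1, 2]`` in cm.  The hull is robust to
    trajectories that cut corners, unlike wall detection from coordinate
    extrema.
    """
    pts = np.column_stack([track.x, track.y])
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise FitError(f"degenerate path, cannot estimate boundary: {exc}")
    verts = pts[hull.vertices]
    return np.vstack([verts, verts[:1]])


def distance_to_boundary(x, y, boundary: np.ndarray) -> np.ndarray:
    """Distance (cm) from each point to the boundary polyline."""
    ring = LinearRing(boundary)
    pts = shapely.points(np.column_stack([np.asarray(x, float).ravel(),
                                          np.asarray(y, float).ravel()]))
    d = shapely.distance(pts, ring)
    return d.reshape(np.shape(x))


def polygon_area(boundary: np.ndarray) -> float:
    from shapely.geometry import Polygon
    return float(Polygon(boundary).area)


def border_analysis(rmap: RateMap, boundary: np.ndarray,
                    distance_bin: float = 3.0) -> BorderModel:
    """Firing rate as a function of distance from the boundary.

    Each visited map bin contributes its rate at the distance of its centre
    from the boundary; the distance-binned curve is an occupancy-weighted
    mean, and the reported correlation is the product-moment correlation
    between per-bin rate and distance (negative for border-hugging units).
    """
    cx, cy = rmap.bin_centres()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    dist = distance_to_boundary(gx, gy, boundary)
    ok = rmap.visited & np.isfinite(rmap.rate)
    d = dist[ok]
    lam = rmap.rate[ok]
    occ = rmap.occupancy[ok]
    if d.size < 3 or np.std(d) == 0 or np.std(lam) == 0:
        raise UndefinedStatisticError("degenerate border-distance data")
    r = float(np.corrcoef(lam, d)[0, 1])
    edges = np.arange(0.0, d.max() + distance_bin, distance_bin)
    idx = np.minimum(np.floor(d / distance_bin).astype(int), edges.size - 2)
    n_bins = edges.size - 1
    wsum = np.bincount(idx, weights=occ * lam, minlength=n_bins)
    w = np.bincount(idx, weights=occ, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(w > 0, wsum / np.where(w > 0, w, 1.0), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return BorderModel(boundary=boundary, bin_distance=dist,
                       distance_centres=centres, distance_rates=curve,
                       distance_occupancy=w, correlation=r)


def _gompertz(d, a, b, c):
    return a * np.exp(-b * np.exp(-c * d))


def gradient_fit(model: BorderModel, n_restarts: int = 8,
                 restart_seed: int = 0) -> dict:
    """Fit a Gompertz curve ``a exp(-b exp(-c d))`` to rate vs distance.

    The Gompertz sigmoid grows slowly both at the border and towards the
    arena centre, which matches "gradient" units whose rate rises smoothly
    away from the wall.  Reports the three parameters, the inflection
    distance ``ln(b)/c`` and R^2.  Raises ``FitError`` when no restart
    converges, and flags ``is_gradient=False`` when the fit explains little
    variance or degenerates to a constant.
    """
    ok = np.isfinite(model.distance_rates)
    d = model.distance_centres[ok]
    y = model.distance_rates[ok]
    if d.size < 6:
        raise InsufficientDataError("need at least 6 distance bins")
    rng = np.random.default_rng(restart_seed)
    ymax = max(float(y.max()), 1e-9)
    best = None
    starts = [(ymax, 5.0, 0.3)] + [
        (ymax * rng.uniform(0.5, 1.5), rng.uniform(0.5, 20.0),
         rng.uniform(0.01, 1.0)) for _ in range(n_restarts - 1)]
    for p0 in starts:
        try:
            popt, _ = curve_fit(_gompertz, d, y, p0=p0, maxfev=10000,
                                bounds=([0.0, 1e-9, 1e-9],
                                        [np.inf, np.inf, np.inf]))
        except (RuntimeError, ValueError):
            continue
        resid = y - _gompertz(d, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("Gompertz fit did not converge in any restart")
    sse, (a, b, c) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return {"a": float(a), "b": float(b), "c": float(c),
            "inflection_cm": float(np.log(b) / c) if b > 0 and c > 0 else np.nan,
            "r_squared": float(r2),
            "is_gradient": bool(r2 > 0.5 and c > 1e-3)}
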