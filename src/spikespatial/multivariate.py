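"""Multi-predictor firing-rate regression and population classification.

The instantaneous firing rate of a unit is regressed on five behavioural
predictors — location, head direction, speed, angular velocity and border
distance.  Because tuning shapes are idiosyncratic (a place field is not a
plane), each predictor enters the design not as its raw value but as the
unit's *average-rate-map value* at the animal's current state; a perfectly
location-driven unit then has a location column that is itself the expected
rate.  Predictive power is the semi-partial r-squared of each predictor
(the drop in total R-squared when it is removed); the partial r-squared is
also reported.  Population classification clusters units by their
per-variable coefficients with k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InsufficientDataError, InvalidArgumentError
from .io_session import SpatialTrack, SpikeTrain
from .spatial_maps import RateMap, _bin_indices
from .tuning_1d import TuningCurve

PREDICTORS = ("location", "hd", "speed", "ahv", "border_distance")
DEFAULT_TIME_BIN_S = 0.1


@dataclass
class RateDesign:
    """Time-binned observed rate plus rate-map-encoded predictor columns."""

    observed: np.ndarray           # Hz per kept time bin
    predictors: pd.DataFrame       # one column per predictor
    time_bin: float
    n_dropped: int

    @property
    def n_bins(self) -> int:
        return int(self.observed.size)


@dataclass
class RegressionResult:
    r_squared: float
    semi_partial_r2: dict          # predictor -> R2(full) - R2(without)
    partial_r2: dict               # predictor -> (R2f - R2r) / (1 - R2r)
    coefficients: dict
    n_bins: int
    degenerate: bool = False
    dropped_columns: tuple = ()


def _curve_lookup(curve: TuningCurve, values: np.ndarray) -> np.ndarray:
    """Average-rate value of a 1D tuning curve at arbitrary variable values.

    Values beyond the curve's range (e.g. speeds above the cap) are clamped
    to the edge bins, so tail states do not discard whole time bins; bins
    the animal never occupied still yield NaN.
    """
    lo = curve.centres[0] - curve.bin_width / 2
    idx = np.floor((values - lo) / curve.bin_width).astype(int)
    idx = np.clip(idx, 0, curve.centres.size - 1)
    return curve.rate[idx]


def build_design(train: SpikeTrain, track: SpatialTrack, maps: dict,
                 time_bin: float = DEFAULT_TIME_BIN_S) -> RateDesign:
    """Assemble the regression design matrix.

    ``maps`` holds the unit's average-rate structures:
    ``{"location": RateMap, "hd"|"speed"|"ahv"|"border_distance":
    TuningCurve}``.  For each time bin the observed rate is the spike count
    divided by the bin width, and each predictor column is the average-rate
    value at the state (position / heading / speed / ...) averaged over the
    track samples in the bin.  Bins whose state falls in unvisited map or
    curve bins are dropped; more than 50% dropped raises.
    """
    missing = [k for k in PREDICTORS if k not in maps]
    if missing:
        raise InvalidArgumentError(f"maps missing predictors {missing}")
    duration = track.duration
    n_bins = int(duration / time_bin)
    if n_bins < 10:
        raise InsufficientDataError("too few time bins")
    # per-sample predictor values
    rmap: RateMap = maps["location"]
    ix, iy, ok = _bin_indices(track.x, track.y, rmap.origin, rmap.bin_size,
                              *rmap.shape)
    loc_val = np.full(track.n, np.nan)
    loc_val[ok] = rmap.rate[ix[ok], iy[ok]]
    cols = {"location": loc_val}
    for name in PREDICTORS[1:]:
        cols[name] = _curve_lookup(maps[name], track.channel(name))
    # average per time bin
    bin_idx = np.minimum((track.t / time_bin).astype(int), n_bins - 1)
    design = {}
    for name, vals in cols.items():
        finite = np.isfinite(vals)
        s = np.bincount(bin_idx[finite], weights=vals[finite],
                        minlength=n_bins)
        c = np.bincount(bin_idx[finite], minlength=n_bins)
        c_all = np.bincount(bin_idx, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            design[name] = np.where((c > 0) & (c == c_all),
                                    s / np.where(c > 0, c, 1.0), np.nan)
    counts = np.histogram(train.timestamps,
                          bins=np.arange(0.0, (n_bins + 1) * time_bin,
                                         time_bin)[:n_bins + 1])[0]
    observed = counts / time_bin
    df = pd.DataFrame(design)
    keep = df.notna().all(axis=1).values
    n_dropped = int((~keep).sum())
    if n_dropped > 0.5 * n_bins:
        raise InsufficientDataError(
            f"{n_dropped}/{n_bins} time bins in unvisited states")
    return RateDesign(observed=observed[keep], predictors=df.loc[keep],
                      time_bin=time_bin, n_dropped=n_dropped)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        return 0.0
    return 1.0 - float(resid @ resid) / sst


def fit_rate_regression(design: RateDesign) -> RegressionResult:
    """Ordinary least squares of observed rate on all predictors.

    The predictive power of predictor j is the semi-partial r-squared
    ``R2(full) - R2(all but j)``; the partial r-squared normalises by the
    unexplained variance of the reduced model.  Collinear columns are
    dropped with a warning; a degenerate (constant) observed rate is
    flagged.  Both quantities are invariant to affine rescaling of the
    predictor columns.
    """
    y = design.observed
    names = list(design.predictors.columns)
    if design.n_bins < 10 * len(names):
        raise InsufficientDataError("need >= 10x more time bins than predictors")
    X = design.predictors.values.astype(float)
    degenerate = float(np.std(y)) == 0.0
    # drop collinear / constant columns
    dropped = []
    keep_idx = []
    for j in range(X.shape[1]):
        cand = X[:, keep_idx + [j]]
        if np.std(X[:, j]) == 0 or np.linalg.matrix_rank(
                np.column_stack([np.ones(y.size), cand])) < cand.shape[1] + 1:
            dropped.append(names[j])
        else:
            keep_idx.append(j)
    if dropped:
        warnings.warn(f"dropping collinear/constant predictors: {dropped}")
    kept = [names[j] for j in keep_idx]
    Xk = X[:, keep_idx]
    if not kept or degenerate:
        return RegressionResult(0.0, {n: 0.0 for n in names},
                                {n: 0.0 for n in names},
                                {n: 0.0 for n in names}, design.n_bins,
                                degenerate=True, dropped_columns=tuple(dropped))
    r2_full = _ols_r2(y, Xk)
    Xc = np.column_stack([np.ones(y.size), Xk])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    coefs = {n: float(b) for n, b in zip(kept, beta[1:])}
    semi = {}
    partial = {}
    for j, name in enumerate(kept):
        rest = np.delete(Xk, j, axis=1)
        r2_red = _ols_r2(y, rest) if rest.shape[1] else 0.0
        semi[name] = max(0.0, r2_full - r2_red)
        partial[name] = (max(0.0, r2_full - r2_red) / (1.0 - r2_red)
                         if r2_red < 1.0 else 0.0)
    for name in dropped:
        semi[name] = 0.0
        partial[name] = 0.0
        coefs[name] = 0.0
    return RegressionResult(r_squared=r2_full, semi_partial_r2=semi,
                            partial_r2=partial, coefficients=coefs,
                            n_bins=design.n_bins, degenerate=degenerate,
                            dropped_columns=tuple(dropped))


def classify_units(coeff_table: pd.DataFrame, k: int = 2, seed: int = 0,
                   hd_column: str = "hd") -> dict:
    """K-means classification of units from per-variable coefficients.

    Columns are standardized (z-scored) before clustering; k-means runs with
    20 restarts from a fixed seed.  The head-direction cluster is identified
    as the centroid with the largest (unstandardized) mean value in
    ``hd_column``.  Returns labels (input order), centroids in original
    units, and the HD cluster label.
    """
    if coeff_table.isna().any().any():
        raise InvalidArgumentError("coefficient table contains missing values")
    n = len(coeff_table)
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > n:
        raise InvalidArgumentError("k exceeds the number of units")
    X = coeff_table.values.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(Z)
    centroids = km.cluster_centers_ * sd + mu
    cent = pd.DataFrame(centroids, columns=coeff_table.columns)
    hd_label = int(cent[hd_column].idxmax()) if hd_column in cent else 0
    return {"labels": labels, "centroids": cent, "hd_label": hd_label}
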