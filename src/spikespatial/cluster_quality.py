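"""Waveform-feature extraction and cluster-separation metrics.

Spike-sorting quality is quantified by the overlap between per-spike
waveform-feature clouds: the Bhattacharyya coefficient (1 for identical
distributions, 0 for disjoint) under a Gaussian closed form, and the
derived Hellinger distance ``sqrt(1 - BC)``.  The same metrics compare a
cluster across recordings to flag a unit recorded twice.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import InvalidArgumentError, MissingDataError
from .io_session import SpikeTrain

FEATURES_PER_CHANNEL = ("peak", "trough", "energy", "width_us")
RIDGE_FRACTION = 1e-6  # of trace/dim, added to singular covariances


@dataclass
class FeatureCloud:
    """Per-spike feature vectors for one cluster."""

    features: np.ndarray     # [n_spikes, n_features]
    names: tuple
    label: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] < 2:
            raise InvalidArgumentError(
                "feature cloud needs >= 2 spikes of fixed dimension")


def waveform_features(train: SpikeTrain, label: str = "") -> FeatureCloud:
    """Per-spike, per-channel features: peak, trough, energy and
    peak-to-trough width (microseconds)."""
    if train.waveforms is None:
        raise MissingDataError("spike train carries no waveforms")
    wf = train.waveforms
    n_spikes, n_chan, _ = wf.shape
    dt_us = 1e6 / (train.waveform_rate or 1.0)
    cols = []
    names = []
    for c in range(n_chan):
        w = wf[:, c, :]
        ipk = np.argmax(w, axis=1)
        peak = w[np.arange(n_spikes), ipk]
        # trough after the peak; fall back to global min when peak is last
        trough = np.empty(n_spikes)
        width = np.empty(n_spikes)
        for s in range(n_spikes):
            after = w[s, ipk[s]:]
            if after.size > 1:
                j = int(np.argmin(after))
                trough[s] = after[j]
                width[s] = j * dt_us
            else:
                trough[s] = w[s].min()
                width[s] = 0.0
        energy = np.sum(w ** 2, axis=1)
        cols.extend([peak, trough, energy, width])
        names.extend([f"ch{c}_{f}" for f in FEATURES_PER_CHANNEL])
    return FeatureCloud(np.column_stack(cols), tuple(names), label)


def _moments(cloud: FeatureCloud):
    x = cloud.features
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    return mu, cov


def _regularize(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        ridge = RIDGE_FRACTION * np.trace(cov) / d
        ridge = max(ridge, 1e-12)
        warnings.warn("singular covariance regularized with ridge "
                      f"{ridge:.3g}")
        return cov + ridge * np.eye(d)


def bhattacharyya_coefficient(a: FeatureCloud, b: FeatureCloud) -> float:
    """Gaussian closed-form Bhattacharyya coefficient from sample moments.

    ``BC = exp(-D_B)`` with
    ``D_B = (mu1-mu2)' S^-1 (mu1-mu2) / 8 + ln(det S / sqrt(det S1 det S2)) / 2``
    and ``S`` the average covariance.  Symmetric in its arguments and
    invariant under a common affine transform of both clouds.
    """
    if a.features.shape[1] != b.features.shape[1]:
        raise InvalidArgumentError("clouds must share a feature dimension")
    mu1, c1 = _moments(a)
    mu2, c2 = _moments(b)
    c1 = _regularize(c1)
    c2 = _regularize(c2)
    cm = _regularize((c1 + c2) / 2.0)
    diff = mu1 - mu2
    term1 = float(diff @ np.linalg.solve(cm, diff)) / 8.0
    s, logdet_m = np.linalg.slogdet(cm)
    _, logdet_1 = np.linalg.slogdet(c1)
    _, logdet_2 = np.linalg.slogdet(c2)
    term2 = 0.5 * (logdet_m - 0.5 * (logdet_1 + logdet_2))
    db = term1 + term2
    return float(np.clip(np.exp(-db), 0.0, 1.0))


def hellinger_distance(a: FeatureCloud, b: FeatureCloud) -> float:
    """``sqrt(1 - BC)``; a metric in [0, 1], 0 for identical clusters."""
    return float(np.sqrt(max(0.0, 1.0 - bhattacharyya_coefficient(a, b))))
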