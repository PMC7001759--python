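"""Figure builders for every analysis family.

Each function returns a matplotlib ``Figure``; the per-unit driver decides
filenames and formats.  The non-interactive Agg backend is forced so batch
runs work headless.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _fig(title: str):
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.set_title(title, fontsize=9)
    return fig, ax


def fig_waveform(summary):
    n_chan = summary.mean.shape[0]
    fig, axes = plt.subplots(1, n_chan, figsize=(2.2 * n_chan, 2.5),
                             sharey=True)
    axes = np.atleast_1d(axes)
    t = np.arange(summary.mean.shape[1]) / summary.rate * 1e3
    for c, ax in enumerate(axes):
        ax.plot(t, summary.mean[c], "k", lw=1)
        ax.fill_between(t, summary.mean[c] - summary.sd[c],
                        summary.mean[c] + summary.sd[c], color="g", alpha=0.3)
        ax.set_xlabel("ms")
    axes[0].set_ylabel("uV")
    fig.suptitle("mean waveform +/- SD", fontsize=9)
    return fig


def fig_correlogram(corr, title="ISI histogram", refractory=None):
    fig, ax = _fig(title)
    ax.bar(corr.centres * 1e3, corr.counts, width=corr.bin_width * 1e3,
           color="0.3")
    if refractory is not None:
        ax.axvline(refractory * 1e3, color="r", ls=":")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("count")
    return fig


def fig_theta_fit(corr, fit):
    from .spike_metrics import _theta_model
    fig, ax = _fig(f"ACG theta fit f={fit.frequency:.1f} Hz "
                   f"MI={fit.modulation_index:.2f}")
    ax.bar(corr.centres * 1e3, corr.counts, width=corr.bin_width * 1e3,
           color="0.6")
    if np.isfinite(fit.frequency):
        tau = corr.centres
        p = fit.params
        scale = max(corr.counts.max(), 1)
        model = _theta_model(tau, p["a"], p["f"], p["d"], p["c"])
        ax.plot(tau * 1e3, model, "r", lw=1)
    ax.set_xlabel("lag (ms)")
    return fig


def fig_path_spikes(track, train):
    fig, ax = _fig("path and spikes")
    ax.plot(track.x, track.y, "k", lw=0.3)
    sx = np.interp(train.timestamps, track.t, track.x)
    sy = np.interp(train.timestamps, track.t, track.y)
    ax.plot(sx, sy, "r.", ms=2)
    ax.set_aspect("equal")
    ax.set_xlabel("cm")
    return fig


def fig_rate_map(rmap, title="firing rate map"):
    fig, ax = _fig(title)
    cx, cy = rmap.bin_centres()
    im = ax.pcolormesh(cx, cy, rmap.rate.T, shading="nearest",
                       cmap="viridis")
    fig.colorbar(im, ax=ax, label="Hz")
    ax.set_aspect("equal")
    return fig


def fig_spatial_autocorr(ac):
    fig, ax = _fig("spatial autocorrelation")
    im = ax.imshow(ac.values.T, origin="lower", cmap="jet", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax)
    return fig


def fig_polar_tuning(curve, stats=None):
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    theta = np.radians(np.append(curve.centres, curve.centres[0]))
    r = np.nan_to_num(np.append(curve.rate, curve.rate[0]))
    ax.plot(theta, r, "b", lw=1)
    title = "head-direction tuning"
    if stats is not None:
        title += f" (R={stats.resultant_length:.2f})"
    ax.set_title(title, fontsize=9)
    return fig


def fig_linear_tuning(curve, fit=None, title="speed tuning"):
    fig, ax = _fig(title)
    ax.plot(curve.centres, curve.rate, "ko", ms=3)
    if fit is not None:
        x = np.array([curve.centres[0], curve.centres[-1]])
        ax.plot(x, fit["intercept"] + fit["slope"] * x, "r", lw=1)
    ax.set_xlabel(curve.variable)
    ax.set_ylabel("Hz")
    return fig


def fig_border(model):
    fig, ax = _fig(f"rate vs border distance (r={model.correlation:.2f})")
    ax.plot(model.distance_centres, model.distance_rates, "k.-", lw=1)
    ax.set_xlabel("distance to border (cm)")
    ax.set_ylabel("Hz")
    return fig


def fig_shuffle(null):
    fig, ax = _fig(f"shuffled {null.statistic} (n={null.n_shuffles})")
    ax.hist(null.values, bins=40, color="0.5")
    ax.axvline(null.cutoffs[0], color="r",
               label=f"{null.percentile_levels[0]:g}th pct")
    ax.axvline(null.observed, color="b", label="observed")
    ax.legend(fontsize=7)
    return fig


def fig_shift_profile(profile):
    fig, ax = _fig("time-shift profile")
    ax.plot(profile.shifts * 1e3, profile.values, "k.-")
    ax.axvline(profile.argmax_shift * 1e3, color="r", ls=":")
    ax.set_xlabel("shift (ms)")
    return fig


def fig_regression(result):
    fig, ax = _fig(f"predictive power (R2={result.r_squared:.2f})")
    names = list(result.semi_partial_r2)
    vals = [result.semi_partial_r2[n] for n in names]
    ax.bar(names, vals, color="0.4")
    ax.set_ylabel("semi-partial r2")
    ax.tick_params(axis="x", labelsize=7, rotation=30)
    return fig


def fig_spectrum(spec):
    fig, ax = _fig("LFP power spectrum")
    ax.semilogy(spec.frequencies, spec.power, "k", lw=1)
    ax.set_xlim(0, 50)
    ax.set_xlabel("Hz")
    ax.set_ylabel("uV^2/Hz")
    return fig


def fig_phase(sample):
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    counts, edges = np.histogram(np.radians(sample.phases),
                                 bins=36, range=(0, 2 * np.pi))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="0.5")
    ax.plot([np.radians(sample.mean_phase)] * 2, [0, counts.max()], "r")
    ax.set_title(f"spike phases (mean {sample.mean_phase:.0f} deg)",
                 fontsize=9)
    return fig


def fig_coupling(plv_profile, sfc_profile):
    fig, ax = _fig("spike-field coupling")
    ax.plot(plv_profile.frequencies, plv_profile.plv, "b", label="PLV")
    ax2 = ax.twinx()
    ax2.plot(sfc_profile.frequencies, sfc_profile.sfc, "r", label="SFC (%)")
    ax.set_xlabel("Hz")
    ax.set_ylabel("PLV")
    ax2.set_ylabel("SFC (%)")
    return fig
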