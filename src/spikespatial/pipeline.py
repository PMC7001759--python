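"""Per-unit and batch drivers: run enabled analyses, collect one results row
per unit, save figures, and append parametric results to the session file.

Per-analysis failures are caught, logged into the results row (column
``error_<analysis>``) and do not stop the run; batch entries are isolated
the same way.  All randomized analyses draw from one generator seeded per
unit from the config seed, so a fixed config and seed reproduce the results
table byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import (cluster_quality, lfp_coupling, multivariate, plots,
               randomization, spatial_maps, spike_metrics, tuning_1d)
from .config import AnalysisConfig
from .errors import InvalidArgumentError, SpikeSpatialError
from .io_session import (Session, append_results, derive_kinematics,
                         make_unit_id, read_session, verify_batch)

log = logging.getLogger("spikespatial")


def _ensure_kinematics(session: Session) -> None:
    if session.spatial.speed is None:
        session.spatial = derive_kinematics(session.spatial)


def _round_floats(row: dict, ndigits: int = 6) -> dict:
    out = {}
    for k, v in row.items():
        if isinstance(v, (float, np.floating)):
            out[k] = round(float(v), ndigits)
        elif isinstance(v, (np.integer,)):
            out[k] = int(v)
        else:
            out[k] = v
    return out


def run_unit(session: Session, tetrode_no: int, unit_no: int,
             config: AnalysisConfig, out_dir, session_path=None) -> dict:
    """Run every enabled analysis on one unit.

    Returns ``{"row": dict, "figures": [paths]}``.  Figures are written as
    ``<unit_id>_<analysis>.<ext>`` into ``out_dir``; scalar results are
    appended under the unit's results group when ``session_path`` is given.
    """
    _ensure_kinematics(session)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train = session.unit(tetrode_no, unit_no)
    track = session.spatial
    lfp = session.lfps.get(config.lfp_name)
    unit_id = make_unit_id(session.record_id, tetrode_no, unit_no,
                           config.lfp_name)
    seed = int(np.random.default_rng(
        [config.seed, tetrode_no, unit_no]).integers(2 ** 31))
    row = {"unit_id": unit_id, "record_id": session.record_id,
           "tetrode": tetrode_no, "unit": unit_no,
           "n_spikes": train.n_spikes, "mean_rate": train.mean_rate,
           "seed": seed}
    figures = []
    enabled = set(config.analyses)
    ext = config.figure_format
    cache = {}

    def save(name, fig):
        path = out_dir / f"{unit_id}_{name}.{ext}"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        figures.append(path)

    def step(name, fn):
        if name not in enabled:
            return
        try:
            fn()
            log.info("%s: %s ok", unit_id, name)
        except SpikeSpatialError as exc:
            row[f"error_{name}"] = str(exc)
            log.warning("%s: %s failed: %s", unit_id, name, exc)

    def get_rate_map():
        if "rmap" not in cache:
            cache["rmap"] = spatial_maps.rate_map(
                train, track, bin_size=config.map_bin_cm,
                smooth_bins=config.map_smooth_bins,
                smooth_order=config.smooth_order)
        return cache["rmap"]

    # --- spike-train analyses -------------------------------------------
    def do_waveform():
        s = spike_metrics.waveform_properties(train)
        row["wave_amplitude_uv"] = float(np.max(s.amplitude))
        row["wave_width_us"] = float(np.nanmean(s.width_us))
        save("waveform", plots.fig_waveform(s))

    def do_isi():
        corr, viol = spike_metrics.isi_histogram(train)
        row["refractory_violations"] = viol
        burst = spike_metrics.burst_properties(train)
        row["burst_propensity"] = burst["propensity"]
        row["n_bursts"] = burst["n_bursts"]
        save("isi", plots.fig_correlogram(corr, "ISI histogram",
                                          spike_metrics.REFRACTORY_S))

    def do_autocorr():
        cache["acg"] = spike_metrics.isi_autocorrelation(train)
        save("autocorr", plots.fig_correlogram(cache["acg"],
                                               "spike-train autocorrelogram"))

    def do_theta():
        acg = cache.get("acg") or spike_metrics.isi_autocorrelation(train)
        fit = spike_metrics.theta_indices(acg)
        row["theta_frequency"] = fit.frequency
        row["theta_modulation_index"] = fit.modulation_index
        row["theta_skipping_index"] = fit.skipping_index
        save("theta", plots.fig_theta_fit(acg, fit))

    # --- spatial analyses ------------------------------------------------
    def do_ratemap():
        rmap = get_rate_map()
        row["peak_rate"] = rmap.peak_rate
        row["mean_map_rate"] = rmap.mean_rate
        row["skaggs_bits_per_spike"] = spatial_maps.skaggs_information(rmap)
        row["sparsity"] = spatial_maps.sparsity(rmap)
        row["spatial_coherence"] = spatial_maps.spatial_coherence(rmap)
        save("path", plots.fig_path_spikes(track, train))
        save("ratemap", plots.fig_rate_map(rmap))

    def do_place_field():
        f = spatial_maps.detect_place_field(get_rate_map())
        if f is None:
            row["field_size_cm2"] = np.nan
        else:
            row["field_size_cm2"] = f.size_cm2
            row["field_x"] = f.centroid[0]
            row["field_y"] = f.centroid[1]
            row["field_peak_rate"] = f.peak_rate

    def do_grid():
        ac = spatial_maps.spatial_autocorrelation(get_rate_map())
        g = spatial_maps.grid_score(ac)
        row["gridness"] = g.gridness
        row["grid_spacing_cm"] = g.spacing
        row["grid_orientation_deg"] = g.orientation
        save("grid", plots.fig_spatial_autocorr(ac))

    def get_border_model():
        if "border" not in cache:
            boundary = spatial_maps.estimate_border(track)
            cache["border"] = spatial_maps.border_analysis(get_rate_map(),
                                                           boundary)
        return cache["border"]

    def do_border():
        m = get_border_model()
        row["border_rate_distance_r"] = m.correlation
        save("border", plots.fig_border(m))

    def do_gradient():
        fit = spatial_maps.gradient_fit(get_border_model())
        row["gompertz_a"] = fit["a"]
        row["gompertz_b"] = fit["b"]
        row["gompertz_c"] = fit["c"]
        row["gompertz_r2"] = fit["r_squared"]

    # --- 1D tuning -------------------------------------------------------
    def do_hd():
        curve = tuning_1d.tuning_curve(train, track, "hd",
                                       bin_width=config.hd_bin_deg)
        stats = tuning_1d.circular_stats(curve)
        row["hd_preferred_deg"] = stats.preferred_direction
        row["hd_peak_rate"] = stats.peak_rate
        row["hd_resultant"] = stats.resultant_length
        row["hd_rayleigh_z"] = stats.rayleigh_z
        row["hd_rayleigh_p"] = stats.rayleigh_p
        row["hd_kappa"] = stats.kappa
        row["hd_half_width_deg"] = stats.half_width
        _, ratio = tuning_1d.expected_rate_from_place(get_rate_map(), track,
                                                      "hd", observed=curve)
        row["hd_distributive_ratio"] = ratio
        save("hd", plots.fig_polar_tuning(curve, stats))

    def do_speed():
        curve = tuning_1d.tuning_curve(train, track, "speed",
                                       bin_width=config.speed_bin)
        fit = tuning_1d.linear_rate_correlation(curve)
        row["speed_slope"] = fit["slope"]
        row["speed_r"] = fit["r"]
        row["speed_p"] = fit["p"]
        save("speed", plots.fig_linear_tuning(curve, fit))

    def do_ahv():
        split = tuning_1d.hd_by_rotation(train, track,
                                         config.ahv_threshold)
        for name in ("cw", "ccw"):
            curve = tuning_1d.tuning_curve(
                train, track, "ahv", bin_width=config.ahv_bin,
                value_range=((-200.0, 0.0) if name == "cw" else (0.0, 200.0)))
            try:
                fit = tuning_1d.linear_rate_correlation(curve)
                row[f"ahv_{name}_slope"] = fit["slope"]
                row[f"ahv_{name}_r"] = fit["r"]
            except SpikeSpatialError:
                row[f"ahv_{name}_slope"] = np.nan
        if split["flags"]:
            row["ahv_flags"] = ";".join(split["flags"])

    # --- multivariate ----------------------------------------------------
    def do_regression():
        maps = {"location": get_rate_map()}
        for name in ("hd", "speed", "ahv", "border_distance"):
            maps[name] = tuning_1d.tuning_curve(train, track, name)
        design = multivariate.build_design(train, track, maps,
                                           time_bin=config.time_bin_s)
        res = multivariate.fit_rate_regression(design)
        row["regression_r2"] = res.r_squared
        for name in multivariate.PREDICTORS:
            row[f"pp_{name}"] = res.semi_partial_r2.get(name, np.nan)
            row[f"partial_r2_{name}"] = res.partial_r2.get(name, np.nan)
        save("regression", plots.fig_regression(res))

    # --- randomization ---------------------------------------------------
    def do_shuffle():
        null = randomization.shuffle_null(
            train, track, randomization.skaggs_statistic(config.map_bin_cm),
            n=config.shuffles, min_shift=config.min_shift_s, seed=seed,
            mode=config.shuffle_mode, percentiles=(config.percentile,))
        row["skaggs_observed"] = null.observed
        row["skaggs_null_cutoff"] = float(null.cutoffs[0])
        row["skaggs_exceeds_null"] = null.exceeds
        save("shuffle", plots.fig_shuffle(null))

    def do_time_shift():
        shifts = np.arange(config.shift_min_s,
                           config.shift_max_s + 1e-9, config.shift_step_s)
        prof = randomization.time_shift_profile(
            train, track, randomization.skaggs_statistic(config.map_bin_cm),
            shifts)
        row["best_shift_s"] = prof.argmax_shift
        save("shift", plots.fig_shift_profile(prof))

    # --- LFP -------------------------------------------------------------
    def do_lfp_spectrum():
        if lfp is None:
            raise InvalidArgumentError(f"no LFP named {config.lfp_name!r}")
        spec = lfp_coupling.welch_spectrum(lfp)
        for name, b in spec.bands.items():
            row[f"lfp_{name}_rel_power"] = b["relative"]
        save("spectrum", plots.fig_spectrum(spec))

    def do_phase():
        if lfp is None:
            raise InvalidArgumentError(f"no LFP named {config.lfp_name!r}")
        sample = lfp_coupling.spike_phase_distribution(
            lfp, train, tuple(config.lfp_band))
        row["phase_mean_deg"] = sample.mean_phase
        row["phase_resultant"] = sample.resultant_length
        row["phase_rayleigh_p"] = sample.rayleigh_p
        save("phase", plots.fig_phase(sample))

    def do_coupling():
        if lfp is None:
            raise InvalidArgumentError(f"no LFP named {config.lfp_name!r}")
        plv = lfp_coupling.phase_locking_value(lfp, train)
        sfc = lfp_coupling.spike_field_coherence(lfp, train)
        band = tuple(config.lfp_band)
        sel = (plv.frequencies >= band[0]) & (plv.frequencies < band[1])
        row["plv_theta_max"] = float(plv.plv[sel].max())
        row["sfc_theta_max"] = float(sfc.sfc[sel].max())
        save("coupling", plots.fig_coupling(plv, sfc))

    for name, fn in (("waveform", do_waveform), ("isi", do_isi),
                     ("autocorr", do_autocorr), ("theta", do_theta),
                     ("ratemap", do_ratemap), ("place_field", do_place_field),
                     ("grid", do_grid), ("border", do_border),
                     ("gradient", do_gradient), ("hd", do_hd),
                     ("speed", do_speed), ("ahv", do_ahv),
                     ("regression", do_regression), ("shuffle", do_shuffle),
                     ("time_shift", do_time_shift),
                     ("lfp_spectrum", do_lfp_spectrum), ("phase", do_phase),
                     ("coupling", do_coupling)):
        step(name, fn)

    row = _round_floats(row)
    if session_path is not None:
        scalars = {k: v for k, v in row.items()
                   if isinstance(v, (int, float, bool, str))}
        append_results(session_path, unit_id, scalars)
    return {"row": row, "figures": figures}


def run_batch(entries, config: AnalysisConfig, out_dir) -> dict:
    """Run :func:`run_unit` for every valid batch entry.

    Returns the aggregated results table, a per-entry status list and the
    path of the exported CSV.  Entries whose files or units are missing, or
    whose analysis raises, are reported in the status list and skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = verify_batch(entries)
    rows = []
    status = []
    sessions = {}
    n_valid = int(report["ok"].sum())
    if n_valid == 0:
        raise InvalidArgumentError("no valid batch entries")
    for entry, ok in zip(entries, report["ok"]):
        if not ok:
            status.append({"record_id": entry.record_id, "ok": False,
                           "reason": "failed verification"})
            continue
        try:
            key = str(entry.data_path)
            if key not in sessions:
                sessions[key] = read_session(entry.data_path)
            cfg = AnalysisConfig(**{**config.__dict__,
                                    "lfp_name": entry.lfp_name,
                                    "analyses": list(config.analyses)})
            res = run_unit(sessions[key], entry.tetrode_no, entry.unit_no,
                           cfg, out_dir, session_path=entry.data_path)
            rows.append(res["row"])
            status.append({"record_id": entry.record_id, "ok": True,
                           "reason": ""})
        except Exception as exc:  # isolate per-entry failures
            log.warning("batch entry %s failed: %s", entry.record_id, exc)
            status.append({"record_id": entry.record_id, "ok": False,
                           "reason": str(exc)})
    table = pd.DataFrame(rows)
    csv_path = out_dir / "results.csv"
    table.to_csv(csv_path, index=False)
    try:
        table.to_excel(out_dir / "results.xlsx", index=False)
    except Exception:
        pass
    return {"table": table, "status": status, "csv_path": csv_path}


def tetrode_summary(directory, out_dir=None, recursive: bool = False) -> list:
    """One PNG per tetrode per session file found in ``directory``.

    Each image shows the animal's path with spike locations and the rate map
    for every unit on the tetrode.  Unreadable session files are skipped
    with a logged warning; tetrodes without units produce no image.
    """
    directory = Path(directory)
    out_dir = Path(out_dir) if out_dir is not None else directory
    out_dir.mkdir(parents=True, exist_ok=True)
    pattern = "**/*.h5" if recursive else "*.h5"
    images = []
    for path in sorted(directory.glob(pattern)):
        try:
            session = read_session(path)
        except Exception as exc:
            log.warning("skipping unreadable session %s: %s", path, exc)
            continue
        _ensure_kinematics(session)
        by_tetrode = {}
        for u in session.units:
            by_tetrode.setdefault(u.tetrode_no, []).append(u)
        for tet, units in sorted(by_tetrode.items()):
            fig, axes = plt.subplots(2, len(units),
                                     figsize=(3 * len(units), 6),
                                     squeeze=False)
            for j, u in enumerate(units):
                track = session.spatial
                axes[0][j].plot(track.x, track.y, "k", lw=0.3)
                sx = np.interp(u.timestamps, track.t, track.x)
                sy = np.interp(u.timestamps, track.t, track.y)
                axes[0][j].plot(sx, sy, "r.", ms=2)
                axes[0][j].set_title(f"unit {u.unit_no}", fontsize=8)
                axes[0][j].set_aspect("equal")
                try:
                    rmap = spatial_maps.rate_map(u, track)
                    cx, cy = rmap.bin_centres()
                    axes[1][j].pcolormesh(cx, cy, rmap.rate.T,
                                          shading="nearest", cmap="viridis")
                    axes[1][j].set_aspect("equal")
                except SpikeSpatialError:
                    axes[1][j].set_axis_off()
            img = out_dir / f"{session.record_id}_TT{tet}_summary.png"
            fig.savefig(img, dpi=90)
            plt.close(fig)
            images.append(img)
    return images
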