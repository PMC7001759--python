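"""Session data model, HDF5/CSV persistence, unit nomenclature and batch lists.

A *session* is one continuous recording from a freely behaving animal: the
tracked position/head-direction of the animal, one or more spike-sorted
units (optionally with tetrode waveforms), and one or more LFP channels.
Everything is stored in a single HDF5 file per session, with raw data under
``/raw`` and per-unit analysis results under ``/results/<unit_id>``.

Time base is seconds with t = 0 at session start; all binning throughout the
package uses half-open intervals [a, b).  Head direction is degrees
counter-clockwise from the +x axis, in [0, 360); angular velocity is signed
with positive = counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, SpikeSpatialError

FORMAT_VERSION = "1"

#: column schema of a batch list (CSV or XLSX)
BATCH_COLUMNS = ("directory", "record_id", "tetrode", "unit", "lfp")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Spike timestamps of one sorted unit, optionally with waveforms.

    Parameters
    ----------
    timestamps
        Spike times in seconds, strictly ascending, all within
        ``[0, duration]``.
    duration
        Length of the recording in seconds.
    tetrode_no, unit_no
        Electrode number and cluster tag from spike sorting.
    waveforms
        Optional array ``[n_spikes, n_channels, n_samples]`` in microvolts.
    waveform_rate
        Sampling rate of the waveform snippets in Hz.
    """

    timestamps: np.ndarray
    duration: float
    tetrode_no: int = 1
    unit_no: int = 1
    waveforms: Optional[np.ndarray] = None
    waveform_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise InvalidArgumentError("timestamps must be 1-D")
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) <= 0):
                raise InvalidArgumentError("timestamps must be strictly ascending")
            if self.timestamps[0] < 0 or self.timestamps[-1] > self.duration:
                raise InvalidArgumentError(
                    "timestamps must lie within [0, duration]"
                )
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)
            if self.waveforms.ndim != 3:
                raise InvalidArgumentError(
                    "waveforms must be [n_spikes, n_channels, n_samples]"
                )
            if self.waveforms.shape[0] != self.timestamps.size:
                raise InvalidArgumentError(
                    "waveforms first dimension must match number of spikes"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration

    def shifted(self, shift: float) -> "SpikeTrain":
        """Return a copy with all spike times circularly shifted by ``shift``
        seconds (wrapping modulo the duration). Waveforms are dropped."""
        ts = np.sort(np.mod(self.timestamps + shift, self.duration))
        return SpikeTrain(ts, self.duration, self.tetrode_no, self.unit_no)

    def restricted(self, t0: float, t1: float, rezero: bool = False) -> "SpikeTrain":
        """Spikes within [t0, t1); optionally re-referenced to t0."""
        keep = (self.timestamps >= t0) & (self.timestamps < t1)
        ts = self.timestamps[keep]
        wf = self.waveforms[keep] if self.waveforms is not None else None
        if rezero:
            return SpikeTrain(ts - t0, t1 - t0, self.tetrode_no, self.unit_no,
                              wf, self.waveform_rate)
        return SpikeTrain(ts, self.duration, self.tetrode_no, self.unit_no,
                          wf, self.waveform_rate)


@dataclass
class SpatialTrack:
    """Uniformly sampled animal track with derived kinematic channels."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    head_direction: np.ndarray
    speed: Optional[np.ndarray] = None
    angular_velocity: Optional[np.ndarray] = None
    border_distance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "head_direction"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise InvalidArgumentError("track needs at least 2 samples")
        for name in ("x", "y", "head_direction"):
            if getattr(self, name).size != n:
                raise InvalidArgumentError(f"{name} length must match t")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - dt[0]) > 1e-6):
            raise InvalidArgumentError("t must be uniformly sampled")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InvalidArgumentError("x, y must be finite")
        if np.any(self.head_direction < 0) or np.any(self.head_direction >= 360):
            raise InvalidArgumentError("head_direction must be in [0, 360)")
        for name in ("speed", "angular_velocity", "border_distance"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise InvalidArgumentError(f"{name} length must match t")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Duration covered by the track (each sample owns one dt of dwell)."""
        return self.n * self.dt

    def channel(self, name: str) -> np.ndarray:
        """Access a variable channel by short name (hd|speed|ahv|border_distance)."""
        alias = {"hd": "head_direction", "ahv": "angular_velocity",
                 "border": "border_distance"}
        arr = getattr(self, alias.get(name, name), None)
        if arr is None:
            raise InvalidArgumentError(f"track has no channel {name!r}")
        return arr

    def restricted(self, t0: float, t1: float, rezero: bool = False) -> "SpatialTrack":
        keep = (self.t >= t0) & (self.t < t1)

        def cut(v):
            return None if v is None else v[keep]

        t = self.t[keep] - (t0 if rezero else 0.0)
        return SpatialTrack(t, self.x[keep], self.y[keep],
                            self.head_direction[keep], cut(self.speed),
                            cut(self.angular_velocity), cut(self.border_distance))


@dataclass
class LfpSignal:
    """Uniformly sampled local field potential trace in microvolts."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise InvalidArgumentError("rate must be positive")
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be 1-D")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate


@dataclass
class Session:
    """One recording session: track + sorted units + LFP channels + events."""

    record_id: str
    spatial: SpatialTrack
    units: list = field(default_factory=list)
    lfps: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise InvalidArgumentError("record_id must be non-empty")
        tol = self.spatial.dt
        for u in self.units:
            if abs(u.duration - self.spatial.duration) > tol + 1e-9:
                raise InvalidArgumentError(
                    "unit duration disagrees with track duration"
                )

    def unit(self, tetrode_no: int, unit_no: int) -> SpikeTrain:
        for u in self.units:
            if u.tetrode_no == tetrode_no and u.unit_no == unit_no:
                return u
        raise InvalidArgumentError(
            f"no unit TT{tetrode_no} cluster {unit_no} in session"
        )


@dataclass
class BatchEntry:
    """One row of a batch list: which unit of which session to analyse."""

    data_path: Path
    record_id: str
    tetrode_no: int
    unit_no: int
    lfp_name: str


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

def make_unit_id(record_id: str, tet_no: int, unit_no: int, eeg_ext: str) -> str:
    """Unique name for one unit of one session.

    The id is ``<record_id>TT<tet_no>_SS_<unit_no>_<eeg_ext>`` with plain
    decimal integers (no zero padding). It keys figure filenames, results
    rows and the per-unit results group in the session HDF5 file.
    """
    if not record_id:
        raise InvalidArgumentError("record_id must be non-empty")
    if tet_no < 0 or unit_no < 0:
        raise InvalidArgumentError("tet_no and unit_no must be >= 0")
    return f"{record_id}TT{tet_no:d}_SS_{unit_no:d}_{eeg_ext}"


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def _write_track(grp: h5py.Group, track: SpatialTrack) -> None:
    for name in ("t", "x", "y", "head_direction", "speed",
                 "angular_velocity", "border_distance"):
        v = getattr(track, name)
        if v is not None:
            grp.create_dataset(name, data=v)
    grp.attrs["rate"] = track.rate


def write_session(session: Session, path) -> None:
    """Write a full session to one HDF5 file (layout documented in README)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["record_id"] = session.record_id
        raw = f.create_group("raw")
        _write_track(raw.create_group("spatial"), session.spatial)
        units = raw.create_group("units")
        for u in session.units:
            g = units.create_group(f"TT{u.tetrode_no}/unit_{u.unit_no}")
            g.create_dataset("timestamps", data=u.timestamps)
            g.attrs["duration"] = u.duration
            if u.waveforms is not None:
                g.create_dataset("waveforms", data=u.waveforms)
                g.attrs["waveform_rate"] = u.waveform_rate or 0.0
        lfp = raw.create_group("lfp")
        for name, sig in session.lfps.items():
            g = lfp.create_group(name)
            g.create_dataset("samples", data=sig.samples)
            g.attrs["rate"] = sig.rate
        ev = f.create_group("events")
        for name, times in session.events.items():
            ev.create_dataset(name, data=np.asarray(times, dtype=float))
        f.require_group("results")


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`FormatError` naming the first missing mandatory group, or
    on a format-version mismatch.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise FormatError("missing mandatory attribute 'format_version'")
        if str(version) != FORMAT_VERSION:
            raise FormatError(
                f"format version {version!r} not supported (expected "
                f"{FORMAT_VERSION!r})"
            )
        for grp in ("raw", "raw/spatial", "raw/units", "raw/lfp"):
            if grp not in f:
                raise FormatError(f"missing mandatory group '/{grp}'")
        sp = f["raw/spatial"]

        def opt(name):
            return sp[name][()] if name in sp else None

        track = SpatialTrack(sp["t"][()], sp["x"][()], sp["y"][()],
                             sp["head_direction"][()], opt("speed"),
                             opt("angular_velocity"), opt("border_distance"))
        units = []
        for tt_name in sorted(f["raw/units"]):
            tet_no = int(tt_name[2:])
            for u_name in sorted(f[f"raw/units/{tt_name}"]):
                g = f[f"raw/units/{tt_name}/{u_name}"]
                wf = g["waveforms"][()] if "waveforms" in g else None
                wf_rate = float(g.attrs["waveform_rate"]) if wf is not None else None
                units.append(SpikeTrain(g["timestamps"][()],
                                        float(g.attrs["duration"]),
                                        tet_no, int(u_name.split("_")[1]),
                                        wf, wf_rate))
        lfps = {}
        for name in sorted(f["raw/lfp"]):
            g = f[f"raw/lfp/{name}"]
            lfps[name] = LfpSignal(g["samples"][()], float(g.attrs["rate"]))
        events = {}
        if "events" in f:
            for name in sorted(f["events"]):
                events[name] = f["events"][name][()]
        return Session(str(f.attrs["record_id"]), track, units, lfps, events)


def append_results(path, unit_id: str, results: dict) -> None:
    """Append (or overwrite) scalar analysis results for one unit.

    Results live under ``/results/<unit_id>``; raw data groups are never
    touched, so re-analysis cannot corrupt the recording.
    """
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"results/{unit_id}")
        for key, val in results.items():
            if key in grp:
                del grp[key]
            if val is None:
                continue
            if isinstance(val, str):
                grp.create_dataset(key, data=val)
            else:
                grp.create_dataset(key, data=np.asarray(val))


# ---------------------------------------------------------------------------
# CSV import/export (plain-text alternative to HDF5)
# ---------------------------------------------------------------------------

def read_track_csv(path) -> SpatialTrack:
    """Track CSV with columns ``t,x,y,hd``."""
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "hd"} - set(df.columns)
    if missing:
        raise FormatError(f"track CSV missing columns {sorted(missing)}")
    return SpatialTrack(df["t"].values, df["x"].values, df["y"].values,
                        df["hd"].values)


def write_track_csv(track: SpatialTrack, path) -> None:
    pd.DataFrame({"t": track.t, "x": track.x, "y": track.y,
                  "hd": track.head_direction}).to_csv(path, index=False)


def read_spikes_csv(path, duration: float, tetrode_no: int = 1,
                    unit_no: int = 1) -> SpikeTrain:
    """Spike CSV: one timestamp (s) per line, no header."""
    ts = np.loadtxt(path, ndmin=1)
    return SpikeTrain(ts, duration, tetrode_no, unit_no)


def write_spikes_csv(train: SpikeTrain, path) -> None:
    np.savetxt(path, train.timestamps, fmt="%.6f")


def read_lfp_csv(path) -> LfpSignal:
    """LFP CSV: first line ``rate=<Hz>``, then one sample (uV) per line."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("rate="):
            raise FormatError("LFP CSV must start with a 'rate=<Hz>' line")
        rate = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh, ndmin=1)
    return LfpSignal(samples, rate)


def write_lfp_csv(sig: LfpSignal, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"rate={sig.rate:g}\n")
        np.savetxt(fh, sig.samples, fmt="%.4f")


# ---------------------------------------------------------------------------
# batch lists
# ---------------------------------------------------------------------------

def parse_batch_list(table_path) -> list[BatchEntry]:
    """Parse a CSV or XLSX batch list into :class:`BatchEntry` rows.

    Expected columns: ``directory, record_id, tetrode, unit, lfp``.  The
    session file is ``<directory>/<record_id>.h5``.
    """
    table_path = Path(table_path)
    try:
        if table_path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(table_path)
        else:
            df = pd.read_csv(table_path)
    except FormatError:
        raise
    except Exception as exc:  # unreadable / not tabular
        raise FormatError(f"cannot read batch list {table_path}: {exc}") from exc
    unknown = [c for c in df.columns if c not in BATCH_COLUMNS]
    if unknown:
        raise FormatError(
            f"unknown batch columns {unknown}; known columns are "
            f"{list(BATCH_COLUMNS)}"
        )
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise FormatError(
            f"batch list missing columns {missing}; known columns are "
            f"{list(BATCH_COLUMNS)}"
        )
    entries = []
    for _, row in df.iterrows():
        entries.append(BatchEntry(
            data_path=Path(str(row["directory"])) / f"{row['record_id']}.h5",
            record_id=str(row["record_id"]),
            tetrode_no=int(row["tetrode"]),
            unit_no=int(row["unit"]),
            lfp_name=str(row["lfp"]),
        ))
    return entries


def verify_batch(entries: list[BatchEntry]) -> pd.DataFrame:
    """Check every entry against the files on disk before a long batch run.

    Returns a report DataFrame in input order with boolean columns
    ``missing_file``, ``missing_unit``, ``missing_lfp`` and an overall ``ok``.
    Entries are never mutated.
    """
    rows = []
    for e in entries:
        missing_file = not Path(e.data_path).is_file()
        missing_unit = missing_lfp = False
        if not missing_file:
            try:
                with h5py.File(e.data_path, "r") as f:
                    unit_path = f"raw/units/TT{e.tetrode_no}/unit_{e.unit_no}"
                    missing_unit = unit_path not in f
                    missing_lfp = f"raw/lfp/{e.lfp_name}" not in f
            except OSError:
                missing_file = True
        rows.append({"data_path": str(e.data_path), "record_id": e.record_id,
                     "tetrode": e.tetrode_no, "unit": e.unit_no,
                     "lfp": e.lfp_name, "missing_file": missing_file,
                     "missing_unit": missing_unit, "missing_lfp": missing_lfp,
                     "ok": not (missing_file or missing_unit or missing_lfp)})
    return pd.DataFrame(rows, columns=["data_path", "record_id", "tetrode",
                                       "unit", "lfp", "missing_file",
                                       "missing_unit", "missing_lfp", "ok"])


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _boxcar(v: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return v
    kernel = np.ones(n) / n
    # reflect-pad so the ends are not biased towards zero
    pad = n // 2
    vp = np.pad(v, pad, mode="edge")
    out = np.convolve(vp, kernel, mode="same")
    return out[pad:pad + v.size]


def derive_kinematics(track: SpatialTrack, smooth_window: float = 0.4,
                      boundary=None) -> SpatialTrack:
    """Derive speed, angular velocity and border distance from a raw track.

    Positions and unwrapped head direction are smoothed with a boxcar of
    ``smooth_window`` seconds before central differencing; this suppresses
    tracker jitter that would otherwise dominate the derivatives.  Angular
    velocity is computed on the unwrapped heading, so crossings of 0/360 do
    not produce spikes; the sign is positive for counter-clockwise turns.
    Border distance is the distance to the estimated arena boundary (convex
    hull of the path unless an explicit boundary polyline is given).
    """
    if track.n < 3:
        raise InvalidArgumentError("need at least 3 samples to differentiate")
    n_win = max(1, int(round(smooth_window * track.rate)))
    xs = _boxcar(track.x, n_win)
    ys = _boxcar(track.y, n_win)
    speed = np.hypot(np.gradient(xs, track.dt), np.gradient(ys, track.dt))
    hd_unwrapped = np.unwrap(track.head_direction, period=360.0)
    hd_s = _boxcar(hd_unwrapped, n_win)
    ahv = np.gradient(hd_s, track.dt)
    from .spatial_maps import distance_to_boundary, estimate_border
    if boundary is None:
        try:
            boundary = estimate_border(track)
        except SpikeSpatialError:
            # degenerate path (e.g. 1-D motion): no meaningful boundary
            return replace(track, speed=speed, angular_velocity=ahv)
    border = distance_to_boundary(track.x, track.y, boundary)
    return replace(track, speed=speed, angular_velocity=ahv,
                   border_distance=border)
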