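"""Analysis configuration: a flat, YAML-serialisable set of parameters.

The configuration lists which analyses to run and carries every tunable
parameter with its default.  Unknown keys in a YAML file are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import FormatError

#: every analysis the per-unit driver knows how to run
ALL_ANALYSES = (
    "waveform", "isi", "autocorr", "theta", "ratemap", "place_field",
    "grid", "border", "gradient", "hd", "speed", "ahv", "regression",
    "shuffle", "time_shift", "lfp_spectrum", "phase", "coupling",
)


@dataclass
class AnalysisConfig:
    analyses: list = field(default_factory=lambda: list(ALL_ANALYSES))
    figure_format: str = "png"       # png | pdf
    seed: int = 0
    # spatial maps
    map_bin_cm: float = 3.0
    map_smooth_bins: int = 5
    smooth_order: str = "pre"        # smooth counts/occupancy before division
    # 1D tuning
    hd_bin_deg: float = 5.0
    speed_bin: float = 2.5
    ahv_bin: float = 10.0
    ahv_threshold: float = 30.0
    # randomization
    shuffles: int = 500
    min_shift_s: float = 20.0
    shuffle_mode: str = "shift"      # shift | redraw
    percentile: float = 95.0
    shift_min_s: float = -0.2
    shift_max_s: float = 0.4
    shift_step_s: float = 0.025
    # regression
    time_bin_s: float = 0.1
    # LFP
    lfp_name: str = "eeg"
    lfp_band: list = field(default_factory=lambda: [4.0, 12.0])

    def __post_init__(self) -> None:
        if self.figure_format not in ("png", "pdf"):
            raise FormatError("figure_format must be 'png' or 'pdf'")
        unknown = [a for a in self.analyses if a not in ALL_ANALYSES]
        if unknown:
            raise FormatError(f"unknown analyses {unknown}; known: "
                              f"{list(ALL_ANALYSES)}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise FormatError(f"unknown config keys {unknown}; known keys: "
                              f"{sorted(known)}")
        return cls(**data)
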