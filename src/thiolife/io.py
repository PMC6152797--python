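"""Table formats and run configuration.

The canonical on-disk table is a UTF-8 TSV with a ``transcript_id`` column
and one column per chase timepoint labeled ``t<minutes>`` (minutes may be
fractional, '.' decimal separator).  Metadata (channel, condition,
replicate) travel in ``# key=value`` comment lines above the header.  The
spike-in RNA is an ordinary row whose id matches the configured spike id
for the channel (defaults: ``rcc1_Xl`` in the decay channel, ``srp1a_Hs``
in the synthesis channel — exogenous Xenopus and human spikes); on read it
is peeled off and attached as the spike series of every transcript row.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import DECAY, SYNTHESIS, TimecourseSet

DEFAULT_SPIKE_IDS = {DECAY: "rcc1_Xl", SYNTHESIS: "srp1a_Hs"}
_TIME_RE = re.compile(r"^t(\d+(?:\.\d+)?)$")


class CountsParseError(ValueError):
    """The counts table violates the format contract."""


@dataclass
class RunConfig:
    """Pipeline-wide settings, loadable from YAML."""

    timepoints: tuple = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    th_bounds: tuple = (0.1, 600.0)
    eff_bounds: tuple = (0.01, 1.0)
    n_starts: int = 5
    r2_poor: float = 0.8
    r2_high: float = 0.95
    expression_threshold: float = 1e-3
    spike_ids: dict = field(default_factory=lambda: dict(DEFAULT_SPIKE_IDS))
    noise_sigma: float = 0.05
    spike_level: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.r2_poor < 1 and 0 < self.r2_high < 1):
            raise ValueError("R² thresholds must lie in (0, 1)")
        for lo, hi in (self.th_bounds, self.eff_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered (min < max)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})

    def with_overrides(self, pairs) -> "RunConfig":
        """Apply ``key=value`` override strings (YAML-parsed values)."""
        data = asdict(self)
        for pair in pairs:
            key, _, raw = pair.partition("=")
            if key not in data:
                raise KeyError(f"unknown config key {key!r}")
            val = yaml.safe_load(raw)
            data[key] = tuple(val) if isinstance(val, list) else val
        return RunConfig(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _parse_time_columns(cols) -> list:
    times = []
    for c in cols:
        m = _TIME_RE.match(c)
        if not m:
            raise CountsParseError(f"column {c!r} is not a t<minutes> label")
        times.append(float(m.group(1)))
    if times and (times[0] != 0 or np.any(np.diff(times) <= 0)):
        raise CountsParseError(f"time labels must start at t0 and increase: {times}")
    return times


def read_counts(path, channel: str, condition: str = "", replicate: str = "",
                spike_id: Optional[str] = None) -> TimecourseSet:
    """Read a counts TSV into a :class:`TimecourseSet`.

    The spike row (id ``spike_id``, default per channel) is removed from the
    transcript table and attached as the spike series.  Metadata comment
    lines in the file override the ``channel``/``condition``/``replicate``
    arguments.
    """
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if val:
                meta[key.strip()] = val.strip()
            pos += len(line)
    channel = meta.get("channel", channel)
    condition = meta.get("condition", condition)
    replicate = meta.get("replicate", replicate)
    if spike_id is None:
        spike_id = DEFAULT_SPIKE_IDS.get(channel)

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    if "transcript_id" not in df.columns:
        raise CountsParseError("missing transcript_id column")
    dup = df["transcript_id"].duplicated()
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise CountsParseError(f"duplicate transcript ids at data line(s) {lines}")
    times = _parse_time_columns([c for c in df.columns if c != "transcript_id"])
    df = df.set_index("transcript_id")
    df.columns = times

    if spike_id not in df.index:
        raise CountsParseError(f"spike row {spike_id!r} missing from {path.name}")
    spike = df.loc[spike_id].astype(float)
    values = df.drop(index=spike_id).astype(float)
    return TimecourseSet(values=values, spike=spike, channel=channel,
                         condition=condition, replicate=replicate)


def write_counts(path, tc: TimecourseSet, spike_id: Optional[str] = None) -> None:
    """Write a :class:`TimecourseSet` (spike row included) as a counts TSV."""
    if spike_id is None:
        spike_id = DEFAULT_SPIKE_IDS[tc.channel]
    df = tc.values.copy()
    df.loc[spike_id] = tc.spike.to_numpy()
    df.columns = [f"t{t:g}" for t in tc.timepoints]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# channel={tc.channel}\n")
        if tc.condition:
            fh.write(f"# condition={tc.condition}\n")
        if tc.replicate:
            fh.write(f"# replicate={tc.replicate}\n")
        df.to_csv(fh, sep="\t", index_label="transcript_id", lineterminator="\n")


def write_fits(path, fits: pd.DataFrame) -> None:
    """Write a fit table as TSV with a fixed column order."""
    fits.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str})


def write_json(path, payload: dict, config: Optional[RunConfig] = None,
               seed: Optional[int] = None) -> None:
    """Write a JSON report with sorted keys and a provenance block."""
    from . import __version__

    out = dict(payload)
    out["provenance"] = {
        "version": __version__,
        "config_sha256": config.digest() if config is not None else None,
        "seed": seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, sort_keys=True, indent=2, default=float)
        fh.write("\n")
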