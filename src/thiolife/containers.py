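"""Core in-memory containers for chase-labeling time-course data.

A chase experiment follows two RNA pools after the metabolic label is added
at t = 0: the pre-existing unlabeled pool (decay channel, measured in the
streptavidin flowthrough) and the newly synthesized labeled pool (synthesis
channel, measured in the eluate).  Each channel is quantified per transcript
across the chase timepoints together with an exogenous spike-in RNA that
anchors absolute scale across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DECAY = "decay"
SYNTHESIS = "synthesis"
CHANNELS = (DECAY, SYNTHESIS)


class DegenerateSpikeError(ValueError):
    """A spike-in measurement is zero or negative at some timepoint."""


class ZeroAnchorError(ValueError):
    """The t = 0 measurement of a decay series is zero; the series cannot be
    normalized to its anchor and the transcript is flagged unfit downstream."""


@dataclass
class TimecourseSet:
    """Per-transcript signal across chase timepoints in one channel.

    Parameters
    ----------
    values : pandas.DataFrame
        Transcripts x timepoints signal matrix.  The index holds transcript
        ids; columns are chase times in minutes (floats, strictly
        increasing, first one 0).
    spike : pandas.Series
        Spike-in signal per timepoint (same columns as ``values``); must be
        strictly positive.
    channel : str
        ``"decay"`` (unlabeled flowthrough) or ``"synthesis"`` (labeled
        eluate).
    condition, replicate : str
        Free-form experiment labels.
    normalized : bool
        True once spike and anchor normalization have been applied.
    """

    values: pd.DataFrame
    spike: pd.Series
    channel: str
    condition: str = ""
    replicate: str = ""
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        t = self.timepoints
        if len(t) < 3:
            raise ValueError(f"need at least 3 timepoints, got {len(t)}")
        if t[0] != 0:
            raise ValueError(f"first timepoint must be 0, got {t[0]}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        self.spike = self.spike.reindex(self.values.columns)
        if self.spike.isna().any():
            raise ValueError("spike series does not cover all timepoints")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def series(self, transcript_id: str) -> np.ndarray:
        return self.values.loc[transcript_id].to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, **kw) -> "TimecourseSet":
        return replace(self, values=values, **kw)
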