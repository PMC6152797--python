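"""Spike-in and t0 normalization of raw chase time courses.

Raw signals are first divided by the spike-in signal at each timepoint
(removing per-timepoint recovery/scale differences), then decay-channel
series are divided by their t = 0 value so the fitted model starts at 1.
Synthesis-channel series are spike-normalized only: their t = 0 signal is
~0 by construction, so a t0 ratio would be numerically meaningless, and the
linear synthesis fit absorbs overall scale.  Replicates are normalized
independently and never pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import DECAY, DegenerateSpikeError, TimecourseSet, ZeroAnchorError


class SpikeNormalizer(BaseEstimator, TransformerMixin):
    """Divide every transcript series (and the spike itself) by the spike-in.

    Stateless transformer; ``fit`` only validates. After ``transform`` the
    spike series is all ones and transcript values are unitless ratios to
    the spike.
    """

    def fit(self, X: TimecourseSet, y=None):
        self._check_spike(X)
        self.n_features_in_ = len(X.timepoints)
        return self

    def transform(self, X: TimecourseSet) -> TimecourseSet:
        self._check_spike(X)
        spike = X.spike.to_numpy(dtype=float)
        values = X.values / spike
        ones = pd.Series(np.ones_like(spike), index=X.values.columns)
        return TimecourseSet(
            values=values,
            spike=ones,
            channel=X.channel,
            condition=X.condition,
            replicate=X.replicate,
        )

    @staticmethod
    def _check_spike(X: TimecourseSet) -> None:
        spike = X.spike.to_numpy(dtype=float)
        bad = np.flatnonzero(~(spike > 0))
        if bad.size:
            t_bad = np.asarray(X.values.columns, dtype=float)[bad]
            raise DegenerateSpikeError(
                f"spike signal is not positive at timepoint(s) {t_bad.tolist()}"
            )


class TZeroNormalizer(BaseEstimator, TransformerMixin):
    """Divide each decay-channel series by its t = 0 value.

    Synthesis-channel sets pass through unchanged unless
    ``force_synthesis=True``.  Transcripts with a zero t = 0 anchor either
    raise (``on_zero_anchor="raise"``) or are dropped and recorded in
    ``dropped_ids_`` so the fit stage can report them as unfit.
    """

    def __init__(self, force_synthesis: bool = False, on_zero_anchor: str = "raise"):
        self.force_synthesis = force_synthesis
        self.on_zero_anchor = on_zero_anchor

    def fit(self, X: TimecourseSet, y=None):
        if self.on_zero_anchor not in ("raise", "drop"):
            raise ValueError("on_zero_anchor must be 'raise' or 'drop'")
        self.n_features_in_ = len(X.timepoints)
        return self

    def transform(self, X: TimecourseSet) -> TimecourseSet:
        self.fit(X)
        if X.channel != DECAY and not self.force_synthesis:
            self.dropped_ids_ = []
            return X.with_values(X.values, normalized=True)
        anchor = X.values.iloc[:, 0].to_numpy(dtype=float)
        zero = ~(anchor > 0)
        if zero.any():
            ids = X.values.index[zero].tolist()
            if self.on_zero_anchor == "raise":
                raise ZeroAnchorError(f"zero t=0 signal for transcript(s) {ids}")
            self.dropped_ids_ = ids
        else:
            self.dropped_ids_ = []
        keep = ~zero
        values = X.values.loc[keep].div(anchor[keep], axis=0)
        return X.with_values(values, normalized=True)


def spike_normalize(tc: TimecourseSet) -> TimecourseSet:
    """Functional form of :class:`SpikeNormalizer`."""
    return SpikeNormalizer().fit(tc).transform(tc)


def t0_normalize(tc: TimecourseSet, force_synthesis: bool = False,
                 on_zero_anchor: str = "raise") -> TimecourseSet:
    """Functional form of :class:`TZeroNormalizer`."""
    return TZeroNormalizer(force_synthesis, on_zero_anchor).fit(tc).transform(tc)


def normalize(tc: TimecourseSet, on_zero_anchor: str = "drop") -> TimecourseSet:
    """Full normalization: spike division followed by t0 anchoring."""
    return t0_normalize(spike_normalize(tc), on_zero_anchor=on_zero_anchor)
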