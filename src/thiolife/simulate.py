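"""Synthetic 4TU-chase experiments with known ground truth.

The simulator draws a transcriptome of true half-lives, abundances and
labeling/separation efficiencies, then emits the two measured channels of a
chase experiment:

* decay channel (unlabeled flowthrough).  Pre-existing RNA decays as
  ``A * 2**(-t/Th)``; a fraction ``1 - eff`` of newly made labeled RNA
  escapes separation and leaks into this measurement.  At steady state the
  leak accumulates as ``A * (1 - eff) * (1 - 2**(-t/Th))``, so the noiseless
  signal is ``U(t) = A * (eff * 2**(-t/Th) + (1 - eff))`` — after t0
  normalization exactly the efficiency-modified decay model that is fit
  downstream.
* synthesis channel (labeled eluate).  Labeled RNA accumulates as
  ``L(t) = eff * A * (1 - 2**(-t/Th))``, whose early-time slope is
  ``eff * A * ln2 / Th``.

Measurement noise is multiplicative lognormal (positive, heteroscedastic
signals, as in sequencing/qPCR readouts); an optional Poisson count layer
can be stacked on top.  The spike-in is simulated as its own series subject
to the same noise, so spike normalization is exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DECAY, SYNTHESIS, TimecourseSet

#: Default chase timepoint grid (minutes).  Chosen to straddle the ~3.6 min
#: median half-life of a fast-turnover transcriptome: two points inside the
#: first median half-life, and a 32 min endpoint that pins the (1 - eff)
#: plateau for all but the longest-lived transcripts.
DEFAULT_TIMEPOINTS = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0)

TRUE_PARAM_COLUMNS = ("transcript_id", "true_half_life", "true_abundance", "true_eff", "steady_state")


@dataclass
class SimulationDesign:
    """Measurement design of one simulated chase channel.

    noise_sigma is the standard deviation of log-signal (lognormal
    multiplicative noise); spike_level the constant true spike signal.
    ``poisson_scale``, if set, additionally resamples each measurement as
    ``Poisson(signal * scale) / scale`` to emulate counting noise.
    """

    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    noise_sigma: float = 0.05
    spike_level: float = 1.0
    channel: str = DECAY
    seed: int = 0
    poisson_scale: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("timepoints must be a 1-D grid with >= 2 points")
        if t[0] != 0:
            raise ValueError("timepoints must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spike_level <= 0:
            raise ValueError("spike_level must be > 0")
        if self.channel not in (DECAY, SYNTHESIS):
            raise ValueError(f"unknown channel {self.channel!r}")
        self.timepoints = tuple(float(x) for x in t)


def sample_true_params(
    n: int,
    half_life_log_median: float = 3.6,
    half_life_log_sigma: float = 0.7,
    abundance_log_median: float = 10.0,
    abundance_log_sigma: float = 1.0,
    eff_beta_a: float = 20.0,
    eff_beta_b: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a ground-truth transcriptome.

    Half-lives and abundances are lognormal (the half-life marginal of a fast
    transcriptome is right-skewed and spans more than an order of magnitude);
    the labeling/separation efficiency ``eff`` is Beta(a, b) mapped into
    (0, 1].  Defaults put the half-life median at 3.6 min and most
    efficiencies above 0.9.

    Returns a DataFrame with columns transcript_id, true_half_life,
    true_abundance, true_eff, steady_state.  Identical seeds give identical
    tables.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if half_life_log_median <= 0 or abundance_log_median <= 0:
        raise ValueError("log-medians must be > 0")
    if half_life_log_sigma < 0 or abundance_log_sigma < 0:
        raise ValueError("log-sigmas must be >= 0")
    if eff_beta_a <= 0 or eff_beta_b <= 0:
        raise ValueError("Beta shape parameters must be > 0")

    rng = np.random.default_rng(seed)
    th = np.exp(rng.normal(np.log(half_life_log_median), half_life_log_sigma, size=n))
    ab = np.exp(rng.normal(np.log(abundance_log_median), abundance_log_sigma, size=n))
    eff = rng.beta(eff_beta_a, eff_beta_b, size=n)
    # Beta support is open (0, 1); nudge the measure-zero endpoints into (0, 1].
    eff = np.clip(eff, np.finfo(float).tiny, 1.0)
    width = max(len(str(n)), 1) if n else 1
    ids = [f"txp{i:0{width}d}" for i in range(n)]
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "true_half_life": th,
            "true_abundance": ab,
            "true_eff": eff,
            "steady_state": np.ones(n, dtype=bool),
        }
    )


def _validate_params(params: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRUE_PARAM_COLUMNS) - set(params.columns)
    if missing:
        raise ValueError(f"params table missing columns: {sorted(missing)}")
    if params["transcript_id"].duplicated().any():
        raise ValueError("duplicate transcript_id in params table")
    if (params["true_half_life"] <= 0).any() or (params["true_abundance"] <= 0).any():
        raise ValueError("true_half_life and true_abundance must be > 0")
    if ((params["true_eff"] <= 0) | (params["true_eff"] > 1)).any():
        raise ValueError("true_eff must lie in (0, 1]")
    return params


def decay_signal(t: np.ndarray, half_life: float, abundance: float, eff: float) -> np.ndarray:
    """Noiseless unlabeled-channel signal U(t) at steady state."""
    return abundance * (eff * np.power(2.0, -t / half_life) + (1.0 - eff))


def synthesis_signal(t: np.ndarray, half_life: float, abundance: float, eff: float) -> np.ndarray:
    """Noiseless labeled-channel signal L(t) at steady state."""
    return eff * abundance * (1.0 - np.power(2.0, -t / half_life))


def _apply_noise(signal: np.ndarray, design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    out = signal
    if design.noise_sigma > 0:
        out = out * rng.lognormal(0.0, design.noise_sigma, size=signal.shape)
    if design.poisson_scale is not None:
        out = rng.poisson(out * design.poisson_scale) / design.poisson_scale
    return out


def _simulate_channel(params: pd.DataFrame, design: SimulationDesign, channel: str) -> TimecourseSet:
    params = _validate_params(params)
    if design.channel != channel:
        raise ValueError(f"design.channel is {design.channel!r}; expected {channel!r}")
    if not params["steady_state"].all():
        raise ValueError(
            "chase simulation assumes steady state at t=0; non-steady-state rows present"
        )
    t = np.asarray(design.timepoints)
    model = decay_signal if channel == DECAY else synthesis_signal
    clean = np.vstack(
        [
            model(t, row.true_half_life, row.true_abundance, row.true_eff)
            for row in params.itertuples()
        ]
    ) if len(params) else np.empty((0, len(t)))

    rng = np.random.default_rng(design.seed)
    noisy = _apply_noise(clean, design, rng)
    spike = _apply_noise(np.full(len(t), design.spike_level), design, rng)
    spike = np.maximum(spike, np.finfo(float).tiny)  # spike must stay positive

    values = pd.DataFrame(noisy, index=pd.Index(params["transcript_id"], name="transcript_id"), columns=t)
    return TimecourseSet(values=values, spike=pd.Series(spike, index=values.columns), channel=channel)


def simulate_decay_timecourse(params: pd.DataFrame, design: SimulationDesign) -> TimecourseSet:
    """Simulate the unlabeled (decay) channel of a chase experiment."""
    return _simulate_channel(params, design, DECAY)


def simulate_synthesis_timecourse(params: pd.DataFrame, design: SimulationDesign) -> TimecourseSet:
    """Simulate the labeled (synthesis) channel of a chase experiment."""
    return _simulate_channel(params, design, SYNTHESIS)
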