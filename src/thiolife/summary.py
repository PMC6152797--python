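"""Transcriptome-level statistics over a table of decay fits.

Covers the headline descriptors of a half-life dataset: mean and median
half-life over transcripts that fit well, the abundance-weighted bulk
transcriptome half-life (obtained by summing spike-normalized signal over
all transcripts and fitting the pooled series — long-lived abundant
transcripts weigh more there than in the per-transcript mean), the fraction
of transcripts labeled/separated above efficiency thresholds, mean lifetime
(Th / ln 2), cross-replicate agreement, and the long-lived class
(> k SD above the mean half-life).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DECAY, TimecourseSet
from .kinetics import STATUS_OK, DecayModelFitter, fit_decay_series
from .normalize import SpikeNormalizer, t0_normalize

LN2 = math.log(2.0)


class EmptySummaryError(ValueError):
    """No ok fits to summarize."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 shared ok transcripts between two fit tables."""


@dataclass
class TranscriptomeSummary:
    n_total: int
    n_ok: int
    mean_half_life: float
    median_half_life: float
    frac_eff_gt_090: float
    frac_eff_gt_080: float
    frac_r2_gt_095: float
    mean_lifetime: float
    bulk_half_life: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def mean_lifetime(half_life: float) -> float:
    """Mean lifetime of a first-order decaying pool: Th / ln 2."""
    if not half_life > 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return half_life / LN2


def _ok(fits: pd.DataFrame) -> pd.DataFrame:
    return fits[fits["status"] == STATUS_OK]


def summarize_half_lives(fits: pd.DataFrame) -> TranscriptomeSummary:
    """Half-life and efficiency statistics of a fit table.

    Half-life statistics run over status==ok rows only.  Efficiency and R²
    fractions run over all rows with a finite estimate, using strict
    greater-than thresholds.
    """
    ok = _ok(fits)
    if ok.empty:
        raise EmptySummaryError("no ok fits in table")
    th = ok["half_life"].to_numpy(dtype=float)
    eff = fits["eff"].to_numpy(dtype=float)
    eff = eff[np.isfinite(eff)]
    r2 = fits["r_squared"].to_numpy(dtype=float)
    r2 = r2[np.isfinite(r2)]
    mean_th = float(th.mean())
    return TranscriptomeSummary(
        n_total=len(fits),
        n_ok=len(ok),
        mean_half_life=mean_th,
        median_half_life=float(np.median(th)),
        frac_eff_gt_090=float((eff > 0.90).mean()) if eff.size else float("nan"),
        frac_eff_gt_080=float((eff > 0.80).mean()) if eff.size else float("nan"),
        frac_r2_gt_095=float((r2 > 0.95).mean()) if r2.size else float("nan"),
        mean_lifetime=mean_lifetime(mean_th),
    )


def bulk_half_life(raws: TimecourseSet, **fit_params) -> float:
    """Half-life of the abundance-summed transcriptome pool.

    Spike-normalized signal is summed across transcripts per timepoint, the
    pooled series is t0-normalized and the efficiency-modified decay model
    fit to it.  Abundant long-lived transcripts dominate the pool, so this
    exceeds the per-transcript mean for a typical fast-turnover
    transcriptome.
    """
    if raws.channel != DECAY:
        raise ValueError("bulk_half_life requires a decay-channel set")
    spiked = raws if raws.normalized else SpikeNormalizer().fit(raws).transform(raws)
    pooled = spiked.values.sum(axis=0).to_numpy(dtype=float)
    anchor = pooled[0]
    if not anchor > 0:
        raise ValueError("pooled t=0 signal is zero")
    fit = fit_decay_series(raws.timepoints, pooled / anchor, "bulk", **fit_params)
    return fit.half_life


def replicate_agreement(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                        log_space: bool = True) -> float:
    """Pearson correlation of half-lives on shared ok transcripts.

    Computed on log10 half-lives by default — the half-life distribution
    spans more than an order of magnitude, and linear-space r is dominated
    by the long-lived tail.
    """
    a = _ok(fits_a).set_index("transcript_id")["half_life"]
    b = _ok(fits_b).set_index("transcript_id")["half_life"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"need >= 3 shared ok transcripts, got {len(shared)}")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if log_space:
        x, y = np.log10(x), np.log10(y)
    return float(stats.pearsonr(x, y).statistic)


def long_lived_set(fits: pd.DataFrame, k: float = 1.0) -> set:
    """Transcripts with half-life > mean + k * SD (sample SD, ddof=1)."""
    ok = _ok(fits)
    if len(ok) < 2:
        raise ValueError("need >= 2 ok fits")
    th = ok["half_life"].to_numpy(dtype=float)
    cut = th.mean() + k * th.std(ddof=1)
    return set(ok.loc[ok["half_life"] > cut, "transcript_id"])


def summarize(raws: TimecourseSet, **fit_params) -> Tuple[TranscriptomeSummary, pd.DataFrame]:
    """Fit a raw decay-channel set and produce its full summary (incl. bulk)."""
    est = DecayModelFitter(**fit_params).fit(raws)
    s = summarize_half_lives(est.fits_)
    s.bulk_half_life = bulk_half_life(raws)
    return s, est.fits_
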