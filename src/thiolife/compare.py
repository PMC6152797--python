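"""Control-vs-perturbation half-life comparisons.

Two mechanistic models make opposite predictions about how translation
perturbations change mRNA stability:

* stalled-ribosome-triggered decay (SR): slow ribosomes recruit the decay
  machinery, so slowing elongation should destabilize transcripts; the
  model makes no clear prediction for initiation inhibition.
* translation-factor protection (TP): bound initiation factors/ribosomes
  shield the transcript, so slowing elongation stabilizes and inhibiting
  initiation destabilizes.

Each (perturbation, model) pair therefore maps to a directional prediction
(stabilize / destabilize) that is tested with a one-sided paired t-test on
matched control/treated half-lives.  Transcriptome-wide shifts use the
two-sided paired Wilcoxon signed-rank test, distribution shapes the ECDF,
rank agreement across conditions Spearman's rho, and the His/Gly
codon-count threshold analysis groups per-transcript half-life fold changes
by how many stall-prone codons a transcript carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import STATUS_OK

STABILIZE = "stabilize"
DESTABILIZE = "destabilize"

#: (perturbation class, mechanistic model) -> predicted direction of the
#: half-life change.  None: the model makes no clear prediction.
MODEL_PREDICTIONS: Dict[Tuple[str, str], Optional[str]] = {
    ("elongation_inhibition", "TP"): STABILIZE,
    ("elongation_inhibition", "SR"): DESTABILIZE,
    ("initiation_inhibition", "TP"): DESTABILIZE,
    ("initiation_inhibition", "SR"): None,
}


@dataclass
class PairedComparison:
    """Matched control/treated half-lives with the comparison statistics."""

    transcript_ids: list
    th_control: np.ndarray
    th_treated: np.ndarray
    p_tp: Optional[float] = None
    p_sr: Optional[float] = None
    wilcoxon_p: Optional[float] = None
    spearman_rho: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": len(self.transcript_ids),
            "p_tp": self.p_tp,
            "p_sr": self.p_sr,
            "wilcoxon_p": self.wilcoxon_p,
            "spearman_rho": self.spearman_rho,
        }


def _pairs(th_control, th_treated) -> Tuple[np.ndarray, np.ndarray]:
    c = np.asarray(th_control, dtype=float)
    t = np.asarray(th_treated, dtype=float)
    if c.shape != t.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {t.shape}")
    return c, t


def paired_model_test(th_control, th_treated, prediction: str,
                      log_space: bool = False) -> float:
    """One-sided paired t-test of a directional model prediction.

    prediction="stabilize" tests the alternative treated > control;
    "destabilize" tests treated < control.  Differences are taken on raw
    half-lives by default (log_space applies log10 first).
    """
    c, t = _pairs(th_control, th_treated)
    if len(c) < 2:
        raise ValueError(f"need >= 2 pairs, got {len(c)}")
    if prediction not in (STABILIZE, DESTABILIZE):
        raise ValueError(f"prediction must be stabilize/destabilize, got {prediction!r}")
    if log_space:
        c, t = np.log10(c), np.log10(t)
    alternative = "greater" if prediction == STABILIZE else "less"
    d = t - c
    if d.std(ddof=1) == 0.0:
        # degenerate paired t: identical pairs sit at the null center (p=0.5);
        # a constant nonzero shift is infinitely significant in its direction
        if d.mean() == 0.0:
            return 0.5
        up = d.mean() > 0
        return 0.0 if up == (prediction == STABILIZE) else 1.0
    res = stats.ttest_rel(t, c, alternative=alternative)
    return float(res.pvalue)


def wilcoxon_paired(th_control, th_treated) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (signed-rank convention).  The exact null
    distribution is used for up to 25 informative tie-free pairs; larger or
    tied samples use the normal approximation with continuity correction.
    """
    c, t = _pairs(th_control, th_treated)
    d = t - c
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def half_life_ecdf(fits: pd.DataFrame) -> pd.DataFrame:
    """Right-continuous ECDF over ok half-lives.

    Returns a (half_life, cumulative_frequency) table with one row per
    distinct value; the last cumulative frequency is exactly 1.
    """
    th = fits.loc[fits["status"] == STATUS_OK, "half_life"].to_numpy(dtype=float)
    if th.size == 0:
        raise ValueError("no ok fits")
    ecdf = stats.ecdf(th).cdf
    return pd.DataFrame({
        "half_life": ecdf.quantiles,
        "cumulative_frequency": ecdf.probabilities,
    })


def cross_condition_spearman(fits_a: pd.DataFrame, fits_b: pd.DataFrame) -> float:
    """Spearman rank correlation of half-lives on shared ok transcripts."""
    a = fits_a.loc[fits_a["status"] == STATUS_OK].set_index("transcript_id")["half_life"]
    b = fits_b.loc[fits_b["status"] == STATUS_OK].set_index("transcript_id")["half_life"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ok transcripts, got {len(shared)}")
    return float(stats.spearmanr(a.loc[shared], b.loc[shared]).statistic)


def fold_change_by_count(th_control: pd.Series, th_treated: pd.Series,
                         codon_counts: pd.Series, threshold: int = 2) -> pd.DataFrame:
    """Half-life fold changes grouped by a per-transcript codon count.

    Transcripts are split at count <= threshold vs count > threshold and the
    per-transcript fold change treated/control summarized per group.  A
    group with no members is reported with size 0 and NaN summaries.
    Transcripts with non-positive control half-life are excluded.
    """
    idx = th_control.index.intersection(th_treated.index).intersection(codon_counts.index)
    c = th_control.loc[idx].astype(float)
    t = th_treated.loc[idx].astype(float)
    k = codon_counts.loc[idx].astype(int)
    if (k < 0).any():
        raise ValueError("codon counts must be >= 0")
    valid = c > 0
    fold = (t[valid] / c[valid])
    k = k[valid]
    rows = []
    for name, mask in (("low", k <= threshold), ("high", k > threshold)):
        f = fold[mask]
        rows.append({
            "group": name,
            "n": int(mask.sum()),
            "mean_fold": float(f.mean()) if len(f) else float("nan"),
            "median_fold": float(f.median()) if len(f) else float("nan"),
        })
    return pd.DataFrame(rows).set_index("group")


def compare_conditions(fits_control: pd.DataFrame, fits_treated: pd.DataFrame,
                       prediction_tp: Optional[str] = None,
                       prediction_sr: Optional[str] = None,
                       log_space: bool = False) -> PairedComparison:
    """Full paired comparison of two fit tables on their shared ok transcripts."""
    a = fits_control.loc[fits_control["status"] == STATUS_OK].set_index("transcript_id")["half_life"]
    b = fits_treated.loc[fits_treated["status"] == STATUS_OK].set_index("transcript_id")["half_life"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ok transcripts, got {len(shared)}")
    c = a.loc[shared].to_numpy()
    t = b.loc[shared].to_numpy()
    comp = PairedComparison(list(shared), c, t)
    if prediction_tp:
        comp.p_tp = paired_model_test(c, t, prediction_tp, log_space=log_space)
    if prediction_sr:
        comp.p_sr = paired_model_test(c, t, prediction_sr, log_space=log_space)
    try:
        comp.wilcoxon_p = wilcoxon_paired(c, t)
    except ValueError:  # all differences zero: no transcriptome-wide shift to test
        comp.wilcoxon_p = None
    comp.spearman_rho = float(stats.spearmanr(c, t).statistic)
    return comp
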