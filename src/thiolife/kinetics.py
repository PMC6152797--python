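"""Per-transcript kinetic model fitting.

Decay channel.  After spike and t0 normalization the unlabeled signal of a
transcript at steady state follows

    RNA(t) = eff * 2**(-t/Th) + (1 - eff)

where ``Th`` is the half-life (minutes) and ``eff`` is the bulk
labeling/separation efficiency: the fraction of newly made RNA that is
successfully labeled, biotinylated and removed.  The complement ``1 - eff``
appears as a non-decaying baseline, and ignoring it (fitting a plain
exponential) systematically inflates half-life estimates.

Because the model is linear in ``eff`` at fixed ``Th``
(``RNA = 1 + eff * (2**(-t/Th) - 1)``), the least-squares efficiency is
available in closed form and the fit reduces to a one-dimensional bounded
search over ``Th``: a coarse log-spaced grid locates candidate basins and
bounded Brent refinement polishes the best ones.  This profiled fit is
deterministic and needs no random starts.

Synthesis channel.  The spike-normalized labeled signal is fit to a line
``RNA(t) = ks * t + offset`` by ordinary least squares; ``ks`` is the
synthesis rate in normalized units per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .containers import DECAY, SYNTHESIS, TimecourseSet
from .normalize import SpikeNormalizer, TZeroNormalizer

STATUS_OK = "ok"
STATUS_POOR = "poor_fit"
STATUS_UNFIT = "unfit"
STATUS_LOW_EXPR = "low_expression"

FIT_COLUMNS = (
    "transcript_id", "half_life", "eff", "r_squared", "status",
    "high_quality", "at_bound", "n_points", "mean_raw_signal",
)


class InsufficientDataError(ValueError):
    """Too few timepoints to fit the requested model."""


@dataclass
class DecayFit:
    """Result of fitting the efficiency-modified decay model to one series."""

    transcript_id: str
    half_life: float
    eff: float
    r_squared: float
    status: str
    high_quality: bool = False
    at_bound: bool = False
    n_points: int = 0
    mean_raw_signal: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthesisFit:
    """Ordinary least-squares line fit to one labeled-channel series."""

    transcript_id: str
    ks: float
    offset: float
    r_squared: float
    n_points: int = 0


def decay_model(t: np.ndarray, half_life: float, eff: float) -> np.ndarray:
    """Normalized unlabeled-channel model: eff * 2**(-t/Th) + (1 - eff)."""
    return eff * np.power(2.0, -np.asarray(t, dtype=float) / half_life) + (1.0 - eff)


def _profile_eff(t: np.ndarray, y: np.ndarray, log2_th: float,
                 eff_bounds: Tuple[float, float]) -> Tuple[float, float]:
    """Closed-form least-squares eff at fixed Th (clipped to bounds), and SS_res."""
    x = np.exp2(-t / np.exp2(log2_th)) - 1.0
    sxx = float(x @ x)
    if sxx == 0.0:  # Th far above the window: no decay visible
        eff = eff_bounds[0]
    else:
        eff = float(x @ (y - 1.0)) / sxx
        eff = min(max(eff, eff_bounds[0]), eff_bounds[1])
    r = y - 1.0 - eff * x
    return eff, float(r @ r)


def _ss_fixed_eff(t: np.ndarray, y: np.ndarray, log2_th: float, eff: float) -> float:
    r = y - decay_model(t, np.exp2(log2_th), eff)
    return float(r @ r)


def _search_th(objective, th_bounds: Tuple[float, float], n_grid: int, n_refine: int) -> float:
    """Minimize a 1-D objective over log2(Th) within bounds; deterministic."""
    lo, hi = np.log2(th_bounds[0]), np.log2(th_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    ss = np.array([objective(g) for g in grid])
    order = np.argsort(ss, kind="stable")[:max(n_refine, 1)]
    best_x, best_ss = grid[order[0]], ss[order[0]]
    for i in order:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]
        if a == b:
            continue
        res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        if res.fun < best_ss:
            best_x, best_ss = float(res.x), float(res.fun)
    return best_x


def _r_squared(y: np.ndarray, ss_res: float) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _check_series(t: np.ndarray, y: np.ndarray, min_points: int) -> None:
    if len(t) < min_points:
        raise InsufficientDataError(f"need >= {min_points} timepoints, got {len(t)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")


def fit_decay_series(
    t: np.ndarray,
    y: np.ndarray,
    transcript_id: str = "",
    th_bounds: Tuple[float, float] = (0.1, 600.0),
    eff_bounds: Tuple[float, float] = (0.01, 1.0),
    n_starts: int = 5,
    n_grid: int = 120,
    eff_fixed: Optional[float] = None,
) -> DecayFit:
    """Fit the decay model to one normalized series (t=0 value should be 1).

    ``eff_fixed`` clamps the efficiency (``eff_fixed=1`` is the naive plain
    exponential whose half-life bias the efficiency term exists to remove).
    A series with zero variance is reported with status ``unfit``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_series(t, y, 3)
    if np.ptp(y) == 0.0:
        return DecayFit(transcript_id, float("nan"), float("nan"), float("nan"),
                        STATUS_UNFIT, n_points=len(t))

    if eff_fixed is not None:
        if not (0.0 < eff_fixed <= 1.0):
            raise ValueError("eff_fixed must be in (0, 1]")
        objective = lambda g: _ss_fixed_eff(t, y, g, eff_fixed)
    else:
        objective = lambda g: _profile_eff(t, y, g, eff_bounds)[1]

    best = _search_th(objective, th_bounds, n_grid, n_starts)
    th = float(np.exp2(best))
    if eff_fixed is not None:
        eff, ss = eff_fixed, _ss_fixed_eff(t, y, best, eff_fixed)
    else:
        eff, ss = _profile_eff(t, y, best, eff_bounds)
    r2 = _r_squared(y, ss)
    rel = 1e-6
    at_bound = th <= th_bounds[0] * (1 + rel) or th >= th_bounds[1] * (1 - rel)
    if eff_fixed is None:
        at_bound = at_bound or eff <= eff_bounds[0] * (1 + rel)
        # eff at the upper bound only counts when that bound is below the
        # physical ceiling of 1 (eff == 1 is a legitimate perfect-efficiency fit)
        if eff_bounds[1] < 1.0:
            at_bound = at_bound or eff >= eff_bounds[1] * (1 - rel)
    if not np.isfinite(r2):
        return DecayFit(transcript_id, float("nan"), float("nan"), float("nan"),
                        STATUS_UNFIT, n_points=len(t))
    return DecayFit(transcript_id, th, eff, r2, STATUS_OK,
                    at_bound=bool(at_bound), n_points=len(t))


def fit_decay(tc: TimecourseSet, transcript_id: str,
              th_bounds: Tuple[float, float] = (0.1, 600.0),
              eff_bounds: Tuple[float, float] = (0.01, 1.0),
              n_starts: int = 5) -> DecayFit:
    """Fit the decay model to one transcript of a normalized decay set."""
    if tc.channel != DECAY:
        raise ValueError("fit_decay requires a decay-channel set")
    return fit_decay_series(tc.timepoints, tc.series(transcript_id), transcript_id,
                            th_bounds=th_bounds, eff_bounds=eff_bounds, n_starts=n_starts)


def fit_decay_fixed_eff(tc: TimecourseSet, transcript_id: str, eff_fixed: float = 1.0,
                        th_bounds: Tuple[float, float] = (0.1, 600.0)) -> DecayFit:
    """Fit with the efficiency clamped (eff_fixed=1 is the naive estimator)."""
    if tc.channel != DECAY:
        raise ValueError("fit_decay_fixed_eff requires a decay-channel set")
    return fit_decay_series(tc.timepoints, tc.series(transcript_id), transcript_id,
                            th_bounds=th_bounds, eff_fixed=eff_fixed)


def fit_synthesis_series(t: np.ndarray, y: np.ndarray, transcript_id: str = "") -> SynthesisFit:
    """OLS line fit RNA(t) = ks*t + offset to one labeled-channel series."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError(f"need >= 2 timepoints, got {len(t)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    A = np.vstack([t, np.ones_like(t)]).T
    (ks, offset), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_res = float(res[0]) if res.size else float(np.sum((y - ks * t - offset) ** 2))
    r2 = _r_squared(y, ss_res)
    return SynthesisFit(transcript_id, float(ks), float(offset),
                        float(r2) if np.isfinite(r2) else float("nan"), len(t))


def fit_synthesis(tc: TimecourseSet, transcript_id: str) -> SynthesisFit:
    if tc.channel != SYNTHESIS:
        raise ValueError("fit_synthesis requires a synthesis-channel set")
    return fit_synthesis_series(tc.timepoints, tc.series(transcript_id), transcript_id)


def classify_fit(fit: DecayFit, expression_threshold: float = 1e-3,
                 r2_poor: float = 0.8, r2_high: float = 0.95) -> DecayFit:
    """Assign fit status per the filtering thresholds.

    Precedence: low expression (mean spike-normalized signal below threshold)
    beats everything; then unfit (no converged parameters); then poor fit
    (R² < 0.8); otherwise ok, annotated high_quality when R² > 0.95.
    """
    if np.isfinite(fit.mean_raw_signal) and fit.mean_raw_signal < expression_threshold:
        fit.status = STATUS_LOW_EXPR
        fit.high_quality = False
        return fit
    if not np.isfinite(fit.r_squared) or not np.isfinite(fit.half_life):
        fit.status = STATUS_UNFIT
        fit.high_quality = False
        return fit
    if fit.r_squared < r2_poor:
        fit.status = STATUS_POOR
        fit.high_quality = False
    else:
        fit.status = STATUS_OK
        fit.high_quality = fit.r_squared > r2_high
    return fit


class DecayModelFitter(BaseEstimator):
    """Transcriptome-wide decay-model fitting with filtering.

    Accepts a raw decay-channel :class:`TimecourseSet`; applies spike and t0
    normalization, fits the efficiency-modified decay model to every
    transcript, and classifies each fit (ok / poor_fit / unfit /
    low_expression).  An already-normalized set is fit as-is, in which case
    the expression filter is inactive (no raw signal to filter on).

    Parameters
    ----------
    th_bounds, eff_bounds : (min, max)
        Box bounds for half-life (minutes) and efficiency.
    n_starts : int
        Number of coarse-grid candidates refined by bounded Brent search.
    n_grid : int
        Coarse log-grid resolution over the half-life bounds.
    expression_threshold : float
        Transcripts whose mean spike-normalized signal falls below this are
        reported low_expression and excluded from half-life statistics.
    r2_poor, r2_high : float
        R² classification thresholds (poor fit below 0.8; high-quality
        annotation above 0.95).

    Attributes
    ----------
    fits_ : pandas.DataFrame
        One row per transcript with half_life, eff, r_squared, status,
        high_quality, at_bound, n_points, mean_raw_signal.
    status_counts_ : dict
        Count of transcripts per status.
    """

    def __init__(self, th_bounds=(0.1, 600.0), eff_bounds=(0.01, 1.0),
                 n_starts: int = 5, n_grid: int = 120,
                 expression_threshold: float = 1e-3,
                 r2_poor: float = 0.8, r2_high: float = 0.95):
        self.th_bounds = th_bounds
        self.eff_bounds = eff_bounds
        self.n_starts = n_starts
        self.n_grid = n_grid
        self.expression_threshold = expression_threshold
        self.r2_poor = r2_poor
        self.r2_high = r2_high

    def fit(self, X: TimecourseSet, y=None):
        if X.channel != DECAY:
            raise ValueError("DecayModelFitter requires a decay-channel set")
        if len(X) == 0:
            raise ValueError("empty timecourse set")

        if X.normalized:
            norm, mean_raw, dropped = X, {}, []
        else:
            spiked = SpikeNormalizer().fit(X).transform(X)
            mean_raw = spiked.values.mean(axis=1).to_dict()
            t0 = TZeroNormalizer(on_zero_anchor="drop").fit(spiked)
            norm = t0.transform(spiked)
            dropped = t0.dropped_ids_

        t = norm.timepoints
        fits = []
        for tid in X.transcript_ids:
            raw_mean = mean_raw.get(tid, float("nan"))
            if tid in dropped:
                f = DecayFit(tid, float("nan"), float("nan"), float("nan"),
                             STATUS_UNFIT, n_points=len(t), mean_raw_signal=raw_mean)
            else:
                f = fit_decay_series(
                    t, norm.series(tid), tid,
                    th_bounds=self.th_bounds, eff_bounds=self.eff_bounds,
                    n_starts=self.n_starts, n_grid=self.n_grid,
                )
                f.mean_raw_signal = raw_mean
            fits.append(classify_fit(f, self.expression_threshold, self.r2_poor, self.r2_high))

        self.fits_ = pd.DataFrame([f.to_dict() for f in fits], columns=FIT_COLUMNS)
        self.status_counts_ = self.fits_["status"].value_counts().to_dict()
        return self

    def predict(self, t: np.ndarray) -> pd.DataFrame:
        """Evaluate each fitted model curve on a time grid (ok fits only)."""
        ok = self.fits_[self.fits_["status"] == STATUS_OK]
        t = np.asarray(t, dtype=float)
        curves = {row.transcript_id: decay_model(t, row.half_life, row.eff)
                  for row in ok.itertuples()}
        return pd.DataFrame(curves, index=t).T


class SynthesisRateFitter(BaseEstimator):
    """OLS synthesis-rate fitting for a labeled-channel set.

    Spike-normalizes (if raw) and fits RNA(t) = ks*t + offset per transcript.

    Attributes
    ----------
    fits_ : pandas.DataFrame with ks, offset, r_squared, n_points per transcript.
    """

    def fit(self, X: TimecourseSet, y=None):
        if X.channel != SYNTHESIS:
            raise ValueError("SynthesisRateFitter requires a synthesis-channel set")
        if len(X) == 0:
            raise ValueError("empty timecourse set")
        norm = X if X.normalized else SpikeNormalizer().fit(X).transform(X)
        t = norm.timepoints
        rows = [fit_synthesis_series(t, norm.series(tid), tid) for tid in X.transcript_ids]
        self.fits_ = pd.DataFrame([asdict(r) for r in rows])
        return self


def fit_transcriptome(tc: TimecourseSet, **params) -> Tuple[pd.DataFrame, dict]:
    """Fit every transcript of a decay-channel set; return (fits, status counts)."""
    est = DecayModelFitter(**params).fit(tc)
    return est.fits_, est.status_counts_
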