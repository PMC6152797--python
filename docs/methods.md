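# Methods

## The measurement and its model

A 4TU chase follows two pools after label addition at t = 0. The
pre-existing (unlabeled) pool of a transcript with abundance `A` and
half-life `Th` decays as `A·2^(−t/Th)`. Newly made RNA is thio-labeled,
biotinylated and removed on streptavidin beads — but only a fraction `eff`
of it, set by 4TU uptake and uracil content, crosslinking yield and bead
separation. The escaping fraction `(1 − eff)` accumulates in the
"unlabeled" measurement; at steady state (synthesis balancing decay) it
accumulates exactly as the pre-existing pool decays, so the noiseless
unlabeled signal is

```
U(t) = A · [ eff · 2^(−t/Th) + (1 − eff) ]
```

After normalizing to `U(0) = A` this is the fit model
`RNA(t) = eff·2^(−t/Th) + (1 − eff)`. Ignoring the baseline (fitting a
plain exponential) always biases `Th` upward, and the bias grows as `eff`
falls — the simulator and test suite reproduce this monotone bias, and the
`fit_decay_fixed_eff(…, eff_fixed=1)` estimator exists precisely to exhibit
it. The labeled channel is the complement
`L(t) = eff·A·(1 − 2^(−t/Th))`, whose early-time slope `eff·A·ln2/Th` is
the synthesis rate; it is fit as a line `ks·t + offset`.

Assumptions: first-order decay of a single pool, steady state at t = 0,
`eff` constant per transcript across the chase, spike-in recovery
proportional to sample recovery at every timepoint.

## Normalization

Raw signals are divided by the spike-in signal at each timepoint (the spike
is an exogenous RNA added at constant amount, so this removes per-timepoint
extraction/library scale), then decay series are divided by their t = 0
value. Synthesis series are *not* t0-normalized: their t = 0 signal is ~0
by construction and the ratio would be numerically meaningless; the linear
fit absorbs overall scale instead (`TZeroNormalizer(force_synthesis=True)`
overrides this). Replicates are normalized and fit independently;
cross-replicate agreement is assessed on fitted half-lives. A transcript
with zero t = 0 signal cannot be anchored and is reported `unfit`.

## Fitting

At fixed `Th` the model is linear in `eff`:
`RNA(t) = 1 + eff·(2^(−t/Th) − 1)`, so the least-squares efficiency has the
closed form `eff* = Σx(y−1)/Σx²` with `x_t = 2^(−t/Th) − 1`, clipped to its
bounds. The fit therefore reduces to a one-dimensional bounded minimization
over `log2 Th`: a coarse log-spaced grid (default 120 points across
Th ∈ [0.1, 600] min) locates candidate basins and the best 5 brackets are
polished by bounded Brent search (xatol 1e−10). This profiled search is
deterministic, needs no random multi-starts, and on every series tested
attains the optimum of an exhaustive (Th × eff) grid search to within
1e−8 in SS_res. Default bounds: `Th ∈ [0.1, 600]` min,
`eff ∈ [0.01, 1.0]`; a fit landing on a bound is flagged (`at_bound`), not
errored. `eff = 1` is not flagged — perfect efficiency is a legitimate
estimate, not a box artifact.

R² is computed on the normalized values, including the t = 0 anchor, about
the series mean. Classification: mean spike-normalized signal below the
expression threshold (default 1e−3 of the spike) → `low_expression`; no
finite parameters (zero-variance series, zero anchor) → `unfit`;
R² < 0.8 → `poor_fit`; otherwise `ok`, annotated high-quality when
R² > 0.95. The expression threshold is configurable; the filter exists
because fits to near-background signal are dominated by noise, and 1e−3 of
the spike is far below any reasonably expressed transcript in the
simulated regime.

## The simulator

`sample_true_params` draws half-lives lognormal (log-median 3.6 min,
log-sd 0.7 — a right-skewed distribution spanning well over an order of
magnitude, from under 1 min to over 30 min), abundances lognormal, and
efficiencies Beta(20, 2) mapped into (0, 1] (median ≈ 0.92; most
transcripts above 0.8). Both channels are emitted on a default grid of
{0, 2, 4, 8, 16, 32} min, chosen to put two points inside the first median
half-life and to pin the `(1 − eff)` plateau by 32 min. Noise is
multiplicative lognormal per measurement (positive, heteroscedastic, as in
sequencing/qPCR readouts; default log-sd 0.05), applied independently to
every transcript value *and* to the spike-in series, so spike normalization
injects realistic error instead of being assumed perfect. An optional
Poisson layer (`poisson_scale`) adds counting noise; it is off by default.

What the simulator does **not** emulate: read-level sampling and mapping
artifacts, transcript-specific bead background, correlation of `eff` with
uracil content, cell-cycle or stress dynamics (synthesis and decay rates
are constant), and non-steady-state initial conditions. Passing tests on
simulated data therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every failure
mode of a wet experiment.

A consequence worth stating plainly: under this design the t0-anchor
division correlates the noise of all points and roughly doubles the
effective per-point error, and for half-lives beyond ~8 min the grid
carries little curvature information, so even the exact global
least-squares estimator recovers `Th` within 10% for only ~55–60% of
transcripts at 5% measurement noise (median relative error ≈ 8–11%).
Efficiency, by contrast, is pinned by the late plateau and its median
absolute error is below 0.01. Tightening recovery would require more
timepoints, replicate fits, or lower noise — not a better optimizer, as the
grid-oracle equivalence shows.

## Statistics

* Directional tests: one-sided paired t-test on raw half-life differences
  (a log-scale option exists). The caller maps (perturbation, model) to a
  prediction: elongation inhibition → TP predicts stabilize, SR predicts
  destabilize; initiation inhibition → TP predicts destabilize, SR makes no
  prediction (p not computed). Identical pairs return p = 0.5 (null
  center); a zero-variance nonzero shift returns 0 or 1 by direction.
* Transcriptome-wide shifts: two-sided paired Wilcoxon signed-rank, zero
  differences dropped; exact null for ≤ 25 tie-free informative pairs
  (validated against full 2^n sign enumeration), normal approximation with
  continuity correction otherwise.
* Comparisons join on the intersection of transcripts with status `ok` in
  both conditions. No multiple-testing correction is applied to the
  per-transcript directional tests (they are reported singly); a
  Benjamini–Hochberg step is available through statsmodels for batch use if
  needed.
* ECDFs are right-continuous with terminal value exactly 1; Spearman uses
  average ranks for ties.
* Replicate agreement: Pearson r on log10 half-lives by default, because
  the distribution spans an order of magnitude and linear-space r is
  dominated by the long-lived tail; linear space is an option.
* Long-lived class: half-life above mean + k·SD (sample SD, ddof = 1,
  k = 1 by default).

## Feature correlation

Feature tables arrive precomputed (computing TE/CAI/nTE from sequence or
profiling data is out of scope). Correlations are Spearman with
average-rank ties on pairwise-complete observations — external feature
datasets rarely cover identical transcript sets — with a minimum overlap of
3 transcripts per pair, enforced with an error naming the offending pair.
The correlation matrix is clustered on Euclidean distances between its rows
with average linkage (UPGMA), the most common heatmap default; features are
pre-sorted lexicographically so equal-height merges resolve
deterministically. The heatmap uses a diverging orange/blue palette with
the self-correlation diagonal masked gray; it is a rendering convenience
and carries no analysis weight.

## Bulk transcriptome half-life

The bulk value pools spike-normalized (not t0-normalized) signal across
transcripts per timepoint, t0-normalizes the *pooled* series once, and fits
the decay model to it. Pooling before t0 normalization preserves abundance
weighting: abundant long-lived transcripts dominate the summed pool, which
is why the bulk half-life exceeds the per-transcript mean whenever
abundance and stability are positively associated. The pooled curve is a
mixture of exponentials and the single-`Th` fit returns an effective
weighted value strictly between the fastest and slowest components.

## Problem sizes and numerical choices

The test suite and the acceptance script run transcriptomes of 300–5000
transcripts on the 6-point default grid, sizes at which the full pipeline
(normalize, 1-D profiled fit per transcript, summaries) completes in tens
of seconds; the grid-search oracle used for validation is 1500 × 200 to
6000 × 1200 (Th × eff) depending on the required resolution. All
randomness flows through explicit integer seeds (numpy `default_rng`);
fitting itself is seed-free and deterministic. Convergence: Brent xatol
1e−10 on log2 Th; ties in the coarse grid are broken by stable argsort, so
results are independent of input row order.

## Known limitations

- Single-pool first-order kinetics only: no deadenylation/decapping
  multi-step models, no degradation-rate changes during the chase.
- `eff` is a per-transcript constant; systematic trends (e.g. with uracil
  content) are neither simulated nor modeled.
- The bulk half-life from a single-`Th` fit to a mixture is an effective
  value; it depends on the timepoint window as well as the abundance
  weights.
- Half-life recovery beyond ~2× the last timepoint is weakly identified;
  such fits tend to hit the upper half-life bound and should be read as
  censored ("longer than the window resolves") rather than point estimates.
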