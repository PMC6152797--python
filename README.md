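# thiolife

Analysis toolkit for **non-invasive mRNA half-life measurement by
4-thiouracil (4TU) chase labeling**.

In a 4TU chase, the label is added at t = 0 and incorporated into all newly
made RNA. Biotinylation of the thiol group lets labeled (new) RNA be pulled
out on streptavidin beads, so the unlabeled flowthrough tracks the decay of
the pre-existing mRNA pool while the labeled eluate tracks synthesis — all
without halting transcription or translation. Because labeling, biotin
crosslinking and bead separation are never perfect, a fraction of new RNA
leaks into the "unlabeled" measurement and makes transcripts look more
stable than they are. `thiolife` is built around the decay model that
absorbs this leak:

```
RNA(t) = eff · 2^(−t/Th) + (1 − eff)
```

where `Th` is the half-life (minutes) and `eff ∈ (0, 1]` is the bulk
labeling/separation efficiency; `(1 − eff)` shows up as a non-decaying
baseline. The synthesis channel is fit to a line `RNA(t) = ks·t + offset`.
The package is for anyone running (or simulating) metabolic-labeling decay
experiments who needs per-transcript half-lives with honest handling of
capture inefficiency, plus the downstream statistics: transcriptome
summaries, control-vs-perturbation tests, and feature-correlation
clustering.

## What's inside

- `thiolife.simulate` — seeded generator of ground-truth transcriptomes and
  simulated chase measurements (decay + synthesis channels, noisy spike-in,
  multiplicative lognormal noise, optional Poisson layer). Also reproduces
  the demonstration that naive exponential fits overestimate half-lives
  when capture is inefficient.
- `thiolife.normalize` — `SpikeNormalizer` and `TZeroNormalizer`
  (scikit-learn transformers): divide by the spike-in per timepoint, then
  anchor decay series to their t = 0 value.
- `thiolife.kinetics` — `DecayModelFitter` / `SynthesisRateFitter`
  estimators. The decay model is linear in `eff` at fixed `Th`, so `eff` is
  profiled out in closed form and `Th` found by a bounded 1-D search;
  fits are classified ok / poor_fit (R² < 0.8) / unfit / low_expression,
  with a high-quality annotation at R² > 0.95.
- `thiolife.summary` — mean/median half-life, abundance-weighted bulk
  transcriptome half-life, efficiency fractions, mean lifetime (`Th/ln 2`),
  replicate Pearson agreement, long-lived class (> 1 SD above the mean).
- `thiolife.compare` — one-sided paired t-tests of the stalled-ribosome
  (SR) vs translation-factor-protection (TP) predictions, paired Wilcoxon
  (exact for ≤ 25 tie-free pairs), half-life ECDFs, cross-condition
  Spearman, codon-count-threshold fold-change grouping.
- `thiolife.features` — `FeatureCorrelation`: pairwise-complete Spearman
  matrix over transcript features (half-life, TE, CAI, nTE, polyA length,
  abundance, UTR lengths, GC, ORF length) with UPGMA clustering on
  Euclidean row distances and a diverging heatmap.
- `thiolife.cli` — `thiolife simulate|fit|summarize|compare|correlate` over
  TSV/JSON/YAML files.

## Worked example

```python
from thiolife import (sample_true_params, simulate_decay_timecourse,
                      SimulationDesign, DecayModelFitter,
                      summarize_half_lives, bulk_half_life)

params = sample_true_params(1000, seed=42)          # known ground truth
design = SimulationDesign(noise_sigma=0.05, seed=43)
tc = simulate_decay_timecourse(params, design)      # raw decay channel

est = DecayModelFitter().fit(tc)                    # normalize + fit + classify
print("status counts:", est.status_counts_)
s = summarize_half_lives(est.fits_)
s.bulk_half_life = bulk_half_life(tc)
print(f"mean half-life    {s.mean_half_life:.2f} min")
print(f"median half-life  {s.median_half_life:.2f} min")
print(f"bulk half-life    {s.bulk_half_life:.2f} min")
print(f"mean lifetime     {s.mean_lifetime:.2f} min")
```

prints

```
status counts: {'ok': 998, 'poor_fit': 2}
mean half-life    5.03 min
median half-life  3.93 min
bulk half-life    3.48 min
mean lifetime     7.25 min
```

998 of 1000 simulated transcripts fit the model; the mean and median
half-lives recover the generator's fast-turnover distribution (log-median
3.6 min). The bulk value is the half-life of the *summed* signal of all
transcripts — here abundance was drawn independently of half-life, so it
sits near the typical transcript; when long-lived transcripts are abundant
(as in real transcriptomes) it rises well above the mean. The mean lifetime
is the mean half-life divided by ln 2.

The same pipeline from the shell:

```sh
thiolife simulate --n 1000 --seed 42 --out counts.tsv --truth-out truth.tsv
thiolife fit --counts counts.tsv --out fits.tsv --summary-out status.json
thiolife summarize --fits fits.tsv --counts counts.tsv --out summary.json
```

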