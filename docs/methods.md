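# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `stimmap`. Conventions throughout: signals in
microvolts, times in milliseconds from recording start, 0-based channel
indices, 16 ms power bins addressed by their centers.

## Preprocessing

**Bad channels.** The exclusion criterion is a robust z on log-RMS per
channel within its CAR block: a channel is flagged when
`|log_rms − median| / (1.4826·MAD)` exceeds `mad_factor` (default 5).
This is a scale-free, block-local reading of "excessive noise";
`mad_factor = inf` disables the filter. A block whose channels are all
flagged is an error — that block is unusable.

**Decimation.** Recordings sampled above 1 kHz are low-passed with a
zero-phase FIR (cutoff 400 Hz, 30·q+1 taps, forward–backward) and
downsampled by the integer factor q. Zero-phase filtering avoids
latency bias in the CCEP timing; non-integer ratios are rejected with
instructions to resample. Event and pulse times are stored in ms and
are unaffected.

**Common average reference.** Within each block the instantaneous mean
of the non-bad channels is subtracted from each non-bad channel; bad
channels pass through unreferenced and are excluded downstream. The
operation is idempotent and removes any signal common to a block.

## High-gamma mapping (STFM)

The band-limited analytic envelope is computed by masking the
whole-record spectrum: unity gain in 70–150 Hz, Gaussian shoulders
(σ = 5 Hz) outside, zeros within ±4 Hz of 60 and 120 Hz; negative
frequencies zeroed and positive doubled, inverse transform, magnitude.
Masking the full-length transform rather than per-window coefficients is
a deliberate leakage-control choice: at 128-sample resolution a 60 Hz
tone leaks ≈ −14 dB into the passband bins and cannot be notched,
whereas at full resolution line and out-of-band tones are suppressed to
the power floor exactly. The 128 ms/112 ms-overlap analysis scheme is
realized as the power-averaging stage: squared envelope averaged in
128 ms windows hopped every 16 ms, floored at ε = 10⁻¹² µV² and
natural-log transformed. The analytic magnitude of `A·cos(2πft)` is `A`
(per-bin power `A²`); scaling the raw signal by c shifts log power by
`2·ln c` and leaves all test statistics unchanged.

Window timestamps sit at window centers (first bin 64 ms after record
start). Epochs are cut on the common 16 ms grid anchored at the bin
nearest each stimulus onset, so alignment error is under half a bin;
trials extending past the recording are dropped with a warning.

**Significance.** Each time×channel bin's across-trial values are
compared against the channel's pooled baseline (all −1000…−200 ms bins ×
trials) with a two-sided Welch t-test; zero-variance baselines yield
p = 1 with a warning. Benjamini–Hochberg runs jointly over all
channel×bin p-values of a task (the conservative reading of a single
correction family) at q = 0.05. A channel is STFM+ iff at least one
surviving bin has positive t — the mask alone is not enough, since the
label denotes an *increase*. With several tasks, a channel positive in
any task is positive overall. Calibration note: with ≥ 40 trials per
bin the empirical probability of any false discovery on a global-null
raster is ≈ 0.04–0.05; at 20 trials the extreme tail of the Welch
approximation becomes slightly liberal, so the null-calibration
experiments use 50 trials, matching the 50–100 trials per recorded task.

## CCEP analysis

Pulse-locked epochs (−500…+300 ms) are demeaned by their own baseline
(−500…−10 ms) and averaged (≥10 complete epochs required). Per-epoch
demeaning removes slow 1/f drift and keeps the baseline SD of the
average stable. The 0–10 ms span is stimulation artifact: it is zeroed
before a 5 ms zero-phase boxcar smooths the average, so artifact energy
cannot leak into the search window through the kernel. Smoothing
matters quantitatively: the N1 statistic is the *maximum* absolute
deviation from the baseline mean within 10–50 ms, and with broadband
residual noise the max over ~41 samples is upward-biased by about one
z-unit at low response amplitudes; after smoothing the bias is within
the ±1 recovery tolerance at 3× baseline SD.

The z-score divides that peak deviation by the baseline SD of the
(smoothed) averaged waveform; it is a ratio, hence invariant to
amplitude scaling, and the absolute-deviation detector is agnostic to
montage polarity. Responses with z > 6 (strict) are significant and
become edges stim-pair → channel; stimulated and bad channels are never
response channels. Non-significant z-scores are retained for the
z-weighted network feature.

Two deliberate departures from a literal pipeline reading:

* **No CAR before CCEP scoring.** Re-referencing a single-pulse session
  would inject each channel's evoked deflection into every other channel
  of its block (bleed of order Σ amplitudes / block size), biasing z at
  true targets downward and at silent channels upward. CCEPs are
  therefore analyzed in the recording reference (bad-channel exclusion
  and decimation still apply).
* **Search window.** The observed cohort mean N1 latency (9.63 ms) lies
  below the stated 10–50 ms window; the implementation keeps the stated
  window, and the generator truncates its latency distribution to it.

## Network features

* `HG_alltime[c]`: sum over FDR-masked, positive-t, post-stimulus bins
  of (trial-mean log power − baseline mean); 0 for STFM− channels.
* **PCA windows**: principal components of the trial-averaged
  post-stimulus time courses of STFM+ channels (channels = variables,
  bins = observations, per-channel centering); the smallest component
  set explaining ≥ 80% variance is kept and a bin is selected when any
  kept component's |temporal score| reaches 50% of that component's
  maximum. The exact windowing procedure is under-determined in the
  source literature; this 80%/50% rule is the declared substitute.
  Fewer than two STFM+ channels, or degenerate covariance, falls back to
  all post-stimulus bins with a warning. `HG_pca` is the same integral
  restricted to selected bins, so `0 ≤ HG_pca ≤ HG_alltime` always.
* **Centrality**: PageRank (damping 0.85) on the graph of positive
  Pearson correlations between STFM+ channels' trial-averaged HG time
  courses (negative correlations clipped to 0 — PageRank needs
  nonnegative weights; self-edges removed; zero-variance channels keep
  their node but lose their edges). Scores sum to 1 over STFM+
  channels; STFM− channels score 0.
* **Pair features** (Σ_stim = the pair's two electrodes, Σ_grid = all
  non-bad electrodes, `#el` = their count):
  `f_alltime = Σ_stim HG_alltime²`, `f_pca = Σ_stim HG_pca²`,
  `f_centrality = Σ_stim Centrality²`,
  `f_ccep_z = Σ_grid (N1-z × HG_pca) / #el` using every response
  channel's raw z (significant or not),
  `f_ccep_edges = edge_count × Σ_grid HG_pca / #el`.
  Pairs never probed with single-pulse stimulation get missing CCEP
  features and are dropped from (not imputed into) CCEP-based fits.

## Models and evaluation

ESM outcome (1 = language-positive) is modeled as
`logit P(ESM+) = linear combination` of the variant's features — the
only coherent reading of a logistic/GLM fit. Variants: `eq1`
(f_alltime), `eq2` (f_pca), `eq3_centrality_only` (f_pca, f_centrality),
`eq3_ccep_z` and `eq3_ccep_edges` (adding the respective CCEP term).

Evaluation is stratified 5-fold CV with a fixed seed (14–18 pairs per
patient make unstratified folds degenerate): features standardized with
training-fold statistics, maximum-likelihood logistic fit, out-of-fold
probabilities pooled, classified at 0.5. Perfect separation (detected
by a perfectly classifying unpenalized fit or diverging coefficients)
engages a tiny ridge (λ = 10⁻⁶ on standardized features) to keep
coefficients finite without materially biasing them. Reports carry the
confusion counts (model+∧ESM+, model−∧ESM+, model−∧ESM−, model+∧ESM−),
sensitivity/specificity/accuracy in percent (one decimal; an empty
class makes the corresponding rate NaN with a warning), and AUC on the
pooled out-of-fold probabilities. Cohort summaries are unweighted means
across patients; model variants are compared with a pooled-variance
two-sample two-sided t-test on the per-patient metrics.

## Synthetic data generator

The generator defines the study conditions; every downstream claim about
recovery is relative to it.

**Background.** Per-channel pink (1/f) Gaussian noise band-limited to
≥ 1 Hz (the amplifier high-pass analogue; default RMS 10 µV) scaled by
lognormal per-channel gains (σ = 0.4 — realistic impedance spread;
identical-variance channels would make the robust bad-channel statistic
degenerately tight), plus a shared per-block pink common mode (5 µV, so
CAR has something to remove), plus a 60 Hz line sinusoid (5 µV).

**Task sessions.** 40 trials (default) at 3.2–4.0 s intervals; at each
active channel a burst of 70–150 Hz band-limited Gaussian noise (not a
tone — broadband high gamma, and no notch interaction) with a Gaussian
envelope, onset 200 ms + N(0, 20 ms) jitter, duration 400 ms, amplitude
`hg_burst_gain ×` that channel's in-band background RMS (the in-band
fraction of a pink spectrum is computed analytically). With small CAR
blocks, a fraction `√k/N` of the k active channels' bursts bleeds into
the other block members as a weak but statistically detectable increase;
real grids have much larger blocks, so synthetic STFM+ sets are a
superset of the planted active set, with activation magnitudes an order
of magnitude apart. Rank-based and model-level claims are unaffected;
exact-support recovery would require larger blocks than desk scale
allows.

**SPES sessions.** 50 pulses (default) at jittered 2–5 s intervals; a
damped 300 Hz artifact confined to 0–8 ms (inside the blanking span) at
all channels, large at the stimulated pair; at each connected response
channel a negative Gaussian trough (σ = 3 ms) at a latency drawn once
per channel from N(9.63, 8.94²) ms truncated to [10, 50]. Connectivity
weights are in units of target z: the generator measures the baseline SD
of the trial-averaged, demeaned, smoothed background *before* adding
deflections and scales the planted amplitude so the smoothed trough
equals `weight × SD` — a weight of 10 aims at z ≈ 10. Because the
common-mode noise survives un-referenced averaging, z errors are
correlated across channels of a block; means over ~8 planted targets
recover the weight to within about ±1.

**ESM labels.** Per pair, three planted features: own activation
(Σ over the pair of squared activation indicators), planted centrality
(uniform over active channels — co-bursting sites are near-perfectly
correlated, so their PageRank is uniform), and connectivity-weighted
network activation (Σ_c connectivity[pair, c]·active[c]/n_channels).
Features are z-scored across pairs, combined with coefficients
(γ₀, γ₁, γ₂, γ₃) — default (0, 0.3, 0, 4): weak own-activation, strong
connectivity — and the linear predictor is median-centered before the
Bernoulli draw so ESM+ prevalence sits near 50% at any coefficient
scale, matching the near-balanced recorded cohorts (11/6, 10/7).
Without centering, stronger coefficients skew per-patient class balance
and a majority-class baseline contaminates model comparisons. Labels
come from a dedicated seed stream, so they can be re-planted with new
coefficients without touching the signals.

All draws derive from per-purpose streams spawned from the config seed
(ground truth → gains → task noise/bursts → per-pair SPES → labels), so
identical configs are bit-identical.

## The cohort experiment

`stimmap.experiments.connectivity_gap_experiment` simulates five
pseudo-patients (20 channels, two blocks, 18 pairs each — the recorded
cohorts had 14–18 ESM pairs), requires ≥ 5 pairs of each class (as in
the recorded cohorts), and evaluates all model variants at three planted
connectivity strengths γ₃ ∈ {0, 1.5, 4} on the *same* recordings with
re-planted labels. Expected behavior, and what the acceptance checks
assert: the combined model (`eq3_ccep_z`, whose z-weighted term mirrors
the planted network feature) beats the HG-all-duration model by well
over 5 accuracy points at the strong setting, and the gap grows
monotonically with γ₃. The edge-count variant carries strictly less
information (a scalar count per pair) and shows a smaller, noisier gap.
The null anchor γ₃ = 0 is part of the design: at two nearby weak
settings the gap difference is smaller than desk-scale Monte-Carlo
noise.

What passing does *not* show: the generator has no volume conduction,
no afterdischarges, no task-stage structure, stationary noise, and
labels generated from the very feature family the models use — real
ESM–STFM discordance involves mechanisms the generator does not emulate.
The experiments validate the *pipeline's* correctness and the
direction of the modeling claim, not clinical performance.

## Problem sizes and limits

Default experiment sizes (5 patients × [1 task run + 18 single-pulse
runs], 2000-map null calibration at 4 channels × 50 trials × 125 bins,
1000 random p-lists, 20 random 6-node graphs) complete in about a
minute each on one CPU; they were chosen as the smallest sizes at which
the Monte-Carlo error of each check is comfortably below its tolerance.
Known limitations: the synthetic STFM+ set overshoots the planted active
set under small CAR blocks (above); CCEP z recovery wobbles ~±1 through
block-correlated common-mode noise; and the AUC comparison between
model variants is reported with the same pooled t-test as accuracy,
although the printed AUC p-value of the source cohort is not exactly
reproducible by that test (left as reported).
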