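# Methods

`dyadcrp` quantifies 24-hour mother–child autonomic synchrony from heart-rate
variability and relates it to maternal parenting stress. This note documents
the models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic cohort does and does not
establish.

## HRV indices

Three indices are computed from artifact-filtered N-N intervals on a sliding
window (default width 300 s, step 60 s, trailing and half-open, so the value
at grid time *t* summarizes beats in (*t* − 300 s, *t*]):

- **SDNN** (ms): sample standard deviation (divisor *n* − 1) of the intervals
  in the window. Global HRV.
- **CSI / CVI**: from the Lorenz (Poincaré) scatter of each interval *I_k*
  against its successor *I_{k+1}*. With sd1 the sample standard deviation of
  (*I_k* − *I_{k+1}*)/√2 and sd2 of (*I_k* + *I_{k+1}*)/√2, the transverse and
  longitudinal axis lengths are T = 4·sd1 and L = 4·sd2, and
  CSI = L/T (sympathetic balance), CVI = log₁₀(L·T) (vagal tone).
  A degenerate cloud (T = 0 or L = 0) yields missing values.

All three indices share one 60 s grid so the downstream 24-h segments align;
the windowing applies to SDNN as well, which is a package choice — only the
CSI/CVI windowing is canonical.

Artifact handling is parameterized because no single rule is standard:
intervals outside [300, 2000] ms are removed, as are intervals deviating from
the running median of the previous five kept intervals by more than 30%.
Recordings losing more than 5% of beats are flagged; the caller decides
whether to exclude them (the pipeline excludes).

## Day preparation

Index series are cut into 1440-point days starting at 22:00 local clock time;
incomplete days are dropped. Days missing more than 20% of slots are rejected
(exactly 20% is kept — the rule excludes only days *exceeding* the threshold);
smaller gaps are filled with the day's own observed mean, which leaves the
day's mean unchanged. Values are then min–max scaled to [0, 1] per subject,
pooling over all of that subject's days of one index, and rounded to one
decimal (ties half away from zero, for cross-platform determinism), giving 11
discrete levels.

Open choices resolved here: the normalization method is unstated in the
source analysis; min–max per subject was chosen because the stated purpose is
to remove differences in *fluctuation range*, and because 11 levels make
exact-match recurrences (ε = 0) non-degenerate — z-scoring followed by
one-decimal rounding would scatter values over ~60 levels and empty the
plots. The fill mean is within-day (a per-subject alternative is exposed as
an option). Per-subject rather than per-subject-day pooling preserves
day-to-day level differences.

## Recurrence and cross-recurrence plots

For one discretized day, the recurrence plot is R_ij = 1 iff
|level_i − level_j| ≤ 10·ε; ε = 0 (the default) is exact level equality,
implemented on integer levels so no floating-point comparison is involved.
The cross-recurrence plot of a dyad compares the child's level at time *i*
with the mother's at time *j*; rows index child time (vertical axis), columns
mother time (horizontal). The main diagonal is the line of synchrony.

Quantification helpers: the overall recurrence rate; the τ-recurrence profile
(mean of each superdiagonal — peaks mark periodicity, and the first
nonzero-lag prominent peak's lag is the dominant period; peak detection uses
`scipy.signal.find_peaks` with a prominence of 0.1 on the recurrence-fraction
scale to ignore sampling jitter); and a per-block main-diagonal recurrence
fraction for locating stretches of intact synchrony.

For SOM input, plots are block-mean downsampled. The default factor 10 turns
a 1440×1440 day plot into a 144×144 image (20 736 dimensions), preserving the
day/night block structure at tractable cost; the source analysis never states
the resolution it used. Binary plots carry no chroma, so images are a single
intensity channel.

## SOM feature extraction

One 4×4 self-organizing map is trained per plot family × index
({mother RP, child RP, dyad CRP} × {SDNN, CSI, CVI} = 9 maps). Training is
the classic online algorithm — per step the best-matching unit is found and
all weights move toward the input under a Gaussian neighborhood on the map
grid — with learning rate and radius decaying linearly across epochs
(defaults: α 0.5 → 0.01, radius 2 → 0.5, 100 epochs). Training restarts 25
times from consecutive seeds; the restart with the lowest quantization error
(mean distance to the BMU) is kept, since the selection criterion is
otherwise unstated.

Initial prototypes are drawn from the training images. In 20 000+ dimensions,
uniform-random prototypes start ~40 units away from the data manifold and
some neurons never win a single input ("dead units"), leaving their distance
features as pure noise; sampling initialization is standard practice and
avoids this. Uniform initialization remains available (`init="uniform"`).

Each plot image is then summarized by its **activity vector**: the 16
Euclidean distances from the image to the trained weight vectors, row-major.

A known limitation, measured on the synthetic cohort: a 4×4 map is
constrained to a two-dimensional topology, so its 16 prototypes cannot span
16 informative directions of image space. Ordinary least squares on the 16
distances recovers only about half of the predictive signal that the same
regression on 16 principal-component scores of the same images recovers.
This bounds how reliably the CRP-based model beats the RP-based models on
small cohorts (see the studies module and the test suite).

## Stress regression

For each of the 9 maps, PSI_i ~ d₁…d₁₆ is fitted by OLS with intercept
(statsmodels). One row per day-plot: a mother with *d* days contributes *d*
rows sharing her PSI total, mirroring a cohort with more plots than mothers;
a strict one-row-per-mother mode (`unit="subject"`, averaging her activity
vectors) is available because repeated measures are otherwise unmodelled.
Reported per model: adjusted R², the overall F-test p-value (significance at
0.05, no multiple-testing correction across the 9 models), in-sample RMSE and
MAE, and a ±1σ tolerance band (σ = sample standard deviation of residuals;
for Gaussian residuals its coverage approaches 68.3%). Models are ranked by
RMSE, ties by MAE; metrics are in-sample by design, with an optional
leave-one-subject-out mode off by default. The fit requires at least 18
observations (p + 2 with p = 16) and a full-rank design; pipelines too small
to support it carry an explicit failure status in the report instead.

## PSI scoring

78 items rated 1–5; positively worded items are reverse-scored (6 − raw);
the total (78–390) flags high parenting-stress risk at ≥ 221. The identity of
reversed items is proprietary to the instrument and must be supplied; the
synthetic cohort uses none.

## Synthetic cohort

No public mother–child 24-h HRV cohort exists, so the generator plants known
structure:

- **Circadian profile** c(t): night level over 22:00–06:00, day level
  otherwise, 60-min linear transitions, continuous across midnight-adjacent
  days. Per-index levels (day, night, noise σ): SDNN (40, 70, 8) ms,
  CSI (3.5, 2.0, 0.45), CVI (3.0, 5.0, 0.6) — overall HRV and vagal tone rise
  in sleep, sympathetic tone in waking, with noise ≈ 0.3× the day–night
  amplitude.
- **Coupling**: mother(t) = c(t) + σ(√ρ·z + √(1−ρ)·z_m),
  child(t) = c(t) + σ(√ρ·z + √(1−ρ)·z_c), where z, z_m, z_c are independent
  unit-variance AR(1) processes, so the mother–child noise correlation is
  exactly ρ. The per-minute lag-1 autocorrelation defaults to φ = 0.995
  (state persistence ≈ 3 h, the scale of sleep/wake bouts and sustained
  activity states); this slow mixing is what makes a dyad's coupling visible
  in a cross-recurrence plot, since matching persists across the broad
  near-diagonal band.
- **Stress link**: per dyad, ρ ~ Uniform(0.1, 0.9) shared across indices and
  days, and PSI = clamp(round(110 + 150·ρ + N(0, 10)), 78, 390), giving
  totals spanning roughly 125–260, comparable to a community sample.
- **R-R level**: an AR(1) interval generator with prescribed Poincaré axes
  (σ² = (sd1² + sd2²)/2, φ = (sd2² − sd1²)/(sd1² + sd2²)) exercises the HRV
  extraction end to end; it is deliberately independent of the index-level
  generator.

What the generator does *not* emulate: ultradian sleep-cycle structure,
naps and schedule irregularity, device artifacts beyond simple gaps,
non-Gaussian index distributions, and any mother–child asymmetry. Passing
tests therefore demonstrate that the pipeline recovers a planted linear
coupling–stress link under clean circadian structure — not that it would do
so on real recordings.

## Simulation studies and problem sizes

The studies module runs desk-scale experiments: cohorts of 24 dyads × 3 days
(within the 1–3 days-per-dyad range of the cohort the generator mirrors),
one index, 144×144 images, and lightly trained SOMs (12 epochs, 2 restarts)
so a 50-seed study completes in minutes. Under these conditions the dyad-CRP
regression out-fits both single-member RP regressions in roughly 70–75% of
seeds; replacing the 16 SOM distances with 16 principal-component scores of
the same images raises this to ~90%, locating the gap in the SOM's
two-dimensional topological bottleneck rather than in the plots or the
planted link. The Spearman correlation between a dyad's planted ρ and its
mean CRP recurrence rate has a 20-seed median of ≈ 0.55 at these defaults.

## Numerical and degenerate-input conventions

Missing values propagate as NaN inside index series and are masked
explicitly in day segments. Constant subjects normalize to 0.5 and are
flagged degenerate. SDNN needs ≥ 2 beats, Lorenz axes ≥ 3; windows failing
these yield missing grid points. BMU ties break to the lowest neuron index.
The ±1σ band counts numerically zero residuals (|r| < 10⁻⁸) as inside, so a
perfect fit reports full coverage. All randomness flows from explicit seeds;
the pipeline derives per-stage seeds by hashing the stage name with the
top-level seed (SHA-256, reduced below 2³¹), so stages are reproducible and
independent.
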