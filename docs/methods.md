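# Methods

`eegvuln` re-creates, end to end and at desk scale, a two-group EEG study of
*vulnerability to depression*: non-clinical participants scoring high vs low
on summed standardized rumination/depression questionnaires (PTQ, RRS,
CES-D), recorded at rest (5 min, eyes closed) and during a sustained
attention to response task (SART) with embedded thought probes that rate the
"stickiness" of ongoing thought on a 1–9 scale.  Because no real recordings
ship with the package, every analysis runs on synthetic cohorts with
*planted, known* group effects, which turns the pipeline into a testable
object: an effect the generator plants must come back out of the statistics,
and an effect it does not plant must not.

## Synthetic cohorts

**Montage and channels.** 32 scalp electrodes in the Biosemi 10–20 layout,
projected azimuthally onto the unit disc, plus two EOG channels.  The
montage carries a k-nearest-neighbour graph (default k = 4) used for
bad-channel interpolation.

**Background signal.** Each channel is 1/f-shaped noise (power spectral
density ∝ 1/f^β, default β = 1) produced by spectral shaping of white
Gaussian noise, scaled to a baseline SD of 10 µV (scalp) / 15 µV (EOG).
Log-normal gains add amplitude variability: SD 0.15 (log scale) per subject
and 0.10 per channel.  The subject-gain value is constrained from above by
the package's own recoverability requirement — a ×1.5 band-amplitude effect
at n = 20 + 20 must be detectable after FDR correction in ≥ 90 % of
replicates — and from below by wanting visible overlap between groups; 0.15
satisfies both.  Blink artifacts are smooth positive bumps (Hann² template,
~0.45 s) on the EOG channels at 0.07 events/s, leaking at 25–40 % amplitude
into the four frontal channels, so that peak-to-peak rejection has something
realistic to reject (≈ 10–15 % of task trials, matching typical rejection
proportions).

**Planted effects.**
*Amplitude*: the named band of the named channel is scaled by a
multiplicative factor in the high-vulnerability group only, implemented as
`x + (factor − 1)·bandpass(x)` so only the band component grows.
*Coupling*: a shared band-limited noise carrier (band-passed white noise,
never a sinusoid, so coherence/PLV/PLI stay non-degenerate) is added to
both channels of a pair; the second channel receives the carrier with a
constant phase lag applied through its analytic signal.  A nonzero lag is
what makes the coupling visible to the phase-lag index, which by design
ignores zero-lag (volume-conducted) mixtures.  Mixing coefficients are per
group (default: high only).

**Task structure.** SART trials are cross (sampled from
{1480, 1640, 1800, 1960, 2020} ms) + word 320 ms + mask 880 ms + ISI
3020 ms, 8 blocks × 90 trials = 720 trials, no-go probability 1/9.  Thought
probes occur after each trial with probability `probe_rate` (a free
parameter — the study design does not fix a probe frequency; default 0.1);
each probe's rating (uniform 1–9) labels the five preceding trials, with
1–4 → "less sticky", 6–9 → "more sticky", 5 excluded.

**Questionnaires.** Scores are drawn from untruncated normal distributions
with the published group means/SDs (e.g. PTQ high 45.85 ± 4.70 vs low
25.10 ± 8.33).  Instrument score ranges are not modelled, so draws can
exceed nominal maxima — accepted, since only group-difference statistics
consume these columns.  By default 3 high-group and 1 low-group subjects
lack the intensity/frequency ratings of the negative-event writing task
(capped so at least two rated subjects remain per group in tiny cohorts),
reproducing the n = 17/19 degrees of freedom of those comparisons.

**What the generator does not emulate:** volume conduction through a head
model, evoked responses to the word stimuli, non-stationarity across the
session, realistic artifact taxonomies (muscle, drift), or any coupling
between questionnaire scores and EEG.  Passing tests therefore demonstrate
the *pipeline's* correctness and sensitivity, not claims about real EEG.

## Preprocessing

Filter → segment → baseline → reject → interpolate → re-reference → trim,
all pure functions:

* zero-phase band-pass 0.5–40 Hz, 4th-order Butterworth run forward and
  backward (`sosfiltfilt`), so pass-band gain is (≈) unity and pulse
  symmetry is preserved;
* epochs −500..+1300 ms around word onset; sample convention
  `start = onset + round(tmin·fs)`, length `round((tmax−tmin)·fs)`,
  half-open — 922 samples at 512 Hz;
* baseline: subtract the per-trial/channel mean of the pre-stimulus
  interval;
* artifact rejection: a trial is dropped iff any scalp channel's
  peak-to-peak amplitude exceeds 150 µV (an automatic proxy for manual
  marking, which is not reproducible; ICA is likewise out of scope, blinks
  are handled by rejection alone);
* bad channels: samplewise mean of the non-bad montage neighbours (k = 4);
* average reference over scalp (non-EOG) channels;
* final crop to −200..+1300 ms (768 samples).

Resting recordings are tiled into consecutive 2-s pseudo-epochs.

## Biomarkers

Per subject, band (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–40 Hz; "raw" = 0.5–40) and channel or pair:

* **Band power** — Welch PSD (2-s Hann windows, 50 % overlap → 0.5 Hz
  resolution, enough to resolve delta) integrated over [low, high),
  averaged over epochs.  **Group statistics use log₁₀ power**: under the
  multiplicative gain model (and in real EEG) across-subject power is
  log-normal, so t-tests operate on the log scale.  Relative power divides
  by total 0.5–40 Hz power.
* **Alpha asymmetry** — ln P_α(F4) − ln P_α(F3) (pair configurable).
* **Correlation** — Pearson r per epoch, averaged.
* **Coherency** — cross-spectrum normalised by auto-spectra, Welch-averaged
  over all windows of all epochs; the magnitude and |imaginary part| are
  then averaged over the band's bins.
* **PLV / PLI** — instantaneous phases from the analytic signal of
  band-filtered data (5 % of samples trimmed per edge against filter
  transients); PLV = |⟨e^{iΔφ}⟩|, PLI = |⟨sign sin Δφ⟩| over time and
  epochs.  A dead zone (|sin Δφ| < 10⁻⁹ → 0) prevents float-level phase
  noise between near-identical signals from registering as a consistent
  lag.  Connectivity is computed per epoch and averaged (the alternative —
  concatenating epochs — is not used).
* **HFD** — Higuchi curve lengths L(k), k = 1..8, dimension = slope of
  ln L(k) vs ln(1/k); ≈ 1 for smooth trends, ≈ 2 for white noise.
* **DFA** — RMS fluctuation of linearly detrended profile windows over
  log-spaced scales 4..N/4; α ≈ 0.5 white noise, 1.0 pink, 1.5 random walk.

Feature tables carry one row per subject (default) or per subject × epoch,
with `measure|band|channel` descriptors that round-trip through TSV.

## Statistics

Independent two-sample t-tests, pooled-variance by default (the published
df = 38 at n = 20 + 20 implies pooled; Welch is available), also computable
from printed summary statistics.  The 2×2 chi-square of homogeneity defaults
to no continuity correction, which is what reproduces the published gender
statistic (χ² = 5.23).  Multiple comparisons across a feature family (e.g.
32 channels of one measure × band) are handled by the Benjamini–Hochberg
step-up at q = 0.05; the threshold is the largest p(i) ≤ i·q/m.  Per-channel
topographies export (channel, x, y, t, p, masked t, rejected), with masked
t exactly 0 at non-significant channels.  For pair-wise measures, a
channel's topographic value is its connectivity *strength* — the mean over
all pairs containing it.

## Feature selection

Binary wrapper selection over *biomarker blocks* (one bit per
measure × band; column-level selection optional) with three metaheuristics:
grey-wolf optimization (continuous positions in [0,1] driven toward the
three leaders, control parameter a: 2 → 0, stochastic sigmoid binarization),
a genetic algorithm (tournament 3, one-point crossover 0.9, bit mutation
0.05, elitism 1) and binary PSO (inertia 0.7, cognitive/social 1.5, velocity
clamp ±4, stochastic sigmoid transfer).  Fitness is stratified k-fold
(default 5, clamped to the minority class size) accuracy of a Gini decision
tree (default depth 40) minus an optional sparsity penalty λ·(bits set)/d;
an empty mask has defined fitness −1 so optimizers can traverse it.
Population 10 × 20 iterations by default; all three keep an elitist best, so
the reported trace never worsens.  Note the fitness itself depends on the
CV-split seed: comparisons against exhaustive search must evaluate both
under the same seed.

## Classification

Windows of 32 samples (never crossing epoch boundaries) labelled by the
source subject's group.  Families: Gini decision tree and MLP
(scikit-learn; MLP default hidden 16/8, Adam β₁ = 0.9, β₂ = 0.999,
lr = 0.001, batch 32) and the package's own NumPy networks — 1-D CNN (two
valid conv blocks, default 32/64 filters, kernel 3, max-pool, global average
pool), LSTM and bidirectional LSTM (default 256 units ×2 directions,
dropout 0.2, dense head 64/32) — trained with Adam on softmax cross-entropy,
early stopping on validation loss (patience 5, cap 50 epochs), gradients
verified against numerical differentiation.  Splits: `sample_level`
(stratified 60:20:20 over pooled windows — the protocol that *can leak*
subject identity between partitions) and `subject_level` (whole subjects per
partition; the honest protocol), plus stratified/grouped k-fold (default
k = 5).  The package deliberately demonstrates the leakage phenomenon:
with subject-specific signatures planted and *no* group effect, sample-level
splitting scores far above chance while subject-level stays at chance.

## Numerical and scale choices

Test and acceptance runs use reduced problem sizes chosen to keep the full
suite comfortably re-runnable on one CPU: 30-s resting recordings for
amplitude-effect recovery (20 replicates), 20 s for coupling recovery,
6-s recordings × 100–200 replicates for the null-FDR check, d = 8–10
feature bits for the exhaustive-search oracle, and a few hundred 3 × 32
windows with small hidden sizes for the classifier checks.  The planted
effects and group sizes (n = 20 + 20, factor 1.5) are the study conditions;
only durations, replicate counts and network widths are scaled.

## Known limitations

* The NumPy networks are desk-scale: no GPU, no convolutional striding or
  padding options, single recurrent layer per direction.
* The generator's effects are stationary and additive; no head-volume
  conduction model, so "channels" are statistically independent except for
  planted couplings and blink leakage.
* BH-FDR control is exact under independence/PRDS; the shared subject gain
  induces positive dependence between channels, which PRDS covers.
* EDF input/output is not implemented; the container formats are NumPy
  binary and TSV.
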