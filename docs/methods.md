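# Methods

`mmgforce` estimates isometric knee-extension force from multichannel
mechanomyography (MMG).  The pipeline has five stages: signal conditioning,
sliding-window feature extraction, gray relational feature selection,
cuckoo-search hyperparameter tuning, and epsilon-SVR regression.  This note
records the models, the parameter choices that matter, and the places where
the design was genuinely open.

## Signal model and synthetic protocol

The synthetic generator emulates a standard isometric protocol: a seated
subject holds one of eight force levels (10–80% of maximal voluntary
contraction, MVC) for 6 s while three accelerometers over the rectus
femoris, vastus lateralis and vastus medialis record MMG at 1 kHz alongside
a load-cell force trace.

Each MMG channel is modelled as Gaussian noise shaped by the package's own
5–100 Hz band-pass (so its spectral support matches what the conditioning
stage assumes), rescaled to an RMS of `amp(l) = 0.2 + 0.8 l` at level `l`,
plus white measurement noise of SD 0.05.  The affine amplitude law encodes
the working premise of MMG force estimation — signal amplitude grows
monotonically with motor-unit recruitment — and is the only force-dependent
property of the default generator; spectral content does not shift with
level, which is what makes the amplitude-vs-spectral feature-ranking check
meaningful.  The force trace is the nominal level plus a 0.3 Hz sinusoidal
drift and a 2 Hz-low-passed random wobble whose combined excursion is
bounded by half of `fluctuation_frac` (default 0.04), keeping every trial
inside the 5% stable-segment admission rule by construction.

What the generator does **not** emulate: motor-unit firing statistics,
force-dependent spectral compression, fatigue drift, motion artifacts,
inter-subject variability, or cross-channel correlation.  Passing tests
therefore demonstrate that the pipeline recovers force when amplitude
carries the signal, not that it would perform identically on recorded
human data.

Dataset sizing: a 6-s trial yields 6 windows under the 1000/100 windowing,
so 9 trials per level are generated and the first 50 windows per level are
kept, giving the canonical 400-window dataset (8 levels × 50).

## Signal conditioning

MMG channels pass through a fourth-order Butterworth band-pass (5–100 Hz)
and the force trace through a third-order 2 Hz low-pass.  Both are applied
forward–backward (`sosfiltfilt`): offline analysis has no causality
constraint, zero phase keeps windows and force targets aligned, and the
effective attenuation order doubles.  The stable segment is the earliest
6-s span whose filtered-force fluctuation `(max − min)/mean` is below 5%
with a positive mean.  Windows are 1000 samples with 100 samples shared
between neighbours (step 900); the per-window force target is the mean of
the filtered force over the window — the natural reduction for a stable
isometric hold.

Standardisation uses the z-score with the n−1 sample SD, fitted on training
rows only and reused on test rows; zero-variance columns are dropped with a
warning.  This scaler is hand-written because the contract (sample SD,
column dropping, strict not-fitted errors) differs from scikit-learn's
population-SD `StandardScaler`.

## Features (25 per channel)

* **Time domain (7)**: RMS, Pearson kurtosis (Gaussian → 3; the convention
  is stated because the excess convention differs by 3), sample SD,
  slope-sign changes, mean absolute value, zero crossings, waveform length.
  ZC counts strict sign changes with zero treated as positive; SSC counts
  interior samples with `(x_k − x_{k−1})(x_k − x_{k+1}) > 0`.  No noise
  deadband is applied (threshold 0, configurable in principle).
* **Frequency domain (2)**: mean power frequency (spectral centroid) and
  median frequency of a Welch spectrum (Hann window, segment
  `min(n, 512)`, 50% overlap).  The 512-sample segment is a deliberate
  compromise: at 1 kHz it gives a 1.95 Hz grid, fine enough that the median
  frequency of a pure tone lands within half a hertz of the truth, while
  still averaging two segments per 1000-sample window.
* **Time–frequency (9)**: total and per-band energies of a 3-level db4
  wavelet-packet decomposition with terminal nodes in natural frequency
  order (WP1 = 0–62.5 Hz at 1 kHz).  db4 is the common biosignal default;
  energy is the sum of squared coefficients, so WPE = ΣWPᵢ identically.
* **Nonlinear dynamics (7)**: normalized Lempel–Ziv complexity
  (median-binarized, LZ76 exhaustive parse, normalization `c·log₂n/n`),
  SampEn and ApEn with the literature defaults m = 2, r = 0.2·SD, FuzzyEn
  (baseline-removed templates, membership `exp(−d²/r)`), DistEn (m = 2,
  512 distance-histogram bins spanning `[0, d_max]`, which makes it
  scale-invariant), box-counting fractal dimension of the unit-square
  signal graph (box sizes 2⁻¹…2⁻⁶), and the largest Lyapunov exponent by
  the Rosenstein divergence-curve method (embedding dimension 5, delay at
  the first autocorrelation zero-crossing, mean-period Theiler exclusion,
  slope over the first 20 divergence steps, units 1/sample).

The entropy and complexity routines are implemented here (vectorized
template counting) and are cross-checked in the test suite against
independent brute-force direct-definition oracles to 1e-10.

## Gray relational analysis

With force F(k) and feature sequences xᵢ(k), GRA forms Δᵢ(k) = |F(k) −
xᵢ(k)|, takes the global extremes of Δ over all features and windows
jointly, and scores

    ξᵢ(k) = (Δmin + ρ Δmax) / (Δᵢ(k) + ρ Δmax),    rᵢ = mean_k ξᵢ(k)

with resolution coefficient ρ = 0.5 (valid range (0,1); discrimination is
sharpest for ρ ≤ 0.5463, and the default sits at the conventional value).
Both sides are z-scored first — absolute differences between a force in
newtons and, say, a count of zero crossings are meaningless without a
common scale.  Feature combinations A–E keep features with rᵢ ≥ 0.60,
0.75, 0.80, 0.85, 0.90 respectively (boundaries inclusive), so the
selections nest: E ⊆ D ⊆ C ⊆ B ⊆ A.  Degenerate edge case: if every
sequence equals the reference, Δmax = 0 and all coefficients are defined
as 1.  GRA is computed per dataset; nothing precludes pooling several
subjects' matrices first.

## Cuckoo search and the improved variant

Candidate (C, σ) pairs are nests.  Per iteration: (1) every nest proposes a
Lévy move `x + a0 · s · (x − x_best)` with Mantegna steps
`s = φ μ |v|^(−1/β)` (μ, v standard normal, β = 1.5, φ the Mantegna scale
with its 1/β exponent — the printed form of the scale factor omits the
exponent, without which the steps are not Lévy-stable); the proposal keeps
the nest if better.  (2) The empty-nests step rebuilds abandoned nests by a
biased random walk `x + r·(x_p1 − x_p2)` along the difference of two
shuffled nests, applied per coordinate where a uniform draw exceeds Pa and
with one shared scalar multiplier r; rebuilt nests are kept when better.
(3) The global best is retained (elitism), so best-fitness traces are
non-increasing.  Positions are clamped to the search box (reflection was
considered and rejected for simplicity).  This is the canonical
reference-implementation loop; it reproduces the published 50-run
statistics of both algorithms on all four benchmark functions, which
looser readings of the update rule (random-host comparison, per-nest
abandonment) miss by several orders of magnitude on Rosenbrock.

Plain CS fixes Pa = 0.25 and a0 = 0.01.  The improved variant (ICS) makes
two changes:

* **Tent-chaotic initialization.**  Per dimension, iterates of the tent map
  `x → 2x (x ≤ ½), 2(1−x)` are mapped affinely into the bounds.  The tent
  map's invariant density is uniform, but its orbit spreads more evenly
  than i.i.d. draws at small population sizes (the mean minimum pairwise
  distance is measurably larger).  One numerical subtlety: both tent
  branches are exact in binary floating point, so every float orbit reaches
  0 within ~53 iterations and sticks on the unstable set {0, ½, ⅔, 1}.
  When an iterate lands there the sequence is re-seeded with a fresh
  uniform draw, which preserves the uniform invariant density for long
  sequences (a fixed deterministic nudge would instead inject a biased
  doubling transient every ~50 steps).
* **Adaptive schedules.**  `a0(t) = a_min + ½(a_max − a_min)(cos(π ln(1 +
  (e−1)t/T)) + 1)` decays from 0.2 to 0.001 (natural log — required for
  the endpoint a0(T) = a_min), and `Pa(t) = Pa_min + (Pa_max − Pa_min)
  ((T−t)/T)²` decays from 0.70 to 0.10.  Early iterations explore with
  large steps and high turnover; late iterations exploit.

Benchmark functions (2-D): Rosenbrock on [−2.048, 2.048]², Griewank on
[−600, 600]², cross-in-tray on [−10, 10]² (minimum −2.06261 at
(±1.3491, ±1.3491)), Schaffer on [−10, 10]² with the denominator
coefficient 0.01 as used in the source study (the textbook variant uses
0.001; both have f(0,0) = 0).  The comparison harness runs each
algorithm 50 times with seeds `master + run index` at population 20 and
200 iterations and reports min / max / mean / sample SD.

## SVR model and evaluation protocol

The regressor is an epsilon-SVR with RBF kernel
`k(u, w) = exp(−‖u−w‖²/(2σ²))`; σ is the tuned width, mapped to
scikit-learn's convention as γ = 1/(2σ²).  Features and targets are
z-scored on the training split; predictions are mapped back to newtons.
The insensitive tube is ε = 0.01 on z-scored targets (the tube width is
rarely reported in this literature; 0.01 is small enough not to bias the
fit on standardised data and is configurable).

The tuning fitness is the 5-fold cross-validated RMSE on the training
split, folds fixed by seed — in-sample RMSE would reward the degenerate
corner of the (C, σ) box.  The search box is [0.001, 500]² for both
parameters.  The default tuning budget is 10 nests × 15 iterations, a
deliberately lighter workload than the 20 × 200 benchmark-study settings:
the CV-RMSE surface over a 2-D box is far cheaper to optimise than the
benchmark suite, and in practice the tuned loss already beats 20-draw
random search at this budget.  Both settings are plain parameters of
`ICSParams`.

The evaluation protocol mirrors the study design: 10 repetitions, each
re-shuffling the windows with its own seed (`master + repetition`),
splitting 90/10, fitting the scaler and tuner on the training side only,
and scoring RMSE (newtons), MAPE (fraction; zero targets would be excluded
with a warning, though isometric targets are strictly positive) and
Pearson R on the held-out side.  Means and n−1 SDs are reported over
repetitions.  Re-seeding both the split and the optimizer per repetition
is the conservative reading of a mean ± SD protocol.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the study's own scales
where those are cheap — 50-run batches at population 20 and 200 iterations
for the optimizer statistics, the full 400-window / 75-feature synthetic
dataset with 10 repetitions for the end-to-end recovery check — and at
reduced scales for auxiliary statistical checks (20-seed feature-ranking
tendencies use 2 trials per level and the time/frequency feature groups;
optimizer-behaviour unit tests use tiny iteration counts).  Entropy
oracles are compared on 50 signals of length 300, where the O(n²)
brute-force definition is exact and fast.

## Known limitations

* The synthetic generator is an amplitude-coding model; conclusions about
  feature rankings transfer to real MMG only insofar as amplitude dominates
  spectral cues at 1 kHz sampling.
* GRA scores linear co-movement of z-scored sequences; a feature related to
  force through a non-monotone map can be under-ranked.
* The Lyapunov estimate on stochastic band-limited signals is a descriptive
  divergence-rate statistic, not evidence of deterministic chaos.
* MAPE is undefined at zero force; the exclusion policy only matters if the
  protocol is extended to rest periods.
* Hyperparameter tuning optimises CV RMSE only; no nested CV is performed,
  so the reported per-repetition test metrics are the honest generalisation
  estimate.
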