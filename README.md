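# mmgforce

Estimation of isometric knee-extension force from multichannel
mechanomyography (MMG) — the low-frequency mechanical vibration of
contracting muscle recorded with accelerometers over the rectus femoris,
vastus lateralis and vastus medialis.  Because MMG amplitude and spectrum
track motor-unit recruitment, windowed signal features can be regressed
onto the force a subject holds; the package is aimed at researchers in
neuromuscular biomechanics and rehabilitation engineering who want a
transparent, fully seeded reference implementation of that pipeline.

The pipeline:

1. **Conditioning** — zero-phase Butterworth filters (4th-order 5–100 Hz
   band-pass for MMG, 3rd-order 2 Hz low-pass for force), selection of a
   6-s segment whose relative force fluctuation is below 5%, and sliding
   windows of 1000 samples with 100-sample overlap.
2. **Features** — 25 per channel and window (75 for three channels):
   time-domain (RMS, kurtosis, SD, SSC, MAV, ZC, WL), frequency-domain
   (MPF, MDF), 3-level db4 wavelet-packet band energies (WPE, WP1–WP8),
   and nonlinear dynamics (LZC, SampEn, ApEn, FuzzyEn, DistEn, box-counting
   FD, largest Lyapunov exponent).
3. **Selection** — gray relational analysis (GRA).  With z-scored force
   F(k) and feature sequences xᵢ(k), Δᵢ(k) = |F(k) − xᵢ(k)|,

       ξᵢ(k) = (min min Δ + ρ·max max Δ) / (Δᵢ(k) + ρ·max max Δ),
       rᵢ    = (1/n) Σₖ ξᵢ(k),        ρ = 0.5,

   and thresholding rᵢ at 0.60/0.75/0.80/0.85/0.90 defines the nested
   feature combinations A–E.
4. **Regression** — epsilon-SVR with RBF kernel
   k(u,w) = exp(−‖u−w‖²/2σ²), with (C, σ) ∈ [0.001, 500]² tuned by an
   improved cuckoo search (ICS): Lévy flights
   X_i^{t+1} = X_i^t + a0·φμ|v|^{−1/β}·(X_i^t − X_best^t) with β = 1.5,
   tent-chaotic initialization, and adaptive schedules a0(t): 0.2 → 0.001,
   Pa(t): 0.70 → 0.10 over T = 200 iterations.  Fitness is 5-fold
   cross-validated RMSE on the training split.

No human recordings ship with the package; a seeded synthetic generator
reproduces the study conditions (8 force levels at 10–80% MVC, 6-s trials
at 1 kHz, 400 windows) so every stage is testable end to end.  Externally
recorded data in the documented CSV dialect (`time_s, mmg_<muscle>...,
force_N`) can replace the generator at any stage boundary.

## Worked example

```python
from mmgforce import (SyntheticConfig, generate_dataset, feature_force_gra,
                      select_combination, evaluate_protocol)
from mmgforce.features import extract_dataset

cfg = SyntheticConfig()                      # 8 levels, 6 s at 1 kHz
recordings = generate_dataset(cfg, trials_per_level=2, seed=42)
fm = extract_dataset(recordings, groups=("time", "freq"),
                     windows_per_level=None)
gra = feature_force_gra(fm)
print(gra.ranking().head(5).to_string(index=False))

combo = select_combination(gra, "D")         # features with r >= 0.85
report = evaluate_protocol(fm, combination=combo, n_reps=10, seed=0)
print(report.summary())
```

Output:

```
feature        r
  VM_SD 0.960349
 VM_RMS 0.960289
  VL_SD 0.960236
 VL_RMS 0.960216
  RF_SD 0.960037
Repeated 90/10 evaluation
========================================
feature combination: D
repetitions:         10
train/test rows:     86/10
RMSE: 6.6112 +/- 1.2857
MAPE: 0.0508 +/- 0.0127
R:    0.9952 +/- 0.0029
```

The amplitude-carrying features (SD, RMS) dominate the GRA ranking because
the generator encodes force in MMG amplitude; combination D keeps the 12
features with relational degree at least 0.85.  Feeding them to the tuned
SVR recovers the held-out force with a correlation of 0.995 and a 5% mean
absolute percentage error; RMSE is in newtons on forces spanning 30–240 N.

The same pipeline is available from the shell, one stage per subcommand:

```sh
mmgforce simulate --out data/ --seed 1
mmgforce extract --input data/ --out features.csv
mmgforce gra --features features.csv --out ranking.csv
mmgforce estimate --features features.csv --combination D --reps 10 --seed 1
mmgforce run --out results/          # everything end to end
```

Optimizer benchmarking (population 20, 200 iterations, seeded runs):

```sh
$ mmgforce benchmark --algo both --func cross_in_tray --runs 10 --seed 0
     function algorithm   optimal     worst   average           sd  n_runs  master_seed
cross_in_tray        cs -2.062612 -2.062612 -2.062612 2.982734e-11      10            0
cross_in_tray       ics -2.062612 -2.062612 -2.062612 5.695386e-11      10            0
```

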