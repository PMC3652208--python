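# Methods

This note documents the models and procedures implemented in `ecgmmc`,
the parameter choices that matter, what the synthetic fixtures do and do
not establish, and the design decisions taken where the design was
genuinely open.

## 1. Signal model and synthetic data

Each synthetic beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
per-wave amplitude (mV), offset from the R peak (s) and width (s).  The
normal-beat defaults give physiologic scales: QRS ≈ 0.07 s, PR ≈ 0.17 s,
ST ≈ 0.22 s, R ≈ 1.5 mV, P ≈ 0.12 mV, T ≈ 0.35 mV, at 60 bpm with
optional multiplicative RR jitter.  Gaussian bumps were chosen over a
dynamical ECG model because the landmark positions are then known in
closed form, so detectors and feature extractors can be scored against
exact indices.

AAMI classes are parameter shifts of the normal template: **S** shortens
the preceding RR to 0.6×; **V** widens the QRS complex roughly 2.5×,
removes the P wave, and arrives early (RR 0.75×); **F** is an intermediate
QRS widening; **Q** perturbs amplitudes.  These shifts make the nine
features discriminative by construction.

Noise is additive: deterministic zero-phase sinusoids for baseline wander
(default 0.3 Hz, the respiration band) and powerline interference, plus
seeded white Gaussian noise for the EMG band.  Zero phase keeps the
sinusoidal components exactly additive across composed specs, which the
property tests assert at tolerance 0.

Labeled cluster fixtures are isotropic unit-variance Gaussian blobs whose
centroids form a regular simplex with pairwise distance `separation`
(hence "separation" is in units of the within-cluster s.d.), with sizes as
equal as possible.

**What passing tests on these fixtures shows — and does not.**  They
establish algorithmic correctness: the detectors recover landmarks the
generator planted, and the clustering recovers partitions that exist by
construction.  They do not establish clinical performance: real ECG has
non-Gaussian wave shapes, inter-patient morphology drift, non-stationary
noise, and class overlap far beyond the parameter shifts emulated here.

## 2. The wavelet/LMS adaptive filter

The filter has four steps: (i) choose the least dyadic depth `i` whose
approximation band `[0, fs/2^(i+1)]` is at or below `f_high` (default
50 Hz) — this drops EMG/powerline noise while keeping QRS energy; (ii)
reconstruct the depth-`i` approximation **E1** (details zeroed, not
thresholded — the intent is removal, not shrinkage) as the primary input;
(iii) decompose E1 a further `j` levels, the least depth with
`fs/2^(i+j+1) <= f_low`, and reconstruct the approximation **E2** as the
drift reference; (iv) cancel E2 from E1 with a normalized LMS filter,
whose error output is the cleaned ECG.

**The reference band bound `f_low` (default 0.7 Hz).**  This is the one
parameter that decides whether the filter helps or hurts.  Because E2 is
derived from the record itself, the adaptive stage converges to
subtracting *everything* in the reference band, signal included.  If the
reference band extends to several hertz it contains the T and P waves and
the beat-rate harmonics of the R comb — most of the ECG's own power — and
the "denoised" output is badly distorted (measured on the fixtures:
correlation with the clean signal *drops* from 0.53 to 0.34 when the
reference edge sits at 5.6 Hz).  Baseline wander and respiration-band
motion artifact are physically sub-1 Hz phenomena, so the default bounds
the reference at 0.7 Hz (band edge 0.35 Hz at 360 Hz sampling), which
removes the drift while leaving beat harmonics untouched: correlation
rises from 0.53 to 0.91 on the same fixtures.  `f_low` remains
configurable for aggressive drift removal at known fidelity cost.

**LMS step size and order.**  The update is power-normalized
(`w += mu * e * r / (eps + ||r||^2)`), stable for `0 < mu < 2` regardless
of reference amplitude; defaults `mu = 0.01`, `order = 8`.  Two effects
bound performance.  First, adaptation itself distorts a *clean* record
(the filter slowly tracks whatever low-frequency signal leaks into E2):
with defaults the clean-input correlation is ≈ 0.96, approaching 0.99 only
as `mu → 5e-4`.  Second, steady-state cancellation depth is limited by
gradient noise — the ECG itself perturbs the weights at every update — so
deep (> 20 dB) cancellation of a sinusoidal interferer requires a small
step and a long record; the harness demonstrates 22.6 dB with `mu = 5e-4`,
order 8, on a 120 s record.  Wavelet family: `db4` (compact support
matching QRS sharpness), symmetric extension to avoid edge spikes.

## 3. Waveform delineation

R peaks are detected on the rectified first difference — the R upstroke
has the steepest slope of the cycle — smoothed by a 25 ms moving average.
The smoothing is essential on noisy records: isolated broadband-noise
samples create single-sample difference spikes that the bare rule accepts;
averaging over ~9 samples suppresses them while the sustained QRS slope
survives.  The lower limit is adaptive: 0.4× the running mean of the last
8 accepted peak heights (bootstrapped from the first two seconds).  A
200 ms refractory period after each acceptance rejects tall-T candidates,
and any RR gap exceeding 1.66× the median RR is re-scanned at half the
threshold (escaped-beat search-back).  Accepted candidates snap to the raw
signal's local maximum within ±60 ms.

Q and S are "turning points" within 0.1 s of R, found by walking outward
from R until the signal stops falling (derivative sign change) or the
slope flattens below 10 % of the steepest descent seen — this
operationalizes "the point connecting falling edge and baseline" without
needing a baseline estimator.  P is the voltage maximum within 0.16 s
before Q; T the maximum between S and the next beat's P (0.4 s fallback
window for the final beat, flagged).  An absent morphology (the P of a
ventricular beat) still yields an argmax, flagged low-confidence when its
amplitude over the local median is < 0.05 mV.  Delineation never raises on
degenerate geometry; beats with truncated windows or disordered landmarks
are flagged invalid and dropped downstream.

## 4. Features

Nine time-domain quantities per beat, spanning two cardiac cycles:
preceding and following RR intervals, QRS (Q-to-S), PR (P-to-R), QT, ST,
and the R/P/T amplitudes.  All intervals are seconds, amplitudes mV —
"normalized" here means conversion to physical units, which matches the
magnitudes of published beat tables (RR ≈ 0.85 s, R ≈ 1.8 mV).  Two
definitions were open: **QT** is measured Q-peak to T-peak (T-wave *end*
is never delineated, and this choice is consistent with ST = T-peak − S);
the **baseline** for amplitudes is the median of the PR-segment samples
between P and Q of the same beat.  Rows with missing landmarks or
non-positive intervals are dropped with a warning, so retained rows always
satisfy positivity and QRS < RR.  An optional z-score step (population
s.d.; constant columns map to zeros, never NaN) prepares the matrix for
kernel clustering.

## 5. Maximum-margin clustering by immune search

### Inner problem

For fixed labels the square-loss SVM

    min 1/2 ||w||^2 + C/2 sum eta_i^2   s.t.  y_i (w.phi(x_i) + b) = 1 - eta_i

is the least-squares SVM.  The slack is per-sample (a single shared slack
would make the KKT system degenerate), and the solution comes from one
symmetric (n+1)×(n+1) linear solve; a 1e-10 ridge is added on singularity
(duplicate points).  `J >= 0` is clipped at tiny negative rounding, and
the affinity `F = exp(-J)` may underflow to 0 for poor labelings, so all
comparisons inside the search rank by `J`, never by `F`.

### Kernels

The canonical kernel is the exponential form `exp(-||x-x'|| / sigma^2)`
with the *unsquared* Euclidean norm; the conventional Gaussian
`exp(-||x-x'||^2 / sigma^2)` and the linear kernel are selectable.  The
default bandwidth is the median pairwise distance.  With that default the
exponential kernel is deliberately "flat" (entries compressed toward 1);
empirically this smooths the search landscape — the 2-blob recovery tests
pass 20/20 with it, while a sharper bandwidth destabilizes the search.

### Bias/label refinement

With `w` fixed, minimizing `sum (s_i + b - y_i)^2` over balanced labelings
and `b` has closed structure: for any `b` the optimal balanced labeling is
a *threshold* labeling in sorted-score order (flipping costs are monotone
in `s`), and for a threshold labeling the optimal bias is
`b = mean(y - s)`.  The implementation therefore enumerates the midpoint
splits of the sorted scores, keeps those whose split position satisfies
`|sum y| <= l` (rounded outward on parity conflicts, e.g. odd n with
l = 0), evaluates each with its closed-form bias, and returns the best —
attaining the exact constrained optimum, which the tests verify against
exhaustive enumeration over all sign vectors.  Evaluating the midpoint
bias itself, as a literal reading of the procedure suggests, is generally
suboptimal; the split-enumeration view is the form that makes the scan
exact.  Sign ties map to +1.

### The immune loop

One antibody = one balanced labeling.  Per generation: evaluate all
(each evaluation runs the KKT solve, then iterates the Lamarckian
refinement — re-threshold, re-solve — while `J` strictly decreases, up to
10 rounds, caching the result so re-evaluation is a no-op); clone the
`N_c = 5` best of the remainder with rank-proportional copy counts; mutate
clones and the next-best pool members by flipping opposite-signed label
*pairs* (conserving `sum y` exactly), 1 pair for the best rank up to
`f_max = max(2, n/10)` for the worst, keeping mutants only when affinity
improves; reselect the best `N_m = 5` into the elite memory set
(deduplicated under global sign, which `J` is invariant to); receptor-edit
the worst 20 % of the remainder with fresh random balanced antibodies; and
refill to the population size of 20.  Initial antibodies are pairwise
more than `t_s = n/10` Hamming apart under canonical sign.  Termination:
50 generations or 10 without best-`J` improvement.  Elitism makes the
best-fitness history non-decreasing, which is asserted per run.  All
randomness flows from one master seed through named substreams
(initialization, mutation, editing), so runs are bit-reproducible.

Two initialization schemes exist: pure random (the default — the search
recovers 6-s.d.-separated blobs from random starts in ≥19/20 seeded runs),
and `init="kmeans"`, which adds a single centroid-seeded antibody
(balance-repaired by flipping boundary samples) to an otherwise random
population.

### Restarts and C

The search is stochastic; following the method's own evaluation protocol,
the pipeline's clustering stage repeats the binary search three times with
distinct sub-seeds and keeps the lowest objective, and the CLI can scan
the regularization candidates C ∈ {1, 10, 100, 500} (default C = 10).

### Multiclass

The native problem is binary; k clusters are produced by recursively
bipartitioning the currently largest cluster.  Intermediate splits relax
the balance bound to 0.6× the subset size (each side still ≥ 20 %),
because a subset holding m > 2 of the final clusters must be divided
1:(m−1), which the tight symmetric bound forbids.  With the
centroid-seeded initialization, five well-separated blobs (n = 250,
separation 8) are recovered exactly (ARI 1.0).  **Limitation:** with pure
random initialization the recursive splits strand a few points per peel at
subset sizes ≳150 (ARI ≈ 0.8–0.9 on the same fixture); the seeded variant
is recommended for k > 2.

## 6. Evaluation

Cluster ids are matched to classes by the agreement-maximizing permutation
(exhaustive, k ≤ 8; Hungarian assignment for rectangular cases).  Metrics
follow the standard one-vs-rest pooling of the matched confusion matrix —
sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy (TP+TN)/n, in
percent — and the pooled sensitivity is 100 × trace/total.  An empty class
yields "undefined", never NaN.  Three reference tables from a published
1,682-beat MIT-BIH IEMMC evaluation are packaged verbatim as fixtures for
the metric arithmetic (including an internal V/F row-total swap between
two of the original tables, preserved as printed); the packaged per-class
performance figures are not recomputable from the packaged confusion
matrix under any consistent reading — only the pooled sensitivity
(90.3 %) ties the two together, and only that pooled figure is used as a
numeric anchor.

## 7. Problem sizes

The shipped tests and the acceptance script use: 10–20 s records at
360 Hz for detection (20 seeds), a 120 s record for steady-state LMS
cancellation, n = 60 blob problems (20 seeds) and one n = 250 multiclass
problem for clustering, n ≤ 10 exhaustive enumerations for the oracles,
and a ~120-beat noisy two-class record end-to-end.  These sizes keep the
full suite under half a minute while leaving every statistical margin
(e.g. ≥19/20, ≥99 % detection) non-trivial.

## 8. Known limitations

* The filter's adaptive stage inevitably trades some clean-signal
  fidelity (correlation ≈ 0.96 at defaults) for drift removal; it is not
  an identity on noise-free input.
* Delineation assumes upright R peaks and single-lead morphology; no
  onset/offset (QRS onset, T end) delineation, no template refinement.
* The class-balance constraint caps attainable accuracy when true classes
  are more imbalanced than the bound (e.g. a 2:1 record under l = 0.2 n
  cannot exceed ~93 % pooled sensitivity); this is a property of the
  objective, not of the optimizer.
* Immune-search hyperparameters (population 20, N_c = N_m = 5, edit
  fraction 0.2, t_s = n/10, 50 generations, stall 10) are pragmatic
  defaults; no tuning service is provided.
* Multiclass clustering is a recursive-bipartition heuristic, not a joint
  k-way margin objective.
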