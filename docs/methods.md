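# Methods

`miconn` re-implements, as a tested pipeline over synthetic data with known
ground truth, the analysis chain of a three-condition motor-imagery (MI) EEG
study: event-related desynchronisation (ERD), sub-band CSP + LDA left/right
classification, and transfer-entropy (TE) effective connectivity contrasted
between conditions. The original recordings are not available, so every
stage is exercised on a generator that plants the effects the analyses are
meant to recover; what the tests demonstrate is therefore *recovery of known
truths through the full chain*, not reproduction of the original cohort's
numbers.

## Synthetic sessions

A session follows the paradigm: trials of fixation (−2–0 s), motor imagery
(0–10 s) and rest (10–13 s); three conditions (tMI, rmMI, bcMI) × two hands
× 20 trials per hand = 120 trials, generated at 1000 Hz on a nine-channel
frontal/central/parietal montage (F3, Fz, F4, C3, Cz, C4, P3, Pz, P4).

Per trial and channel the signal is a sum of:

* **Background**: unit-variance white Gaussian noise plus a weak 1/f
  component (weight 0.5), scaled by `noise_sd` (default 1.0). This gives an
  EEG-like spectrum without modelling artifacts — eye/EMG artifacts and the
  manual ICA step used on real data are deliberately out of scope, and a
  hook for artifact removal is simply not needed on clean synthetic data.
* **Alpha rhythm**: narrowband-filtered noise (8–13 Hz, unit RMS, amplitude
  `alpha_amp` = 1.0) on the motor channels C3/C4. Narrowband noise rather
  than a pure sinusoid gives the oscillation a realistic nonzero bandwidth
  and a fluctuating envelope. During the MI stage only, the amplitude on the
  hand-contralateral channel is multiplied by `erd_depth` (default 0.5) —
  the planted ERD. Since power scales as amplitude squared, the planted ERD
  in percent is 100·(erd_depth² − 1) = −75% at the default.
* **Directed couplings**: for each configured edge active in the trial's
  condition, the sink channel receives the source channel's band-limited
  signal delayed by `lag` samples and scaled by `strength`, restricted to
  the MI stage. Band-limiting the source to the coupling's band makes the
  plant visible to per-band connectivity analysis; the default lag of 4
  native samples equals one sample at the 250 Hz analysis rate, matching
  the estimator's prediction horizon u = 1.

With `noise_sd` = 1 and `alpha_amp` = 1, the broadband noise contributes
only ≈ 4% of the alpha-band power, so the measured ERD is biased by only a
few points toward zero — small against the ±10-point recovery tolerance.
The noise level was chosen so that contralateral-vs-ipsilateral
lateralisation is reliably detectable in a 14-subject cohort, which is the
regime the analyses operate in; it is not calibrated to any real subject's
SNR, which the source study does not report.

A single session seed spawns per-trial substreams through
`numpy.random.SeedSequence`, so sessions are reproducible while trials stay
independent. The same mechanism derives per-subject and per-stage seeds from
an experiment's master seed.

What the generator does **not** emulate: volume conduction and realistic
topographies (channels are independent up to the planted couplings),
artifacts, non-stationary band power apart from the planted modulation, and
per-subject variability in responsive frequency bands. Passing tests show
the chain recovers what was planted at realistic SNR; they say nothing about
head-model effects or artifact robustness on real recordings.

## Preprocessing

Continuous recordings are band-passed 0.5–50 Hz with a zero-phase FIR
filter, decimated 1000 → 250 Hz, and cut into epochs of −2 to +13 s around
each MI onset, grouped by condition × hand — filter, then downsample, then
epoch, in that order.

The FIR is a Hamming-windowed sinc; the transition width is
min(2 Hz, 0.25·lo), giving ≈ 53 dB stopband attenuation and < 0.1 dB
passband ripple. Tap count is capped at one third of the signal length so
short segments remain filterable (this soft-caps the 0.5 Hz edge on short
recordings). The kernel is applied in a single centred pass with reflect
padding of one kernel length, so group delay is exactly zero and epoch
boundaries see no transient. Decimation uses a standard anti-alias FIR
(zero-phase); event indices are rescaled rounding toward zero.

Two beta definitions coexist on purpose: 13–30 Hz for classification
features and 14–30 Hz for TE connectivity, mirroring the analysis each band
set feeds.

## ERD/ERS

ERD% = 100·(A − R)/R with R the mean band power over the −2–0 s fixation
baseline and A the power after MI onset. The time course is computed in the
classic four steps — band-pass each trial, square, average across trials,
smooth over time — with a 0.25 s moving average: longer than one alpha
cycle, shorter than the ERD dynamics. Summaries average the time course
over 0–5 s of the MI stage (configurable; the full 0–10 s window is a
config change away). Group lateralisation uses the paired two-sided
Wilcoxon signed-rank test on per-subject contralateral vs ipsilateral
summaries.

## CSP + LDA classification

Per-class covariances are averages of trace-normalised per-trial
covariances (trace normalisation guards against amplitude drift between
trials). The filters solve R1·e = λ·R2·e with the normalisation
EᵀR2E = I, EᵀR1E = D, eigenvalues sorted descending; rank-deficient
pooled covariance raises with a pointer to the optional ridge flag.
Features are the normalised log-variances of trials projected on the first
and last m filters — the standard CSP feature map, which the source
analysis leaves unstated and is recorded here as an assumption. Sub-band
CSP concatenates features over the alpha and beta bands.

Classification is Fisher LDA; with balanced classes the boundary sits at
the midpoint of projected class means. Evaluation is stratified k-fold
cross-validation (k = 10) repeated with fresh shuffles, CSP and LDA
refitted inside each training fold — the only reading of "repeated 10-fold"
that is free of information leakage. The m sweep (1–8 where the montage
allows; 2m ≤ channels) picks the highest mean accuracy, ties toward
smaller m. Classification uses the 0–10 s MI window of each epoch.

## Transfer entropy

TE(Y→X) is the four-term joint-entropy combination over delay-embedded
states,

    TE(Y→X) = H(Xp, Yp) − H(Xf, Xp, Yp) + H(Xf, Xp) − H(Xp),

with Xp the sink's d-dimensional embedding (delay τ), Yp the source's
m-dimensional embedding, and Xf the sink u samples ahead. The joint
entropies are estimated with shared-radius Kraskov k-nearest-neighbour
estimates (max-norm, K = 4, u = 1, Theiler window 1 — the estimator's
operative settings): the Kth-neighbour distance in the full joint space
sets each point's radius, neighbours are counted within that radius in the
three marginal spaces, and the combination collapses to the digamma form
ψ(K) − ⟨ψ(n_{xf,xp}+1) + ψ(n_{xp,yp}+1) − ψ(n_{xp}+1)⟩. The shared radius
cancels the dominant bias term, which four independent entropy estimates
would retain; on the linear-Gaussian reference (below) this lands within a
few percent of the closed form at n = 5000. All values are in nats.
Dimensions are standardised before the neighbour search, so estimates are
invariant to affine rescaling of either series. The Theiler window excludes
temporally adjacent points (|Δt| ≤ 1, within the same trial) from every
search.

Embedding selection: τ from the first 1/e decay of the autocorrelation
(bounded to [1, 20]), d from Cao's E1 saturation with an E2 stochasticity
screen — E1(d) ≥ 0.92 marks deterministic saturation, and the largest d
with |E2(d) − 1| ≥ 0.18 bounds how much history carries predictive
information for stochastic series; the smaller of the two is used. The
median (not mean) over neighbour-distance ratios guards E(d) against
near-zero denominators in low dimensions. Both thresholds were calibrated
on reference signals with known answers (white noise → 1, noiseless cycle
→ 2, lag-1 autoregression ≤ 2). The two selection roles (a dimension
criterion and a delay criterion) are deliberately assigned this way — Cao's
method estimates dimension, not delay — and both are overridable through
`EmbeddingParams`. The source embedding dimension defaults to the sink's d;
the source keeps its own selected τ.

Trial handling: embedded points are pooled across trials within a window
before the neighbour search (points from different trials are never
Theiler-excluded). A 2 s fixation baseline alone (500 samples at 250 Hz) is
too short for stable k-NN estimation; pooling 20 trials gives ~10⁴
candidate points. Long ensembles are subsampled by within-trial striding to
`max_points` (2000 by default). Relative TE is the MI-window matrix minus
the fixation-window matrix, element-wise; negative values are kept — the
baseline subtraction legitimately admits them.

The linear-Gaussian reference pair (X white Gaussian,
Y_t = c·X_{t−lag} + ε) has the closed-form TE(X→Y) = ½·ln(1 + c²/σ²) and
exactly zero reverse TE; it anchors the estimator tests, and the closed
form itself is cross-checked in-suite against the Gaussian mutual
information computed from the realised lagged correlation.

## Group statistics

Per directed pair, per-subject relative-TE values of two conditions meet in
a paired two-sided Wilcoxon signed-rank test: exact null distribution for
n ≤ 25 via dynamic programming over sign assignments (equivalent to
enumerating all 2ⁿ patterns; ties mid-ranked, zero differences dropped and
counted), continuity- and tie-corrected normal approximation above. The
test is implemented in-package because the exact-with-mid-ranked-ties
contract is not available from the standard libraries; scipy's exact mode
(tie-free inputs) and a brute-force enumeration serve as independent
cross-checks in the suite. All tests are two-sided; reported effect
directions come from the sign of the median difference after the two-sided
retention decision.

FDR control is Benjamini–Hochberg step-up (delegated to statsmodels,
verified against the literal step-up definition), applied over the family
of 72 directed pairs within one band × hand × contrast — matching a
per-panel presentation; whether the original analysis pooled families
across bands or hands is not stated, and per-panel is recorded in the
output metadata. An edge is retained when adjusted p < 0.05.

## Down-scaled study sizes

The full paradigm (14 subjects × 120 trials × 15 s × 1000 Hz, TE over 72
pairs × 3 bands × 2 hands × 2 windows) is larger than any verification
needs, so the verification studies run a reduced protocol chosen once:

* end-to-end recovery: 14 subjects, 2 conditions, one hand, one band
  (beta 14–30 Hz), 4 trials per condition, 2 s MI stage, TE on ≤ 400 pooled
  points with fixed embedding d = 1, τ = 1. A pilot on the generator showed
  that for the planted lag-1 couplings the first-order sink embedding
  maximises the per-subject contrast effect (narrowband signals make deeper
  sink histories absorb most of the source information) while halving cost;
  this is the scaled protocol's fixed setting, with per-channel selection
  remaining the default elsewhere.
* estimator checks: n = 5000 samples, 20 seeds (null and oracle level),
  100 seeds for direction recovery;
* ERD recovery: 100 trials, two channels.

Planted couplings in the recovery study use strength 1.0, which puts the
in-band source contribution at roughly the sink's own band power — a strong
but not degenerate coupling.

## Known limitations

* The generator's channels are statistically independent apart from planted
  couplings; real EEG's volume conduction produces instantaneous mixing
  that TE analyses must confront and this pipeline does not model.
* Cao-style dimension selection on stochastic narrowband signals is
  heuristic; the thresholds are calibrated on clean references, and the
  per-channel selections should be treated as defaults, not truth.
* A planted coupling source→sink also raises the *reverse* pair's relative
  TE (the sink's signal carries the source's past — shared information, not
  a planted flow), so contrast replicates can retain reverse edges alongside
  the planted ones. Recovery metrics count only the planted direction.
* The exact Wilcoxon assumes exchangeable signs under the null; heavy
  discreteness (many equal |differences|) is handled by mid-ranks but the
  test remains conservative there.
* EDF export is not provided (no writer in the supported dependency set);
  sessions serialise as delimited matrix + JSON sidecar, and EDF reading is
  available through the optional MNE dependency.
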