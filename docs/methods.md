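# Methods

This package implements a complete, self-contained analysis chain for
time-resolved EEG decoding of feature-based attention in rapid serial
designs, together with a synthetic-data generator that provides a known
ground truth for every downstream stage.  This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
results do and do not show.

## Experimental design model

A session consists of 64 sequences of briefly flashed stimuli.  Every
stimulus is a pair of overlaid oriented line patches in two colours (blue,
orange); one colour is cued for the whole sequence and the observer responds
when the cued colour shows the sequence's target orientation (0° or 90°).
The analysable stimuli use orientations {22.5°, 67.5°, 112.5°, 157.5°} with
the two colours always 45° apart, giving 8 combinations.  This makes the two
colours' orientations mutually uninformative once decoding is run within an
orientation pair (the "analysis groups" 22.5/112.5 and 67.5/157.5): for each
decoded orientation, both orientations of the other colour occur equally
often.

Each sequence contains exactly 104 non-target presentations, counterbalanced
over ISI × stimulus type: in the varied-ISI condition the 13 × 8 table of
(ISI, combination) cells is filled exactly once; in the constant-ISI
condition each combination occurs 13 times at 200 ms.  ISIs live on the
60 Hz display frame grid and are stored internally as integer frame counts
(6–18 frames ≙ 100–300 ms) so the counterbalanced values never accumulate
floating-point error.  Stimulus duration is fixed at 100 ms (6 frames), so
stimulus-onset asynchrony is 300 ms (constant) or 200–400 ms (varied).

On top of the non-targets, each sequence carries 1–2 target events (target
orientation in the cued colour) and 1–2 foil events (target orientation in
the uncued colour), plus padding: 4 presentations at each sequence boundary,
3 before and 4 after every event.  Padding stimuli are drawn without
replacement from the 8 combinations *within each contiguous padding block*
(each block has at most 4 items; drawing without replacement across all of a
sequence's padding would require more than 8 draws, so the per-block reading
is the only feasible one).  Event blocks are placed uniformly at random in
distinct gaps between non-targets, so they can neither merge nor touch the
boundary padding.  Only the 104 non-targets are flagged analysable.

The 32 design cells (cued colour × target orientation × ISI condition ×
event-count combination) each occur exactly twice per 64-sequence session.
Reduced sessions (used for simulation studies) take a prefix of a cell
ordering in which the ISI condition alternates fastest, so the
constant/varied split stays even at any even size.

## Synthetic EEG forward model

The scientific scenario the simulator encodes is simple: attended and ignored
orientations are coded identically early on, and their coding diverges at a
configurable latency.  Each presentation evokes, in every channel,

    A · [ g_att(dt) · k(dt) · p_cued  +  g_unatt(dt) · k(dt) · p_uncued ]

where `dt` is time since that presentation's onset, `k` is a raised-cosine
amplitude kernel supported on [80, 400) ms and peaking at 170 ms, `p_cued`
and `p_uncued` are unit-norm orientation-selective channel patterns
(orthogonalised random vectors, fresh per participant), and the gains are 1
for `dt < τ` (default τ = 230 ms) and (g_att, g_unatt) = (1.0, 0.4)
afterwards.  The gain divergence is a step, not a ramp: it is the simplest
mechanism that produces a well-defined onset to recover.  Responses of
successive presentations add linearly, which is exactly the overlap regime
of a 200–400 ms SOA design; epochs therefore share samples with their
neighbours by construction.  Target/foil orientations (0/45/90/135°) project
onto separate unit patterns; they are excluded from analysis, so only their
overlap into neighbouring epochs matters.

Noise is an AR(1) process over time (φ = 0.95, innovation SD σ = 1 µV)
with spatial covariance from a rank-8 random factor model plus a diagonal,
normalised to unit mean diagonal; stationary per-channel SD is
σ/√(1−φ²) ≈ 3.2 µV.  Temporal correlation is the reason
leave-one-sequence-out cross-validation matters: epochs within a sequence
share noise, and any fold scheme that splits a sequence would leak.

Defaults were chosen once: peak evoked amplitude A = 2.5 µV (between-
participant SD 0.5 µV, truncated at 0) puts single-participant peak decoding
near 70%, the middle of the range typical for published EEG orientation
decoding.  All parameters are overridable per run.

What the simulator does **not** emulate: realistic head geometry or channel
adjacency, eye/muscle artefacts, electrode drift, 1/f spectral shape beyond
AR(1), ISI-dependent neural effects (so temporal-expectation contrasts are
true nulls by construction), and any relationship between the stimulus
orientations' angular distance and pattern similarity (patterns are
orthogonal, not tuning-curve-like).  Passing tests therefore validate the
*analysis machinery* — counterbalancing, leakage-free cross-validation,
calibrated chance level, correctly localised onsets — not claims about real
EEG.

## Preprocessing

Filter → average reference → downsample → epoch, in that order.  The filter
is a zero-phase Hamming-window FIR band-pass (0.1–100 Hz) designed with the
transition-bandwidth conventions of established EEG software
(min(max(f·0.25, 2 Hz), f)); at 0.1 Hz this gives a ~33 s kernel, so each
simulated sequence carries a 0.5 s lead-in and 0.9 s tail and the slow-drift
edge distortion is spread over the sequence.  Decimation to 250 Hz applies a
101-tap zero-phase FIR at 80% of the new Nyquist before taking every 4th
sample (>40 dB stopband at 140 Hz).  Epochs span −100 to 800 ms (226 samples
at 4 ms).  No baseline correction is applied: at these SOAs the pre-stimulus
window contains the previous stimulus' response, and subtracting it would
inject structured signal into the epoch.

## Decoding

Per timepoint, features are the channel vector at that timepoint.  The
classifier is a regularised linear discriminant: pooled within-class
covariance S, shrunk as S + λ·mean(diag(S))·I with λ = 0.01, discriminant
w = S_r⁻¹(µ₁−µ₀), threshold at the midpoint of the projected means (equal
priors).  Cross-validation leaves one sequence out; accuracy is pooled over
folds (total correct / total tested — identical to the mean of fold means
when folds are balanced, which they are here).  Decoding runs within an
analysis group, and the two groups' curves are averaged, keeping chance at
50%.  Each physical epoch contributes one trial to the cued task and one to
the uncued task; the tasks are evaluated independently, so no leakage
arises.  The production path computes all folds and timepoints from pooled
per-class sums and second moments with the held-out sequence subtracted;
the tests assert bit-level equality with the naive per-fold, per-timepoint
closed-form LDA.

Derived contrasts per participant: attention = cued − uncued (per ISI
filter), expectation = constant − varied averaged over the cued and uncued
conditions, interaction = attention(varied) − attention(constant).

## Group inference

At each timepoint a one-sample t statistic over participants (against 50%
for accuracies, 0 for paired differences) is converted to an interval-null
Bayes factor: the alternative prior is Cauchy(0, r = 0.707) on the
standardised effect size, truncated to δ ≥ 0.5 for directional contrasts
(half-Cauchy) or |δ| ≥ 0.5 for the interaction (no predicted direction), and
renormalised; the null is the point δ = 0.  BF10 is the ratio of the
noncentral-t marginal likelihood under this prior to the central-t density.
The integral uses adaptive quadrature after the substitution
δ = a + u/(1−u) mapping [a, ∞) to (0, 1), with relative tolerance 1e-10;
the tests check agreement with an independent fine-grid trapezoidal
integration to better than 1e-6 relative error.  Raw accuracies (and their
paired differences) enter the t statistic directly; no transform is applied.
Zero-variance samples are an error, not a silent NaN.

Evidence categories use the conventional 1/10, 1/3, 3, 10 thresholds.  The
onset of an effect is the *second* of the first pair of consecutive
post-stimulus timepoints with BF10 > 10, so an isolated suprathreshold
timepoint never counts.  Uncertainty bands are percentile bootstrap CIs over
participants (default 10,000 resamples, seeded); percentile bootstrap
slightly undercovers at n ≈ 20–30, which the coverage test acknowledges by
accepting 90–98.5% empirical coverage at the 95% nominal level.

## Problem sizes and reproducibility

Simulation studies are desk-scaled: the chance-level calibration pools
three replicate groups of 10 signal-free participants × 8 sequences × 32
channels (grand mean pair-averaged accuracy within 2 Monte-Carlo SEs of
50%, the SE estimated across the 30 participants); the parameter-recovery
study uses 20
participants × 16 sequences × 32 channels for the effect run (onset required
within τ ± 40 ms, and BF10 < 3 everywhere in 0 ≤ t ≤ τ − 40 ms — the same
±40 ms allowance, since zero-phase filtering smears the gain step by a few
milliseconds) and ten equal-gain replicate groups of 10 participants × 6
sequences, of which at least 9 must yield no detected onset.  Every
stochastic stage derives its seed from a master seed and the stage name via
SHA-256, so runs are bit-reproducible and independent of parallelism.

## Known limitations

- The sustained-pair onset rule does not control the family-wise false
  detection rate across an epoch.  The directional interval-null BF crosses
  10 already at t ≈ 2.9 for 10–20 participants, so each null timepoint
  exceeds the onset threshold with probability ~0.5–0.9%; over the ~200
  post-stimulus timepoints of an epoch, a moderately autocorrelated null
  accuracy-difference timecourse produces a false "second consecutive
  suprathreshold" onset in roughly a quarter to a third of simulated null
  groups (the equal-gain replicate study in the test suite measures this
  directly: 3 of 10 null groups showed a false onset).  Isolated
  suprathreshold timepoints under a true null are expected behaviour of
  this inference procedure, not a simulator artefact; onset claims from a
  single group should therefore be read together with the surrounding BF
  timecourse.
- The evoked kernel and gain step are phenomenological; onsets recovered on
  synthetic data validate the detection machinery, not physiological
  latencies (with this kernel, above-chance decoding emerges ~110 ms, later
  than the kernel onset at 80 ms, because the rise is slow relative to the
  noise level).
- The interval-null BF is computed as a single truncated-prior integral
  ratio; the equivalent two-interval posterior-odds formulation is not
  implemented separately (the oracle test covers the equivalence
  numerically).
- Per-sequence recordings are filtered independently, mirroring the
  generator's per-sequence structure rather than a single continuous
  recording session.
- `n_sequences` below 64 preserves the constant/varied balance but not the
  full 32-cell counterbalance (cells are truncated in a fixed balanced
  order); only the full session realises the exact two-per-cell design.
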