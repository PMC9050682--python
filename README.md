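# attndecode

**Time-resolved EEG decoding of feature-based attention in rapid serial
designs — with a synthetic ground truth.**

When two stimuli occupy the same place at the same time and only one of them
is task-relevant, when does the brain start to prioritise the relevant one?
Time-resolved multivariate decoding of EEG can answer this: decode the
attended and the ignored stimulus feature separately at every timepoint and
ask when the two accuracy timecourses diverge.  Doing that credibly requires
a carefully counterbalanced design (so the ignored feature is never
informative about the attended one), leakage-free cross-validation under
temporally correlated noise, and group-level inference that can quantify
evidence *for* a null as well as against it.

`attndecode` packages that entire chain for rapid serial designs with
overlaid oriented stimuli, and — because the interesting claims are about
*onsets* — ships a synthetic-data generator with a known divergence latency
so the whole pipeline can be validated by parameter recovery.  It is aimed
at cognitive-neuroscience researchers building or stress-testing decoding
pipelines, and at anyone who wants a worked, tested reference implementation
of interval-null Bayes-factor timecourse inference.

## What is implemented

- **design** — counterbalanced sessions: 64 sequences × 104 analysable
  presentations, 8 orientation combinations (two colours always 45° apart),
  constant (200 ms) vs varied (100–300 ms, 13 steps on the 60 Hz frame
  grid) ISIs, target/foil events wrapped in padding, BIDS-style events TSVs.
- **synth** — linear pattern-superposition forward model: per-presentation
  evoked kernel on [80, 400) ms, attended/unattended gains equal before a
  divergence latency τ (default 230 ms) and diverging after, AR(1) noise
  with factor-model spatial covariance, between-participant variability.
- **preprocess** — zero-phase Hamming FIR band-pass (0.1–100 Hz), average
  reference, anti-aliased decimation to 250 Hz, epochs −100..800 ms.
- **decode** — per-timepoint regularised LDA
  (S + λ·mean(diag S)·I, λ = 0.01), leave-one-sequence-out CV, orthogonal
  orientation pairs ("analysis groups") averaged so chance stays at 50%.
- **bayes** — per-timepoint one-sample t → interval-null Cauchy-prior
  Bayes factors (r = 0.707, effect sizes |δ| < 0.5 excluded; directional
  half-Cauchy except for the interaction contrast), percentile bootstrap
  CIs, and onset detection (second consecutive timepoint with BF10 > 10).
- **pipeline / CLI** — `attn-decode run` orchestrates everything
  deterministically from a master seed; numeric tables are the canonical
  outputs.

The statistical core at each timepoint is

    BF10 = ∫ f_nct(t; ν, δ√n) π(δ) dδ / f_t(t; ν),
    π(δ) ∝ Cauchy(δ; 0, 0.707) · 1[δ ≥ 0.5]   (directional)

with `t` the group t statistic over `n` participants (ν = n−1), computed by
adaptive quadrature and verified against brute-force integration.

## Worked example

```python
import pandas as pd
from attndecode import simulate_participants, run_all_conditions
from attndecode.preprocess import preprocess_participant
from attndecode.bayes import bf_timecourse, onset_time

# 8 simulated participants, 8 sequences each, 32 channels;
# ground-truth attention-gain divergence at 230 ms
sims = simulate_participants(8, base_seed=42, n_sequences=8, n_channels=32)
curves = pd.concat(
    [run_all_conditions(preprocess_participant(s), s.session.participant_id)
     for s in sims],
    ignore_index=True,
)
bf = bf_timecourse(curves, "attention_effect")
print("attention onset:", onset_time(bf), "ms")
for c in ("cued_vs_chance", "uncued_vs_chance"):
    print(c, "onset:", onset_time(bf_timecourse(curves, c)), "ms")
```

Output from this exact snippet (a few minutes on one core):

```
attention onset: 232.0 ms
cued_vs_chance onset: 112.0 ms
uncued_vs_chance onset: 116.0 ms
```

Read: cued and uncued orientations become decodable at the same time
(~112–116 ms — both are coded equally early), while the *difference* between
them only shows sustained strong evidence from 232 ms, one sample after the
simulated 230 ms gain divergence.  The pipeline recovers the planted onset.

The same run from the shell:

```bash
attn-decode run --seed 42 --participants 8 --sequences 8 --out runs/demo
# runs/demo/decoding.csv, summary_<contrast>.csv, onsets.json, provenance.json
```

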