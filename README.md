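# songlearn

Statistical learning of melodies with a hierarchical Bayesian chunking
model — and a measurement pipeline for what the learned structure does to
musical rhythm.

`songlearn` is for researchers in auditory statistical learning and music
cognition who want a tested, reproducible simulation of how a learner that
tracks both transition *probabilities* and their *reliabilities* segments
melodies into chunks, builds a hierarchy of units over repeated exposure,
composes new melodies from what it has learned, and shifts the
amplitude-modulation (AM) rhythm of its output toward the slow "delta" band
(1–3 Hz) that characterizes phrased, long-note music.

## The model

**Learning.** Songs are tokenized into base symbols (absolute MIDI pitch ×
quantized duration). For every context unit *i* the learner keeps a
Dirichlet posterior over successors with pseudo-counts α. It derives

- transition probability: the posterior mean `P(j|i) = α_ij / α_i0`;
- reliability: the inverse marginal (Beta) variance
  `r_ij = α_i0²(α_i0+1) / (α_ij (α_i0 − α_ij))`.

Reliability grows with evidence even at a fixed mean — nine B's after ten
A's and ninety B's after a hundred A's both give `P = 0.9`, but reliability
rises from ≈122 to ≈1122 — so the model's state genuinely depends on the
*amount* of learning, unlike a maximum-likelihood Markov model.

**Chunking.** After each pass over the corpus, any transition whose
normalized probability × reliability product exceeds a constant `c = 5`
(normalization against the fresh-prior baseline of its row, by default) is
merged into a chunk unit. Chunks participate in parsing and can themselves
be chunked, cascading into a hierarchy of units; the inventory never
shrinks. Each pass re-parses every song with the current inventory and
updates transition rows at every representation level.

**Surprise.** Every row update contributes the Bayesian surprise
`D_KL(P‖Q) = Σ P(i) log(P(i)/Q(i))` between the predictive row before and
after the event. Summed per trial, surprise falls as the corpus becomes
predictable.

**Production.** New songs are sampled from the learned rows at the highest
populated hierarchy level and expanded recursively to notes.

**Rhythm.** Generated songs are rendered to audio (deterministic sine
voice), z-normalized, and decomposed as `y_t = m_t · c_t` into a slow
positive modulator and a fast carrier by MAP inference: the log-modulator
carries a stationary Gaussian-process prior (`m = exp(g)` keeps it
positive), the carrier a unit-variance Gaussian prior. The modulator's
Morlet scalogram over 0.5–15 Hz is summarized as mean power in the 1–3 Hz
and 3–5 Hz bands.

## Worked example

The bundled demo learns a 30-song synthetic corpus with a planted 3-note
motif for 15 trials, generates 20 songs per trial model, and analyses the
rhythm of the first and last models' output:

```bash
songlearn demo --seed 0 --out demo-run
```

prints (abridged):

```json
{
 "motifs_recovered": [true],
 "final_chunks": 641,
 "final_hierarchy": 5,
 "surprise_trial_1": 2.864,
 "surprise_final": 1.446,
 "js_drift_spearman": 0.561,
 "band_powers_by_trial": {
  "1":  {"band_power_1_3": 8.653, "band_power_3_5": 3.512},
  "15": {"band_power_1_3": 8.733, "band_power_3_5": 3.193}
 }
}
```

Reading the numbers: the planted motif was discovered as a hierarchical
unit; the chunk inventory grew to 641 units across 5 levels while the
per-trial Bayesian surprise fell from 2.86 to 1.45 nats; the
Jensen–Shannon distance between generated and original note-bigram
distributions rose with the amount of learning (Spearman ρ = +0.56); and
the heavily-trained model's songs carry slightly more slow-band (1–3 Hz)
and less 3–5 Hz AM power than the trial-1 model's songs. Per-trial tables
(`metrics.csv`, `trajectory.csv`, `band_powers.csv`, `spectra.csv`,
`embedding.csv`) and generated MIDI are written to `demo-run/`.

The `examples/` directory holds one short script per capability: learning
curves, song generation, rhythm analysis, and the drift embedding. The
library API (`songlearn.model`, `learning`, `composer`, `rhythm`,
`analytics`, `pipeline`) is the primary interface; the `songlearn` CLI is a
thin wrapper with `learn`, `generate`, `rhythm`, `report` and `demo`
subcommands.

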