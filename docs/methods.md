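# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## The Dirichlet–Markov learner

Each context unit *i* (a base token or a chunk) owns a Dirichlet posterior
over successors. Rows start as a symmetric prior with pseudo-count
`alpha_prior = 1` per symbol of the vocabulary known at row creation;
symbols that enter the vocabulary later join a row lazily, also at the
prior floor. One observation adds exactly one pseudo-count, so counts are
conserved and every row's posterior-mean probabilities sum to 1.

Reliability is the inverse of the marginal Beta variance
`Var = α_i(α_0−α_i)/(α_0²(α_0+1))`. Two properties matter:

- at fixed mean, reliability grows linearly with the total count — the
  model distinguishes "9 of 10" from "90 of 100";
- the variance is symmetric in `α_i ↔ α_0−α_i`, so *rare* continuations of
  well-observed contexts are also highly reliable ("reliably
  unpredictable"). This symmetry shapes the chunking normalization below.

Surprise per observation is `KL(row before ‖ row after)`, evaluated in
closed form, `log((α_0+1)/α_0) + (α_j/α_0) log(α_j/(α_j+1))`, which equals
the generic KL of the two posterior-mean distributions (tested).

## Chunking criterion and its normalization

A transition is merged into a chunk when its normalized
probability × reliability product exceeds `c = 5`. The raw product
simplifies to `p·r = α_0(α_0+1)/(α_0−α_i)`: it grows with the row total
regardless of which successor is involved, so the normalization determines
the model's behaviour. Four strategies are implemented
(`ModelConfig.normalization`):

- **`prior_baseline` (default):** divide by the product a fresh symmetric
  prior row of the same width would give. The score then grows with
  accumulated evidence, scaled by transition strength — chunks appear
  progressively over trials, strongest transitions first, which is what
  makes the chunk count and hierarchy depth climb across all fifteen
  trials and the generated output drift gradually. Under this reading the
  threshold is naturally "decided by the sample length and the number of
  learning trials": `c` sets how much exposure a transition of given
  strength needs before it consolidates.
- **`row_loo_product`:** divide by the leave-one-out mean product of the
  context's other continuations (plus the row's prior baseline). This
  cancels evidence growth and reduces to a near-static threshold on
  transition probability (~`1 − 1/c`): inventories stay minimal (only the
  planted motifs chunk) but all structure is found within the first trials
  and the learning dynamics saturate.
- **`level_loo_product` / `mean_separate`:** normalize against all observed
  transitions whose merge would sit at the same hierarchy level, on the
  product or on probability and reliability separately. Separate
  normalization is dominated by the reliability of rare continuations (the
  Beta symmetry above) and is kept only for comparison.

Chunks are pairwise merges; longer units arise by cascade, to `max_level =
5` by default (a bound against runaway cascades on degenerate corpora).
Detection runs once at the end of each trial, on a snapshot of the
statistics, creating the strongest-scoring chunks first; chunks are never
removed.

## Parsing

Each song is represented at level 0 (raw tokens) and re-parsed at every
hierarchy level whose chunks change the segmentation; adjacent unit pairs
at every representation update their rows. Parsing assigns chunks to
non-overlapping token spans in priority order — longest expansion first,
then earliest creation (which, by the detection order above, means the
stronger unit) — claiming occurrences left to right. A pure left-to-right
longest-match scan was rejected: once weak chunks exist, it fragments
strong units that happen to start one position later, and planted-motif
recovery degrades (measured recall 0.6 versus 1.0 with priority parsing).
Matching runs on a private-use-character encoding of the token stream so
occurrence search is a C-speed substring scan.

## Learning protocol and metrics

One model per corpus; trial *k* is one pass over all songs in fixed
manifest order followed by chunk detection (a per-song-model protocol is
available as `run_learning_per_song`). Per trial we record the cumulative
chunk count, the hierarchy depth and the summed surprise of the pass;
z-scores use the population SD, with constant series mapping to zeros.

Total surprise is not monotone in the first trials: when a new hierarchy
level opens, its rows start at the prior and inject fresh surprise (on the
standard corpus: ≈2.9, 3.8, 4.3 nats over trials 1–3, then a monotone fall
to ≈0.02–1). The robust, tested statements are the endpoint decrease
(trial 15 ≪ trial 1) and a strongly negative rank trend. Within a fixed
model state (no chunk detection between passes) a second pass over the
same song is always less surprising than the first.

## Synthetic corpora

The generator emulates a children's-song corpus as token streams over a
12-symbol alphabet (diatonic pitches × a duration): at each emission step,
with probability `motif_rate = 0.5` a planted 2–4-token motif is emitted
whole, otherwise one uniform random token. Defaults: 50 songs × 60 tokens,
one 3-token motif, all randomness from one seed. Optional per-motif
weights plant motifs of graded strength; per-token durations let motif
notes be long (1 beat ≙ 2 Hz at 120 BPM) against short noise notes, which
is what links learned structure to slow-band rhythm in the demo.

What this does not capture: real melodies have tonal and metrical
constraints, non-uniform note marginals, rests, and motif variants. Tests
passing on these corpora show that the machinery behaves as specified
under known ground truth, not that the effect sizes match any real corpus.

## Amplitude demodulation (MAP)

The z-normalized signal is modelled as `y_t = m_t c_t` with `m_t =
exp(g_t)`, `g` a stationary Gaussian process (squared-exponential
covariance, timescale 0.0187 s ⇒ half-power near 10 Hz, prior SD 2), and
the carrier white with unit variance. In the exact-reconstruction limit
the carrier is `y/m` and the MAP objective over `g` is

`−½ Σ y_t² e^{−2 g_t} − ½ gᵀ K⁻¹ g`.

`g` is parameterized by Fourier features at the DFT frequencies below the
10 Hz modulator cutoff, where the SE prior is diagonal (spectral density
`∝ exp(−2π²τ²f²)`; the DC coefficient gets a broad prior so the envelope
mean is learned). Optimization is L-BFGS with analytic gradients,
initialized from the projected log local power; at most 500 iterations,
relative tolerance 1e-8; the recorded log-posterior trace is monotone. The
optimizer runs on the signal decimated to 2 kHz — the sine voice's carrier
content lies well below that Nyquist rate — and the log-modulator is
interpolated back to the input rate, so positivity and exact
reconstruction (`m·c = y`, residual ~1e-16) hold at full resolution.
Calibration is by the frequency-recovery property: synthetic AM tones at
1–4 Hz are localized within ±0.5 Hz and a 2 Hz noise-carrier envelope is
recovered with r ≥ 0.96; an unmodulated carrier yields a near-constant
modulator (CV ≈ 0.002). Recursive (cascaded) demodulation is available by
re-applying `pad_demodulate` to a modulator but is not needed for the
1–3/3–5 Hz readout.

## Scalogram and band powers

Before the wavelet transform the modulator is de-meaned, low-pass filtered
at 15 Hz (zero-phase Butterworth) and decimated to 100 Hz. The transform
is a complex Morlet (ω₀ = 6) over 48 log-spaced frequencies from 0.5 to
15 Hz; power is the squared magnitude, time-averaged per frequency, and
band powers are means over the closed intervals [1, 3] and [3, 5] Hz.
Signals shorter than two cycles of the lowest frequency have the grid
trimmed with a warning.

## Distributional comparisons

All comparisons are made at the base-token bigram level (chunk output is
expanded first) so generated and original songs share a support. KL uses
natural logs; additive smoothing (1e-9, renormalized) is applied to Q only
when it has sampling zeros on P's support, so exact inputs are compared
exactly. Drift is the Jensen–Shannon *distance* (√JS divergence, bounded
by √ln 2), which needs no smoothing. t-SNE embeds the original-corpus
distribution plus one averaged distribution per trial (perplexity 5,
precomputed JS metric, random init, fixed seed). Because 20-song
distributions carry a JS sampling floor of ≈0.13, the drift acceptance
statistic is the Spearman correlation of the *seed-averaged* trajectory
(five seeds), with the per-seed t-SNE rank correlations averaged the same
way.

## Generation policy

The start unit is drawn from the marginal of observed contexts at the
highest populated level; successors from the posterior-mean row
renormalized over successors actually observed (the prior floor
regularizes probabilities but never emits a never-seen continuation); a
context with no observed successor at the current level falls back level
by level, ultimately to the level-0 row of its last expanded token.
Sampled units are expanded recursively and the song truncated to the
target length. With an empty inventory this is exactly a first-order
Markov sampler on base tokens (tested: total-variation ≤ 0.1 at 200
tokens against the learned matrix).

## Problem sizes

Defaults throughout: 50 songs × 60 tokens × 15 trials (learning runs in
~2 s); 20 generated songs per model; rhythm analysis on 4 songs per
compared trial at 16 kHz render / 2 kHz inference; recall over 10 seeds
and drift over 5 seeds. The full test suite runs in ~3 minutes, the
acceptance script in ~1.5 minutes, the demo pipeline in ~40 s.

## Known limitations

- The chunking normalization is a modelling choice; the four variants can
  yield qualitatively different inventory sizes (minimal vs. comprehensive),
  and only the relative, documented behaviours are tested.
- Monophonic only; polyphony is reduced by a highest-pitch rule.
- The sine-voice renderer is deliberately simple; absolute band powers
  depend on it, so only within-pipeline comparisons are meaningful.
- Rhythm-band differences between early- and late-trial models are small
  on synthetic corpora and are reported as a trend, not tested as an
  effect size.
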