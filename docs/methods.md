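# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `ctrscoder`.

## Data model and preprocessing

A session is an ordered list of talk turns, each with a speaker role
(therapist/patient), text, and start/end times, plus four categorical
metadata variables (clinic, level of care, population, assessment time)
and, when fully coded, the eleven CTRS codes on the 0–6 scale.  The total
CTRS is always recomputed as the sum of the codes and binarized at 40
(`high` iff total ≥ 40).  Sessions missing any code load as unlabeled and
flow through embedding and prediction; training operations reject them.

Turn merging joins adjacent same-role turns whose silence gap is *strictly*
shorter than 2 s (a gap of exactly 2 s does not merge), applied
transitively left to right.  Texts are joined with a single space and no
punctuation, since automatic transcripts carry none.  Merging conserves
word content and per-role speech time.

Metadata encodes as concatenated one-hot blocks with one reserved
unknown slot per variable.  The vocabulary is fit on training folds only;
the unknown slot absorbs categories (for example an entire clinic) that a
cross-validation split removes from training, keeping train and test
dimensions equal.

## Utterance embeddings

An utterance's vector is the mean of its per-token final-layer vectors,
cropped to the first 64 tokens.  Special boundary tokens and padding are
excluded from the mean (exclusion is a package choice — exposed as a flag —
since either convention is defensible).  Empty utterances map to the zero
vector rather than being dropped, preserving turn indexing.  Sessions are
truncated to a cap (default 256 utterances therapist-only, 512 for all
utterances) keeping the *first* cap utterances; the simplest deterministic
rule, chosen as default because most sessions fit under the cap.

Two backends satisfy the embedding protocol:

- **hash backend** (default for studies and tests): each distinct token
  maps to a fixed pseudo-random unit vector keyed by a cryptographic hash
  of (token, seed).  Deterministic across processes, download-free, and
  near-orthogonal across tokens, so planted marker tokens are linearly
  separable from filler in expectation.
- **tiny transformer encoder**: a compact BERT-style encoder (default 2
  layers, width 32, 2 heads, learned token/position/segment embeddings)
  with masked-token and next-sentence heads, trainable by the adaptation
  module and then usable as a frozen feature extractor.

## Domain-adaptive continued pretraining

Sentence-pair instances pair each utterance with its true successor
(positives) or with a uniformly drawn utterance from the corpus re-drawn
until it is not the true successor (negatives, 50%).  With probability 0.5
a pair is built to a target length sampled between a quarter of the budget
and the budget — the lower floor exists because single-token segments make
pair-order prediction undecidable.  Masking selects 15% of non-special
tokens; 80% become the mask symbol, 10% a random vocabulary token, 10%
stay unchanged (the standard recipe).  The train/eval split is at the
session level, so no evaluation utterance appears inside a training
instance.  Role-filtered instance building treats consecutive therapist
turns as consecutive, matching how a therapist-only encoder sees a corpus.

The full-scale configuration (10,000 steps, learning rate 2e-5, batch 64,
64-token sequences) ships as the config default; the scaled-down profile
used by the simulation studies runs 500 steps at learning rate 3e-3 on the
2-layer/width-32 encoder, where the larger rate is appropriate for a small
model trained briefly from scratch.

## Scoring networks

Both architectures embed the session, run one bidirectional GRU layer
(64 units per direction; update convention
h' = (1−z)⊙h + z⊙ĥ with candidate gate ĥ = tanh(x_h + (r⊙h)U_h)), apply
additive self-attention (10-unit score layer per head), concatenate the
one-hot metadata vector into every head's MLP input, and finish with a
20-unit ReLU MLP.  Optimization is Adam at learning rate 0.001, up to 200
epochs with early stopping on validation loss at patience 10; the
parameters of the best-validation epoch are returned.  The validation set
is a therapist-grouped slice (~10% of therapists) of the training data.

Numerical and design choices:

- Multi-task outputs are linear during training (plain per-code MSE summed
  over the 11 codes, no clipping inside the loss) and clipped to [0, 6] at
  inference only, which honors both the unbounded linear activation and
  the bounded code scale without changing gradients.
- Single-task uses class-weighted binary cross-entropy with
  w_c = n/(2·n_c), which normalizes the mean sample weight to 1;
  probabilities are clamped to [1e-7, 1−1e-7] inside the loss.  The
  decision threshold on the sigmoid output is 0.5.
- Attention softmax masks padded positions to exactly zero weight; every
  profile sums to 1 over valid positions.  Padded positions also freeze
  the GRU state, so batching with padding is bitwise equivalent to
  unpadded runs at valid positions.
- Input conditioning: utterance vectors are scaled by the reciprocal RMS
  norm of the training vectors (mean-pooled embeddings are short, which
  otherwise parks the recurrent layer deep in its linear regime), and
  multi-task output biases start at the per-code training means.  Both are
  fitted on training data only and stored with the model.
- No dropout or weight decay by default; regularization is left to early
  stopping (configurable).

All networks run on an in-package reverse-mode autodiff engine over numpy
arrays.  Every primitive is gradient-checked against central finite
differences in the test suite; the GRU time step is a single fused tape
node whose hand-derived backward is additionally checked against the
primitive composition.

## Evaluation

Cross-validation assigns *therapists* to folds — shuffled by seed, ordered
by descending session count, each placed into the currently smallest fold —
so fold sizes stay balanced and no therapist appears in two folds (checked
at run time on every split).  The metric is macro-F1 over {low, high}; a
class with zero predicted and zero true positives contributes F1 = 0.

The paired bootstrap resamples sessions with replacement (multinomial
weights, vectorized) and computes the macro-F1 difference between a
candidate and a reference system per resample; the one-sided p-value is
the fraction of resamples where the candidate fails to improve.  One-sided
is the package's pin (a flagged two-sided variant would double the
p-value); identical predictions give p = 1 exactly.

The experiment grid evaluates architecture × metadata × utterance set ×
backend under one shared fold assignment, making all comparisons paired,
and reports per-technique marginal means with relative improvement
(yes − no)/no.  Fold-local state — metadata vocabulary, tf-idf vocabulary
and idf, feature selection — is re-fit inside each training fold.

The frequency baseline is session-level unigram tf-idf (smoothed idf
ln((1+N)/(1+df))+1, L2-normalized rows), univariate ANOVA F-test selection
of the 32 best features (zero-variance features take F = 0; ties break
toward lower column index), and a class-weighted linear SVM.

## Attention saliency

Sessions differ in length, so profile weights are binned onto a fixed
100-bin relative-position grid (utterance t of length-L profile → bin
⌊t·100/L⌋) and rescaled by the bin count, making the uniform profile the
constant 1.0 at any length.  Curves average the binned vectors of held-out
(test-fold) predictions per head; a mean-of-codes curve averages the 11
per-code curves.  The time axis is utterance index; wall-clock time is a
possible variant the package does not implement.

## Synthetic corpora

The generator emulates the statistical structure of a real coded CBT
archive at the scale of its published summary statistics: ~430 ± 230 talk
turns per session with ~47% therapist-attributed, 60 therapists × 10
sessions by default, and a latent additive score model

    x_sc     = base + skill_t + lexical noise        (code c, session s)
    score_sc = clamp(round(x_sc + delta_s + noise), 0, 6)

with per-therapist skill (sd 0.8), per-variable categorical metadata
shifts summing to delta_s, and small observation noise (sd 0.25).  The
defaults put 20–35% of sessions at or above the competence threshold,
matching the imbalance such archives show (roughly a quarter competent).

Lexical evidence is planted as invented marker tokens in therapist turns
at a rate of 10·max(x − 1.5, 0) markers per 100 therapist turns: below a
latent floor a skill leaves no lexical trace; above it the marker rate
grows with the skill.  Rate (not count) encoding is deliberate — softmax
attention reads per-position evidence density, so the recoverable signal
must be length-invariant.  Localization per code: agenda-like codes plant
only in the first 15% of therapist turns; homework-like codes split their
evidence into two *complementary* half-signals (early and late windows,
each reflecting x plus independent noise of sd 0.7), so an accurate
readout must attend to both session ends — mirroring reviewing versus
assigning homework; all other codes plant uniformly.  Patient turns carry
filler only by default (a flag leaks signal into patient turns to emulate
the all-utterances condition), and an optional token deletion/substitution
rate emulates transcription noise.

The metadata shifts are what make metadata fusion genuinely informative:
delta_s never reaches the text, so the no-metadata model faces
irreducible extra error.

A second generator builds the adaptation corpus: codewords form one global
cyclic topic sequence; each utterance carries several copies of its own
topic codeword and the next one, so true successors share a codeword and
the successor relation is corpus-wide — an encoder that learns it on
training sessions can decide adjacency on held-out sessions.  (An earlier
session-local chain design was learnable only by memorizing
session-specific pairs and did not transfer.)

What passing on this data does and does not show: the pipeline recovers
planted, lexically clean, additively generated signal under realistic
session lengths, imbalance, and therapist grouping.  Real therapy language
has no single-token skill markers, correlated codes, annotator noise, and
ASR errors with structure; absolute scores here say nothing about
performance on real corpora.

## Study sizes and budgets

The headline recovery study trains on the default 600-session corpus with
the 64-dimensional hash backend, a therapist-grouped 70/10/20 split, and an
epoch cap of 70 (early stopping typically fires around epoch 40–55, where
validation loss has plateaued).  The adaptation study uses 120 sessions ×
30 turns, 500 steps, batch 64.  Bootstrap calibration uses 200 repetitions
of 2,000 resamples at n = 400.  These sizes make the full acceptance run
reproducible in minutes on a single CPU core.

## Known limitations

- Only dyadic two-role sessions are modeled; group therapy does not map
  onto the therapist/patient role pair and is rejected at parse time.
- The transformer encoder is compact by design; it demonstrates the
  adaptation machinery and serves as a real backend, but it is not a
  pretrained language model and its embeddings are not linguistically
  meaningful beyond the corpus it is trained on.
- The generator's score model is additive Gaussian with rounding; it
  cannot express code-specific rater styles, halo effects between codes,
  or nonmonotone metadata interactions.
- Truncation keeps session starts; sessions longer than the cap lose
  their ends, which dampens late-session saliency for long sessions (the
  edge-preserving truncation variant is configurable but not the default).
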