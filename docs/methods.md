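# Methods

## Tasks and data model

The package addresses two user-level binary screening tasks learned jointly:

* **suicide-ideation side (s)** — users annotated on a 4-level risk taxonomy
  (none / low / moderate / severe) plus a separate unannotated control pool.
  Two collapses are supported: *flagged* (positive = low ∪ moderate ∪
  severe) and *urgent* (positive = moderate ∪ severe).
* **mental-disorder side (m)** — users with a self-reported diagnosis vs
  matched controls, already binary.

A "document" is one user's posts, cleaned, concatenated in timestamp order
and tokenized.  Users with fewer than `min_tokens` surviving tokens (50 for
long-form corpora, 20 for tweet-style) are discarded; the threshold is
applied to the post-cleaning, post-stopword count — i.e. the token stream
the model actually consumes — and this timing is recorded in the cleaning
configuration so it can be flipped.

### Cleaning

Fixed order: URL / @mention / #hashtag / retweet-marker / emoji / ASCII
emoticon / standalone-number removal → lowercasing → contraction expansion
(frozen table in `data/contractions.json`) → punctuation removal →
whitespace collapse.  Expansion must precede punctuation stripping because
it consumes apostrophes; apostrophes in unknown forms are deleted in place
("dog's" → "dogs") while other punctuation becomes a space ("well-known" →
"well known").  Hashtag removal strips the whole token, not just the `#`
sign.  The retweet rule matches the raw-case marker `RT` (start of post or
before a mention) *before* lowercasing, which is what makes cleaning
idempotent — a guaranteed and property-tested invariant.  Emoji are removed
by Unicode block ranges (pictographs, emoticons, transport, supplemental
symbols, flags, variation selectors, ZWJ, skin tones); ASCII emoticons by a
fixed regex (`:-)`, `;P`, `<3`, …).  Digit runs are removed only when they
form standalone number tokens; digits embedded in words survive.

Stopwords (frozen list in `data/stopwords.txt`) are removed **except all
personal pronouns** (three persons; subject, object, possessive and
reflexive forms): first-person-singular frequency is itself a depression
marker and must reach the model.

### Corpus assembly

Positives and annotated negatives are balanced by sampling the deficit from
the control pool, uniformly without replacement, seeded; the sampled ids go
into the run manifest.  The two balanced single-task datasets are aligned
into pair rows — positives with positives, controls with controls, via a
seeded within-class permutation — because the soft-sharing penalty compares
the two branches' representations row-wise and would otherwise mix classes.
Stratified 80/20 shuffle splits (five by default, scikit-learn's
`StratifiedShuffleSplit`) operate on pair rows, whose labels agree by
construction.  The vocabulary is frequency-ranked over the *pooled* training
text of both tasks (ties broken lexicographically, default cap 20 000,
indices 0 = padding and 1 = out-of-vocabulary reserved) so the branches
share an index space.  Sequences are truncated to the chronological head at
`max_len` (default: 95th percentile of training document lengths, capped)
and right-padded.

## Network

Per branch: trainable embedding (default 300-d, seeded uniform ±0.05) → two
1-D convolution channels (kernels 3 and 4, 256 filters, ReLU or LeakyReLU
α = 0.2) → global max pooling per channel → dropout p = 0.5 (applied
per channel, after pooling and before the dense layer) → dense 512 per
channel → concatenation into the task vector (1024-d at defaults).  An
optional auxiliary input (scaled lexicon-category scores) passes through a
small dense layer (8 units by default; 16 and 32 are the published settings
for the urgent and cross-platform variants) whose output is appended,
giving 1032-d task vectors.  The two task vectors concatenate into the
shared representation (2048-d default) read directly by both softmax heads
(no intermediate layer).  When auxiliary inputs are present the soft-share
penalty applies to the post-merge (1032-d) vectors.

Loss: `CCE_s + CCE_m + λ·MSE(v_s, v_m)` with λ = 1 by default ("summing"
the terms) and exposed for ablation; MSE is the batch mean of the
elementwise mean squared difference.  L1 and L2 penalties (1e-5 each) apply
to convolution and dense kernels only — not embeddings, biases or heads.
The log in the cross-entropy is clipped at 1e-7.

The single-task baseline is one branch *without* the per-channel dense
layers — embedding → conv channels → max pool → dropout → concatenation →
softmax — trained with plain cross-entropy under the identical protocol.

The whole network is implemented as a compact NumPy forward/backward engine
(`nn.py`): convolution as a matrix product over unfolded token windows,
max-pool backward by argmax scatter, embedding gradients by scatter-add,
inverted dropout, Adam (β₁ 0.9, β₂ 0.999, ε 1e-7).  Analytic gradients were
verified against float64 central differences to < 1e-4 relative error;
float32 is used in production for speed.  All randomness (initialization,
dropout, sampling) flows from explicit seeds through
`numpy.random.SeedSequence` spawns, so runs are bit-stable on one platform
(across BLAS builds, small last-bit differences are possible; histories are
compared exactly only within one environment).

## Training protocol

Adam at lr 0.001; mini-batches of 8 formed from the stored row order and
**never reshuffled** (batch composition is hashed per epoch and asserted
constant) so that pair alignment is preserved; at most 10 epochs; early
stopping when validation loss has not improved for 3 epochs; learning rate
× 0.1 after 2 non-improving epochs, floored at 1e-8.  "Improvement" means a
strict decrease of ≥ 1e-6 below the best; both patience counters reference
the same best value and run independently.  The 10-epoch limit acts as a
hard cap over the patience rule.  Validation loss for selection includes
the soft-share MSE term (it is part of the summed objective; configurable).
The weights of the best-validation epoch are restored.  One model is
trained per stratified split with a per-split seed derived from the run
seed; inference averages the ensemble's class probabilities elementwise
before the argmax.

Evaluation reports macro precision/recall/F1 (unweighted over the two
classes, 0/0 defined as 0), accuracy, and macro ROC AUC (rank formulation,
ties credited ½; for binary tasks the macro average equals the
positive-class AUC).  Annotator agreement on a 4×4 risk confusion matrix is
the positive-class F1 after collapsing both axes through a task rule; the
expert axis is treated as reference, though F1 is invariant under swapping
the annotators (transposition swaps FP and FN).  Metrics delegate to
scikit-learn and are cross-checked in the test suite against exhaustive
brute-force oracles on small inputs.

## Synthetic paired-corpus generator

The generator emulates the *statistical* structure the MTL experiments
assume, not natural language.  Vocabulary: `V` = 3000 synthetic tokens with
a Zipf(s = 1.1) background distribution (rank = token index), giving
realistic frequency skew.  A lexicon of `K` = 14 pairwise-disjoint
categories × `m` = 20 terms is sampled from the vocabulary; 4 categories
form the suicide task's signal set, and the disorder task shares
`round(ρ·4)` of them (fresh categories for the remainder), so the fraction
of shared signal vocabulary is the overlap parameter ρ ∈ [0, 1].  Overlap
is implemented at category granularity, which makes the shared-term count
exact at ρ = 0 and 1 and within one category's worth of terms elsewhere.

Each document draws tokens i.i.d.: a latent-positive user's token comes
from the uniform distribution over its task's signal set with probability
π (`signal_rate`) and from the background otherwise; controls draw from the
background only.  Document length is Poisson(400) truncated below at
`min_tokens`, emitted as 3–10 timestamped posts, so every generated user
survives the minimum-token filter by construction.  Expected normalized
category scores have closed forms (`expected_aux_signal`): `b_c` for
controls and `π·|c∩S|/|S| + (1−π)·b_c` for positives, where `b_c` is the
category's background mass; Monte-Carlo means are tested against them.

Study-shaped structure: the suicide side carries risk levels for latent
positives in the published train proportions (low:moderate:severe =
50:113:206 for the flagged task; moderate:severe = 113:206 and a
none:low = 127:50 negative mix for urgent), an annotated-negative group
scaled from the published 127/369 (or 177/319) ratio, and a control pool
1.5× the balancing deficit; test sets follow the published imbalanced
ratios (93:32 flagged, 80:45 urgent), scaled to `n_per_class` (default 369
to mirror the published training size).

Observed labels receive **symmetric swap noise** (`label_noise`, default
0.10): `round(rate·min(n₊, n₋))` positives exchange labels with as many
negatives.  This emulates crowdsource annotation error — the published
expert-vs-crowdsource confusion implies roughly 10–16% binary
disagreement — while preserving class marginals exactly, which the
cross-task alignment requires.  Swaps apply to annotated users of both
tasks, train and test; the control pool is left clean.  The generator
without noise is near-perfectly separable at π ≳ 0.1 (a unigram mixture
with hundreds of signal tokens per document), which would pin every
classifier at a scoreless ceiling; the noise gives the benchmark a
meaningful one.

What the generator does **not** emulate: word order and syntax (the CNN's
n-gram machinery is exercised but n-gram *content* carries no extra
signal), topic drift over time, per-user style, platform register
differences, correlated annotation errors, or covariate shift between train
and test.  Tests passing on this generator therefore validate the
machinery and protocol, not clinical performance on real corpora.

## Desk-scale experiment sizes

The end-to-end multi-task-vs-baseline experiments in the test suite run at
the generator's default corpus scale (369 users per class per task,
400-token documents, vocabulary 3000, sequence length 300, batch 8, 10
epochs, 5 splits, 3 seeds) with reduced network dimensions — embedding 16,
12 filters, dense 32 — chosen so a full ensemble trains in well under a
minute on one CPU core; the architecture-width assertions use the full
default dimensions (they only instantiate the network).

## Known limitations

* At the default generator operating point the classification tasks are
  easy enough that both the multi-task ensemble and the single-task models
  converge to the annotation-noise ceiling; the measured multi-task
  advantage is then dominated by the ensemble-averaging effect (ensemble
  vs mean-of-members), which does not depend on the cross-task overlap ρ.
  Separating the *transfer* component of the advantage from the ensemble
  component would require a harder operating point (lower signal rate,
  shorter documents, or fewer users) than the defaults fix.
* The NumPy engine is single-threaded matrix algebra; it is meant for
  reference-scale experiments, not for the full 300-d/256-filter
  configuration on large corpora.
* Cross-platform (tweet-side) experiments are supported through the
  cleaning profile and the `crossplatform10` preset, but the generator
  models a single synthetic platform.
* Lexicon term inventories are data: the category presets fix *names* only,
  and "suicide_topw" in particular must be user-supplied for real corpora.
  Multi-word lexicon terms are matched as token bigrams.
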