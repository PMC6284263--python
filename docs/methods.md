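# Methods

This note records the model, the conventions the implementation commits
to where more than one reading was possible, the synthetic data design,
and what the tests do and do not establish.

## Sequence model

A sentence x₁…xₙ is embedded (one vector per token), encoded by two
independent LSTMs reading left-to-right and right-to-left, and the
concatenated hidden states are affinely projected to an n×3 emission
matrix P over the labels (B, I, O).

**LSTM cell.** The cell is the coupled-gate peephole variant: there is no
separate forget gate — the forget coefficient is (1 − i_t) — and the input
and output gates receive peephole terms W_ci·c_{t−1} and W_co·c_t.  The
peephole weights are full matrices, matching the written form of the
recurrence rather than the diagonal restriction some implementations use.
Both facts change the gradient flow (the output gate sees the *current*
cell state, so ∂loss/∂c_t picks up a W_coᵀ term), which is why the
backward pass is hand-derived and checked against central finite
differences (worst relative error ≈ 1e-5 at h = 1e-5, i.e. at the noise
floor of the difference quotient).

**CRF.** Path score s(X, y) = Σᵢ P[i, yᵢ] + Σᵢ₌₀ⁿ A[yᵢ, yᵢ₊₁].  The n+1
transition terms require boundary labels; they are realized as augmented
START and STOP states in a 5×5 transition matrix, with the START row and
STOP column used only at the sentence edges.  log Z is the log-space
forward recursion; the NLL gradient is expectation − observation from the
forward–backward marginals.  Viterbi ties break toward the lower label
index in the fixed order B < I < O, making decoding deterministic and the
enumeration oracle exact.  Transition legality is fully learned; an
optional decode-time flag (`--constrain-bio`) sets A[O, I] = −∞ instead of
hard-coding the constraint into training.

**Training.** Plain SGD on sentence-level NLL, learning rate 0.05 by
default, gradient clipping at global norm 5 (an engineering addition for
stability), input dropout (inverted, rate 0.5) on the embedded tokens
during training only.  The dropout switch is on by default; a rate of
1.0 would zero every input, so the rate is a real hyper-parameter with
default 0.5.  Tokens are lowercased for embedding lookup only — surface
case is preserved for abbreviation handling — and unseen tokens map to an
UNK row.  The UNK row is given a real representation by word-level
dropout: during training each token is replaced by UNK with probability
0.05, so the model learns to tag from context alone when the word is
unknown (without this, the UNK embedding would never receive a gradient
and out-of-vocabulary words inside multi-word names would be dropped).  With dev documents supplied, the epoch with the best
dev mention F1 is returned.  Initialization is Glorot-uniform weights and
zero biases from a seeded generator; runs are bit-reproducible
single-threaded.

**Ablations.** `use_crf=False` trains a per-token softmax over P and
decodes by argmax (illegal I prefixes are repaired to B by the codec);
`use_bilstm=False` feeds the embedded token directly to the emission
projection, i.e. a per-token affine classifier, so the CRF still receives
an n×3 emission matrix.

## Embeddings

Skip-gram with negative sampling over a fixed window (truncated at
sentence edges).  The noise distribution is unigram^0.75 — the standard
choice; the exponent is configurable.  Defaults: dimension 200, window 5,
k = 5 negatives (the small-corpus end of the usual [5, 20] guidance),
5 epochs, learning rate decaying linearly from 0.025.  Frequent-word
subsampling is off by default and exposed as a config flag.  Input
vectors start uniform in [−0.5/D, 0.5/D], output vectors at zero, so
early σ(s) ≈ 0.5.  Updates are sequential per pair (positive first, then
each negative), which fixes the arithmetic order and makes training
bit-reproducible for a seed.

## Tokenization and offsets

Character offsets are 0-based, half-open, into `title + " " + abstract`
(the convention common to PubTator-style corpora).  The tokenizer splits
on whitespace and detaches leading/trailing punctuation `.,;:()[]{}"!?`
into single-character tokens; hyphens and internal apostrophes are kept,
so *insulin-dependent* is one token.  A token partially overlapping a
mention counts as inside it (boundaries snap outward), and an `I` without
a preceding `B`/`I` is repaired to `B`.  Sentences split after `.?!`
followed by whitespace and an uppercase letter; no further boundary
disambiguation is attempted.

## Abbreviations

Definition sites are parenthesized tokens of 1–10 characters containing
a letter; the long-form window is the preceding words of the sentence up
to min(2·|SF| + 2, |SF| + 5) words (the classical relaxed length
restriction).  Strategies are tried in fixed reliability order — FC
(each SF character matches the first character of consecutive-from-the-
right words), FCG (a character may also match right after an internal
non-alphanumeric character, so *IDDM* matches *insulin-dependent diabetes
mellitus*), then an FC variant allowing one skipped word — and the first
success wins, one pair per site.  Strategy matching is case-insensitive;
short-form propagation is case-sensitive and token-bounded, document-wide.
Merging gives abbreviation-derived mentions precedence on any overlap but
never deletes a tagger mention merely because the abbreviation layer is
silent about it.

One FC subtlety is deliberate: because hyphenated compounds are single
tokens, FC alone validates pairs like *ID* ↔ *insulin-dependent diabetes*
(I from the compound's first character).  FCG is still required whenever
the short form has more characters than the window has words.

## Evaluation

Exact-span matching (identical start and end offsets), the stricter of
the possible mention-matching conventions, declared in the report header.
Zero-denominator metrics are 0.  The bootstrap resamples whole documents
with replacement (default 100 rounds) and reports a percentile interval
(not BCa — only the level and round count are part of the procedure's
definition).

## Synthetic data

The NER generator emulates the *shape* of an annotated PubMed abstract
corpus: by default 10 sentences per document and ≈ 21 words per sentence
(sentences are padded with filler vocabulary toward the target).  Disease
names combine Greco-Latin roots and affixes into single-word, hyphenated,
and 2–4-word forms with modifiers, so the tagger sees the morphology,
compounding, and multi-word cases that make real disease NER hard.  With
probability `p_abbrev_definition` (default 0.3) a document introduces a
multi-word disease as `Long Form (SF)` and reuses the SF later (all
occurrences gold-annotated); independently it may define a *procedure*
abbreviation whose initials collide with a disease short form in other
documents.  Short-form reuse sentences use the same templates for disease
and procedure short forms, so token identity is genuinely ambiguous at
the type level and only the document-local definition disambiguates —
the situation the abbreviation merge exists for.

The generator does **not** emulate real PubMed language: its sentences
are templated, its vocabulary closed, and its label signal strong.
Passing tests therefore demonstrate that the machinery is correct and
that each component contributes as designed — not that the pipeline
reaches any particular accuracy on real corpora, which additionally
requires large-scale pretrained embeddings and a real annotated corpus.

The embedding generator plants `cluster_count` word clusters; every
sentence draws from one cluster, so co-occurrence structure forces
intra-cluster similarity.  Separation is measured as mean intra-cluster
minus mean inter-cluster cosine.

## Problem sizes used by the tests and the acceptance script

Chosen once as desk-scale study conditions: CRF enumeration oracles use
200 instances with n ≤ 8; gradient checks use 50–100 instances of a
word-dim 3 / hidden 2 model with every parameter perturbed; memorization
trains on 50 sentences (30-dim embeddings, 25 hidden units, dropout 0,
30 epochs); generalization trains on 500 documents of 4 sentences and
tests on 100 (dropout 0.2, 4 epochs); embedding recovery uses 40 words in
2 clusters over 20,000 tokens, 30 dimensions, 3 epochs; the BIO codec
round-trip covers 10,000 generated sentences plus randomized I-repair
corruptions; bootstrap widths use 100 rounds at the 95% level on 1, 10,
and 100 documents.  Hidden size 25 (rather than the tuned 100) and
4-sentence documents in the generalization run are capacity/size choices
appropriate to the synthetic task's difficulty.

## Known limitations

* No character-level features; rare-morphology generalization rests
  entirely on word embeddings and context.
* Part-of-speech information is not used anywhere.
* The seventeen-strategy reliability search of full abbreviation
  resolvers is represented by three strategies with a fixed precedence;
  the strategy list is extensible.
* Concept identifiers are carried opaquely and never normalized.
* Training is pure-NumPy SGD on one CPU; it is meant for corpora of
  thousands of sentences, not millions.
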