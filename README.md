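# disner

Disease named-entity recognition for biomedical abstracts: negative-sampling
skip-gram word embeddings, a bidirectional LSTM encoder with a linear-chain
CRF output layer, abbreviation (short-form/long-form) resolution, and
mention-level bootstrap evaluation.

## The problem

Disease mentions in biomedical text are hard to locate reliably: names are
built from Greek/Latin roots and affixes (*hemo-chromatosis*), carry
descriptive modifiers (*recurrent cat-eye syndrome*), span several words,
and are frequently replaced by ambiguous abbreviations — *CT* may mean
*Copper Toxicosis* (a disease) or *Computed Tomography* (a procedure).
`disner` implements a hybrid tagger for this setting, aimed at text-mining
practitioners who need character-offset disease mentions from
PubTator-style annotated corpora.

## The model

Sentences are tokenized and labeled with the **BIO** scheme (k = 3 labels).
Three stages produce the labels:

1. **Word embeddings.** Skip-gram with negative sampling: the score of a
   center/context pair is s(w, c) = v_w · v′_c, and each observed pair is
   contrasted with k noise words drawn from Q(w) ∝ count(w)^0.75 by
   ascending L = log σ(s(w, c)) + Σᵢ log σ(−s(w̃ᵢ, c)).

2. **Bi-LSTM encoder.** A coupled-gate peephole cell,

       i_t = σ(W_xi x_t + W_hi h_{t−1} + W_ci c_{t−1} + b_i)
       c_t = (1 − i_t) ⊙ c_{t−1} + i_t ⊙ tanh(W_xc x_t + W_hc h_{t−1} + b_c)
       o_t = σ(W_xo x_t + W_ho h_{t−1} + W_co c_t + b_o)
       h_t = o_t ⊙ tanh(c_t)

   run in both directions; the per-token concatenation is projected to an
   n×3 emission matrix P.

3. **Linear-chain CRF.** A path y is scored
   s(X, y) = Σᵢ P[i, yᵢ] + Σᵢ A[yᵢ, yᵢ₊₁] with learned transitions A and
   START/STOP boundary states; p(y|X) = exp s(X, y) / Σ_ỹ exp s(X, ỹ).
   Training minimizes the negative log-likelihood by SGD (gradients are
   hand-derived and finite-difference checked); decoding is Viterbi.

A fourth, rule-based stage detects abbreviation definitions
(`Long Form (SF)`) with first-character matching strategies (FC, FCG, and
an FC variant allowing one skipped word).  If a long form overlaps a
tagged disease mention, all document occurrences of the short form become
disease mentions, and on conflicts the abbreviation-derived span wins.

Evaluation is exact-span mention-level precision/recall/F1 with an
optional put-back (with-replacement) document bootstrap for confidence
intervals.

## Worked example

```bash
disner make-fixtures --preset ner --seed 4 --out fx --docs 8 --sentences 4
disner train-tagger --train fx/corpus.pubtator --out model.json \
    --word-dim 10 --hidden 6 --dropout 0 --epochs 2 --seed 1
disner tag --model model.json --input fx/corpus.pubtator --output pred.pubtator
disner abbrev --input fx/corpus.pubtator | head -2
disner evaluate --gold fx/corpus.pubtator --pred pred.pubtator --bootstrap 20 --seed 2
```

The `abbrev` step prints detected definition sites as TSV, e.g.

```
10003  197  199  CC    168  195  cephalo-sclerosis carcinoma            FC
10005  217  221  CPHA  178  215  computed perfusion histology analysis  FC
```

(doc id, short-form offsets and text, long-form offsets and text, and the
strategy that validated the pair — here FC, first-character matching).
`evaluate` prints a fixed-order report; for the deliberately tiny model
above it shows the tagger has learned nothing yet:

```
matching        exact-span
tp      0
fp      0
fn      18
precision       0.0000
recall  0.0000
f1      0.0000
rounds  20
level   0.9500
f1_low  0.0000
f1_high 0.0000
```

Trained at realistic settings (500 training documents, 30-dim embeddings,
25 hidden units, 4 epochs — see `docs/methods.md`) the same pipeline
reaches exact-span F1 of 0.95–1.00 on held-out synthetic documents, and
the abbreviation merge lifts recall on abbreviation-rich fixtures (for
example +0.27 recall at a 0.5 definition rate in one seeded run of
`scripts/acceptance.py`).

The library surface mirrors the CLI: `disner.train_skipgram`,
`disner.train_tagger`, `disner.tag_document`, `disner.resolve_pairs` /
`merge_labels`, `disner.evaluate_documents` / `bootstrap_f1`, and
`disner.run_pipeline` for the whole staged run.

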