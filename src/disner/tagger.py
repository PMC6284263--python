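"""Bi-LSTM encoder with a linear-chain CRF output layer for BIO tagging.

The encoder is the coupled-gate peephole LSTM cell

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + W_ci c_{t-1} + b_i)
    c_t = (1 - i_t) (.) c_{t-1} + i_t (.) tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + W_co c_t + b_o)
    h_t = o_t (.) tanh(c_t)

— there is no separate forget gate; the forget coefficient is (1 - i_t),
and the input/output gates peek at the cell state through W_ci and W_co.
Forward and backward direction cells are independent; their hidden states
are concatenated per token and projected to an n×3 emission score matrix
P over the labels (B, I, O).

A label path y is scored by emissions plus learned transition scores,

    s(X, y) = sum_i P[i, y_i] + sum_{i=0..n} A[y_i, y_{i+1}]

with boundary terms realized as augmented START/STOP states in a 5×5
transition matrix A.  Training minimizes the negative conditional
log-likelihood  log Z(X) - s(X, y_gold)  by plain SGD with gradient
clipping; decoding is max-product Viterbi (ties broken toward the lower
label index in the fixed order B < I < O).

All gradients are hand-derived and validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .corpus_io import (
    AnnotatedDocument,
    Mention,
    Token,
    bio_to_mentions,
    mentions_to_bio,
    split_sentences,
    tokenize,
)
from .embeddings import EmbeddingModel

__all__ = [
    "LABELS",
    "START",
    "STOP",
    "LSTMCellParams",
    "TaggerConfig",
    "TaggerModel",
    "lstm_step",
    "bilstm_encode",
    "emission_scores",
    "sequence_score",
    "log_partition",
    "viterbi_decode",
    "crf_nll",
    "nll_loss",
    "train_tagger",
    "tag_document",
    "doc_to_sentences",
    "save_tagger",
    "load_tagger",
]

LABELS = ("B", "I", "O")
K = len(LABELS)
START, STOP = K, K + 1  # augmented boundary states in the transition matrix
UNK = "<unk>"


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------------

_CELL_FIELDS = (
    "W_xi", "W_hi", "W_ci", "b_i",
    "W_xc", "W_hc", "b_c",
    "W_xo", "W_ho", "W_co", "b_o",
)


@dataclass
class LSTMCellParams:
    """Parameters of one coupled-gate peephole LSTM direction."""

    W_xi: np.ndarray
    W_hi: np.ndarray
    W_ci: np.ndarray
    b_i: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    b_c: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    W_co: np.ndarray
    b_o: np.ndarray

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        """Glorot-uniform weights, zero biases."""

        def glorot(rows: int, cols: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-limit, limit, size=(rows, cols))

        H, D = hidden_dim, input_dim
        return cls(
            W_xi=glorot(H, D), W_hi=glorot(H, H), W_ci=glorot(H, H), b_i=np.zeros(H),
            W_xc=glorot(H, D), W_hc=glorot(H, H), b_c=np.zeros(H),
            W_xo=glorot(H, D), W_ho=glorot(H, H), W_co=glorot(H, H), b_o=np.zeros(H),
        )

    @property
    def hidden_dim(self) -> int:
        return self.b_i.shape[0]

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _CELL_FIELDS}


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    cell: LSTMCellParams,
    *,
    cache: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the coupled-gate peephole recurrence; returns (h_t, c_t)."""
    H, D = cell.W_xi.shape
    if x_t.shape != (D,) or h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for cell with H={H}, D={D}"
        )
    i = _sigmoid(cell.W_xi @ x_t + cell.W_hi @ h_prev + cell.W_ci @ c_prev + cell.b_i)
    g = np.tanh(cell.W_xc @ x_t + cell.W_hc @ h_prev + cell.b_c)
    c = (1.0 - i) * c_prev + i * g
    o = _sigmoid(cell.W_xo @ x_t + cell.W_ho @ h_prev + cell.W_co @ c + cell.b_o)
    tanh_c = np.tanh(c)
    h = o * tanh_c
    if cache is not None:
        cache.append((x_t, h_prev, c_prev, i, g, c, o, tanh_c))
    return h, c


def _lstm_step_backward(cell, cache_t, dh, dc_in, grads):
    """Backprop one step; returns (dx, dh_prev, dc_prev)."""
    x, h_prev, c_prev, i, g, c, o, tanh_c = cache_t
    do = dh * tanh_c
    da_o = do * o * (1.0 - o)
    dc = dh * o * (1.0 - tanh_c**2) + dc_in + cell.W_co.T @ da_o
    di = dc * (g - c_prev)
    dg = dc * i
    da_g = dg * (1.0 - g**2)
    da_i = di * i * (1.0 - i)

    grads["W_xi"] += np.outer(da_i, x)
    grads["W_hi"] += np.outer(da_i, h_prev)
    grads["W_ci"] += np.outer(da_i, c_prev)
    grads["b_i"] += da_i
    grads["W_xc"] += np.outer(da_g, x)
    grads["W_hc"] += np.outer(da_g, h_prev)
    grads["b_c"] += da_g
    grads["W_xo"] += np.outer(da_o, x)
    grads["W_ho"] += np.outer(da_o, h_prev)
    grads["W_co"] += np.outer(da_o, c)
    grads["b_o"] += da_o

    dc_prev = dc * (1.0 - i) + cell.W_ci.T @ da_i
    dh_prev = cell.W_hi.T @ da_i + cell.W_hc.T @ da_g + cell.W_ho.T @ da_o
    dx = cell.W_xi.T @ da_i + cell.W_xc.T @ da_g + cell.W_xo.T @ da_o
    return dx, dh_prev, dc_prev


def _run_direction(xs, cell, reverse: bool):
    """Run one LSTM direction over xs (n×D); returns (hs n×H, caches, order)."""
    n = xs.shape[0]
    H = cell.hidden_dim
    h = np.zeros(H)
    c = np.zeros(H)
    order = range(n - 1, -1, -1) if reverse else range(n)
    hs = np.zeros((n, H))
    caches: list = []
    for t in order:
        h, c = lstm_step(xs[t], h, c, cell, cache=caches)
        hs[t] = h
    return hs, caches, list(order)


def _direction_backward(cell, caches, order, dhs):
    """Backprop a direction given per-position output grads dhs (n×H)."""
    grads = {name: np.zeros_like(arr) for name, arr in cell.arrays().items()}
    dxs = np.zeros((len(order), cell.W_xi.shape[1]))
    dh_carry = np.zeros(cell.hidden_dim)
    dc_carry = np.zeros(cell.hidden_dim)
    for step in range(len(order) - 1, -1, -1):
        t = order[step]
        dx, dh_carry, dc_carry = _lstm_step_backward(
            cell, caches[step], dhs[t] + dh_carry, dc_carry, grads
        )
        dxs[t] = dx
    return grads, dxs


def bilstm_encode(xs: np.ndarray, model: "TaggerModel") -> np.ndarray:
    """Encode an embedded sentence (n×D) to n×2H context vectors.

    Forward pass left-to-right and backward pass right-to-left with
    independent parameters, both from zero initial states; output is the
    per-position concatenation [h_fwd ; h_bwd].
    """
    if xs.ndim != 2 or xs.shape[0] < 1:
        raise ValueError("bilstm_encode requires at least one embedded token")
    hf, _, _ = _run_direction(xs, model.forward_cell, reverse=False)
    hb, _, _ = _run_direction(xs, model.backward_cell, reverse=True)
    return np.concatenate([hf, hb], axis=1)


# ---------------------------------------------------------------------------
# CRF layer
# ---------------------------------------------------------------------------

def emission_scores(context: np.ndarray, model: "TaggerModel") -> np.ndarray:
    """Affine projection of context vectors to raw n×3 label scores."""
    return context @ model.emission_W.T + model.emission_b


def sequence_score(P: np.ndarray, A: np.ndarray, y: Sequence[int]) -> float:
    """Path score: emissions plus transitions with START/STOP boundary terms."""
    n = P.shape[0]
    if len(y) != n:
        raise ValueError("label path length does not match emission rows")
    total = A[START, y[0]] + P[np.arange(n), y].sum() + A[y[-1], STOP]
    for t in range(n - 1):
        total += A[y[t], y[t + 1]]
    return float(total)


def _forward_alphas(P: np.ndarray, A: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    alpha = np.zeros((n, K))
    alpha[0] = P[0] + A[START, :K]
    for t in range(1, n):
        alpha[t] = P[t] + logsumexp(alpha[t - 1][:, None] + A[:K, :K], axis=0)
    return alpha


def log_partition(P: np.ndarray, A: np.ndarray) -> float:
    """log sum over all 3^n label paths of exp(path score), computed in log space."""
    alpha = _forward_alphas(P, A)
    return float(logsumexp(alpha[-1] + A[:K, STOP]))


def viterbi_decode(
    P: np.ndarray, A: np.ndarray, *, constrain_bio: bool = False
) -> tuple[list[int], float]:
    """Highest-scoring label path and its score (max-product DP).

    Ties break toward the lower label index (B < I < O).  With
    ``constrain_bio`` the O→I transition is forbidden at decode time.
    """
    if constrain_bio:
        A = A.copy()
        A[LABELS.index("O"), LABELS.index("I")] = -np.inf
    n = P.shape[0]
    delta = P[0] + A[START, :K]
    back = np.zeros((n, K), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + A[:K, :K]  # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index wins
        delta = P[t] + cand[back[t], np.arange(K)]
    final = delta + A[:K, STOP]
    y = [int(np.argmax(final))]
    for t in range(n - 1, 0, -1):
        y.append(int(back[t, y[-1]]))
    y.reverse()
    return y, float(final[y[-1]])


def crf_nll(
    P: np.ndarray, A: np.ndarray, gold: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log-likelihood  log Z - s(X, y_gold)  and its gradients.

    Returns ``(loss, dP, dA)`` where the gradients are expectation-minus-
    observation terms from the forward-backward marginals.
    """
    n = P.shape[0]
    gold = list(gold)
    if any(not 0 <= g < K for g in gold):
        raise ValueError(f"illegal gold labels {gold}")
    alpha = _forward_alphas(P, A)
    logZ = float(logsumexp(alpha[-1] + A[:K, STOP]))

    beta = np.zeros((n, K))
    beta[-1] = A[:K, STOP]
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(A[:K, :K] + (P[t + 1] + beta[t + 1])[None, :], axis=1)

    unary = np.exp(alpha + beta - logZ)  # p(y_t = j | X)
    dP = unary.copy()
    dP[np.arange(n), gold] -= 1.0

    dA = np.zeros_like(A)
    dA[START, :K] = unary[0]
    dA[START, gold[0]] -= 1.0
    dA[:K, STOP] = unary[-1]
    dA[gold[-1], STOP] -= 1.0
    for t in range(n - 1):
        pair = np.exp(
            alpha[t][:, None] + A[:K, :K] + (P[t + 1] + beta[t + 1])[None, :] - logZ
        )
        dA[:K, :K] += pair
        dA[gold[t], gold[t + 1]] -= 1.0

    loss = logZ - sequence_score(P, A, gold)
    return loss, dP, dA


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class TaggerConfig:
    """Tagger hyper-parameters.

    Defaults follow the tuned setting for this architecture: 200-dimensional
    word vectors, 100 hidden units per LSTM direction, plain SGD, and input
    dropout (rate 0.5) applied to embedded tokens during training only.
    """

    word_dim: int = 200
    hidden_dim: int = 100
    dropout: float = 0.5
    #: probability of replacing a token with UNK during training, so the
    #: UNK embedding learns a context-driven representation for OOV words
    word_dropout: float = 0.05
    learning_rate: float = 0.05
    lr_decay: float = 0.0  # per-epoch multiplicative decay; 0 disables
    epochs: int = 30
    clip_norm: float = 5.0
    seed: int = 0
    use_bilstm: bool = True
    use_crf: bool = True
    lowercase: bool = True
    min_count: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.hidden_dim < 1 or self.word_dim < 1:
            raise ValueError("dimensions must be >= 1")


@dataclass
class TaggerModel:
    """All trainable state of the Bi-LSTM-CRF tagger."""

    config: TaggerConfig
    words: list[str]  # index 0 is the UNK token
    embedding: np.ndarray  # |V| x D
    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    emission_W: np.ndarray  # 3 x (2H or D)
    emission_b: np.ndarray  # 3
    transitions: np.ndarray  # 5 x 5 with START/STOP
    label_order: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.words)}

    @classmethod
    def init(
        cls,
        words: Sequence[str],
        config: TaggerConfig,
        pretrained: EmbeddingModel | None = None,
    ) -> "TaggerModel":
        config.validate()
        rng = np.random.default_rng(config.seed)
        vocab = [UNK] + [w for w in words if w != UNK]
        D, H = config.word_dim, config.hidden_dim
        emb = (rng.random((len(vocab), D)) - 0.5) / D
        if pretrained is not None:
            if pretrained.dimension != D:
                raise ValueError(
                    f"pretrained dimension {pretrained.dimension} != word_dim {D}"
                )
            for i, w in enumerate(vocab):
                if w in pretrained.vocab:
                    emb[i] = pretrained.vector(w)
        ctx_dim = 2 * H if config.use_bilstm else D

        def glorot(rows, cols):
            limit = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-limit, limit, size=(rows, cols))

        return cls(
            config=config,
            words=vocab,
            embedding=emb,
            forward_cell=LSTMCellParams.init(D, H, rng),
            backward_cell=LSTMCellParams.init(D, H, rng),
            emission_W=glorot(K, ctx_dim),
            emission_b=np.zeros(K),
            transitions=np.zeros((K + 2, K + 2)),
        )

    def word_ids(self, words: Iterable[str]) -> np.ndarray:
        lookup = (
            (w.lower() for w in words) if self.config.lowercase else iter(words)
        )
        return np.asarray([self._index.get(w, 0) for w in lookup], dtype=np.intp)

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name → array view of every trainable parameter."""
        params = {"embedding": self.embedding}
        if self.config.use_bilstm:
            for side, cell in (("fwd", self.forward_cell), ("bwd", self.backward_cell)):
                for name, arr in cell.arrays().items():
                    params[f"{side}.{name}"] = arr
        params["emission_W"] = self.emission_W
        params["emission_b"] = self.emission_b
        if self.config.use_crf:
            params["transitions"] = self.transitions
        return params


def nll_loss(
    model: TaggerModel,
    word_ids: np.ndarray,
    gold: Sequence[int],
    *,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Sentence NLL and gradients for every trainable parameter.

    With the CRF enabled the loss is the path NLL (log Z − gold score);
    without it, the per-token softmax cross-entropy over emission rows.
    ``dropout_mask`` (n×D), if given, multiplies the embedded inputs.
    """
    xs = model.embedding[word_ids]
    if dropout_mask is not None:
        xs = xs * dropout_mask
    grads: dict[str, np.ndarray] = {}

    if model.config.use_bilstm:
        hf, cf, of = _run_direction(xs, model.forward_cell, reverse=False)
        hb, cb, ob = _run_direction(xs, model.backward_cell, reverse=True)
        context = np.concatenate([hf, hb], axis=1)
    else:
        context = xs
    P = emission_scores(context, model)

    if model.config.use_crf:
        loss, dP, dA = crf_nll(P, model.transitions, gold)
        grads["transitions"] = dA
    else:
        shifted = P - P.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        n = P.shape[0]
        loss = -float(np.log(probs[np.arange(n), gold] + 1e-300).sum())
        dP = probs.copy()
        dP[np.arange(n), gold] -= 1.0

    grads["emission_W"] = dP.T @ context
    grads["emission_b"] = dP.sum(axis=0)
    dcontext = dP @ model.emission_W

    if model.config.use_bilstm:
        H = model.config.hidden_dim
        gf, dxf = _direction_backward(model.forward_cell, cf, of, dcontext[:, :H])
        gb, dxb = _direction_backward(model.backward_cell, cb, ob, dcontext[:, H:])
        for name, arr in gf.items():
            grads[f"fwd.{name}"] = arr
        for name, arr in gb.items():
            grads[f"bwd.{name}"] = arr
        dxs = dxf + dxb
    else:
        dxs = dcontext.copy()

    if dropout_mask is not None:
        dxs = dxs * dropout_mask
    demb = np.zeros_like(model.embedding)
    np.add.at(demb, word_ids, dxs)
    grads["embedding"] = demb
    return loss, grads


# ---------------------------------------------------------------------------
# Sentence extraction & decoding
# ---------------------------------------------------------------------------

def doc_to_sentences(
    doc: AnnotatedDocument,
) -> list[tuple[list[Token], list[str]]]:
    """Split a document into sentences of (tokens, BIO tags).

    Token offsets stay global (into ``doc.text``) so decoded tags map back
    to character-offset mentions.
    """
    text = doc.text
    tokens = tokenize(text)
    tags = mentions_to_bio(tokens, doc.mentions)
    sentences: list[tuple[list[Token], list[str]]] = []
    for lo, hi in split_sentences(text):
        idx = [i for i, t in enumerate(tokens) if t.start >= lo and t.end <= hi]
        if idx:
            sentences.append(([tokens[i] for i in idx], [tags[i] for i in idx]))
    return sentences


def tag_document(
    model: TaggerModel, doc: AnnotatedDocument, *, constrain_bio: bool = False
) -> list[Mention]:
    """Decode BIO labels for every sentence and return predicted mentions."""
    text = doc.text
    mentions: list[Mention] = []
    for tokens, _ in doc_to_sentences(doc):
        ids = model.word_ids(t.text for t in tokens)
        xs = model.embedding[ids]
        context = bilstm_encode(xs, model) if model.config.use_bilstm else xs
        P = emission_scores(context, model)
        if model.config.use_crf:
            y, _ = viterbi_decode(P, model.transitions, constrain_bio=constrain_bio)
        else:
            y = list(np.argmax(P, axis=1))
        tags = [LABELS[j] for j in y]
        mentions.extend(bio_to_mentions(tokens, tags, text=text))
    return mentions


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _mention_f1(model: TaggerModel, docs: Sequence[AnnotatedDocument]) -> float:
    from .evaluation import match_mentions, prf

    tp = fp = fn = 0
    for doc in docs:
        a, b, c = match_mentions(doc.mentions, tag_document(model, doc))
        tp, fp, fn = tp + a, fp + b, fn + c
    return prf(tp, fp, fn)[2]


def train_tagger(
    train_docs: Sequence[AnnotatedDocument],
    dev_docs: Sequence[AnnotatedDocument] | None,
    embeddings: EmbeddingModel | None,
    config: TaggerConfig | None = None,
    *,
    log: list[dict] | None = None,
) -> TaggerModel:
    """Train the tagger with sentence-level SGD.

    Input dropout is applied to embedded tokens during training only.  If
    dev documents are given, the parameters with the best dev mention F1
    are returned; otherwise the final parameters.  Deterministic for a
    fixed seed under single-threaded execution.
    """
    config = config or TaggerConfig()
    config.validate()
    if not train_docs:
        raise ValueError("empty training set")

    sentences = [s for doc in train_docs for s in doc_to_sentences(doc)]
    counts: dict[str, int] = {}
    for tokens, _ in sentences:
        for t in tokens:
            w = t.text.lower() if config.lowercase else t.text
            counts[w] = counts.get(w, 0) + 1
    words = sorted(
        (w for w, c in counts.items() if c >= config.min_count),
        key=lambda w: (-counts[w], w),
    )
    model = TaggerModel.init(words, config, pretrained=embeddings)

    encoded = [
        (model.word_ids(t.text for t in toks), [LABELS.index(t) for t in tags])
        for toks, tags in sentences
    ]
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    best_f1, best_params = -1.0, None
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(len(encoded))
        total_loss = 0.0
        for si in order:
            ids, gold = encoded[si]
            if len(ids) == 0:
                continue
            if config.word_dropout > 0:
                ids = np.where(
                    rng.random(len(ids)) < config.word_dropout, 0, ids
                )
            mask = None
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                mask = (rng.random((len(ids), config.word_dim)) < keep) / keep
            loss, grads = nll_loss(model, ids, gold, dropout_mask=mask)
            total_loss += loss
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            scale = lr * (config.clip_norm / norm if norm > config.clip_norm else 1.0)
            for name, g in grads.items():
                params[name] -= scale * g
        record = {"epoch": epoch, "loss": total_loss / max(1, len(encoded)), "lr": lr}
        if dev_docs:
            f1 = _mention_f1(model, dev_docs)
            record["dev_f1"] = f1
            if f1 > best_f1:
                best_f1 = f1
                best_params = {k: v.copy() for k, v in params.items()}
        if log is not None:
            log.append(record)
        if config.lr_decay > 0:
            lr *= 1.0 - config.lr_decay
    if best_params is not None:
        for name, arr in params.items():
            arr[...] = best_params[name]
    return model


# ---------------------------------------------------------------------------
# Checkpoints (self-describing JSON container)
# ---------------------------------------------------------------------------

def save_tagger(model: TaggerModel, path: str | Path) -> None:
    payload = {
        "format": "disner-tagger/1",
        "config": asdict(model.config),
        "label_order": list(model.label_order),
        "words": model.words,
        "arrays": {
            name: arr.tolist() for name, arr in model.parameters().items()
        },
        "transitions": model.transitions.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_tagger(path: str | Path) -> TaggerModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "disner-tagger/1":
        raise ValueError(f"not a tagger checkpoint: {path}")
    config = TaggerConfig(**payload["config"])
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in payload["arrays"].items()}
    H, D = config.hidden_dim, config.word_dim

    def cell(prefix: str) -> LSTMCellParams:
        if config.use_bilstm:
            return LSTMCellParams(**{
                name: arrays[f"{prefix}.{name}"] for name in _CELL_FIELDS
            })
        rng = np.random.default_rng(config.seed)
        return LSTMCellParams.init(D, H, rng)

    model = TaggerModel(
        config=config,
        words=list(payload["words"]),
        embedding=arrays["embedding"],
        forward_cell=cell("fwd"),
        backward_cell=cell("bwd"),
        emission_W=arrays["emission_W"],
        emission_b=arrays["emission_b"],
        transitions=np.asarray(payload["transitions"], dtype=np.float64),
        label_order=tuple(payload["label_order"]),
    )
    return model
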