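"""Skip-gram word embeddings trained with negative sampling (NEG).

The model keeps two vector tables: input vectors v_w for center words and
output vectors v'_c for context words.  The score of a (center, context)
pair is the inner product s(w, c) = v_w . v'_c, and each observed pair is
contrasted against k words drawn from a noise distribution Q(w) by
maximizing

    L(w, c) = log sigma(s(w, c)) + sum_{i=1..k} log sigma(-s(w_i, c))

with stochastic gradient ascent.  Q(w) is the unigram distribution raised
to a power (0.75 by default), the standard NEG choice.

Everything is plain NumPy and single-threaded; a fixed seed makes training
bit-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Vocabulary",
    "EmbeddingModel",
    "NoiseDistribution",
    "SkipgramConfig",
    "build_vocab",
    "noise_distribution",
    "pair_score",
    "neg_objective",
    "neg_objective_grad",
    "train_skipgram",
    "cosine_similarity",
    "nearest_neighbors",
]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def _log_sigmoid(x):
    # log sigma(x) = -log(1 + e^-x), stable on both tails
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))


@dataclass(frozen=True)
class Vocabulary:
    """Ordered word list with occurrence counts (descending count, ties lexicographic)."""

    words: tuple[str, ...]
    counts: tuple[int, ...]
    min_count: int = 1

    def __post_init__(self) -> None:
        if len(self.words) != len(set(self.words)):
            raise ValueError("duplicate words in vocabulary")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    @property
    def index(self) -> dict[str, int]:
        if not hasattr(self, "_index"):
            object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})
        return self._index  # type: ignore[attr-defined]


@dataclass
class EmbeddingModel:
    """Vocabulary plus input (center) and output (context) vector tables."""

    vocab: Vocabulary
    input_vectors: np.ndarray  # |V| x D
    output_vectors: np.ndarray  # |V| x D

    def __post_init__(self) -> None:
        if self.input_vectors.shape != self.output_vectors.shape:
            raise ValueError("input/output tables must share a shape")
        if not (np.isfinite(self.input_vectors).all() and np.isfinite(self.output_vectors).all()):
            raise ValueError("non-finite entries in embedding tables")

    @property
    def dimension(self) -> int:
        return self.input_vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.input_vectors[self.vocab.index[word]]
        except KeyError:
            raise KeyError(f"word not in vocabulary: {word!r}") from None


@dataclass(frozen=True)
class NoiseDistribution:
    """Q(w) ∝ count(w)^power over the vocabulary, normalized."""

    probabilities: np.ndarray
    power: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(len(self.probabilities), size=size, p=self.probabilities)


def build_vocab(token_stream: Iterable[str], min_count: int = 1) -> Vocabulary:
    """Count tokens and keep those with count >= ``min_count``.

    Ordering is deterministic: descending count, ties broken lexicographically.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = Counter(token_stream)
    kept = sorted(
        ((w, c) for w, c in counts.items() if c >= min_count),
        key=lambda wc: (-wc[1], wc[0]),
    )
    return Vocabulary(
        words=tuple(w for w, _ in kept),
        counts=tuple(c for _, c in kept),
        min_count=min_count,
    )


def noise_distribution(vocab: Vocabulary, power: float = 0.75) -> NoiseDistribution:
    """Unigram-to-a-power noise distribution for negative sampling."""
    if len(vocab) == 0:
        raise ValueError("cannot build a noise distribution over an empty vocabulary")
    if power < 0:
        raise ValueError("power must be >= 0")
    weights = np.asarray(vocab.counts, dtype=np.float64) ** power
    return NoiseDistribution(probabilities=weights / weights.sum(), power=power)


def pair_score(center_index: int, context_index: int, model: EmbeddingModel) -> float:
    """Inner product of the center's input vector with the context's output vector."""
    v = model.input_vectors[center_index]
    v_out = model.output_vectors[context_index]
    return float(v @ v_out)


def neg_objective(
    center: int, context: int, negatives: Sequence[int], model: EmbeddingModel
) -> float:
    """The NEG objective for one positive pair and its sampled negatives.

    log sigma(s(center, context)) + sum_i log sigma(-s(neg_i, context)),
    an objective to *maximize*.  An empty negative list yields only the
    positive term.
    """
    total = float(_log_sigmoid(pair_score(center, context, model)))
    for neg in negatives:
        total += float(_log_sigmoid(-pair_score(neg, context, model)))
    return total


def neg_objective_grad(
    center: int, context: int, negatives: Sequence[int], model: EmbeddingModel
):
    """Analytic gradient of :func:`neg_objective` wrt the touched vectors.

    Returns ``(grad_input, grad_output)`` as dicts mapping row index to a
    D-vector; rows hit multiple times (repeated negatives) accumulate.
    """
    v_ctx = model.output_vectors[context]
    grad_in: dict[int, np.ndarray] = {}
    grad_out: dict[int, np.ndarray] = {context: np.zeros(model.dimension)}

    g_pos = 1.0 - _sigmoid(pair_score(center, context, model))
    grad_in[center] = g_pos * v_ctx
    grad_out[context] = grad_out[context] + g_pos * model.input_vectors[center]

    for neg in negatives:
        g_neg = -_sigmoid(pair_score(neg, context, model))
        grad_in[neg] = grad_in.get(neg, np.zeros(model.dimension)) + g_neg * v_ctx
        grad_out[context] = grad_out[context] + g_neg * model.input_vectors[neg]
    return grad_in, grad_out


@dataclass
class SkipgramConfig:
    """Training hyper-parameters for NEG skip-gram.

    ``k_negatives`` defaults to 5, the small-corpus end of the usual [5, 20]
    guidance; window, epochs, and the linearly decayed learning rate are the
    conventional defaults for this family of models.
    """

    dimension: int = 200
    window: int = 5
    k_negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 0.0001
    min_count: int = 1
    noise_power: float = 0.75
    subsample: float = 0.0  # frequent-word subsampling threshold; 0 disables
    seed: int = 0

    def validate(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.k_negatives < 0:
            raise ValueError("k_negatives must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def train_skipgram(
    corpus: Sequence[Sequence[str]], config: SkipgramConfig | None = None
) -> EmbeddingModel:
    """Train NEG skip-gram embeddings on tokenized sentences.

    For every position t and every context offset j in [-window, window],
    j != 0 (fixed window, truncated at sentence edges), one positive update
    and ``k_negatives`` noise-sample updates ascend the NEG objective.
    Deterministic for a fixed seed.
    """
    config = config or SkipgramConfig()
    config.validate()
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("empty corpus")

    vocab = build_vocab((w for sent in corpus for w in sent), config.min_count)
    if len(vocab) == 0:
        raise ValueError("no word reaches min_count")
    noise = noise_distribution(vocab, config.noise_power)
    rng = np.random.default_rng(config.seed)

    dim = config.dimension
    inputs = (rng.random((len(vocab), dim)) - 0.5) / dim
    outputs = np.zeros((len(vocab), dim))

    index = vocab.index
    encoded = [
        np.asarray([index[w] for w in sent if w in index], dtype=np.int64)
        for sent in corpus
    ]
    encoded = [s for s in encoded if len(s) > 0]

    total_counts = np.asarray(vocab.counts, dtype=np.float64)
    keep_prob = None
    if config.subsample > 0:
        freq = total_counts / total_counts.sum()
        keep_prob = np.minimum(1.0, np.sqrt(config.subsample / freq))

    n_updates = config.epochs * sum(len(s) for s in encoded)
    lr0 = config.learning_rate
    lr_min = min(config.min_learning_rate, lr0)
    done = 0
    for _epoch in range(config.epochs):
        for sent in encoded:
            if keep_prob is not None:
                sent = sent[rng.random(len(sent)) < keep_prob[sent]]
            n = len(sent)
            for t in range(n):
                lr = max(lr_min, lr0 * (1.0 - done / n_updates))
                done += 1
                center = sent[t]
                lo, hi = max(0, t - config.window), min(n, t + config.window + 1)
                for j in range(lo, hi):
                    if j == t:
                        continue
                    context = sent[j]
                    negatives = noise.sample(rng, config.k_negatives)
                    v_ctx = outputs[context].copy()
                    # positive pair: ascend log sigma(s)
                    g = 1.0 - _sigmoid(inputs[center] @ v_ctx)
                    outputs[context] += lr * g * inputs[center]
                    inputs[center] += lr * g * v_ctx
                    # negatives: ascend log sigma(-s), sequential SGD updates
                    for neg in negatives:
                        g = -_sigmoid(inputs[neg] @ outputs[context])
                        delta_out = lr * g * inputs[neg]
                        inputs[neg] += lr * g * outputs[context]
                        outputs[context] += delta_out
    return EmbeddingModel(vocab=vocab, input_vectors=inputs, output_vectors=outputs)


def cosine_similarity(word_a: str, word_b: str, model: EmbeddingModel) -> float:
    """Cosine similarity of two words over the input-vector table."""
    va, vb = model.vector(word_a), model.vector(word_b)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(va @ vb / denom)


def nearest_neighbors(
    word: str, model: EmbeddingModel, top_n: int = 10
) -> list[tuple[str, float]]:
    """Top-n words by cosine similarity, descending, ties lexicographic, query excluded."""
    query = model.vector(word)
    qn = np.linalg.norm(query)
    norms = np.linalg.norm(model.input_vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = model.input_vectors @ query / np.where(norms * qn > 0, norms * qn, np.inf)
    ranked = sorted(
        (
            (w, float(sims[i]))
            for i, w in enumerate(model.vocab.words)
            if w != word
        ),
        key=lambda ws: (-ws[1], ws[0]),
    )
    return ranked[:top_n]
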