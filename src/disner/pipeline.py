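"""End-to-end pipeline: embeddings → Bi-LSTM-CRF tagger → abbreviation merge → evaluation.

The :class:`RunConfig` gathers every knob of the full system: the word and
hidden dimensions, which components are enabled (each ablation — no word
embeddings, no Bi-LSTM, no CRF, no abbreviation merge — is reachable by a
flag), dropout, optimizer settings, and the seeds.  A resolved config is
hashed and the hash embedded in every output file header, so a run is
identifiable from its artifacts; identical config + seed + single thread
reproduces outputs bit-for-bit.

The "-Bi-LSTM" ablation replaces the encoder with a per-token affine
classifier over the embedded word, so the CRF still receives an n×3
emission matrix.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .abbrev import abbreviation_labels, merge_labels, resolve_pairs
from .corpus_io import AnnotatedDocument, read_pubtator
from .embeddings import EmbeddingModel, SkipgramConfig, train_skipgram
from .evaluation import BootstrapReport, EvalReport, bootstrap_f1, evaluate_documents
from .tagger import TaggerConfig, TaggerModel, tag_document, train_tagger

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Fully resolved settings for one pipeline run.

    Precedence when building one: built-in defaults, then a YAML config
    file, then command-line flags.
    """

    # architecture (tuned defaults for this model family)
    word_dim: int = 200
    hidden_dim: int = 100
    bidirectional: bool = True
    use_embeddings: bool = True
    use_crf: bool = True
    use_abbrev: bool = True
    input_dropout: float = 0.5
    optimizer: str = "sgd"
    learning_rate: float = 0.05
    epochs: int = 30
    constrain_bio: bool = False
    # embeddings stage
    embedding_window: int = 5
    embedding_negatives: int = 5
    embedding_epochs: int = 5
    # reproducibility
    seed: int = 0
    threads: int = 1
    # inputs
    train_path: str | None = None
    dev_path: str | None = None
    test_path: str | None = None
    embedding_corpus_path: str | None = None
    evaluate: bool = True
    bootstrap_rounds: int = 0
    bootstrap_level: float = 0.95

    def validate(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.threads != 1:
            raise ValueError("only single-threaded execution is supported")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def tagger_config(self) -> TaggerConfig:
        return TaggerConfig(
            word_dim=self.word_dim,
            hidden_dim=self.hidden_dim,
            dropout=self.input_dropout,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed,
            use_bilstm=self.bidirectional,
            use_crf=self.use_crf,
        )


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """defaults ← YAML file ← keyword overrides."""
    settings: dict = {}
    if path is not None:
        import yaml

        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        settings.update(loaded)
    settings.update({k: v for k, v in overrides.items() if v is not None})
    config = RunConfig(**settings)
    config.validate()
    return config


@dataclass
class PipelineResult:
    config: RunConfig
    tagged_docs: list[AnnotatedDocument]
    report: EvalReport | None
    bootstrap: BootstrapReport | None
    embeddings: EmbeddingModel | None
    model: TaggerModel
    log: list[dict] = field(default_factory=list)


def _load(path: str | None) -> list[AnnotatedDocument] | None:
    if path is None:
        return None
    with open(path, encoding="utf-8") as fh:
        return read_pubtator(fh)


def predict_document(
    model: TaggerModel,
    doc: AnnotatedDocument,
    *,
    use_abbrev: bool = True,
    constrain_bio: bool = False,
) -> AnnotatedDocument:
    """Tag one document, optionally merging abbreviation-derived mentions."""
    tagged = tag_document(model, doc, constrain_bio=constrain_bio)
    if use_abbrev:
        pairs = resolve_pairs(doc.text)
        abbrev_set = abbreviation_labels(doc, tagged, pairs)
        tagged = merge_labels(tagged, abbrev_set)
    return doc.with_mentions(tagged)


def run_pipeline(
    config: RunConfig,
    *,
    train_docs: Sequence[AnnotatedDocument] | None = None,
    dev_docs: Sequence[AnnotatedDocument] | None = None,
    test_docs: Sequence[AnnotatedDocument] | None = None,
    embedding_corpus: Sequence[Sequence[str]] | None = None,
) -> PipelineResult:
    """Execute the staged pipeline and return tagged documents plus metrics.

    Documents may be passed directly (tests) or loaded from the configured
    paths.  Evaluation requires gold mentions on the test documents.
    """
    config.validate()
    log: list[dict] = []
    train_docs = list(train_docs) if train_docs is not None else _load(config.train_path)
    dev_docs = list(dev_docs) if dev_docs is not None else _load(config.dev_path)
    test_docs = list(test_docs) if test_docs is not None else _load(config.test_path)
    if not train_docs:
        raise ValueError("pipeline requires training documents")
    if test_docs is None:
        raise ValueError("pipeline requires test documents to tag")
    if config.evaluate and not any(d.mentions for d in test_docs):
        raise ValueError(
            "evaluation requested but the test documents carry no gold mentions"
        )

    embeddings = None
    if config.use_embeddings and (
        embedding_corpus is not None or config.embedding_corpus_path
    ):
        t0 = time.perf_counter()
        if embedding_corpus is None:
            with open(config.embedding_corpus_path, encoding="utf-8") as fh:
                embedding_corpus = [line.split() for line in fh if line.strip()]
        embeddings = train_skipgram(
            embedding_corpus,
            SkipgramConfig(
                dimension=config.word_dim,
                window=config.embedding_window,
                k_negatives=config.embedding_negatives,
                epochs=config.embedding_epochs,
                seed=config.seed,
            ),
        )
        log.append({
            "stage": "embeddings", "seconds": time.perf_counter() - t0,
            "seed": config.seed, "vocab": len(embeddings.vocab),
        })

    t0 = time.perf_counter()
    history: list[dict] = []
    model = train_tagger(
        train_docs, dev_docs, embeddings, config.tagger_config(), log=history
    )
    log.append({
        "stage": "tagger", "seconds": time.perf_counter() - t0,
        "seed": config.seed, "sentences": sum(1 for _ in train_docs),
        "epochs": config.epochs, "history": history,
    })

    t0 = time.perf_counter()
    tagged = [
        predict_document(
            model, doc,
            use_abbrev=config.use_abbrev, constrain_bio=config.constrain_bio,
        )
        for doc in test_docs
    ]
    log.append({
        "stage": "tag+abbrev", "seconds": time.perf_counter() - t0,
        "documents": len(tagged),
        "mentions": sum(len(d.mentions) for d in tagged),
    })

    report = bootstrap = None
    if config.evaluate:
        gold = [d.mentions for d in test_docs]
        pred = [d.mentions for d in tagged]
        report = evaluate_documents(gold, pred)
        if config.bootstrap_rounds > 0:
            bootstrap = bootstrap_f1(
                gold, pred,
                rounds=config.bootstrap_rounds,
                level=config.bootstrap_level,
                seed=config.seed,
            )
    return PipelineResult(
        config=config, tagged_docs=tagged, report=report,
        bootstrap=bootstrap, embeddings=embeddings, model=model, log=log,
    )
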