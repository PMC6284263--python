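"""Deterministic synthetic corpora for end-to-end testing without downloads.

Two generators are provided:

* :func:`generate_ner_corpus` — annotated abstracts whose sentences are
  built from templates.  Disease names come from a generated lexicon that
  combines Greco-Latin roots and affixes (``hemo-chromatosis``-style
  single words, hyphenated compounds, and 2–4-word forms with modifiers),
  so morphology and out-of-vocabulary handling are exercised.  With a
  configurable probability a document introduces a mention as a
  ``Long Form (SF)`` definition and reuses the short form later; documents
  may also define *non-disease* procedure abbreviations whose short forms
  collide with disease short forms across documents, reproducing the
  abbreviation-ambiguity problem the merge layer addresses.  All gold
  offsets are character-exact.

* :func:`generate_embedding_corpus` — a token stream with planted word
  clusters: words of one cluster are emitted in shared sentence contexts,
  so skip-gram training must place them nearer each other than
  cross-cluster pairs.

Both are byte-reproducible for a fixed seed.  The default document shape
(10 sentences per abstract, about 21 words per sentence) mirrors typical
PubMed disease-corpus statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedDocument, Mention

__all__ = [
    "FixtureConfig",
    "DiseaseName",
    "make_disease_lexicon",
    "generate_ner_corpus",
    "generate_embedding_corpus",
]

_MODIFIERS = (
    "recurrent", "chronic", "acute", "congenital",
    "familial", "juvenile", "severe", "progressive",
)
_ROOTS = (
    "hemo", "neuro", "cardio", "nephro", "hepato", "osteo", "myelo",
    "dermato", "gastro", "entero", "angio", "arthro", "broncho",
    "cephalo", "glyco", "fibro", "lipo", "melano", "thrombo", "adeno",
)
_SUFFIXES = (
    "chromatosis", "pathy", "itis", "oma", "osis",
    "plasia", "sclerosis", "dystrophy", "megaly", "algia",
)
_HEADS = (
    "syndrome", "disease", "disorder", "deficiency",
    "carcinoma", "anemia", "lymphoma",
)

#: procedure words by initial, used to build non-disease long forms whose
#: short forms collide with disease short forms
_PROC_WORDS = {
    "a": ("automated", "acquisition", "analysis"),
    "b": ("baseline", "biopsy", "blotting"),
    "c": ("computed", "contrast", "cytometry"),
    "d": ("digital", "density", "detection"),
    "e": ("enhanced", "electrode", "evaluation"),
    "f": ("functional", "frequency", "filtration"),
    "g": ("guided", "gradient", "genotyping"),
    "h": ("helical", "histology", "hybridization"),
    "j": ("joint", "junction", "judgment"),
    "l": ("longitudinal", "luminance", "labeling"),
    "m": ("magnetic", "mobility", "monitoring"),
    "n": ("normalized", "nuclear", "navigation"),
    "o": ("optical", "oscillation", "observation"),
    "p": ("portable", "perfusion", "profiling"),
    "r": ("rapid", "resonance", "recording"),
    "s": ("serial", "spectral", "screening"),
    "t": ("targeted", "tissue", "tomography"),
}

_FILLER = (
    "the", "of", "in", "and", "with", "for", "during", "between", "among",
    "patients", "subjects", "cohort", "study", "levels", "values", "samples",
    "baseline", "clinical", "observed", "reported", "measured", "analysis",
    "significant", "treatment", "response", "outcome", "period", "group",
    "controls", "criteria", "assessment", "protocol", "records", "data",
    "findings", "results", "moderate", "elevated", "reduced", "stable",
)

_MENTION_TEMPLATES = (
    ("We investigated", None, "in a prospective cohort of adult patients"),
    ("Patients diagnosed with", None, "showed significantly elevated serum marker levels"),
    ("The clinical presentation of", None, "was confirmed by histological examination"),
    ("Genetic analysis revealed that", None, "segregates with a dominant inheritance pattern"),
    ("Early detection of", None, "remains difficult because initial symptoms are nonspecific"),
    ("Several families affected by", None, "were enrolled after informed consent"),
)

_FILLER_TEMPLATES = (
    "The remaining participants completed the questionnaire and returned for follow-up visits",
    "Statistical comparisons used nonparametric tests with correction for multiple testing",
    "Samples were collected at baseline and processed within two hours of acquisition",
    "Informed consent was obtained from all participants before any study procedure",
    "No serious adverse events were recorded during the observation period",
)

_REUSE_TEMPLATES = (
    ("The", "group was monitored at regular intervals throughout the study period"),
    ("All", "cases were reviewed independently by two experienced clinicians"),
    ("Follow-up of the", "subgroup continued for an additional twelve months"),
)


@dataclass(frozen=True)
class DiseaseName:
    """A lexicon entry; multi-word names carry a derivable short form."""

    text: str

    @property
    def words(self) -> list[str]:
        return self.text.split(" ")

    @property
    def short_form(self) -> str | None:
        if len(self.words) < 2:
            return None
        return "".join(w[0].upper() for w in self.words)


@dataclass
class FixtureConfig:
    """Shape and randomness of the generated corpora."""

    n_docs: int = 50
    sentences_per_doc: int = 10
    words_per_sentence: int = 21
    seed: int = 0
    disease_lexicon_size: int = 40
    p_multiword: float = 0.5
    p_abbrev_definition: float = 0.3
    p_mention_sentence: float = 0.6
    vocab_size: int = 200
    cluster_count: int = 2
    n_tokens: int = 20000

    def validate(self) -> None:
        for name in ("p_multiword", "p_abbrev_definition", "p_mention_sentence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.sentences_per_doc, self.words_per_sentence,
               self.disease_lexicon_size, self.vocab_size, self.cluster_count) < 1:
            raise ValueError("sizes must be >= 1")
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if self.cluster_count > self.vocab_size:
            raise ValueError("cluster_count cannot exceed vocab_size")


def make_disease_lexicon(config: FixtureConfig) -> list[DiseaseName]:
    """Generate the disease-name lexicon for a configuration (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < config.disease_lexicon_size:
        root = _ROOTS[rng.integers(len(_ROOTS))]
        suffix = _SUFFIXES[rng.integers(len(_SUFFIXES))]
        if suffix[0] in "aeiou" and root.endswith("o"):
            base = root[:-1] + suffix
        else:
            base = root + suffix
        if rng.random() < 0.3:
            base = root + "-" + suffix  # hyphenated compound, kept as one token
        if rng.random() < config.p_multiword:
            words = [base, _HEADS[rng.integers(len(_HEADS))]]
            while len(words) < 4 and rng.random() < 0.4:
                words.insert(0, _MODIFIERS[rng.integers(len(_MODIFIERS))])
            name = " ".join(words)
        else:
            name = base
        if name not in seen:
            seen.add(name)
            names.append(name)
    return [DiseaseName(n) for n in names]


def _procedure_for(sf: str) -> str:
    """A non-disease long form whose initials spell ``sf``."""
    letters = [ch.lower() for ch in sf]
    words = []
    for pos, ch in enumerate(letters):
        pool = _PROC_WORDS.get(ch, ("generic",))
        idx = 0 if pos == 0 else (len(pool) - 1 if pos == len(letters) - 1 else 1)
        words.append(pool[min(idx, len(pool) - 1)])
    return " ".join(words)


class _DocBuilder:
    """Accumulates sentence strings and character-exact gold mentions."""

    def __init__(self) -> None:
        self.sentences: list[str] = []
        self.mentions: list[Mention] = []
        self._cursor = 0  # length of text assembled so far (joined by " ")

    def add(self, parts: Sequence[tuple[str, bool]]) -> None:
        """Add one sentence from (chunk, is_gold_mention) parts.

        Chunks are joined with single spaces and a period is appended.
        A chunk of the form ``(SF)`` with the gold flag marks only the
        inner short form.
        """
        pos = self._cursor if self._cursor == 0 else self._cursor + 1
        start = pos
        words: list[str] = []
        for chunk, is_gold in parts:
            if words:
                pos += 1  # joining space
            if is_gold:
                if chunk.startswith("(") and chunk.endswith(")"):
                    inner = chunk[1:-1]
                    self.mentions.append(
                        Mention(pos + 1, pos + 1 + len(inner), inner, "Disease")
                    )
                else:
                    self.mentions.append(
                        Mention(pos, pos + len(chunk), chunk, "Disease")
                    )
            words.append(chunk)
            pos += len(chunk)
        sentence = " ".join(words) + "."
        self.sentences.append(sentence)
        self._cursor = start + len(sentence)

    def document(self, doc_id: str) -> AnnotatedDocument:
        title = self.sentences[0] if self.sentences else ""
        abstract = " ".join(self.sentences[1:])
        doc = AnnotatedDocument(doc_id, title, abstract, sorted(self.mentions))
        doc.validate()
        return doc


def _pad(parts: list[tuple[str, bool]], rng, target: int) -> list[tuple[str, bool]]:
    """Append filler words until the sentence approaches the target length."""
    n_words = sum(len(chunk.split(" ")) for chunk, _ in parts)
    extra = max(0, target - n_words - 1)
    jitter = int(rng.integers(0, 3)) - 1
    for _ in range(max(0, extra + jitter)):
        parts.append((str(_FILLER[rng.integers(len(_FILLER))]), False))
    return parts


def generate_ner_corpus(config: FixtureConfig) -> list[AnnotatedDocument]:
    """Generate annotated documents with character-exact gold mentions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lexicon = make_disease_lexicon(config)
    multiword = [d for d in lexicon if d.short_form is not None]
    docs: list[AnnotatedDocument] = []
    target = config.words_per_sentence

    for i in range(config.n_docs):
        builder = _DocBuilder()
        specs: list[tuple] = []

        used_sfs: set[str] = set()
        # disease abbreviation definition + later reuse
        if multiword and rng.random() < config.p_abbrev_definition:
            d = multiword[rng.integers(len(multiword))]
            used_sfs.add(d.short_form)
            specs.append(("def", d.text, d.short_form, True))
            for _ in range(int(rng.integers(1, 3))):
                specs.append(("reuse", d.short_form, True))
        # non-disease procedure abbreviation with a colliding short form
        if multiword and rng.random() < config.p_abbrev_definition:
            other = multiword[rng.integers(len(multiword))]
            if other.short_form not in used_sfs:
                proc = _procedure_for(other.short_form)
                specs.append(("def", proc, other.short_form, False))
                specs.append(("reuse", other.short_form, False))

        while len(specs) < config.sentences_per_doc:
            if rng.random() < config.p_mention_sentence:
                d = lexicon[rng.integers(len(lexicon))]
                specs.append(("mention", d.text))
            else:
                specs.append(("filler",))
        specs = specs[: config.sentences_per_doc]
        # keep definitions before their reuses: stable order, shuffle fillers in
        order = rng.permutation(len(specs))
        anchored = [s for s in specs if s[0] in ("def", "reuse")]
        floating = [specs[j] for j in order if specs[j][0] not in ("def", "reuse")]
        slots = sorted(rng.choice(len(specs), size=len(anchored), replace=False))
        final: list[tuple | None] = [None] * len(specs)
        for slot, spec in zip(slots, anchored):
            final[slot] = spec
        fi = iter(floating)
        final = [s if s is not None else next(fi) for s in final]

        for spec in final:
            kind = spec[0]
            if kind == "def":
                _, lf, sf, is_disease = spec
                head, _slot, tail = _MENTION_TEMPLATES[
                    rng.integers(len(_MENTION_TEMPLATES))
                ]
                parts = [(head, False), (lf, is_disease),
                         (f"({sf})", is_disease), (tail, False)]
            elif kind == "reuse":
                _, sf, is_disease = spec
                lead, tail = _REUSE_TEMPLATES[rng.integers(len(_REUSE_TEMPLATES))]
                parts = [(lead, False), (sf, is_disease), (tail, False)]
            elif kind == "mention":
                head, _slot, tail = _MENTION_TEMPLATES[
                    rng.integers(len(_MENTION_TEMPLATES))
                ]
                parts = [(head, False), (spec[1], True), (tail, False)]
            else:
                parts = [(_FILLER_TEMPLATES[rng.integers(len(_FILLER_TEMPLATES))],
                          False)]
            builder.add(_pad(parts, rng, target))
        docs.append(builder.document(str(10000 + i)))
    return docs


def generate_embedding_corpus(config: FixtureConfig) -> list[list[str]]:
    """Token stream (as sentences) with planted word clusters.

    Words are partitioned into ``cluster_count`` clusters; every sentence
    draws all its words from a single cluster, so words sharing a cluster
    share contexts.  The total token count equals ``n_tokens`` exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per = config.vocab_size // config.cluster_count
    clusters = [
        [f"w{c}_{i}" for i in range(per)] for c in range(config.cluster_count)
    ]
    sentences: list[list[str]] = []
    remaining = config.n_tokens
    while remaining > 0:
        c = int(rng.integers(config.cluster_count))
        length = min(remaining, int(rng.integers(8, 13)))
        words = [clusters[c][rng.integers(per)] for _ in range(length)]
        sentences.append(words)
        remaining -= length
    return sentences
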