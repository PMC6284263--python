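"""Corpus formats, tokenization, and the BIO span codec.

Annotated abstracts are exchanged in the PubTator dialect: a ``PMID|t|title``
line, a ``PMID|a|abstract`` line, then zero or more tab-separated annotation
lines ``PMID<TAB>start<TAB>end<TAB>text<TAB>type<TAB>conceptID`` with
character offsets into ``title + " " + abstract``, and a blank line between
documents.  Offsets are 0-based, half-open.  Concept identifiers are carried
as opaque strings and never resolved.

Tokenization is deliberately simple and deterministic: whitespace split with
leading/trailing punctuation detached into their own tokens.  Hyphens and
internal apostrophes are kept, so a compound such as ``insulin-dependent``
stays a single token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "Mention",
    "Token",
    "AnnotatedDocument",
    "CorpusError",
    "ParseError",
    "AnnotationError",
    "read_pubtator",
    "write_pubtator",
    "read_conll",
    "write_conll",
    "tokenize",
    "split_sentences",
    "mentions_to_bio",
    "bio_to_mentions",
    "read_word_vectors",
    "write_word_vectors",
]

BIO_LABELS = ("B", "I", "O")

#: punctuation detached from token edges; hyphens/apostrophes are kept inside
_EDGE_PUNCT = set('.,;:()[]{}"!?')


class CorpusError(ValueError):
    """Base class for corpus-format errors."""


class ParseError(CorpusError):
    """A structurally malformed input line or record."""


class AnnotationError(CorpusError):
    """An annotation whose offsets or text disagree with the document."""


@dataclass(frozen=True, order=True)
class Mention:
    """A character-offset entity span (half-open ``[start, end)``)."""

    start: int
    end: int
    text: str
    label: str = "Disease"
    concept_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid mention offsets ({self.start}, {self.end})"
            )

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Token:
    """A surface token with character offsets into its source string."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.text or self.end - self.start != len(self.text):
            raise CorpusError(f"inconsistent token {self.text!r} at {self.start}")


@dataclass
class AnnotatedDocument:
    """A title+abstract record with character-offset entity mentions.

    Mention offsets index into :attr:`text`, the concatenation
    ``title + " " + abstract``.
    """

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    def validate(self) -> None:
        text = self.text
        seen: set[tuple[int, int]] = set()
        for m in self.mentions:
            if m.end > len(text):
                raise AnnotationError(
                    f"{self.doc_id}: mention ({m.start}, {m.end}) beyond text"
                )
            if text[m.start : m.end] != m.text:
                raise AnnotationError(
                    f"{self.doc_id}: mention text {m.text!r} != document "
                    f"substring {text[m.start:m.end]!r} at ({m.start}, {m.end})"
                )
            if (m.start, m.end) in seen:
                raise AnnotationError(
                    f"{self.doc_id}: duplicate mention span ({m.start}, {m.end})"
                )
            seen.add((m.start, m.end))

    def with_mentions(self, mentions: Iterable[Mention]) -> "AnnotatedDocument":
        return replace(self, mentions=sorted(mentions))


# ---------------------------------------------------------------------------
# PubTator dialect
# ---------------------------------------------------------------------------

def read_pubtator(stream: TextIO | Iterable[str]) -> list[AnnotatedDocument]:
    """Parse PubTator-style records into :class:`AnnotatedDocument` objects.

    Raises :class:`ParseError` for structural problems (missing title or
    abstract line) and :class:`AnnotationError` when an annotation's text
    field disagrees with the substring at its offsets.
    """
    docs: list[AnnotatedDocument] = []
    block: list[tuple[int, str]] = []

    def flush(block: list[tuple[int, str]]) -> None:
        if not block:
            return
        title = abstract = None
        doc_id = None
        mentions: list[Mention] = []
        for lineno, line in block:
            m = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
            if m:
                doc_id, title = m.group(1), m.group(2)
                continue
            m = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
            if m:
                abstract = m.group(2)
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: unrecognized line {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad offsets in {line!r}") from exc
            label = parts[4] if len(parts) > 4 else "Disease"
            concept = parts[5] if len(parts) > 5 else ""
            mentions.append(Mention(start, end, parts[3], label, concept))
        if doc_id is None or title is None:
            raise ParseError("document block missing a title (|t|) line")
        if abstract is None:
            raise ParseError(f"{doc_id}: missing abstract (|a|) line")
        doc = AnnotatedDocument(doc_id, title, abstract, sorted(mentions))
        doc.validate()
        docs.append(doc)

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("#"):  # header/comment lines (e.g. config hash)
            continue
        if not line.strip():
            flush(block)
            block = []
        else:
            block.append((lineno, line))
    flush(block)
    return docs


def write_pubtator(docs: Iterable[AnnotatedDocument], stream: TextIO) -> None:
    """Serialize documents in the PubTator dialect (round-trip stable)."""
    for doc in docs:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions):
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.label}\t{m.concept_id}\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[Token]:
    """Split ``text`` into offset-annotated tokens.

    Whitespace separates tokens; leading and trailing punctuation characters
    from ``.,;:()[]{}"!?`` become single-character tokens of their own.
    Every non-whitespace character lands in exactly one token.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        lo, hi = 0, len(chunk)
        head: list[Token] = []
        tail: list[Token] = []
        while lo < hi and chunk[lo] in _EDGE_PUNCT:
            head.append(Token(chunk[lo], base + lo, base + lo + 1))
            lo += 1
        while hi > lo and chunk[hi - 1] in _EDGE_PUNCT:
            tail.append(Token(chunk[hi - 1], base + hi - 1, base + hi))
            hi -= 1
        tokens.extend(head)
        if hi > lo:
            tokens.append(Token(chunk[lo:hi], base + lo, base + hi))
        tokens.extend(reversed(tail))
    return tokens


_SENT_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences: break after ``.?!`` + space + uppercase."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

def mentions_to_bio(tokens: Sequence[Token], mentions: Sequence[Mention]) -> list[str]:
    """Encode offset mentions as per-token B/I/O labels.

    A token overlapping a mention at all counts as inside it (boundaries are
    snapped outward); the first such token of each mention gets ``B``.
    Overlapping mentions are rejected.
    """
    ordered = sorted(mentions)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise AnnotationError(
                f"overlapping mentions ({a.start},{a.end}) and ({b.start},{b.end})"
            )
    tags = ["O"] * len(tokens)
    for m in ordered:
        first = True
        for idx, tok in enumerate(tokens):
            if tok.start < m.end and m.start < tok.end:
                tags[idx] = "B" if first else "I"
                first = False
    return tags


def bio_to_mentions(
    tokens: Sequence[Token],
    tags: Sequence[str],
    *,
    text: str | None = None,
    label: str = "Disease",
) -> list[Mention]:
    """Decode B/I/O labels back to character-offset mentions.

    Maximal ``B I*`` runs become mentions; an ``I`` with no preceding ``B``
    or ``I`` is repaired to ``B``.  If ``text`` is given, mention surface
    strings are taken from it; otherwise token texts are joined with spaces.
    """
    if len(tokens) != len(tags):
        raise CorpusError(f"{len(tokens)} tokens vs {len(tags)} tags")
    for t in tags:
        if t not in BIO_LABELS:
            raise CorpusError(f"illegal tag {t!r}")
    mentions: list[Mention] = []
    run: list[Token] = []
    for tok, tag in zip(tokens, tags):
        if tag == "B" or (tag == "I" and not run):
            if run:
                mentions.append(_span_mention(run, text, label))
            run = [tok]
        elif tag == "I":
            run.append(tok)
        else:
            if run:
                mentions.append(_span_mention(run, text, label))
            run = []
    if run:
        mentions.append(_span_mention(run, text, label))
    return mentions


def _span_mention(run: list[Token], text: str | None, label: str) -> Mention:
    start, end = run[0].start, run[-1].end
    surface = text[start:end] if text is not None else " ".join(t.text for t in run)
    return Mention(start, end, surface, label)


# ---------------------------------------------------------------------------
# CoNLL dialect
# ---------------------------------------------------------------------------

def write_conll(
    sentences: Iterable[tuple[Sequence[Token], Sequence[str]]], stream: TextIO
) -> None:
    """One ``token<TAB>tag`` line per token, blank line between sentences."""
    for tokens, tags in sentences:
        if len(tokens) != len(tags):
            raise CorpusError("token/tag length mismatch")
        for tok, tag in zip(tokens, tags):
            stream.write(f"{tok.text}\t{tag}\n")
        stream.write("\n")


def read_conll(stream: TextIO | Iterable[str]) -> list[tuple[list[str], list[str]]]:
    """Read sentences as (words, tags) pairs; offsets are not reconstructed."""
    sentences: list[tuple[list[str], list[str]]] = []
    words: list[str] = []
    tags: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if words:
                sentences.append((words, tags))
            words, tags = [], []
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'token<TAB>tag'")
        if parts[1] not in BIO_LABELS:
            raise ParseError(f"line {lineno}: illegal tag {parts[1]!r}")
        words.append(parts[0])
        tags.append(parts[1])
    if words:
        sentences.append((words, tags))
    return sentences


# ---------------------------------------------------------------------------
# word2vec text vectors
# ---------------------------------------------------------------------------

def read_word_vectors(stream: TextIO | Iterable[str]):
    """Read a word2vec text table: header ``V D``, then ``word v1 … vD``.

    Returns ``(words, matrix)`` with ``matrix`` a ``V×D`` float64 array.
    """
    import numpy as np

    it = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        raise ParseError("empty vector file") from None
    try:
        n_words, dim = (int(x) for x in header.split())
    except ValueError as exc:
        raise ParseError(f"bad header {header!r}") from exc
    words: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(it, start=2):
        parts = line.rstrip("\n").split(" ")
        if len(parts) < 2 and not line.strip():
            continue
        word, values = parts[0], parts[1:]
        if len(values) != dim:
            raise ParseError(
                f"line {lineno}: expected {dim} values, got {len(values)}"
            )
        if word in seen:
            raise ParseError(f"line {lineno}: duplicate word {word!r}")
        seen.add(word)
        words.append(word)
        rows.append([float(v) for v in values])
    if len(words) != n_words:
        raise ParseError(f"header declared {n_words} words, found {len(words)}")
    return words, np.asarray(rows, dtype=np.float64).reshape(len(words), dim)


def write_word_vectors(words: Sequence[str], matrix, stream: TextIO) -> None:
    """Write the word2vec text format (round-trips to within 1e-6)."""
    import numpy as np

    mat = np.asarray(matrix, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != len(words):
        raise CorpusError("matrix shape does not match word list")
    stream.write(f"{len(words)} {mat.shape[1]}\n")
    for word, row in zip(words, mat):
        stream.write(word + " " + " ".join(f"{v:.8g}" for v in row) + "\n")
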