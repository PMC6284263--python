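"""Abbreviation (short-form / long-form) detection and the label merge.

Biomedical abstracts define abbreviations as ``Long Form (SF)``.  Matching
a short form back to its long form uses a small ordered battery of
strategies, tried from most to least reliable:

* ``FC``  — each short-form character matches the first character of a
  word in the long form, consecutive from the right.
* ``FCG`` — like FC, but a character may also match the character
  immediately following a non-alphanumeric, non-space character inside a
  word (so ``IDDM`` matches ``insulin-dependent diabetes mellitus``).
* ``FC-skip`` — FC allowing one long-form word to be skipped.

Detected pairs extend the statistical tagger: if a pair's long form
overlaps a tagged disease mention, every token-boundary occurrence of the
short-form string becomes a disease mention, and on any overlap conflict
the abbreviation-derived mention takes precedence over the tagger's.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

from .corpus_io import AnnotatedDocument, Mention, Token, split_sentences, tokenize

__all__ = [
    "AbbrevPair",
    "find_candidates",
    "match_strategy_fc",
    "match_strategy_fcg",
    "match_strategy_fc_skip",
    "resolve_pairs",
    "abbreviation_labels",
    "merge_labels",
]

#: maximum long-form window, in words, for a short form of length L
def _max_window(sf_len: int) -> int:
    return min(2 * sf_len + 2, sf_len + 5)


@dataclass(frozen=True)
class AbbrevPair:
    """A validated short-form / long-form definition site."""

    short_form: Mention
    long_form: Mention
    strategy: str

    def __post_init__(self) -> None:
        if len(self.short_form.text) >= len(self.long_form.text):
            raise ValueError("short form must be shorter than its long form")
        if not self.strategy:
            raise ValueError("strategy identifier must be non-empty")


def _is_sf_candidate(text: str) -> bool:
    return 1 <= len(text) <= 10 and any(ch.isalpha() for ch in text)


def find_candidates(
    text: str,
) -> list[tuple[list[Token], Token]]:
    """Locate ``( SF )`` sites and their preceding long-form windows.

    For each parenthesized single token of 1–10 characters containing at
    least one letter, the candidate window is the preceding words of the
    same sentence, truncated to the relaxed length limit
    ``min(2·|SF| + 2, |SF| + 5)``.  Returns (window tokens, SF token) pairs
    in document order.
    """
    candidates: list[tuple[list[Token], Token]] = []
    sent_spans = split_sentences(text)
    tokens = tokenize(text)
    for k in range(1, len(tokens) - 1):
        if tokens[k - 1].text != "(" or tokens[k + 1].text != ")":
            continue
        sf = tokens[k]
        if not _is_sf_candidate(sf.text):
            continue
        sent = next(
            ((lo, hi) for lo, hi in sent_spans if lo <= sf.start < hi),
            (0, len(text)),
        )
        window = [
            t
            for t in tokens
            if sent[0] <= t.start and t.end <= tokens[k - 1].start
            and any(ch.isalnum() for ch in t.text)
        ]
        limit = _max_window(len(sf.text))
        candidates.append((window[-limit:], sf))
    return candidates


def _sf_chars(sf: str) -> list[str]:
    return [ch.lower() for ch in sf if ch.isalnum()]


def _internal_points(word: str) -> list[str]:
    """FCG match characters inside a word: each character immediately
    following a non-alphanumeric, non-space character (hyphen, slash),
    in left-to-right order."""
    return [
        ch.lower()
        for prev, ch in zip(word, word[1:])
        if not prev.isalnum() and not prev.isspace()
    ]


def _word_can_absorb(word: str, chars: Sequence[str]) -> bool:
    """Can ``word`` supply all of ``chars`` in order, the first from its
    first character and the rest from internal FCG match points?"""
    if not chars or chars[0] != word[0].lower():
        return False
    points = _internal_points(word)
    pi = 0
    for ch in chars[1:]:
        while pi < len(points) and points[pi] != ch:
            pi += 1
        if pi == len(points):
            return False
        pi += 1
    return True


def _match_fcg(sf: str, window: Sequence[Token]) -> tuple[int, int] | None:
    """Align SF characters to consecutive-from-the-right window words,
    each word absorbing >= 1 characters (FCG rule); minimal suffix wins."""
    chars = _sf_chars(sf)
    if not chars or not window:
        return None

    def solve(wi: int, ci: int) -> int | None:
        # chars[0..ci] remain; window[wi] is the next word from the right
        if ci < 0:
            return wi + 1
        if wi < 0:
            return None
        word = window[wi].text
        # prefer absorbing more characters -> fewest words -> minimal suffix
        for q in range(ci + 1, 0, -1):
            if _word_can_absorb(word, chars[ci - q + 1 : ci + 1]):
                start = solve(wi - 1, ci - q)
                if start is not None:
                    return start
        return None

    start_wi = solve(len(window) - 1, len(chars) - 1)
    if start_wi is None:
        return None
    return window[start_wi].start, window[-1].end


def match_strategy_fc(sf: str, window: Sequence[Token]) -> tuple[int, int] | None:
    """First-character strategy: SF chars ↔ first chars of consecutive words."""
    chars = _sf_chars(sf)
    if not chars or len(chars) > len(window):
        return None
    suffix = window[-len(chars) :]
    for ch, tok in zip(chars, suffix):
        if tok.text[0].lower() != ch:
            return None
    return suffix[0].start, suffix[-1].end


def match_strategy_fcg(sf: str, window: Sequence[Token]) -> tuple[int, int] | None:
    """FC generalized: a char may also match after an internal non-alnum
    character (hyphen, slash), so one word can absorb several SF chars."""
    return _match_fcg(sf, window)


def match_strategy_fc_skip(sf: str, window: Sequence[Token]) -> tuple[int, int] | None:
    """Fallback: FC that may skip one long-form word (e.g. a function word).

    The skipped word stays inside the returned span when it falls between
    matched words, so ``DL`` still covers ``disease of liver``.
    """
    if not _sf_chars(sf):
        return None
    for skip in range(len(window) - 2, -1, -1):
        reduced = list(window[:skip]) + list(window[skip + 1 :])
        hit = match_strategy_fc(sf, reduced)
        if hit is not None:
            return hit
    return None


#: strategies in decreasing reliability; first success wins
STRATEGIES: tuple[tuple[str, Callable], ...] = (
    ("FC", match_strategy_fc),
    ("FCG", match_strategy_fcg),
    ("FC-skip", match_strategy_fc_skip),
)


def resolve_pairs(text: str) -> list[AbbrevPair]:
    """Find and validate all definition sites in a document text.

    Strategies are tried in the fixed reliability order; the first that
    validates a candidate wins, and at most one pair is produced per
    parenthesis site.
    """
    pairs: list[AbbrevPair] = []
    for window, sf in find_candidates(text):
        for name, strategy in STRATEGIES:
            hit = strategy(sf.text, window)
            if hit is None:
                continue
            start, end = hit
            lf = Mention(start, end, text[start:end], "LongForm")
            if len(sf.text) >= len(lf.text):
                continue
            pairs.append(
                AbbrevPair(
                    short_form=Mention(sf.start, sf.end, sf.text, "ShortForm"),
                    long_form=lf,
                    strategy=name,
                )
            )
            break
    return pairs


def _occurrences(text: str, needle: str) -> list[tuple[int, int]]:
    """Token-boundary, case-sensitive occurrences of ``needle`` in ``text``."""
    spans = []
    pattern = re.compile(
        r"(?<![0-9A-Za-z])" + re.escape(needle) + r"(?![0-9A-Za-z])"
    )
    for m in pattern.finditer(text):
        spans.append((m.start(), m.end()))
    return spans


def abbreviation_labels(
    doc: AnnotatedDocument,
    tagger_mentions: Sequence[Mention],
    pairs: Sequence[AbbrevPair],
) -> list[Mention]:
    """Disease mentions derived from abbreviation definitions.

    If a pair's long form overlaps a tagged disease mention, every
    token-boundary, case-sensitive occurrence of the short-form string in
    the document (including the defining one) becomes a disease mention.
    Propagation is document-wide.
    """
    text = doc.text
    out: dict[tuple[int, int], Mention] = {}
    for pair in pairs:
        if not any(pair.long_form.overlaps(m) for m in tagger_mentions):
            continue
        for start, end in _occurrences(text, pair.short_form.text):
            out[(start, end)] = Mention(start, end, text[start:end], "Disease")
    return sorted(out.values())


def merge_labels(
    tagger_mentions: Sequence[Mention], abbrev_mentions: Sequence[Mention]
) -> list[Mention]:
    """Union of tagger and abbreviation mentions with abbreviation precedence.

    Where spans overlap with differing extents, the abbreviation-derived
    mention replaces the overlapping tagger mention(s); the output is
    non-overlapping and sorted.  Absence of an abbreviation mention never
    deletes a tagger mention.
    """
    result: list[Mention] = list(dict.fromkeys(abbrev_mentions))
    for m in tagger_mentions:
        if not any(m.overlaps(a) for a in result):
            result.append(m)
    result = sorted(set(result))
    return result
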