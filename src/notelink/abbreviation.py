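"""Dictionary-driven abbreviation detection and context-based expansion.

Disambiguation is zero-shot: no sense-labeled training data is used.
Instead, each candidate expansion carries up to a configured number of
context samples (sentences harvested from a reference corpus by reverse
substitution — sentences that contain the expansion text verbatim).  At
disambiguation time the sentence surrounding a detected abbreviation is
compared, by embedding cosine similarity, against every context sample of
every candidate expansion; the expansion owning the most similar sample
wins, provided the similarity clears a minimum gate.  Below the gate the
abbreviation is left untouched — no similar context justifies an expansion.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


from .embedding import EmbeddingProvider

__all__ = [
    "Expansion",
    "AbbreviationDictionary",
    "AbbreviationMatch",
    "OffsetMap",
    "split_sentences",
    "sentence_containing",
    "harvest_hyphen_pairs",
    "detect",
    "disambiguate",
    "collect_context_samples",
    "expand_all",
]

DEFAULT_MAX_CONTEXT_SAMPLES = 30


@dataclass
class Expansion:
    text: str
    context_samples: list[str] = field(default_factory=list)


@dataclass
class AbbreviationDictionary:
    """Map from abbreviation (normalized key) to its candidate expansions."""

    entries: dict[str, list[Expansion]] = field(default_factory=dict)
    max_context_samples: int = DEFAULT_MAX_CONTEXT_SAMPLES

    @staticmethod
    def normalize_key(abbreviation: str) -> str:
        return abbreviation.strip()

    def add(self, abbreviation: str, expansion_text: str) -> None:
        key = self.normalize_key(abbreviation)
        senses = self.entries.setdefault(key, [])
        if not any(e.text.lower() == expansion_text.lower() for e in senses):
            senses.append(Expansion(text=expansion_text))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AbbreviationDictionary":
        d = cls()
        for abbrev, expansion in pairs:
            d.add(abbrev, expansion)
        return d

    # -- delimited-file persistence ---------------------------------------

    @classmethod
    def load(cls, path: str | Path, delimiter: str = "\t") -> "AbbreviationDictionary":
        d = cls()
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter=delimiter):
                if len(row) >= 2 and row[0].strip():
                    d.add(row[0], row[1])
        return d

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            for abbrev in sorted(self.entries):
                for exp in self.entries[abbrev]:
                    w.writerow([abbrev, exp.text])

    def save_context_samples(self, path: str | Path, delimiter: str = "\t") -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            for abbrev in sorted(self.entries):
                for exp in self.entries[abbrev]:
                    for sample in exp.context_samples:
                        w.writerow([abbrev, exp.text, sample])

    def load_context_samples(self, path: str | Path, delimiter: str = "\t") -> None:
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter=delimiter):
                if len(row) < 3:
                    continue
                for exp in self.entries.get(self.normalize_key(row[0]), []):
                    if exp.text == row[1] and len(exp.context_samples) < self.max_context_samples:
                        exp.context_samples.append(row[2])


@dataclass
class AbbreviationMatch:
    span: tuple[int, int]  # 0-based, half-open
    abbreviation: str
    chosen_expansion: Expansion | None = None
    score: float | None = None


# ---------------------------------------------------------------------------
# dictionary harvesting

_HYPHEN_SPLIT = re.compile(r"^\s*(\w+)\s*[-–—]\s+(.+?)\s*$")


def harvest_hyphen_pairs(terms: Iterable[str]) -> list[tuple[str, str]]:
    """Mine (abbreviation, expansion) pairs from hyphenated terminology terms.

    A term like ``"AP - abdominal pain"`` yields ``("AP", "abdominal pain")``
    when the token's letters match, in order, the first letters of the
    phrase's words (case-insensitive).  Non-matching terms are skipped.
    """
    pairs = []
    for term in terms:
        m = _HYPHEN_SPLIT.match(term)
        if not m:
            continue
        token, phrase = m.group(1), m.group(2)
        words = phrase.split()
        if len(token) != len(words):
            continue
        if all(w and ch.lower() == w[0].lower() for ch, w in zip(token, words)):
            pairs.append((token, phrase))
    return pairs


# ---------------------------------------------------------------------------
# sentence utilities (shared with the entity linker's local contexts)

_SENTENCE_BREAK = re.compile(r"(?<=[.!?])\s+|\n+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences, split at terminal punctuation/newlines."""
    spans = []
    start = 0
    for m in _SENTENCE_BREAK.finditer(text):
        if m.start() > start:
            spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def sentence_containing(text: str, position: int) -> str:
    for s, e in split_sentences(text):
        if s <= position < e:
            return text[s:e]
    return text


# ---------------------------------------------------------------------------
# detection

def _key_pattern(key: str) -> re.Pattern:
    # all-uppercase keys stay case-sensitive so e.g. "AP" never fires inside
    # lowercase prose; mixed/lower-case curated entries match case-insensitively
    flags = 0 if key.isupper() else re.IGNORECASE
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(key) + r"(?![A-Za-z0-9])", flags
    )


def detect(text: str, dictionary: AbbreviationDictionary) -> list[AbbreviationMatch]:
    """Find dictionary abbreviations at token boundaries, longest-first.

    Longer keys claim their positions before shorter ones, preventing the
    premature expansion of abbreviations nested inside longer ones; retained
    matches never overlap.
    """
    if not dictionary.entries:
        raise ValueError("abbreviation dictionary is empty")
    claimed: list[tuple[int, int]] = []
    matches: list[AbbreviationMatch] = []
    for key in sorted(dictionary.entries, key=lambda k: (-len(k), k)):
        for m in _key_pattern(key).finditer(text):
            span = (m.start(), m.end())
            if any(span[0] < e and s < span[1] for s, e in claimed):
                continue
            claimed.append(span)
            matches.append(AbbreviationMatch(span=span, abbreviation=key))
    matches.sort(key=lambda a: a.span)
    return matches


# ---------------------------------------------------------------------------
# disambiguation

def disambiguate(
    match: AbbreviationMatch,
    context: str,
    dictionary: AbbreviationDictionary,
    provider: EmbeddingProvider,
    min_similarity: float = 0.3,
) -> AbbreviationMatch:
    """Resolve one detected abbreviation against its expansion candidates.

    The score is the maximum cosine similarity between the local context and
    any context sample of any candidate expansion; the arg-max expansion is
    chosen iff the score clears ``min_similarity``.  Expansions with no
    context samples are never selectable.  Ties break lexicographically on
    expansion text for determinism.
    """
    senses = dictionary.entries.get(dictionary.normalize_key(match.abbreviation))
    if not senses:
        raise RuntimeError(f"no expansions known for '{match.abbreviation}'")
    samples: list[str] = []
    owners: list[Expansion] = []
    for exp in senses:
        for s in exp.context_samples:
            samples.append(s)
            owners.append(exp)
    if not samples:
        return AbbreviationMatch(match.span, match.abbreviation, None, None)
    vectors = provider.embed(samples)
    query = provider.embed([context])[0]
    scores = vectors @ query
    best = max(range(len(samples)), key=lambda i: (scores[i], owners[i].text))
    # arg-max over samples; tie on score resolved toward the lexicographically
    # larger owner text by max(); flip to smaller for the documented contract
    best_score = float(scores[best])
    tied = [owners[i] for i in range(len(samples)) if scores[i] == best_score]
    chosen = min(tied, key=lambda e: e.text)
    if best_score >= min_similarity:
        return AbbreviationMatch(match.span, match.abbreviation, chosen, best_score)
    return AbbreviationMatch(match.span, match.abbreviation, None, best_score)


def collect_context_samples(
    corpus: Iterable[str],
    dictionary: AbbreviationDictionary,
    n: int = DEFAULT_MAX_CONTEXT_SAMPLES,
) -> AbbreviationDictionary:
    """Harvest up to ``n`` context sentences per expansion from a corpus.

    Reverse-substitution style: a sentence is a sample for an expansion iff
    it contains the expansion text verbatim (case-insensitive), taken in
    first-encounter order.  Expansions absent from the corpus keep zero
    samples and therefore stay unselectable by context.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    expansions = [exp for senses in dictionary.entries.values() for exp in senses]
    needles = [(exp, exp.text.lower()) for exp in expansions]
    for exp in expansions:
        exp.context_samples = []
    for doc in corpus:
        lowered = doc.lower()
        if all(len(exp.context_samples) >= n for exp, _ in needles):
            break
        for s, e in split_sentences(doc):
            sentence = doc[s:e]
            sentence_lower = lowered[s:e]
            for exp, needle in needles:
                if len(exp.context_samples) < n and needle in sentence_lower:
                    exp.context_samples.append(sentence)
    return dictionary


# ---------------------------------------------------------------------------
# full-text expansion with offset mapping

class OffsetMap:
    """Bidirectional position map between original and expanded text.

    Built from non-overlapping replacement spans.  Positions inside a
    replaced region map to the region's start on the other side, so the
    back-then-forward composition is idempotent.
    """

    def __init__(self, replacements: Sequence[tuple[int, int, int]]):
        # (orig_start, orig_end, new_length), sorted by orig_start
        self._repl = sorted(replacements)
        self._orig_starts = [r[0] for r in self._repl]
        exp_starts = []
        delta = 0
        for os, oe, nlen in self._repl:
            exp_starts.append(os + delta)
            delta += nlen - (oe - os)
        self._exp_starts = exp_starts
        self._total_delta = delta

    def to_original(self, expanded_pos: int) -> int:
        i = bisect_right(self._exp_starts, expanded_pos) - 1
        if i < 0:
            return expanded_pos
        os, oe, nlen = self._repl[i]
        es = self._exp_starts[i]
        if expanded_pos < es + nlen:
            return os  # inside a replacement → clamp to its start
        return expanded_pos - (es + nlen) + oe

    def to_expanded(self, original_pos: int) -> int:
        i = bisect_right(self._orig_starts, original_pos) - 1
        if i < 0:
            return original_pos
        os, oe, nlen = self._repl[i]
        es = self._exp_starts[i]
        if original_pos < oe:
            return es
        return original_pos - oe + es + nlen


def expand_all(
    text: str,
    dictionary: AbbreviationDictionary,
    provider: EmbeddingProvider,
    min_similarity: float = 0.3,
) -> tuple[str, OffsetMap, list[AbbreviationMatch]]:
    """Detect, disambiguate and replace every resolvable abbreviation.

    Returns the expanded text, an :class:`OffsetMap` translating expanded
    positions back to original coordinates (needed so entity-link spans can
    be reported against the original document), and the per-match table.
    """
    matches = detect(text, dictionary) if dictionary.entries else []
    resolved: list[AbbreviationMatch] = []
    for m in matches:
        context = sentence_containing(text, m.span[0])
        resolved.append(disambiguate(m, context, dictionary, provider, min_similarity))
    pieces = []
    cursor = 0
    replacements = []
    for m in resolved:
        if m.chosen_expansion is None:
            continue
        s, e = m.span
        pieces.append(text[cursor:s])
        pieces.append(m.chosen_expansion.text)
        replacements.append((s, e, len(m.chosen_expansion.text)))
        cursor = e
    pieces.append(text[cursor:])
    return "".join(pieces), OffsetMap(replacements), resolved
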