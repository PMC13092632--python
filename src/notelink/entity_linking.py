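"""Semantic entity linking: candidate identification and candidate selection.

The linker maps free-text spans to terminology concepts in two phases.

**Candidate identification** (high recall) runs four steps in order:

1. build an abbreviation table — dictionary matches with spans and
   context-disambiguated expansions, longest abbreviations first;
2. tokenize on non-alphanumeric boundaries and form all n-grams of token
   length 1..``max_ngram_len`` (long n-grams let the linker align with long
   pre-coordinated concept names);
3. drop n-grams containing a prohibited infix (defaults: a full stop or a
   hyphen followed by whitespace — signs of a span crossing a sentence or
   bullet boundary), then expand abbreviations inside the survivors while
   keeping the original, pre-expansion character spans;
4. retrieve the top-k most similar concept descriptions for every n-gram by
   embedding cosine similarity — each (n-gram, concept) pair becomes a
   candidate.

**Candidate selection** (precision) runs four steps in order:

1. *threshold filter* — drop candidates below the similarity threshold;
2. *pinpointing* — where overlapping n-grams link the same concept, keep
   only the most representative (highest-similarity) one;
3. *context-collection filter* — per-concept positive/negative context
   samples, accumulated by online learning from feedback, dismiss links
   whose local context resembles negative evidence more than positive;
4. *nesting minimization* — a link nested inside a wider link is dismissed
   when omitting its text lowers the outer n-gram's similarity to the outer
   concept (the inner text was semantically subsumed); if similarity rises,
   the nested link carries new information and both are kept.

Spans are 0-based half-open intervals over the *original* document text,
so reported links line up with standoff gold annotations.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import abbreviation as abbrev_mod
from .abbreviation import AbbreviationDictionary, sentence_containing
from .embedding import EmbeddingCache, EmbeddingProvider, cosine
from .terminology import TerminologyIndex

__all__ = [
    "NGram",
    "EntityLinkCandidate",
    "EntityLink",
    "ContextCollection",
    "LinkerConfig",
    "identify_candidates",
    "threshold_filter",
    "pinpoint",
    "context_filter",
    "minimize_nesting",
    "update_collections",
    "link_document",
    "read_pubtator",
    "read_pipe_standoff",
    "write_link_table",
]

_TOKEN = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class NGram:
    char_span: tuple[int, int]  # original-document coordinates
    text: str                   # after abbreviation expansion
    length_tokens: int


@dataclass(frozen=True)
class EntityLinkCandidate:
    ngram: NGram
    concept_id: str
    matched_description: str
    similarity: float


@dataclass(frozen=True)
class EntityLink:
    char_span: tuple[int, int]
    concept_id: str
    similarity: float
    provenance: tuple[str, ...] = ()


@dataclass
class ContextCollection:
    """Per-concept positive/negative context samples for online learning."""

    positive: dict[str, list[str]] = field(default_factory=dict)
    negative: dict[str, list[str]] = field(default_factory=dict)

    def add_positive(self, concept_id: str, sample: str) -> None:
        self.positive.setdefault(concept_id, []).append(sample)

    def add_negative(self, concept_id: str, sample: str) -> None:
        self.negative.setdefault(concept_id, []).append(sample)

    def is_blacklisted(self, concept_id: str) -> bool:
        """Only negative evidence → the concept is never linked again."""
        return bool(self.negative.get(concept_id)) and not self.positive.get(concept_id)


@dataclass
class LinkerConfig:
    max_ngram_len: int = 30
    top_k: int = 10
    selection_threshold: float = 0.95
    prohibited_infixes: tuple[str, ...] = (". ", "- ")

    def __post_init__(self) -> None:
        if not (0.0 <= self.selection_threshold <= 1.0):
            raise ValueError("selection_threshold must lie in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.max_ngram_len < 1:
            raise ValueError("max_ngram_len must be >= 1")


# ---------------------------------------------------------------------------
# candidate identification


def _abbreviation_table(
    text: str,
    dictionary: AbbreviationDictionary | None,
    provider: EmbeddingProvider,
    abbrev_gate: float,
) -> list[tuple[tuple[int, int], str]]:
    """(span, expansion) pairs for every resolvable abbreviation in ``text``."""
    if dictionary is None or not dictionary.entries:
        return []
    table = []
    for m in abbrev_mod.detect(text, dictionary):
        context = sentence_containing(text, m.span[0])
        resolved = abbrev_mod.disambiguate(m, context, dictionary, provider, abbrev_gate)
        if resolved.chosen_expansion is not None:
            table.append((resolved.span, resolved.chosen_expansion.text))
    return table


def enumerate_ngrams(text: str, max_ngram_len: int) -> list[NGram]:
    """All token n-grams of length 1..max_ngram_len with original char spans."""
    tokens = [(m.start(), m.end()) for m in _TOKEN.finditer(text)]
    t = len(tokens)
    out = []
    for n in range(1, min(max_ngram_len, t) + 1):
        for i in range(t - n + 1):
            start, end = tokens[i][0], tokens[i + n - 1][1]
            out.append(NGram((start, end), text[start:end], n))
    return out


def _expand_within(ngram: NGram, table: list[tuple[tuple[int, int], str]]) -> NGram:
    """Splice abbreviation expansions into an n-gram, keeping its span."""
    s, e = ngram.char_span
    inside = [(span, exp) for span, exp in table if span[0] >= s and span[1] <= e]
    if not inside:
        return ngram
    text = ngram.text
    for (a, b), exp in sorted(inside, reverse=True):
        text = text[: a - s] + exp + text[b - s :]
    return NGram(ngram.char_span, text, ngram.length_tokens)


def identify_candidates(
    text: str,
    index: TerminologyIndex,
    dictionary: AbbreviationDictionary | None,
    provider: EmbeddingProvider | EmbeddingCache,
    config: LinkerConfig,
    with_abbrev: bool = True,
    abbrev_gate: float = 0.3,
) -> list[EntityLinkCandidate]:
    """Four-step high-recall candidate retrieval (see module docstring)."""
    if index.embedding_index is None:
        raise RuntimeError("terminology index has no embeddings; "
                           "call build_description_index first")
    if not text.strip():
        return []
    base = provider.provider if isinstance(provider, EmbeddingCache) else provider
    table = _abbreviation_table(text, dictionary, base, abbrev_gate) if with_abbrev else []

    ngrams = enumerate_ngrams(text, config.max_ngram_len)
    kept = [
        g for g in ngrams
        if not any(infix in g.text for infix in config.prohibited_infixes)
    ]
    kept = [_expand_within(g, table) for g in kept]
    if not kept:
        return []

    unique_texts = sorted({g.text for g in kept})
    vectors = provider.embed(unique_texts)
    row_of = {t: i for i, t in enumerate(unique_texts)}
    hits_per_text = index.embedding_index.batch_top_k(vectors, config.top_k)

    desc_text = {d.description_id: d.text for d in index.descriptions.values()}
    candidates = []
    for g in kept:
        for hit in hits_per_text[row_of[g.text]]:
            for concept_id in hit.concept_ids:
                candidates.append(
                    EntityLinkCandidate(
                        ngram=g,
                        concept_id=concept_id,
                        matched_description=desc_text[hit.description_id],
                        similarity=hit.score,
                    )
                )
    return candidates


# ---------------------------------------------------------------------------
# candidate selection


def threshold_filter(
    candidates: Sequence[EntityLinkCandidate], selection_threshold: float
) -> list[EntityLinkCandidate]:
    """Selection step 1: keep candidates with similarity ≥ threshold."""
    return [c for c in candidates if c.similarity >= selection_threshold]


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def pinpoint(candidates: Sequence[EntityLinkCandidate]) -> list[EntityLinkCandidate]:
    """Selection step 2: one representative per concept per overlap cluster.

    Candidates sharing a concept are grouped into connected components of
    the span-overlap graph (computed by an interval sweep — overlapping
    intervals sorted by start form exactly these components); within each
    component only the highest-similarity candidate survives.  Ties prefer
    the shorter span, then the leftmost.  Non-overlapping repeats of a
    concept elsewhere in the document all survive.
    """
    by_concept: dict[str, list[EntityLinkCandidate]] = {}
    for c in candidates:
        by_concept.setdefault(c.concept_id, []).append(c)
    survivors = []
    for group in by_concept.values():
        group.sort(key=lambda c: c.ngram.char_span)
        component: list[EntityLinkCandidate] = []
        max_end = -1
        for c in group:
            s, e = c.ngram.char_span
            if component and s >= max_end:
                survivors.append(_best_of(component))
                component = []
                max_end = -1
            component.append(c)
            max_end = max(max_end, e)
        if component:
            survivors.append(_best_of(component))
    survivors.sort(key=lambda c: (c.ngram.char_span, c.concept_id))
    return survivors


def _best_of(component: list[EntityLinkCandidate]) -> EntityLinkCandidate:
    return max(
        component,
        key=lambda c: (
            c.similarity,
            -(c.ngram.char_span[1] - c.ngram.char_span[0]),  # shorter span wins ties
            -c.ngram.char_span[0],                            # then leftmost
        ),
    )


def context_filter(
    candidates: Sequence[EntityLinkCandidate],
    collections: ContextCollection,
    text: str,
    provider: EmbeddingProvider | EmbeddingCache,
) -> list[EntityLinkCandidate]:
    """Selection step 3: dismiss candidates contradicted by context evidence.

    A candidate is dropped iff its concept is blacklisted (only negative
    samples) or has both kinds of samples and the best negative similarity
    to the local sentence strictly exceeds the best positive one.  Concepts
    with no samples pass through — absence of evidence is not evidence.
    """
    kept = []
    for c in candidates:
        if collections.is_blacklisted(c.concept_id):
            continue
        pos = collections.positive.get(c.concept_id, [])
        neg = collections.negative.get(c.concept_id, [])
        if pos and neg:
            local = sentence_containing(text, c.ngram.char_span[0])
            query = provider.embed([local])[0]
            best_pos = float(np.max(provider.embed(pos) @ query))
            best_neg = float(np.max(provider.embed(neg) @ query))
            if best_neg > best_pos:
                continue
        kept.append(c)
    return kept


def minimize_nesting(
    candidates: Sequence[EntityLinkCandidate],
    provider: EmbeddingProvider | EmbeddingCache,
) -> list[EntityLink]:
    """Selection step 4: dismiss semantically nested inner links.

    For each (outer, inner) pair with the inner span strictly contained in
    the outer span, the outer n-gram is re-scored against its matched
    description with the inner text excised.  A similarity drop means the
    inner text was carrying the outer concept's meaning — the inner link is
    redundant and dismissed.  A rise (or no drop) means the inner link adds
    information and both are kept.
    """
    dismissed: set[int] = set()
    items = list(candidates)
    for i, inner in enumerate(items):
        for outer in items:
            if outer is inner:
                continue
            os_, oe = outer.ngram.char_span
            is_, ie = inner.ngram.char_span
            strictly_inside = os_ <= is_ and ie <= oe and (os_, oe) != (is_, ie)
            if not strictly_inside:
                continue
            reduced = _excise(outer.ngram, inner.ngram)
            if not reduced.strip():
                dismissed.add(i)
                break
            new_sim = cosine(
                provider.embed([reduced])[0],
                provider.embed([outer.matched_description])[0],
            )
            if new_sim < outer.similarity:
                dismissed.add(i)
                break
    links = []
    for i, c in enumerate(items):
        if i in dismissed:
            continue
        links.append(
            EntityLink(
                char_span=c.ngram.char_span,
                concept_id=c.concept_id,
                similarity=c.similarity,
                provenance=("threshold", "pinpoint", "context", "nesting"),
            )
        )
    links.sort(key=lambda l: (l.char_span, l.concept_id))
    return links


def _excise(outer: NGram, inner: NGram) -> str:
    """Outer n-gram text with the inner n-gram's text removed once.

    Abbreviation expansion can desynchronize texts from raw coordinate
    arithmetic, so substring removal is tried first and coordinate splicing
    is the fallback.
    """
    if inner.text and inner.text in outer.text:
        i = outer.text.find(inner.text)
        return outer.text[:i] + outer.text[i + len(inner.text):]
    rel_s = inner.char_span[0] - outer.char_span[0]
    rel_e = inner.char_span[1] - outer.char_span[0]
    return outer.text[:rel_s] + outer.text[rel_e:]


# ---------------------------------------------------------------------------
# online learning


def update_collections(
    links: Sequence[EntityLink],
    gold: Sequence[tuple[tuple[int, int], str]],
    text: str,
    collections: ContextCollection,
) -> ContextCollection:
    """Fold one document's feedback into the context collections.

    Gold-linked concepts gain their surrounding sentence as positive
    evidence; predicted links absent from gold gain it as negative
    evidence.  Call this only *after* the document's own linking is done —
    the pipeline never lets a document's feedback influence its own links.
    """
    for (s, e), concept_id in gold:
        if not (0 <= s <= e <= len(text)):
            raise ValueError(f"gold span ({s}, {e}) outside document of length {len(text)}")
        collections.add_positive(concept_id, sentence_containing(text, s))
    gold_set = {(tuple(span), cid) for span, cid in gold}
    for link in links:
        if (link.char_span, link.concept_id) not in gold_set:
            collections.add_negative(
                link.concept_id, sentence_containing(text, link.char_span[0])
            )
    return collections


# ---------------------------------------------------------------------------
# end-to-end


def link_document(
    text: str,
    index: TerminologyIndex,
    dictionary: AbbreviationDictionary | None,
    collections: ContextCollection,
    provider: EmbeddingProvider | EmbeddingCache,
    config: LinkerConfig,
    with_abbrev: bool = True,
    abbrev_gate: float = 0.3,
) -> list[EntityLink]:
    """Run candidate identification and all four selection steps in order."""
    stages: list[tuple[str, object]] = []
    try:
        stage = "candidate-identification"
        candidates = identify_candidates(
            text, index, dictionary, provider, config, with_abbrev, abbrev_gate
        )
        stage = "threshold-filter"
        candidates = threshold_filter(candidates, config.selection_threshold)
        stage = "pinpointing"
        candidates = pinpoint(candidates)
        stage = "context-filter"
        candidates = context_filter(candidates, collections, text, provider)
        stage = "nesting-minimization"
        return minimize_nesting(candidates, provider)
    except (ValueError, KeyError, RuntimeError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc


# ---------------------------------------------------------------------------
# standoff readers / writers


def read_pubtator(path: str | Path) -> dict[str, tuple[str, list[tuple[tuple[int, int], str]]]]:
    """Read PubTator-format documents with entity annotations.

    Returns ``{doc_id: (text, [(span, concept_id), ...])}`` where the text
    is title and abstract joined by a newline and spans index into it.
    """
    docs: dict[str, dict] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "|t|" in line or "|a|" in line:
                doc_id, kind, content = line.split("|", 2)
                slot = docs.setdefault(doc_id, {"t": "", "a": "", "ann": []})
                slot[kind] = content
            else:
                parts = line.split("\t")
                if len(parts) >= 6:
                    doc_id, start, end, _mention, _type, concept = parts[:6]
                    docs.setdefault(doc_id, {"t": "", "a": "", "ann": []})["ann"].append(
                        ((int(start), int(end)), concept)
                    )
    out = {}
    for doc_id, slot in docs.items():
        text = slot["t"] + ("\n" + slot["a"] if slot["a"] else "")
        out[doc_id] = (text, slot["ann"])
    return out


def read_pipe_standoff(
    path: str | Path,
) -> tuple[dict[str, list[tuple[tuple[int, int], str]]], dict[str, int]]:
    """Read pipe-delimited standoff annotations: ``doc|start-end[,…]|concept``.

    ``CUI-less`` annotations are excluded and disjoint-span annotations are
    skipped (the linker emits contiguous spans only); both are tallied in
    the returned counters so evaluations can report unreachable gold.
    """
    gold: dict[str, list[tuple[tuple[int, int], str]]] = {}
    skipped = {"cui_less": 0, "disjoint": 0}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            doc_id, span_field, concept = line.split("|")[:3]
            if concept.upper() == "CUI-LESS":
                skipped["cui_less"] += 1
                continue
            pieces = span_field.split(",")
            if len(pieces) > 1:
                skipped["disjoint"] += 1
                continue
            start, end = pieces[0].split("-")
            gold.setdefault(doc_id, []).append(((int(start), int(end)), concept))
    return gold, skipped


def write_link_table(
    links_per_doc: dict[str, Sequence[EntityLink]],
    table_path: str | Path,
    provenance_path: str | Path | None = None,
    config: LinkerConfig | None = None,
) -> None:
    """Write links as a TSV table plus an optional JSON provenance sidecar."""
    with Path(table_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["doc_id", "start", "end", "concept_id", "similarity"])
        for doc_id in sorted(links_per_doc):
            for link in links_per_doc[doc_id]:
                w.writerow(
                    [doc_id, link.char_span[0], link.char_span[1],
                     link.concept_id, f"{link.similarity:.6f}"]
                )
    if provenance_path is not None:
        payload = {
            "config": vars(config) if config else None,
            "documents": {
                doc_id: [
                    {"span": list(l.char_span), "concept_id": l.concept_id,
                     "similarity": l.similarity, "provenance": list(l.provenance)}
                    for l in links
                ]
                for doc_id, links in links_per_doc.items()
            },
        }
        Path(provenance_path).write_text(
            json.dumps(payload, indent=2, default=str), encoding="utf-8"
        )
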