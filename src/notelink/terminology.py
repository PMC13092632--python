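"""Terminology ingestion: SNOMED-CT RF2 snapshots and UMLS RRF tables.

A loaded :class:`TerminologyIndex` holds active concepts, their deduplicated
description texts, the is-a hierarchy with a memoized ancestor closure, and
(after :func:`build_description_index`) an embedded description index for
top-k semantic retrieval.

Two release dialects are supported:

* RF2 snapshot — tab-delimited ``sct2_Concept`` / ``sct2_Description`` /
  ``sct2_Relationship`` tables; only active rows are kept and only the
  "is a" relationship type (116680003) contributes hierarchy edges.
* RRF — pipe-delimited MRCONSO/MRSTY tables; every non-suppressed atom name
  becomes a description.  The metathesaurus carries no explicit is-a edges
  in these tables, so RRF concepts get empty parent sets and ancestor
  expansion is a no-op for them.

Descriptions are deduplicated case-insensitively: one
:class:`ConceptDescription` per unique folded text, carrying the set of all
concepts that use that text.  A description attached to two or more
concepts is *ambiguous* — the situation the context-collection filter in
the entity linker exists to resolve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .embedding import DescriptionIndex, EmbeddingCache, EmbeddingProvider

__all__ = [
    "Concept",
    "ConceptDescription",
    "TerminologyIndex",
    "TerminologyFormatError",
    "IS_A_TYPE_ID",
    "load_rf2",
    "load_rrf",
    "write_rf2",
]

IS_A_TYPE_ID = "116680003"
FSN_TYPE_ID = "900000000000003001"


class TerminologyFormatError(ValueError):
    """A release file is missing a column or references an unknown id."""


@dataclass
class Concept:
    concept_id: str
    preferred_name: str
    category: str = ""
    parent_ids: set[str] = field(default_factory=set)
    active: bool = True


@dataclass
class ConceptDescription:
    description_id: str
    text: str
    concept_ids: set[str]

    @property
    def is_ambiguous(self) -> bool:
        return len(self.concept_ids) >= 2


def _fsn_category(fsn: str) -> str:
    """Extract the semantic-tag category from a fully specified name."""
    if fsn.endswith(")") and "(" in fsn:
        return fsn[fsn.rfind("(") + 1 : -1]
    return ""


class TerminologyIndex:
    """Queryable concept store with ancestor closure and description index."""

    def __init__(
        self,
        concepts: Mapping[str, Concept],
        descriptions: Mapping[str, ConceptDescription],
    ):
        self.concepts: dict[str, Concept] = dict(concepts)
        self.descriptions: dict[str, ConceptDescription] = dict(descriptions)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self.embedding_index: DescriptionIndex | None = None
        self._validate()

    def _validate(self) -> None:
        dangling = sorted(
            cid
            for d in self.descriptions.values()
            for cid in d.concept_ids
            if cid not in self.concepts
        )
        if dangling:
            raise TerminologyFormatError(
                f"descriptions reference unknown concept ids: {dangling}"
            )
        dangling_parents = sorted(
            pid
            for c in self.concepts.values()
            for pid in c.parent_ids
            if pid not in self.concepts
        )
        if dangling_parents:
            raise TerminologyFormatError(
                f"is-a edges reference unknown concept ids: {dangling_parents}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TerminologyIndex):
            return NotImplemented
        mine = {
            cid: (c.preferred_name, c.category, frozenset(c.parent_ids))
            for cid, c in self.concepts.items()
        }
        theirs = {
            cid: (c.preferred_name, c.category, frozenset(c.parent_ids))
            for cid, c in other.concepts.items()
        }
        my_desc = {(d.text.lower(), frozenset(d.concept_ids)) for d in self.descriptions.values()}
        their_desc = {
            (d.text.lower(), frozenset(d.concept_ids)) for d in other.descriptions.values()
        }
        return mine == theirs and my_desc == their_desc

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """Transitive is-a closure of ``concept_id``, excluding itself."""
        if concept_id not in self.concepts:
            raise KeyError(f"unknown concept id: {concept_id}")
        cached = self._ancestor_cache.get(concept_id)
        if cached is not None:
            return cached
        result: set[str] = set()
        stack = list(self.concepts[concept_id].parent_ids)
        while stack:
            pid = stack.pop()
            if pid in result:
                continue
            result.add(pid)
            done = self._ancestor_cache.get(pid)
            if done is not None:
                result |= done
            else:
                stack.extend(self.concepts[pid].parent_ids)
        frozen = frozenset(result)
        self._ancestor_cache[concept_id] = frozen
        return frozen

    def find_ambiguous_descriptions(self) -> list[ConceptDescription]:
        return sorted(
            (d for d in self.descriptions.values() if d.is_ambiguous),
            key=lambda d: d.description_id,
        )

    # -- embedding ---------------------------------------------------------

    def build_description_index(
        self, provider: EmbeddingProvider | EmbeddingCache
    ) -> DescriptionIndex:
        """Embed every description text and build the exact cosine index.

        Deterministic for a fixed provider: descriptions are embedded in
        ascending description-id order, so rebuilding yields a bit-identical
        matrix.  Passing an :class:`EmbeddingCache` makes re-runs cheap.
        """
        if not self.descriptions:
            raise RuntimeError("cannot embed an empty terminology")
        ordered = sorted(self.descriptions.values(), key=lambda d: d.description_id)
        texts = [d.text for d in ordered]
        try:
            matrix = provider.embed(texts)
        except Exception as exc:
            raise RuntimeError(
                f"embedding provider failed while indexing {len(texts)} descriptions"
            ) from exc
        self.embedding_index = DescriptionIndex(
            [d.description_id for d in ordered],
            [sorted(d.concept_ids) for d in ordered],
            np.asarray(matrix),
        )
        return self.embedding_index


# ---------------------------------------------------------------------------
# loading helpers


def _read_delimited(
    path: str | Path, delimiter: str, required: list[str]
) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise TerminologyFormatError(f"{path.name}: missing column '{col}'")
        return [row for row in reader]


def _dedup_descriptions(
    rows: Iterable[tuple[str, str, str]]
) -> dict[str, ConceptDescription]:
    """Group (native_id, text, concept_id) rows into unique-text descriptions.

    The representative id and casing are the lexicographically smallest
    native id in the group, making the grouping order-independent.
    """
    by_text: dict[str, dict] = {}
    for native_id, text, concept_id in rows:
        key = text.strip().lower()
        if not key:
            continue
        slot = by_text.setdefault(key, {"ids": [], "texts": {}, "concepts": set()})
        slot["ids"].append(native_id)
        slot["texts"][native_id] = text.strip()
        slot["concepts"].add(concept_id)
    out: dict[str, ConceptDescription] = {}
    for slot in by_text.values():
        rep = min(slot["ids"])
        out[rep] = ConceptDescription(
            description_id=rep, text=slot["texts"][rep], concept_ids=set(slot["concepts"])
        )
    return out


def load_rf2(
    concept_file: str | Path,
    description_file: str | Path,
    relationship_file: str | Path,
) -> TerminologyIndex:
    """Load an RF2 snapshot; inactive rows and non-is-a relations are dropped."""
    concept_rows = _read_delimited(concept_file, "\t", ["id", "active"])
    description_rows = _read_delimited(
        description_file, "\t", ["id", "active", "conceptId", "typeId", "term"]
    )
    relationship_rows = _read_delimited(
        relationship_file,
        "\t",
        ["id", "active", "sourceId", "destinationId", "typeId"],
    )

    concepts: dict[str, Concept] = {}
    for row in concept_rows:
        if row["active"] != "1":
            continue
        concepts[row["id"]] = Concept(concept_id=row["id"], preferred_name="")

    desc_triples: list[tuple[str, str, str]] = []
    for row in description_rows:
        if row["active"] != "1":
            continue
        cid = row["conceptId"]
        if cid not in concepts:
            continue  # description of an inactive concept
        if row["typeId"] == FSN_TYPE_ID:
            category = _fsn_category(row["term"])
            name = row["term"]
            if category:  # strip the trailing semantic tag from the name
                name = name[: name.rfind("(")].rstrip()
            concepts[cid].preferred_name = name
            concepts[cid].category = category
            continue  # FSNs name the concept; synonyms feed the index
        desc_triples.append((row["id"], row["term"], cid))

    for row in relationship_rows:
        if row["active"] != "1" or row["typeId"] != IS_A_TYPE_ID:
            continue
        src, dst = row["sourceId"], row["destinationId"]
        if src in concepts and dst in concepts:
            concepts[src].parent_ids.add(dst)

    for c in concepts.values():
        if not c.preferred_name:
            c.preferred_name = c.concept_id
    return TerminologyIndex(concepts, _dedup_descriptions(desc_triples))


# MRCONSO column order (pipe-delimited, 18 fields)
_MRCONSO_COLS = [
    "CUI", "LAT", "TS", "LUI", "STT", "SUI", "ISPREF", "AUI", "SAUI",
    "SCUI", "SDUI", "SAB", "TTY", "CODE", "STR", "SRL", "SUPPRESS", "CVF",
]
_MRSTY_COLS = ["CUI", "TUI", "STN", "STY", "ATUI", "CVF"]


def _read_rrf(path: str | Path, columns: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            if len(parts) - 1 < len(columns):  # trailing pipe yields one extra
                raise TerminologyFormatError(
                    f"{path.name}: line {lineno} has {len(parts) - 1} fields, "
                    f"expected {len(columns)}"
                )
            rows.append(dict(zip(columns, parts)))
    return rows


def load_rrf(conso_file: str | Path, semantic_type_file: str | Path) -> TerminologyIndex:
    """Load UMLS-style MRCONSO/MRSTY tables; suppressed atoms are dropped.

    Every unique CUI becomes a concept with an empty parent set; every
    atom name becomes a description of its CUI.  The semantic type of the
    first MRSTY row per CUI becomes the concept category.
    """
    conso = _read_rrf(conso_file, _MRCONSO_COLS)
    sty = _read_rrf(semantic_type_file, _MRSTY_COLS)
    categories: dict[str, str] = {}
    for row in sty:
        categories.setdefault(row["CUI"], row["STY"])

    concepts: dict[str, Concept] = {}
    triples: list[tuple[str, str, str]] = []
    for row in conso:
        if row["SUPPRESS"] in ("O", "E", "Y"):
            continue
        cui = row["CUI"]
        if cui not in concepts:
            concepts[cui] = Concept(
                concept_id=cui,
                preferred_name=row["STR"],
                category=categories.get(cui, ""),
            )
        triples.append((row["AUI"], row["STR"], cui))
    return TerminologyIndex(concepts, _dedup_descriptions(triples))


# ---------------------------------------------------------------------------
# fixture writer (RF2 dialect) — enables round-trip tests and file-based runs

_RF2_CONCEPT_HEADER = ["id", "effectiveTime", "active", "moduleId", "definitionStatusId"]
_RF2_DESC_HEADER = [
    "id", "effectiveTime", "active", "moduleId", "conceptId",
    "languageCode", "typeId", "term", "caseSignificanceId",
]
_RF2_REL_HEADER = [
    "id", "effectiveTime", "active", "moduleId", "sourceId", "destinationId",
    "relationshipGroup", "typeId", "characteristicTypeId", "modifierId",
]


def write_rf2(index: TerminologyIndex, out_dir: str | Path) -> dict[str, Path]:
    """Write an index back out as RF2-dialect snapshot TSVs.

    Round-trip guarantee: ``load_rf2(**write_rf2(index, d))`` compares equal
    to ``index`` (preferred names are emitted as FSN rows with the category
    re-attached as a semantic tag when present).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "concept_file": out_dir / "sct2_Concept_Snapshot.txt",
        "description_file": out_dir / "sct2_Description_Snapshot.txt",
        "relationship_file": out_dir / "sct2_Relationship_Snapshot.txt",
    }
    with paths["concept_file"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RF2_CONCEPT_HEADER)
        for cid in sorted(index.concepts):
            w.writerow([cid, "20230531", "1", "900000000000207008", "900000000000074008"])
    with paths["description_file"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RF2_DESC_HEADER)
        fsn_serial = 0
        for cid in sorted(index.concepts):
            concept = index.concepts[cid]
            fsn_serial += 1
            fsn = concept.preferred_name
            if concept.category and not fsn.endswith(")"):
                fsn = f"{fsn} ({concept.category})"
            w.writerow(
                [f"fsn{fsn_serial:06d}", "20230531", "1", "900000000000207008",
                 cid, "en", FSN_TYPE_ID, fsn, "900000000000448009"]
            )
        for did in sorted(index.descriptions):
            desc = index.descriptions[did]
            for k, cid in enumerate(sorted(desc.concept_ids)):
                row_id = did if k == 0 else f"{did}.{k}"
                w.writerow(
                    [row_id, "20230531", "1", "900000000000207008", cid, "en",
                     "900000000000013009", desc.text, "900000000000448009"]
                )
    with paths["relationship_file"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RF2_REL_HEADER)
        serial = 0
        for cid in sorted(index.concepts):
            for pid in sorted(index.concepts[cid].parent_ids):
                serial += 1
                w.writerow(
                    [f"rel{serial:06d}", "20230531", "1", "900000000000207008",
                     cid, pid, "0", IS_A_TYPE_ID, "900000000000011006", "900000000000451002"]
                )
    return paths
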