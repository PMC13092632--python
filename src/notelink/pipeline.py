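"""Batch orchestration of the four pipeline stages.

Stage order mirrors the clinical workflow: (1) abbreviation disambiguation,
(2) optional translation through a pluggable external command (identity by
default — the library makes no translation quality claims of its own),
(3) entity linking against an embedded terminology, (4) heart-failure
classification from linked concepts plus EHR features.

Every artifact written by these runners carries the resolved configuration,
the seed and the library version as JSON provenance, so results can be
traced back to their exact settings.  Structured progress logging goes to
stderr; results go only to the declared output paths.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .abbreviation import AbbreviationDictionary, expand_all, split_sentences
from .embedding import EmbeddingCache, get_provider
from .entity_linking import (
    ContextCollection,
    EntityLink,
    LinkerConfig,
    identify_candidates,
    context_filter,
    minimize_nesting,
    pinpoint,
    threshold_filter,
    update_collections,
    write_link_table,
)
from .hf_classification import PatientRecord, TrainConfig, cross_validate
from .metrics import score_links
from .terminology import TerminologyIndex

__all__ = [
    "PipelineConfig",
    "translate",
    "run_disambiguate",
    "run_link",
    "run_classify",
    "write_provenance",
]

log = logging.getLogger("notelink")

DEFAULT_SWEEP = tuple(round(0.90 + 0.01 * i, 2) for i in range(10))


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one pipeline run.

    Defaults: abbreviation expansion gate 0.3; selection threshold 0.95
    (the F1 optimum of the linking sweep); top-10 candidate concepts per
    n-gram; n-grams up to 30 tokens, long enough for lengthy
    pre-coordinated concept names; 30 context samples per sense; seed 2026.
    """

    abbrev_gate: float = 0.3
    selection_threshold: float = 0.95
    top_k: int = 10
    max_ngram_len: int = 30
    context_samples_per_sense: int = 30
    seed: int = 2026
    provider_name: str = "hash-3gram"
    provider_dim: int = 256
    translation_command: str | None = None
    translation_chunk_chars: int = 1000

    def __post_init__(self) -> None:
        for name in ("abbrev_gate", "selection_threshold"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    def linker_config(self, selection_threshold: float | None = None) -> LinkerConfig:
        return LinkerConfig(
            max_ngram_len=self.max_ngram_len,
            top_k=self.top_k,
            selection_threshold=(
                self.selection_threshold if selection_threshold is None
                else selection_threshold
            ),
        )

    def provider(self) -> EmbeddingCache:
        return EmbeddingCache(get_provider(self.provider_name, self.provider_dim))


def provenance(config: PipelineConfig) -> dict:
    return {"config": asdict(config), "seed": config.seed, "notelink_version": __version__}


def write_provenance(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(provenance(config), indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# translation hook


def _chunk_sentences(text: str, budget: int) -> list[str]:
    """Split at sentence boundaries into chunks of at most ``budget`` chars
    (a single over-long sentence becomes its own chunk)."""
    chunks: list[str] = []
    current = ""
    for s, e in split_sentences(text):
        sentence = text[s:e]
        if current and len(current) + len(sentence) + 1 > budget:
            chunks.append(current)
            current = sentence
        else:
            current = f"{current} {sentence}".strip()
    if current:
        chunks.append(current)
    return chunks


def translate(text: str, config: PipelineConfig) -> str:
    """Pluggable translation: identity unless an external command is set.

    With a command configured, the text is chunked at sentence boundaries
    under a character budget (models impose token limits), each chunk is
    piped through the command's stdin, and the outputs are reassembled.
    """
    if not config.translation_command:
        return text
    pieces = []
    for chunk in _chunk_sentences(text, config.translation_chunk_chars):
        result = subprocess.run(
            shlex.split(config.translation_command),
            input=chunk,
            capture_output=True,
            text=True,
            check=True,
        )
        pieces.append(result.stdout.strip())
    return " ".join(pieces)


# ---------------------------------------------------------------------------
# stage runners


def run_disambiguate(
    documents: Mapping[str, str],
    dictionary: AbbreviationDictionary,
    config: PipelineConfig,
) -> tuple[dict[str, str], list[dict]]:
    """Expand abbreviations across a corpus; returns texts + match table."""
    provider = config.provider()
    expanded: dict[str, str] = {}
    table: list[dict] = []
    for doc_id in sorted(documents):
        text, _offsets, matches = expand_all(
            documents[doc_id], dictionary, provider, config.abbrev_gate
        )
        expanded[doc_id] = text
        resolved = 0
        for m in matches:
            if m.chosen_expansion is not None:
                resolved += 1
            table.append(
                {
                    "doc_id": doc_id,
                    "start": m.span[0],
                    "end": m.span[1],
                    "abbreviation": m.abbreviation,
                    "expansion": m.chosen_expansion.text if m.chosen_expansion else None,
                    "score": m.score,
                }
            )
        log.info("disambiguate %s: %d matches, %d expanded", doc_id, len(matches), resolved)
    return expanded, table


def run_link(
    documents: Mapping[str, str],
    index: TerminologyIndex,
    dictionary: AbbreviationDictionary | None,
    config: PipelineConfig,
    with_abbrev: bool = True,
    gold: Mapping[str, Sequence[tuple[tuple[int, int], str]]] | None = None,
    collections: ContextCollection | None = None,
    sweep: Sequence[float] | None = None,
) -> dict:
    """Link a corpus; optionally evaluate against gold over a threshold sweep.

    Candidates are identified once per document and the four selection
    steps are replayed per threshold, so a full sweep costs little more
    than a single run.  With gold supplied, each document's feedback is
    folded into the context collections *after* that document is linked
    (online learning), and a metrics row is reported per threshold.
    """
    if index.embedding_index is None:
        raise RuntimeError("terminology index has no embeddings; "
                           "call build_description_index first")
    provider = config.provider()
    collections = collections if collections is not None else ContextCollection()
    thresholds = list(sweep) if sweep is not None else [config.selection_threshold]

    links_per_doc: dict[str, list[EntityLink]] = {}
    per_threshold_links: dict[float, dict[str, list]] = {t: {} for t in thresholds}
    candidate_recall_hits: dict[float, int] = {t: 0 for t in thresholds}
    gold_total = 0
    for doc_id in sorted(documents):
        text = documents[doc_id]
        candidates = identify_candidates(
            text, index, dictionary, provider, config.linker_config(),
            with_abbrev, config.abbrev_gate,
        )
        log.info("link %s: %d candidates", doc_id, len(candidates))
        doc_gold = list(gold.get(doc_id, [])) if gold else []
        gold_total += len(doc_gold)
        for t in thresholds:
            selected = threshold_filter(candidates, t)
            if doc_gold:
                reachable = {
                    (c.ngram.char_span, c.concept_id) for c in selected
                }
                candidate_recall_hits[t] += sum(
                    1 for span, cid in doc_gold if (tuple(span), cid) in reachable
                )
            selected = pinpoint(selected)
            selected = context_filter(selected, collections, text, provider)
            links = minimize_nesting(selected, provider)
            per_threshold_links[t][doc_id] = [
                (l.char_span, l.concept_id) for l in links
            ]
            if t == thresholds[0]:
                links_per_doc[doc_id] = links
        if gold is not None:
            update_collections(links_per_doc[doc_id], doc_gold, text, collections)

    result: dict = {
        "links": links_per_doc,
        "collections": collections,
        "metrics": None,
        "sweep": None,
    }
    if gold is not None:
        rows = []
        for t in thresholds:
            report = score_links(per_threshold_links[t], gold)
            rows.append(
                {
                    "threshold": t,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                    "candidate_recall": (
                        candidate_recall_hits[t] / gold_total if gold_total else 0.0
                    ),
                }
            )
        result["sweep"] = rows
        result["metrics"] = rows[0]
    return result


def run_classify(
    records: Sequence[PatientRecord],
    index: TerminologyIndex,
    config: PipelineConfig,
    feature_modes: Sequence[str] = ("ehr_only", "concepts_only", "combined"),
) -> list[dict]:
    """Cross-validate the classifier in each feature mode (comparison table)."""
    train_config = TrainConfig(random_seed=config.seed)
    rows = []
    for mode in feature_modes:
        result = cross_validate(records, index, train_config, feature_mode=mode)
        log.info(
            "classify %s: P=%.3f R=%.3f F1=%.3f",
            mode, result["precision"], result["recall"], result["f1"],
        )
        rows.append(result)
    return rows


def save_link_run(
    result: dict,
    out_dir: str | Path,
    config: PipelineConfig,
) -> None:
    """Persist a linking run: link table, provenance, optional metrics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_link_table(
        result["links"], out_dir / "links.tsv", out_dir / "links_provenance.json",
        config.linker_config(),
    )
    write_provenance(config, out_dir / "run_provenance.json")
    if result["sweep"] is not None:
        (out_dir / "metrics.json").write_text(
            json.dumps({"provenance": provenance(config), "sweep": result["sweep"]},
                       indent=2),
            encoding="utf-8",
        )
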