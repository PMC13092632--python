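"""Deterministic synthetic study data with planted ground truth.

The licensed corpora a full deployment consumes — a terminology release,
reference corpora for context harvesting, sense-labeled abbreviation
snippets, gold-annotated documents and a labeled patient cohort — are
emulated here by pure generator functions of ``(spec, seed)``.  Every
generator plants its own ground truth and returns it alongside the data,
so each pipeline stage can be evaluated offline against known answers.

Design properties the generators guarantee *for every seed*:

* vocabulary words are rejection-sampled so any two distinct planted words
  have hashing-embedder cosine below 0.5; consequently planted mentions are
  the only n-grams reaching the 0.9 linking threshold, and end-to-end
  planted-truth linking is exact;
* abbreviation senses get disjoint discriminative keyword pools, so the
  correct sense's context samples dominate the similarity comparison;
* each generator draws from its own random stream, seeded by the master
  seed and the generator's name, so adding one generator never shifts
  another's output;
* generated files are written in exactly the dialects the production
  readers consume (RF2-style TSV, PubTator, pipe-delimited standoff,
  delimited dictionaries, CSV cohort).

The synthetic language is not clinical prose: words are pronounceable
nonsense.  The hashing embedder is language-agnostic, so nothing in the
pipeline depends on the words meaning anything.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .abbreviation import AbbreviationDictionary, collect_context_samples
from .embedding import HashingEmbeddingProvider
from .hf_classification import CLASSES, PatientRecord
from .terminology import Concept, ConceptDescription, TerminologyIndex, write_rf2

__all__ = [
    "FixtureSpec",
    "TerminologyFixture",
    "AbbrevFixture",
    "AnnotatedDocsFixture",
    "CohortFixture",
    "make_terminology",
    "make_abbrev_corpus",
    "make_annotated_docs",
    "make_cohort",
    "write_cohort_csv",
    "load_cohort_csv",
]

# class prevalence of a specialty heart-failure cohort: No-HF 41.5%, HFrEF 22.8%, HFmrEF 20.7%, HFpEF 15.0%
CLASS_MIX = (0.415, 0.228, 0.207, 0.150)

_WORD_SEPARATION = 0.5  # max allowed pairwise hash-embedding cosine of planted words


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic study conditions (defaults = test scale)."""

    seed: int = 2026
    n_concepts: int = 60
    hierarchy_depth: int = 4
    synonyms_per_concept: int = 2
    ambiguity_rate: float = 0.1
    n_abbrevs: int = 10
    senses_per_abbrev: int = 2
    n_snippets: int = 100
    n_docs: int = 20
    mentions_per_doc: int = 3
    nesting_rate: float = 0.2
    n_patients: int = 200
    markers_per_class: int = 5
    ehr_noise_features: int = 2
    signal_strength: float = 1.0
    context_samples_per_sense: int = 30

    def rng(self, generator_name: str) -> np.random.Generator:
        """Independent stream per generator: seeded by (seed, name)."""
        return np.random.default_rng([self.seed, zlib.crc32(generator_name.encode())])


# ---------------------------------------------------------------------------
# word sampling

_CONSONANTS = list("bcdfgklmnprstvz")
_VOWELS = list("aeiou")
_PROVIDER = HashingEmbeddingProvider()


class _WordSampler:
    """Draws pronounceable nonsense words, mutually separated in 3-gram space.

    A candidate is rejected if its hashing-embedder cosine with any word
    accepted so far (or supplied as pre-existing) reaches the separation
    bound — this is what makes planted-mention retrieval exact at high
    thresholds regardless of the seed.
    """

    def __init__(self, rng: np.random.Generator, avoid: Sequence[str] = ()):
        self.rng = rng
        self.words: list[str] = []
        self._matrix = (
            _PROVIDER.embed(list(avoid)) if avoid else np.empty((0, _PROVIDER.dim))
        )

    def _candidate(self) -> str:
        n_syllables = int(self.rng.integers(3, 6))
        return "".join(
            self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
            for _ in range(n_syllables)
        )

    def draw(self) -> str:
        for _ in range(200):
            word = self._candidate()
            vec = _PROVIDER.embed_one(word)
            if self._matrix.shape[0] and float(np.max(self._matrix @ vec)) >= _WORD_SEPARATION:
                continue
            self._matrix = np.vstack([self._matrix, vec])
            self.words.append(word)
            return word
        raise RuntimeError("word sampler failed to find a separated word")  # pragma: no cover

    def draw_many(self, n: int) -> list[str]:
        return [self.draw() for _ in range(n)]


# ---------------------------------------------------------------------------
# terminology


@dataclass
class TerminologyFixture:
    index: TerminologyIndex
    true_ancestors: dict[str, frozenset[str]]
    ambiguous_description_ids: set[str]
    mention_pool: list[tuple[str, str]]  # (description text, sole concept id)
    wrappers: list[tuple[str, str, str, str]]  # (outer text, outer cid, inner text, inner cid)
    description_words: list[str]


def _brute_force_ancestors(parents: dict[str, set[str]]) -> dict[str, frozenset[str]]:
    out = {}
    for cid in parents:
        seen: set[str] = set()
        frontier = set(parents[cid])
        while frontier:
            p = frontier.pop()
            if p not in seen:
                seen.add(p)
                frontier |= parents[p]
        out[cid] = frozenset(seen)
    return out


def make_terminology(spec: FixtureSpec, out_dir: str | Path | None = None) -> TerminologyFixture:
    """Toy is-a terminology with synonyms, planted ambiguity and wrappers.

    Concepts form a forest capped at ``hierarchy_depth``.  Each concept gets
    ``synonyms_per_concept`` descriptions of one or two unique words; an
    ``ambiguity_rate`` fraction of descriptions is attached to a second
    concept.  On top, a set of *wrapper* concepts is added whose single
    description embeds another concept's description verbatim (the nested
    "family history: hypertension" pattern), to exercise nesting
    minimization.  Truth tables carry brute-force ancestors, the planted
    ambiguous set, and the pool of unambiguous single-concept mentions.
    """
    if spec.ambiguity_rate > 0 and spec.n_concepts < 2:
        raise ValueError("ambiguity requires at least two concepts")
    rng = spec.rng("terminology")
    sampler = _WordSampler(rng)

    concept_ids = [f"{1000 + i}009" for i in range(spec.n_concepts)]
    depth: dict[str, int] = {}
    parents: dict[str, set[str]] = {cid: set() for cid in concept_ids}
    categories = ["finding", "procedure", "body structure"]
    concepts: dict[str, Concept] = {}
    for i, cid in enumerate(concept_ids):
        if i > 0 and rng.random() < 0.8:
            parent = concept_ids[int(rng.integers(0, i))]
            if depth[parent] + 1 < spec.hierarchy_depth:
                parents[cid].add(parent)
        depth[cid] = 1 + max((depth[p] for p in parents[cid]), default=-1)
        name_word = sampler.draw()
        concepts[cid] = Concept(
            concept_id=cid,
            preferred_name=name_word.capitalize(),
            category=categories[i % len(categories)],
            parent_ids=set(parents[cid]),
        )

    descriptions: dict[str, ConceptDescription] = {}
    mention_pool: list[tuple[str, str]] = []
    serial = 0
    for cid in concept_ids:
        for _ in range(spec.synonyms_per_concept):
            serial += 1
            n_words = int(rng.integers(1, 3))
            text = " ".join(sampler.draw_many(n_words))
            descriptions[f"d{serial:05d}"] = ConceptDescription(
                description_id=f"d{serial:05d}", text=text, concept_ids={cid}
            )

    desc_ids = sorted(descriptions)
    n_ambiguous = int(round(spec.ambiguity_rate * len(desc_ids)))
    ambiguous_ids = set()
    if n_ambiguous:
        chosen = rng.choice(len(desc_ids), size=n_ambiguous, replace=False)
        for j in sorted(int(c) for c in chosen):
            did = desc_ids[j]
            owner = next(iter(descriptions[did].concept_ids))
            others = [c for c in concept_ids if c != owner]
            descriptions[did].concept_ids.add(others[int(rng.integers(0, len(others)))])
            ambiguous_ids.add(did)

    for did in desc_ids:
        d = descriptions[did]
        if not d.is_ambiguous:
            mention_pool.append((d.text, next(iter(d.concept_ids))))

    # wrapper concepts: one per nesting slot, covering up to n_docs nest events
    wrappers = []
    n_wrappers = max(1, int(np.ceil(spec.nesting_rate * spec.n_docs)))
    single_word_mentions = [m for m in mention_pool if " " not in m[0]]
    rng.shuffle(single_word_mentions)
    for w in range(min(n_wrappers, len(single_word_mentions))):
        inner_text, inner_cid = single_word_mentions[w]
        prefix = sampler.draw()
        serial += 1
        outer_cid = f"{9000 + w}005"
        outer_text = f"{prefix} {inner_text}"
        concepts[outer_cid] = Concept(
            concept_id=outer_cid,
            preferred_name=f"{prefix.capitalize()} situation",
            category="situation",
        )
        descriptions[f"d{serial:05d}"] = ConceptDescription(
            description_id=f"d{serial:05d}", text=outer_text, concept_ids={outer_cid}
        )
        wrappers.append((outer_text, outer_cid, inner_text, inner_cid))
        mention_pool.remove((inner_text, inner_cid))

    all_parents = {cid: set(c.parent_ids) for cid, c in concepts.items()}
    index = TerminologyIndex(concepts, descriptions)
    fixture = TerminologyFixture(
        index=index,
        true_ancestors=_brute_force_ancestors(all_parents),
        ambiguous_description_ids=ambiguous_ids,
        mention_pool=sorted(mention_pool),
        wrappers=wrappers,
        description_words=list(sampler.words),
    )
    if out_dir is not None:
        write_rf2(index, out_dir)
    return fixture


# ---------------------------------------------------------------------------
# abbreviation corpus


@dataclass
class Snippet:
    text: str
    span: tuple[int, int]
    abbreviation: str
    gold_expansion: str


@dataclass
class AbbrevFixture:
    dictionary: AbbreviationDictionary
    corpus: list[str]
    snippets: list[Snippet]
    sense_keywords: dict[tuple[str, str], list[str]]
    zero_context_senses: list[tuple[str, str]]


def _unique_abbreviations(rng: np.random.Generator, n: int) -> list[str]:
    letters = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    out: list[str] = []
    seen = set()
    while len(out) < n:
        length = int(rng.integers(2, 4))
        cand = "".join(rng.choice(letters) for _ in range(length))
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def make_abbrev_corpus(spec: FixtureSpec, out_dir: str | Path | None = None) -> AbbrevFixture:
    """Abbreviation dictionary, context corpus and sense-labeled snippets.

    Each abbreviation has ``senses_per_abbrev`` expansions with disjoint
    five-word discriminative keyword pools.  The context corpus contains,
    per selectable sense, more sentences than the per-sense cap (each built
    from the expansion text plus keyword draws), so harvesting exercises the
    cap.  Snippets place the abbreviation next to keywords of the gold
    sense.  The last abbreviation's final sense is deliberately absent from
    the corpus — a zero-context sense that must never be selected.
    """
    rng = spec.rng("abbreviations")
    sampler = _WordSampler(rng)
    abbrevs = _unique_abbreviations(rng, spec.n_abbrevs)

    dictionary = AbbreviationDictionary(max_context_samples=spec.context_samples_per_sense)
    sense_keywords: dict[tuple[str, str], list[str]] = {}
    zero_context: list[tuple[str, str]] = []
    corpus_sentences: list[str] = []
    for a_idx, abbrev in enumerate(abbrevs):
        for s_idx in range(spec.senses_per_abbrev):
            expansion = " ".join(sampler.draw_many(2))
            dictionary.add(abbrev, expansion)
            keywords = sampler.draw_many(5)
            sense_keywords[(abbrev, expansion)] = keywords
            is_zero_context = (
                a_idx == len(abbrevs) - 1 and s_idx == spec.senses_per_abbrev - 1
            )
            if is_zero_context:
                zero_context.append((abbrev, expansion))
                continue
            n_sentences = spec.context_samples_per_sense + 10
            for _ in range(n_sentences):
                picked = rng.choice(keywords, size=3, replace=False)
                corpus_sentences.append(f"{expansion} {' '.join(picked)}.")
    rng.shuffle(corpus_sentences)
    corpus = [" ".join(corpus_sentences[i::7]) for i in range(7)]  # 7 synthetic documents
    collect_context_samples(corpus, dictionary, spec.context_samples_per_sense)

    snippets: list[Snippet] = []
    selectable = [k for k in sense_keywords if k not in zero_context]
    for i in range(spec.n_snippets):
        abbrev, expansion = selectable[i % len(selectable)]
        keywords = sense_keywords[(abbrev, expansion)]
        picked = rng.choice(keywords, size=3, replace=False)
        prefix = ""
        text = f"{prefix}{abbrev} {' '.join(picked)}."
        snippets.append(
            Snippet(
                text=text,
                span=(len(prefix), len(prefix) + len(abbrev)),
                abbreviation=abbrev,
                gold_expansion=expansion,
            )
        )

    fixture = AbbrevFixture(dictionary, corpus, snippets, sense_keywords, zero_context)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dictionary.save(out_dir / "abbreviations.tsv")
        dictionary.save_context_samples(out_dir / "context_samples.tsv")
        with (out_dir / "snippets.tsv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["text", "start", "end", "abbreviation", "gold_expansion"])
            for s in snippets:
                w.writerow([s.text, s.span[0], s.span[1], s.abbreviation, s.gold_expansion])
    return fixture


# ---------------------------------------------------------------------------
# annotated documents


@dataclass
class AnnotatedDocsFixture:
    documents: dict[str, str]
    gold: dict[str, list[tuple[tuple[int, int], str]]]


def make_annotated_docs(
    spec: FixtureSpec,
    terminology: TerminologyFixture,
    out_dir: str | Path | None = None,
) -> AnnotatedDocsFixture:
    """Documents with planted verbatim mentions and exact standoff gold.

    Every mention is an unambiguous terminology description copied verbatim
    between filler words (filler is rejection-sampled against all planted
    description words, so no filler n-gram resembles a description).  A
    ``nesting_rate`` fraction of documents plants a wrapper mention — gold
    then contains the *outer* link only, since the inner text is
    semantically subsumed and nesting minimization must dismiss it.
    """
    rng = spec.rng("annotated_docs")
    filler_sampler = _WordSampler(rng, avoid=terminology.description_words)
    filler = filler_sampler.draw_many(12)
    pool = list(terminology.mention_pool)
    wrappers = list(terminology.wrappers)
    n_nested = int(round(spec.nesting_rate * spec.n_docs))

    documents: dict[str, str] = {}
    gold: dict[str, list[tuple[tuple[int, int], str]]] = {}
    for d in range(spec.n_docs):
        doc_id = f"doc{d:03d}"
        parts: list[str] = []
        annotations: list[tuple[tuple[int, int], str]] = []
        cursor = 0

        def _append(fragment: str) -> None:
            nonlocal cursor
            parts.append(fragment)
            cursor += len(fragment)

        n_mentions = spec.mentions_per_doc
        use_wrapper = d < n_nested and wrappers
        for m in range(n_mentions):
            _append(str(rng.choice(filler)) + " ")
            if m == 0 and use_wrapper:
                outer_text, outer_cid, _inner_text, _inner_cid = wrappers[d % len(wrappers)]
                annotations.append(((cursor, cursor + len(outer_text)), outer_cid))
                _append(outer_text)
            else:
                text, cid = pool[int(rng.integers(0, len(pool)))]
                annotations.append(((cursor, cursor + len(text)), cid))
                _append(text)
            _append(" " + str(rng.choice(filler)) + ". ")
        documents[doc_id] = "".join(parts).rstrip()
        gold[doc_id] = annotations

    fixture = AnnotatedDocsFixture(documents, gold)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with (out_dir / "corpus.pubtator").open("w", encoding="utf-8") as fh:
            for doc_id in sorted(documents):
                fh.write(f"{doc_id}|t|{documents[doc_id]}\n")
                for (s, e), cid in gold[doc_id]:
                    mention = documents[doc_id][s:e]
                    fh.write(f"{doc_id}\t{s}\t{e}\t{mention}\tMention\t{cid}\n")
                fh.write("\n")
        with (out_dir / "gold.standoff").open("w", encoding="utf-8") as fh:
            for doc_id in sorted(gold):
                for (s, e), cid in gold[doc_id]:
                    fh.write(f"{doc_id}|{s}-{e}|{cid}\n")
    return fixture


# ---------------------------------------------------------------------------
# patient cohort


@dataclass
class CohortFixture:
    records: list[PatientRecord]
    markers: dict[str, list[str]]  # class -> exclusive marker concept ids
    class_counts: dict[str, int]


# per-class EHR profile at full signal: (ejection fraction mean, nt-proBNP-like mean)
_EHR_PROFILE = {
    "NoHF": (60.0, 100.0),
    "HFrEF": (32.0, 2500.0),
    "HFmrEF": (45.0, 1200.0),
    "HFpEF": (56.0, 900.0),
}


def make_cohort(
    spec: FixtureSpec,
    terminology: TerminologyFixture,
    out_dir: str | Path | None = None,
) -> CohortFixture:
    """Class-conditional patient cohort: marker concepts + shifted EHR.

    Class sizes follow the prevalence mix observed in a specialty heart
    failure cohort (41.5 / 22.8 / 20.7 / 15.0 %).  Each class owns
    ``markers_per_class`` exclusive marker concepts; a patient carries each
    of their class's markers with probability ``0.8 × signal_strength``
    plus background concepts shared across classes.  Numeric EHR features
    (ejection fraction and a natriuretic-peptide-like analyte) have class
    means interpolated toward a common value as ``signal_strength`` → 0;
    age, sex and noise features carry no class signal.  About 5 % of EHR
    values are missing, exercising imputation.
    """
    rng = spec.rng("cohort")
    concept_ids = sorted(terminology.index.concepts)
    needed = spec.markers_per_class * len(CLASSES)
    if needed + 5 > len(concept_ids):
        raise ValueError("not enough concepts for the requested marker count")
    marker_flat = [
        concept_ids[int(i)]
        for i in rng.choice(len(concept_ids), size=needed, replace=False)
    ]
    markers = {
        cls: marker_flat[i * spec.markers_per_class : (i + 1) * spec.markers_per_class]
        for i, cls in enumerate(CLASSES)
    }
    background = [c for c in concept_ids if c not in set(marker_flat)]

    # largest-remainder apportionment of the class mix
    raw = np.array(CLASS_MIX) * spec.n_patients
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: spec.n_patients - counts.sum()]:
        counts[i] += 1
    labels = [cls for cls, n in zip(CLASSES, counts) for _ in range(n)]
    rng.shuffle(labels)

    s = spec.signal_strength
    ef_base = float(np.mean([v[0] for v in _EHR_PROFILE.values()]))
    bnp_base = float(np.mean([v[1] for v in _EHR_PROFILE.values()]))
    records = []
    for i, label in enumerate(labels):
        bag = [
            m for m in markers[label] if rng.random() < 0.8 * s
        ]
        n_bg = int(rng.integers(3, 8))
        bag += [background[int(j)] for j in rng.integers(0, len(background), size=n_bg)]
        rng.shuffle(bag)

        ef_mean = ef_base + s * (_EHR_PROFILE[label][0] - ef_base)
        bnp_mean = bnp_base + s * (_EHR_PROFILE[label][1] - bnp_base)
        ehr: dict[str, object] = {
            "age": float(np.round(rng.normal(68, 11), 1)),
            "sex": str(rng.choice(["female", "male"])),
            "ejection_fraction": float(np.round(rng.normal(ef_mean, 7.0), 1)),
            "ntprobnp": float(np.round(max(10.0, rng.normal(bnp_mean, 600.0)), 1)),
        }
        for k in range(spec.ehr_noise_features):
            ehr[f"lab{k}"] = float(np.round(rng.normal(0, 1), 3))
        for key in list(ehr):
            if key != "sex" and rng.random() < 0.05:
                ehr[key] = None
        records.append(
            PatientRecord(patient_id=f"p{i:04d}", concept_ids=bag, ehr=ehr, label=label)
        )
    fixture = CohortFixture(
        records=records,
        markers=markers,
        class_counts={cls: int(n) for cls, n in zip(CLASSES, counts)},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(records, out_dir / "ehr.csv", out_dir / "concepts.tsv")
    return fixture


def write_cohort_csv(
    records: Sequence[PatientRecord],
    ehr_path: str | Path,
    concepts_path: str | Path,
    label_column: str = "diagnosis",
) -> None:
    feature_names = sorted({k for r in records for k in r.ehr})
    with Path(ehr_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["patient_id", *feature_names, label_column])
        for r in records:
            row = [r.patient_id]
            for k in feature_names:
                v = r.ehr.get(k)
                row.append("" if v is None else v)
            row.append(r.label)
            w.writerow(row)
    with Path(concepts_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient_id", "concept_id"])
        for r in records:
            for cid in r.concept_ids:
                w.writerow([r.patient_id, cid])


def load_cohort_csv(
    ehr_path: str | Path,
    concepts_path: str | Path,
    label_column: str = "diagnosis",
) -> list[PatientRecord]:
    """Read a cohort back from the CSV/TSV pair written by the generator."""
    concept_bags: dict[str, list[str]] = {}
    with Path(concepts_path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            concept_bags.setdefault(row["patient_id"], []).append(row["concept_id"])
    records = []
    with Path(ehr_path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row.pop("patient_id")
            label = row.pop(label_column)
            ehr: dict[str, object] = {}
            for k, v in row.items():
                if v == "":
                    ehr[k] = None
                else:
                    try:
                        ehr[k] = float(v)
                    except ValueError:
                        ehr[k] = v
            records.append(
                PatientRecord(
                    patient_id=pid,
                    concept_ids=concept_bags.get(pid, []),
                    ehr=ehr,
                    label=label,
                )
            )
    return records
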