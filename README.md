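# notelink

Clinical-note processing pipeline: context-based abbreviation
disambiguation, semantic entity linking of free-text spans to SNOMED-CT /
UMLS concepts, and ontology-aware four-class heart-failure classification
from linked concepts plus tabular EHR features.

## What it does

Clinical notes are dense with ambiguous abbreviations ("HT" — hypertension
or head trauma?) and free-text mentions of clinical concepts. The pipeline
turns a note into standardized terminology concepts and, per patient, a
heart-failure diagnosis, in four stages:

1. **Abbreviation disambiguation** (`notelink.abbreviation`). A dictionary
   maps each abbreviation to its candidate expansions, each carrying up to
   30 *context samples* — sentences harvested from a reference corpus where
   the expansion appears spelled out. At disambiguation time the sentence
   surrounding an abbreviation is embedded and compared against every
   sample of every sense; the best-scoring sense wins if its similarity
   clears a gate (default 0.3). No sense-labeled training data is needed
   (zero-shot).
2. **Translation hook** (`notelink.pipeline.translate`). Identity by
   default; optionally pipes sentence-boundary chunks through an external
   command.
3. **Entity linking** (`notelink.entity_linking`). High-recall *candidate
   identification*: all token n-grams up to 30 tokens (minus spans crossing
   sentence/bullet boundaries), abbreviation-expanded in place, each
   retrieving its top-10 most similar concept descriptions by embedding
   cosine. Then four precision-oriented *selection* steps: similarity
   threshold (default 0.95), pinpointing (best span per overlapping
   cluster per concept), a context-collection filter fed by online
   learning from feedback, and nesting minimization (an inner link is
   dismissed when excising its text lowers the outer link's similarity —
   "hypertension" inside "family history: hypertension" links only the
   family-history concept).
4. **Heart-failure classification** (`notelink.hf_classification`).
   Patients are represented by a TF-IDF-weighted bag of their linked
   concepts *plus all is-a ancestors*, concatenated with normalized EHR
   features, and classified into NoHF / HFrEF / HFmrEF / HFpEF by a
   hinge-loss linear SVM with balanced class weights under stratified
   5-fold cross-validation.

Embeddings come from a pluggable provider. The default,
`HashingEmbeddingProvider`, is a fully deterministic character-3-gram
signed-hashing embedder (BLAKE2b, 256 dimensions, L2-normalized) that
needs no model downloads and is bit-identical across processes and
platforms; an optional neural provider using `sentence-transformers` can
be swapped in (`pip install notelink[neural]`).

Because licensed corpora (SNOMED-CT, UMLS, clinical datasets) cannot ship
with the package, `notelink.fixtures` generates a complete synthetic study
environment — terminology release, abbreviation corpus, gold-annotated
documents, labeled patient cohort — with *planted ground truth*, fully
determined by a single seed.

## Worked example

```bash
# generate synthetic study data (terminology, corpus, gold, cohort)
notelink fixtures data --seed 1

# link the corpus against the terminology and score against gold
notelink link data/linking/corpus.pubtator data/terminology run \
    --gold data/linking/gold.standoff --selection-threshold 0.9

# cross-validate the heart-failure classifier
notelink classify data/cohort/ehr.csv data/cohort/concepts.tsv \
    data/terminology classify.json
```

With seed 1 the link step reports `P=100.0% R=100.0% F1=100.0%` — the
fixture generator rejection-samples its vocabulary so planted mentions are
the only spans reaching the threshold — and the classify step prints the
three-mode comparison:

```
ehr_only: P=65.5% R=65.0% F1=65.0%
concepts_only: P=99.0% R=99.0% F1=99.0%
combined: P=97.1% R=97.0% F1=97.0%
```

The same operations are available as a library; see the module docstrings
in `src/notelink/` and `docs/methods.md` for the model details.

## Reproducing results

`scripts/acceptance.py` regenerates all fixtures from a master seed, runs
disambiguation, linking (with online learning) and classification, and
writes the headline quantities as JSON:

```bash
python scripts/acceptance.py --seed 2026 --out results/acceptance.json
```

Every generator draws from its own seed-derived stream, cross-validation
splits are seeded, and the default embedder is deterministic, so repeated
runs are bit-identical; `tests/test_acceptance.py` checks each of these
guarantees, the metric arithmetic, and the algorithmic primitives against
independent brute-force oracles.
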