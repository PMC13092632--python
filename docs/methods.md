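# Methods

This document records the model implemented by `notelink`, the parameter
defaults and why they were chosen, the scope of the synthetic-data
generators, and the numerical conventions.

## Model

### Embeddings

All semantic comparisons reduce to cosine similarity between text
embeddings from an `EmbeddingProvider`. The default provider
(`HashingEmbeddingProvider`, name `hash-3gram`) is deterministic and
dependency-free:

1. lowercase, collapse runs of whitespace, pad with one leading/trailing
   space;
2. for every character 3-gram, hash with BLAKE2b (8-byte digest, big
   endian integer `v`), add `+1` or `−1` (sign bit `(v // dim) & 1`) to
   bucket `v % dim`, with `dim = 256`;
3. L2-normalize (an all-zero vector falls back to axis 0).

This is a signed feature-hashing ("hashing trick") embedder: surface
overlap of character 3-grams approximates semantic similarity well enough
to drive the pipeline's comparisons on synthetic data, while being
bit-identical across processes and platforms. A neural provider backed by
`sentence-transformers` implements the same interface for real clinical
text (extra `neural`); nothing downstream depends on which provider is
used. An `EmbeddingCache` memoizes embeddings keyed by (provider, text).

Retrieval (`DescriptionIndex`) is an exact dense scan: scores are a
matrix–vector product, top-k is selected with ties broken by ascending
description id, making results independent of insertion order.

### Terminology

`TerminologyIndex` holds concepts (id, preferred name, semantic category,
parent ids) and descriptions (id, text, owning concept ids). Two release
dialects are parsed: RF2 snapshot tables (active rows only; hierarchy from
the "is a" relationship type 116680003; FSN rows supply the preferred name
with the trailing semantic tag split into the category) and RRF
(MRCONSO/MRSTY; suppressed atoms dropped; no hierarchy edges). Ancestor
sets are memoized iterative transitive closures. A description attached to
two or more concepts is *ambiguous*; descriptions identical up to case are
deduplicated into one entry holding the union of concept ids.

### Abbreviation disambiguation

Detection scans for dictionary keys at non-alphanumeric boundaries,
longest key first; an all-uppercase key matches case-sensitively (so "ap"
never triggers "AP"). Disambiguation embeds the sentence containing the
match and takes, over every sense's context samples, the maximum cosine;
the best sense is chosen iff that score reaches the gate
(`abbrev_gate`, default 0.3). Senses without samples are never chosen.
Context samples are harvested from a reference corpus by verbatim
case-insensitive sentence match, capped at 30 per sense in encounter
order. `expand_all` rewrites the text and returns an `OffsetMap` so later
spans can be mapped between original and expanded coordinates.

The gate trades recall against expansion accuracy: raising it refuses
low-evidence expansions, so recall is non-increasing in the gate (a tested
invariant). 0.3 is the default operating point; sweeps over 0.1–0.9 are
the intended evaluation protocol.

### Entity linking

Candidate identification (recall): (1) build the abbreviation table;
(2) enumerate token n-grams of length 1..30 over non-alphanumeric
boundaries (long n-grams align with long pre-coordinated concept names);
(3) drop n-grams containing ". " or "- " (spans crossing sentence or
bullet boundaries), splice abbreviation expansions into the survivors
while keeping original character spans; (4) retrieve the top-10 most
similar descriptions per n-gram; each (n-gram, concept) pair is a
candidate.

Candidate selection (precision), in order:

1. **Threshold** — keep candidates with similarity ≥ t, t ∈ [0.9, 0.99]
   (default 0.95, the grid's F1 optimum under the intended protocol).
2. **Pinpointing** — per concept, overlapping spans are grouped into
   connected components of the overlap graph (interval sweep); only the
   highest-similarity candidate per component survives (ties: shorter
   span, then leftmost).
3. **Context-collection filter** — online learning accumulates per-concept
   positive sentences (gold links) and negative sentences (predictions
   absent from gold), strictly after the document's own linking. A concept
   with only negative evidence is blacklisted; with both kinds, a
   candidate is dismissed when the best negative similarity to its local
   sentence strictly exceeds the best positive one.
4. **Nesting minimization** — for an inner span strictly contained in an
   outer span, the outer n-gram is re-scored against its matched
   description with the inner text excised; a similarity drop means the
   inner text carried the outer concept's meaning, so the inner link is
   dismissed; a rise or tie keeps both.

Scoring is exact: a predicted link is a true positive only when span and
concept id both match gold in the same document; counts are pooled across
documents (micro) by default.

### Heart-failure classification

Feature vector per patient = TF-IDF-weighted concept bag ⊕ normalized EHR
features. Each linked concept contributes itself plus all is-a ancestors,
so rare specific findings generalize upward. TF-IDF uses the smoothed
formulation `idf = ln((1+N)/(1+df)) + 1` with L2-normalized rows;
vocabulary and idf come from training folds only. EHR normalization infers
feature types at fit: numeric features are z-scored (zero variance → unit
divisor; missing → training median), categoricals one-hot encoded with an
explicit "missing" level (unseen categories fold into it); unknown
features at transform time are schema errors.

Classifier: `SGDClassifier(loss="hinge", class_weight="balanced",
random_state=seed)` — a one-vs-rest linear SVM — over the classes NoHF,
HFrEF, HFmrEF, HFpEF. Evaluation: `StratifiedKFold(5, shuffle=True,
random_state=seed)`; predictions pooled across test folds; reported as
support-weighted and macro precision/recall/F1 plus a row-normalized
confusion matrix. Decision values are softmax-normalized for reporting
only — hinge margins are not calibrated probabilities.

## Metrics conventions

* Every 0/0 ratio is 0 (empty evaluations score nothing).
* Percentages round half-up to one decimal (`decimal.Decimal`, not
  banker's rounding).
* Expansion accuracy = correct / (correct + incorrect attempted
  expansions); total accuracy = detection recall × expansion accuracy.
* Cohen's kappa uses the textbook marginal-product expected agreement;
  the degenerate p_e = 1 case returns 1. The "kappa paradox" (high raw
  agreement, low kappa under imbalanced marginals) is reproduced in tests.

## Synthetic data generators

`notelink.fixtures` replaces the licensed corpora with pure functions of a
`FixtureSpec`. Each generator draws from `default_rng([seed,
crc32(name)])`, so streams are independent and adding a generator never
shifts another's output. Scope and guarantees:

* **Vocabulary separation.** All planted words are rejection-sampled so
  any two distinct words have hashing-embedder cosine < 0.5. Consequently
  planted mentions are the only n-grams reaching a 0.9 linking threshold
  and planted-truth linking is exact for every seed — a design property,
  not a tuned outcome.
* **Terminology**: a forest of 60 concepts (depth ≤ 4), two synonyms per
  concept, 10% of descriptions planted ambiguous, plus wrapper concepts
  whose description embeds another concept's description verbatim (the
  "family history: hypertension" nesting pattern). Truth tables carry
  brute-force ancestor sets and the ambiguous id set.
* **Abbreviation corpus**: 10 abbreviations × 2 senses with disjoint
  5-word keyword pools; the reference corpus contains more sentences per
  sense than the 30-sample cap (exercising the cap); one sense is absent
  from the corpus (a zero-context sense that must never be selected);
  100 sense-labeled snippets.
* **Annotated documents**: 20 documents × 3 verbatim mentions between
  filler words (filler rejection-sampled against description words); 20%
  of documents plant a wrapper mention whose gold is the *outer* concept
  only, so nesting minimization must dismiss the inner link.
* **Cohort**: 200 patients at class mix 41.5 / 22.8 / 20.7 / 15.0%
  (largest-remainder apportionment); each class owns 5 exclusive marker
  concepts carried with probability 0.8 × signal_strength over 3–7
  background concepts; numeric EHR features (ejection fraction, an
  NT-proBNP-like analyte) with class means interpolated toward a common
  value as signal_strength → 0; ~5% missing values. The generators are
  label-faithful: zero signal removes all class information, which the
  permuted-label acceptance check exploits from the other direction.

Limits: the synthetic language is pronounceable nonsense, not clinical
prose; separation is enforced only for planted words, so real-text recall
characteristics (near-synonyms, paraphrase) are out of scope for the
fixtures; the hashing embedder measures surface overlap, not meaning.

## Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| `abbrev_gate` | 0.3 | operating point between recall and expansion accuracy; sweep 0.1–0.9 |
| `selection_threshold` | 0.95 | F1 optimum on the 0.90–0.99 evaluation grid |
| `top_k` | 10 | candidate descriptions per n-gram |
| `max_ngram_len` | 30 | covers long pre-coordinated concept names |
| `prohibited_infixes` | ". ", "- " | spans crossing sentence/bullet boundaries |
| context samples / sense | 30 | harvest cap |
| embedding dim | 256 | hashing-provider bucket count |
| CV folds / seed | 5 / 2026 | stratified shuffled splits |
| `translation_chunk_chars` | 1000 | chunking at sentence boundaries under a character budget (external models impose token limits; no chunk size is canonical, so it is a config knob) |

## Open design decisions

* The selection threshold for the classification corpus run is a config
  choice (0.95), not a fixed constant of the method.
* Translation is a hook only; the library makes no translation-quality
  claims. Chunk boundaries are sentence boundaries under a character
  budget.
* The deterministic hashing embedder is the default so that tests and the
  acceptance run are offline and reproducible; swapping in a neural
  provider changes the similarity geometry but no interfaces.

## Limitations

* Exact dense retrieval scans all descriptions; for multi-million-entry
  terminologies an approximate nearest-neighbour index would be needed.
* Online learning assumes document-level gold feedback; without feedback
  the context filter passes everything through.
* The confusion between near-identical sibling descriptions is limited
  only by the embedding provider; the fixtures deliberately avoid it.
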