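"""Candidate identification, the four selection steps, and online learning."""

import itertools

import numpy as np
import pytest

from notelink.abbreviation import AbbreviationDictionary
from notelink.embedding import EmbeddingCache
from notelink.entity_linking import (
    ContextCollection,
    EntityLinkCandidate,
    LinkerConfig,
    NGram,
    context_filter,
    enumerate_ngrams,
    identify_candidates,
    link_document,
    minimize_nesting,
    pinpoint,
    read_pipe_standoff,
    read_pubtator,
    threshold_filter,
    update_collections,
    write_link_table,
)
from notelink.terminology import Concept, ConceptDescription, TerminologyIndex


def _mini_index(provider, desc_to_concepts, parents=None):
    concepts = {}
    for concepts_for_desc in desc_to_concepts.values():
        for cid in concepts_for_desc:
            concepts.setdefault(cid, Concept(cid, cid, parent_ids=set((parents or {}).get(cid, []))))
    descriptions = {
        f"d{i:03d}": ConceptDescription(f"d{i:03d}", text, set(cids))
        for i, (text, cids) in enumerate(sorted(desc_to_concepts.items()))
    }
    index = TerminologyIndex(concepts, descriptions)
    index.build_description_index(EmbeddingCache(provider))
    return index


def _cand(span, concept, sim, text=None, desc="x"):
    return EntityLinkCandidate(
        ngram=NGram(span, text or "t" * (span[1] - span[0]), 1),
        concept_id=concept,
        matched_description=desc,
        similarity=sim,
    )


class TestNGramEnumeration:
    def test_counts_match_combinatorial_formula(self):
        text = " ".join(f"tok{i}" for i in range(30))
        for max_len in (1, 5, 30, 40):
            grams = enumerate_ngrams(text, max_len)
            t = 30
            expected = sum(t - n + 1 for n in range(1, min(max_len, t) + 1))
            assert len(grams) == expected
            # brute-force oracle over token windows
            tokens = text.split()
            seen = {(g.char_span, g.text) for g in grams}
            brute = set()
            pos = 0
            starts = []
            for tok in tokens:
                starts.append(text.index(tok, pos))
                pos = starts[-1] + len(tok)
            for n in range(1, min(max_len, t) + 1):
                for i in range(t - n + 1):
                    s = starts[i]
                    e = starts[i + n - 1] + len(tokens[i + n - 1])
                    brute.add(((s, e), text[s:e]))
            assert seen == brute

    def test_spans_are_original_coordinates(self):
        grams = enumerate_ngrams("ab, cd", 2)
        assert {(g.char_span, g.text) for g in grams} == {
            ((0, 2), "ab"), ((4, 6), "cd"), ((0, 6), "ab, cd"),
        }


class TestIdentifyCandidates:
    def test_prohibited_infix_drops_cross_sentence_ngrams(self, provider):
        index = _mini_index(provider, {"therapy": ["c1"], "family": ["c2"]})
        config = LinkerConfig(top_k=1, selection_threshold=0.9)
        cands = identify_candidates(
            "family. Therapy", index, None, provider, config
        )
        texts = {c.ngram.text for c in cands}
        assert "family. Therapy" not in texts
        assert {"family", "Therapy"} <= texts

    def test_empty_document_yields_no_candidates(self, provider):
        index = _mini_index(provider, {"x y": ["c1"]})
        assert identify_candidates("   ", index, None, provider, LinkerConfig()) == []

    def test_unembedded_index_is_state_error(self, provider):
        index = TerminologyIndex(
            {"c1": Concept("c1", "c1")},
            {"d1": ConceptDescription("d1", "text", {"c1"})},
        )
        with pytest.raises(RuntimeError):
            identify_candidates("text", index, None, provider, LinkerConfig())

    def test_abbreviation_expanded_inside_ngram_with_span_preserved(self, provider):
        index = _mini_index(provider, {"hypertension runs in the family": ["c1"]})
        d = AbbreviationDictionary.from_pairs([("HT", "hypertension")])
        d.entries["HT"][0].context_samples = ["hypertension runs in the family"]
        config = LinkerConfig(top_k=1, selection_threshold=0.9)
        cands = identify_candidates(
            "HT runs in the family", index, d, provider, config, with_abbrev=True
        )
        exact = [c for c in cands if c.similarity > 0.999]
        assert exact
        assert exact[0].ngram.char_span == (0, len("HT runs in the family"))
        assert exact[0].ngram.text == "hypertension runs in the family"

    def test_ambiguous_description_yields_one_candidate_per_concept(self, provider):
        index = _mini_index(provider, {"cell": ["c1", "c2"]})
        cands = identify_candidates(
            "cell", index, None, provider, LinkerConfig(top_k=1)
        )
        assert {(c.concept_id, round(c.similarity, 6)) for c in cands} == {
            ("c1", 1.0), ("c2", 1.0),
        }


class TestThresholdFilter:
    def test_keeps_only_scores_at_or_above_threshold(self):
        cands = [
            _cand((0, 7), "hospital-patient", 0.83),
            _cand((0, 7), "patient", 1.0),
        ]
        kept = threshold_filter(cands, 0.9)
        assert [c.concept_id for c in kept] == ["patient"]

    def test_zero_threshold_is_identity(self):
        cands = [_cand((0, 3), "a", 0.1), _cand((4, 5), "b", 0.9)]
        assert threshold_filter(cands, 0.0) == cands

    def test_monotone_nesting_of_outputs(self, rng):
        cands = [
            _cand((int(s), int(s) + 3), f"c{i}", float(x))
            for i, (s, x) in enumerate(zip(rng.integers(0, 50, 40), rng.random(40)))
        ]
        for t1, t2 in [(0.2, 0.5), (0.5, 0.9), (0.0, 1.0)]:
            assert set(map(id, threshold_filter(cands, t2))) <= set(
                map(id, threshold_filter(cands, t1))
            )


class TestPinpoint:
    def test_overlapping_same_concept_keeps_most_representative(self):
        outer = _cand((0, 11), "116154003", 0.93, text="The patient")
        inner = _cand((4, 11), "116154003", 1.0, text="patient")
        assert pinpoint([outer, inner]) == [inner]

    def test_disjoint_repeats_of_a_concept_all_survive(self):
        a = _cand((0, 7), "c", 1.0)
        b = _cand((20, 27), "c", 1.0)
        assert pinpoint([a, b]) == [a, b]

    def test_equal_similarity_prefers_shorter_then_leftmost(self):
        wide = _cand((0, 10), "c", 0.95)
        tight = _cand((2, 8), "c", 0.95)
        assert pinpoint([wide, tight]) == [tight]
        left = _cand((0, 6), "c", 0.95)
        right = _cand((4, 10), "c", 0.95)
        assert pinpoint([left, right]) == [left]

    def test_matches_bruteforce_component_oracle(self, rng):
        for _ in range(20):
            cands = []
            for i in range(int(rng.integers(2, 15))):
                s = int(rng.integers(0, 40))
                e = s + int(rng.integers(1, 10))
                cands.append(_cand((s, e), f"c{int(rng.integers(0, 3))}", float(rng.random())))
            # oracle: per concept, connected components of the overlap graph
            expected = []
            for cid in {c.concept_id for c in cands}:
                group = [c for c in cands if c.concept_id == cid]
                comp_of = {id(c): {id(c)} for c in group}
                for a, b in itertools.combinations(group, 2):
                    if a.ngram.char_span[0] < b.ngram.char_span[1] and b.ngram.char_span[0] < a.ngram.char_span[1]:
                        merged = comp_of[id(a)] | comp_of[id(b)]
                        for member in merged:
                            comp_of[member] = merged
                seen = set()
                for c in group:
                    key = frozenset(comp_of[id(c)])
                    if key in seen:
                        continue
                    seen.add(key)
                    members = [x for x in group if id(x) in key]
                    expected.append(
                        max(members, key=lambda c: (
                            c.similarity,
                            -(c.ngram.char_span[1] - c.ngram.char_span[0]),
                            -c.ngram.char_span[0],
                        ))
                    )
            got = pinpoint(cands)
            assert sorted(map(id, got)) == sorted(map(id, expected))


class TestContextFilter:
    def test_only_negative_evidence_blacklists_concept(self, provider):
        coll = ContextCollection()
        coll.add_negative("c1", "some bad context")
        kept = context_filter([_cand((0, 3), "c1", 1.0)], coll, "doc text", provider)
        assert kept == []

    def test_no_evidence_passes_through(self, provider):
        kept = context_filter(
            [_cand((0, 3), "c1", 1.0)], ContextCollection(), "doc text", provider
        )
        assert len(kept) == 1

    def test_mixed_evidence_follows_max_comparison(self, provider):
        text = "the patient shows clear signs of infection today"
        coll = ContextCollection()
        # positive matches the document sentence nearly verbatim; negative unrelated
        coll.add_positive("c1", "patient shows clear signs of infection")
        coll.add_negative("c1", "completely different verbiage altogether")
        kept = context_filter([_cand((4, 11), "c1", 1.0)], coll, text, provider)
        assert len(kept) == 1
        # flip the evidence → dismissed
        coll2 = ContextCollection()
        coll2.add_positive("c1", "completely different verbiage altogether")
        coll2.add_negative("c1", "patient shows clear signs of infection")
        assert context_filter([_cand((4, 11), "c1", 1.0)], coll2, text, provider) == []

    def test_hand_enumerated_max_rule(self, provider):
        text = "alpha beta gamma"
        local = "alpha beta gamma"
        pos = ["alpha beta", "unrelated words"]
        neg = ["beta gamma delta", "other stuff"]
        coll = ContextCollection(positive={"c1": pos}, negative={"c1": neg})
        q = provider.embed_one(local)
        best_pos = max(float(provider.embed_one(s) @ q) for s in pos)
        best_neg = max(float(provider.embed_one(s) @ q) for s in neg)
        kept = context_filter([_cand((0, 5), "c1", 1.0)], coll, text, provider)
        assert bool(kept) == (best_neg <= best_pos)


class TestMinimizeNesting:
    def test_semantically_nested_inner_link_is_dismissed(self, provider):
        # the planted nested pattern: outer description contains the inner text
        outer = EntityLinkCandidate(
            NGram((16, 44), "family history: hypertension", 3),
            "160357008", "family history: hypertension", 1.0,
        )
        inner = EntityLinkCandidate(
            NGram((32, 44), "hypertension", 1), "38341003", "hypertension", 1.0
        )
        links = minimize_nesting([outer, inner], provider)
        assert [(l.concept_id) for l in links] == ["160357008"]

    def test_no_nesting_is_identity(self, provider):
        a = _cand((0, 5), "c1", 0.95)
        b = _cand((10, 15), "c2", 0.96)
        links = minimize_nesting([a, b], provider)
        assert {(l.char_span, l.concept_id) for l in links} == {
            ((0, 5), "c1"), ((10, 15), "c2"),
        }

    def test_inner_kept_when_its_removal_raises_outer_similarity(self, provider):
        # outer matched a description equal to the outer text *minus* the
        # inner part → removing the inner must increase similarity → keep both
        outer = EntityLinkCandidate(
            NGram((0, 17), "red panda sleeping", 3),
            "cOuter", "red sleeping",
            float(provider.embed_one("red panda sleeping") @ provider.embed_one("red sleeping")),
        )
        inner = EntityLinkCandidate(NGram((4, 9), "panda", 1), "cInner", "panda", 1.0)
        links = minimize_nesting([outer, inner], provider)
        assert {l.concept_id for l in links} == {"cOuter", "cInner"}


class TestUpdateCollections:
    def test_all_correct_adds_only_positives(self):
        text = "alpha beta. gamma delta."
        coll = ContextCollection()
        links = minimize_nesting([_cand((0, 5), "c1", 1.0)], None)  # no nesting → provider unused
        gold = [((0, 5), "c1")]
        update_collections(links, gold, text, coll)
        assert coll.positive == {"c1": ["alpha beta."]}
        assert coll.negative == {}

    def test_false_positive_adds_exactly_one_negative(self):
        text = "alpha beta. gamma delta."
        coll = ContextCollection()
        links = minimize_nesting(
            [_cand((0, 5), "c1", 1.0), _cand((12, 17), "c2", 1.0)], None
        )
        update_collections(links, [((0, 5), "c1")], text, coll)
        assert coll.negative == {"c2": ["gamma delta."]}

    def test_gold_span_outside_document_rejected(self):
        with pytest.raises(ValueError):
            update_collections([], [((0, 99), "c1")], "short", ContextCollection())

    def test_two_pass_run_drops_poisoned_concept(self, provider):
        # "cell" is ambiguous between two concepts; the gold always means cGood.
        index = _mini_index(provider, {"cell": ["cBad", "cGood"], "unrelated": ["c3"]})
        config = LinkerConfig(top_k=2, selection_threshold=0.9)
        coll = ContextCollection()
        doc = "cell"
        links1 = link_document(doc, index, None, coll, provider, config)
        assert {l.concept_id for l in links1} == {"cBad", "cGood"}
        update_collections(links1, [((0, 4), "cGood")], doc, coll)
        # pass 2 on a new document: cBad now has only negative evidence
        links2 = link_document(doc, index, None, coll, provider, config)
        assert {l.concept_id for l in links2} == {"cGood"}


class TestLinkDocument:
    def test_single_planted_synonym_yields_exactly_that_link(self, provider):
        index = _mini_index(provider, {"verbatim mention": ["c1"], "other words": ["c2"]})
        doc = "prefix filler verbatim mention suffix"
        links = link_document(
            doc, index, None, ContextCollection(), provider,
            LinkerConfig(selection_threshold=0.9),
        )
        assert [(l.char_span, l.concept_id) for l in links] == [
            ((doc.index("verbatim"), doc.index("mention") + 7), "c1")
        ]

    def test_with_abbrev_differs_only_at_dictionary_hits(self, provider):
        index = _mini_index(provider, {"magnetic resonance": ["c1"], "stable sign": ["c2"]})
        d = AbbreviationDictionary.from_pairs([("MR", "magnetic resonance")])
        d.entries["MR"][0].context_samples = ["magnetic resonance imaging context"]
        doc = "stable sign then MR today"
        base = link_document(doc, index, None, ContextCollection(), provider,
                             LinkerConfig(selection_threshold=0.9),
                             with_abbrev=False, abbrev_gate=0.0)
        with_ab = link_document(doc, index, d, ContextCollection(), provider,
                                LinkerConfig(selection_threshold=0.9),
                                with_abbrev=True, abbrev_gate=0.0)
        base_set = {(l.char_span, l.concept_id) for l in base}
        with_set = {(l.char_span, l.concept_id) for l in with_ab}
        # the shared non-abbreviation link is identical in both runs
        shared = ((0, len("stable sign")), "c2")
        assert shared in base_set and shared in with_set
        only_new = with_set - base_set
        assert only_new == {((doc.index("MR"), doc.index("MR") + 2), "c1")}

    def test_selection_is_a_subset_chain(self, provider, embedded_term, docs_fixture):
        doc = docs_fixture.documents["doc005"]
        config = LinkerConfig(selection_threshold=0.9)
        cands = identify_candidates(doc, embedded_term.index, None, provider, config)
        step1 = threshold_filter(cands, config.selection_threshold)
        step2 = pinpoint(step1)
        step3 = context_filter(step2, ContextCollection(), doc, provider)
        links = minimize_nesting(step3, provider)
        assert set(map(id, step1)) <= set(map(id, cands))
        assert set(map(id, step2)) <= set(map(id, step1))
        assert set(map(id, step3)) <= set(map(id, step2))
        link_keys = {(l.char_span, l.concept_id) for l in links}
        assert link_keys <= {(c.ngram.char_span, c.concept_id) for c in step3}

    def test_candidate_order_does_not_change_final_links(self, provider, rng):
        index = _mini_index(provider, {"verbatim mention": ["c1"], "another name": ["c2"]})
        doc = "verbatim mention and another name here"
        config = LinkerConfig(selection_threshold=0.9)
        cands = identify_candidates(doc, index, None, provider, config)
        reference = None
        for _ in range(5):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            selected = threshold_filter(shuffled, config.selection_threshold)
            selected = pinpoint(selected)
            selected = context_filter(selected, ContextCollection(), doc, provider)
            links = minimize_nesting(selected, provider)
            keys = [(l.char_span, l.concept_id) for l in links]
            if reference is None:
                reference = keys
            assert keys == reference


class TestStandoffIO:
    def test_pubtator_round_trip(self, tmp_path, docs_fixture, spec, term_fixture):
        from notelink.fixtures import make_annotated_docs

        make_annotated_docs(spec, term_fixture, tmp_path)
        loaded = read_pubtator(tmp_path / "corpus.pubtator")
        assert set(loaded) == set(docs_fixture.documents)
        for doc_id, (text, anns) in loaded.items():
            assert text == docs_fixture.documents[doc_id]
            assert anns == docs_fixture.gold[doc_id]
            for (s, e), cid in anns:
                assert 0 <= s < e <= len(text)

    def test_pipe_standoff_filters_cuiless_and_disjoint(self, tmp_path):
        p = tmp_path / "gold.standoff"
        p.write_text(
            "doc1|0-4|C123\n"
            "doc1|5-9|CUI-less\n"
            "doc1|10-14,20-24|C456\n"
            "doc2|3-8|C789\n",
            encoding="utf-8",
        )
        gold, skipped = read_pipe_standoff(p)
        assert gold == {"doc1": [((0, 4), "C123")], "doc2": [((3, 8), "C789")]}
        assert skipped == {"cui_less": 1, "disjoint": 1}

    def test_link_table_writer_emits_tsv_and_provenance(self, tmp_path):
        links = minimize_nesting([_cand((0, 4), "c1", 0.987654)], None)
        write_link_table({"docA": links}, tmp_path / "links.tsv",
                         tmp_path / "prov.json", LinkerConfig())
        lines = (tmp_path / "links.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["doc_id", "start", "end", "concept_id", "similarity"]
        assert lines[1].split("\t") == ["docA", "0", "4", "c1", "0.987654"]
        assert "selection_threshold" in (tmp_path / "prov.json").read_text()
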