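"""Terminology loading, ancestor closure and the description index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notelink.embedding import EmbeddingCache
from notelink.terminology import (
    Concept,
    ConceptDescription,
    TerminologyFormatError,
    TerminologyIndex,
    load_rf2,
    load_rrf,
    write_rf2,
)

FSN = "900000000000003001"
SYN = "900000000000013009"
ISA = "116680003"


def _write(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _rf2_files(tmp_path, concepts, descriptions, relationships):
    c = _write(tmp_path / "concepts.txt",
               ["id", "effectiveTime", "active", "moduleId", "definitionStatusId"],
               [[cid, "20230531", act, "m", "d"] for cid, act in concepts])
    d = _write(tmp_path / "descriptions.txt",
               ["id", "effectiveTime", "active", "moduleId", "conceptId",
                "languageCode", "typeId", "term", "caseSignificanceId"],
               [[did, "20230531", act, "m", cid, "en", typ, term, "cs"]
                for did, act, cid, typ, term in descriptions])
    r = _write(tmp_path / "relationships.txt",
               ["id", "effectiveTime", "active", "moduleId", "sourceId",
                "destinationId", "relationshipGroup", "typeId",
                "characteristicTypeId", "modifierId"],
               [[rid, "20230531", act, "m", src, dst, "0", typ, "c", "mo"]
                for rid, act, src, dst, typ in relationships])
    return c, d, r


class TestLoadRf2:
    def test_counted_toy_release(self, tmp_path):
        files = _rf2_files(
            tmp_path,
            concepts=[("100", "1"), ("200", "1"), ("300", "1")],
            descriptions=[
                ("d1", "1", "100", FSN, "Root thing (finding)"),
                ("d2", "1", "100", SYN, "root"),
                ("d3", "1", "200", SYN, "child"),
                ("d4", "1", "200", SYN, "kid"),
                ("d5", "1", "300", SYN, "grandchild"),
            ],
            relationships=[
                ("r1", "1", "200", "100", ISA),
                ("r2", "1", "300", "200", ISA),
            ],
        )
        index = load_rf2(*files)
        assert len(index.concepts) == 3
        assert len(index.descriptions) == 4
        assert index.concepts["100"].preferred_name == "Root thing"
        assert index.concepts["100"].category == "finding"
        assert index.concepts["200"].parent_ids == {"100"}

    def test_non_isa_relationships_ignored(self, tmp_path):
        files = _rf2_files(
            tmp_path,
            concepts=[("100", "1"), ("200", "1")],
            descriptions=[("d1", "1", "100", SYN, "a"), ("d2", "1", "200", SYN, "b")],
            relationships=[("r1", "1", "200", "100", "363698007")],  # finding-site
        )
        index = load_rf2(*files)
        assert index.concepts["200"].parent_ids == set()

    def test_inactive_content_dropped_from_concepts_and_closure(self, tmp_path):
        files = _rf2_files(
            tmp_path,
            concepts=[("100", "1"), ("200", "0"), ("300", "1")],
            descriptions=[
                ("d1", "1", "100", SYN, "a"),
                ("d2", "1", "200", SYN, "b"),
                ("d3", "1", "300", SYN, "c"),
                ("d4", "0", "300", SYN, "retired name"),
            ],
            relationships=[
                ("r1", "1", "300", "200", ISA),
                ("r2", "1", "200", "100", ISA),
            ],
        )
        index = load_rf2(*files)
        assert set(index.concepts) == {"100", "300"}
        assert all("200" not in d.concept_ids for d in index.descriptions.values())
        assert all(d.text != "retired name" for d in index.descriptions.values())
        # the edge through the inactive middle concept disappears entirely
        assert index.ancestors("300") == frozenset()

    def test_missing_column_names_file_and_column(self, tmp_path):
        files = _rf2_files(tmp_path, [("100", "1")], [("d1", "1", "100", SYN, "a")], [])
        bad = tmp_path / "bad_concepts.txt"
        bad.write_text("id\teffectiveTime\n100\t20230531\n", encoding="utf-8")
        with pytest.raises(TerminologyFormatError, match="bad_concepts.txt.*active"):
            load_rf2(bad, files[1], files[2])


class TestLoadRrf:
    def _rrf(self, tmp_path, conso_rows, sty_rows):
        conso = tmp_path / "MRCONSO.RRF"
        conso.write_text(
            "".join(
                f"{cui}|ENG|P|L|PF|S|Y|{aui}|||||PT|{aui}|{name}|0|{sup}||\n"
                for cui, aui, name, sup in conso_rows
            ),
            encoding="utf-8",
        )
        sty = tmp_path / "MRSTY.RRF"
        sty.write_text(
            "".join(f"{cui}|{tui}|A1.2|{sty_name}|AT1||\n" for cui, tui, sty_name in sty_rows),
            encoding="utf-8",
        )
        return conso, sty

    def test_shared_cui_collapses_to_one_concept(self, tmp_path):
        conso, sty = self._rrf(
            tmp_path,
            [("C001", "A1", "heart attack", "N"), ("C001", "A2", "myocardial infarction", "N")],
            [("C001", "T047", "Disease or Syndrome")],
        )
        index = load_rrf(conso, sty)
        assert len(index.concepts) == 1
        assert len(index.descriptions) == 2
        assert index.concepts["C001"].category == "Disease or Syndrome"
        assert index.concepts["C001"].parent_ids == set()

    def test_identical_name_under_two_cuis_is_ambiguous(self, tmp_path):
        conso, sty = self._rrf(
            tmp_path,
            [("C001", "A1", "cell", "N"), ("C002", "A2", "cell", "N")],
            [("C001", "T025", "Cell"), ("C002", "T081", "Quantitative Concept")],
        )
        index = load_rrf(conso, sty)
        ambiguous = index.find_ambiguous_descriptions()
        assert len(ambiguous) == 1
        assert ambiguous[0].concept_ids == {"C001", "C002"}

    def test_suppressed_rows_dropped(self, tmp_path):
        conso, sty = self._rrf(
            tmp_path,
            [("C001", "A1", "kept", "N"), ("C001", "A2", "hidden", "O")],
            [("C001", "T047", "Disease or Syndrome")],
        )
        index = load_rrf(conso, sty)
        assert [d.text for d in index.descriptions.values()] == ["kept"]


def _index_from_parents(parents):
    concepts = {
        cid: Concept(cid, cid, parent_ids=set(ps)) for cid, ps in parents.items()
    }
    descriptions = {
        f"d{cid}": ConceptDescription(f"d{cid}", f"name {cid}", {cid}) for cid in parents
    }
    return TerminologyIndex(concepts, descriptions)


class TestAncestors:
    def test_chain_and_root(self):
        index = _index_from_parents({"A": [], "B": ["A"], "C": ["B"]})
        assert index.ancestors("C") == {"A", "B"}
        assert index.ancestors("A") == frozenset()

    def test_diamond(self):
        index = _index_from_parents({"A": [], "B1": ["A"], "B2": ["A"], "C": ["B1", "B2"]})
        assert index.ancestors("C") == {"B1", "B2", "A"}

    def test_unknown_id_is_lookup_error(self):
        with pytest.raises(KeyError):
            _index_from_parents({"A": []}).ancestors("zz")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_random_dag_matches_bruteforce_closure(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 25))
        ids = [f"c{i}" for i in range(n)]
        # edges only to earlier nodes → guaranteed acyclic
        parents = {
            ids[i]: [ids[j] for j in range(i) if r.random() < 0.3] for i in range(n)
        }
        index = _index_from_parents(parents)

        def brute(cid, seen=None):
            seen = set()
            frontier = set(parents[cid])
            while frontier:
                p = frontier.pop()
                if p not in seen:
                    seen.add(p)
                    frontier |= set(parents[p])
            return seen

        for cid in ids:
            assert index.ancestors(cid) == brute(cid)

    def test_monotone_under_edge_addition(self):
        parents = {"A": [], "B": ["A"], "C": ["B"], "D": []}
        before = _index_from_parents(parents)
        sets_before = {cid: before.ancestors(cid) for cid in parents}
        parents_after = {**parents, "D": ["C"]}
        after = _index_from_parents(parents_after)
        for cid in parents:
            assert sets_before[cid] <= after.ancestors(cid)


class TestAmbiguityAndIndex:
    def test_planted_ambiguous_set_recovered(self, term_fixture):
        found = {d.description_id for d in term_fixture.index.find_ambiguous_descriptions()}
        assert found == term_fixture.ambiguous_description_ids

    def test_no_shared_names_means_empty(self):
        index = _index_from_parents({"A": [], "B": []})
        assert index.find_ambiguous_descriptions() == []

    def test_rebuild_is_bit_identical_and_cache_backed(self, term_fixture, provider):
        cache = EmbeddingCache(provider)
        first = term_fixture.index.build_description_index(cache)
        misses = cache.misses
        second = term_fixture.index.build_description_index(cache)
        assert cache.misses == misses  # all cache hits on rebuild
        assert np.array_equal(first.matrix, second.matrix)
        assert first.matrix.shape[0] == len(term_fixture.index.descriptions)

    def test_empty_terminology_cannot_be_embedded(self, provider):
        index = TerminologyIndex({}, {})
        with pytest.raises(RuntimeError):
            index.build_description_index(provider)


def test_round_trip_through_rf2_files(tmp_path, term_fixture):
    paths = write_rf2(term_fixture.index, tmp_path)
    reloaded = load_rf2(**paths)
    assert reloaded == term_fixture.index
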