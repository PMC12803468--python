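"""Graph assembly, path queries (vs. brute-force oracle) and exports."""

import itertools
import json
import random

import pytest

from bioprockg.documents import Sentence
from bioprockg.errors import QueryPatternError
from bioprockg.extraction import ImpactRelation
from bioprockg.kg import (
    IMPACT_TYPES,
    QuerySpec,
    build_graph,
    export_graph,
    format_path_table,
    import_bulk_csv,
    import_graphml,
    query_paths,
    _scalarized,
)
from bioprockg.lexicon import ConceptMatch, DictionaryConcept, Lexicon


def make_relation(lex, doc_id, aff, afd, rtype, trigger="affect"):
    """Fabricate a typed relation between two canonical concept names."""
    by_name = {c.canonical_name: c for c in lex.concepts.values()}
    text = f"{aff} {trigger}s {afd}."
    sent = Sentence(sent_id=f"{doc_id}:0:0", text=text,
                    section_title="Abstract", doc_id=doc_id,
                    doc_kind="abstract", start=0, end=len(text))
    return ImpactRelation(
        affector=ConceptMatch(by_name[aff], aff, (0, len(aff))),
        affected=ConceptMatch(by_name[afd], afd, (0, len(afd))),
        trigger=trigger, relation_type=rtype, pattern_id="P1_simple",
        sentence=sent,
    )


def random_kg(seed, n_concepts=20, n_edges=40):
    """Random concept graph wrapped in a KnowledgeGraph (no ontology)."""
    rng = random.Random(seed)
    concepts = [
        DictionaryConcept(f"COID{k:06d}", f"term{k:02d}", frozenset(),
                          "C1", "t")
        for k in range(n_concepts)
    ]
    lex = Lexicon(concepts)
    rels = []
    for e in range(n_edges):
        a, b = rng.sample(range(n_concepts), 2)
        rtype = rng.choice(IMPACT_TYPES)
        rels.append(make_relation(lex, str(1000 + e % 7),
                                  f"term{a:02d}", f"term{b:02d}", rtype))
    return build_graph(rels, lex), rels


def brute_force_paths(kg, q):
    """Exhaustive bounded-depth enumeration over the flat step list."""
    allowed = set(q.rel_types) if q.rel_types is not None else set(IMPACT_TYPES)
    steps = [s for s in kg.steps if s.rel_type in allowed]

    def name(coid):
        return kg.concept_name(coid)

    def match(pattern, coid):
        if pattern is None:
            return True
        return name(coid).casefold() == pattern.casefold()

    found = set()

    def extend(chain, nodes):
        if match(q.affected, chain[-1].affected_coid):
            found.add(tuple((name(s.affector_coid), s.rel_type,
                             name(s.affected_coid)) for s in chain))
        if len(chain) >= q.max_degree:
            return
        for s in steps:
            if (s.affector_coid == chain[-1].affected_coid
                    and s.affected_coid not in nodes):
                extend(chain + [s], nodes | {s.affected_coid})

    for s in steps:
        if match(q.affector, s.affector_coid):
            extend([s], {s.affector_coid, s.affected_coid})
    return found


def path_key(p):
    return tuple((s.affector, s.rel_type, s.affected) for s in p.steps)


class TestBuildGraph:
    def test_empty_relations_keep_scaffolding(self, lexicon, ontology):
        kg = build_graph([], lexicon, ontology)
        labels = {d["label"] for _, d in kg.graph.nodes(data=True)}
        assert labels == {"DictionaryConcept", "OntologyClass"}
        assert kg.steps == []

    def test_provenance_merges_across_documents(self, lexicon):
        rels = [
            make_relation(lexicon, "111", "manganese", "afucosylation",
                          "positively_correlated"),
            make_relation(lexicon, "222", "manganese", "afucosylation",
                          "positively_correlated"),
        ]
        kg = build_graph(rels, lexicon)
        (step,) = kg.steps
        assert len(step.provenance) == 2
        assert {p["doc_id"] for p in step.provenance} == {"111", "222"}

    def test_provenance_conservation(self, worked_relations, worked_kg):
        expected = sorted(
            (r.affector.concept.coid, r.affected.concept.coid,
             r.relation_type, r.sentence.doc_id)
            for r in worked_relations
        )
        got = sorted(
            (s.affector_coid, s.affected_coid, s.rel_type, p["doc_id"])
            for s in worked_kg.steps
            for p in s.provenance
        )
        assert got == expected

    def test_term_nodes_deduplicated_per_surface(self, lexicon):
        rels = [
            make_relation(lexicon, "111", "manganese", "afucosylation",
                          "positively_correlated"),
            make_relation(lexicon, "222", "manganese", "galactosylation",
                          "positively_correlated"),
        ]
        kg = build_graph(rels, lexicon)
        affectors = [n for n, d in kg.graph.nodes(data=True)
                     if d.get("label") == "Affector"]
        assert affectors == ["Affector::manganese"]

    def test_mentioned_in_source_nodes(self, worked_kg):
        g = worked_kg.graph
        assert g.nodes["Source::30597531"]["label"] == "Article"
        mentions = [v for u, v, k in g.edges(keys=True)
                    if k == "IS_MENTIONED_IN"]
        assert "Source::30597531" in mentions


class TestQueries:
    def test_direct_query_degree_one(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(affector="manganese"))
        pairs = {(p.steps[0].affector, p.steps[0].affected) for p in res}
        assert ("manganese", "afucosylation") in pairs
        assert ("manganese", "galactosylation") in pairs
        assert all(len(p) == 1 for p in res)

    def test_transitive_query_joins_on_concept(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(affector="manganese",
                                               affected="ADCC",
                                               max_degree=2))
        assert len(res) == 1
        (p,) = res
        assert path_key(p) == (
            ("manganese", "positively_correlated", "afucosylation"),
            ("afucosylation", "positively_correlated", "ADCC"),
        )
        assert p.steps[0].evidence == ("30597531",)
        assert p.steps[1].evidence == ("30597531",)

    def test_rel_type_filter(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(
            affector="osmolality", affected="ADCC",
            rel_types=frozenset({"positively_correlated",
                                 "negatively_correlated"}),
            max_degree=2))
        (p,) = res
        assert p.concepts == ("osmolality", "core fucosylation", "ADCC")
        assert "33804825" in p.steps[0].evidence
        assert "20639190" in p.steps[1].evidence

    def test_class_level_query(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(
            affector_class="trace metals or minerals",
            affected_class="glycosylation"))
        affectors = {p.steps[0].affector for p in res}
        affecteds = {p.steps[0].affected for p in res}
        assert affectors == {"nickel", "manganese", "iron", "copper chloride"}
        assert affecteds <= {"glycosylation", "galactosylation",
                             "sialylation", "afucosylation"}

    def test_class_query_equals_union_of_member_queries(self, worked_kg):
        kg = worked_kg
        res_class = query_paths(kg, QuerySpec(
            affector_class="trace metals or minerals", max_degree=2))
        members = kg.ontology.concepts_under(
            kg.lexicon, "trace metals or minerals")
        res_union = []
        for c in sorted(members, key=lambda c: c.canonical_name):
            res_union.extend(
                query_paths(kg, QuerySpec(affector=c.canonical_name,
                                          max_degree=2)))
        assert {path_key(p) for p in res_class} == \
            {path_key(p) for p in res_union}

    def test_wildcard_is_case_insensitive_substring(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(affector="*FUCOS*"))
        affectors = {p.steps[0].affector for p in res}
        assert affectors == {"afucosylation", "core fucosylation"}

    def test_malformed_pattern_raises(self, worked_kg):
        with pytest.raises(QueryPatternError):
            query_paths(worked_kg, QuerySpec(affector=""))

    def test_degree_bounds_enforced(self):
        with pytest.raises(ValueError):
            QuerySpec(max_degree=7)
        with pytest.raises(ValueError):
            QuerySpec(max_degree=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_query_matches_brute_force_oracle(self, seed):
        kg, _ = random_kg(seed, n_concepts=12, n_edges=24)
        rng = random.Random(seed + 1000)
        for trial in range(4):
            q = QuerySpec(
                affector=(f"term{rng.randrange(12):02d}"
                          if rng.random() < 0.7 else None),
                affected=(f"term{rng.randrange(12):02d}"
                          if rng.random() < 0.5 else None),
                rel_types=(frozenset(rng.sample(IMPACT_TYPES, 2))
                           if rng.random() < 0.5 else None),
                max_degree=rng.randint(1, 5),
            )
            got = {path_key(p) for p in query_paths(kg, q)}
            assert got == brute_force_paths(kg, q)

    @pytest.mark.parametrize("seed", range(4))
    def test_results_monotone_in_degree(self, seed):
        kg, _ = random_kg(seed, n_concepts=10, n_edges=20)
        prev = set()
        for k in range(1, 6):
            cur = {path_key(p)
                   for p in query_paths(kg, QuerySpec(affector="term00",
                                                      max_degree=k))}
            assert prev <= cur
            prev = cur

    def test_deterministic_ordering(self, worked_kg):
        q = QuerySpec(affector="*o*", max_degree=2)
        a = [path_key(p) for p in query_paths(worked_kg, q)]
        b = [path_key(p) for p in query_paths(worked_kg, q)]
        assert a == b
        # ordered by path length, then concept-name sequence
        assert a == sorted(a, key=lambda k: (
            len(k),
            (k[0][0],) + tuple(s[2] for s in k),
            tuple(s[1] for s in k),
        ))


class TestFormatting:
    def test_same_pmid_displayed_twice(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(affector="manganese",
                                               affected="ADCC",
                                               max_degree=2))
        ((path_str, evidence),) = format_path_table(res)
        assert evidence == "30597531, 30597531"
        assert path_str.count("||") == 1

    def test_single_step_has_no_delimiter(self, worked_kg):
        res = query_paths(worked_kg, QuerySpec(affector="cell death"))
        rows = format_path_table(res)
        assert rows and all("||" not in r[0] for r in rows)

    def test_three_step_path_formatting(self, lexicon):
        rels = [
            make_relation(lexicon, "901", "manganese", "afucosylation",
                          "positively_correlated"),
            make_relation(lexicon, "902", "afucosylation", "ADCC",
                          "positively_correlated"),
            make_relation(lexicon, "903", "ADCC", "safety",
                          "correlated_not_specified"),
        ]
        kg = build_graph(rels, lexicon)
        res = query_paths(kg, QuerySpec(affector="manganese",
                                        affected="safety", max_degree=3))
        ((path_str, evidence),) = format_path_table(res)
        assert path_str.count("||") == 2
        assert path_str.count("(") == 3
        assert evidence == "901, 902, 903"


class TestExports:
    def test_jsonl_triples_contain_use_case_edge(self, worked_kg, tmp_path):
        dest = tmp_path / "triples.jsonl"
        export_graph(worked_kg, "jsonl_triples", dest)
        rows = [json.loads(line) for line in dest.read_text().splitlines()]
        triples = {(r["head"], r["relation"], r["tail"]) for r in rows}
        assert ("manganese", "positively_correlated",
                "afucosylation") in triples

    def test_empty_graph_exports_valid_files(self, lexicon, tmp_path):
        kg = build_graph([], lexicon)
        export_graph(kg, "bulk_csv", tmp_path / "csv")
        g = import_bulk_csv(tmp_path / "csv")
        assert g.number_of_nodes() == len(lexicon)

    def test_graphml_round_trip(self, worked_kg, tmp_path):
        dest = tmp_path / "g.graphml"
        export_graph(worked_kg, "graphml", dest)
        g2 = import_graphml(dest)
        g1 = _scalarized(worked_kg.graph)
        assert set(g1.nodes) == set(g2.nodes)
        assert {(u, v, k) for u, v, k in g1.edges(keys=True)} == \
            {(u, v, k) for u, v, k in g2.edges(keys=True)}
        for n in g1.nodes:
            assert g1.nodes[n] == g2.nodes[n]

    def test_bulk_csv_round_trip_random_graph(self, tmp_path):
        kg, _ = random_kg(3)
        export_graph(kg, "bulk_csv", tmp_path / "csv")
        g2 = import_bulk_csv(tmp_path / "csv")
        g1 = kg.graph
        assert set(g1.nodes) == set(g2.nodes)
        assert {(u, v, k) for u, v, k in g1.edges(keys=True)} == \
            {(u, v, k) for u, v, k in g2.edges(keys=True)}
        for u, v, k in g1.edges(keys=True):
            assert g1.edges[u, v, k] == g2.edges[u, v, k]
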