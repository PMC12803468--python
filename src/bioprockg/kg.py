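"""Labeled property graph over extracted relations, with path queries.

The graph keeps the Neo4j-style model: Affector/Affected term nodes
(deduplicated per surface form) connected by typed impact edges carrying
merged provenance, HAS_CONCEPT links from terms to their dictionary
concepts, INSTANCE_OF links from concepts to ontology classes, the typed
class hierarchy, and IS_MENTIONED_IN links to Article/BookChapter source
nodes.

Path queries follow the pattern
``DictionaryConcept <- Affector -> [impact] -> Affected -> DictionaryConcept``:
consecutive steps join on the shared dictionary concept (so the
"afucosylation" mention of one article chains with the "afucosylation"
mention of another), up to a degree of separation of 5, over simple
paths only.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from .errors import IntegrityError, QueryPatternError
from .extraction import ImpactRelation
from .lexicon import Lexicon
from .ontology import Ontology

IMPACT_TYPES = (
    "positively_correlated",
    "negatively_correlated",
    "not_correlated",
    "correlated_not_specified",
)

MAX_DEGREE = 5


class Step(NamedTuple):
    """One concept-level impact edge with its merged provenance."""

    affector_coid: str
    affected_coid: str
    rel_type: str
    provenance: tuple[dict, ...]


class KnowledgeGraph:
    """networkx MultiDiGraph wrapper plus concept-level step index."""

    def __init__(self, graph: nx.MultiDiGraph, lex: Lexicon,
                 ontology: Ontology | None = None):
        self.graph = graph
        self.lexicon = lex
        self.ontology = ontology
        self._steps_by_source: dict[str, list[Step]] = {}
        self._index_steps()

    def _index_steps(self) -> None:
        concept_of: dict[str, str] = {}
        for u, v, key in self.graph.edges(keys=True):
            if key == "HAS_CONCEPT":
                concept_of[u] = self.graph.nodes[v]["coid"]
        merged: dict[tuple[str, str, str], list[dict]] = {}
        for u, v, key, data in self.graph.edges(keys=True, data=True):
            if key not in IMPACT_TYPES:
                continue
            cu, cv = concept_of.get(u), concept_of.get(v)
            if cu is None or cv is None:
                continue
            merged.setdefault((cu, cv, key), []).extend(
                data.get("provenance", [])
            )
        for (cu, cv, rel), prov in sorted(merged.items()):
            self._steps_by_source.setdefault(cu, []).append(
                Step(cu, cv, rel, tuple(prov))
            )

    @property
    def steps(self) -> list[Step]:
        return [s for ss in self._steps_by_source.values() for s in ss]

    def concept_name(self, coid: str) -> str:
        return self.lexicon.concepts[coid].canonical_name


def build_graph(relations: Iterable[ImpactRelation], lex: Lexicon,
                ontology: Ontology | None = None) -> KnowledgeGraph:
    """Assemble the property graph from relations + dictionary + ontology.

    Term nodes are deduplicated per (label, surface form); repeated
    extractions of the same (affector term, affected term, type) triple
    merge into one edge with the union of their provenance records.
    """
    g = nx.MultiDiGraph()
    if ontology is not None:
        for c in ontology.classes.values():
            g.add_node(f"Class::{c.class_id}", label="OntologyClass",
                       name=c.name, class_id=c.class_id)
        for c in ontology.classes.values():
            for parent_id, rel in c.parents:
                g.add_edge(f"Class::{c.class_id}", f"Class::{parent_id}",
                           key=rel)
    for concept in lex.concepts.values():
        g.add_node(f"Concept::{concept.coid}", label="DictionaryConcept",
                   name=concept.canonical_name, coid=concept.coid,
                   type_id=concept.type_id, type_name=concept.type_name)
        if ontology is not None:
            class_id = ontology.instance_links.get(concept.coid)
            if class_id is not None:
                g.add_edge(f"Concept::{concept.coid}", f"Class::{class_id}",
                           key="INSTANCE_OF")
    for r in relations:
        for side in (r.affector, r.affected):
            if side.concept.coid not in lex.concepts:
                raise IntegrityError(
                    f"relation references unknown concept {side.concept.coid}"
                )
        s = r.sentence
        aff_surface = r.affector.matched_text.casefold()
        afd_surface = r.affected.matched_text.casefold()
        aff_node = f"Affector::{aff_surface}"
        afd_node = f"Affected::{afd_surface}"
        g.add_node(aff_node, label="Affector", name=aff_surface)
        g.add_node(afd_node, label="Affected", name=afd_surface)
        for node, concept in ((aff_node, r.affector.concept),
                              (afd_node, r.affected.concept)):
            if not g.has_edge(node, f"Concept::{concept.coid}",
                              key="HAS_CONCEPT"):
                g.add_edge(node, f"Concept::{concept.coid}",
                           key="HAS_CONCEPT")
        src_node = f"Source::{s.doc_id}"
        src_label = "BookChapter" if s.doc_kind == "book_chapter" else "Article"
        g.add_node(src_node, label=src_label, doc_id=s.doc_id)
        prov = {
            "doc_id": s.doc_id,
            "doc_kind": s.doc_kind,
            "chapter_number": s.chapter_number,
            "section_title": s.section_title,
            "sentence": s.text,
            "trigger": r.trigger,
        }
        rel_type = r.relation_type or "correlated_not_specified"
        if g.has_edge(aff_node, afd_node, key=rel_type):
            g.edges[aff_node, afd_node, rel_type]["provenance"].append(prov)
        else:
            g.add_edge(aff_node, afd_node, key=rel_type, provenance=[prov])
        for node in (aff_node, afd_node):
            if not g.has_edge(node, src_node, key="IS_MENTIONED_IN"):
                g.add_edge(node, src_node, key="IS_MENTIONED_IN")
    return KnowledgeGraph(g, lex, ontology)


# ---------------------------------------------------------------------------
# queries

@dataclass(frozen=True)
class QuerySpec:
    """A term/class-level path query with bounded degree of separation."""

    affector: str | None = None
    affected: str | None = None
    affector_class: str | None = None
    affected_class: str | None = None
    rel_types: frozenset[str] | None = None  # None -> all four
    max_degree: int = 1

    def __post_init__(self):
        if not (1 <= self.max_degree <= MAX_DEGREE):
            raise ValueError(
                f"max_degree must be in [1, {MAX_DEGREE}], got {self.max_degree}"
            )
        if self.rel_types is not None:
            unknown = set(self.rel_types) - set(IMPACT_TYPES)
            if unknown:
                raise ValueError(f"unknown relation types: {sorted(unknown)}")


class PathStep(NamedTuple):
    affector: str   # canonical concept name
    rel_type: str
    affected: str
    evidence: tuple[str, ...]     # doc ids, in provenance order, deduplicated
    sentences: tuple[str, ...]


@dataclass(frozen=True)
class PathResult:
    steps: tuple[PathStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def concepts(self) -> tuple[str, ...]:
        return tuple([self.steps[0].affector] +
                     [s.affected for s in self.steps])


def _pattern_matcher(pattern: str):
    """Exact (case-insensitive) concept-name match, or a wildcard pattern
    where ``*`` matches any run of characters."""
    if pattern is None or pattern == "":
        raise QueryPatternError("empty query pattern")
    if "*" in pattern:
        try:
            rx = re.compile(
                ".*".join(re.escape(p) for p in pattern.split("*")),
                re.IGNORECASE,
            )
        except re.error as exc:  # pragma: no cover - escape() prevents this
            raise QueryPatternError(str(exc)) from exc
        return lambda name: rx.search(name) is not None
    low = pattern.casefold()
    return lambda name: name.casefold() == low


def _endpoint_coids(kg: KnowledgeGraph, term: str | None, class_ref: str | None
                    ) -> set[str] | None:
    """Concept ids satisfying a term pattern and/or class filter
    (None = unconstrained)."""
    coids: set[str] | None = None
    if term is not None:
        match = _pattern_matcher(term)
        coids = {
            coid
            for coid, c in kg.lexicon.concepts.items()
            if match(c.canonical_name) or any(match(a) for a in c.alt_names)
        }
    if class_ref is not None:
        if kg.ontology is None:
            raise QueryPatternError("class-level query requires an ontology")
        members = {
            c.coid for c in kg.ontology.concepts_under(kg.lexicon, class_ref)
        }
        coids = members if coids is None else coids & members
    return coids


def query_paths(kg: KnowledgeGraph, q: QuerySpec) -> list[PathResult]:
    """All simple directed impact paths of 1..max_degree steps.

    Start concepts satisfy the affector term/class constraints, end
    concepts the affected constraints, every edge type is in
    ``rel_types``, and consecutive steps join on the shared dictionary
    concept. No concept is revisited within a path. Results are ordered
    by path length, then lexicographically by concept names.
    """
    allowed = set(q.rel_types) if q.rel_types is not None else set(IMPACT_TYPES)
    starts = _endpoint_coids(kg, q.affector, q.affector_class)
    ends = _endpoint_coids(kg, q.affected, q.affected_class)
    if starts is None:
        starts = set(kg._steps_by_source)
    results: list[PathResult] = []

    def ok_end(coid: str) -> bool:
        return ends is None or coid in ends

    def dfs(path: list[Step], visited: set[str]) -> None:
        last = path[-1].affected_coid
        if ok_end(last):
            results.append(PathResult(tuple(_mk_step(kg, s) for s in path)))
        if len(path) >= q.max_degree:
            return
        for step in kg._steps_by_source.get(last, ()):
            if step.rel_type in allowed and step.affected_coid not in visited:
                dfs(path + [step], visited | {step.affected_coid})

    for start in sorted(starts):
        for step in kg._steps_by_source.get(start, ()):
            if step.rel_type in allowed:
                dfs([step], {start, step.affected_coid})
    results.sort(key=lambda p: (len(p), p.concepts,
                                tuple(s.rel_type for s in p.steps)))
    return results


def _mk_step(kg: KnowledgeGraph, s: Step) -> PathStep:
    docs: list[str] = []
    sents: list[str] = []
    for prov in s.provenance:
        if prov["doc_id"] not in docs:
            docs.append(prov["doc_id"])
        sents.append(prov["sentence"])
    return PathStep(
        affector=kg.concept_name(s.affector_coid),
        rel_type=s.rel_type,
        affected=kg.concept_name(s.affected_coid),
        evidence=tuple(docs),
        sentences=tuple(sents),
    )


def format_path_table(results: Iterable[PathResult]
                      ) -> list[tuple[str, str]]:
    """Render paths as ('A —rel→ B (ID) || B —rel→ C (ID)', 'ID, ID') rows.

    The evidence column lists identifiers comma-separated in step order,
    repeating a source that supports several steps.
    """
    rows: list[tuple[str, str]] = []
    for p in results:
        parts = [
            f"{s.affector} —{s.rel_type}→ {s.affected} "
            f"({', '.join(s.evidence)})"
            for s in p.steps
        ]
        evidence = ", ".join(doc for s in p.steps for doc in s.evidence)
        rows.append((" || ".join(parts), evidence))
    return rows


def paths_to_payload(results: Iterable[PathResult]) -> dict:
    """JSON nodes+edges payload for rendering query results."""
    nodes: dict[str, dict] = {}
    edges: list[dict] = []
    for p in results:
        for s in p.steps:
            for name in (s.affector, s.affected):
                nodes.setdefault(name, {"id": name, "name": name})
            edges.append({
                "source": s.affector,
                "target": s.affected,
                "rel_type": s.rel_type,
                "evidence": list(s.evidence),
            })
    return {"nodes": list(nodes.values()), "edges": edges}


# ---------------------------------------------------------------------------
# export / import

def export_graph(kg: KnowledgeGraph, format: str, dest) -> list[Path]:
    """Export the graph; returns the list of files written.

    ``graphml`` writes one file (provenance JSON-encoded in edge
    attributes); ``jsonl_triples`` writes one <head, relation, tail> +
    provenance object per impact edge; ``bulk_csv`` writes a
    ``nodes.csv``/``edges.csv`` pair for bulk import.
    """
    dest = Path(dest)
    if format == "graphml":
        g = _scalarized(kg.graph)
        nx.write_graphml(g, dest)
        return [dest]
    if format == "jsonl_triples":
        with open(dest, "w", encoding="utf-8") as fh:
            for u, v, key, data in sorted(
                kg.graph.edges(keys=True, data=True)
            ):
                if key not in IMPACT_TYPES:
                    continue
                fh.write(json.dumps({
                    "head": kg.graph.nodes[u]["name"],
                    "relation": key,
                    "tail": kg.graph.nodes[v]["name"],
                    "provenance": data.get("provenance", []),
                }, ensure_ascii=False) + "\n")
        return [dest]
    if format == "bulk_csv":
        dest.mkdir(parents=True, exist_ok=True)
        nodes_path = dest / "nodes.csv"
        edges_path = dest / "edges.csv"
        with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "label", "properties_json"])
            for node, data in sorted(kg.graph.nodes(data=True)):
                props = {k: v for k, v in data.items() if k != "label"}
                w.writerow([node, data.get("label", ""),
                            json.dumps(props, ensure_ascii=False,
                                       sort_keys=True)])
        with open(edges_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "edge_type", "properties_json"])
            for u, v, key, data in sorted(kg.graph.edges(keys=True,
                                                         data=True)):
                w.writerow([u, v, key,
                            json.dumps(data, ensure_ascii=False,
                                       sort_keys=True)])
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format {format!r}")


def _scalarized(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    out = nx.MultiDiGraph()
    for node, data in g.nodes(data=True):
        out.add_node(node, **{
            k: (v if isinstance(v, (str, int, float, bool)) else
                json.dumps(v, ensure_ascii=False, sort_keys=True))
            for k, v in data.items() if v is not None
        })
    for u, v, key, data in g.edges(keys=True, data=True):
        out.add_edge(u, v, key=key, **{
            k: (v if isinstance(v, (str, int, float, bool)) else
                json.dumps(v, ensure_ascii=False, sort_keys=True))
            for k, v in data.items() if v is not None
        })
    return out


def import_graphml(path) -> nx.MultiDiGraph:
    """Read a GraphML export back, JSON-decoding the provenance column."""
    g = nx.read_graphml(path, force_multigraph=True)
    out = nx.MultiDiGraph()
    for node, data in g.nodes(data=True):
        out.add_node(node, **data)
    for u, v, key, data in g.edges(keys=True, data=True):
        data = dict(data)
        if "provenance" in data and isinstance(data["provenance"], str):
            data["provenance"] = json.loads(data["provenance"])
        out.add_edge(u, v, key=key, **data)
    return out


def import_bulk_csv(directory) -> nx.MultiDiGraph:
    directory = Path(directory)
    g = nx.MultiDiGraph()
    with open(directory / "nodes.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            props = json.loads(row["properties_json"])
            g.add_node(row["node_id"], label=row["label"], **props)
    with open(directory / "edges.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            props = json.loads(row["properties_json"])
            g.add_edge(row["source"], row["target"], key=row["edge_type"],
                       **props)
    return g
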