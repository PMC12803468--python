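"""Domain ontology: typed class hierarchy and class-level concept lookup.

Classes are connected by ``is_a``, ``role``, ``catalyst`` and ``result``
edges; dictionary concepts attach to their lowest subclass through
INSTANCE_OF links. Only ``is_a`` edges participate in class expansion for
queries (membership of "trace metals or minerals" is its instances plus
those of all is_a descendants); the other edge kinds are stored and
reportable but not traversed for membership.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx
import pandas as pd

from .errors import CycleError, FormatError, IntegrityError, OntologyLookupError
from .lexicon import DictionaryConcept, Lexicon

RELATION_KINDS = ("is_a", "role", "catalyst", "result")


@dataclass(frozen=True)
class OntologyClass:
    class_id: str
    name: str
    parents: tuple[tuple[str, str], ...] = ()  # (parent class_id, relation)


class Ontology:
    def __init__(self, classes: Iterable[OntologyClass],
                 instance_links: dict[str, str] | None = None):
        self.classes: dict[str, OntologyClass] = {c.class_id: c for c in classes}
        self.instance_links: dict[str, str] = dict(instance_links or {})
        self._name_index = {c.name.casefold(): c.class_id
                            for c in self.classes.values()}
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        for c in self.classes.values():
            for parent_id, rel in c.parents:
                if rel not in RELATION_KINDS:
                    raise FormatError(
                        f"unknown ontological relation {rel!r} on {c.class_id}"
                    )
                if parent_id not in self.classes:
                    raise IntegrityError(
                        f"class {c.class_id} references missing parent {parent_id}"
                    )
                if rel == "is_a":
                    g.add_edge(c.class_id, parent_id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            names = [u for u, _ in cycle] + [cycle[-1][1]]
            raise CycleError(f"is_a cycle: {' -> '.join(names)}", cycle=names)
        for coid, class_id in self.instance_links.items():
            if class_id not in self.classes:
                raise IntegrityError(
                    f"instance link {coid} -> missing class {class_id}"
                )
        depth = max(
            (len(self.ancestors(cid)) + 1 for cid in self.classes), default=0
        )
        if depth > 4:
            warnings.warn(
                f"is_a hierarchy depth {depth} exceeds the expected four levels",
                stacklevel=2,
            )

    # -- lookup -------------------------------------------------------------
    def resolve(self, class_ref: str) -> str:
        """Resolve a class id or (case-insensitive) class name to its id."""
        if class_ref in self.classes:
            return class_ref
        cid = self._name_index.get(class_ref.casefold())
        if cid is None:
            raise OntologyLookupError(f"unknown ontology class {class_ref!r}")
        return cid

    def ancestors(self, class_ref: str, relations=("is_a",)) -> list[str]:
        """Transitive ancestors in breadth-first order, deduplicated."""
        start = self.resolve(class_ref)
        rels = set(relations)
        seen: list[str] = []
        seen_set = {start}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for parent_id, rel in self.classes[cur].parents:
                if rel in rels and parent_id not in seen_set:
                    seen_set.add(parent_id)
                    seen.append(parent_id)
                    queue.append(parent_id)
        return seen

    def descendants(self, class_ref: str, relations=("is_a",)) -> set[str]:
        start = self.resolve(class_ref)
        rels = set(relations)
        children: dict[str, set[str]] = {cid: set() for cid in self.classes}
        for c in self.classes.values():
            for parent_id, rel in c.parents:
                if rel in rels:
                    children[parent_id].add(c.class_id)
        out: set[str] = set()
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for child in children[cur]:
                if child not in out:
                    out.add(child)
                    queue.append(child)
        return out

    def concepts_under(self, lex: Lexicon, class_ref: str
                       ) -> set[DictionaryConcept]:
        """All concepts INSTANCE_OF the class or any is_a descendant."""
        target = self.resolve(class_ref)
        classes = {target} | self.descendants(target)
        return {
            lex.concepts[coid]
            for coid, cid in self.instance_links.items()
            if cid in classes and coid in lex.concepts
        }

    def to_graphml(self, path) -> None:
        g = nx.MultiDiGraph()
        for c in self.classes.values():
            g.add_node(c.class_id, name=c.name, label="OntologyClass")
        for c in self.classes.values():
            for parent_id, rel in c.parents:
                g.add_edge(c.class_id, parent_id, key=rel, relation=rel)
        nx.write_graphml(g, path)


def load_ontology(classes_table, edges_table, instances_table) -> Ontology:
    """Load the three-table ontology (classes, typed edges, instance links).

    ``classes``: class_id, name. ``edges``: child_id, relation, parent_id.
    ``instances``: coid, class_id. Dangling references raise
    :class:`IntegrityError`; an is_a cycle raises :class:`CycleError`.
    """
    classes_df = _read(classes_table)
    edges_df = _read(edges_table)
    inst_df = _read(instances_table)
    parents: dict[str, list[tuple[str, str]]] = {}
    declared = set(classes_df["class_id"])
    for row in edges_df.itertuples(index=False):
        if row.child_id not in declared:
            raise IntegrityError(f"edge references undeclared class {row.child_id}")
        parents.setdefault(row.child_id, []).append((row.parent_id, row.relation))
    classes = [
        OntologyClass(
            class_id=row.class_id,
            name=row.name,
            parents=tuple(parents.get(row.class_id, ())),
        )
        for row in classes_df.itertuples(index=False)
    ]
    instance_links = {
        row.coid: row.class_id for row in inst_df.itertuples(index=False)
    }
    return Ontology(classes, instance_links)


def _read(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
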