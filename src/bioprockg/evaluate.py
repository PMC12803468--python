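"""Relation-level scoring against gold annotations.

A predicted relation is correct when its document, affector concept and
affected concept match a gold annotation (mode ``pair_only``), plus the
relation type in mode ``pair_and_type``. Matching is greedy one-to-one
within a document: each gold item is consumed by at most one prediction,
duplicates of an already-matched gold count as false positives.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R), all 0 by
convention when the denominator is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from .documents import RELATION_TYPES, GoldAnnotation
from .extraction import ImpactRelation
from .lexicon import Lexicon, ground_phrase


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


@dataclass(frozen=True)
class TypeScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "TypeScore":
        return cls(tp, fp, fn, *_prf(tp, fp, fn))


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_type: dict[str, TypeScore] = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1,
            "per_type": {
                t: vars(s) for t, s in self.per_type.items()
            },
        }
        return json.dumps(obj, indent=2)

    def to_table(self) -> str:
        lines = [
            f"{'type':<28}{'TP':>5}{'FP':>5}{'FN':>5}"
            f"{'P':>8}{'R':>8}{'F1':>8}"
        ]
        rows = list(self.per_type.items()) + [
            ("overall", TypeScore(self.tp, self.fp, self.fn,
                                  self.precision, self.recall, self.f1))
        ]
        for name, s in rows:
            lines.append(
                f"{name:<28}{s.tp:>5}{s.fp:>5}{s.fn:>5}"
                f"{s.precision:>8.3f}{s.recall:>8.3f}{s.f1:>8.3f}"
            )
        return "\n".join(lines)


def _concept_id(lex: Lexicon | None, term: str, doc_id: str | None = None
                ) -> str:
    """Normalize a gold term to its dictionary concept id (or a casefolded
    string when no lexicon is supplied)."""
    if lex is None:
        return term.casefold().strip()
    hit = lex.lookup(term, doc_id)
    if hit is not None:
        return hit.coid
    matches = ground_phrase(lex, term, doc_id)
    if matches:
        return matches[0].concept.coid
    return term.casefold().strip()


def score_relations(predicted: Iterable[ImpactRelation | dict],
                    gold: Iterable[GoldAnnotation],
                    mode: str = "pair_and_type",
                    lexicon: Lexicon | None = None) -> EvalReport:
    """Score predictions against gold with overall and per-type metrics."""
    if mode not in ("pair_only", "pair_and_type"):
        raise ValueError(f"unknown mode {mode!r}")

    def pred_key(p) -> tuple[str, str, str, str]:
        if isinstance(p, ImpactRelation):
            return (p.sentence.doc_id, p.affector.concept.coid,
                    p.affected.concept.coid,
                    p.relation_type or "correlated_not_specified")
        return (p["doc_id"], p["affector_coid"], p["affected_coid"],
                p["relation_type"])

    gold = list(gold)
    gold_items = [
        (
            (g.doc_id,
             _concept_id(lexicon, g.affector_term, g.doc_id),
             _concept_id(lexicon, g.affected_term, g.doc_id),
             g.relation_type),
            False,  # matched flag
        )
        for g in gold
    ]
    gold_items = [[key, False] for key, _ in gold_items]

    tp_by_type = {t: 0 for t in RELATION_TYPES}
    fp_by_type = {t: 0 for t in RELATION_TYPES}
    fn_by_type = {t: 0 for t in RELATION_TYPES}

    for p in predicted:
        doc, aff, afd, rtype = pred_key(p)
        matched = False
        for item in gold_items:
            (gdoc, gaff, gafd, gtype), used = item
            if used or (gdoc, gaff, gafd) != (doc, aff, afd):
                continue
            if mode == "pair_and_type" and gtype != rtype:
                continue
            item[1] = True
            matched = True
            tp_by_type[gtype] += 1
            break
        if not matched:
            fp_by_type[rtype] += 1
    for (_, _, _, gtype), used in gold_items:
        if not used:
            fn_by_type[gtype] += 1

    per_type = {
        t: TypeScore.from_counts(tp_by_type[t], fp_by_type[t], fn_by_type[t])
        for t in RELATION_TYPES
    }
    tp = sum(tp_by_type.values())
    fp = sum(fp_by_type.values())
    fn = sum(fn_by_type.values())
    return EvalReport(tp, fp, fn, *_prf(tp, fp, fn), per_type=per_type)
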