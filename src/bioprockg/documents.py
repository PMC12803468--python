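"""Document model: sources, provenance-carrying sentences, gold annotations.

Three literature source kinds are supported — PubMed abstracts, sectioned
full-text articles (JATS-like XML) and book chapters — all reduced to a
uniform :class:`SourceDocument` whose sections are split into
:class:`Sentence` units carrying their section title, document identifiers
and character span, so every extracted relation can cite its evidence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import IO, Iterable

from lxml import etree

from .errors import (
    ConfigurationError,
    DocumentParseError,
    IntegrityError,
    InvalidDocumentError,
)
from .textnorm import normalize, split_sentence_spans

DOC_KINDS = ("abstract", "article", "book_chapter")

RELATION_TYPES = (
    "positively_correlated",
    "negatively_correlated",
    "not_correlated",
    "correlated_not_specified",
)


@dataclass(frozen=True)
class SourceDocument:
    """A text source identified by PMID, PMCID or ISBN (+ chapter)."""

    doc_id: str
    doc_kind: str
    sections: tuple[tuple[str, str], ...]
    chapter_number: int | None = None

    def __post_init__(self):
        if not self.doc_id:
            raise InvalidDocumentError("doc_id must be non-empty")
        if self.doc_kind not in DOC_KINDS:
            raise InvalidDocumentError(f"unknown doc_kind {self.doc_kind!r}")
        if (self.chapter_number is not None) != (self.doc_kind == "book_chapter"):
            raise InvalidDocumentError(
                "chapter_number is required for book chapters and "
                "forbidden otherwise"
            )
        if self.doc_kind == "abstract":
            titles = [t for t, _ in self.sections]
            if titles != ["Abstract"]:
                raise InvalidDocumentError(
                    "abstracts must have exactly one section titled 'Abstract'"
                )

    def section_text(self, title: str) -> str:
        for t, text in self.sections:
            if t == title:
                return text
        raise KeyError(title)


@dataclass(frozen=True)
class Sentence:
    """One sentence with provenance back into its source section."""

    sent_id: str
    text: str
    section_title: str
    doc_id: str
    doc_kind: str
    start: int
    end: int
    chapter_number: int | None = None

    @property
    def char_span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "doc_kind": self.doc_kind,
            "chapter_number": self.chapter_number,
            "section_title": self.section_title,
            "sent_id": self.sent_id,
            "char_span": [self.start, self.end],
            "text": self.text,
        }


@dataclass(frozen=True)
class GoldAnnotation:
    """A manually annotated impact relation used for evaluation."""

    doc_id: str
    affector_term: str
    affected_term: str
    relation_type: str
    sentence_text: str

    def __post_init__(self):
        if self.relation_type not in RELATION_TYPES:
            raise InvalidDocumentError(
                f"unknown relation_type {self.relation_type!r}"
            )


def read_document(raw: str | bytes, format: str, ids: dict) -> SourceDocument:
    """Parse one raw input into a :class:`SourceDocument`.

    ``format`` is one of ``plain_abstract``, ``jats_xml``, ``chapter_text``.
    ``ids`` supplies the identifiers appropriate to the format
    (``{"PMID": ...}``, ``{"PMID"/"PMCID": ...}``,
    ``{"ISBN": ..., "chapter": ...}``).
    """
    if isinstance(raw, bytes):
        raw_text = raw.decode("utf-8")
    else:
        raw_text = raw
    if not raw_text or not raw_text.strip():
        raise InvalidDocumentError("empty input document")

    if format == "plain_abstract":
        pmid = ids.get("PMID") or ids.get("pmid")
        if not pmid:
            raise ConfigurationError("plain_abstract requires a PMID")
        return SourceDocument(
            doc_id=str(pmid),
            doc_kind="abstract",
            sections=(("Abstract", normalize(raw_text.strip())),),
        )

    if format == "jats_xml":
        doc_id = ids.get("PMID") or ids.get("pmid") or ids.get("PMCID") or ids.get("pmcid")
        if not doc_id:
            raise ConfigurationError("jats_xml requires a PMID or PMCID")
        data = raw.encode("utf-8") if isinstance(raw, str) else raw
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise DocumentParseError(
                f"malformed XML at byte offset ~{exc.position}: {exc}",
                offset=exc.position[1] if exc.position else None,
            ) from exc
        sections: list[tuple[str, str]] = []
        for abstract in root.iter("abstract"):
            text = " ".join(" ".join(abstract.itertext()).split())
            if text:
                sections.append(("Abstract", normalize(text)))
        for sec in root.iter("sec"):
            title_el = sec.find("title")
            title = (
                " ".join(title_el.itertext()).strip()
                if title_el is not None
                else "Untitled"
            )
            paras = [
                " ".join(" ".join(p.itertext()).split()) for p in sec.findall("p")
            ]
            body = " ".join(p for p in paras if p)
            if body:
                sections.append((title, normalize(body)))
        if not sections:
            raise InvalidDocumentError("XML document contains no sections")
        return SourceDocument(
            doc_id=str(doc_id), doc_kind="article", sections=tuple(sections)
        )

    if format == "chapter_text":
        isbn = ids.get("ISBN") or ids.get("isbn")
        chapter = ids.get("chapter") or ids.get("chapter_number")
        if not isbn or chapter is None:
            raise ConfigurationError(
                "chapter_text requires ISBN and chapter number"
            )
        text = _select_chapter(raw_text, int(chapter))
        lines = text.strip().splitlines()
        title = lines[0].strip() if lines else f"Chapter {chapter}"
        body = "\n".join(lines[1:]).strip() or title
        return SourceDocument(
            doc_id=str(isbn),
            doc_kind="book_chapter",
            chapter_number=int(chapter),
            sections=((title, normalize(body)),),
        )

    raise ConfigurationError(f"unknown document format {format!r}")


_CHAPTER_MARKER = "=== CHAPTER"


def _select_chapter(text: str, chapter: int) -> str:
    """Pick one chapter from a marker-delimited book file.

    Markers look like ``=== CHAPTER 3 ===`` on their own line; a file with
    no markers is taken to be a single pre-split chapter.
    """
    if _CHAPTER_MARKER not in text:
        return text
    chunks: dict[int, list[str]] = {}
    current: int | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith(_CHAPTER_MARKER):
            digits = "".join(c for c in stripped if c.isdigit())
            current = int(digits) if digits else None
            chunks[current] = []
        elif current is not None:
            chunks[current].append(line)
    if chapter not in chunks:
        raise InvalidDocumentError(f"chapter {chapter} not found in book file")
    return "\n".join(chunks[chapter])


def segment_sentences(doc: SourceDocument) -> list[Sentence]:
    """Split every section of *doc* into provenance-carrying sentences."""
    out: list[Sentence] = []
    counter = 0
    for sec_idx, (title, text) in enumerate(doc.sections):
        for a, b in split_sentence_spans(text):
            out.append(
                Sentence(
                    sent_id=f"{doc.doc_id}:{sec_idx}:{counter}",
                    text=text[a:b],
                    section_title=title,
                    doc_id=doc.doc_id,
                    doc_kind=doc.doc_kind,
                    chapter_number=doc.chapter_number,
                    start=a,
                    end=b,
                )
            )
            counter += 1
    return out


def sentences_to_jsonl(sentences: Iterable[Sentence], fh: IO[str]) -> None:
    for s in sentences:
        fh.write(json.dumps(s.to_json(), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# document JSON (round-trippable corpus serialization)

def document_to_json(doc: SourceDocument) -> dict:
    d = dataclasses.asdict(doc)
    d["sections"] = [list(s) for s in doc.sections]
    return d


def document_from_json(obj: dict) -> SourceDocument:
    return SourceDocument(
        doc_id=obj["doc_id"],
        doc_kind=obj["doc_kind"],
        sections=tuple((t, x) for t, x in obj["sections"]),
        chapter_number=obj.get("chapter_number"),
    )


def documents_to_jsonl(docs: Iterable[SourceDocument], fh: IO[str]) -> None:
    for d in docs:
        fh.write(json.dumps(document_to_json(d), ensure_ascii=False) + "\n")


def documents_from_jsonl(fh: IO[str]) -> list[SourceDocument]:
    return [document_from_json(json.loads(line)) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# BioC gold annotations

def read_bioc_gold(bioc_xml: str | bytes) -> list[GoldAnnotation]:
    """Read entity/relation annotations from BioC XML into gold records.

    Entities carry an infon ``type`` of Affector/Affected; relations carry
    an infon ``type`` with the correlation label and two node refs with
    roles. A relation referencing a missing entity id raises
    :class:`IntegrityError`.
    """
    data = bioc_xml.encode("utf-8") if isinstance(bioc_xml, str) else bioc_xml
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise DocumentParseError(
            f"malformed BioC XML: {exc}",
            offset=exc.position[1] if exc.position else None,
        ) from exc
    golds: list[GoldAnnotation] = []
    for doc_el in root.iter("document"):
        doc_id = (doc_el.findtext("id") or "").strip()
        for passage in doc_el.iter("passage"):
            sentence_text = (passage.findtext("text") or "").strip()
            entities: dict[str, str] = {}
            for ann in passage.findall("annotation"):
                entities[ann.get("id")] = (ann.findtext("text") or "").strip()
            for rel in passage.findall("relation"):
                rtype = None
                for infon in rel.findall("infon"):
                    if infon.get("key") == "type":
                        rtype = (infon.text or "").strip()
                roles = {}
                for node in rel.findall("node"):
                    refid = node.get("refid")
                    if refid not in entities:
                        raise IntegrityError(
                            f"relation {rel.get('id')!r} references missing "
                            f"entity id {refid!r}"
                        )
                    roles[node.get("role")] = entities[refid]
                golds.append(
                    GoldAnnotation(
                        doc_id=doc_id,
                        affector_term=roles.get("Affector", ""),
                        affected_term=roles.get("Affected", ""),
                        relation_type=rtype or "correlated_not_specified",
                        sentence_text=sentence_text,
                    )
                )
    return golds


def write_bioc_gold(golds: Iterable[GoldAnnotation]) -> str:
    """Serialize gold annotations back to BioC XML (inverse of the reader)."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "bioprockg"
    by_doc: dict[str, list[GoldAnnotation]] = {}
    for g in golds:
        by_doc.setdefault(g.doc_id, []).append(g)
    for doc_id, items in by_doc.items():
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc_id
        for i, g in enumerate(items):
            passage = etree.SubElement(doc_el, "passage")
            etree.SubElement(passage, "offset").text = "0"
            etree.SubElement(passage, "text").text = g.sentence_text
            for j, (role, term) in enumerate(
                (("Affector", g.affector_term), ("Affected", g.affected_term))
            ):
                ann = etree.SubElement(passage, "annotation", id=f"T{i}_{j}")
                infon = etree.SubElement(ann, "infon", key="type")
                infon.text = role
                etree.SubElement(ann, "text").text = term
            rel = etree.SubElement(passage, "relation", id=f"R{i}")
            infon = etree.SubElement(rel, "infon", key="type")
            infon.text = g.relation_type
            etree.SubElement(rel, "node", refid=f"T{i}_0", role="Affector")
            etree.SubElement(rel, "node", refid=f"T{i}_1", role="Affected")
    return etree.tostring(root, pretty_print=True, encoding="unicode")
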