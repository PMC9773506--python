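"""Three-table corpus model for literature triage.

A corpus is held as three tables mirroring how triage pipelines store
screened literature:

* **documents** — one row per document, with metadata (identifier, title,
  journal, publication date, publication types).
* **contents** — one row per document section (title, abstract, body
  sections), ordered by position within the document.
* **meaning units** — one row per sentence-level unit, produced later by
  :mod:`adrtriage.preprocess` with character offsets into the parent
  section text.

Two interchange formats are supported: a JSONL fixture format (one document
per line) and read-only PubMed efetch XML (``PubmedArticle`` records).
Figure/table content and reference lists in the XML are never read;
only the title and abstract parts are collected.
"""

from __future__ import annotations

import json
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree
from pydantic import BaseModel, Field, field_validator


class SectionLabel(str, Enum):
    """Closed vocabulary of section types; unknown headers map to OTHER."""

    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"
    INTRO = "INTRO"
    METHODS = "METHODS"
    RESULTS = "RESULTS"
    DISCUSS = "DISCUSS"
    CASE = "CASE"
    CONCL = "CONCL"
    OTHER = "OTHER"

    @classmethod
    def coerce(cls, raw: Optional[str]) -> "SectionLabel":
        """Map a free-text section header onto the closed vocabulary."""
        if not raw:
            return cls.OTHER
        key = raw.strip().upper()
        aliases = {
            "INTRODUCTION": cls.INTRO,
            "BACKGROUND": cls.INTRO,
            "OBJECTIVE": cls.INTRO,
            "OBJECTIVES": cls.INTRO,
            "METHOD": cls.METHODS,
            "MATERIALS AND METHODS": cls.METHODS,
            "PATIENTS AND METHODS": cls.METHODS,
            "RESULT": cls.RESULTS,
            "FINDINGS": cls.RESULTS,
            "DISCUSSION": cls.DISCUSS,
            "CASE REPORT": cls.CASE,
            "CASE PRESENTATION": cls.CASE,
            "CONCLUSION": cls.CONCL,
            "CONCLUSIONS": cls.CONCL,
        }
        try:
            return cls(key)
        except ValueError:
            return aliases.get(key, cls.OTHER)


class ContentSection(BaseModel):
    doc_id: str
    section_label: SectionLabel
    position: int = Field(ge=0)
    text: str

    @field_validator("text")
    @classmethod
    def _non_blank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("section text empty after whitespace normalization")
        return v


class Document(BaseModel):
    doc_id: str
    title: str = ""
    journal: Optional[str] = None
    pub_date: Optional[date] = None
    pub_types: list[str] = Field(default_factory=list)
    sections: list[ContentSection] = Field(default_factory=list)

    @field_validator("sections")
    @classmethod
    def _positions_increasing(cls, v: list[ContentSection]) -> list[ContentSection]:
        positions = [s.position for s in v]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("section positions must be strictly increasing")
        return v


class MeaningUnit(BaseModel):
    """A sentence-level unit.

    Offsets are 0-based half-open character offsets (Unicode code points)
    into the text of the parent section, identified by ``doc_id`` and
    ``section_position``.
    """

    mu_id: str
    doc_id: str
    section_label: SectionLabel
    section_position: int = Field(ge=0)
    char_start: int = Field(ge=0)
    char_end: int
    text: str
    word_count: int = Field(gt=0)

    @field_validator("char_end")
    @classmethod
    def _end_after_start(cls, v: int, info) -> int:
        if "char_start" in info.data and v <= info.data["char_start"]:
            raise ValueError("char_end must exceed char_start")
        return v


class LoadReport(BaseModel):
    n_loaded: int = 0
    n_skipped: int = 0
    errors: list[str] = Field(default_factory=list)


class CorpusTables(BaseModel):
    """The three-table corpus container.

    Sections live inside their parent :class:`Document`; the ``contents``
    view flattens them so the object still presents the three-table surface.
    """

    documents: list[Document] = Field(default_factory=list)
    meaning_units: list[MeaningUnit] = Field(default_factory=list)

    @property
    def contents(self) -> list[ContentSection]:
        return [sec for doc in self.documents for sec in doc.sections]

    def document(self, doc_id: str) -> Document:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)

    def section_text(self, doc_id: str, position: int) -> str:
        for sec in self.document(doc_id).sections:
            if sec.position == position:
                return sec.text
        raise KeyError((doc_id, position))

    def check_integrity(self) -> None:
        """Raise ValueError on duplicate doc_ids or dangling references."""
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_id in corpus")
        known = set(ids)
        for sec in self.contents:
            if sec.doc_id not in known:
                raise ValueError(f"section references unknown doc_id {sec.doc_id!r}")
        for mu in self.meaning_units:
            if mu.doc_id not in known:
                raise ValueError(f"meaning unit references unknown doc_id {mu.doc_id!r}")


# ---------------------------------------------------------------------------
# JSONL fixture format
# ---------------------------------------------------------------------------

def _document_from_record(rec: dict) -> Document:
    if "doc_id" not in rec or rec["doc_id"] in (None, ""):
        raise ValueError("record missing doc_id")
    doc_id = str(rec["doc_id"])
    sections = []
    pos = 0
    for raw in rec.get("sections", []):
        text = raw.get("text", "")
        if not text.strip():
            continue  # blank sections carry no content
        sections.append(
            ContentSection(
                doc_id=doc_id,
                section_label=SectionLabel.coerce(raw.get("label")),
                position=pos,
                text=text,
            )
        )
        pos += 1
    pub_date = rec.get("pub_date")
    return Document(
        doc_id=doc_id,
        title=rec.get("title", ""),
        journal=rec.get("journal"),
        pub_date=date.fromisoformat(pub_date) if pub_date else None,
        pub_types=list(rec.get("pub_types") or []),
        sections=sections,
    )


def _document_to_record(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "journal": doc.journal,
        "pub_date": doc.pub_date.isoformat() if doc.pub_date else None,
        "pub_types": doc.pub_types,
        "sections": [
            {"label": s.section_label.value, "text": s.text} for s in doc.sections
        ],
    }


def read_fixture_corpus(
    path: str | Path, format: str = "jsonl"
) -> tuple[CorpusTables, LoadReport]:
    """Load documents and sections from a fixture file.

    Malformed records (e.g. missing ``doc_id``) are skipped and counted in
    the returned :class:`LoadReport`; an unreadable file raises.
    Meaning units are left empty — they are built by the preprocessing step.
    """
    path = Path(path)
    if format == "jsonl":
        tables, report = _read_jsonl(path)
    elif format == "pubmed_xml":
        tables, report = _read_pubmed_xml(path)
    else:
        raise ValueError(f"unsupported corpus format {format!r}")
    tables.check_integrity()
    return tables, report


def _read_jsonl(path: Path) -> tuple[CorpusTables, LoadReport]:
    docs: list[Document] = []
    report = LoadReport()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                docs.append(_document_from_record(json.loads(line)))
                report.n_loaded += 1
            except (ValueError, KeyError, TypeError) as exc:
                report.n_skipped += 1
                report.errors.append(f"line {lineno}: {exc}")
    return CorpusTables(documents=docs), report


# ---------------------------------------------------------------------------
# PubMed efetch XML (read-only)
# ---------------------------------------------------------------------------

_MONTHS = {m: i for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"], 1)}


def _parse_pubdate(node) -> Optional[date]:
    if node is None:
        return None
    year = node.findtext("Year")
    if not year:
        return None
    month_raw = node.findtext("Month") or "1"
    month = _MONTHS.get(month_raw[:3], None)
    if month is None:
        try:
            month = int(month_raw)
        except ValueError:
            month = 1
    day = node.findtext("Day") or "1"
    try:
        return date(int(year), month, int(day))
    except ValueError:
        return None


def _read_pubmed_xml(path: Path) -> tuple[CorpusTables, LoadReport]:
    tree = etree.parse(str(path))
    docs: list[Document] = []
    report = LoadReport()
    for art in tree.iter("PubmedArticle"):
        try:
            docs.append(_pubmed_article_to_document(art))
            report.n_loaded += 1
        except ValueError as exc:
            report.n_skipped += 1
            report.errors.append(str(exc))
    return CorpusTables(documents=docs), report


def _pubmed_article_to_document(art) -> Document:
    pmid = art.findtext(".//MedlineCitation/PMID")
    if not pmid:
        raise ValueError("PubmedArticle without PMID")
    article = art.find(".//MedlineCitation/Article")
    title_node = None if article is None else article.find("ArticleTitle")
    title = "".join(title_node.itertext()).strip() if title_node is not None else ""
    journal = None if article is None else article.findtext("Journal/Title")
    pub_date = None
    if article is not None:
        pub_date = _parse_pubdate(article.find("Journal/JournalIssue/PubDate"))
    pub_types = []
    if article is not None:
        pub_types = [
            (pt.text or "").strip()
            for pt in article.findall("PublicationTypeList/PublicationType")
            if (pt.text or "").strip()
        ]
    sections: list[ContentSection] = []
    pos = 0
    if title:
        sections.append(
            ContentSection(doc_id=pmid, section_label=SectionLabel.TITLE,
                           position=pos, text=title)
        )
        pos += 1
    if article is not None:
        # One section per labelled abstract part; unlabelled parts stay ABSTRACT.
        for part in article.findall("Abstract/AbstractText"):
            text = "".join(part.itertext()).strip()
            if not text:
                continue
            label = SectionLabel.coerce(
                part.get("NlmCategory") or part.get("Label") or "ABSTRACT"
            )
            if label is SectionLabel.OTHER:
                label = SectionLabel.ABSTRACT
            sections.append(
                ContentSection(doc_id=pmid, section_label=label,
                               position=pos, text=text)
            )
            pos += 1
    return Document(
        doc_id=pmid,
        title=title,
        journal=journal,
        pub_date=pub_date,
        pub_types=pub_types,
        sections=sections,
    )


# ---------------------------------------------------------------------------
# Table persistence and filters
# ---------------------------------------------------------------------------

def write_tables(tables: CorpusTables, dir: str | Path) -> dict[str, int]:
    """Write the three tables as JSONL; returns ``{filename: n_records}``.

    ``read_tables`` on the written directory returns an equal corpus.
    """
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    doc_rows = []
    for doc in tables.documents:
        rec = _document_to_record(doc)
        rec.pop("sections")
        doc_rows.append(rec)
    content_rows = [
        {"doc_id": s.doc_id, "section_label": s.section_label.value,
         "position": s.position, "text": s.text}
        for s in tables.contents
    ]
    mu_rows = [mu.model_dump(mode="json") for mu in tables.meaning_units]
    for name, rows in [("documents.jsonl", doc_rows),
                       ("contents.jsonl", content_rows),
                       ("meaning_units.jsonl", mu_rows)]:
        with (out / name).open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
        manifest[name] = len(rows)
    return manifest


def read_tables(dir: str | Path) -> CorpusTables:
    """Inverse of :func:`write_tables`."""
    out = Path(dir)

    def rows(name: str) -> Iterable[dict]:
        with (out / name).open("r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    yield json.loads(line)

    sections_by_doc: dict[str, list[ContentSection]] = {}
    for rec in rows("contents.jsonl"):
        sec = ContentSection(
            doc_id=rec["doc_id"],
            section_label=SectionLabel(rec["section_label"]),
            position=rec["position"],
            text=rec["text"],
        )
        sections_by_doc.setdefault(sec.doc_id, []).append(sec)
    docs = []
    for rec in rows("documents.jsonl"):
        secs = sorted(sections_by_doc.get(rec["doc_id"], []), key=lambda s: s.position)
        docs.append(
            Document(
                doc_id=rec["doc_id"],
                title=rec.get("title", ""),
                journal=rec.get("journal"),
                pub_date=date.fromisoformat(rec["pub_date"]) if rec.get("pub_date") else None,
                pub_types=rec.get("pub_types") or [],
                sections=secs,
            )
        )
    mus = [MeaningUnit(**rec) for rec in rows("meaning_units.jsonl")]
    tables = CorpusTables(documents=docs, meaning_units=mus)
    tables.check_integrity()
    return tables


def filter_recent(
    tables: CorpusTables, years_window: int = 6, today: Optional[date] = None
) -> CorpusTables:
    """Keep documents published within the trailing window of years.

    Undated documents are kept (lenient default): dropping them would
    silently discard potentially relevant records.
    """
    today = today or date.today()
    cutoff = today - timedelta(days=round(365.25 * years_window))
    kept = [d for d in tables.documents if d.pub_date is None or d.pub_date >= cutoff]
    ids = {d.doc_id for d in kept}
    return CorpusTables(
        documents=kept,
        meaning_units=[mu for mu in tables.meaning_units if mu.doc_id in ids],
    )
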