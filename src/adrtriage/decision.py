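"""Decision engine: from meaning units to hits, kept documents and a funnel.

A meaning unit is a *hit* when it passes the whole decision conjunction:

1. **drug gate** — the unit mentions a query drug (exact dictionary match);
   everything else stops here, which also keeps the expensive stages off
   the vast majority of units;
2. **generic regex rules** — unit-level regular expressions that on their
   own indicate an adverse-event mention ("adverse event(s)", "TRAEs", ...)
   or a serious one ("SAE(s)", "grade 4/5 reactions", ...); they are run on
   every drug-containing unit before any classifier;
3. **relationship** — the unit states a drug–event causality relationship
   (classifier score at or above ``relationship_threshold``, or a generic
   AE regex hit);
4. **entities** — NER runs when the relationship score reaches
   ``ner_gate_threshold`` or a generic AE regex fired; the unit needs at
   least one DRUG span and one AE evidence (a model span or a generic AE
   regex hit, recorded as a synthetic span with ``source="regex"``);
5. **seriousness** — the seriousness label is ``serious``, or a generic
   serious regex fired, or (for units the classifier rejected) an
   always-serious term is rescued by fuzzy matching.

Documents are kept when they have at least one hit and ranked by
``w_max_score * max(hit_score) + w_n_hits * log2(1 + n_hits)``; ties break
on the document identifier, so ordering is reproducible.  Stage-by-stage
document and meaning-unit counts are collected in a funnel, which is
non-increasing by construction.
"""

from __future__ import annotations

import math
import re
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from .classify import (
    ClassifierBackend,
    EntitySpan,
    EntityType,
    RelationshipResult,
    SeriousnessLabel,
    SeriousnessResult,
)
from .corpus import CorpusTables, MeaningUnit
from .lexsearch import (
    ExactMatcher,
    FuzzyExpression,
    LexiconEntry,
    Query,
    TermMatch,
    expressions_for_entry,
    find_fuzzy,
    tag_document_indications,
)


class PipelineConfig(BaseModel):
    """All tunable constants of the pipeline, with their defaults."""

    relationship_threshold: float = Field(default=0.2, ge=0.0, le=1.0)
    ner_gate_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    ner_span_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    max_gap: int = Field(default=20, gt=0)
    short_min: int = Field(default=4, gt=0)
    short_max: int = Field(default=10, gt=0)
    neighbor_max: int = Field(default=20, gt=0)
    years_window: int = Field(default=6, gt=0)
    w_max_score: float = 1.0
    w_n_hits: float = 0.1
    use_generic_ae_regex: bool = True
    use_generic_serious_regex: bool = True
    use_serious_rescue: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8"
        )


class Stage(str, Enum):
    DRUG_GATE = "drug_gate"
    RELATIONSHIP = "relationship"
    ENTITIES = "entities"
    SERIOUSNESS = "seriousness"


class AnnotatedUnit(BaseModel):
    mu: MeaningUnit
    drug_matches: list[TermMatch] = Field(default_factory=list)
    relationship: Optional[RelationshipResult] = None
    entities: list[EntitySpan] = Field(default_factory=list)
    seriousness: Optional[SeriousnessResult] = None
    regex_ae: bool = False
    regex_serious: bool = False
    rescue_serious_terms: list[TermMatch] = Field(default_factory=list)
    is_hit: bool = False
    hit_score: float = 0.0
    stage_reached: Stage = Stage.DRUG_GATE


class DocumentResult(BaseModel):
    doc_id: str
    hits: list[AnnotatedUnit] = Field(default_factory=list)
    indication_tags: list[str] = Field(default_factory=list)
    rank_score: float = 0.0
    kept: bool = False


class FunnelStage(BaseModel):
    stage: str
    n_docs: int
    n_mu: int


class FunnelStats(BaseModel):
    stages: list[FunnelStage] = Field(default_factory=list)

    def assert_monotone(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_docs > prev.n_docs or cur.n_mu > prev.n_mu:
                raise AssertionError(
                    f"funnel not monotone: {prev.stage}->{cur.stage}"
                )


# ---------------------------------------------------------------------------
# Generic regex rules
# ---------------------------------------------------------------------------

# All-caps acronyms are matched case-sensitively so e.g. "Caesarean" cannot
# produce a spurious AE mention; phrase families are case-insensitive.
_AE_ACRONYM = re.compile(r"\b(?:TRAEs?|AEs?|SAEs?)\b")
_AE_PHRASE = re.compile(
    r"\b(?:side|adverse)[ -](?:events?|effects?|reactions?)\b", re.IGNORECASE
)
_SERIOUS_ACRONYM = re.compile(r"\bSAEs?\b")
_SERIOUS_PHRASE = re.compile(
    r"\bserious[ -]adverse[ -](?:events?|effects?|reactions?)\b", re.IGNORECASE
)
_GRADE_PHRASE = re.compile(
    r"\bgrade[ -](?:4/5|5/4|[45])[ -](?:events?|effects?|reactions?|toxicit(?:y|ies))\b",
    re.IGNORECASE,
)


def match_generic_ae(text: str) -> tuple[bool, list[str]]:
    """Generic adverse-event mentions that stand on their own."""
    found = [m.group(0) for m in _AE_ACRONYM.finditer(text)]
    found += [m.group(0) for m in _AE_PHRASE.finditer(text)]
    return bool(found), found


def match_generic_serious(text: str) -> tuple[bool, list[str]]:
    """Generic *serious* adverse-event mentions (SAE family, grade 4/5)."""
    found = [m.group(0) for m in _SERIOUS_ACRONYM.finditer(text)]
    found += [m.group(0) for m in _SERIOUS_PHRASE.finditer(text)]
    found += [m.group(0) for m in _GRADE_PHRASE.finditer(text)]
    return bool(found), found


# ---------------------------------------------------------------------------
# Serious-term rescue
# ---------------------------------------------------------------------------

def build_rescue_expressions(
    serious_terms: list[LexiconEntry], max_expand_tokens: int = 5
) -> tuple[list[FuzzyExpression], dict[str, Optional[str]]]:
    """Fuzzy expressions plus canonical -> outcome-category map."""
    exprs: list[FuzzyExpression] = []
    categories: dict[str, Optional[str]] = {}
    for entry in serious_terms:
        exprs.extend(expressions_for_entry(entry, max_expand_tokens=max_expand_tokens))
        categories[entry.canonical] = entry.outcome_category
    return exprs, categories


def rescue_serious(
    text: str,
    serious_terms: list[LexiconEntry],
    max_gap: int = 20,
) -> list[TermMatch]:
    """Fuzzy-match always-serious terms in a unit the classifier rejected.

    Only called for units whose seriousness label is not ``serious``; each
    match carries its outcome category.
    """
    exprs, categories = build_rescue_expressions(serious_terms)
    matches = find_fuzzy(exprs, text, max_gap=max_gap)
    for m in matches:
        m.outcome_category = categories.get(m.term_id)
    return matches


# ---------------------------------------------------------------------------
# Per-unit decision diagram
# ---------------------------------------------------------------------------

class DecisionEngine:
    """Precompiled pipeline over one query/backend/config triple."""

    def __init__(
        self,
        query: Query,
        backend: ClassifierBackend,
        config: Optional[PipelineConfig] = None,
        serious_terms: Optional[list[LexiconEntry]] = None,
    ):
        from .classify import default_serious_terms

        self.query = query
        self.backend = backend
        self.config = config or PipelineConfig()
        self.serious_terms = (
            serious_terms if serious_terms is not None else default_serious_terms()
        )
        self._drug_matcher = ExactMatcher(query.drug_surfaces)
        if self.serious_terms:
            self._rescue_exprs, self._rescue_categories = build_rescue_expressions(
                self.serious_terms
            )
        else:
            self._rescue_exprs, self._rescue_categories = [], {}

    def process_unit(self, mu: MeaningUnit) -> AnnotatedUnit:
        cfg = self.config
        unit = AnnotatedUnit(mu=mu)

        # (1) drug gate
        unit.drug_matches = self._drug_matcher.find(mu.text)
        if not unit.drug_matches:
            return unit

        # (2) generic regex rules on every drug-containing unit
        if cfg.use_generic_ae_regex:
            unit.regex_ae, _ = match_generic_ae(mu.text)
        if cfg.use_generic_serious_regex:
            unit.regex_serious, _ = match_generic_serious(mu.text)

        # (3) relationship classification
        unit.relationship = self.backend.classify_relationship(mu.text)
        unit.stage_reached = Stage.RELATIONSHIP
        rel_positive = (
            unit.relationship.score >= cfg.relationship_threshold or unit.regex_ae
        )
        if not rel_positive:
            return unit

        # (4) entity extraction, gated on the relationship score
        if unit.relationship.score >= cfg.ner_gate_threshold or unit.regex_ae:
            unit.entities = [
                s for s in self.backend.extract_entities(mu.text)
                if s.score >= cfg.ner_span_threshold
            ]
        if unit.regex_ae:
            # a generic AE mention counts as AE evidence
            unit.entities = unit.entities + [
                EntitySpan(entity_type=EntityType.AE, char_start=0,
                           char_end=len(mu.text), score=1.0, source="regex")
            ]
        unit.stage_reached = Stage.ENTITIES
        has_drug = any(e.entity_type is EntityType.DRUG for e in unit.entities)
        has_ae = any(e.entity_type is EntityType.AE for e in unit.entities)
        if not (has_drug and has_ae):
            return unit

        # (5) seriousness, with regex and rescue evidence
        unit.seriousness = self.backend.classify_seriousness(mu.text)
        unit.stage_reached = Stage.SERIOUSNESS
        serious = unit.seriousness.label is SeriousnessLabel.SERIOUS
        if not serious and cfg.use_serious_rescue and self._rescue_exprs:
            unit.rescue_serious_terms = find_fuzzy(
                self._rescue_exprs, mu.text, max_gap=cfg.max_gap
            )
            for m in unit.rescue_serious_terms:
                m.outcome_category = self._rescue_categories.get(m.term_id)
        serious_evidence = (
            serious or unit.regex_serious or bool(unit.rescue_serious_terms)
        )
        if not serious_evidence:
            return unit

        # (6) hit
        unit.is_hit = True
        unit.hit_score = unit.relationship.score
        return unit

    def process_corpus(
        self, tables: CorpusTables
    ) -> tuple[list[DocumentResult], FunnelStats]:
        annotated = [self.process_unit(mu) for mu in tables.meaning_units]
        indication_tags = (
            tag_document_indications(tables, self.query, max_gap=self.config.max_gap)
            if self.query.indications
            else {}
        )

        def funnel_stage(name: str, units: list[AnnotatedUnit]) -> FunnelStage:
            return FunnelStage(
                stage=name,
                n_docs=len({u.mu.doc_id for u in units}),
                n_mu=len(units),
            )

        gated = [u for u in annotated if u.drug_matches]
        rel = [
            u for u in gated
            if u.relationship is not None
            and (u.relationship.score >= self.config.relationship_threshold or u.regex_ae)
        ]
        ents = [
            u for u in rel
            if any(e.entity_type is EntityType.DRUG for e in u.entities)
            and any(e.entity_type is EntityType.AE for e in u.entities)
        ]
        hits = [u for u in annotated if u.is_hit]
        funnel = FunnelStats(stages=[
            FunnelStage(stage="collected",
                        n_docs=len(tables.documents),
                        n_mu=len(tables.meaning_units)),
            funnel_stage("drug_gate", gated),
            funnel_stage("relationship", rel),
            funnel_stage("entities", ents),
            funnel_stage("serious_hit", hits),
        ])
        funnel.assert_monotone()

        results = []
        hits_by_doc: dict[str, list[AnnotatedUnit]] = {}
        for u in hits:
            hits_by_doc.setdefault(u.mu.doc_id, []).append(u)
        for doc in tables.documents:
            doc_hits = hits_by_doc.get(doc.doc_id, [])
            results.append(
                DocumentResult(
                    doc_id=doc.doc_id,
                    hits=doc_hits,
                    indication_tags=sorted(indication_tags.get(doc.doc_id, set())),
                    rank_score=rank_score(doc_hits, self.config),
                    kept=bool(doc_hits),
                )
            )
        return results, funnel


def rank_score(hits: list[AnnotatedUnit], config: PipelineConfig) -> float:
    if not hits:
        return 0.0
    return (
        config.w_max_score * max(h.hit_score for h in hits)
        + config.w_n_hits * math.log2(1 + len(hits))
    )


def rank_documents(
    results: list[DocumentResult], config: Optional[PipelineConfig] = None
) -> list[DocumentResult]:
    """Kept documents in rank order (score descending, doc_id tie-break)."""
    del config  # scores are already attached; kept for interface symmetry
    kept = [r for r in results if r.kept]
    return sorted(kept, key=lambda r: (-r.rank_score, r.doc_id))


# Convenience wrappers matching the functional surface ----------------------

def process_unit(
    mu: MeaningUnit,
    query: Query,
    backend: ClassifierBackend,
    config: Optional[PipelineConfig] = None,
    serious_terms: Optional[list[LexiconEntry]] = None,
) -> AnnotatedUnit:
    return DecisionEngine(query, backend, config, serious_terms).process_unit(mu)


def process_corpus(
    tables: CorpusTables,
    query: Query,
    backend: ClassifierBackend,
    config: Optional[PipelineConfig] = None,
    serious_terms: Optional[list[LexiconEntry]] = None,
) -> tuple[list[DocumentResult], FunnelStats]:
    return DecisionEngine(query, backend, config, serious_terms).process_corpus(tables)
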