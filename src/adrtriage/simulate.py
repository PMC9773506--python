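"""Synthetic sectioned corpora with planted drug–AE–seriousness structure.

The generator emulates the statistical shape of a triage workload: short
biomedical sentences organised into labelled document sections, where
relevant statements (a drug, a causality cue, an adverse event and a
serious outcome in one sentence) are rare — the default planted-hit rate
is 0.2% of meaning units, matching the imbalance a drug-safety reviewer
faces — and surrounded by distractors that individually share features
with hits without satisfying the full conjunction:

* non-serious ADR statements (drug + cue + mild AE, no serious outcome),
* negated statements ("No treatment-related deaths occurred with X"),
* generic AE mentions ("TRAEs were reported ...") with or without a drug,
* serious events without any drug mention,
* neutral filler.

Sentences are template-generated, never sampled from a language model, so
every sentence has an exact gold label and the whole corpus is a pure
function of the seed.  All templates are at least 11 words long, which
keeps them above the short-sentence merge band: meaning units then map
one-to-one onto generated sentences and gold labels can be keyed directly
by meaning-unit id.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .classify import _load_lines, default_serious_terms
from .corpus import ContentSection, CorpusTables, Document, SectionLabel
from .evaluate import GoldLabel
from .lexsearch import LexiconEntry, Query
from .preprocess import build_meaning_units

_CONTENT_LABELS = [
    SectionLabel.ABSTRACT, SectionLabel.INTRO, SectionLabel.METHODS,
    SectionLabel.RESULTS, SectionLabel.DISCUSS, SectionLabel.CASE,
    SectionLabel.CONCL,
]

_MILD_AES = ["rash", "nausea", "headache", "fatigue", "dizziness", "pruritus"]
_SERIOUS_AES = [
    "myositis", "pneumonia", "ventricular fibrillation", "intracranial bleeding",
    "agranulocytosis", "rhabdomyolysis", "sepsis", "respiratory failure",
]


class GeneratorConfig(BaseModel):
    n_docs: int = Field(default=100, gt=0)
    sections_per_doc: int = Field(default=3, gt=0)
    sentences_per_section: tuple[int, int] = (3, 8)
    hit_rate: float = Field(default=0.002, ge=0.0, le=1.0)
    nonserious_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    negated_rate: float = Field(default=0.005, ge=0.0, le=1.0)
    generic_ae_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    serious_no_drug_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    drugs: list[str] = Field(default_factory=lambda: _load_lines("drugs.txt"))
    mild_aes: list[str] = Field(default_factory=lambda: list(_MILD_AES))
    serious_aes: list[str] = Field(default_factory=lambda: list(_SERIOUS_AES))
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        total = (self.hit_rate + self.nonserious_rate + self.negated_rate
                 + self.generic_ae_rate + self.serious_no_drug_rate)
        if total > 1.0:
            raise ValueError("template rates sum above 1")
        if not self.drugs or not self.mild_aes or not self.serious_aes:
            raise ValueError("vocabularies must be non-empty")
        lo, hi = self.sentences_per_section
        if lo <= 0 or hi < lo:
            raise ValueError("bad sentences_per_section range")
        return self


class PlantedSentence(BaseModel):
    doc_id: str
    section_position: int
    sentence_index: int
    template: str
    is_hit: bool


class GoldCorpus(BaseModel):
    tables: CorpusTables
    gold_units: list[GoldLabel]
    gold_docs: dict[str, bool]
    manifest: list[PlantedSentence]
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Sentence templates (all >= 11 words: no unit merging, exact gold mapping)
# ---------------------------------------------------------------------------

def _hit_sentence(rng: random.Random, drug: str, sae: str) -> str:
    forms = [
        f"There was one treatment-related death due to {sae} in the {drug} group.",
        f"{drug.capitalize()}-induced {sae} resulting in death was reported in two patients during follow-up.",
        f"Fatal {sae} attributed to {drug} required prolonged hospitalization of three patients overall.",
    ]
    return rng.choice(forms)


def _nonserious_sentence(rng: random.Random, drug: str, mild: str) -> str:
    forms = [
        f"We observed {drug}-associated {mild} in a minority of the enrolled patients.",
        f"Mild {mild} due to {drug} resolved without intervention in most of the patients.",
    ]
    return rng.choice(forms)


def _negated_sentence(rng: random.Random, drug: str) -> str:
    forms = [
        f"No treatment-related deaths occurred among patients receiving {drug} during the entire study period.",
        f"Importantly, no drug-related hospitalizations were recorded in the {drug} arm over two years.",
    ]
    return rng.choice(forms)


def _generic_ae_sentence(rng: random.Random, drug: str) -> str:
    forms = [
        "Grade 1 TRAEs were recorded in both arms throughout the whole study period.",
        f"TRAEs of any grade were reported among patients receiving {drug} during treatment.",
        f"Adverse events of mild intensity were collected for all patients on {drug} therapy.",
    ]
    return rng.choice(forms)


def _serious_no_drug_sentence(rng: random.Random, sae: str) -> str:
    forms = [
        f"Severe {sae} requiring hospitalization was observed in several patients of the control arm.",
        f"Two patients in the placebo group died of {sae} during the follow-up period.",
    ]
    return rng.choice(forms)


def _filler_sentence(rng: random.Random) -> str:
    forms = [
        f"The study enrolled {rng.randint(40, 900)} patients across {rng.randint(3, 40)} centers between 2014 and 2020.",
        "Baseline characteristics were well balanced between the two study arms at entry.",
        f"Median follow-up for the whole cohort was {rng.randint(6, 60)} months at the time of this analysis.",
        "The primary endpoint was progression-free survival assessed by an independent central review committee.",
        f"Patients received the study medication every {rng.randint(2, 6)} weeks until progression or unacceptable toxicity occurred.",
        "Secondary endpoints included overall survival, objective response rate and quality of life measures.",
    ]
    return rng.choice(forms)


def _draw_sentence(rng: random.Random, cfg: GeneratorConfig) -> tuple[str, str, bool]:
    """Return (template name, sentence text, is gold hit)."""
    r = rng.random()
    drug = rng.choice(cfg.drugs)
    if r < cfg.hit_rate:
        return "hit", _hit_sentence(rng, drug, rng.choice(cfg.serious_aes)), True
    r -= cfg.hit_rate
    if r < cfg.nonserious_rate:
        return "nonserious_adr", _nonserious_sentence(rng, drug, rng.choice(cfg.mild_aes)), False
    r -= cfg.nonserious_rate
    if r < cfg.negated_rate:
        return "negated", _negated_sentence(rng, drug), False
    r -= cfg.negated_rate
    if r < cfg.generic_ae_rate:
        return "generic_ae", _generic_ae_sentence(rng, drug), False
    r -= cfg.generic_ae_rate
    if r < cfg.serious_no_drug_rate:
        return "serious_no_drug", _serious_no_drug_sentence(rng, rng.choice(cfg.serious_aes)), False
    return "filler", _filler_sentence(rng), False


def generate_corpus(config: Optional[GeneratorConfig] = None, **kwargs) -> GoldCorpus:
    """Generate a sectioned corpus with gold labels; pure function of the seed."""
    cfg = config or GeneratorConfig(**kwargs)
    rng = random.Random(cfg.seed)
    docs: list[Document] = []
    manifest: list[PlantedSentence] = []
    for d in range(cfg.n_docs):
        doc_id = f"SYN{d:05d}"
        sections: list[ContentSection] = []
        title = (
            f"A randomized phase {rng.randint(1, 3)} study of combination therapy "
            f"in {rng.randint(40, 900)} patients with advanced disease."
        )
        sections.append(ContentSection(
            doc_id=doc_id, section_label=SectionLabel.TITLE, position=0, text=title,
        ))
        manifest.append(PlantedSentence(
            doc_id=doc_id, section_position=0, sentence_index=0,
            template="title", is_hit=False,
        ))
        for s in range(cfg.sections_per_doc):
            label = _CONTENT_LABELS[s % len(_CONTENT_LABELS)]
            n_sent = rng.randint(*cfg.sentences_per_section)
            sentences = []
            for idx in range(n_sent):
                template, text, is_hit = _draw_sentence(rng, cfg)
                sentences.append(text)
                manifest.append(PlantedSentence(
                    doc_id=doc_id, section_position=s + 1, sentence_index=idx,
                    template=template, is_hit=is_hit,
                ))
            sections.append(ContentSection(
                doc_id=doc_id, section_label=label, position=s + 1,
                text=" ".join(sentences),
            ))
        docs.append(Document(
            doc_id=doc_id,
            title=title,
            journal="Synthetic Journal of Pharmacovigilance",
            pub_types=["Journal Article"],
            sections=sections,
        ))

    tables = build_meaning_units(CorpusTables(documents=docs))

    # templates are all above the merge band, so units == sentences
    by_slot = {(p.doc_id, p.section_position, p.sentence_index): p for p in manifest}
    gold_units: list[GoldLabel] = []
    gold_docs: dict[str, bool] = {doc.doc_id: False for doc in docs}
    n_units_per_section: dict[tuple[str, int], int] = {}
    for mu in tables.meaning_units:
        idx = n_units_per_section.get((mu.doc_id, mu.section_position), 0)
        n_units_per_section[(mu.doc_id, mu.section_position)] = idx + 1
        planted = by_slot[(mu.doc_id, mu.section_position, idx)]
        gold_units.append(GoldLabel(
            mu_id=mu.mu_id, is_hit_gold=planted.is_hit,
            doc_id=mu.doc_id, section_label=mu.section_label.value,
        ))
        if planted.is_hit:
            gold_docs[mu.doc_id] = True
    n_sentences = len(manifest)
    if len(tables.meaning_units) != n_sentences:
        raise AssertionError(
            "template sentences merged unexpectedly; gold alignment broken"
        )
    return GoldCorpus(
        tables=tables, gold_units=gold_units, gold_docs=gold_docs,
        manifest=manifest, config=cfg,
    )


def make_query_for_corpus(gold: GoldCorpus) -> Query:
    """Query whose drug lexicon equals the generator's drug vocabulary."""
    drugs = gold.config.drugs
    if not drugs:
        raise ValueError("generator has an empty drug vocabulary")
    return Query(
        main_drug=LexiconEntry(canonical=drugs[0], synonyms=list(drugs[1:]))
    )


def write_gold_corpus(gold: GoldCorpus, out_dir: str | Path) -> dict[str, str]:
    """Write fixture JSONL, gold sidecars and the planting manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    corpus_path = out / "corpus.jsonl"
    with corpus_path.open("w", encoding="utf-8") as fh:
        for doc in gold.tables.documents:
            rec = {
                "doc_id": doc.doc_id,
                "title": doc.title,
                "journal": doc.journal,
                "pub_date": doc.pub_date.isoformat() if doc.pub_date else None,
                "pub_types": doc.pub_types,
                "sections": [
                    {"label": s.section_label.value, "text": s.text}
                    for s in doc.sections
                ],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    paths["corpus"] = str(corpus_path)
    gold_units_path = out / "gold_units.jsonl"
    with gold_units_path.open("w", encoding="utf-8") as fh:
        for g in gold.gold_units:
            fh.write(json.dumps(g.model_dump(), sort_keys=True) + "\n")
    paths["gold_units"] = str(gold_units_path)
    gold_docs_path = out / "gold_docs.jsonl"
    with gold_docs_path.open("w", encoding="utf-8") as fh:
        for doc_id in sorted(gold.gold_docs):
            fh.write(json.dumps(
                {"doc_id": doc_id, "is_relevant": gold.gold_docs[doc_id]},
                sort_keys=True) + "\n")
    paths["gold_docs"] = str(gold_docs_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(
        {
            "config": gold.config.model_dump(),
            "n_documents": len(gold.tables.documents),
            "n_meaning_units": len(gold.tables.meaning_units),
            "n_gold_hits": sum(g.is_hit_gold for g in gold.gold_units),
            "sentences": [p.model_dump() for p in gold.manifest],
        },
        indent=2, sort_keys=True), encoding="utf-8")
    paths["manifest"] = str(manifest_path)
    return paths


def write_query_tsv(query: Query, path: str | Path) -> None:
    """Write a query as the lexicon TSV format."""
    lines = ["role\tcanonical\tsynonym\toutcome_category"]
    def entry_rows(role: str, entry: LexiconEntry) -> list[str]:
        if not entry.synonyms:
            return [f"{role}\t{entry.canonical}\t\t"]
        return [f"{role}\t{entry.canonical}\t{syn}\t" for syn in entry.synonyms]
    lines += entry_rows("main_drug", query.main_drug)
    if query.second_drug:
        lines += entry_rows("second_drug", query.second_drug)
    for ind in query.indications:
        lines += entry_rows("indication", ind)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
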