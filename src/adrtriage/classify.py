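"""Three-task sentence classification: relationship, NER, seriousness.

The pipeline needs three independent judgements about a meaning unit:

1. *relationship* — does the sentence state an established drug–event
   causality relationship? (binary, with a score in [0, 1])
2. *entities* — which spans name a DRUG or an AE?
3. *seriousness* — does the stated event meet the regulatory seriousness
   definition (death, life-threatening, hospitalisation, disability,
   congenital anomaly), is it an important medical event, or neither?

Backends are pluggable.  The shipped backend is a deterministic
rule/lexicon system driven by editable cue lists: causality suffix and
phrase cues with negation guards for task 1, query/vocabulary dictionary
matching for task 2, and outcome-cue plus always-serious-term lookup for
task 3.  It emits hard scores (1.0 on a cue hit, 0.0 otherwise), which is
all the thresholded decision logic downstream requires, and it is pure:
identical text yields identical output on every run and platform.

A transformer adapter satisfying the same contract can be registered for
production-scale runs; it is intentionally not exercised by the test
suite (no model weights ship with the package).  Fine-tuning metadata for
such backends (learning rate, optimizer, batch size, split ratios, base
checkpoint per task) is captured in :class:`FineTuneConfig`.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Protocol

from pydantic import BaseModel, Field, model_validator

from .lexsearch import ExactMatcher, LexiconEntry, Query, load_serious_terms, normalize_term, lower_preserve


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

class RelationshipLabel(str, Enum):
    HAS_CAUSALITY = "has_causality"
    HAS_NO_CAUSALITY = "has_no_causality"


class RelationshipResult(BaseModel):
    label: RelationshipLabel
    score: float = Field(ge=0.0, le=1.0)


class EntityType(str, Enum):
    DRUG = "DRUG"
    AE = "AE"


class EntitySpan(BaseModel):
    entity_type: EntityType
    char_start: int = Field(ge=0)
    char_end: int
    score: float = Field(ge=0.0, le=1.0)
    source: str = "model"  # model | regex


class SeriousnessLabel(str, Enum):
    SERIOUS = "serious"
    IMPORTANT_MEDICAL_EVENT = "important_medical_event"
    NONE = "none"


class SeriousnessResult(BaseModel):
    label: SeriousnessLabel
    score: float = Field(ge=0.0, le=1.0)


class FineTuneConfig(BaseModel):
    learning_rate: float
    optimizer: str
    batch_size: int
    split_ratio: tuple[float, float, float]
    base_model: str

    @model_validator(mode="after")
    def _split_sums_to_one(self):
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        return self


class ClassifierBackend(Protocol):
    """Contract every classification backend must satisfy."""

    def classify_relationship(self, text: str) -> RelationshipResult: ...

    def extract_entities(self, text: str) -> list[EntitySpan]: ...

    def classify_seriousness(self, text: str) -> SeriousnessResult: ...


# ---------------------------------------------------------------------------
# Cue-list loading
# ---------------------------------------------------------------------------

def _load_lines(name: str, path: Optional[str | Path] = None) -> list[str]:
    if path is None:
        text = resources.files("adrtriage.data").joinpath(name).read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def default_serious_terms() -> list[LexiconEntry]:
    with resources.as_file(
        resources.files("adrtriage.data").joinpath("serious_terms.tsv")
    ) as p:
        return load_serious_terms(p)


# ---------------------------------------------------------------------------
# Rule-based baseline backend
# ---------------------------------------------------------------------------

def _phrase_present(phrase: str, lowered: str, original: str) -> bool:
    """Word-boundary occurrence check for a normalized phrase."""
    start = 0
    while True:
        idx = lowered.find(phrase, start)
        if idx < 0:
            return False
        end = idx + len(phrase)
        before_ok = idx == 0 or not original[idx - 1].isalnum()
        after_ok = end == len(original) or not original[end].isalnum()
        if before_ok and after_ok:
            return True
        start = idx + 1


def _suffix_cue_present(cue: str, lowered: str) -> bool:
    """A cue like ``-induced`` must be attached to a preceding word."""
    start = 0
    while True:
        idx = lowered.find(cue, start)
        if idx < 0:
            return False
        end = idx + len(cue)
        attached = idx > 0 and lowered[idx - 1].isalnum()
        after_ok = end == len(lowered) or not lowered[end].isalnum()
        if attached and after_ok:
            return True
        start = idx + 1


class RuleBasedBackend:
    """Deterministic cue/lexicon backend.

    Parameters
    ----------
    drug_surfaces:
        Mapping normalized drug surface form -> canonical name (usually the
        query's drug lexicon), used for DRUG spans.
    ae_terms:
        Specific adverse-event vocabulary for AE spans.
    causality_cues:
        Phrases (or ``-suffix`` cues) stating a drug-event relationship.
    negation_guards:
        Phrases that veto a causality cue in the same unit.
    serious_outcome_cues:
        Outcome phrases of the regulatory seriousness categories.
    serious_terms:
        Always-serious term entries (the rescue lexicon); they also count
        as AE vocabulary and as seriousness evidence.
    """

    name = "baseline"

    def __init__(
        self,
        drug_surfaces: dict[str, str],
        ae_terms: Iterable[str],
        causality_cues: Iterable[str],
        negation_guards: Iterable[str],
        serious_outcome_cues: Iterable[str],
        serious_terms: Iterable[LexiconEntry] = (),
    ):
        serious_terms = list(serious_terms)
        self._drug_matcher = ExactMatcher(drug_surfaces) if drug_surfaces else None
        ae_vocab = {normalize_term(t): t for t in ae_terms}
        for entry in serious_terms:
            for s in entry.surfaces:
                ae_vocab.setdefault(s, entry.canonical)
        self._ae_matcher = ExactMatcher(ae_vocab) if ae_vocab else None
        self._ae_vocab = set(ae_vocab)
        self._suffix_cues = [normalize_term(c) for c in causality_cues if c.startswith("-")]
        self._phrase_cues = [normalize_term(c) for c in causality_cues if not c.startswith("-")]
        self._negation_guards = [normalize_term(g) for g in negation_guards]
        self._serious_cues = [normalize_term(c) for c in serious_outcome_cues]
        serious_surfaces = {s for e in serious_terms for s in e.surfaces}
        self._serious_term_matcher = (
            ExactMatcher(serious_surfaces) if serious_surfaces else None
        )

    @classmethod
    def default(cls, query: Optional[Query] = None, **overrides) -> "RuleBasedBackend":
        """Backend wired from the packaged cue lists.

        DRUG spans come from the query lexicon when one is given, else
        from the packaged default drug vocabulary.
        """
        if query is not None:
            drug_surfaces = query.drug_surfaces
        else:
            drug_surfaces = {normalize_term(d): d for d in _load_lines("drugs.txt")}
        kwargs = dict(
            drug_surfaces=drug_surfaces,
            ae_terms=_load_lines("ae_terms.txt"),
            causality_cues=_load_lines("causality_cues.txt"),
            negation_guards=_load_lines("negation_guards.txt"),
            serious_outcome_cues=_load_lines("serious_outcome_cues.txt"),
            serious_terms=default_serious_terms(),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    # -- task 1 -------------------------------------------------------------
    def classify_relationship(self, text: str) -> RelationshipResult:
        lowered = lower_preserve(text)
        for guard in self._negation_guards:
            if _phrase_present(guard, lowered, text):
                return RelationshipResult(
                    label=RelationshipLabel.HAS_NO_CAUSALITY, score=0.0
                )
        cue_hit = any(_suffix_cue_present(c, lowered) for c in self._suffix_cues) or any(
            _phrase_present(c, lowered, text) for c in self._phrase_cues
        )
        if cue_hit:
            return RelationshipResult(label=RelationshipLabel.HAS_CAUSALITY, score=1.0)
        return RelationshipResult(label=RelationshipLabel.HAS_NO_CAUSALITY, score=0.0)

    # -- task 2 -------------------------------------------------------------
    def extract_entities(self, text: str) -> list[EntitySpan]:
        spans: list[EntitySpan] = []
        if self._drug_matcher is not None:
            for m in self._drug_matcher.find(text):
                spans.append(
                    EntitySpan(entity_type=EntityType.DRUG, char_start=m.char_start,
                               char_end=m.char_end, score=1.0, source="model")
                )
        if self._ae_matcher is not None:
            for m in self._ae_matcher.find(text):
                spans.append(
                    EntitySpan(entity_type=EntityType.AE, char_start=m.char_start,
                               char_end=m.char_end, score=1.0, source="model")
                )
        return _drop_nested_same_type(spans)

    # -- task 3 -------------------------------------------------------------
    def classify_seriousness(self, text: str) -> SeriousnessResult:
        lowered = lower_preserve(text)
        serious = any(_phrase_present(c, lowered, text) for c in self._serious_cues)
        if not serious and self._serious_term_matcher is not None:
            serious = bool(self._serious_term_matcher.find(text))
        if serious:
            return SeriousnessResult(label=SeriousnessLabel.SERIOUS, score=1.0)
        adr_evidence = (self._ae_matcher is not None and bool(self._ae_matcher.find(text))) or any(
            _suffix_cue_present(c, lowered) for c in self._suffix_cues
        ) or any(_phrase_present(c, lowered, text) for c in self._phrase_cues)
        if adr_evidence:
            return SeriousnessResult(
                label=SeriousnessLabel.IMPORTANT_MEDICAL_EVENT, score=1.0
            )
        return SeriousnessResult(label=SeriousnessLabel.NONE, score=1.0)


def _drop_nested_same_type(spans: list[EntitySpan]) -> list[EntitySpan]:
    """Resolve overlapping spans of one entity type by keeping the longest."""
    out: list[EntitySpan] = []
    for etype in EntityType:
        typed = sorted(
            (s for s in spans if s.entity_type is etype),
            key=lambda s: (-(s.char_end - s.char_start), s.char_start),
        )
        kept: list[EntitySpan] = []
        for span in typed:
            if all(span.char_end <= k.char_start or span.char_start >= k.char_end
                   for k in kept):
                kept.append(span)
        out.extend(sorted(kept, key=lambda s: s.char_start))
    return out


# ---------------------------------------------------------------------------
# Contract-level convenience functions
# ---------------------------------------------------------------------------

def classify_relationship(backend: ClassifierBackend, text: str) -> RelationshipResult:
    if not text.strip():
        raise ValueError("empty text")
    return backend.classify_relationship(text)


def extract_entities(
    backend: ClassifierBackend, text: str, span_threshold: float = 0.5
) -> list[EntitySpan]:
    """Entities from the backend with sub-threshold spans dropped.

    Threshold comparison is inclusive (>=).
    """
    if not text.strip():
        raise ValueError("empty text")
    return [s for s in backend.extract_entities(text) if s.score >= span_threshold]


def classify_seriousness(backend: ClassifierBackend, text: str) -> SeriousnessResult:
    if not text.strip():
        raise ValueError("empty text")
    return backend.classify_seriousness(text)


# ---------------------------------------------------------------------------
# Fine-tuning metadata and backend registry
# ---------------------------------------------------------------------------

_BASE_MODELS = {
    "relationship": "UMLSBert_ENG",
    "ner": "BiomedNLP-PubMedBERT-base-uncased-abstract-fulltext",
    "seriousness": "BiomedNLP-PubMedBERT-base-uncased-abstract-fulltext",
}


def make_finetune_config(task: str) -> FineTuneConfig:
    """Default fine-tuning configuration for a transformer backend task.

    Learning rate 3e-5 with Adam, batch size 16, and an 8:1:1
    train/valid/test split; the base checkpoint is UMLS-pretrained for the
    relationship task and PubMed-pretrained for NER and seriousness.
    """
    if task not in _BASE_MODELS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(_BASE_MODELS)}")
    return FineTuneConfig(
        learning_rate=3e-5,
        optimizer="Adam",
        batch_size=16,
        split_ratio=(0.8, 0.1, 0.1),
        base_model=_BASE_MODELS[task],
    )


class TransformerBackend:
    """Adapter stub for transformer checkpoints satisfying the contract.

    Instantiating it requires the optional ``transformers`` dependency and
    local fine-tuned checkpoints; the rule-based backend is the supported
    default for offline use.
    """

    name = "transformer"

    def __init__(self, model_dir: str):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError(
                "the transformer backend requires the 'transformers' package"
            ) from exc
        raise NotImplementedError(
            "wire fine-tuned checkpoints here; see make_finetune_config()"
        )


def get_backend(name: str, query: Optional[Query] = None, **kwargs) -> ClassifierBackend:
    if name == "baseline":
        return RuleBasedBackend.default(query=query, **kwargs)
    if name == "transformer":
        return TransformerBackend(**kwargs)
    raise ValueError(f"unknown backend {name!r}")
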