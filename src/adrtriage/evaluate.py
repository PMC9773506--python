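"""Evaluation against gold labels: sentence level, per section, per document.

Sentence-level evaluation is ordinary binary precision / recall / F1 on
hit predictions aligned by meaning-unit id; the per-section breakdown
reports one row per observed section label plus an overall row whose
volume equals the sum of the section volumes.  At document level only
precision (fraction of kept documents that are gold-relevant) is
computed: recall over the literature at large cannot be estimated
without an unbiased sample of relevant documents, so none is reported.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field
from sklearn.metrics import precision_recall_fscore_support

from .decision import AnnotatedUnit, DocumentResult


class GoldLabel(BaseModel):
    mu_id: str
    is_hit_gold: bool
    doc_id: str
    section_label: str


class MetricsRow(BaseModel):
    scope: str
    precision: float = Field(ge=0.0, le=1.0)
    recall: float = Field(ge=0.0, le=1.0)
    f1: float = Field(ge=0.0, le=1.0)
    volume: int = Field(ge=0)
    tp: int = 0
    fp: int = 0
    fn: int = 0


Predictions = Union[Sequence[AnnotatedUnit], Mapping[str, bool]]


def _prediction_map(predicted: Predictions) -> dict[str, bool]:
    if isinstance(predicted, Mapping):
        return dict(predicted)
    return {u.mu.mu_id: u.is_hit for u in predicted}


def _section_map(predicted: Predictions) -> dict[str, str]:
    if isinstance(predicted, Mapping):
        return {}
    return {u.mu.mu_id: u.mu.section_label.value for u in predicted}


def _metrics(y_true: list[bool], y_pred: list[bool], scope: str) -> MetricsRow:
    tp = sum(t and p for t, p in zip(y_true, y_pred))
    fp = sum((not t) and p for t, p in zip(y_true, y_pred))
    fn = sum(t and (not p) for t, p in zip(y_true, y_pred))
    if (tp + fp == 0) or (tp + fn == 0):
        warnings.warn(f"zero denominator in metrics for scope {scope!r}", stacklevel=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0,
        )
    return MetricsRow(
        scope=scope, precision=float(precision), recall=float(recall),
        f1=float(f1), volume=len(y_true), tp=tp, fp=fp, fn=fn,
    )


def _aligned_vectors(
    gold: Sequence[GoldLabel], predicted: Predictions
) -> tuple[list[str], list[bool], list[bool], dict[str, str]]:
    pred_map = _prediction_map(predicted)
    sec_map = _section_map(predicted)
    ids = [g.mu_id for g in gold]
    known = set(ids)
    sections = {g.mu_id: g.section_label for g in gold}
    # predicted positives outside the gold set still count as false positives
    extras = sorted(m for m, hit in pred_map.items() if hit and m not in known)
    for m in extras:
        ids.append(m)
        sections[m] = sec_map.get(m, "OTHER")
    truth = {g.mu_id: g.is_hit_gold for g in gold}
    y_true = [truth.get(m, False) for m in ids]
    y_pred = [pred_map.get(m, False) for m in ids]
    return ids, y_true, y_pred, sections


def sentence_metrics(gold: Sequence[GoldLabel], predicted: Predictions) -> MetricsRow:
    """Overall precision / recall / F1 of hit prediction at sentence level.

    Units absent from the predictions are counted as predicted-negative;
    predicted hits absent from the gold set count as false positives.
    """
    _, y_true, y_pred, _ = _aligned_vectors(gold, predicted)
    return _metrics(y_true, y_pred, "overall")


def section_breakdown(
    gold: Sequence[GoldLabel], predicted: Predictions
) -> list[MetricsRow]:
    """One metrics row per observed section label plus the overall row."""
    ids, y_true, y_pred, sections = _aligned_vectors(gold, predicted)
    rows = [_metrics(y_true, y_pred, "overall")]
    for label in sorted({sections[m] for m in ids}):
        idx = [i for i, m in enumerate(ids) if sections[m] == label]
        rows.append(
            _metrics([y_true[i] for i in idx], [y_pred[i] for i in idx], label)
        )
    return rows


def document_precision(
    gold_docs: Mapping[str, bool], results: Sequence[DocumentResult]
) -> float:
    """Fraction of kept documents that are gold-relevant."""
    kept = [r for r in results if r.kept]
    if not kept:
        warnings.warn("no documents kept; document precision undefined, returning 0")
        return 0.0
    relevant = sum(bool(gold_docs.get(r.doc_id, False)) for r in kept)
    return relevant / len(kept)


# ---------------------------------------------------------------------------
# Gold JSONL sidecar and report writing
# ---------------------------------------------------------------------------

def read_gold_units(path: str | Path) -> list[GoldLabel]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(GoldLabel(**json.loads(line)))
    return out


def read_gold_docs(path: str | Path) -> dict[str, bool]:
    out: dict[str, bool] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out[str(rec["doc_id"])] = bool(rec["is_relevant"])
    return out


def metrics_frame(rows: Iterable[MetricsRow]) -> pd.DataFrame:
    """Tabular metrics layout: Section, Recall, Precision, F1-score, Volume."""
    return pd.DataFrame(
        [
            {
                "Section": r.scope,
                "Recall": round(r.recall, 4),
                "Precision": round(r.precision, 4),
                "F1-score": round(r.f1, 4),
                "Volume": r.volume,
            }
            for r in rows
        ]
    )


def write_metrics(
    rows: Sequence[MetricsRow],
    out_dir: str | Path,
    doc_precision: Optional[float] = None,
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "sentence": [r.model_dump() for r in rows],
        "document_precision": doc_precision,
    }
    (out / "metrics.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    metrics_frame(rows).to_csv(out / "metrics.csv", index=False)
    return {"metrics.json": str(out / "metrics.json"),
            "metrics.csv": str(out / "metrics.csv")}
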