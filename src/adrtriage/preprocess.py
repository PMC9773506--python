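"""Sentence splitting and meaning-unit construction.

Meaning units are the atomic text units the downstream classifiers see.
Sections are split into sentences with a rule-based splitter tuned for
biomedical prose (protected abbreviations such as ``i.v.`` or ``Fig.``,
no breaks inside decimal numbers), then short sentences are concatenated
with a neighbouring sentence: a sentence of at most ``short_max`` words is
merged with the previous unit when that unit currently has fewer than
``neighbor_max`` words, otherwise with the next sentence when that
sentence has fewer than ``neighbor_max`` words.  The pass is a single
left-to-right sweep and each short sentence is merged at most once, so
the result is a partition of the sentence sequence into consecutive
groups.  The motivation is that a very short sentence rarely carries a
full drug–event statement on its own; its context usually sits next door.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import CorpusTables, MeaningUnit


@dataclass(frozen=True)
class SentenceSpan:
    """Half-open character span of one sentence within a section text."""

    char_start: int
    char_end: int
    word_count: int


def load_protected_abbreviations(path: Optional[str | Path] = None) -> frozenset[str]:
    """Load the protected-abbreviation list (one entry per line, # comments)."""
    if path is None:
        text = resources.files("adrtriage.data").joinpath(
            "protected_abbreviations.txt").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    entries = {
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }
    return frozenset(entries)


# Candidate break: terminal punctuation, optional closing quotes/brackets,
# then whitespace.  Decimal points never match (no whitespace after them).
_BREAK = re.compile(r'[.!?]+["\')\]]*(?=\s)')
_INITIAL = re.compile(r"^[A-Z]\.$")


def split_sentences(
    text: str, protected: Optional[Iterable[str]] = None
) -> list[SentenceSpan]:
    """Split a section text into ordered, non-overlapping sentence spans.

    Spans exclude leading/trailing whitespace; every non-whitespace
    character of ``text`` falls in exactly one span.  Empty or blank text
    yields an empty list.
    """
    if not text.strip():
        return []
    protected_set = (
        frozenset(p.casefold() for p in protected)
        if protected is not None
        else load_protected_abbreviations()
    )
    breaks: list[int] = []
    for m in _BREAK.finditer(text):
        prefix = text[: m.end()]
        last_token = prefix.split()[-1]
        # strip leading quotes/brackets so ("e.g." is recognised
        token_core = last_token.lstrip("\"'([{")
        if token_core.casefold() in protected_set:
            continue
        if _INITIAL.match(token_core):
            continue  # personal-name initial, e.g. "J. Smith"
        breaks.append(m.end())
    segments: list[tuple[int, int]] = []
    start = 0
    for b in breaks:
        segments.append((start, b))
        start = b
    segments.append((start, len(text)))

    spans: list[SentenceSpan] = []
    for seg_start, seg_end in segments:
        chunk = text[seg_start:seg_end]
        stripped = chunk.strip()
        if not stripped:
            continue
        lead = len(chunk) - len(chunk.lstrip())
        s = seg_start + lead
        e = s + len(stripped)
        spans.append(SentenceSpan(s, e, word_count=len(stripped.split())))
    return spans


def merge_short_units(
    spans: Sequence[SentenceSpan],
    short_min: int = 4,
    short_max: int = 10,
    neighbor_max: int = 20,
) -> list[list[SentenceSpan]]:
    """Group sentences so short ones share a unit with a neighbour.

    A sentence is *short* when its word count is at most ``short_max``;
    sentences below ``short_min`` (fragments, headings) are treated as
    short too, since they carry the same missing-context risk.  Merging
    prefers the previous unit (eligible while its accumulated word count
    is below ``neighbor_max``) and otherwise takes the next sentence when
    that sentence has fewer than ``neighbor_max`` words.  Single
    left-to-right pass; one merge per short sentence; no cascading.

    Returns the partition as a list of consecutive groups.
    """
    del short_min  # retained as a documented knob; anything <= short_max is short
    groups: list[list[SentenceSpan]] = []
    group_words: list[int] = []  # accumulated word count per group
    i = 0
    n = len(spans)
    while i < n:
        span = spans[i]
        if span.word_count > short_max:
            groups.append([span])
            group_words.append(span.word_count)
            i += 1
            continue
        # short sentence: previous unit first, then next sentence
        if groups and group_words[-1] < neighbor_max:
            groups[-1].append(span)
            group_words[-1] += span.word_count
            i += 1
        elif i + 1 < n and spans[i + 1].word_count < neighbor_max:
            nxt = spans[i + 1]
            groups.append([span, nxt])
            group_words.append(span.word_count + nxt.word_count)
            i += 2
        else:
            groups.append([span])
            group_words.append(span.word_count)
            i += 1
    return groups


def build_meaning_units(
    tables: CorpusTables,
    short_min: int = 4,
    short_max: int = 10,
    neighbor_max: int = 20,
    protected: Optional[Iterable[str]] = None,
) -> CorpusTables:
    """Populate ``meaning_units`` for every section of the corpus.

    Unit identifiers are deterministic: ``{doc_id}:{section_position}:{index}``.
    Empty sections produce no units.
    """
    if protected is None:
        protected = load_protected_abbreviations()
    units: list[MeaningUnit] = []
    for doc in tables.documents:
        for sec in doc.sections:
            sentence_spans = split_sentences(sec.text, protected)
            groups = merge_short_units(
                sentence_spans, short_min=short_min,
                short_max=short_max, neighbor_max=neighbor_max,
            )
            for idx, group in enumerate(groups):
                start = group[0].char_start
                end = group[-1].char_end
                unit_text = sec.text[start:end]
                units.append(
                    MeaningUnit(
                        mu_id=f"{doc.doc_id}:{sec.position}:{idx}",
                        doc_id=doc.doc_id,
                        section_label=sec.section_label,
                        section_position=sec.position,
                        char_start=start,
                        char_end=end,
                        text=unit_text,
                        word_count=len(unit_text.split()),
                    )
                )
    return CorpusTables(documents=tables.documents, meaning_units=units)
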