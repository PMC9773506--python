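"""Lexicon loading and lexical search.

Drug names have an essentially invariant spelling in the literature, so
drug (and synonym) search is exact multi-pattern matching with an
Aho–Corasick automaton, restricted to word boundaries and case-insensitive.

Indication terms are multi-token and surface in permuted or truncated
forms ("B-cell chronic lymphocytic leukaemia" appearing as "lymphocytic
leukaemia of B-cell").  They are therefore matched with a fuzzy scheme:
a root term is expanded into every ordered permutation of every token
subset of size >= 2 (deterministic, deduplicated), and an expression
matches when its tokens occur in order, each on word boundaries, with at
most ``max_gap`` characters between the end of one token and the start
of the next.

The same fuzzy machinery serves the always-serious term rescue in the
decision engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, Field

DEFAULT_STOP_TOKENS = frozenset({"of", "the", "and", "in"})


# ---------------------------------------------------------------------------
# Text helpers
# ---------------------------------------------------------------------------

def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(term.split()).casefold()


def lower_preserve(text: str) -> str:
    """Lower-case while preserving string length (offset-safe)."""
    lowered = text.lower()
    if len(lowered) == len(text):
        return lowered
    return "".join(c.lower()[0] if c.lower() else c for c in text)


def _is_boundary(text: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not text[start - 1].isalnum()
    after_ok = end == len(text) or not text[end].isalnum()
    return before_ok and after_ok


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class TermMatch(BaseModel):
    term_id: str
    surface: str
    char_start: int = Field(ge=0)
    char_end: int
    kind: str = "exact"  # exact | fuzzy
    outcome_category: Optional[str] = None


class LexiconEntry(BaseModel):
    canonical: str
    synonyms: list[str] = Field(default_factory=list)
    outcome_category: Optional[str] = None

    @property
    def surfaces(self) -> list[str]:
        """Deduplicated normalized surface forms, canonical first."""
        seen: dict[str, None] = {}
        for raw in [self.canonical, *self.synonyms]:
            norm = normalize_term(raw)
            if norm:
                seen.setdefault(norm)
        return list(seen)


class Query(BaseModel):
    main_drug: LexiconEntry
    second_drug: Optional[LexiconEntry] = None
    indications: list[LexiconEntry] = Field(default_factory=list)

    @property
    def drug_surfaces(self) -> dict[str, str]:
        """Mapping normalized surface form -> canonical drug name."""
        out: dict[str, str] = {}
        for entry in [self.main_drug] + ([self.second_drug] if self.second_drug else []):
            for s in entry.surfaces:
                out.setdefault(s, entry.canonical)
        return out


class FuzzyExpression(BaseModel):
    """An ordered token sequence derived from a root indication term."""

    root: str
    tokens: tuple[str, ...]


@dataclass
class LexiconLoadReport:
    n_entries: int = 0
    n_duplicate_synonyms: int = 0


# ---------------------------------------------------------------------------
# Lexicon TSV loading
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {"role", "canonical", "synonym"}


def _read_lexicon_rows(path: str | Path) -> tuple[dict[str, dict[str, LexiconEntry]], LexiconLoadReport]:
    path = Path(path)
    report = LexiconLoadReport()
    by_role: dict[str, dict[str, LexiconEntry]] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = _REQUIRED_COLUMNS - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"lexicon {path} missing columns: {sorted(missing)}")
        for row in reader:
            role = (row["role"] or "").strip()
            canonical = (row["canonical"] or "").strip()
            if not role or not canonical:
                continue
            entries = by_role.setdefault(role, {})
            key = normalize_term(canonical)
            entry = entries.get(key)
            if entry is None:
                entry = LexiconEntry(
                    canonical=canonical,
                    outcome_category=(row.get("outcome_category") or "").strip() or None,
                )
                entries[key] = entry
                report.n_entries += 1
            synonym = (row.get("synonym") or "").strip()
            if synonym:
                if normalize_term(synonym) in {normalize_term(s) for s in entry.surfaces}:
                    report.n_duplicate_synonyms += 1
                else:
                    entry.synonyms.append(synonym)
    return by_role, report


def load_query(path: str | Path) -> Query:
    """Build a Query from a lexicon TSV (roles main_drug / second_drug / indication)."""
    by_role, _ = _read_lexicon_rows(path)
    mains = list(by_role.get("main_drug", {}).values())
    if not mains:
        raise ValueError(f"lexicon {path} defines no main_drug entry")
    seconds = list(by_role.get("second_drug", {}).values())
    return Query(
        main_drug=mains[0],
        second_drug=seconds[0] if seconds else None,
        indications=list(by_role.get("indication", {}).values()),
    )


def load_serious_terms(path: str | Path) -> list[LexiconEntry]:
    """Load the always-serious outcome term list (role ``serious_term``)."""
    by_role, _ = _read_lexicon_rows(path)
    return list(by_role.get("serious_term", {}).values())


def load_lexicon(path: str | Path) -> Union[Query, list[LexiconEntry]]:
    """Load a TSV lexicon; returns a Query when drug roles are present,
    otherwise the serious-term entry list."""
    by_role, _ = _read_lexicon_rows(path)
    if "main_drug" in by_role:
        return load_query(path)
    return list(by_role.get("serious_term", {}).values())


# ---------------------------------------------------------------------------
# Aho–Corasick exact multi-pattern search
# ---------------------------------------------------------------------------

class AhoCorasick:
    """Classic Aho–Corasick automaton over code points.

    Reports every occurrence of every pattern, including overlapping
    occurrences of different patterns.
    """

    def __init__(self, patterns: Iterable[tuple[str, object]]):
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._output: list[list[tuple[int, object]]] = [[]]  # (pattern_len, payload)
        for pattern, payload in patterns:
            self._insert(pattern, payload)
        self._build_failure_links()

    def _insert(self, pattern: str, payload: object) -> None:
        if not pattern:
            raise ValueError("empty pattern")
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto[state][ch] = nxt
                self._goto.append({})
                self._fail.append(0)
                self._output.append([])
            state = nxt
        self._output[state].append((len(pattern), payload))

    def _build_failure_links(self) -> None:
        from collections import deque

        queue = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self._goto[state].items():
                queue.append(child)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._output[child] = self._output[child] + self._output[self._fail[child]]

    def iter_matches(self, text: str):
        """Yield ``(start, end, payload)`` for every pattern occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for length, payload in self._output[state]:
                yield i + 1 - length, i + 1, payload


class ExactMatcher:
    """Word-boundary, case-insensitive multi-term matcher (precompiled)."""

    def __init__(self, terms: Union[Mapping[str, str], Iterable[str]]):
        if isinstance(terms, Mapping):
            pairs = [(normalize_term(s), tid) for s, tid in terms.items()]
        else:
            pairs = [(normalize_term(s), normalize_term(s)) for s in terms]
        pairs = [(s, tid) for s, tid in pairs if s]
        if not pairs:
            raise ValueError("no non-empty terms")
        # dedupe on surface, keeping the first term_id
        seen: dict[str, str] = {}
        for s, tid in pairs:
            seen.setdefault(s, tid)
        self._automaton = AhoCorasick((s, (s, tid)) for s, tid in seen.items())

    def find(self, text: str) -> list[TermMatch]:
        lowered = lower_preserve(text)
        matches = []
        for start, end, (surface, term_id) in self._automaton.iter_matches(lowered):
            if _is_boundary(text, start, end):
                matches.append(
                    TermMatch(
                        term_id=str(term_id),
                        surface=text[start:end],
                        char_start=start,
                        char_end=end,
                        kind="exact",
                    )
                )
        matches.sort(key=lambda m: (m.char_start, m.char_end, m.term_id))
        return matches


def find_exact(
    terms: Union[Mapping[str, str], Iterable[str]], text: str
) -> list[TermMatch]:
    """All word-boundary occurrences of any term in ``text`` (case-insensitive).

    ``terms`` is either a set of surface forms or a mapping
    ``surface -> term_id``.  Overlapping matches of different terms are
    all reported.
    """
    return ExactMatcher(terms).find(text)


# ---------------------------------------------------------------------------
# Fuzzy indication matching
# ---------------------------------------------------------------------------

def tokenize_root(root: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> list[str]:
    """Whitespace tokens of a root term, minus stop tokens, case-folded."""
    return [t for t in normalize_term(root).split() if t not in stop_tokens]


def expand_indication(
    root: str,
    stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS,
    max_expand_tokens: int = 5,
) -> list[FuzzyExpression]:
    """Deterministic expansion of a root term into fuzzy expressions.

    Every ordered permutation of every token subset of size >= 2,
    deduplicated.  For roots longer than ``max_expand_tokens`` tokens only
    subsets of size >= n - 2 are enumerated to bound the output.  A
    one-token root is returned as a single exact expression.
    """
    tokens = tokenize_root(root, stop_tokens)
    if not tokens:
        return []
    if len(tokens) == 1:
        return [FuzzyExpression(root=root, tokens=(tokens[0],))]
    n = len(tokens)
    min_size = 2 if n <= max_expand_tokens else max(2, n - 2)
    seen: dict[tuple[str, ...], None] = {}
    for k in range(min_size, n + 1):
        for subset in combinations(range(n), k):
            subset_tokens = [tokens[i] for i in subset]
            for perm in permutations(subset_tokens):
                seen.setdefault(perm)
    return [FuzzyExpression(root=root, tokens=perm) for perm in seen]


def _token_occurrences(token: str, lowered: str, original: str) -> list[tuple[int, int]]:
    occs = []
    start = 0
    while True:
        idx = lowered.find(token, start)
        if idx < 0:
            break
        end = idx + len(token)
        if _is_boundary(original, idx, end):
            occs.append((idx, end))
        start = idx + 1
    return occs


def find_fuzzy(
    expressions: Sequence[FuzzyExpression],
    text: str,
    max_gap: int = 20,
) -> list[TermMatch]:
    """Match fuzzy expressions against ``text`` with bounded inter-token gaps.

    Tokens must occur in expression order, each on word boundaries, with
    between 0 and ``max_gap`` characters between the end of one token and
    the start of the next.  The reported span runs from the first token's
    start to the last token's end.  Overlapping spans of the same root are
    collapsed to the longest span.
    """
    lowered = lower_preserve(text)
    spans_by_root: dict[str, list[tuple[int, int]]] = {}
    for expr in expressions:
        occs = [_token_occurrences(tok, lowered, text) for tok in expr.tokens]
        if any(not o for o in occs):
            continue
        # chase chains: from each first-token occurrence extend greedily over
        # all admissible successor occurrences (texts are sentence-scale, so
        # exhaustive chaining stays cheap)
        chains: list[tuple[int, int]] = [(s, e) for s, e in occs[0]]
        for level in occs[1:]:
            new_chains = []
            for start, end in chains:
                for s, e in level:
                    if s >= end and s - end <= max_gap:
                        new_chains.append((start, e))
            chains = new_chains
            if not chains:
                break
        if chains:
            spans_by_root.setdefault(expr.root, []).extend(chains)

    matches: list[TermMatch] = []
    for root, spans in spans_by_root.items():
        for start, end in _collapse_to_longest(spans):
            matches.append(
                TermMatch(
                    term_id=root,
                    surface=text[start:end],
                    char_start=start,
                    char_end=end,
                    kind="fuzzy",
                )
            )
    matches.sort(key=lambda m: (m.char_start, m.char_end, m.term_id))
    return matches


def _collapse_to_longest(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Cluster overlapping spans and keep the longest span per cluster."""
    spans = sorted(set(spans))
    clusters: list[list[tuple[int, int]]] = []
    for span in spans:
        if clusters and span[0] < max(e for _, e in clusters[-1]):
            clusters[-1].append(span)
        else:
            clusters.append([span])
    return [max(cluster, key=lambda se: (se[1] - se[0], -se[0])) for cluster in clusters]


def expressions_for_entry(
    entry: LexiconEntry,
    stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS,
    max_expand_tokens: int = 5,
) -> list[FuzzyExpression]:
    """Fuzzy expressions for every surface form of a lexicon entry.

    All expressions carry the entry's canonical name as root so matches
    aggregate per entry.
    """
    exprs: dict[tuple[str, ...], FuzzyExpression] = {}
    for surface in entry.surfaces:
        for expr in expand_indication(surface, stop_tokens, max_expand_tokens):
            exprs.setdefault(
                expr.tokens, FuzzyExpression(root=entry.canonical, tokens=expr.tokens)
            )
    return list(exprs.values())


def tag_document_indications(
    tables, query: Query, max_gap: int = 20
) -> dict[str, set[str]]:
    """Tag each document with the indications found in any of its sections.

    Matching is per-section: tokens split across sections never combine.
    The tag is purely lexical; no drug–indication relationship is claimed.
    """
    expr_by_indication = {
        ind.canonical: expressions_for_entry(ind) for ind in query.indications
    }
    tags: dict[str, set[str]] = {doc.doc_id: set() for doc in tables.documents}
    for doc in tables.documents:
        for sec in doc.sections:
            for canonical, exprs in expr_by_indication.items():
                if canonical in tags[doc.doc_id]:
                    continue
                if find_fuzzy(exprs, sec.text, max_gap=max_gap):
                    tags[doc.doc_id].add(canonical)
    return tags
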