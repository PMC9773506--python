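"""Independent oracles the suite checks the implementation against.

These deliberately use the dumbest possible strategies (naive scans,
regexes, brute-force enumeration, a literal restatement of the merge
rule) and never call into the code paths they verify.
"""

from __future__ import annotations

import re
from itertools import combinations, permutations


def naive_exact_scan(terms, text: str) -> list[tuple[int, int, str]]:
    """All case-insensitive word-boundary occurrences of each term."""
    lowered = text.lower()
    out = []
    for term in terms:
        t = term.lower()
        start = 0
        while True:
            idx = lowered.find(t, start)
            if idx < 0:
                break
            end = idx + len(t)
            before = idx == 0 or not text[idx - 1].isalnum()
            after = end == len(text) or not text[end].isalnum()
            if before and after:
                out.append((idx, end, t))
            start = idx + 1
    return sorted(out)


def regex_fuzzy_present(tokens, text: str, max_gap: int = 20) -> bool:
    """Bounded-gap ordered-token match via one big regex."""
    boundary_l = r"(?<![A-Za-z0-9])"
    boundary_r = r"(?![A-Za-z0-9])"
    parts = []
    for i, tok in enumerate(tokens):
        if i:
            parts.append(".{0,%d}?" % max_gap)
        parts.append(boundary_l + re.escape(tok) + boundary_r)
    pattern = re.compile("".join(parts), re.IGNORECASE | re.DOTALL)
    return pattern.search(text) is not None


def enumerate_expansions(tokens, min_size: int = 2) -> set[tuple[str, ...]]:
    """All ordered permutations of all token subsets of size >= min_size."""
    out = set()
    for k in range(min_size, len(tokens) + 1):
        for subset in combinations(tokens, k):
            out.update(permutations(subset))
    return out


def closed_form_expansion_count(n: int) -> int:
    """Sum over k >= 2 of C(n, k) * k!."""
    from math import comb, factorial

    return sum(comb(n, k) * factorial(k) for k in range(2, n + 1))


def reference_merge(counts, short_max: int = 10, neighbor_max: int = 20):
    """Literal restatement of the short-sentence merge rule on word counts.

    Returns the partition as a list of lists of original indices.
    Single left-to-right pass; a sentence of <= short_max words merges
    into the previous unit while that unit holds < neighbor_max words,
    otherwise grabs the next sentence if it has < neighbor_max words;
    each short sentence merges at most once and merges never cascade.
    """
    groups: list[list[int]] = []
    totals: list[int] = []
    i = 0
    while i < len(counts):
        wc = counts[i]
        if wc > short_max:
            groups.append([i])
            totals.append(wc)
            i += 1
        elif groups and totals[-1] < neighbor_max:
            groups[-1].append(i)
            totals[-1] += wc
            i += 1
        elif i + 1 < len(counts) and counts[i + 1] < neighbor_max:
            groups.append([i, i + 1])
            totals.append(wc + counts[i + 1])
            i += 2
        else:
            groups.append([i])
            totals.append(wc)
            i += 1
    return groups


def confusion_counts(y_true, y_pred):
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif t and not p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
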