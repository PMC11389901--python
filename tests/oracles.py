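"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: the textbook dynamic program for
edit distance, exhaustive scans, and enumeration — no shared code with the
package's own fast paths.
"""

from __future__ import annotations

import unicodedata
from typing import Optional, Sequence

from rwdtextminer.types import DictionaryEntry


def lev_dp(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) Levenshtein dynamic program."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (0 if ai == b[j - 1] else 1),
            )
        prev = cur
    return prev[n]


def canon(s: str) -> str:
    return unicodedata.normalize("NFKC", s).strip().lower()


def brute_force_link(
    surface: str, entries: Sequence[DictionaryEntry], cutoff: float = 70.0
) -> tuple[Optional[str], float, str, frozenset[str]]:
    """Scan every dictionary surface with the DP; returns
    (concept or None, best score, status, winner concept set)."""
    cs = canon(surface)
    best = -1.0
    winners: set[str] = set()
    seen: set[tuple[str, str]] = set()
    for e in entries:
        key = (canon(e.surface), e.concept_id)
        if key in seen:
            continue
        seen.add(key)
        s, c = key
        score = 100.0 * (1.0 - lev_dp(cs, s) / max(len(cs), len(s)))
        if score > best + 1e-12:
            best, winners = score, {c}
        elif abs(score - best) <= 1e-12:
            winners.add(c)
    if best < cutoff:
        return None, best, "unlinked", frozenset(winners)
    if len(winners) > 1:
        return None, best, "ambiguous", frozenset(winners)
    return next(iter(winners)), best, "linked", frozenset(winners)


def recount_frequency(lists: dict[str, list[tuple[str, Optional[str]]]]) -> dict:
    """Independent recount of every frequency-report field."""
    events = [e for e, occ in lists.items() if occ]
    per_entities, per_normalized, per_concepts = [], [], []
    vocab, concepts = set(), set()
    total_entities = total_normalized = 0
    for e in events:
        occ = lists[e]
        linked = [c for _, c in occ if c is not None]
        per_entities.append(len(occ))
        per_normalized.append(len(linked))
        per_concepts.append(len(set(linked)))
        total_entities += len(occ)
        total_normalized += len(linked)
        for s, c in occ:
            vocab.add(s)
            if c is not None:
                concepts.add(c)

    def stats(vals):
        if not vals:
            return None
        vals = sorted(vals)
        n = len(vals)
        median = (
            vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2.0
        )
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / n
        return {"median": float(median), "mean": mean, "std": var**0.5}

    return {
        "total_events_with_entities": len(events),
        "total_entities": total_entities,
        "vocabulary_size": len(vocab),
        "total_normalized": total_normalized,
        "normalized_rate": (total_normalized / total_entities) if total_entities else None,
        "total_concepts": len(concepts),
        "entities_per_event": stats(per_entities),
        "normalized_per_event": stats(per_normalized),
        "concepts_per_event": stats(per_concepts),
    }


def venn_enumerate(a: set, b: set, c: set) -> dict[str, int]:
    """Count the 7 exclusive regions by per-element membership pattern."""
    counts = {"A": 0, "B": 0, "C": 0, "AB": 0, "AC": 0, "BC": 0, "ABC": 0}
    for x in a | b | c:
        key = ("A" if x in a else "") + ("B" if x in b else "") + ("C" if x in c else "")
        counts[key] += 1
    counts["union"] = len(a | b | c)
    return counts
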