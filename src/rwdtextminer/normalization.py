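"""Entity normalization: fuzzy linking of surfaces to medical concepts.

Disease mentions are linked to ICD-10-shaped codes and drug mentions (and
medication-order product names) to pharmaceutical ingredients, by scoring
every dictionary surface with a normalized Levenshtein score

    nls(a, b) = 100 * (1 - lev(a, b) / max(|a|, |b|))

and accepting the best-scoring concept at a cutoff (default 70, inclusive).
When the top score ties across surfaces of two or more distinct concepts
the mention is *ambiguous* and excluded from concept-level analysis rather
than guessed.

Strings are NFKC-normalized, whitespace-trimmed, and Latin-case-folded
before comparison (full/half-width and case variants are common in mixed
script clinical vocabularies). Edit distances are computed by edlib.
"""

from __future__ import annotations

import unicodedata
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

from .types import (
    DictionaryEntry,
    EntityMention,
    LinkedMO,
    MORecord,
    NormalizedMention,
)

DEFAULT_CUTOFF = 70.0


def canon(s: str) -> str:
    """Canonical matching form: NFKC, trimmed, lowercased."""
    return unicodedata.normalize("NFKC", s).strip().lower()


def levenshtein(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def nls(a: str, b: str) -> float:
    """Normalized Levenshtein score in [0, 100]; 100 iff the canonical
    forms are equal.  Empty strings have no defined score."""
    ca, cb = canon(a), canon(b)
    if not ca or not cb:
        raise ValueError("nls is undefined for empty strings")
    return 100.0 * (1.0 - levenshtein(ca, cb) / max(len(ca), len(cb)))


class ConceptLinker:
    """Links surfaces to the concepts of one dictionary.

    Scores are cached per canonical surface; exact matches short-circuit
    the scan (a score of 100 is only attainable by string equality).
    """

    def __init__(self, entries: Sequence[DictionaryEntry], cutoff: float = DEFAULT_CUTOFF):
        if not entries:
            raise ValueError("cannot link against an empty dictionary")
        self.cutoff = cutoff
        self._surfaces: list[tuple[str, str]] = []  # (canonical surface, concept)
        self._exact: dict[str, set[str]] = {}
        seen: set[tuple[str, str]] = set()
        for e in entries:
            key = (canon(e.surface), e.concept_id)
            if key in seen:
                continue
            seen.add(key)
            self._surfaces.append(key)
            self._exact.setdefault(key[0], set()).add(e.concept_id)
        self._cache: dict[str, tuple[Optional[str], float, str]] = {}

    def best_candidates(self, surface: str) -> tuple[float, frozenset[str]]:
        """Best score over all dictionary surfaces and the concepts that
        attain it (the winner set), before the cutoff is applied."""
        cs = canon(surface)
        if not cs:
            raise ValueError("cannot link an empty surface")
        exact = self._exact.get(cs)
        if exact is not None:
            return 100.0, frozenset(exact)
        best = -1.0
        winners: set[str] = set()
        for surf, concept in self._surfaces:
            score = 100.0 * (1.0 - levenshtein(cs, surf) / max(len(cs), len(surf)))
            if score > best + 1e-12:
                best, winners = score, {concept}
            elif abs(score - best) <= 1e-12:
                winners.add(concept)
        return best, frozenset(winners)

    def link_surface(self, surface: str) -> tuple[Optional[str], float, str]:
        """Return (concept_id or None, best score, status)."""
        cs = canon(surface)
        if not cs:
            raise ValueError("cannot link an empty surface")
        hit = self._cache.get(cs)
        if hit is not None:
            return hit
        best, winners = self.best_candidates(cs)
        result = self._resolve(set(winners), best)
        self._cache[cs] = result
        return result

    def _resolve(self, winners: set[str], best: float) -> tuple[Optional[str], float, str]:
        best = max(0.0, min(100.0, best))
        if best < self.cutoff:
            return None, best, "unlinked"
        if len(winners) > 1:
            return None, best, "ambiguous"
        return next(iter(winners)), best, "linked"


def link_mention(
    mention: EntityMention,
    dictionaries: tuple[Sequence[DictionaryEntry], Sequence[DictionaryEntry]]
    | dict[str, ConceptLinker],
    cutoff: float = DEFAULT_CUTOFF,
) -> NormalizedMention:
    """Link one mention against the dictionary of its entity type."""
    if isinstance(dictionaries, dict):
        linker = dictionaries[mention.entity_type]
    else:
        disease, drug = dictionaries
        linker = ConceptLinker(disease if mention.entity_type == "disease" else drug, cutoff)
    concept, score, status = linker.link_surface(mention.surface)
    return NormalizedMention(mention=mention, concept_id=concept, score=score, status=status)


def make_linkers(
    disease_dictionary: Sequence[DictionaryEntry],
    drug_dictionary: Sequence[DictionaryEntry],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, ConceptLinker]:
    return {
        "disease": ConceptLinker(disease_dictionary, cutoff),
        "drug": ConceptLinker(drug_dictionary, cutoff),
    }


def normalize_corpus(
    mentions: Iterable[EntityMention],
    dictionaries: tuple[Sequence[DictionaryEntry], Sequence[DictionaryEntry]],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[NormalizedMention], dict[str, dict]]:
    """Normalize all (positive) mentions and report link rates per type.

    The report gives, per entity type: total_entities, total_normalized,
    and rate = normalized/total (None when there are no mentions).
    """
    linkers = make_linkers(*dictionaries, cutoff=cutoff)
    normalized = [link_mention(m, linkers) for m in mentions]
    report: dict[str, dict] = {}
    for etype in ("disease", "drug"):
        of_type = [n for n in normalized if n.mention.entity_type == etype]
        total = len(of_type)
        linked = sum(1 for n in of_type if n.status == "linked")
        report[etype] = {
            "total_entities": total,
            "total_normalized": linked,
            "rate": (linked / total) if total else None,
        }
    return normalized, report


def link_mo_products(
    mo_records: Iterable[MORecord],
    drug_dictionary: Sequence[DictionaryEntry],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[LinkedMO]:
    """Link medication-order product names to pharmaceutical ingredients."""
    linker = ConceptLinker(drug_dictionary, cutoff)
    out: list[LinkedMO] = []
    for r in mo_records:
        ingredient, score, status = linker.link_surface(r.product_name)
        out.append(LinkedMO(record=r, ingredient=ingredient, score=score, status=status))
    return out


def write_normalized_mentions(
    normalized: Iterable[NormalizedMention], path: str | Path
) -> None:
    import json

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for n in normalized:
            m = n.mention
            fh.write(
                json.dumps(
                    {
                        "doc_id": m.doc_id,
                        "event_id": m.event_id,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "type": m.entity_type,
                        "factuality": m.factuality,
                        "concept_id": n.concept_id,
                        "score": n.score,
                        "status": n.status,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_normalized_mentions(path: str | Path) -> list[NormalizedMention]:
    import json

    out: list[NormalizedMention] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            mention = EntityMention(
                doc_id=obj["doc_id"],
                event_id=obj["event_id"],
                start=obj["start"],
                end=obj["end"],
                surface=obj["surface"],
                entity_type=obj["type"],
                factuality=obj["factuality"],
            )
            out.append(
                NormalizedMention(
                    mention=mention,
                    concept_id=obj["concept_id"],
                    score=float(obj["score"]),
                    status=obj["status"],
                )
            )
    return out


def write_linked_mo(linked: Iterable[LinkedMO], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("event_id\tproduct_name\troute\tingredient\tscore\tstatus\n")
        for lm in linked:
            r = lm.record
            ing = lm.ingredient if lm.ingredient is not None else ""
            fh.write(
                f"{r.event_id}\t{r.product_name}\t{r.route}\t{ing}\t{lm.score:.6g}\t{lm.status}\n"
            )


def read_linked_mo(path: str | Path) -> list[LinkedMO]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[LinkedMO] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            LinkedMO(
                record=MORecord(
                    event_id=d["event_id"],
                    product_name=d["product_name"],
                    route=d["route"],
                ),
                ingredient=d["ingredient"] or None,
                score=float(d["score"]),
                status=d["status"],
            )
        )
    return out


def read_dictionary(path: str | Path) -> list[DictionaryEntry]:
    """Read a term dictionary TSV (surface, concept_id, concept_name, flag_*)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("surface", "concept_id", "concept_name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    flag_cols = sorted(
        (c for c in df.columns if c.startswith("flag_")),
        key=lambda c: int(c.split("_")[1]),
    )
    entries: list[DictionaryEntry] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        entries.append(
            DictionaryEntry(
                surface=d["surface"],
                concept_id=d["concept_id"],
                concept_name=d["concept_name"],
                ade_flags=tuple(int(d[c]) for c in flag_cols),
            )
        )
    return entries
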