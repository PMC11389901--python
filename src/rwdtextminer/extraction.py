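"""Mention extraction: dictionary tagging, negation filtering, import/export.

The reference tagger is a deterministic longest-match-first scan over the
union of dictionary surfaces.  Production deployments that run a trained
clinical NER tool instead can feed its output through
``import_annotations`` — the rest of the pipeline is agnostic to where
mentions came from.

Factuality follows a crisp cue-window rule: a mention is negated iff a cue
string occurs within ``window`` characters after the mention, or
immediately before it.  Cancelled orders are treated the same as negated
findings (both mean "does not apply to the patient").
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import DictionaryEntry, Document, EntityMention, ENTITY_TYPES

logger = logging.getLogger(__name__)

DEFAULT_NEGATION_WINDOW = 12


def nfkc(s: str) -> str:
    return unicodedata.normalize("NFKC", s)


class DictionaryTagger:
    """Longest-match-first, left-to-right tagger over dictionary surfaces.

    Matching runs on NFKC-normalized text. Matches never overlap; ties on
    length are broken by leftmost start, then disease before drug.
    """

    def __init__(
        self,
        disease_dictionary: Sequence[DictionaryEntry],
        drug_dictionary: Sequence[DictionaryEntry],
    ) -> None:
        # length -> {surface -> entity_type}; disease wins a same-surface tie
        self._by_length: dict[int, dict[str, str]] = {}
        for entries, etype in ((drug_dictionary, "drug"), (disease_dictionary, "disease")):
            for e in entries:
                surf = nfkc(e.surface)
                self._by_length.setdefault(len(surf), {})[surf] = etype
        self._lengths = sorted(self._by_length, reverse=True)

    def tag(self, doc: Document) -> list[EntityMention]:
        text = nfkc(doc.text)
        mentions: list[EntityMention] = []
        i, n = 0, len(text)
        while i < n:
            matched = False
            for length in self._lengths:
                if i + length > n:
                    continue
                cand = text[i : i + length]
                etype = self._by_length[length].get(cand)
                if etype is not None:
                    mentions.append(
                        EntityMention(
                            doc_id=doc.doc_id,
                            event_id=doc.event_id,
                            start=i,
                            end=i + length,
                            surface=cand,
                            entity_type=etype,
                        )
                    )
                    i += length
                    matched = True
                    break
            if not matched:
                i += 1
        return mentions


def tag_entities(
    doc: Document,
    dictionaries: tuple[Sequence[DictionaryEntry], Sequence[DictionaryEntry]],
) -> list[EntityMention]:
    """Tag one document against (disease, drug) dictionaries."""
    return DictionaryTagger(*dictionaries).tag(doc)


def detect_negation(
    doc: Document,
    mentions: Iterable[EntityMention],
    cue_list: Sequence[str],
    window: int = DEFAULT_NEGATION_WINDOW,
) -> list[EntityMention]:
    """Assign factuality: negated iff a cue follows within ``window`` chars
    of the mention end, or immediately precedes the mention."""
    text = nfkc(doc.text)
    cues = [nfkc(c) for c in cue_list]
    out: list[EntityMention] = []
    for m in mentions:
        after = text[m.end : m.end + window]
        before = text[: m.start].rstrip(" ")
        negated = any(c in after for c in cues) or any(before.endswith(c) for c in cues)
        out.append(replace(m, factuality="negated" if negated else "positive"))
    return out


def filter_negated(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    """Keep only positive mentions; removal counts per type are logged."""
    mentions = list(mentions)
    kept = [m for m in mentions if m.factuality == "positive"]
    removed: dict[str, int] = {t: 0 for t in ENTITY_TYPES}
    for m in mentions:
        if m.factuality == "negated":
            removed[m.entity_type] += 1
    logger.info("negation filter removed %s", removed)
    return kept


def removed_counts(mentions: Iterable[EntityMention]) -> dict[str, int]:
    """Per-type counts of negated mentions (for run manifests)."""
    counts = {t: 0 for t in ENTITY_TYPES}
    for m in mentions:
        if m.factuality == "negated":
            counts[m.entity_type] += 1
    return counts


def export_annotations(mentions: Iterable[EntityMention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in mentions:
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
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def import_annotations(
    path: str | Path, documents: Optional[Sequence[Document]] = None
) -> list[EntityMention]:
    """Load externally produced mention annotations (e.g., from an ML NER tool).

    Spans are validated against documents when supplied; unknown entity
    types are skipped with a warning; invalid spans are errors.
    """
    texts = {d.doc_id: nfkc(d.text) for d in documents} if documents else None
    mentions: list[EntityMention] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            etype = obj.get("type")
            if etype not in ENTITY_TYPES:
                logger.warning(
                    "%s:%d: skipping unknown entity type %r", path, line_no, etype
                )
                continue
            start, end = int(obj["start"]), int(obj["end"])
            if start >= end or start < 0:
                raise ValueError(f"{path}:{line_no}: invalid span [{start}, {end})")
            if texts is not None:
                text = texts.get(obj["doc_id"])
                if text is None:
                    raise ValueError(f"{path}:{line_no}: unknown doc_id {obj['doc_id']!r}")
                if end > len(text):
                    raise ValueError(
                        f"{path}:{line_no}: span [{start}, {end}) out of bounds "
                        f"for doc {obj['doc_id']} (length {len(text)})"
                    )
            mentions.append(
                EntityMention(
                    doc_id=str(obj["doc_id"]),
                    event_id=str(obj.get("event_id", "")),
                    start=start,
                    end=end,
                    surface=str(obj["surface"]),
                    entity_type=etype,
                    factuality=str(obj.get("factuality", "positive")),
                )
            )
    return mentions
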