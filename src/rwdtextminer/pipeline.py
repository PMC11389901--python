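"""Convenience orchestration of the library stages in memory.

``process`` runs align -> tag -> negation -> filter -> normalize -> link-MO
on already-loaded inputs and returns everything downstream analyses need.
The CLI offers the same flow over files; this entry point serves scripted
use (notebooks, tests, simulation studies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import extraction, frequency_analytics as fa, ingest, normalization
from .types import (
    DictionaryEntry,
    Document,
    DPCRecord,
    EntityMention,
    LinkedMO,
    MORecord,
    NormalizedMention,
)


@dataclass
class PipelineResult:
    corpus: ingest.AlignedCorpus
    mentions: list[EntityMention]  # factuality assigned, negated included
    normalized: list[NormalizedMention]  # positives only, linked/unlinked/ambiguous
    linked_mo: list[LinkedMO]
    link_report: dict
    lists: dict  # (source, entity_type) -> per-event entity lists


def process(
    dpc: Sequence[DPCRecord],
    mo: Sequence[MORecord],
    docs: Sequence[Document],
    disease_dictionary: Sequence[DictionaryEntry],
    drug_dictionary: Sequence[DictionaryEntry],
    cutoff: float = normalization.DEFAULT_CUTOFF,
    negation_cues: Sequence[str] = ("@no1", "@no2", "@no3"),
    negation_window: int = extraction.DEFAULT_NEGATION_WINDOW,
    mentions: Optional[Sequence[EntityMention]] = None,
) -> PipelineResult:
    """Run the full in-memory pipeline.

    When ``mentions`` is given (e.g., imported from an external NER tool)
    the dictionary tagger is skipped and negation labels are taken as-is.
    """
    corpus = ingest.align(list(dpc), list(mo), list(docs))
    if mentions is None:
        tagger = extraction.DictionaryTagger(disease_dictionary, drug_dictionary)
        mentions = []
        for e in corpus.events:
            d = corpus.docs[e]
            mentions.extend(
                extraction.detect_negation(d, tagger.tag(d), negation_cues, negation_window)
            )
    else:
        mentions = list(mentions)
    positives = extraction.filter_negated(mentions)
    normalized, report = normalization.normalize_corpus(
        positives, (disease_dictionary, drug_dictionary), cutoff
    )
    linked_mo = normalization.link_mo_products(
        [r for e in corpus.events for r in corpus.mo[e]], drug_dictionary, cutoff
    )
    lists = fa.build_event_entity_lists(corpus, normalized, linked_mo)
    return PipelineResult(
        corpus=corpus,
        mentions=list(mentions),
        normalized=normalized,
        linked_mo=linked_mo,
        link_report=report,
        lists=lists,
    )
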