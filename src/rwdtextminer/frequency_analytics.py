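"""Per-source frequency statistics and the structured-vs-text comparison.

Three granularities are counted per source and entity type:

* *entity* — every mention/row occurrence, normalized or not;
* *normalized entity* — occurrences successfully linked to a concept;
* *concept* — distinct concepts (per event, and in total).

Diagnosis-record (DPC) codes are concept-level by construction, so every
DPC entity counts as normalized.  Per-event statistics are computed over
events that contain at least one entity of the type; the standard deviation
uses the population denominator n (the events are a census, not a sample).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import AlignedCorpus
from .normalization import canon
from .types import LinkedMO, NormalizedMention

SOURCES = ("TABLE_DPC", "TABLE_MO", "TEXT")

#: per-event entity occurrences: event_id -> list of (surface, concept_id | None)
EventLists = dict[str, list[tuple[str, Optional[str]]]]


def build_event_entity_lists(
    corpus: AlignedCorpus,
    normalized_mentions: Iterable[NormalizedMention],
    linked_mo: Iterable[LinkedMO],
) -> dict[tuple[str, str], EventLists]:
    """Assemble per-event entity lists for each (source, entity_type) pair.

    TEXT lists come from normalized mentions (positives only upstream), DPC
    disease lists from the up-to-24 ICD columns, MO drug lists from linked
    product names.  Surfaces are canonicalized so that vocabulary counts and
    cross-source intersections compare like with like.
    """
    retained = set(corpus.events)
    lists: dict[tuple[str, str], EventLists] = {
        ("TABLE_DPC", "disease"): {},
        ("TABLE_MO", "drug"): {},
        ("TEXT", "disease"): {},
        ("TEXT", "drug"): {},
    }
    for e in corpus.events:
        rec = corpus.dpc[e]
        lists[("TABLE_DPC", "disease")][e] = [(code, code) for code in rec.icd_codes]
    for lm in linked_mo:
        if lm.event_id in retained:
            lists[("TABLE_MO", "drug")].setdefault(lm.event_id, []).append(
                (canon(lm.record.product_name), lm.ingredient)
            )
    for nm in normalized_mentions:
        e = nm.mention.event_id
        if e in retained:
            lists[("TEXT", nm.mention.entity_type)].setdefault(e, []).append(
                (canon(nm.mention.surface), nm.concept_id)
            )
    return lists


@dataclass(frozen=True)
class PerEventStats:
    median: float
    mean: float
    std: float


@dataclass(frozen=True)
class FrequencyReport:
    """The statistics block for one (source, entity type) pair."""

    source: str
    entity_type: str
    total_events_with_entities: int
    total_entities: int
    vocabulary_size: int
    total_normalized: int
    normalized_rate: Optional[float]
    total_concepts: int
    entities_per_event: Optional[PerEventStats]
    normalized_per_event: Optional[PerEventStats]
    concepts_per_event: Optional[PerEventStats]

    def to_dict(self) -> dict:
        return asdict(self)


def _stats(values: Sequence[int]) -> Optional[PerEventStats]:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return PerEventStats(
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        std=float(arr.std(ddof=0)),
    )


def summarize(lists: EventLists, source: str, entity_type: str) -> FrequencyReport:
    """Compute the frequency report for one source's per-event lists."""
    events = [e for e, occ in lists.items() if occ]
    n_entities, n_normalized, n_concepts = [], [], []
    vocab: set[str] = set()
    concepts: set[str] = set()
    total_entities = total_normalized = 0
    for e in events:
        occ = lists[e]
        linked = [c for _, c in occ if c is not None]
        n_entities.append(len(occ))
        n_normalized.append(len(linked))
        n_concepts.append(len(set(linked)))
        total_entities += len(occ)
        total_normalized += len(linked)
        vocab.update(s for s, _ in occ)
        concepts.update(linked)
    return FrequencyReport(
        source=source,
        entity_type=entity_type,
        total_events_with_entities=len(events),
        total_entities=total_entities,
        vocabulary_size=len(vocab),
        total_normalized=total_normalized,
        normalized_rate=(total_normalized / total_entities) if total_entities else None,
        total_concepts=len(concepts),
        entities_per_event=_stats(n_entities),
        normalized_per_event=_stats(n_normalized),
        concepts_per_event=_stats(n_concepts),
    )


def common_counts(lists_a: EventLists, lists_b: EventLists) -> dict[str, int]:
    """Cross-source intersections of surface vocabularies and concept sets."""
    vocab_a = {s for occ in lists_a.values() for s, _ in occ}
    vocab_b = {s for occ in lists_b.values() for s, _ in occ}
    conc_a = {c for occ in lists_a.values() for _, c in occ if c is not None}
    conc_b = {c for occ in lists_b.values() for _, c in occ if c is not None}
    return {
        "common_entities": len(vocab_a & vocab_b),
        "common_concepts": len(conc_a & conc_b),
    }


@dataclass(frozen=True)
class ConceptFrequencyRow:
    rank: int
    concept_id: str
    description: str
    frequency: int


def top_k(
    lists: EventLists,
    k: int = 20,
    descriptions: Optional[dict[str, str]] = None,
) -> list[ConceptFrequencyRow]:
    """Top-k concepts by normalized-entity frequency.

    Ties are broken by concept_id so the ranking is deterministic.
    """
    counts: dict[str, int] = {}
    for occ in lists.values():
        for _, c in occ:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    descriptions = descriptions or {}
    return [
        ConceptFrequencyRow(
            rank=i + 1,
            concept_id=c,
            description=descriptions.get(c, ""),
            frequency=f,
        )
        for i, (c, f) in enumerate(ordered)
    ]


@dataclass(frozen=True)
class OriginRegression:
    """Least-squares fit of y = slope * x constrained through the origin.

    Two R-squared conventions are reported because they genuinely differ for
    origin-constrained fits: ``r2_uncentered`` = 1 - SSres / sum(y^2) (the
    convention most software uses for no-intercept models, bounded by 1) and
    ``r2_centered`` = 1 - SSres / sum((y - ybar)^2), which can exceed 1 or
    fall below 0 when the origin constraint binds.
    """

    slope: float
    r2_uncentered: float
    r2_centered: float
    n: int


def origin_regression(x: Sequence[float], y: Sequence[float]) -> OriginRegression:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("origin regression requires >= 2 paired points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("origin regression expects strictly positive counts")
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_tot_u = float(np.sum(y**2))
    ss_tot_c = float(np.sum((y - y.mean()) ** 2))
    return OriginRegression(
        slope=slope,
        r2_uncentered=1.0 - ss_res / ss_tot_u,
        r2_centered=(1.0 - ss_res / ss_tot_c) if ss_tot_c > 0 else float("nan"),
        n=int(x.size),
    )


def medication_frequency_pairs(
    text_drug_lists: EventLists,
    mo_drug_lists: EventLists,
    linked_mo: Iterable[LinkedMO],
) -> pd.DataFrame:
    """Per-ingredient (x = TEXT count, y = TABLE count, route) scatter data.

    Counts are normalized-entity frequencies; the route label of an
    ingredient is the majority route among its orders (ties -> injection).
    Only ingredients observed in both sources are returned (the plot and the
    origin regression are defined on strictly positive pairs).
    """

    def conc_counts(lists: EventLists) -> dict[str, int]:
        counts: dict[str, int] = {}
        for occ in lists.values():
            for _, c in occ:
                if c is not None:
                    counts[c] = counts.get(c, 0) + 1
        return counts

    x_counts = conc_counts(text_drug_lists)
    y_counts = conc_counts(mo_drug_lists)
    route_votes: dict[str, dict[str, int]] = {}
    for lm in linked_mo:
        if lm.ingredient is not None:
            votes = route_votes.setdefault(lm.ingredient, {"oral": 0, "injection": 0})
            votes[lm.record.route] += 1
    rows = []
    for concept in sorted(set(x_counts) & set(y_counts)):
        votes = route_votes.get(concept, {"oral": 0, "injection": 0})
        route = "injection" if votes["injection"] >= votes["oral"] else "oral"
        rows.append(
            {"concept": concept, "x": x_counts[concept], "y": y_counts[concept], "route": route}
        )
    return pd.DataFrame(rows, columns=["concept", "x", "y", "route"])


def origin_regression_by_route(pairs: pd.DataFrame) -> dict[str, OriginRegression]:
    """Fit the origin-constrained regression separately per route group.

    Groups with fewer than 2 points cannot be fitted and are omitted from
    the result (fitting a single such group directly raises instead).
    """
    out: dict[str, OriginRegression] = {}
    for route, grp in pairs.groupby("route"):
        if len(grp) < 2:
            continue
        out[str(route)] = origin_regression(grp["x"].to_numpy(), grp["y"].to_numpy())
    return out


def normalized_entity_rate(total_normalized: int, total_entities: int) -> float:
    """Normalized-entity rate as a percentage of total entities."""
    if total_entities <= 0:
        raise ValueError("total_entities must be positive")
    if total_normalized > total_entities:
        raise ValueError("normalized count cannot exceed total entities")
    return 100.0 * total_normalized / total_entities


def events_per_patient(n_events: int, n_patients: int) -> float:
    """Mean number of events (hospitalizations) per patient."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return n_events / n_patients
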