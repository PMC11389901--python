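"""Core domain types shared across the pipeline stages.

The unit of analysis throughout is the *event* — one hospitalization /
discharge.  Structured sources (diagnosis records, medication orders) and
free-text documents are keyed by event ID and joined on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

ENTITY_TYPES = ("disease", "drug")
FACTUALITIES = ("positive", "negated")
ROUTES = ("oral", "injection")

#: ICD-10-shaped code: one letter, 2-3 digits, optional subcategory digit.
ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2,3}[0-9]?$")


@dataclass(frozen=True)
class DPCRecord:
    """One diagnosis-procedure-combination row = one event.

    ``icd_codes`` holds the up-to-24 disease columns, filled left to right;
    they are concept-level ICD-10 codes, so no normalization step applies.
    """

    event_id: str
    patient_id: str
    icd_codes: tuple[str, ...]
    admit_meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.event_id:
            raise ValueError("DPCRecord requires a non-empty event_id")
        if not 1 <= len(self.icd_codes) <= 24:
            raise ValueError(
                f"event {self.event_id}: expected 1..24 ICD codes, got {len(self.icd_codes)}"
            )
        for code in self.icd_codes:
            if not ICD_PATTERN.match(code):
                raise ValueError(f"event {self.event_id}: malformed ICD code {code!r}")


@dataclass(frozen=True)
class MORecord:
    """One medication order: a product name and its administration route."""

    event_id: str
    product_name: str
    route: str
    order_meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.event_id:
            raise ValueError("MORecord requires a non-empty event_id")
        if self.route not in ROUTES:
            raise ValueError(
                f"event {self.event_id}: unknown route {self.route!r} (expected one of {ROUTES})"
            )


@dataclass(frozen=True)
class Document:
    """One free-text note (discharge summary); one document per event."""

    doc_id: str
    event_id: str
    patient_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.event_id:
            raise ValueError(f"document {self.doc_id}: empty event_id")


@dataclass(frozen=True)
class DictionaryEntry:
    """One term-dictionary row: a surface expression linked to a concept.

    For diseases the concept is an ICD-10-shaped code, for drugs a
    pharmaceutical ingredient name.  ``ade_flags`` marks relevance to each
    of the tracked frequent adverse drug effects (binary, default 7 flags).
    """

    surface: str
    concept_id: str
    concept_name: str
    ade_flags: tuple[int, ...] = (0,) * 7

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("dictionary entry with empty surface")
        if any(f not in (0, 1) for f in self.ade_flags):
            raise ValueError(f"surface {self.surface!r}: ADE flags must be 0/1")


@dataclass(frozen=True)
class EntityMention:
    """A recognized span in a document.

    ``start``/``end`` are a 0-based half-open character interval into the
    NFKC-normalized document text; slicing the text at the span yields
    ``surface``.
    """

    doc_id: str
    event_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    factuality: str = "positive"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"doc {self.doc_id}: invalid span [{self.start}, {self.end})"
            )
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"doc {self.doc_id}: unknown entity type {self.entity_type!r}")
        if self.factuality not in FACTUALITIES:
            raise ValueError(f"doc {self.doc_id}: unknown factuality {self.factuality!r}")


LINK_STATUSES = ("linked", "unlinked", "ambiguous")


@dataclass(frozen=True)
class NormalizedMention:
    """A mention after entity normalization.

    ``status`` is ``linked`` when the best fuzzy score reached the cutoff
    and all top-scoring surfaces agree on one concept; ``ambiguous`` when
    the top score ties across distinct concepts (such mentions are excluded
    from concept-level analyses); ``unlinked`` otherwise.
    """

    mention: EntityMention
    concept_id: Optional[str]
    score: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in LINK_STATUSES:
            raise ValueError(f"unknown link status {self.status!r}")
        if self.status == "linked" and self.concept_id is None:
            raise ValueError("linked mention requires a concept_id")
        if self.status in ("unlinked", "ambiguous") and self.concept_id is not None:
            raise ValueError(f"{self.status} mention must not carry a concept_id")
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class LinkedMO:
    """A medication order annotated with its ingredient concept."""

    record: MORecord
    ingredient: Optional[str]
    score: float
    status: str

    @property
    def event_id(self) -> str:
        return self.record.event_id
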