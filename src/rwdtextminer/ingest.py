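"""Readers and event alignment for the three data sources.

Structured tables arrive as UTF-8 TSV with a header row; documents as
JSONL.  IDs are opaque strings (never coerced to numbers).  Alignment
keeps only events present in both the table side (a diagnosis record) and
the text side (a document), mirroring how hospital extracts are joined on
event IDs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .types import ICD_PATTERN, Document, DPCRecord, MORecord, ROUTES

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input file violates the expected schema."""


def read_dpc(path: str | Path) -> list[DPCRecord]:
    """Read diagnosis records; blank ICD cells are dropped, order preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    icd_cols = [f"icd_{i:02d}" for i in range(1, 25) if f"icd_{i:02d}" in df.columns]
    if "event_id" not in df.columns or "patient_id" not in df.columns:
        raise ValidationError(f"{path}: missing event_id/patient_id columns")
    if not icd_cols:
        raise ValidationError(f"{path}: no icd_01..icd_24 columns found")
    meta_cols = [c for c in df.columns if c not in icd_cols + ["event_id", "patient_id"]]
    records: list[DPCRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if not d["event_id"]:
            raise ValidationError(f"{path}:{row_no}: missing event_id")
        codes = tuple(d[c] for c in icd_cols if d[c])
        bad = [c for c in codes if not ICD_PATTERN.match(c)]
        if bad or not codes:
            raise ValidationError(
                f"{path}:{row_no}: event {d['event_id']}: "
                + (f"malformed ICD codes {bad}" if bad else "no ICD codes")
            )
        records.append(
            DPCRecord(
                event_id=d["event_id"],
                patient_id=d["patient_id"],
                icd_codes=codes,
                admit_meta={c: d[c] for c in meta_cols},
            )
        )
    return records


def read_mo(path: str | Path) -> list[MORecord]:
    """Read medication orders; unknown routes are hard errors."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("event_id", "product_name", "route"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    meta_cols = [c for c in df.columns if c not in ("event_id", "product_name", "route")]
    records: list[MORecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if not d["event_id"]:
            raise ValidationError(f"{path}:{row_no}: missing event_id")
        if d["route"] not in ROUTES:
            raise ValidationError(
                f"{path}:{row_no}: unknown route {d['route']!r} (expected one of {ROUTES})"
            )
        records.append(
            MORecord(
                event_id=d["event_id"],
                product_name=d["product_name"],
                route=d["route"],
                order_meta={c: d[c] for c in meta_cols},
            )
        )
    return records


def read_documents(path: str | Path) -> list[Document]:
    """Read documents from JSONL (doc_id, event_id, patient_id, text)."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{line_no}: invalid JSON: {exc}") from exc
            try:
                docs.append(
                    Document(
                        doc_id=str(obj["doc_id"]),
                        event_id=str(obj["event_id"]),
                        patient_id=str(obj.get("patient_id", "")),
                        text=str(obj.get("text", "")),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    return docs


@dataclass
class AlignedCorpus:
    """Events present in both the table side and the text side.

    ``dpc`` maps each retained event to its single diagnosis record, ``mo``
    to its (possibly empty) list of orders, ``docs`` to its document.
    Patient IDs are taken from the DPC side; a conflicting document
    patient_id is logged, not fatal.
    """

    events: list[str]
    dpc: dict[str, DPCRecord]
    mo: dict[str, list[MORecord]]
    docs: dict[str, Document]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def patients(self) -> set[str]:
        return {self.dpc[e].patient_id for e in self.events}

    @property
    def event_to_patient(self) -> dict[str, str]:
        return {e: self.dpc[e].patient_id for e in self.events}


def align(
    dpc: list[DPCRecord], mo: list[MORecord], docs: list[Document]
) -> AlignedCorpus:
    """Intersect table-side and text-side events.

    Only events with a diagnosis record AND at least one document survive;
    orders outside retained events are dropped (and counted).  Multiple
    documents for one event are concatenated in doc_id order (logged).
    Duplicate DPC rows for one event are an error: one DPC row = one event.
    """
    dpc_by_event: dict[str, DPCRecord] = {}
    for r in dpc:
        if r.event_id in dpc_by_event:
            raise ValidationError(f"duplicate DPC row for event {r.event_id}")
        dpc_by_event[r.event_id] = r

    docs_by_event: dict[str, list[Document]] = {}
    for d in docs:
        docs_by_event.setdefault(d.event_id, []).append(d)

    events = sorted(set(dpc_by_event) & set(docs_by_event))
    if not events:
        logger.warning("alignment produced an empty corpus (disjoint event IDs)")

    merged_docs: dict[str, Document] = {}
    n_concat = 0
    for e in events:
        group = sorted(docs_by_event[e], key=lambda d: d.doc_id)
        if len(group) == 1:
            doc = group[0]
        else:
            n_concat += 1
            logger.info("event %s has %d documents; concatenating", e, len(group))
            doc = Document(
                doc_id=group[0].doc_id,
                event_id=e,
                patient_id=group[0].patient_id,
                text=" ".join(g.text for g in group),
            )
        if doc.patient_id and doc.patient_id != dpc_by_event[e].patient_id:
            logger.warning(
                "event %s: document patient_id %s != DPC patient_id %s; using DPC",
                e,
                doc.patient_id,
                dpc_by_event[e].patient_id,
            )
        merged_docs[e] = doc

    retained = set(events)
    mo_by_event: dict[str, list[MORecord]] = {e: [] for e in events}
    n_mo_dropped = 0
    for r in mo:
        if r.event_id in retained:
            mo_by_event[r.event_id].append(r)
        else:
            n_mo_dropped += 1

    return AlignedCorpus(
        events=events,
        dpc={e: dpc_by_event[e] for e in events},
        mo=mo_by_event,
        docs=merged_docs,
        dropped={
            "dpc_events": len(dpc_by_event) - len(events),
            "text_events": len(docs_by_event) - len(events),
            "mo_records": n_mo_dropped,
            "concatenated_multi_doc_events": n_concat,
        },
    )
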