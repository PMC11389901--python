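"""Cohort identification from three sources and Venn-region counting.

A target disease is specified by ICD-10 code prefixes (ranges such as
``E10-14`` expand at load time) and, optionally, a list of ingredient
concepts for medications used only or mainly for that disease.  Patients
(or events) are then identified independently from:

* **DPC** — any of the 24 diagnosis columns starts with a target prefix;
* **MO** — any order links to a target ingredient;
* **TEXT** — any positive, linked disease mention's concept starts with a
  target prefix.

Prefix semantics implement ICD subcategories: C50 matches C50, C501, C509.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .types import DPCRecord, LinkedMO, NormalizedMention

_RANGE = re.compile(r"^([A-Z])(\d+)-(\d+)$")


def expand_icd_ranges(codes: Iterable[str]) -> list[str]:
    """Expand range notation: ``E10-14`` -> E10, E11, E12, E13, E14."""
    out: list[str] = []
    for code in codes:
        code = str(code).strip()
        m = _RANGE.match(code)
        if m:
            letter, lo, hi = m.group(1), m.group(2), m.group(3)
            width = len(lo)
            lo_i, hi_i = int(lo), int(hi)
            if hi_i < lo_i:
                raise ValueError(f"invalid ICD range {code!r}")
            out.extend(f"{letter}{i:0{width}d}" for i in range(lo_i, hi_i + 1))
        else:
            out.append(code)
    return out


@dataclass(frozen=True)
class DiseaseSpec:
    name: str
    icd_prefixes: tuple[str, ...]
    drug_concepts: tuple[str, ...] = ()

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiseaseSpec":
        return cls(
            name=str(d["name"]),
            icd_prefixes=tuple(expand_icd_ranges(d.get("icd", []))),
            drug_concepts=tuple(d.get("drugs", []) or ()),
        )


def load_disease_specs(path: Optional[str | Path] = None) -> list[DiseaseSpec]:
    """Load disease specs from YAML; defaults to the bundled spec file."""
    if path is None:
        text = (
            resources.files("rwdtextminer").joinpath("data/disease_specs.yaml").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    return [DiseaseSpec.from_dict(d) for d in raw["diseases"]]


def _matches(code: str, prefixes: Sequence[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def patients_from_dpc(
    dpc: Iterable[DPCRecord], spec: DiseaseSpec, unit: str = "patient"
) -> set[str]:
    """IDs whose diagnosis columns carry a target ICD code (any of 24)."""
    out: set[str] = set()
    for r in dpc:
        if any(_matches(c, spec.icd_prefixes) for c in r.icd_codes):
            out.add(r.patient_id if unit == "patient" else r.event_id)
    return out


def patients_from_mo(
    linked_mo: Iterable[LinkedMO],
    spec: DiseaseSpec,
    event_to_patient: Mapping[str, str],
    unit: str = "patient",
) -> set[str]:
    """IDs with an order linked to one of the disease's signature drugs."""
    targets = set(spec.drug_concepts)
    if not targets:
        return set()
    out: set[str] = set()
    for lm in linked_mo:
        if lm.ingredient in targets and lm.event_id in event_to_patient:
            out.add(event_to_patient[lm.event_id] if unit == "patient" else lm.event_id)
    return out


def patients_from_text(
    normalized_mentions: Iterable[NormalizedMention],
    spec: DiseaseSpec,
    event_to_patient: Mapping[str, str],
    unit: str = "patient",
) -> set[str]:
    """IDs whose text carries a positive, linked mention of a target concept."""
    out: set[str] = set()
    for nm in normalized_mentions:
        if (
            nm.status == "linked"
            and nm.mention.entity_type == "disease"
            and nm.mention.factuality == "positive"
            and _matches(nm.concept_id, spec.icd_prefixes)
            and nm.mention.event_id in event_to_patient
        ):
            out.add(
                event_to_patient[nm.mention.event_id] if unit == "patient" else nm.mention.event_id
            )
    return out


def venn_counts(a: set, b: set, c: set) -> dict[str, int]:
    """The 7 exclusive Venn regions of three sets, plus the union size."""
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
        "union": len(a | b | c),
    }


@dataclass(frozen=True)
class CohortResult:
    spec: DiseaseSpec
    unit: str
    patients_dpc: frozenset[str]
    patients_mo: frozenset[str]
    patients_text: frozenset[str]
    venn7: dict[str, int] = field(compare=False)


def identify_cohort(
    spec: DiseaseSpec,
    dpc: Iterable[DPCRecord],
    linked_mo: Iterable[LinkedMO],
    normalized_mentions: Iterable[NormalizedMention],
    event_to_patient: Mapping[str, str],
    unit: str = "patient",
) -> CohortResult:
    """Run all three source queries for one disease and count Venn regions."""
    if unit not in ("patient", "event"):
        raise ValueError(f"unknown counting unit {unit!r}")
    a = patients_from_dpc(dpc, spec, unit)
    b = patients_from_mo(linked_mo, spec, event_to_patient, unit)
    c = patients_from_text(normalized_mentions, spec, event_to_patient, unit)
    return CohortResult(
        spec=spec,
        unit=unit,
        patients_dpc=frozenset(a),
        patients_mo=frozenset(b),
        patients_text=frozenset(c),
        venn7=venn_counts(a, b, c),
    )
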