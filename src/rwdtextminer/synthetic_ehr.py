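"""Synthetic EHR corpus generator.

Produces the four inputs the pipeline consumes — term dictionaries,
diagnosis (DPC) records, medication orders (MO), and per-event free-text
documents — together with exact ground truth for every planted mention, so
that extraction, normalization, and the downstream analytics are testable
end to end without any real hospital data.

Conventions (chosen for analytic testability, see docs/methods.md):

* dictionary surfaces are length-10 lowercase strings, so a single random
  character edit yields a normalized Levenshtein score of ~90, safely above
  the default linking cutoff of 70;
* out-of-dictionary surfaces are length 4, so their score against any
  dictionary surface is at most 40, safely below the cutoff;
* filler tokens are uppercase and negation cues start with ``@``, so
  neither can collide with dictionary surfaces;
* negation cues are appended immediately after the negated mention,
  matching the extraction module's cue-window convention exactly.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .types import DictionaryEntry, Document, DPCRecord, MORecord

SURFACE_ALPHABET = string.ascii_lowercase
SURFACE_LEN = 10
OOD_LEN = 4
FILLER_ALPHABET = string.ascii_uppercase
DEFAULT_CUES = ("@no1", "@no2", "@no3")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus.

    Counts are drawn from Poisson distributions (events per patient
    truncated at >= 1: every patient has at least one discharge).
    Identical config + seed reproduces byte-identical output files.
    """

    seed: int = 0
    n_patients: int = 50
    events_per_patient_mean: float = 3.12
    n_disease_concepts: int = 30
    n_drug_concepts: int = 20
    surfaces_per_concept: int = 2
    p_negated: float = 0.0
    p_surface_perturb: float = 0.0
    p_out_of_dictionary: float = 0.0
    mentions_per_doc_mean: float = 8.0
    orders_per_event_mean: float = 5.0
    p_injection: float = 0.4
    ade_flag_density: float = 0.15
    n_ade_flags: int = 7
    ambiguous_surface_fraction: float = 0.0
    p_disease_mention: float = 0.5
    dpc_extra_codes_mean: float = 1.5
    negation_cues: tuple[str, ...] = DEFAULT_CUES

    def __post_init__(self) -> None:
        for name in (
            "p_negated",
            "p_surface_perturb",
            "p_out_of_dictionary",
            "p_injection",
            "ade_flag_density",
            "ambiguous_surface_fraction",
            "p_disease_mention",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_patients",
            "n_disease_concepts",
            "n_drug_concepts",
            "surfaces_per_concept",
            "n_ade_flags",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("events_per_patient_mean", "mentions_per_doc_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orders_per_event_mean < 0:
            raise ValueError("orders_per_event_mean must be >= 0")
        if not self.negation_cues:
            raise ValueError("at least one negation cue is required")


@dataclass(frozen=True)
class PlantedMention:
    """Ground truth for one planted mention; spans index the document text."""

    doc_id: str
    event_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    factuality: str
    true_concept_id: Optional[str]


@dataclass
class GroundTruth:
    mentions: list[PlantedMention] = field(default_factory=list)
    #: event_id -> tuple of ICD codes actually written to the DPC row
    dpc_concepts: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: event_id -> list of true ingredient concepts, one per MO row
    mo_ingredients: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticCorpus:
    config: SynthConfig
    disease_dictionary: list[DictionaryEntry]
    drug_dictionary: list[DictionaryEntry]
    dpc_records: list[DPCRecord]
    mo_records: list[MORecord]
    documents: list[Document]
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts as UTF-8 TSV/JSONL files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "disease_dict": outdir / "disease_dict.tsv",
            "drug_dict": outdir / "drug_dict.tsv",
            "dpc": outdir / "dpc.tsv",
            "mo": outdir / "mo.tsv",
            "docs": outdir / "docs.jsonl",
            "ground_truth": outdir / "ground_truth.jsonl",
        }
        write_dictionary(self.disease_dictionary, paths["disease_dict"])
        write_dictionary(self.drug_dictionary, paths["drug_dict"])
        _write_dpc(self.dpc_records, paths["dpc"])
        _write_mo(self.mo_records, paths["mo"])
        _write_docs(self.documents, paths["docs"])
        _write_ground_truth(self.ground_truth, paths["ground_truth"])
        return paths


def _random_string(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _fresh_surface(rng: np.random.Generator, taken: set[str], length: int = SURFACE_LEN) -> str:
    while True:
        s = _random_string(rng, SURFACE_ALPHABET, length)
        if s not in taken:
            taken.add(s)
            return s


def perturb_surface(surface: str, rng: np.random.Generator) -> str:
    """Apply exactly one random character edit (insert/delete/substitute)."""
    ops = ["insert", "substitute"] + (["delete"] if len(surface) > 1 else [])
    op = ops[rng.integers(0, len(ops))]
    if op == "delete":
        i = int(rng.integers(0, len(surface)))
        return surface[:i] + surface[i + 1 :]
    if op == "insert":
        i = int(rng.integers(0, len(surface) + 1))
        c = SURFACE_ALPHABET[rng.integers(0, len(SURFACE_ALPHABET))]
        return surface[:i] + c + surface[i:]
    i = int(rng.integers(0, len(surface)))
    others = SURFACE_ALPHABET.replace(surface[i], "")
    c = others[rng.integers(0, len(others))]
    return surface[:i] + c + surface[i:]


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    """Poisson draw truncated at >= 1 (rejection sampling)."""
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def generate_dictionaries(
    cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[DictionaryEntry], list[DictionaryEntry]]:
    """Build the disease and drug term dictionaries.

    Disease concepts carry ICD-10-shaped codes (letter + 3 digits) and a
    binary flag per tracked adverse drug effect; drug concepts are
    ingredient names whose surfaces play the role of product names.
    A configurable fraction of surfaces is shared between two concepts to
    exercise the ambiguity-exclusion rule in normalization.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    taken_surfaces: set[str] = set()
    taken_codes: set[str] = set()

    disease: list[DictionaryEntry] = []
    letters = string.ascii_uppercase
    for k in range(cfg.n_disease_concepts):
        while True:
            code = letters[rng.integers(0, 26)] + f"{int(rng.integers(0, 1000)):03d}"
            if code not in taken_codes:
                taken_codes.add(code)
                break
        flags = tuple(
            int(rng.random() < cfg.ade_flag_density) for _ in range(cfg.n_ade_flags)
        )
        name = f"disease_{k:03d}"
        for _ in range(cfg.surfaces_per_concept):
            disease.append(
                DictionaryEntry(
                    surface=_fresh_surface(rng, taken_surfaces),
                    concept_id=code,
                    concept_name=name,
                    ade_flags=flags,
                )
            )

    drug: list[DictionaryEntry] = []
    zero_flags = (0,) * cfg.n_ade_flags
    for k in range(cfg.n_drug_concepts):
        ingredient = f"ing_{_random_string(rng, SURFACE_ALPHABET, 8)}"
        for _ in range(cfg.surfaces_per_concept):
            drug.append(
                DictionaryEntry(
                    surface=_fresh_surface(rng, taken_surfaces),
                    concept_id=ingredient,
                    concept_name=ingredient,
                    ade_flags=zero_flags,
                )
            )

    # ambiguous surfaces: one extra surface mapped to two distinct concepts
    for entries, n_concepts in ((disease, cfg.n_disease_concepts), (drug, cfg.n_drug_concepts)):
        n_amb = int(round(cfg.ambiguous_surface_fraction * n_concepts))
        concepts = sorted({e.concept_id for e in entries})
        if n_amb and len(concepts) >= 2:
            by_concept = {c: [e for e in entries if e.concept_id == c] for c in concepts}
            for _ in range(n_amb):
                i, j = rng.choice(len(concepts), size=2, replace=False)
                shared = _fresh_surface(rng, taken_surfaces)
                for c in (concepts[i], concepts[j]):
                    proto = by_concept[c][0]
                    entries.append(
                        DictionaryEntry(
                            surface=shared,
                            concept_id=proto.concept_id,
                            concept_name=proto.concept_name,
                            ade_flags=proto.ade_flags,
                        )
                    )
    return disease, drug


def generate_tables(
    cfg: SynthConfig,
    dictionaries: tuple[list[DictionaryEntry], list[DictionaryEntry]],
    rng: Optional[np.random.Generator] = None,
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[list[DPCRecord], list[MORecord]]:
    """Generate the structured side: one DPC row per event plus MO rows.

    Each patient gets a truncated-Poisson number of events.  A DPC row
    carries 1..24 distinct ICD codes; each MO row picks an ingredient and
    one of its product-name surfaces, perturbed with probability
    ``p_surface_perturb`` to exercise fuzzy ingredient linking.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    disease, drug = dictionaries
    if not disease or not drug:
        raise ValueError("dictionaries must be non-empty")
    disease_codes = sorted({e.concept_id for e in disease})
    drug_concepts = sorted({e.concept_id for e in drug})
    surfaces_by_drug: dict[str, list[str]] = {}
    for e in drug:
        surfaces_by_drug.setdefault(e.concept_id, []).append(e.surface)

    dpc_records: list[DPCRecord] = []
    mo_records: list[MORecord] = []
    event_idx = 0
    for p in range(cfg.n_patients):
        patient_id = f"P{p:05d}"
        n_events = _truncated_poisson(rng, cfg.events_per_patient_mean)
        for _ in range(n_events):
            event_id = f"E{event_idx:06d}"
            event_idx += 1
            n_codes = min(
                1 + int(rng.poisson(cfg.dpc_extra_codes_mean)), 24, len(disease_codes)
            )
            codes = tuple(
                rng.choice(disease_codes, size=n_codes, replace=False).tolist()
            )
            dpc_records.append(
                DPCRecord(event_id=event_id, patient_id=patient_id, icd_codes=codes)
            )
            if ground_truth is not None:
                ground_truth.dpc_concepts[event_id] = codes
                ground_truth.mo_ingredients.setdefault(event_id, [])
            n_orders = int(rng.poisson(cfg.orders_per_event_mean))
            for _ in range(n_orders):
                ingredient = drug_concepts[rng.integers(0, len(drug_concepts))]
                surfaces = surfaces_by_drug[ingredient]
                product = surfaces[rng.integers(0, len(surfaces))]
                if rng.random() < cfg.p_surface_perturb:
                    product = perturb_surface(product, rng)
                route = "injection" if rng.random() < cfg.p_injection else "oral"
                mo_records.append(
                    MORecord(event_id=event_id, product_name=product, route=route)
                )
                if ground_truth is not None:
                    ground_truth.mo_ingredients[event_id].append(ingredient)
    return dpc_records, mo_records


def generate_documents(
    cfg: SynthConfig,
    dictionaries: tuple[list[DictionaryEntry], list[DictionaryEntry]],
    tables: tuple[list[DPCRecord], list[MORecord]],
    rng: Optional[np.random.Generator] = None,
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[list[Document], GroundTruth]:
    """Generate one document per event with planted, ground-truthed mentions.

    Filler tokens (uppercase) interleave with planted mention surfaces.
    A planted mention is, independently: out-of-dictionary with probability
    ``p_out_of_dictionary`` (a short surface no fuzzy match can reach);
    otherwise a dictionary surface, perturbed by exactly one character edit
    with probability ``p_surface_perturb``; and negated with probability
    ``p_negated`` (a cue token appended immediately after it).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if ground_truth is None:
        ground_truth = GroundTruth()
    disease, drug = dictionaries
    dpc_records, _ = tables
    all_surfaces = {e.surface for e in disease} | {e.surface for e in drug}

    def entries_and_type() -> tuple[list[DictionaryEntry], str]:
        if rng.random() < cfg.p_disease_mention:
            return disease, "disease"
        return drug, "drug"

    documents: list[Document] = []
    for i, rec in enumerate(dpc_records):
        doc_id = f"D{i:06d}"
        tokens: list[str] = []
        pos = 0  # cursor in the final text
        plants: list[PlantedMention] = []

        def emit(token: str) -> int:
            """Append a token; return its start offset in the final text."""
            nonlocal pos
            start = pos + (1 if tokens else 0)
            tokens.append(token)
            pos = start + len(token)
            return start

        n_mentions = int(rng.poisson(cfg.mentions_per_doc_mean))
        for _ in range(n_mentions):
            for _ in range(int(rng.integers(1, 4))):  # 1-3 filler words
                emit(_random_string(rng, FILLER_ALPHABET, int(rng.integers(3, 7))))
            entries, etype = entries_and_type()
            if rng.random() < cfg.p_out_of_dictionary:
                while True:
                    surface = _random_string(rng, SURFACE_ALPHABET, OOD_LEN)
                    if surface not in all_surfaces:
                        break
                concept: Optional[str] = None
            else:
                entry = entries[rng.integers(0, len(entries))]
                surface, concept = entry.surface, entry.concept_id
                if rng.random() < cfg.p_surface_perturb:
                    surface = perturb_surface(surface, rng)
            factuality = "negated" if rng.random() < cfg.p_negated else "positive"
            start = emit(surface)
            plants.append(
                PlantedMention(
                    doc_id=doc_id,
                    event_id=rec.event_id,
                    start=start,
                    end=start + len(surface),
                    surface=surface,
                    entity_type=etype,
                    factuality=factuality,
                    true_concept_id=concept,
                )
            )
            if factuality == "negated":
                cue = cfg.negation_cues[rng.integers(0, len(cfg.negation_cues))]
                emit(cue)
        emit(_random_string(rng, FILLER_ALPHABET, int(rng.integers(3, 7))))
        text = " ".join(tokens)
        for m in plants:
            assert text[m.start : m.end] == m.surface
        documents.append(
            Document(doc_id=doc_id, event_id=rec.event_id, patient_id=rec.patient_id, text=text)
        )
        ground_truth.mentions.extend(plants)
    return documents, ground_truth


def generate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Run all three generation stages under one seed."""
    gt = GroundTruth()
    dictionaries = generate_dictionaries(cfg)
    tables = generate_tables(cfg, dictionaries, ground_truth=gt)
    documents, gt = generate_documents(cfg, dictionaries, tables, ground_truth=gt)
    return SyntheticCorpus(
        config=cfg,
        disease_dictionary=dictionaries[0],
        drug_dictionary=dictionaries[1],
        dpc_records=tables[0],
        mo_records=tables[1],
        documents=documents,
        ground_truth=gt,
    )


@dataclass(frozen=True)
class AdeScenario:
    """Bookkeeping for a planted adverse-effect signal (see plant_ade_signal)."""

    drug_i: str
    drug_j: str
    symptom_concept: str
    symptom_surface: str
    pair_event_ids: tuple[str, ...]
    symptom_event_ids: frozenset[str]
    symptom_rate: float


def plant_ade_signal(
    corpus: SyntheticCorpus,
    n_pair_events: int,
    symptom_rate: float,
    seed: int,
) -> AdeScenario:
    """Plant a drug-pair / symptom co-occurrence signal into a corpus.

    Two fresh ingredient concepts and one fresh symptom concept (ADE flag 1
    set) are added to the dictionaries so that no pre-existing order or
    mention interferes.  ``n_pair_events`` events receive orders for both
    drugs; each such event's document gains a positive symptom mention with
    probability ``symptom_rate``.  The realized co-frequency ratio for the
    pair is then |symptom events| / n_pair_events by construction.
    """
    rng = np.random.default_rng(seed)
    cfg = corpus.config
    if n_pair_events > len(corpus.dpc_records):
        raise ValueError(
            f"requested {n_pair_events} pair events but corpus has only "
            f"{len(corpus.dpc_records)} events"
        )
    taken = {e.surface for e in corpus.disease_dictionary} | {
        e.surface for e in corpus.drug_dictionary
    }
    drug_i, drug_j = "ing_pairdrug_a", "ing_pairdrug_b"
    surf_i = _fresh_surface(rng, taken)
    surf_j = _fresh_surface(rng, taken)
    zero = (0,) * cfg.n_ade_flags
    corpus.drug_dictionary.append(
        DictionaryEntry(surface=surf_i, concept_id=drug_i, concept_name=drug_i, ade_flags=zero)
    )
    corpus.drug_dictionary.append(
        DictionaryEntry(surface=surf_j, concept_id=drug_j, concept_name=drug_j, ade_flags=zero)
    )
    symptom_concept = "Z999"
    symptom_surface = _fresh_surface(rng, taken)
    flags = (1,) + (0,) * (cfg.n_ade_flags - 1)
    corpus.disease_dictionary.append(
        DictionaryEntry(
            surface=symptom_surface,
            concept_id=symptom_concept,
            concept_name="planted_symptom",
            ade_flags=flags,
        )
    )

    idx = rng.choice(len(corpus.dpc_records), size=n_pair_events, replace=False)
    docs_by_event = {d.event_id: k for k, d in enumerate(corpus.documents)}
    pair_events: list[str] = []
    symptom_events: set[str] = set()
    for k in sorted(int(v) for v in idx):
        event_id = corpus.dpc_records[k].event_id
        pair_events.append(event_id)
        for surf, ing in ((surf_i, drug_i), (surf_j, drug_j)):
            corpus.mo_records.append(
                MORecord(event_id=event_id, product_name=surf, route="injection")
            )
            corpus.ground_truth.mo_ingredients.setdefault(event_id, []).append(ing)
        if rng.random() < symptom_rate:
            symptom_events.add(event_id)
            di = docs_by_event[event_id]
            doc = corpus.documents[di]
            start = len(doc.text) + 1
            new_text = doc.text + " " + symptom_surface
            corpus.documents[di] = Document(
                doc_id=doc.doc_id,
                event_id=doc.event_id,
                patient_id=doc.patient_id,
                text=new_text,
            )
            corpus.ground_truth.mentions.append(
                PlantedMention(
                    doc_id=doc.doc_id,
                    event_id=event_id,
                    start=start,
                    end=start + len(symptom_surface),
                    surface=symptom_surface,
                    entity_type="disease",
                    factuality="positive",
                    true_concept_id=symptom_concept,
                )
            )
    return AdeScenario(
        drug_i=drug_i,
        drug_j=drug_j,
        symptom_concept=symptom_concept,
        symptom_surface=symptom_surface,
        pair_event_ids=tuple(pair_events),
        symptom_event_ids=frozenset(symptom_events),
        symptom_rate=symptom_rate,
    )


# ---------------------------------------------------------------------------
# writers


def write_dictionary(entries: Sequence[DictionaryEntry], path: str | Path) -> None:
    n_flags = len(entries[0].ade_flags) if entries else 7
    header = ["surface", "concept_id", "concept_name"] + [
        f"flag_{i + 1}" for i in range(n_flags)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for e in entries:
            row = [e.surface, e.concept_id, e.concept_name] + [str(f) for f in e.ade_flags]
            fh.write("\t".join(row) + "\n")


def _write_dpc(records: Sequence[DPCRecord], path: str | Path) -> None:
    header = ["event_id", "patient_id"] + [f"icd_{i + 1:02d}" for i in range(24)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            codes = list(r.icd_codes) + [""] * (24 - len(r.icd_codes))
            fh.write("\t".join([r.event_id, r.patient_id] + codes) + "\n")


def _write_mo(records: Sequence[MORecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("event_id\tproduct_name\troute\n")
        for r in records:
            fh.write(f"{r.event_id}\t{r.product_name}\t{r.route}\n")


def _write_docs(documents: Sequence[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in documents:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "event_id": d.event_id,
                        "patient_id": d.patient_id,
                        "text": d.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def _write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in gt.mentions:
            fh.write(json.dumps(asdict(m), ensure_ascii=False) + "\n")
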