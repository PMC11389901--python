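"""Adverse-drug-effect signal exploration via co-frequency ratio heatmaps.

For a drug category (e.g., anticancer agents), ``M[i, j]`` counts the
events (hospitalizations) in which both drug *i* and drug *j* were ordered
(diagonal: events ordering drug *i* at all), and ``D[i, j]`` counts how
many of those events also mention the target symptom in their text, as a
positive, concept-linked disease mention.  The element-wise ratio ``D/M``
is the *co-frequency ratio*: among events exposed to a pair, the fraction
whose notes record the symptom.  Cells with fewer than ``min_events``
exposed events are masked rather than shown as unstable ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import DictionaryEntry, LinkedMO, NormalizedMention


@dataclass(frozen=True)
class SymptomSpec:
    """A target symptom, selected either by dictionary ADE flag or ICD prefix."""

    name: str
    mode: str  # "ade_flag" | "icd_prefix"
    flag_index: Optional[int] = None  # 1-based, when mode == "ade_flag"
    icd_prefixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "ade_flag":
            if self.flag_index is None or self.icd_prefixes:
                raise ValueError("ade_flag mode requires flag_index and no icd_prefixes")
        elif self.mode == "icd_prefix":
            if not self.icd_prefixes or self.flag_index is not None:
                raise ValueError("icd_prefix mode requires icd_prefixes and no flag_index")
        else:
            raise ValueError(f"unknown symptom mode {self.mode!r}")


def symptom_events(
    normalized_mentions: Iterable[NormalizedMention],
    spec: SymptomSpec,
    disease_dictionary: Sequence[DictionaryEntry] = (),
) -> set[str]:
    """Event IDs whose text carries the target symptom.

    Only positive, linked disease mentions count.  In ``ade_flag`` mode a
    concept is symptom-relevant iff any dictionary entry for it has the
    flag set; in ``icd_prefix`` mode the linked concept must start with one
    of the prefixes.
    """
    if spec.mode == "ade_flag":
        flagged = {
            e.concept_id
            for e in disease_dictionary
            if e.ade_flags[spec.flag_index - 1] == 1
        }

        def hit(concept: str) -> bool:
            return concept in flagged

    else:

        def hit(concept: str) -> bool:
            return any(concept.startswith(p) for p in spec.icd_prefixes)

    return {
        nm.mention.event_id
        for nm in normalized_mentions
        if nm.status == "linked"
        and nm.mention.entity_type == "disease"
        and nm.mention.factuality == "positive"
        and hit(nm.concept_id)
    }


def select_events_with_drugs(
    linked_mo: Iterable[LinkedMO], drug_category: Sequence[str]
) -> dict[str, frozenset[str]]:
    """Per-event sets of category drugs ordered during that event.

    Repeat orders deduplicate (exposure is per hospitalization); events with
    no category drug are excluded.
    """
    category = set(drug_category)
    if not category:
        raise ValueError("drug category is empty")
    sets: dict[str, set[str]] = {}
    for lm in linked_mo:
        if lm.ingredient in category:
            sets.setdefault(lm.event_id, set()).add(lm.ingredient)
    return {e: frozenset(s) for e, s in sets.items()}


def build_M(
    event_drug_sets: Mapping[str, frozenset[str]], drugs: Sequence[str]
) -> np.ndarray:
    """Pair-exposure event counts; diagonal holds single-drug event counts."""
    index = {d: i for i, d in enumerate(drugs)}
    M = np.zeros((len(drugs), len(drugs)), dtype=np.int64)
    for dset in event_drug_sets.values():
        present = sorted(index[d] for d in dset if d in index)
        for a in range(len(present)):
            M[present[a], present[a]] += 1
            for b in range(a + 1, len(present)):
                i, j = present[a], present[b]
                M[i, j] += 1
                M[j, i] += 1
    return M


def build_D(
    event_drug_sets: Mapping[str, frozenset[str]],
    symptom_event_ids: set[str],
    drugs: Sequence[str],
) -> np.ndarray:
    """Like M, restricted to events whose text records the target symptom."""
    sympt = {
        e: dset for e, dset in event_drug_sets.items() if e in symptom_event_ids
    }
    return build_M(sympt, drugs)


def ratio_heatmap(M: np.ndarray, D: np.ndarray, min_events: int = 0) -> np.ndarray:
    """Element-wise D/M; cells with M below max(1, min_events) become NaN."""
    if M.shape != D.shape:
        raise ValueError(f"shape mismatch: M {M.shape} vs D {D.shape}")
    threshold = max(1, min_events)
    ratio = np.full(M.shape, np.nan, dtype=float)
    ok = M >= threshold
    ratio[ok] = D[ok] / M[ok]
    return ratio


def odds_ratio_matrix(
    event_drug_sets: Mapping[str, frozenset[str]],
    symptom_event_ids: set[str],
    drugs: Sequence[str],
) -> np.ndarray:
    """Optional finer-grained view: per-pair odds ratio of symptom given
    pair exposure, over all category events (Haldane-Anscombe 0.5
    correction). Off the default output path."""
    index = {d: i for i, d in enumerate(drugs)}
    n = len(drugs)
    OR = np.full((n, n), np.nan, dtype=float)
    events = list(event_drug_sets)
    exposed = np.zeros((n, n, 2, 2), dtype=np.int64)
    for e in events:
        dset = event_drug_sets[e]
        s = 1 if e in symptom_event_ids else 0
        present = [index[d] for d in dset if d in index]
        flags = np.zeros(n, dtype=bool)
        flags[present] = True
        for i in range(n):
            for j in range(i, n):
                x = 1 if (flags[i] and flags[j]) else 0
                exposed[i, j, x, s] += 1
    for i in range(n):
        for j in range(i, n):
            t = exposed[i, j].astype(float) + 0.5
            val = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
            OR[i, j] = OR[j, i] = val
    return OR


def export_matrices(
    M: np.ndarray,
    D: np.ndarray,
    ratio: np.ndarray,
    drugs: Sequence[str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write M.csv, D.csv, ratio.csv with the drug list as header row/column."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, mat in (("M", M), ("D", D), ("ratio", ratio)):
        df = pd.DataFrame(mat, index=list(drugs), columns=list(drugs))
        path = outdir / f"{name}.csv"
        df.to_csv(path, float_format="%.6g", lineterminator="\n")
        paths[name] = path
    return paths


def plot_heatmap(
    ratio: np.ndarray,
    drugs: Sequence[str],
    path: str | Path,
    title: str = "co-frequency ratio",
) -> None:
    """Render the ratio matrix as a PNG heatmap (masked cells blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(drugs) * 0.5),) * 2)
    masked = np.ma.masked_invalid(ratio)
    im = ax.imshow(masked, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(drugs)), drugs, rotation=90, fontsize=7)
    ax.set_yticks(range(len(drugs)), drugs, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
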