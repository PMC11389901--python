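# Methods

## The unit of analysis

Everything is keyed by the *event*: one hospitalization ending in a
discharge. The structured side contributes one diagnosis (DPC) row per
event — up to 24 ICD-10-coded disease columns, filled left to right — and
zero or more medication-order (MO) rows, each a product name plus a route
(oral or injection). The text side contributes one discharge summary per
event. Alignment keeps only events present on both sides (a DPC row *and* a
document); duplicate DPC rows for one event are rejected rather than
merged, because one DPC row is definitionally one event. When several
documents share an event ID they are concatenated in document-ID order —
a pragmatic choice for multi-summary events, logged so it is visible.

## Extraction and factuality

The built-in tagger is a longest-match-first, left-to-right scan of the
NFKC-normalized text against the union of dictionary surfaces. It is
deterministic by construction: ties on match length break by leftmost
start, then disease before drug. This is deliberately not a model of
clinical language — real deployments run a trained clinical NER tool and
feed its spans through `import_annotations`; the dictionary tagger exists
so the downstream computation is exactly testable.

Factuality follows a crisp rule rather than a classifier: a mention is
negated iff a configured cue string occurs within a window (default 12
characters) after the mention, or immediately before it. Cancelled orders
and ruled-out findings are treated alike — both mean the concept does not
apply to the patient. The window value is a convention shared with the
synthetic generator, which appends cues directly after negated plants, so
ground-truth agreement is exact rather than approximate; on real text the
rule is a coarse NegEx-style heuristic and a trained factuality classifier
should be preferred.

## Normalization

The linking score is the normalized Levenshtein similarity
`100 × (1 − lev(a, b) / max(|a|, |b|))` on NFKC-normalized, trimmed,
Latin-case-folded strings. Max-length normalization makes the score
scale-free, so one fixed cutoff works for short and long vocabularies; the
cutoff is 70, inclusive. Every dictionary surface is scored (edit distances
via edlib; results cached per canonical surface; a score of 100 is only
attainable by string equality, so exact hits short-circuit the scan). Three
outcomes:

* **linked** — best score ≥ 70 and all top-scoring surfaces map to one
  concept;
* **ambiguous** — the top score ties across ≥ 2 distinct concepts; the
  mention is excluded from concept-level analysis instead of guessed;
* **unlinked** — best score < 70.

Floating-point ties use a 1e-12 tolerance; scores here are multiples of
rational numbers with small denominators, so this only guards against
representation noise. MO product names go through the same linker against
the drug dictionary.

## Frequency statistics

Three granularities per source and entity type: *entities* (every
occurrence), *normalized entities* (occurrences that linked), *concepts*
(distinct linked concepts). DPC codes are concept-level by construction
and count as 100 % normalized. Per-event statistics (median/mean/std) are
computed over events with at least one entity of the type — events without
any are reported in the totals gap, not averaged in as zeros. The standard
deviation uses the population denominator *n*: the event set is a census
of the extract, not a sample from it.

Cross-source "common entities" intersect NFKC-canonicalized surface
vocabularies (raw-vs-canonical is not specified anywhere authoritative;
canonical avoids width/case artifacts dominating the count).

The medication scatter fits `y = βx` through the origin per route group
(β = Σxy / Σx², x = text count, y = table count per ingredient, both > 0).
Two R² conventions are reported because they genuinely disagree for
origin-constrained fits: the uncentered form `1 − SSres/Σy²` (bounded by
1, the usual convention for no-intercept models) and the centered form
`1 − SSres/Σ(y−ȳ)²` (can leave [0, 1] when the constraint binds). Reporting
both sidesteps guessing which convention any given published figure used.
Log scaling is a display choice; the fit itself runs on raw counts.

## Cohorts and Venn regions

A disease spec is a list of ICD-10 prefixes (ranges like `E10-14` expand at
load time) plus an optional list of signature ingredients. Prefix matching
implements subcategory inclusion (C50 matches C509). The counting unit is
the patient by default, switchable to events — the two readings are both
defensible and the choice is surfaced rather than hidden. Eight bundled
disease specs (Alzheimer's, breast cancer, diabetes, HIV, hypercholesterolemia,
hypertension, Parkinson's, rheumatism) carry curated ICD lists; their drug
lists are deployment-specific and ship empty, which makes the MO source
yield the empty set until a user supplies them. The 7 exclusive Venn
regions are set differences/intersections; their sum equals the union size
by construction, and tests verify this against per-element enumeration.

## ADE co-frequency ratios

For a drug category, exposure is per hospitalization: repeat orders of one
ingredient deduplicate within an event. `M[i, j]` counts events exposed to
both *i* and *j* (diagonal: exposed to *i* at all — the natural
single-drug reading of a square heatmap, configurable off by simply
ignoring the diagonal). `D` restricts `M` to events whose text carries a
positive, linked mention of the target symptom; symptoms are taken from
text only, since symptom-grade concepts are precisely what the structured
side underrecords. A symptom is selected either by a dictionary ADE-flag
column or by ICD prefix. The ratio `D/M` is undefined (masked, never 0)
where `M` is below `max(1, min_events)`; `min_events` exists because
small-`M` cells produce unstable ratios. An odds-ratio matrix (2×2 per
pair over category events, Haldane–Anscombe corrected) is available as an
optional finer-grained view but is off the default path: the ratio is the
primary screening statistic, not an effect estimate.

## The synthetic generator

The generator emulates the *shape* of a hospital extract, not its
language. Documents are token sequences: uppercase filler words
interleaved with planted mention surfaces, joined by single spaces. Design
constants were chosen once for analytic testability:

* dictionary surfaces are length-10 lowercase strings, so a single random
  character edit gives nls ≈ 90, safely above the cutoff — perturbed
  plants must link;
* out-of-dictionary surfaces are length 4, so nls ≤ 40 against any
  surface — they must not link;
* filler is uppercase and negation cues start with `@`, so neither can
  collide with a surface, and surfaces contain no spaces, so no match can
  cross a token boundary.

Defaults mirror the structure of a cancer-cohort extract: 3.12 events per
patient on average (truncated Poisson, min 1 — every patient has at least
one discharge), 1 + Poisson(1.5) ICD codes per DPC row (capped at 24),
Poisson(5) orders per event with 40 % injections, Poisson(8) planted
mentions per document split evenly between diseases and drugs, and 7
binary ADE-relevance flags per disease entry at 15 % density. Noise
channels (negation rate, perturbation rate, out-of-dictionary rate,
ambiguous-surface fraction) default to 0 and are switched on per study.
`plant_ade_signal` adds two fresh ingredients and one fresh flagged
symptom concept so a planted pair/symptom co-occurrence at a known rate is
recoverable without interference from the background corpus.

What passing tests on this corpus do show: the bookkeeping — spans,
alignment, counting, linking decisions, matrix construction — is exact,
and the fuzzy linker agrees with a brute-force dynamic program. What they
do not show: performance on natural clinical language (morphology,
abbreviation, context-dependent negation), NER quality, or dictionary
coverage of a real vocabulary. On real data, extraction should come from a
trained NER tool via the import adapter, and reported link rates will
reflect dictionary coverage, not the ~(1 − p_ood) rates seen here.

## Numerical and degenerate-input choices

* Empty strings (after canonicalization) have no defined similarity score
  and raise, rather than returning 0 or 100.
* A zero-mention corpus reports a null link rate, not 0 %.
* Zero-exposure ratio cells are NaN (masked), never 0 — absence of
  evidence is not a 0 % symptom rate.
* Origin regression requires ≥ 2 strictly positive pairs per group; the
  per-route wrapper omits unfittable groups instead of failing the run.
* Top-k concept ranking breaks frequency ties by concept ID so output is
  stable across runs and platforms.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical config + seed reproduces
  byte-identical artifacts.

## Problem sizes in the bundled studies

The test suite and `scripts/acceptance.py` run the linker-oracle study on
1,000 query surfaces against a 200-surface dictionary, clean-corpus
recovery on ~500 events, frequency recounts on 50 corpora of ≤ 200 events,
200 random Venn triples, and a planted ADE signal across 220 pair-exposed
events at rate 0.4 (three binomial standard errors ≈ 0.10 at that size).
These sizes give the binomial checks adequate power while keeping a full
run in the seconds-to-minutes range; all scale linearly if larger studies
are wanted.

## Known limitations

* The cue-window negation rule has no notion of scope or conjunction; it
  is a testing convention and a fallback, not a clinical factuality model.
* Ambiguous mentions are excluded, not disambiguated; corpora with highly
  ambiguous vocabularies will undercount normalized entities.
* The linker scans every dictionary surface per unique mention surface;
  for dictionaries beyond ~10⁵ surfaces a candidate index (n-gram or
  length filtering) would be needed.
* Multi-document events are concatenated, which shifts span offsets
  relative to the original files for all but the first document.
* No temporal ordering is enforced between drug exposure and symptom
  mention within an event; the co-frequency ratio is a screening signal,
  not a causal estimate.
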