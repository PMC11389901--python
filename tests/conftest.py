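from __future__ import annotations

import pytest
from hypothesis import settings

from rwdtextminer import synthetic_ehr as se

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_corpus() -> se.SyntheticCorpus:
    """Corpus with exact dictionary surfaces only: no perturbation,
    no out-of-dictionary mentions, no negation."""
    cfg = se.SynthConfig(
        seed=11,
        n_patients=30,
        p_negated=0.0,
        p_surface_perturb=0.0,
        p_out_of_dictionary=0.0,
    )
    return se.generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus() -> se.SyntheticCorpus:
    """Corpus exercising every noise channel at once."""
    cfg = se.SynthConfig(
        seed=23,
        n_patients=30,
        p_negated=0.3,
        p_surface_perturb=0.15,
        p_out_of_dictionary=0.2,
        ambiguous_surface_fraction=0.1,
    )
    return se.generate_corpus(cfg)
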