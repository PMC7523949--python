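import numpy as np
import pytest

from shoreline import (
    CohortSpec,
    LandscapeSpec,
    generate_amplicon,
    generate_landscape,
    generate_subjects,
)


@pytest.fixture(scope="session")
def planted_landscape():
    """Default planted-island locus with its truth record."""
    spec = LandscapeSpec(seed=3)
    seq, truth = generate_landscape(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def small_amplicon():
    """5-CpG synthetic shore amplicon for alignment tests."""
    return generate_amplicon(n_cpgs=5, spacing=25, seed=11, amplicon_id="ampA")


@pytest.fixture(scope="session")
def cohort_default():
    """One full synthetic cohort at the study's default conditions."""
    return generate_subjects(CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
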