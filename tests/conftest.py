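import numpy as np
import pytest

from lungdose import (
    ParticleSpec,
    assemble_lung,
    load_subject,
    make_waveform,
    simulate_breath,
)

SUBJECT_LABELS = ("infant", "child", "adult")


@pytest.fixture(scope="session")
def subjects():
    return {label: load_subject(label) for label in SUBJECT_LABELS}


@pytest.fixture(scope="session")
def lungs(subjects):
    return {label: assemble_lung(s) for label, s in subjects.items()}


@pytest.fixture(scope="session")
def run_cache(subjects, lungs):
    """Memoized full-breath simulations keyed by (subject, d_p, cells/gen)."""
    cache = {}

    def run(label, d_p, cpg=2):
        key = (label, d_p, cpg)
        if key not in cache:
            s = subjects[label]
            cache[key] = simulate_breath(
                lungs[label],
                make_waveform(s.TV, s.RR),
                ParticleSpec(d_p),
                cells_per_generation=cpg,
            )
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
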