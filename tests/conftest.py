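"""Shared fixtures.

The heavyweight 20-patient evaluation cohort is generated once per session
and reused by the acceptance, classification, and statistics tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from afmi.phantom import PhantomSpec, default_cohort_spec, generate_cohort
from afmi.preprocess import preprocess_stack
from afmi.signatures import cohort_relative_signatures, extract_signatures


@pytest.fixture(scope="session")
def default_cohort():
    """Default 20-patient evaluation cohort (seed 1), degraded stacks."""
    return generate_cohort(default_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def default_rss(default_cohort):
    """Preprocessed sector signature table with rss columns, all patients."""
    frames = []
    for stack in default_cohort:
        corrected, _ = preprocess_stack(stack)
        frames.append(extract_signatures(corrected))
    refs, df, excluded = cohort_relative_signatures(
        pd.concat(frames, ignore_index=True)
    )
    assert not excluded
    return refs, df


@pytest.fixture(scope="session")
def small_patient():
    """One default-noise patient at 256x256 (seed 3)."""
    from afmi.phantom import generate_patient

    spec = PhantomSpec(n_patients=1, image_shape=(256, 256), seed=3)
    return generate_patient(spec, np.random.SeedSequence(3), "P01")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
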