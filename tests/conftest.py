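import numpy as np
import pandas as pd
import pytest

import snfomics as sf
from snfomics.preprocess import standard_normalize


@pytest.fixture(scope="session")
def two_modal_cohort():
    """Moderate-SNR 3-subtype cohort, two informative modalities."""
    spec = sf.CohortSpec(
        n_samples=90,
        n_subtypes_true=3,
        modalities=(
            sf.ModalitySpec("a", 40, signal_strength=1.0),
            sf.ModalitySpec("b", 30, signal_strength=1.0),
        ),
        outcome_effects={"amyloid": 2.0, "cognition_slope": 0.1},
        seed=7,
    )
    return sf.generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_two_modal(two_modal_cohort):
    return [standard_normalize(m) for m in two_modal_cohort.matrices.values()]


@pytest.fixture(scope="session")
def fused_two_modal(processed_two_modal):
    affs = [sf.affinity_from_matrix(m, sf.SNFParams()) for m in processed_two_modal]
    return sf.fuse(affs, affs[0].params), affs


def block_affinity(sizes, within=1.0, between=0.0):
    """Exact block-diagonal affinity with constant within-block weight."""
    n = sum(sizes)
    W = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        W[start : start + s, start : start + s] = within
        start += s
    ids = [f"S{i:03d}" for i in range(n)]
    return sf.AffinityMatrix(sample_ids=ids, W=W, params=sf.SNFParams(K=min(5, n - 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
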