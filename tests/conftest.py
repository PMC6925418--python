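import numpy as np
import pytest

import voiradiomics as vr

#: small extraction grid used throughout the suite where the full 48-combination
#: grid would add nothing but runtime
REDUCED_GRID = vr.ExtractionGrid(
    scales_mm=(1.0, 3.0), quant_algorithms=("equal", "uniform"), gray_levels=(8, 32)
)

#: reduced-replicate selection settings for pipeline-level tests
def reduced_selection(seed: int, mode: str = "univariate") -> vr.SelectionConfig:
    return vr.SelectionConfig(
        shortlist_size=100, final_size=20, n_bootstrap=200, ranking_mode=mode, seed=seed
    )


@pytest.fixture(scope="session")
def small_case():
    """One deterministic synthetic case (baseline mask, anisotropic spacing)."""
    cases = vr.generate_cohort(vr.CohortSpec(n_per_class=1, seed=42))
    return cases[0]


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 12-subject cohort with a strong intensity effect, for fast
    pipeline-level checks."""
    spec = vr.CohortSpec(n_per_class=6, intensity_effect=4.0, seed=7,
                         validation_fraction=0.34)
    return vr.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
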