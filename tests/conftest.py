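import numpy as np
import pytest

from coimpute import (
    DiseaseModel,
    HMMParams,
    PanelSpec,
    ascertain_cases,
    generate_reference_panel,
)


@pytest.fixture
def null_model():
    """Disease model with no genetic, environmental or interaction effect."""
    return DiseaseModel(baseline_odds=1e-3, maf=0.25, p_exposure=0.1)


@pytest.fixture
def main_effect_model():
    """Low-MAF SNP with a genetic main effect (the problematic regime)."""
    return DiseaseModel(
        baseline_odds=1e-3, or_g=2.0, or_e=1.5, maf=0.03, p_exposure=0.1
    )


@pytest.fixture
def small_panel():
    """600-haplotype panel, target MAF 0.3, nine tags spanning r2 0.1-0.9."""
    tags = tuple(
        (r2, 0.3, 10_000 * (i + 1)) for i, r2 in enumerate((0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1))
    )
    spec = PanelSpec(
        n_haplotypes=600, target_maf=0.3, tag_snps=tags, seed=42, target_position=100_000
    )
    return generate_reference_panel(spec)


@pytest.fixture
def small_cases(small_panel, null_model):
    model = null_model.replace(maf=0.3)
    return ascertain_cases(small_panel, model, 300, np.random.default_rng(7))


@pytest.fixture
def tight_hmm():
    """Near-deterministic copying parameters for limit checks."""
    return HMMParams(switch_prob=1e-4, mismatch_prob=1e-4)
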