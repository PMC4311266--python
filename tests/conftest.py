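import numpy as np
import pytest

from glyrare.simulate import (
    EffectSpec,
    FamilySpec,
    HaplotypePool,
    build_g6pc2_like_pool,
    draw_cohort,
)


@pytest.fixture(scope="session")
def g6pc2_pool():
    return build_g6pc2_like_pool(seed=1)


@pytest.fixture(scope="session")
def small_pool():
    """3 variants, 4 haplotypes; each alternate allele on its own haplotype."""
    return HaplotypePool(
        variant_labels=("v1", "v2", "v3"),
        haplotype_alleles=("000", "100", "010", "001"),
        frequencies=np.array([0.5, 0.25, 0.15, 0.1]),
    )


@pytest.fixture(scope="session")
def null_effects_small():
    return EffectSpec(haplotype_effects=np.zeros(4), residual_sd=0.8)


@pytest.fixture(scope="session")
def sibship_spec():
    return FamilySpec({1: 0.5, 2: 0.3, 3: 0.2})


@pytest.fixture(scope="session")
def unrelated_cohort(small_pool, null_effects_small):
    """n=1000 unrelated cohort under the null (quantitative)."""
    return draw_cohort(small_pool, FamilySpec(), null_effects_small, 1000, seed=11)
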