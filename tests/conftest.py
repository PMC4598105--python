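import numpy as np
import pytest

from nichelumps.ratio_pipeline import OccurrenceSample
from nichelumps.synthetic_data import (
    LumpyPoolSpec,
    SamplingSpec,
    generate_cooccurrence_samples,
    generate_lumpy_pool,
)


@pytest.fixture
def three_lump_spec() -> LumpyPoolSpec:
    """Default lumpy pool: 3 lumps spaced by 1.35, mild within-lump noise."""
    return LumpyPoolSpec(
        n_lumps=3,
        base_length=2.0,
        spacing_ratio=1.35,
        within_lump_sd=0.03,
        species_per_lump=15,
        seed=9,
    )


@pytest.fixture
def three_lump_samples(three_lump_spec):
    """500 co-occurrence samples of fixed richness 4 from the 3-lump pool."""
    pool = generate_lumpy_pool(three_lump_spec)
    return generate_cooccurrence_samples(
        pool, SamplingSpec(n_samples=500, richness_law=("fixed", 4), seed=9)
    )


def make_sample(sample_id: str, lengths, prefix: str = "sp") -> OccurrenceSample:
    return OccurrenceSample(
        sample_id,
        tuple((f"{prefix}{i}", float(v)) for i, v in enumerate(lengths)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
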