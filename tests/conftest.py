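import numpy as np
import pytest

from ith_biomarker.model import Effect, VariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_variant():
    def _make(
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        ref_count=60,
        alt_count=40,
        gene="TP53",
        effect=Effect.MISSENSE,
        sample_id="P001",
    ):
        return VariantCall(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            ref_count=ref_count,
            alt_count=alt_count,
            gene=gene,
            effect=effect,
            sample_id=sample_id,
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient synthetic cohort shared by the slower integration tests."""
    from ith_biomarker.simulate import SyntheticCohortConfig, simulate_cohort

    return simulate_cohort(SyntheticCohortConfig(n_patients=12, seed=7))
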