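import numpy as np
import pytest

from mrkit import HarmonizedSet, SummaryStatRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-8, **kw):
    return SummaryStatRecord(
        snp_id=snp_id,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        **kw,
    )


@pytest.fixture
def three_snp_set():
    """The hand-checkable 3-instrument set: IVW slope 140/300, Q = 2/3."""
    return HarmonizedSet.from_arrays(
        gamma_hat=[1.0, 2.0, 3.0],
        sigma_x=[0.05, 0.05, 0.05],
        Gamma_hat=[0.4, 1.0, 1.5],
        sigma_y=[0.1, 0.2, 0.3],
    )


def random_hset(rng, L=10, theta=0.5):
    """A generic well-behaved harmonized set for property checks."""
    gamma = rng.uniform(0.5, 2.0, L)
    sx = rng.uniform(0.01, 0.05, L)
    sy = rng.uniform(0.05, 0.2, L)
    Gamma = theta * gamma + rng.normal(0, sy)
    return HarmonizedSet.from_arrays(gamma, sx, Gamma, sy)
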