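import numpy as np
import pytest

from protarget_mr.sumstats import HarmonizedPair, VariantAssociation


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=None,
    n=10_000,
    **kw,
):
    """Association-record factory with sensible defaults; p derived from z
    unless given."""
    if pvalue is None:
        from scipy import stats

        z = beta / se if se > 0 else 0.0
        pvalue = float(max(2 * stats.norm.sf(abs(z)), 1e-300))
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n, **kw,
    )


def make_pair(variant_id="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.02,
              se_out=0.01, n_exp=10_000, n_out=10_000):
    return HarmonizedPair(
        variant_id=variant_id, effect_allele="A",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf_exp=0.3, eaf_out=0.3, n_exp=n_exp, n_out=n_out,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def pair_factory():
    return make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
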