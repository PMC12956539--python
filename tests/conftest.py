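import numpy as np
import pytest

from sceqtlmr import ExposureDataset, HarmonizedSet, VariantAssociation


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_assoc(variant_id="rs1", beta=0.3, se=0.03, pvalue=1e-8, eaf=0.3,
               effect_allele="A", other_allele="G", pos=100, n=982,
               chrom="1"):
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele, eaf=eaf,
        beta=beta, se=se, pvalue=pvalue, n=n)


def make_harmonized(beta_exp, beta_out, se_exp=None, se_out=None, ld=None,
                    gene="G1", cell_type="CD4 NC", n_exp=982, n_out=50_000):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    k = beta_exp.size
    se_exp = np.full(k, 0.03) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(k, 0.01) if se_out is None else np.asarray(se_out, float)
    return HarmonizedSet(
        gene=gene, cell_type=cell_type,
        variant_ids=tuple(f"rs{i}" for i in range(k)),
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        n_exp=n_exp, n_out=n_out, ld=ld)


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture
def assoc_factory():
    return make_assoc


@pytest.fixture
def random_harmonized(rng):
    """An 8-instrument harmonized set with heterogeneous SEs."""
    k = 8
    return make_harmonized(
        beta_exp=rng.normal(0.3, 0.1, k),
        beta_out=rng.normal(0.1, 0.05, k),
        se_exp=rng.uniform(0.02, 0.05, k),
        se_out=rng.uniform(0.005, 0.02, k))
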