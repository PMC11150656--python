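import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mrbmd.harmonize import HarmonizedPair, harmonize_dataset
from mrbmd.simulate import SimConfig, generate_two_sample_dataset
from mrbmd.summary_io import SummaryStatRecord


def make_record(snp_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G",
                beta=0.1, se=0.02, pval=1e-9, n=18_340, eaf=0.3):
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=ea, other_allele=oa, beta=beta,
                             se=se, pval=pval, n=n, eaf=eaf)


def make_pair(snp_id="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.05,
              se_out=0.02, pval_exp=1e-9, n_exp=18_340, n_out=32_735):
    return HarmonizedPair(snp_id=snp_id, beta_exp=beta_exp, se_exp=se_exp,
                          beta_out=beta_out, se_out=se_out, pval_exp=pval_exp,
                          n_exp=n_exp, n_out=n_out)


def pairs_from_ratios(ratios, ratio_ses, beta_exp=1.0, se_exp=1e-6):
    """Harmonized pairs whose Wald ratios and ratio SEs equal the given
    values exactly (beta_exp = 1 so beta_out = ratio, se_out = ratio SE)."""
    return [
        make_pair(snp_id=f"rs{i+1}", beta_exp=beta_exp, se_exp=se_exp,
                  beta_out=r * beta_exp, se_out=s * abs(beta_exp))
        for i, (r, s) in enumerate(zip(ratios, ratio_ses))
    ]


def simulated_pairs(seed=0, **overrides):
    cfg = SimConfig(seed=seed, **overrides)
    exp, out, truth = generate_two_sample_dataset(cfg)
    pairs, _ = harmonize_dataset(exp, out)
    return pairs, truth


@pytest.fixture
def clean_pairs():
    """30 strong-instrument pairs, causal effect 0.1, no pleiotropy."""
    pairs, _ = simulated_pairs(seed=7)
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
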