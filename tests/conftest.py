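"""Shared fixtures: lightweight builders for records and harmonized pairs."""

from __future__ import annotations

import numpy as np
import pytest

from mrpath.gwas_io import VariantAssociation
from mrpath.harmonize import HarmonizedPair


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-6,
    eaf=0.3,
    n=10_000.0,
) -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_pair(
    snp_id="rs1",
    chrom="1",
    pos=1_000_000,
    beta_exp=0.1,
    se_exp=0.01,
    beta_out=0.05,
    se_out=0.01,
    pval_exp=1e-8,
    eaf_exp=0.3,
) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        pval_exp=pval_exp, pval_out=0.5, eaf_exp=eaf_exp, eaf_out=eaf_exp,
        action="kept",
    )


def make_pairs(beta_exp, beta_out, se_out, se_exp=None, pvals=None) -> list[HarmonizedPair]:
    """Vector-in, list-of-pairs-out builder for estimator tests."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    se_exp = (
        np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
        if se_exp is not None
        else np.full_like(beta_exp, 0.01)
    )
    pvals = pvals if pvals is not None else [1e-8] * len(beta_exp)
    return [
        make_pair(
            snp_id=f"rs{i + 1}",
            pos=1_000_000 + i * 10_000_000,
            beta_exp=float(beta_exp[i]),
            se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
            pval_exp=float(pvals[i]),
        )
        for i in range(len(beta_exp))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1)
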