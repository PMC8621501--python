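"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lipidmr import HarmonizedVariant, SummaryStats, VariantAssociation
from scipy import stats as sps


def make_variant(
    snp_id: str = "rs1",
    chrom: str = "1",
    pos: int = 1000,
    effect_allele: str = "A",
    other_allele: str = "G",
    eaf: float | None = 0.3,
    beta: float = 0.1,
    se: float = 0.01,
    pvalue: float | None = None,
    n: float = 100_000,
) -> VariantAssociation:
    if pvalue is None:
        pvalue = float(np.clip(2 * sps.norm.sf(abs(beta) / se), 5e-324, 1.0))
    return VariantAssociation(
        snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n
    )


def make_pair(
    snp_id: str = "rs1",
    beta_exp: float = 0.1,
    se_exp: float = 0.01,
    beta_out: float = 0.05,
    se_out: float = 0.02,
    **kwargs,
) -> HarmonizedVariant:
    return HarmonizedVariant(
        snp_id=snp_id,
        effect_allele=kwargs.get("effect_allele", "A"),
        other_allele=kwargs.get("other_allele", "G"),
        beta_exp=beta_exp,
        se_exp=se_exp,
        p_exp=float(2 * sps.norm.sf(abs(beta_exp) / se_exp)),
        eaf_exp=kwargs.get("eaf_exp", 0.3),
        beta_out=beta_out,
        se_out=se_out,
        p_out=float(2 * sps.norm.sf(abs(beta_out) / se_out)),
        eaf_out=kwargs.get("eaf_out", 0.3),
        palindromic=False,
        flipped=False,
        chrom=kwargs.get("chrom", "1"),
        pos=kwargs.get("pos", 1000),
    )


def random_pairs(rng: np.random.Generator, n: int) -> list[HarmonizedVariant]:
    """Random harmonized pairs with realistic magnitudes (bx bounded away
    from zero so Wald ratios stay finite)."""
    bx = rng.uniform(0.03, 0.15, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.002, 0.01, n)
    by = rng.normal(0.0, 0.05, n)
    sy = rng.uniform(0.01, 0.05, n)
    return [
        make_pair(f"rs{i + 1}", bx[i], sx[i], by[i], sy[i], pos=1000 * (i + 1))
        for i in range(n)
    ]


def stats_from_records(records, trait_name="trait", trait_type="continuous"):
    return SummaryStats(trait_name, trait_type, list(records))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
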