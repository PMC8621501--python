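"""Cis drug-target Mendelian randomization.

Builds instruments from variants inside a flanked gene window (default
+/- 100 kb) that are genome-wide significant for the lipid trait the
target modulates, clumps them with the looser cis preset (r-squared < 0.2
within 250 kb), orients every variant so the reported exposure effect is a
1-SD *reduction* in the lipid (the pharmacological "inhibition" frame),
and estimates the target-proxied effect on the outcome — IVW (random
effects) when two or more instruments survive, the Wald ratio for one.

Because the cis clumping threshold leaves residual LD among instruments,
the default independent-weights IVW standard error is anti-conservative
in that regime; an LD-aware generalized least-squares estimator is
available behind the ``ld_correlation`` argument and coincides with the
fixed-effects IVW when the LD matrix is the identity.

Gene coordinates (GRCh37) for the seven canonical lipid-lowering targets
ship as an editable TSV fixture; no annotation service is queried.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MethodError, MREstimate, _estimate, _normal_p, ivw, wald_ratio
from .instruments import clump
from .sumstats import (
    HarmonizedVariant,
    InputError,
    LDMatrix,
    SummaryStats,
    harmonize,
)

__all__ = [
    "GeneRegion",
    "TargetInstrumentSet",
    "load_gene_regions",
    "extract_cis",
    "build_target_set",
    "target_mr",
]

DEFAULT_FLANK_BP = 100_000
DEFAULT_CIS_CLUMP_R2 = 0.2
DEFAULT_CIS_CLUMP_WINDOW_BP = 250_000


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene with 1-based inclusive bounds and a flank."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"{self.gene_symbol}: start > end")
        if self.flank_bp < 0:
            raise InputError(f"{self.gene_symbol}: flank_bp must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank_bp), self.end + self.flank_bp


@dataclass
class TargetInstrumentSet:
    """Harmonized, trait-lowering-oriented instruments for one target."""

    gene: GeneRegion
    lipid_trait: str
    variants: list[HarmonizedVariant]
    orientation: str = "lowering"


def load_gene_regions(
    path: str | Path | None = None, flank_bp: int = DEFAULT_FLANK_BP
) -> dict[str, tuple[GeneRegion, str]]:
    """Load the gene-region table (packaged fixture by default).

    Returns ``{gene_symbol: (GeneRegion, lipid_trait)}``; the trait column
    says which lipid fraction the target modulates (LDL-C or TG).
    """
    if path is None:
        with resources.as_file(
            resources.files("lipidmr").joinpath("data/drug_target_genes.tsv")
        ) as p:
            frame = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, tuple[GeneRegion, str]] = {}
    for row in frame.itertuples(index=False):
        out[row.gene_symbol] = (
            GeneRegion(row.gene_symbol, str(row.chrom), int(row.start), int(row.end), flank_bp),
            getattr(row, "lipid_trait", "LDL-C"),
        )
    return out


def extract_cis(
    stats: SummaryStats,
    region: GeneRegion,
    p_threshold: float,
    ld: LDMatrix,
    clump_r2: float = DEFAULT_CIS_CLUMP_R2,
    clump_window_bp: int = DEFAULT_CIS_CLUMP_WINDOW_BP,
) -> SummaryStats:
    """Genome-wide-significant variants inside the flanked gene window,
    clumped with the cis preset. Output is position-sorted; an empty
    window yields an empty container, not an error."""
    lo, hi = region.window
    in_window = [
        r
        for r in stats.records
        if r.chrom == region.chrom and lo <= r.pos <= hi and r.pvalue < p_threshold
    ]
    windowed = SummaryStats(stats.trait_name, stats.trait_type, in_window)
    if not in_window:
        return windowed
    clumped = clump(windowed, ld, clump_r2, clump_window_bp)
    ordered = sorted(clumped.records, key=lambda r: r.pos)
    return SummaryStats(stats.trait_name, stats.trait_type, ordered)


def _orient_lowering(v: HarmonizedVariant) -> HarmonizedVariant:
    """Re-express a pair per 1-SD lipid *reduction*.

    Two steps rolled into one: switch to the lipid-lowering allele when the
    effect allele raises the lipid (negate both betas, swap allele labels,
    complement EAFs), then flip the exposure scale so the positive
    direction means lowering. Net effect: ``beta_exp -> |beta_exp|``,
    ``beta_out -> -sign(beta_exp) * beta_out``, so the Wald ratio changes
    sign relative to the per-SD-increase frame.
    """
    if v.beta_exp < 0:
        # effect allele already lowers the lipid; rescale exposure only
        return replace(v, beta_exp=-v.beta_exp, beta_out=v.beta_out)
    return replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta_exp=v.beta_exp,
        eaf_exp=None if v.eaf_exp is None else 1.0 - v.eaf_exp,
        beta_out=-v.beta_out,
        eaf_out=None if v.eaf_out is None else 1.0 - v.eaf_out,
        flipped=not v.flipped,
    )


def build_target_set(
    region: GeneRegion,
    lipid_trait: str,
    cis_stats: SummaryStats,
    outcome: SummaryStats,
    palindromic_policy: str = "infer_by_eaf",
) -> TargetInstrumentSet:
    """Harmonize cis instruments with the outcome and orient them so the
    exposure effect is per 1-SD lipid lowering."""
    pairs = harmonize(cis_stats, outcome, palindromic_policy)
    oriented = [_orient_lowering(v) for v in pairs]
    return TargetInstrumentSet(region, lipid_trait, oriented, "lowering")


def target_mr(
    target: TargetInstrumentSet,
    ld_correlation: np.ndarray | None = None,
) -> MREstimate:
    """Target-proxied causal estimate per 1-SD lipid lowering.

    Uses random-effects IVW for two or more instruments and the Wald ratio
    for a single one. With ``ld_correlation`` (signed correlation matrix
    aligned to the variant order) the estimate and SE come from
    generalized weighted least squares, which accounts for residual LD
    among cis instruments.
    """
    variants = target.variants
    if not variants:
        raise MethodError(f"{target.gene.gene_symbol}: no harmonized instruments")
    if ld_correlation is not None and len(variants) >= 2:
        bx = np.array([v.beta_exp for v in variants])
        by = np.array([v.beta_out for v in variants])
        sy = np.array([v.se_out for v in variants])
        R = np.asarray(ld_correlation, dtype=float)
        omega = R * np.outer(sy, sy)
        omega_inv = np.linalg.inv(omega)
        denom = float(bx @ omega_inv @ bx)
        beta = float(bx @ omega_inv @ by) / denom
        se = float(np.sqrt(1.0 / denom))
        return _estimate("ivw_gls", beta, se, _normal_p(beta, se), len(variants))
    if len(variants) == 1:
        return wald_ratio(variants[0])
    est, _ = ivw(variants, "random")
    return est
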