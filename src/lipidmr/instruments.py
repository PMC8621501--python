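"""Instrument selection: significance filtering, greedy LD clumping,
outcome-association exclusion, per-variant F statistics and variance
explained.

The selection pipeline applies, in order: (1) exposure genome-wide
significance, (2) greedy LD clumping, (3) harmonization with the outcome,
(4) exclusion of variants genome-wide significant for the outcome, and
(5) the per-variant weak-instrument F filter. Every exclusion is recorded
with its stage and reason so instrument counts per filter are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import (
    HarmonizedVariant,
    InputError,
    LDMatrix,
    SummaryStats,
    VariantAssociation,
    harmonize_detailed,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "InstrumentSet",
    "clump",
    "f_statistic",
    "variance_explained",
    "select_instruments",
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the instrument-selection pipeline.

    The default clump preset is the strict one (r-squared < 0.001 within
    10 Mb); the looser cis preset (r-squared < 0.2 within 250 kb) is used
    for drug-target regions. Both are plain knobs.
    """

    p_exp_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    p_out_threshold: float = GENOME_WIDE_P
    f_threshold: float = 10.0
    palindromic_policy: str = "infer_by_eaf"


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with audit trail."""

    exposure_name: str
    variants: list[HarmonizedVariant]
    f_stats: np.ndarray
    r2_explained: float
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)
    # each log entry: (snp_id, stage, reason)

    def __len__(self) -> int:
        return len(self.variants)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.selection_log, columns=["snp_id", "stage", "reason"]
        )


def f_statistic(v: VariantAssociation | HarmonizedVariant) -> float:
    """Per-variant instrument-strength F statistic, ``(beta/se)^2``."""
    if isinstance(v, HarmonizedVariant):
        beta, se = v.beta_exp, v.se_exp
    else:
        beta, se = v.beta, v.se
    if se <= 0:
        raise InputError("se must be positive")
    return (beta / se) ** 2


def variance_explained(instruments: Iterable[VariantAssociation]) -> float:
    """Total exposure variance explained, ``sum 2 p (1-p) beta^2``, for a
    standardized (unit-variance) exposure."""
    total = 0.0
    for v in instruments:
        if isinstance(v, HarmonizedVariant):
            eaf, beta = v.eaf_exp, v.beta_exp
        else:
            eaf, beta = v.eaf, v.beta
        if eaf is None:
            raise InputError(f"{v.snp_id}: missing eaf")
        total += 2.0 * eaf * (1.0 - eaf) * beta**2
    return total


def clump(
    stats: SummaryStats,
    ld: LDMatrix,
    r2_threshold: float,
    window_bp: int,
    removed_log: list[tuple[str, str]] | None = None,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value (ties
    broken by smaller position, then lexicographic snp_id), retain it as an
    index variant, and remove every remaining variant with
    ``r2 >= r2_threshold`` *and* distance ``<= window_bp`` from it. The
    returned container preserves the input ordering of retained variants.
    """
    if r2_threshold <= 0 or window_bp <= 0:
        raise InputError("clump thresholds must be positive")
    missing = [r.snp_id for r in stats.records if not ld.contains(r.snp_id)]
    if missing:
        raise InputError(f"variants missing from LD matrix: {missing}")

    order = sorted(stats.records, key=lambda r: (r.pvalue, r.pos, r.snp_id))
    alive = {r.snp_id for r in stats.records}
    kept: set[str] = set()
    for idx_variant in order:
        sid = idx_variant.snp_id
        if sid not in alive:
            continue
        kept.add(sid)
        alive.discard(sid)
        i = ld.index(sid)
        for other in list(alive):
            j = ld.index(other)
            dist = abs(int(ld.pos[j]) - int(idx_variant.pos))
            if ld.r2[i, j] >= r2_threshold and dist <= window_bp:
                alive.discard(other)
                if removed_log is not None:
                    removed_log.append((other, f"clumped_by:{sid}"))
    return stats.subset(kept)


def select_instruments(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    params: SelectionParams = SelectionParams(),
) -> InstrumentSet:
    """Run the full instrument-selection pipeline (see module docstring).

    An empty surviving set is returned as an empty :class:`InstrumentSet`
    (with the full exclusion log), never raised.
    """
    log: list[tuple[str, str, str]] = []

    significant = []
    for r in exposure.records:
        if r.pvalue < params.p_exp_threshold:
            significant.append(r)
        else:
            log.append((r.snp_id, "exposure_p", "p_above_threshold"))
    sig_stats = SummaryStats(exposure.trait_name, exposure.trait_type, significant)
    if not significant:
        logger.warning("%s: no genome-wide-significant variants", exposure.trait_name)
        return InstrumentSet(exposure.trait_name, [], np.array([]), 0.0, log)

    clump_removed: list[tuple[str, str]] = []
    clumped = clump(
        sig_stats, ld, params.clump_r2, params.clump_window_bp, clump_removed
    )
    log.extend((sid, "clump", reason) for sid, reason in clump_removed)

    try:
        pairs, harm_excluded = harmonize_detailed(
            clumped, outcome, params.palindromic_policy
        )
    except InputError:
        log.extend((r.snp_id, "harmonize", "not_in_outcome") for r in clumped)
        return InstrumentSet(exposure.trait_name, [], np.array([]), 0.0, log)
    harmonized_ids = {p.snp_id for p in pairs}
    for r in clumped:
        if r.snp_id not in harmonized_ids:
            reason = dict(harm_excluded).get(r.snp_id, "not_in_outcome")
            log.append((r.snp_id, "harmonize", reason))

    retained: list[HarmonizedVariant] = []
    for p in pairs:
        if p.p_out < params.p_out_threshold:
            log.append((p.snp_id, "outcome_p", "outcome_associated"))
        elif f_statistic(p) <= params.f_threshold:
            log.append((p.snp_id, "f_filter", "weak_instrument"))
        else:
            retained.append(p)

    f_stats = np.array([f_statistic(p) for p in retained])
    try:
        r2 = variance_explained(retained)
    except InputError:
        r2 = float("nan")
    logger.info(
        "%s: retained %d instrument(s) of %d input variants",
        exposure.trait_name,
        len(retained),
        len(exposure),
    )
    return InstrumentSet(exposure.trait_name, retained, f_stats, r2, log)
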