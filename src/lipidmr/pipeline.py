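"""End-to-end orchestration of the analysis grid.

Runs exposure x outcome x cohort cells: instrument selection, MR-PRESSO
sensitivity, all applicable estimators, cross-cohort meta-analysis and the
Bonferroni classification, emitting tidy forest-plot tables and a
provenance log. Cell failures are recorded in an error manifest and the
grid continues; partial results are valid output.

Every numeric constant of the analysis (significance thresholds, clumping
presets, the weak-instrument bound, heterogeneity gates, the Bonferroni
grid) lives in :class:`AnalysisConfig` with its conventional default and
can be overridden from a YAML file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .drug_target import GeneRegion, build_target_set, extract_cis, target_mr
from .estimators import (
    MethodError,
    MREstimate,
    egger,
    ivw,
    weighted_median,
    weighted_mode,
)
from .instruments import InstrumentSet, SelectionParams, select_instruments
from .meta import bonferroni_threshold, classify_association, meta
from .presso import DegenerateCorrectionError, presso
from .sumstats import (
    InputError,
    LDMatrix,
    SummaryStats,
    read_ld,
    read_sumstats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ForestRow",
    "GridResult",
    "analyze_pair",
    "run_trait_grid",
    "run_target_grid",
    "render_forest",
    "FOREST_COLUMNS",
]

FOREST_COLUMNS = (
    "exposure",
    "outcome",
    "cohort",
    "method",
    "or_",
    "ci_low",
    "ci_high",
    "pvalue",
    "n_snps",
    "classification",
)


@dataclass(frozen=True)
class ForestRow:
    """One cell of the forest table: one method on one exposure-outcome
    pair in one cohort (or the pooled 'meta' pseudo-cohort)."""

    exposure: str
    outcome: str
    cohort: str
    method: str
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    classification: str


@dataclass
class AnalysisConfig:
    """Configuration of the full analysis grid.

    ``exposures`` maps names to summary-stat paths; ``outcomes`` is a list
    of ``(name, path, cohort)``. ``primary`` picks whether the raw or the
    PRESSO-corrected IVW feeds the forest table when outliers are found
    (both are always emitted).
    """

    exposures: list[tuple[str, str]] = field(default_factory=list)
    outcomes: list[tuple[str, str, str]] = field(default_factory=list)
    ld_path: str | None = None
    selection: SelectionParams = field(default_factory=SelectionParams)
    n_boot: int = 1000
    phi: float = 1.0
    seed: int = 0
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    het_p: float = 0.1
    het_i2: float = 50.0
    alpha: float = 0.05
    n_exposures_grid: int | None = None
    n_outcomes_grid: int | None = None
    primary: str = "raw"
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel = SelectionParams(**raw.pop("selection", {}))
        exposures = [tuple(e) for e in raw.pop("exposures", [])]
        outcomes = [tuple(o) for o in raw.pop("outcomes", [])]
        return cls(exposures=exposures, outcomes=outcomes, selection=sel, **raw)

    def threshold(self) -> float:
        n_exp = self.n_exposures_grid or max(1, len(self.exposures))
        n_out = self.n_outcomes_grid or max(1, len(self.outcomes))
        if n_exp * n_out == 1:
            return self.alpha / 2  # degenerate 1x1 grid still needs a band
        return bonferroni_threshold(self.alpha, n_exp, n_out)


@dataclass
class GridResult:
    rows: list[ForestRow]
    errors: list[dict]
    provenance: dict = field(default_factory=dict)


@dataclass
class PairAnalysis:
    instruments: InstrumentSet
    estimates: list[MREstimate]
    presso_result: object | None
    primary_ivw: MREstimate | None


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    config: AnalysisConfig,
) -> PairAnalysis:
    """Select instruments and run every estimator applicable to the
    surviving count, plus MR-PRESSO when at least four variants remain."""
    inst = select_instruments(exposure, outcome, ld, config.selection)
    variants = inst.variants
    estimates: list[MREstimate] = []
    presso_result = None
    primary_ivw = None
    if len(variants) >= 2:
        est_ivw, _ = ivw(variants, "random")
        estimates.append(est_ivw)
        primary_ivw = est_ivw
    if len(variants) >= 3:
        est_egger, _ = egger(variants)
        estimates.append(est_egger)
        estimates.append(weighted_median(variants, config.n_boot, config.seed))
        estimates.append(
            weighted_mode(variants, config.phi, config.n_boot, config.seed)
        )
    if len(variants) >= 4:
        try:
            presso_result = presso(
                variants,
                config.presso_n_sim,
                config.presso_outlier_alpha,
                config.seed,
            )
        except DegenerateCorrectionError:
            logger.warning("PRESSO flagged every variant; keeping raw IVW")
        if (
            presso_result is not None
            and presso_result.outlier_ids
            and config.primary == "presso_corrected"
        ):
            keep = [v for v in variants if v.snp_id not in presso_result.outlier_ids]
            if len(keep) >= 2:
                primary_ivw, _ = ivw(keep, "random")
    return PairAnalysis(inst, estimates, presso_result, primary_ivw)


def _row(
    exposure: str, outcome: str, cohort: str, est: MREstimate, threshold: float,
    nominal: float,
) -> ForestRow:
    return ForestRow(
        exposure=exposure,
        outcome=outcome,
        cohort=cohort,
        method=est.method,
        or_=est.or_,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        pvalue=est.pvalue,
        n_snps=est.n_snps,
        classification=classify_association(est.pvalue, threshold, nominal),
    )


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[dict[str, SummaryStats], list[tuple[str, str, SummaryStats]], LDMatrix]:
    if config.ld_path is None:
        raise InputError("config.ld_path is required")
    ld = read_ld(config.ld_path)
    exposures = {
        name: read_sumstats(path, trait_name=name, trait_type="continuous")
        for name, path in config.exposures
    }
    outcomes = [
        (name, cohort, read_sumstats(path, trait_name=name, trait_type="binary"))
        for name, path, cohort in config.outcomes
    ]
    return exposures, outcomes, ld


def run_trait_grid(
    config: AnalysisConfig,
    inputs: tuple | None = None,
) -> GridResult:
    """Run the lipid-trait grid: every exposure x outcome x cohort cell,
    then a per-outcome meta-analysis wherever two or more cohorts cover
    the same outcome.

    ``inputs`` may supply pre-loaded ``(exposures_dict, outcomes_list,
    ld)`` to bypass file reading (used by the simulation harness).
    """
    exposures, outcomes, ld = inputs if inputs is not None else _load_inputs(config)
    threshold = config.threshold()
    rows: list[ForestRow] = []
    errors: list[dict] = []
    ivw_by_cell: dict[tuple[str, str], list[MREstimate]] = {}
    provenance: dict = {"threshold": threshold, "cells": {}}

    for exp_name, exp_stats in exposures.items():
        for out_name, cohort, out_stats in outcomes:
            cell = f"{exp_name}|{out_name}|{cohort}"
            try:
                res = analyze_pair(exp_stats, out_stats, ld, config)
            except (InputError, MethodError) as err:
                errors.append({"cell": cell, "error": str(err)})
                continue
            if not res.estimates:
                errors.append({"cell": cell, "error": "no_instruments"})
                continue
            for est in res.estimates:
                rows.append(
                    _row(exp_name, out_name, cohort, est, threshold, config.alpha)
                )
            if res.primary_ivw is not None:
                ivw_by_cell.setdefault((exp_name, out_name), []).append(
                    res.primary_ivw
                )
            provenance["cells"][cell] = {
                "n_instruments": len(res.instruments),
                "r2_explained": res.instruments.r2_explained,
                "n_excluded": len(res.instruments.selection_log),
                "presso_global_p": (
                    None
                    if res.presso_result is None
                    else res.presso_result.global_p
                ),
                "presso_outliers": (
                    []
                    if res.presso_result is None
                    else res.presso_result.outlier_ids
                ),
            }

    for (exp_name, out_name), ests in ivw_by_cell.items():
        if len(ests) >= 2:
            pooled = meta(ests, config.het_p, config.het_i2)
            rows.append(
                ForestRow(
                    exposure=exp_name,
                    outcome=out_name,
                    cohort=f"meta_{pooled.model_used}",
                    method="ivw_re",
                    or_=pooled.or_,
                    ci_low=pooled.ci_low,
                    ci_high=pooled.ci_high,
                    pvalue=pooled.pooled_p,
                    n_snps=ests[0].n_snps,
                    classification=classify_association(
                        pooled.pooled_p, threshold, config.alpha
                    ),
                )
            )
    result = GridResult(rows, errors, provenance)
    if config.output_dir:
        _write_outputs(result, config)
    return result


def run_target_grid(
    config: AnalysisConfig,
    regions: Sequence[tuple[GeneRegion, str]],
    inputs: tuple | None = None,
) -> GridResult:
    """Run the drug-target grid: cis extraction and lowering-oriented MR
    per target x outcome x cohort, with per-outcome meta-analysis.

    ``regions`` is a sequence of ``(GeneRegion, lipid_trait)``; the lipid
    trait names must match exposure names in the config. Duplicate genes
    are de-duplicated with a warning.
    """
    exposures, outcomes, ld = inputs if inputs is not None else _load_inputs(config)
    threshold = config.threshold()
    rows: list[ForestRow] = []
    errors: list[dict] = []
    ivw_by_cell: dict[tuple[str, str], list[MREstimate]] = {}

    seen: set[str] = set()
    unique_regions = []
    for region, trait in regions:
        if region.gene_symbol in seen:
            logger.warning("duplicate gene %s dropped", region.gene_symbol)
            continue
        seen.add(region.gene_symbol)
        unique_regions.append((region, trait))

    for region, trait in unique_regions:
        if trait not in exposures:
            errors.append(
                {"cell": region.gene_symbol, "error": f"no exposure named {trait!r}"}
            )
            continue
        cis = extract_cis(
            exposures[trait],
            region,
            config.selection.p_exp_threshold,
            ld,
            clump_r2=0.2,
            clump_window_bp=250_000,
        )
        for out_name, cohort, out_stats in outcomes:
            cell = f"{region.gene_symbol}|{out_name}|{cohort}"
            if len(cis) == 0:
                errors.append({"cell": cell, "error": "no_instruments"})
                continue
            try:
                target = build_target_set(
                    region, trait, cis, out_stats, config.selection.palindromic_policy
                )
                est = target_mr(target)
            except (InputError, MethodError) as err:
                errors.append({"cell": cell, "error": str(err)})
                continue
            rows.append(
                _row(region.gene_symbol, out_name, cohort, est, threshold, config.alpha)
            )
            ivw_by_cell.setdefault((region.gene_symbol, out_name), []).append(est)

    for (gene, out_name), ests in ivw_by_cell.items():
        if len(ests) >= 2:
            pooled = meta(ests, config.het_p, config.het_i2)
            rows.append(
                ForestRow(
                    exposure=gene,
                    outcome=out_name,
                    cohort=f"meta_{pooled.model_used}",
                    method="ivw_re",
                    or_=pooled.or_,
                    ci_low=pooled.ci_low,
                    ci_high=pooled.ci_high,
                    pvalue=pooled.pooled_p,
                    n_snps=ests[0].n_snps,
                    classification=classify_association(
                        pooled.pooled_p, threshold, config.alpha
                    ),
                )
            )
    result = GridResult(rows, errors, {"threshold": threshold})
    if config.output_dir:
        _write_outputs(result, config, prefix="targets_")
    return result


def rows_to_frame(rows: Sequence[ForestRow]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in rows], columns=list(FOREST_COLUMNS))
    return frame


def _write_outputs(
    result: GridResult, config: AnalysisConfig, prefix: str = ""
) -> None:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_to_frame(result.rows).to_csv(
        out_dir / f"{prefix}forest.tsv", sep="\t", index=False, float_format="%.12g"
    )
    with open(out_dir / f"{prefix}errors.json", "w") as fh:
        json.dump(result.errors, fh, indent=2, sort_keys=True)
    with open(out_dir / f"{prefix}provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True, default=str)


def render_forest(rows: Sequence[ForestRow], path: str | Path) -> Path:
    """Write the tidy forest TSV at ``path`` and a matching figure beside
    it (same stem, ``.png``): one panel per outcome, log-scaled OR axis,
    95% CI whiskers; intervals crossing OR = 1 are drawn open/grey,
    intervals excluding 1 filled/colored."""
    if not rows:
        raise InputError("no rows to render")
    path = Path(path)
    frame = rows_to_frame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = list(dict.fromkeys(frame["outcome"]))
    fig, axes = plt.subplots(
        len(outcomes), 1, figsize=(7, 2 + 1.2 * len(outcomes)), squeeze=False
    )
    for ax, outcome in zip(axes[:, 0], outcomes):
        sub = frame[frame["outcome"] == outcome].reset_index(drop=True)
        for i, row in sub.iterrows():
            crosses = row["ci_low"] <= 1.0 <= row["ci_high"]
            color = "grey" if crosses else "#b2182b"
            ax.errorbar(
                row["or_"],
                i,
                xerr=[[row["or_"] - row["ci_low"]], [row["ci_high"] - row["or_"]]],
                fmt="o",
                mfc="white" if crosses else color,
                mec=color,
                ecolor=color,
                capsize=2,
            )
        ax.axvline(1.0, color="black", lw=0.7, ls="--")
        ax.set_xscale("log")
        ax.set_yticks(range(len(sub)))
        ax.set_yticklabels(
            sub["exposure"] + " / " + sub["cohort"] + " / " + sub["method"],
            fontsize=7,
        )
        ax.set_title(outcome, fontsize=9)
        ax.invert_yaxis()
    axes[-1, 0].set_xlabel("OR (95% CI)")
    fig.tight_layout()
    fig.savefig(path.with_suffix(".png"), dpi=150)
    plt.close(fig)
    return path
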