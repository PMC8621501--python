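"""Monte-Carlo validation studies: calibration, recovery, robustness.

These drive the whole pipeline on synthetic data with known truth and
measure operating characteristics — type-I error of the IVW test, bias
and CI coverage under a true effect, the robustness ordering of the
weighted median versus IVW under directional pleiotropy, the power of the
MR-Egger intercept test, and the MR-PRESSO outlier detection/correction
rates. They are ordinary package functions so that the test suite and the
reproduction script exercise exactly the same code paths.

Study designs (sample sizes, instrument counts, pleiotropy strength) are
fixed here and documented in the methods note; each study derives one
sub-seed per replicate from its base seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimators import egger, ivw, weighted_median, Z95
from .instruments import variance_explained
from .presso import presso
from .simulate import SimConfig, simulate_pair
from .sumstats import SummaryStats, VariantAssociation, harmonize

__all__ = [
    "ivw_null_calibration",
    "presso_null_calibration",
    "ivw_recovery",
    "robustness_study",
    "outlier_injection_study",
    "target_recovery_study",
    "NULL_CONFIG",
    "TARGET_CONFIG",
    "RECOVERY_CONFIG",
    "ROBUSTNESS_CONFIG",
    "INJECTION_CONFIG",
]

#: 100 valid instruments, no causal effect — type-I error of the IVW test.
NULL_CONFIG = SimConfig(m_variants=100, prop_instruments=1.0, theta=0.0)

#: ~100 instruments out of 200 variants, theta = 0.3, exposure variance
#: explained ~7% at n_exp = 190k / n_out = 400k (the generator defaults).
RECOVERY_CONFIG = SimConfig()

#: 40% of 100 instruments carry directional direct effects of mean 0.05
#: (about twice the typical outcome SE) on the exposure-raising allele.
ROBUSTNESS_CONFIG = SimConfig(
    m_variants=100,
    prop_instruments=1.0,
    theta=0.3,
    prop_invalid=0.4,
    mu_alpha=0.05,
    sigma_alpha=0.01,
)

#: instrument set for outlier injection: 25 valid instruments; the
#: strongest one receives an added direct effect of 8x its outcome SE.
#: The set is large enough that the outlier's displacement of the other
#: variants' leave-one-out slopes does not inflate the simulated null
#: residuals, yet small enough that the Bonferroni-adjusted outlier test
#: retains resolution at the simulation count used.
INJECTION_CONFIG = SimConfig(m_variants=25, prop_instruments=1.0, theta=0.3)


def _instrument_pairs(config: SimConfig):
    exposure, outcome, _, truth = simulate_pair(config)
    keep = [r.snp_id for r, flag in zip(exposure.records, truth.is_instrument) if flag]
    pairs = harmonize(exposure.subset(keep), outcome.subset(keep))
    return pairs, truth


def ivw_null_calibration(
    n_reps: int = 2000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the random-effects IVW test under the null
    (theta = 0, valid instruments). Should sit at or slightly below
    ``alpha``."""
    rejections = 0
    for rep in range(n_reps):
        pairs, _ = _instrument_pairs(replace(NULL_CONFIG, seed=seed + rep))
        est, _ = ivw(pairs, "random")
        rejections += est.pvalue < alpha
    return rejections / n_reps


def presso_null_calibration(
    n_reps: int = 300,
    seed: int = 0,
    m_variants: int = 30,
    n_sim: int = 1000,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the MR-PRESSO global test on valid instruments
    (no pleiotropy, true effect present)."""
    config = SimConfig(m_variants=m_variants, prop_instruments=1.0, theta=0.3)
    rejections = 0
    for rep in range(n_reps):
        pairs, _ = _instrument_pairs(replace(config, seed=seed + rep))
        res = presso(pairs, n_sim=n_sim, seed=seed + rep)
        rejections += res.global_p < alpha
    return rejections / n_reps


def ivw_recovery(n_reps: int = 500, seed: int = 0) -> dict[str, float]:
    """Bias and 95% CI coverage of random-effects IVW at theta = 0.3 under
    the default generator regime. Also reports the mean exposure variance
    explained by the (true) instruments."""
    theta = RECOVERY_CONFIG.theta
    estimates = np.empty(n_reps)
    covered = 0
    r2 = np.empty(n_reps)
    for rep in range(n_reps):
        pairs, _ = _instrument_pairs(replace(RECOVERY_CONFIG, seed=seed + rep))
        est, _ = ivw(pairs, "random")
        estimates[rep] = est.beta
        covered += (est.beta - Z95 * est.se) <= theta <= (est.beta + Z95 * est.se)
        r2[rep] = variance_explained(pairs)
    mean_est = float(np.mean(estimates))
    return {
        "theta": float(theta),
        "mean_estimate": mean_est,
        "relative_bias": (mean_est - theta) / theta,
        "coverage": covered / n_reps,
        "mean_variance_explained": float(np.mean(r2)),
        "n_snps": len(pairs),
    }


def robustness_study(n_reps: int = 300, seed: int = 0) -> dict[str, float]:
    """Directional-pleiotropy stress test: per-replicate comparison of
    |bias| for the weighted median versus IVW, and the power of the
    MR-Egger intercept test at alpha = 0.05."""
    theta = ROBUSTNESS_CONFIG.theta
    median_wins = 0
    intercept_rejections = 0
    slopes = np.empty(n_reps)
    for rep in range(n_reps):
        pairs, _ = _instrument_pairs(replace(ROBUSTNESS_CONFIG, seed=seed + rep))
        est_ivw, _ = ivw(pairs, "random")
        est_med = weighted_median(pairs, n_boot=0)
        median_wins += abs(est_med.beta - theta) < abs(est_ivw.beta - theta)
        est_egger, _ = egger(pairs)
        slopes[rep] = est_egger.beta
        intercept_rejections += est_egger.egger_intercept_p < 0.05
    return {
        "median_beats_ivw_rate": median_wins / n_reps,
        "egger_intercept_power": intercept_rejections / n_reps,
        "egger_slope_mean": float(np.mean(slopes)),
        "theta": float(theta),
    }


#: cis gene region: 60 variants, strong local signals (2 causal), tight
#: AR(1) LD, outcome generated with a true raising effect of +0.7 log-odds
#: per SD (i.e. -0.7 per SD lowering).
TARGET_CONFIG = SimConfig(
    m_variants=60, sigma_gamma=0.1, ld_rho=0.8, theta=0.7, prop_instruments=1.0
)


def target_recovery_study(n_reps: int = 200, seed: int = 0) -> dict[str, float]:
    """Drug-target recovery: simulate a cis region, extract and clump cis
    instruments, orient them per 1-SD lipid lowering, and check that the
    95% CI covers the true lowering effect (-theta)."""
    from .drug_target import GeneRegion, build_target_set, extract_cis, target_mr
    from .simulate import simulate_gene_region, simulate_region_outcome

    region = GeneRegion("GENE1", "1", 1_000_000, 1_100_000, flank_bp=100_000)
    theta_lowering = -TARGET_CONFIG.theta
    covered = 0
    estimates = np.empty(n_reps)
    used = 0
    for rep in range(n_reps):
        config = replace(TARGET_CONFIG, seed=seed + rep)
        stats, ld, truth = simulate_gene_region(config, window_bp=100_000, n_causal=2)
        outcome = simulate_region_outcome(stats, truth, config)
        cis = extract_cis(stats, region, 5e-8, ld)
        if len(cis) == 0:
            estimates[rep] = np.nan
            continue
        target = build_target_set(region, "LDL-C", cis, outcome)
        est = target_mr(target)
        estimates[rep] = est.beta
        lo = np.log(est.ci_low)
        hi = np.log(est.ci_high)
        covered += lo <= theta_lowering <= hi
        used += 1
    return {
        "coverage": float(covered / used) if used else 0.0,
        "mean_estimate": float(np.nanmean(estimates)),
        "theta_lowering": float(theta_lowering),
        "n_used": used,
    }


def _inject_outlier(
    outcome: SummaryStats, truth, factor: float = 8.0
) -> tuple[SummaryStats, str]:
    """Add a direct effect of ``factor`` times its outcome SE to the
    strongest instrument; returns the modified outcome and the snp_id."""
    j = int(np.argmax(np.abs(truth.gamma)))
    records = list(outcome.records)
    v = records[j]
    records[j] = VariantAssociation(
        snp_id=v.snp_id,
        chrom=v.chrom,
        pos=v.pos,
        effect_allele=v.effect_allele,
        other_allele=v.other_allele,
        eaf=v.eaf,
        beta=v.beta + factor * v.se,
        se=v.se,
        pvalue=v.pvalue,
        n=v.n,
    )
    return SummaryStats(outcome.trait_name, outcome.trait_type, records), v.snp_id


def outlier_injection_study(
    n_reps: int = 200, seed: int = 0, n_sim: int = 2000
) -> dict[str, float]:
    """MR-PRESSO injection-recovery: detection rate of a single injected
    pleiotropic variant (direct effect 8x its outcome SE on the strongest
    instrument) and, among flagged replicates, how often the corrected IVW
    lands closer to theta than the raw IVW."""
    theta = INJECTION_CONFIG.theta
    flagged = 0
    corrected_closer = 0
    for rep in range(n_reps):
        config = replace(INJECTION_CONFIG, seed=seed + rep)
        exposure, outcome, _, truth = simulate_pair(config)
        outcome, bad_id = _inject_outlier(outcome, truth)
        pairs = harmonize(exposure, outcome)
        res = presso(pairs, n_sim=n_sim, seed=seed + rep)
        if bad_id in res.outlier_ids:
            flagged += 1
            if abs(res.beta_corrected - theta) < abs(res.beta_raw - theta):
                corrected_closer += 1
    return {
        "flag_rate": flagged / n_reps,
        "corrected_closer_rate": corrected_closer / flagged if flagged else 0.0,
        "n_flagged": flagged,
    }
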