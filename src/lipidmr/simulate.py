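"""Synthetic GWAS summary-statistics generator with known ground truth.

Generates exposure/outcome summary statistics that emulate the regime of a
lipid-trait instrumental analysis against rare binary outcomes: a
continuous, standardized exposure (effects in SD units) measured in a
large GWAS, and a rare binary outcome (effects on the log-odds scale).
Every draw is reproducible from a single seed, and the generating truth
(causal effect, per-variant instrument effects, pleiotropic direct
effects) is returned alongside the data so downstream estimators can be
validated by parameter recovery and calibration.

Generative model
----------------
For variant *j* with minor-allele frequency ``p_j ~ U(maf_range)``:

* instruments receive a true exposure effect ``gamma_j ~ N(0, sigma_gamma^2)``
  (equicorrelated within LD blocks with correlation ``ld_rho``); other
  variants have ``gamma_j = 0``;
* a fraction ``prop_invalid`` of instruments are invalid and carry a
  direct (pleiotropic) outcome effect with magnitude
  ``N(mu_alpha, sigma_alpha^2)`` applied on the exposure-raising
  orientation, i.e. the direct effect stored in allele coordinates is
  ``sign(gamma_j) * N(mu_alpha, sigma_alpha^2)``. A nonzero ``mu_alpha``
  therefore produces *directional* pleiotropy: alleles that raise the
  exposure systematically shift the outcome through the extra pathway,
  which is the regime in which the IVW estimator is biased and the
  MR-Egger intercept has an estimand different from zero.
* the true outcome effect is ``b_j = theta * gamma_j + alpha_j``;
* observed effects add sampling noise with the standard GWAS standard
  errors ``se_X = 1/sqrt(2 n_exp p(1-p))`` for a unit-variance continuous
  trait, and ``se_Y = 1/sqrt(2 n_out p(1-p) phi(1-phi))`` for a binary
  trait with case fraction ``phi`` (logistic approximation; aneurysm-like
  outcomes are rare, default ``phi = 0.01``).

P-values are two-sided normal. The exposure and outcome noise draws are
independent (strict two-sample design; no overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .sumstats import LDMatrix, SummaryStats, VariantAssociation

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_pair",
    "simulate_multi_exposure",
    "simulate_gene_region",
    "simulate_region_outcome",
]

_P_FLOOR = 5e-324  # smallest subnormal double; keeps pvalue in (0, 1]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the summary-statistics generator.

    Defaults mirror the study regime the package targets: an exposure GWAS
    of ~190,000 individuals, a rare binary outcome GWAS of ~400,000, about
    100 instruments, and instrument effect sizes chosen so the total
    exposure variance explained lands near 7% (the mid single digits
    typical of lipid instruments).
    """

    m_variants: int = 200
    n_exp: float = 190_000.0
    n_out: float = 400_000.0
    theta: float = 0.3
    prop_instruments: float = 0.5
    sigma_gamma: float = 0.042
    prop_invalid: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    ld_block_size: int = 10
    ld_rho: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    case_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.m_variants < 1:
            raise SimConfigError("m_variants must be >= 1")
        for name in ("prop_instruments", "prop_invalid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        for name in ("sigma_gamma", "sigma_alpha"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 < self.case_fraction < 1.0:
            raise SimConfigError("case_fraction must lie in (0, 1)")
        if self.ld_block_size < 1:
            raise SimConfigError("ld_block_size must be >= 1")
        if not -1.0 < self.ld_rho < 1.0:
            raise SimConfigError("ld_rho must lie in (-1, 1)")
        if self.prop_instruments > 0 and round(self.prop_instruments * self.m_variants) < 1:
            raise SimConfigError(
                "m_variants too small for the requested prop_instruments"
            )


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset.

    ``alpha`` is the pleiotropic direct effect in allele coordinates
    (zero wherever ``is_invalid`` is false); ``theta`` is a scalar for
    single-exposure data and an array for multi-exposure data.
    """

    theta: float | np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    is_instrument: np.ndarray
    is_invalid: np.ndarray
    seed: int
    maf: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if np.any(self.alpha[~self.is_invalid] != 0):
            raise SimConfigError("alpha must be zero for valid variants")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    return np.clip(2.0 * sps.norm.sf(z), _P_FLOOR, 1.0)


def _se_exposure(maf: np.ndarray, n_exp: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n_exp * maf * (1.0 - maf))


def _se_outcome(maf: np.ndarray, n_out: float, phi: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n_out * maf * (1.0 - maf) * phi * (1.0 - phi))


def _records(
    betas: np.ndarray,
    ses: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    n: float,
    chrom: str = "1",
) -> list[VariantAssociation]:
    pvals = _two_sided_p(betas, ses)
    return [
        VariantAssociation(
            snp_id=f"rs{j + 1:06d}",
            chrom=chrom,
            pos=int(pos[j]),
            effect_allele="A",
            other_allele="G",
            eaf=float(maf[j]),
            beta=float(betas[j]),
            se=float(ses[j]),
            pvalue=float(pvals[j]),
            n=n,
        )
        for j in range(len(betas))
    ]


def _draw_structure(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw MAFs, instrument indicators and block-correlated gamma."""
    m = config.m_variants
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    n_inst = int(round(config.prop_instruments * m))
    is_instrument = np.zeros(m, dtype=bool)
    if n_inst:
        is_instrument[np.sort(rng.choice(m, size=n_inst, replace=False))] = True
    # equicorrelated within consecutive blocks: shared factor + idiosyncratic
    rho = config.ld_rho
    block = np.arange(m) // config.ld_block_size
    shared = rng.standard_normal(block.max() + 1)[block]
    own = rng.standard_normal(m)
    z = np.sqrt(abs(rho)) * np.sign(rho) * shared + np.sqrt(1 - abs(rho)) * own
    gamma = np.where(is_instrument, config.sigma_gamma * z, 0.0)
    return maf, is_instrument, gamma


def _draw_pleiotropy(
    config: SimConfig,
    rng: np.random.Generator,
    is_instrument: np.ndarray,
    gamma: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    m = config.m_variants
    is_invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    inst_idx = np.flatnonzero(is_instrument)
    n_invalid = int(round(config.prop_invalid * len(inst_idx)))
    if n_invalid:
        bad = rng.choice(inst_idx, size=n_invalid, replace=False)
        is_invalid[bad] = True
        raw = rng.normal(config.mu_alpha, config.sigma_alpha, size=n_invalid)
        # directional pleiotropy acts on the exposure-raising orientation
        alpha[bad] = np.sign(gamma[bad]) * raw
    return is_invalid, alpha


def _block_ld_matrix(config: SimConfig, pos: np.ndarray) -> LDMatrix:
    m = config.m_variants
    block = np.arange(m) // config.ld_block_size
    r2 = np.where(block[:, None] == block[None, :], config.ld_rho**2, 0.0)
    np.fill_diagonal(r2, 1.0)
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    return LDMatrix(snp_ids, r2, pos)


def simulate_pair(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, SimTruth]:
    """Simulate one exposure GWAS, one outcome GWAS, their LD matrix and
    the generating truth (see the module docstring for the model)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    pos = (np.arange(m) + 1) * 100_000

    maf, is_instrument, gamma = _draw_structure(config, rng)
    is_invalid, alpha = _draw_pleiotropy(config, rng, is_instrument, gamma)

    se_x = _se_exposure(maf, config.n_exp)
    se_y = _se_outcome(maf, config.n_out, config.case_fraction)
    beta_x = gamma + rng.normal(0.0, se_x)
    b_true = config.theta * gamma + alpha
    beta_y = b_true + rng.normal(0.0, se_y)

    exposure = SummaryStats(
        "exposure", "continuous", _records(beta_x, se_x, maf, pos, config.n_exp)
    )
    outcome = SummaryStats(
        "outcome", "binary", _records(beta_y, se_y, maf, pos, config.n_out)
    )
    ld = _block_ld_matrix(config, pos)
    truth = SimTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        is_instrument=is_instrument,
        is_invalid=is_invalid,
        seed=config.seed,
        maf=maf,
    )
    return exposure, outcome, ld, truth


def simulate_multi_exposure(
    config: SimConfig,
    k_exposures: int,
    effect_corr: np.ndarray,
    thetas: Sequence[float] | None = None,
) -> tuple[list[SummaryStats], SummaryStats, SimTruth]:
    """Simulate ``k`` exposures whose true instrument effects are
    multivariate normal with correlation ``effect_corr``, and one outcome
    formed as ``sum_k theta_k * gamma_jk + alpha_j`` plus noise.

    ``thetas`` defaults to ``config.theta`` for every exposure. The truth
    record's ``gamma`` is the ``m x k`` matrix of true exposure effects.
    """
    config.validate()
    effect_corr = np.asarray(effect_corr, dtype=float)
    if effect_corr.shape != (k_exposures, k_exposures):
        raise SimConfigError("effect_corr must be k x k")
    if not np.allclose(effect_corr, effect_corr.T) or not np.allclose(
        np.diag(effect_corr), 1.0
    ):
        raise SimConfigError("effect_corr must be a correlation matrix")
    eigvals = np.linalg.eigvalsh(effect_corr)
    if eigvals.min() < 1e-10:
        raise SimConfigError("effect_corr is not positive definite")
    if thetas is None:
        thetas = np.full(k_exposures, config.theta)
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (k_exposures,):
        raise SimConfigError("thetas length must equal k_exposures")

    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    pos = (np.arange(m) + 1) * 100_000

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    n_inst = int(round(config.prop_instruments * m))
    is_instrument = np.zeros(m, dtype=bool)
    if n_inst:
        is_instrument[np.sort(rng.choice(m, size=n_inst, replace=False))] = True

    chol = np.linalg.cholesky(effect_corr)
    z = rng.standard_normal((m, k_exposures)) @ chol.T
    gamma = np.where(is_instrument[:, None], config.sigma_gamma * z, 0.0)

    # pleiotropy oriented on the first exposure's raising allele
    is_invalid, alpha = _draw_pleiotropy(config, rng, is_instrument, gamma[:, 0])

    se_x = _se_exposure(maf, config.n_exp)
    se_y = _se_outcome(maf, config.n_out, config.case_fraction)
    exposures = []
    for k in range(k_exposures):
        beta_x = gamma[:, k] + rng.normal(0.0, se_x)
        exposures.append(
            SummaryStats(
                f"exposure_{k + 1}",
                "continuous",
                _records(beta_x, se_x, maf, pos, config.n_exp),
            )
        )
    b_true = gamma @ thetas + alpha
    beta_y = b_true + rng.normal(0.0, se_y)
    outcome = SummaryStats(
        "outcome", "binary", _records(beta_y, se_y, maf, pos, config.n_out)
    )
    truth = SimTruth(
        theta=thetas,
        gamma=gamma,
        alpha=alpha,
        is_instrument=is_instrument,
        is_invalid=is_invalid,
        seed=config.seed,
        maf=maf,
    )
    return exposures, outcome, truth


def simulate_gene_region(
    config: SimConfig,
    window_bp: int,
    n_causal: int,
    gene_start: int = 1_000_000,
    gene_end: int = 1_100_000,
    chrom: str = "1",
) -> tuple[SummaryStats, LDMatrix, SimTruth]:
    """Simulate a cis gene region: variants placed uniformly in the flanked
    window, an autoregressive LD correlation over position rank
    (``r = ld_rho ** rank distance``), and ``n_causal`` causal signals whose
    marginal effects propagate through LD as ``beta_marginal = R @ gamma``.

    The truth record's ``gamma`` holds the *marginal* effects (what a GWAS
    of the region estimates); ``is_instrument`` flags the causal variants.
    """
    config.validate()
    if window_bp < 0:
        raise SimConfigError("window_bp must be >= 0")
    if n_causal > config.m_variants:
        raise SimConfigError("n_causal cannot exceed m_variants")
    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    pos = np.sort(
        rng.integers(max(1, gene_start - window_bp), gene_end + window_bp + 1, size=m)
    )
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    rank = np.arange(m)
    corr = config.ld_rho ** np.abs(rank[:, None] - rank[None, :])
    if config.ld_rho == 0.0:
        corr = np.eye(m)

    causal = np.zeros(m, dtype=bool)
    if n_causal:
        causal[rng.choice(m, size=n_causal, replace=False)] = True
    gamma_causal = np.where(causal, rng.normal(0.0, config.sigma_gamma, size=m), 0.0)
    beta_marginal = corr @ gamma_causal

    se_x = _se_exposure(maf, config.n_exp)
    beta_x = beta_marginal + rng.normal(0.0, se_x)
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    records = []
    pvals = _two_sided_p(beta_x, se_x)
    for j in range(m):
        records.append(
            VariantAssociation(
                snp_id=snp_ids[j],
                chrom=chrom,
                pos=int(pos[j]),
                effect_allele="A",
                other_allele="G",
                eaf=float(maf[j]),
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                pvalue=float(pvals[j]),
                n=config.n_exp,
            )
        )
    stats = SummaryStats("exposure", "continuous", records)
    ld = LDMatrix(snp_ids, corr**2, pos)
    truth = SimTruth(
        theta=config.theta,
        gamma=beta_marginal,
        alpha=np.zeros(m),
        is_instrument=causal,
        is_invalid=np.zeros(m, dtype=bool),
        seed=config.seed,
        maf=maf,
    )
    return stats, ld, truth


def simulate_region_outcome(
    region: SummaryStats,
    truth: SimTruth,
    config: SimConfig,
    theta: float | None = None,
    seed: int | None = None,
) -> SummaryStats:
    """Simulate a binary-outcome GWAS over the variants of a gene region.

    True outcome effects are ``theta`` times the region's marginal exposure
    effects (default ``config.theta``); noise uses the rare-binary SE.
    """
    theta = config.theta if theta is None else theta
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    maf = truth.maf
    se_y = _se_outcome(maf, config.n_out, config.case_fraction)
    beta_y = theta * truth.gamma + rng.normal(0.0, se_y)
    pos = np.array([r.pos for r in region.records])
    recs = []
    pvals = _two_sided_p(beta_y, se_y)
    for j, r in enumerate(region.records):
        recs.append(
            VariantAssociation(
                snp_id=r.snp_id,
                chrom=r.chrom,
                pos=r.pos,
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                eaf=r.eaf,
                beta=float(beta_y[j]),
                se=float(se_y[j]),
                pvalue=float(pvals[j]),
                n=config.n_out,
            )
        )
    return SummaryStats("outcome", "binary", recs)
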