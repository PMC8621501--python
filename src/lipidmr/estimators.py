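"""Causal-effect estimators for two-sample Mendelian randomization.

Implements the Wald ratio, inverse-variance-weighted (IVW) estimator with
fixed and multiplicative random effects, MR-Egger regression with the
intercept (directional-pleiotropy) test, the weighted median, the
weighted mode, and multivariable IVW, together with Cochran Q / I-squared
heterogeneity statistics and odds-ratio conversion.

All estimators consume harmonized exposure/outcome pairs. Effects are on
the log-odds-per-SD scale; ``to_odds_ratio`` converts to the OR scale at
the reporting edge.

Notation: for variant *j*, ``(bx_j, sx_j)`` are the exposure effect and SE,
``(by_j, sy_j)`` the outcome effect and SE, ``w_j = 1/sy_j^2`` the IVW
weight, and ``ratio_j = by_j/bx_j`` the per-variant Wald ratio with
first-order SE ``sy_j/|bx_j|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .sumstats import HarmonizedVariant, InputError, SummaryStats, harmonize

__all__ = [
    "MREstimate",
    "HetStats",
    "MethodError",
    "CollinearityError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_median_estimate",
    "weighted_mode",
    "weighted_mode_estimate",
    "mvmr_ivw",
    "mvmr_from_pairs",
    "multivariable_mr",
    "ivw_arrays",
    "to_odds_ratio",
]

Z95 = 1.959964  # two-sided 95% normal quantile, as used in OR CIs
_P_FLOOR = 5e-324

MIN_SNPS = {
    "wald": 1,
    "ivw_fe": 2,
    "ivw_re": 2,
    "egger": 3,
    "weighted_median": 3,
    "weighted_mode": 3,
    "mvmr_ivw": 2,
}


class MethodError(ValueError):
    """Too few variants (or otherwise unusable input) for the method."""


class CollinearityError(ValueError):
    """Rank-deficient multivariable design."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with OR-scale presentation fields."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int
    exposure: str | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


@dataclass(frozen=True)
class HetStats:
    """Cochran Q heterogeneity statistics."""

    Q: float
    df: int
    p_q: float
    i2: float


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI, ``exp(beta -/+ 1.959964 se)``."""
    if se < 0:
        raise InputError("se must be non-negative")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return _P_FLOOR if beta != 0 else 1.0
    return float(np.clip(2.0 * sps.norm.sf(abs(beta) / se), _P_FLOOR, 1.0))


def _estimate(
    method: str,
    beta: float,
    se: float,
    pvalue: float,
    n_snps: int,
    **extra,
) -> MREstimate:
    or_, lo, hi = to_odds_ratio(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=float(pvalue),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=n_snps,
        **extra,
    )


def _as_arrays(
    variants: Sequence[HarmonizedVariant],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([v.beta_exp for v in variants])
    sx = np.array([v.se_exp for v in variants])
    by = np.array([v.beta_out for v in variants])
    sy = np.array([v.se_out for v in variants])
    if np.any(bx == 0):
        raise MethodError("zero exposure effect: Wald ratio undefined")
    return bx, sx, by, sy


def _het_stats(Q: float, df: int) -> HetStats:
    Q = float(max(Q, 0.0))
    p_q = float(sps.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HetStats(Q=Q, df=df, p_q=p_q, i2=i2)


def wald_ratio(v: HarmonizedVariant) -> MREstimate:
    """Single-variant causal estimate: outcome effect over exposure effect,
    with first-order SE ``se_out/|beta_exp|``."""
    if v.beta_exp == 0:
        raise MethodError(f"{v.snp_id}: beta_exp is zero, Wald ratio undefined")
    beta = v.beta_out / v.beta_exp
    se = v.se_out / abs(v.beta_exp)
    return _estimate("wald", beta, se, _normal_p(beta, se), 1)


def ivw_arrays(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, effects_model: str = "random"
) -> tuple[float, float, float]:
    """IVW slope, SE and Cochran Q from raw arrays.

    Weighted regression of ``by`` on ``bx`` through the origin with weights
    ``1/sy^2``; the multiplicative random-effects SE inflates the
    fixed-effects SE by ``max(1, sqrt(Q/(n-1)))``.
    """
    n = len(bx)
    w = 1.0 / sy**2
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se_fixed = np.sqrt(1.0 / s_xx)
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    if effects_model == "fixed":
        se = se_fixed
    elif effects_model == "random":
        se = se_fixed * max(1.0, np.sqrt(Q / (n - 1)))
    else:
        raise InputError(f"unknown effects_model {effects_model!r}")
    return beta, float(se), Q


def ivw(
    variants: Sequence[HarmonizedVariant], effects_model: str = "random"
) -> tuple[MREstimate, HetStats]:
    """Inverse-variance-weighted estimate over two or more variants.

    Cochran Q is computed on the Wald-ratio scale (equivalently, on the
    weighted regression residuals) with ``df = n - 1``; I-squared is
    ``max(0, (Q - df)/Q) * 100``.
    """
    n = len(variants)
    if n < 2:
        raise MethodError("IVW needs >= 2 variants; use wald_ratio for one")
    bx, _, by, sy = _as_arrays(variants)
    beta, se, Q = ivw_arrays(bx, by, sy, effects_model)
    method = "ivw_fe" if effects_model == "fixed" else "ivw_re"
    est = _estimate(method, beta, se, _normal_p(beta, se), n)
    return est, _het_stats(Q, n - 1)


def egger(variants: Sequence[HarmonizedVariant]) -> tuple[MREstimate, HetStats]:
    """MR-Egger: weighted regression of outcome on exposure effects *with*
    an intercept, after orienting every variant so ``beta_exp > 0``.

    The intercept estimates the average directional pleiotropy; its test
    (t distribution, n-2 df) is the directional-pleiotropy check. SEs are
    inflated multiplicatively by ``max(1, sqrt(RSS_w/(n-2)))``.
    """
    n = len(variants)
    if n < 3:
        raise MethodError("MR-Egger needs >= 3 variants")
    bx, _, by, sy = _as_arrays(variants)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, rss_w / (n - 2))
    cov = np.linalg.inv(xtwx) * scale
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))

    t_slope = slope / se_slope
    t_int = intercept / se_int
    p_slope = float(np.clip(2.0 * sps.t.sf(abs(t_slope), n - 2), _P_FLOOR, 1.0))
    p_int = float(np.clip(2.0 * sps.t.sf(abs(t_int), n - 2), _P_FLOOR, 1.0))

    est = _estimate(
        "egger",
        slope,
        se_slope,
        p_slope,
        n,
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=p_int,
    )
    return est, _het_stats(rss_w, n - 2)


def _ratios_weights(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    ratios = by / bx
    se_wald = sy / np.abs(bx)
    return ratios, 1.0 / se_wald**2


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative
    standardized weights ``s_j = (cumsum(w)_j - w_j/2) / sum(w)`` at 0.5."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _parametric_bootstrap(
    estimate_fn,
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    """SE of a ratio-based estimator by resampling (bx, by) from normals
    centred on the observed effects with their reported SEs."""
    rng = np.random.default_rng(seed)
    n = len(bx)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(n)
        by_b = by + sy * rng.standard_normal(n)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        ratios, weights = _ratios_weights(bx_b, by_b, sy)
        est[b] = estimate_fn(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(
    variants: Sequence[HarmonizedVariant], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: consistent when variants contributing at
    least half the weight are valid instruments. SE by seeded parametric
    bootstrap (``n_boot = 0`` skips it and reports NaN)."""
    n = len(variants)
    if n < 3:
        raise MethodError("weighted median needs >= 3 variants")
    bx, sx, by, sy = _as_arrays(variants)
    ratios, weights = _ratios_weights(bx, by, sy)
    beta = weighted_median_estimate(ratios, weights)
    if n_boot:
        se = _parametric_bootstrap(
            weighted_median_estimate, bx, sx, by, sy, n_boot, seed
        )
        p = _normal_p(beta, se)
    else:
        se, p = float("nan"), float("nan")
    return _estimate("weighted_median", beta, se, p, n)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    mad = float(sps.median_abs_deviation(ratios, scale=1.0)) / 0.6745
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def weighted_mode_estimate(
    ratios: np.ndarray,
    weights: np.ndarray,
    phi: float = 1.0,
    grid_size: int = 10_000,
) -> float:
    """Argmax of a weighted Gaussian kernel density over the Wald ratios,
    evaluated on a fixed grid spanning mean(ratios) +/- 5 SD."""
    h = _mode_bandwidth(ratios, phi)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    w = np.asarray(weights) / np.sum(weights)
    centre, sd = float(np.mean(ratios)), float(np.std(ratios, ddof=1))
    grid = np.linspace(centre - 5 * sd, centre + 5 * sd, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def weighted_mode(
    variants: Sequence[HarmonizedVariant],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 10_000,
    boot_grid_size: int = 1001,
) -> MREstimate:
    """Weighted-mode estimator: consistent when the largest group of
    variants with similar ratio estimates are valid instruments.

    The bandwidth is ``phi * 0.9 * min(sd, mad/0.6745) * n^(-1/5)``. The
    point estimate uses a ``grid_size``-point grid; the bootstrap reuses a
    coarser ``boot_grid_size`` grid to keep the SE affordable.
    """
    if phi <= 0:
        raise InputError("phi must be positive")
    n = len(variants)
    if n < 3:
        raise MethodError("weighted mode needs >= 3 variants")
    bx, sx, by, sy = _as_arrays(variants)
    ratios, weights = _ratios_weights(bx, by, sy)
    beta = weighted_mode_estimate(ratios, weights, phi, grid_size)
    if n_boot:
        se = _parametric_bootstrap(
            lambda r, w: weighted_mode_estimate(r, w, phi, boot_grid_size),
            bx, sx, by, sy, n_boot, seed,
        )
        p = _normal_p(beta, se)
    else:
        se, p = float("nan"), float("nan")
    return _estimate("weighted_mode", beta, se, p, n)


def mvmr_ivw(
    bx_matrix: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    exposure_names: Sequence[str] | None = None,
    scale_overdispersion: bool = True,
) -> list[MREstimate]:
    """Multivariable IVW: weighted regression (weights ``1/sy^2``) of the
    outcome effects on the ``n x k`` matrix of exposure effects, no
    intercept. SEs carry a multiplicative overdispersion factor
    ``max(1, sqrt(RSS_w/(n-k)))`` unless ``scale_overdispersion`` is off.

    Raises :class:`CollinearityError` (naming the offending exposures) on
    a rank-deficient design.
    """
    X = np.atleast_2d(np.asarray(bx_matrix, dtype=float))
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    n, k = X.shape
    if exposure_names is None:
        exposure_names = [f"exposure_{i + 1}" for i in range(k)]
    if n <= k:
        raise MethodError(f"multivariable IVW needs more variants ({n}) than exposures ({k})")
    w = 1.0 / sy**2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    svals = np.linalg.svd(xtwx, compute_uv=False)
    if svals.min() <= svals.max() * 1e-10:
        corr = np.corrcoef(X.T)
        offenders = sorted(
            {
                name
                for i, a in enumerate(exposure_names)
                for j, b in enumerate(exposure_names)
                if i < j and abs(corr[i, j]) > 0.9999
                for name in (a, b)
            }
        ) or list(exposure_names)
        raise CollinearityError(f"collinear exposure effects: {offenders}")
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, rss_w / (n - k)) if scale_overdispersion else 1.0
    cov = np.linalg.inv(xtwx) * scale
    ses = np.sqrt(np.diag(cov))
    return [
        _estimate(
            "mvmr_ivw",
            coef[i],
            ses[i],
            _normal_p(coef[i], ses[i]),
            n,
            exposure=str(exposure_names[i]),
        )
        for i in range(k)
    ]


def mvmr_from_pairs(
    pair_sets: Sequence[Sequence[HarmonizedVariant]],
    exposure_names: Sequence[str] | None = None,
    scale_overdispersion: bool = True,
) -> list[MREstimate]:
    """Multivariable IVW from per-exposure harmonized sets sharing the same
    variants in the same order (the outcome side is taken from the first
    set and must agree across sets)."""
    first = pair_sets[0]
    ids = [v.snp_id for v in first]
    for other in pair_sets[1:]:
        if [v.snp_id for v in other] != ids:
            raise InputError("pair sets must cover identical variants in order")
    X = np.column_stack([[v.beta_exp for v in s] for s in pair_sets])
    by = np.array([v.beta_out for v in first])
    sy = np.array([v.se_out for v in first])
    return mvmr_ivw(X, by, sy, exposure_names, scale_overdispersion)


def multivariable_mr(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    snp_ids: Sequence[str] | None = None,
    palindromic_policy: str = "infer_by_eaf",
    scale_overdispersion: bool = True,
) -> list[MREstimate]:
    """Multivariable IVW over a shared instrument set.

    The first exposure's effect alleles define the reference frame: the
    outcome and every further exposure are harmonized onto them, the
    variants present in all traits (optionally restricted to ``snp_ids``,
    e.g. the union of per-trait genome-wide-significant hits) form the
    design, and :func:`mvmr_ivw` fits the joint model.
    """
    if len(exposures) < 1:
        raise MethodError("at least one exposure required")
    ref = exposures[0]
    out_pairs = {v.snp_id: v for v in harmonize(ref, outcome, palindromic_policy)}
    shared = [sid for sid in (s.snp_id for s in ref.records) if sid in out_pairs]
    exp_maps = [{sid: out_pairs[sid] for sid in shared}]  # exposure 1 == reference
    for other in exposures[1:]:
        aligned = {v.snp_id: v for v in harmonize(ref, other, palindromic_policy)}
        shared = [sid for sid in shared if sid in aligned]
        exp_maps.append(aligned)
    if snp_ids is not None:
        keep = set(snp_ids)
        shared = [sid for sid in shared if sid in keep]
    if not shared:
        raise InputError("no variants shared by all traits")
    X = np.column_stack(
        [
            [out_pairs[sid].beta_exp for sid in shared]
            if i == 0
            # harmonize() stored the k-th exposure's effect in beta_out
            else [exp_maps[i][sid].beta_out for sid in shared]
            for i in range(len(exposures))
        ]
    )
    by = np.array([out_pairs[sid].beta_out for sid in shared])
    sy = np.array([out_pairs[sid].se_out for sid in shared])
    names = [e.trait_name for e in exposures]
    return mvmr_ivw(X, by, sy, names, scale_overdispersion)
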