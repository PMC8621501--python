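"""MR-PRESSO: residual-sum-of-squares tests for pleiotropic outliers.

Three simulation-based tests on a harmonized variant set:

* **global test** — does the observed weighted residual sum of squares
  (each variant's residual taken about its leave-one-out IVW slope)
  exceed what sampling noise alone produces?
* **outlier test** — which individual variants have implausibly large
  residuals (per-variant empirical p, Bonferroni-adjusted)?
* **distortion test** — does removing the flagged outliers move the IVW
  estimate further than removing a random subset of the same size would?

Empirical p-values use the ``(1 + count)/(1 + n_sim)`` estimator, so they
always lie in ``(0, 1]``. The whole procedure is deterministic given its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import MethodError, ivw_arrays
from .sumstats import HarmonizedVariant

__all__ = ["PressoResult", "DegenerateCorrectionError", "presso"]


class DegenerateCorrectionError(ValueError):
    """Every variant was flagged as an outlier; no corrected estimate exists."""


@dataclass
class PressoResult:
    """Outputs of the global, outlier and distortion tests."""

    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    outlier_ids: list[str]
    beta_raw: float
    beta_corrected: float | None
    distortion_p: float | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def presso(
    variants: Sequence[HarmonizedVariant],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    ``outlier_alpha`` applies to the Bonferroni-adjusted per-variant
    empirical p-values. Note the smallest attainable adjusted p is
    ``n/(n_sim + 1)``, so ``n_sim`` must comfortably exceed
    ``n/outlier_alpha`` for the outlier test to have any resolution.
    """
    n = len(variants)
    if n < 4:
        raise MethodError("MR-PRESSO needs >= 4 variants")
    if n_sim < 100:
        raise MethodError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)

    ids = [v.snp_id for v in variants]
    bx = np.array([v.beta_exp for v in variants])
    sx = np.array([v.se_exp for v in variants])
    by = np.array([v.beta_out for v in variants])
    sy = np.array([v.se_out for v in variants])
    w = 1.0 / sy**2

    b_loo = _loo_slopes(bx, by, w)
    r_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(r_obs))

    # simulate datasets under the per-variant leave-one-out fitted model
    bx_star = bx + sx * rng.standard_normal((n_sim, n))
    by_star = b_loo * bx + sy * rng.standard_normal((n_sim, n))
    wb = w[None, :]
    s_xy = np.sum(wb * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(wb * bx_star**2, axis=1, keepdims=True)
    b_loo_star = (s_xy - wb * bx_star * by_star) / (s_xx - wb * bx_star**2)
    r_star = wb * (by_star - b_loo_star * bx_star) ** 2
    rss_star = np.sum(r_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(r_star >= r_obs[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_raw * n, 1.0)
    outlier_p = {sid: float(p) for sid, p in zip(ids, p_adj)}
    flagged = [sid for sid, p in zip(ids, p_adj) if p < outlier_alpha]

    beta_raw, _, _ = ivw_arrays(bx, by, sy, "random")

    beta_corrected = None
    distortion_p = None
    if flagged:
        if len(flagged) == n:
            raise DegenerateCorrectionError("all variants flagged as outliers")
        keep = np.array([sid not in flagged for sid in ids])
        beta_corrected, _, _ = ivw_arrays(bx[keep], by[keep], sy[keep], "random")
        d_obs = beta_corrected - beta_raw
        # random subsets of the no-outlier size, without replacement
        k = int(keep.sum())
        d_star = np.empty(n_sim)
        for s in range(n_sim):
            idx = rng.choice(n, size=k, replace=False)
            b_sub = np.sum(w[idx] * bx[idx] * by[idx]) / np.sum(w[idx] * bx[idx] ** 2)
            d_star[s] = b_sub - beta_raw
        distortion_p = float(
            (1 + np.sum(np.abs(d_star) >= abs(d_obs))) / (n_sim + 1)
        )

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outlier_ids=flagged,
        beta_raw=float(beta_raw),
        beta_corrected=None if beta_corrected is None else float(beta_corrected),
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
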