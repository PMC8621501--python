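"""Cross-cohort meta-analysis with a heterogeneity-gated model choice,
plus the multiple-testing screen.

Cohort-level MR estimates (log-OR scale) are pooled with fixed-effect
inverse-variance weights; when Cochran Q signals heterogeneity
(``p_q < 0.1`` *and* ``I^2 > 50%``) the DerSimonian-Laird random-effects
model is used instead. With only two cohorts the tau-squared estimate is
noisy; this is inherent to the moment estimator and is reported as-is.

The significance screen is a Bonferroni correction over the analysis
grid, ``alpha / (n_exposures * n_outcomes)``, with a "suggestive" band
between the corrected and the nominal threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .estimators import MREstimate, to_odds_ratio
from .sumstats import InputError

__all__ = [
    "MetaResult",
    "meta",
    "bonferroni_threshold",
    "classify_association",
    "HETEROGENEITY_P",
    "HETEROGENEITY_I2",
]

#: gating constants for the fixed-vs-random model choice
HETEROGENEITY_P = 0.1
HETEROGENEITY_I2 = 50.0

_P_FLOOR = 5e-324


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity diagnostics."""

    pooled_beta: float
    pooled_se: float
    pooled_p: float
    or_: float
    ci_low: float
    ci_high: float
    Q: float
    p_q: float
    i2: float
    tau2: float
    model_used: str
    k_studies: int


def meta(
    estimates: Sequence[MREstimate],
    het_p: float = HETEROGENEITY_P,
    het_i2: float = HETEROGENEITY_I2,
) -> MetaResult:
    """Pool cohort-level estimates on the log-OR scale.

    Fixed model: weights ``1/se^2``. Random model: DerSimonian-Laird,
    ``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` and weights
    ``1/(se^2 + tau2)``. The random model is used iff ``p_q < het_p`` and
    ``I^2 > het_i2``. A single estimate passes through (fixed) with a
    warning.
    """
    k = len(estimates)
    if k == 0:
        raise InputError("no estimates to pool")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    if np.any(ses <= 0):
        raise InputError("all standard errors must be positive")

    if k == 1:
        warnings.warn("meta() called with a single estimate; passing it through")
        beta, se = float(betas[0]), float(ses[0])
        or_, lo, hi = to_odds_ratio(beta, se)
        p = float(np.clip(2.0 * sps.norm.sf(abs(beta) / se), _P_FLOOR, 1.0))
        return MetaResult(beta, se, p, or_, lo, hi, 0.0, 1.0, 0.0, 0.0, "fixed", 1)

    w = 1.0 / ses**2
    beta_fixed = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fixed) ** 2))
    df = k - 1
    p_q = float(sps.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0

    use_random = (p_q < het_p) and (i2 > het_i2)
    if use_random:
        w_r = 1.0 / (ses**2 + tau2)
        beta = float(np.sum(w_r * betas) / np.sum(w_r))
        se = float(np.sqrt(1.0 / np.sum(w_r)))
        model = "random"
    else:
        beta = beta_fixed
        se = float(np.sqrt(1.0 / np.sum(w)))
        model = "fixed"
    p = float(np.clip(2.0 * sps.norm.sf(abs(beta) / se), _P_FLOOR, 1.0))
    or_, lo, hi = to_odds_ratio(beta, se)
    return MetaResult(beta, se, p, or_, lo, hi, Q, p_q, i2, tau2, model, k)


def bonferroni_threshold(alpha: float, n_exposures: int, n_outcomes: int) -> float:
    """Grid-wide Bonferroni threshold, ``alpha/(n_exposures * n_outcomes)``."""
    if alpha <= 0 or n_exposures <= 0 or n_outcomes <= 0:
        raise InputError("all inputs must be positive")
    return alpha / (n_exposures * n_outcomes)


def classify_association(p: float, threshold: float, nominal: float = 0.05) -> str:
    """Classify a p-value as ``significant`` (below the corrected
    threshold), ``suggestive`` (between corrected and nominal), or
    ``null``."""
    if not 0 < threshold < nominal:
        raise InputError("require 0 < threshold < nominal")
    if p < threshold:
        return "significant"
    if p < nominal:
        return "suggestive"
    return "null"
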