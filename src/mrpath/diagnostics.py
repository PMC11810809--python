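"""Heterogeneity, pleiotropy and outlier diagnostics for an instrument set.

Cochran's Q measures dispersion of the per-SNP estimates around the fitted
IVW slope; under homogeneity it is chi-square with k-1 df, and excess Q
triggers the multiplicative random-effects IVW in the pipeline. The Egger
intercept tests for directional pleiotropy. Leave-one-out refits flag
influential single instruments. MR-PRESSO builds a parametric null for the
weighted residual sum of squares and flags individual outlier SNPs whose
residual is extreme against their own simulated distribution (Bonferroni
adjusted); the pipeline re-estimates without them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .harmonize import HarmonizedPair
from .mr_estimators import MREstimate, _arrays, egger, ivw

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LeaveOneOutEntry",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "mr_presso",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with df, upper-tail p, and the I^2 dispersion index."""

    q: float
    df: int
    pval: float
    i2: float


def cochran_q(pairs: Sequence[HarmonizedPair], slope: float) -> HeterogeneityResult:
    """Cochran's Q of the instrument set at a given causal slope.

    Q = sum w_j (beta_out_j - slope * beta_exp_j)^2 with w_j = 1/se_out_j^2,
    referred to chi-square with k-1 df.
    """
    if len(pairs) < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires at least 2 instruments")
    bx, _, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - slope * bx) ** 2))
    df = len(pairs) - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


class InterceptTest(NamedTuple):
    intercept: float
    se: float
    pval: float


def egger_intercept_test(pairs: Sequence[HarmonizedPair]) -> InterceptTest:
    """Directional-pleiotropy test: the MR-Egger regression intercept."""
    est = egger(pairs)
    return InterceptTest(
        est.aux["egger_intercept"], est.aux["intercept_se"], est.aux["intercept_pval"]
    )


@dataclass(frozen=True)
class LeaveOneOutEntry:
    omitted_snp_id: str
    estimate: MREstimate
    flagged: bool  # omission moves the estimate across zero or outside the full CI


def leave_one_out(pairs: Sequence[HarmonizedPair]) -> list[LeaveOneOutEntry]:
    """Refit the fixed-effect IVW estimate omitting each instrument in turn."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError(
            "leave-one-out requires at least 3 instruments"
        )
    full = ivw(pairs, mode="fixed")
    entries = []
    for i, pair in enumerate(pairs):
        rest = list(pairs[:i]) + list(pairs[i + 1:])
        est = ivw(rest, mode="fixed")
        crossed = np.sign(est.beta) != np.sign(full.beta) and full.beta != 0
        outside = not (full.ci_low <= est.beta <= full.ci_high)
        entries.append(LeaveOneOutEntry(pair.snp_id, est, bool(crossed or outside)))
    return entries


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test and per-SNP outlier calls."""

    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_snp_ids: tuple[str, ...]
    per_snp_pvals: dict[str, float]  # Bonferroni-adjusted
    seed: int | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over the omitted index.

    Supports batched inputs of shape (..., k); weights are 1D of length k.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    The observed statistic is the inverse-variance-weighted sum of squared
    residuals of each SNP against the IVW slope fitted without it. The null
    distribution is built from ``n_sim`` parametric draws that resample both
    the exposure betas (about their observed values) and the outcome betas
    (about the leave-one-out fitted values). Monte-Carlo p-values use the
    (r+1)/(n+1) estimator, so the global p is never exactly zero. Per-SNP
    p-values are Bonferroni-multiplied by k; SNPs below ``outlier_alpha``
    are reported as outliers.

    Identical seeds give identical results.
    """
    k = len(pairs)
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    bx, sx, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    slopes = _loo_slopes(bx, by, w)
    obs_sq = w * (by - slopes * bx) ** 2
    rss_obs = float(obs_sq.sum())

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = slopes * bx + sy * rng.standard_normal((n_sim, k))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w)
    sim_sq = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = sim_sq.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_raw = (1 + np.sum(sim_sq >= obs_sq[None, :], axis=0)) / (n_sim + 1)
    per_adj = np.minimum(1.0, per_raw * k)
    snp_ids = [p.snp_id for p in pairs]
    outliers = tuple(s for s, p in zip(snp_ids, per_adj) if p < outlier_alpha)
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        outlier_snp_ids=outliers,
        per_snp_pvals=dict(zip(snp_ids, per_adj.tolist())),
        seed=seed,
    )


def presso_distortion(pre: MREstimate, post: MREstimate) -> dict:
    """Descriptive pre/post outlier-removal comparison (no significance test)."""
    return {
        "beta_pre": pre.beta,
        "beta_post": post.beta,
        "difference": post.beta - pre.beta,
        "ratio": post.beta / pre.beta if pre.beta != 0 else float("nan"),
    }
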