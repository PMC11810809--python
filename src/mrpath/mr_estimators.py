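"""Causal estimators over harmonized instrument sets.

Each instrument j yields a Wald ratio ``beta_out_j / beta_exp_j`` whose
first-order SE is ``se_out_j / |beta_exp_j|``. The estimators combine them:

* **IVW** — weighted regression of outcome on exposure betas through the
  origin with weights 1/se_out^2; algebraically the inverse-variance-weighted
  mean of the Wald ratios. The fixed-effect SE is (sum w * bx^2)^(-1/2); the
  multiplicative random-effects flavour inflates it by sqrt(Q/(k-1)), floored
  at 1, and is the fallback when Cochran's Q signals heterogeneity.
* **MR-Egger** — the same weighted regression with a free intercept, after
  orienting every instrument to a non-negative exposure effect. The slope is
  the causal estimate (consistent under the InSIDE assumption even with
  directional pleiotropy); a non-zero intercept is the directional-pleiotropy
  test. Inference uses t with k-2 df and multiplicative residual scaling
  floored at 1.
* **Weighted median** — consistent when at least half the instrument weight
  is valid; found by interpolating the cumulative inverse-variance weights of
  the sorted ratios at 0.5. SE by seeded parametric bootstrap.
* **Weighted mode** — argmax of a weighted normal-kernel density over the
  ratios (modified Silverman bandwidth); consistent when the largest group of
  instruments sharing an effect is valid. SE by seeded parametric bootstrap.

Binary-outcome estimates are on the log-odds scale; :func:`to_odds_ratio`
maps an estimate and its CI to the OR scale reported in applied work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError
from .harmonize import HarmonizedPair

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "to_odds_ratio",
]

Z95 = 1.96  # normal 95% critical value, as used in published MR tables


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its first-order standard error."""

    snp_id: str
    ratio: float
    se_ratio: float


@dataclass
class MREstimate:
    """One causal estimate: method, point estimate, CI, p, and method extras."""

    method: str  # ivw_fe | ivw_mre | egger | weighted_median | weighted_mode | wald
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    def to_row(self) -> dict:
        orr, lo, hi = to_odds_ratio(self)
        return {
            "method": self.method,
            "n_snp": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "OR": orr,
            "ci_low": lo,
            "ci_high": hi,
            "pval": self.pval,
        }


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> RatioEstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is first-order (``se_out / |beta_exp|``), which makes the
    IVW-over-ratios identity with the origin regression exact; the
    second-order option adds the exposure-side variance term.
    """
    if pair.beta_exp == 0:
        raise UndefinedRatioError(f"zero exposure effect for {pair.snp_id}")
    ratio = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    if second_order:
        se = float(
            np.sqrt(
                pair.se_out**2 / pair.beta_exp**2
                + pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
            )
        )
    return RatioEstimate(pair.snp_id, ratio, se)


def ivw(pairs: Sequence[HarmonizedPair], mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode`` is ``"fixed"`` or ``"multiplicative_random"``. A single pair
    degrades to the Wald ratio (method ``"wald"``, with a notice in ``aux``).
    Cochran's Q at the fitted slope is always reported in ``aux["q"]``.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise InsufficientInstrumentsError(f"unknown IVW mode {mode!r}")
    if len(pairs) == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if len(pairs) == 1:
        est = wald_ratio(pairs[0])
        se = est.se_ratio
        return MREstimate(
            method="wald",
            beta=est.ratio,
            se=se,
            ci_low=est.ratio - Z95 * se,
            ci_high=est.ratio + Z95 * se,
            pval=_normal_p(est.ratio / se),
            n_snps=1,
            aux={"notice": "single instrument; Wald ratio reported"},
        )
    bx, _, by, sy = _arrays(pairs)
    if np.all(bx == 0):
        raise UndefinedRatioError("all exposure effects are zero")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    k = len(pairs)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    se = se_fixed
    if mode == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    return MREstimate(
        method="ivw_fe" if mode == "fixed" else "ivw_mre",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta / se),
        n_snps=k,
        aux={"q": q, "q_df": k - 1, "se_fixed": se_fixed},
    )


def egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """MR-Egger regression: weighted fit with a free pleiotropy intercept.

    Instruments are oriented so every exposure beta is non-negative (flipping
    both betas of a pair changes nothing substantive, so the fit is invariant
    to the arbitrary choice of effect allele). The slope is the causal
    estimate; the intercept triple in ``aux`` is the directional-pleiotropy
    test. Residual variance is multiplicative, floored at 1; inference uses
    t with k-2 df.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    k = len(pairs)
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / (k - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icept, icept_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    tcrit = float(stats.t.ppf(0.975, k - 2))

    def _t_p(value, se_):
        return float(2.0 * stats.t.sf(abs(value / se_), k - 2))

    return MREstimate(
        method="egger",
        beta=slope,
        se=slope_se,
        ci_low=slope - tcrit * slope_se,
        ci_high=slope + tcrit * slope_se,
        pval=_t_p(slope, slope_se),
        n_snps=k,
        aux={
            "egger_intercept": icept,
            "intercept_se": icept_se,
            "intercept_pval": _t_p(icept, icept_se),
            "rss": rss,
        },
    )


def _ratios_and_weights(bx, by, sy):
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio**2
    return ratios, weights / weights.sum()


def _interp_weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _parametric_boot(bx, sx, by, sy, n_boot, seed, statistic):
    """SE of ``statistic`` under parametric resampling of both beta sides."""
    rng = np.random.default_rng(seed)
    zx = rng.standard_normal((n_boot, len(bx)))
    zy = rng.standard_normal((n_boot, len(bx)))
    out = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx + sx * zx[i]
        bxi[bxi == 0] = np.finfo(float).tiny  # guard the ratio denominator
        out[i] = statistic(bxi, by + sy * zy[i])
    return float(np.std(out, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonizedPair], n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError(
            "weighted median requires at least 3 instruments"
        )
    bx, sx, by, sy = _arrays(pairs)
    ratios, weights = _ratios_and_weights(bx, by, sy)
    beta = _interp_weighted_median(ratios, weights)

    def _stat(bxi, byi):
        r, w = _ratios_and_weights(bxi, byi, sy)
        return _interp_weighted_median(r, w)

    se = _parametric_boot(bx, sx, by, sy, n_boot, seed, _stat)
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta / se) if se > 0 else 1e-300,
        n_snps=len(pairs),
        aux={"bootstrap_reps": n_boot, "seed": seed},
    )


def _mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread_candidates = [v for v in (sd, iqr / 1.34) if v > 0]
    if not spread_candidates:
        return 0.0
    spread = min(spread_candidates)
    return bandwidth_factor * 0.9 * spread * len(ratios) ** (-1 / 5)


def _mode_estimate(ratios, weights, bandwidth_factor, grid_size=512):
    h = _mode_bandwidth(ratios, bandwidth_factor)
    if h == 0.0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (weights[None, :] * stats.norm.pdf(grid[:, None], ratios[None, :], h)).sum(
        axis=1
    )
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-mode causal estimate (kernel-density argmax over ratios)."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError(
            "weighted mode requires at least 3 instruments"
        )
    bx, sx, by, sy = _arrays(pairs)
    ratios, weights = _ratios_and_weights(bx, by, sy)
    beta = _mode_estimate(ratios, weights, bandwidth_factor)

    def _stat(bxi, byi):
        r, w = _ratios_and_weights(bxi, byi, sy)
        return _mode_estimate(r, w, bandwidth_factor)

    se = _parametric_boot(bx, sx, by, sy, n_boot, seed, _stat)
    ci_low, ci_high = beta - Z95 * se, beta + Z95 * se
    return MREstimate(
        method="weighted_mode",
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pval=_normal_p(beta / se) if se > 0 else 1e-300,
        n_snps=len(pairs),
        aux={"bootstrap_reps": n_boot, "seed": seed, "bandwidth_factor": bandwidth_factor},
    )


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Map a log-odds estimate and CI to the odds-ratio scale."""
    return (
        float(np.exp(est.beta)),
        float(np.exp(est.ci_low)),
        float(np.exp(est.ci_high)),
    )
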