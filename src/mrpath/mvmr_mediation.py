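"""Multivariable MR and two-step product-of-coefficients mediation.

The mediation model asks how much of the causal effect of an exposure X
(e.g. a gut-bacterial taxon's abundance) on an outcome Y (e.g. atrial
fibrillation) flows through a mediator M (e.g. a circulating inflammatory
cytokine). On the log-odds scale:

* total effect   — univariable IVW of X on Y;
* step 1 (alpha) — univariable IVW of X on M;
* step 2 (b)     — multivariable IVW coefficient of M on Y conditional on X,
  which guarantees the mediator's effect is net of the exposure's own path;
* indirect effect = alpha * b, with first-order delta-method SE
  sqrt(b^2 se_alpha^2 + alpha^2 se_b^2);
* proportion mediated = indirect / total, reported as a percentage and
  suppressed when the indirect and total effects disagree in sign or the
  indirect CI spans zero (a proportion is then not interpretable).

Candidate (exposure, mediator) pairs are screened by requiring both the
step-1 and the mediator-to-outcome paths to reach p < 0.05 before a
mediation estimate is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedProportionError,
)
from .gwas_io import SummaryDataset, VariantAssociation
from .harmonize import HarmonizedPair, harmonize_datasets
from .iv_select import LDMatrix, clump, filter_by_pvalue
from .mr_estimators import Z95, MREstimate, ivw

__all__ = [
    "MvmrEstimate",
    "IndirectEffect",
    "ProportionResult",
    "MediationResult",
    "MediationConfig",
    "mvmr_ivw",
    "indirect_effect",
    "proportion_mediated",
    "two_step_mediation",
]


@dataclass(frozen=True)
class Coefficient:
    beta: float
    se: float
    pval: float


@dataclass
class MvmrEstimate:
    """Per-trait conditional effects from a multivariable IVW fit."""

    coefficients: dict[str, Coefficient]
    n_snps: int
    conditioning: tuple[str, ...]


def mvmr_ivw(
    beta_exp: Sequence[float],
    beta_med: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    trait_ids: tuple[str, str] = ("exposure", "mediator"),
) -> MvmrEstimate:
    """Multivariable IVW: weighted origin regression of the outcome betas on
    the exposure and mediator betas jointly, weights 1/se_out^2.

    Coefficient SEs come from the weighted normal equations with
    multiplicative residual scaling floored at 1 (t reference, k-p df).
    An all-zero effect column is dropped (its coefficient reported as 0 with
    NaN SE) so the remaining trait is fit univariably; any other rank
    deficiency raises :class:`CollinearityError` naming the traits.
    """
    bx = np.asarray(beta_exp, dtype=float)
    bm = np.asarray(beta_med, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    k = len(by)
    if k < 3:
        raise InsufficientInstrumentsError("MVMR requires at least 3 instruments")
    columns = {trait_ids[0]: bx, trait_ids[1]: bm}
    active = [t for t, col in columns.items() if np.any(col != 0)]
    dropped = [t for t in columns if t not in active]
    X = np.column_stack([columns[t] for t in active]) if active else None
    if X is None or np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(trait_ids)
    w = 1.0 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    df = k - X.shape[1]
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / df)) if df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * scale**2
    coefficients: dict[str, Coefficient] = {}
    for j, trait in enumerate(active):
        se_j = float(np.sqrt(cov[j, j]))
        pval = float(2.0 * stats.t.sf(abs(coef[j] / se_j), df)) if df > 0 else 1.0
        coefficients[trait] = Coefficient(float(coef[j]), se_j, pval)
    for trait in dropped:
        coefficients[trait] = Coefficient(0.0, float("nan"), 1.0)
    return MvmrEstimate(
        coefficients=coefficients, n_snps=k, conditioning=tuple(trait_ids)
    )


@dataclass(frozen=True)
class IndirectEffect:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_: float
    or_ci_low: float
    or_ci_high: float


def indirect_effect(
    beta_xm: float,
    se_xm: float,
    beta_my: float,
    se_my: float,
    second_order: bool = False,
) -> IndirectEffect:
    """Product-of-coefficients indirect effect with delta-method CI.

    beta_indirect = beta_xm * beta_my; the first-order delta-method SE is
    sqrt(beta_my^2 se_xm^2 + beta_xm^2 se_my^2); ``second_order`` adds the
    se_xm^2 * se_my^2 cross term. The OR form exponentiates beta and CI.
    """
    beta = beta_xm * beta_my
    var = beta_my**2 * se_xm**2 + beta_xm**2 * se_my**2
    if second_order:
        var += se_xm**2 * se_my**2
    se = float(np.sqrt(var))
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return IndirectEffect(
        beta=float(beta),
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        or_=float(np.exp(beta)),
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
    )


@dataclass(frozen=True)
class ProportionResult:
    percent: float | None  # None when suppressed
    suppression_reason: str  # none | sign_discordant | indirect_ci_spans_zero


def proportion_mediated(
    beta_indirect: float,
    beta_total: float,
    indirect_ci: tuple[float, float] | None = None,
    suppress: bool = True,
) -> ProportionResult:
    """Proportion of the total effect carried by the indirect path, in %.

    Suppressed (``percent=None``) when the indirect and total effects are
    sign-discordant or when the indirect CI spans zero — a negative or
    over-100% "proportion" has no mediation interpretation. Both betas must
    be on the same (log-odds) scale. Pass ``suppress=False`` to always
    report the raw percentage.
    """
    if beta_total == 0:
        raise UndefinedProportionError("total effect is zero")
    percent = 100.0 * beta_indirect / beta_total
    if suppress:
        if np.sign(beta_indirect) != np.sign(beta_total):
            return ProportionResult(None, "sign_discordant")
        if indirect_ci is not None and indirect_ci[0] <= 0 <= indirect_ci[1]:
            return ProportionResult(None, "indirect_ci_spans_zero")
    return ProportionResult(float(percent), "none")


@dataclass
class MediationConfig:
    """Instrument-selection and screening settings for a mediation run."""

    pval_threshold: float = 1e-5
    window_kb: float = 1000.0
    r2_threshold: float = 0.001
    palindrome_policy: str = "drop"
    screen_alpha: float = 0.05
    suppress_proportion: bool = True
    ld: LDMatrix | None = None


@dataclass
class MediationResult:
    """Two-step mediation decomposition for one exposure/mediator/outcome."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    pval_total: float
    beta_xm: float
    se_xm: float
    pval_xm: float
    beta_my: float
    se_my: float
    pval_my: float
    indirect: IndirectEffect
    proportion: ProportionResult
    screen_passed: bool
    screen_reason: str = "none"
    n_snps_total: int = 0
    n_snps_step1: int = 0
    n_snps_mvmr: int = 0
    aux: dict = field(default_factory=dict)

    @property
    def beta_indirect(self) -> float:
        return self.indirect.beta

    @property
    def beta_direct(self) -> float:
        """Direct effect implied by the decomposition, total - indirect."""
        return self.beta_total - self.indirect.beta

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta_indirect": self.indirect.beta,
            "ci_low": self.indirect.ci_low,
            "ci_high": self.indirect.ci_high,
            "OR": self.indirect.or_,
            "or_ci_low": self.indirect.or_ci_low,
            "or_ci_high": self.indirect.or_ci_high,
            "proportion_mediated": self.proportion.percent,
            "suppression_reason": self.proportion.suppression_reason,
            "screen_passed": self.screen_passed,
        }


def _select_pairs(exposure, outcome, config) -> list[HarmonizedPair]:
    pairs = harmonize_datasets(
        exposure, outcome, palindrome_policy=config.palindrome_policy
    ).pairs
    pairs = filter_by_pvalue(pairs, config.pval_threshold)
    return clump(pairs, config.ld, config.window_kb, config.r2_threshold)


def _aligned_effect(
    record: VariantAssociation, effect_allele: str, other_allele: str
) -> float | None:
    """Beta of ``record`` expressed for ``effect_allele``; None if alleles differ."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    ea, oa = record.effect_allele, record.other_allele
    if (ea, oa) == (effect_allele, other_allele):
        return record.beta
    if (ea, oa) == (other_allele, effect_allele):
        return -record.beta
    if (comp.get(ea), comp.get(oa)) == (effect_allele, other_allele):
        return record.beta
    if (comp.get(ea), comp.get(oa)) == (other_allele, effect_allele):
        return -record.beta
    return None


def two_step_mediation(
    exposure: SummaryDataset,
    mediator: SummaryDataset,
    outcome: SummaryDataset,
    config: MediationConfig | None = None,
) -> MediationResult:
    """Run the full two-step mediation analysis for one triplet.

    Step 1 regresses the mediator on the exposure (univariable IVW over the
    exposure's instruments); step 2 takes the mediator's conditional effect
    on the outcome from a multivariable IVW over the pooled exposure and
    mediator instruments; the total effect is the univariable IVW of the
    exposure on the outcome. Heterogeneity (Cochran's Q p < 0.05) switches
    the univariable fits to multiplicative random effects.

    The pair is screened by requiring step-1 and mediator-to-outcome
    significance at ``screen_alpha``; a failed screen is reported in
    ``screen_passed`` / ``screen_reason`` rather than raising.
    """
    config = config or MediationConfig()

    total_pairs = _select_pairs(exposure, outcome, config)
    total = _auto_ivw(total_pairs)

    step1_pairs = _select_pairs(exposure, mediator, config)
    step1 = _auto_ivw(step1_pairs)

    # Pooled instrument set for the multivariable model: union of exposure
    # and mediator instruments, each SNP present in all three datasets.
    med_out_pairs = _select_pairs(mediator, outcome, config)
    pooled_ids = {p.snp_id for p in total_pairs} | {p.snp_id for p in med_out_pairs}
    exp_by, med_by, out_by = exposure.by_id(), mediator.by_id(), outcome.by_id()
    bx, bm, by, sy = [], [], [], []
    for snp_id in sorted(pooled_ids):
        if snp_id not in exp_by or snp_id not in med_by or snp_id not in out_by:
            continue
        ref = exp_by[snp_id]
        m = _aligned_effect(med_by[snp_id], ref.effect_allele, ref.other_allele)
        y = _aligned_effect(out_by[snp_id], ref.effect_allele, ref.other_allele)
        if m is None or y is None:
            continue
        bx.append(ref.beta)
        bm.append(m)
        by.append(y)
        sy.append(out_by[snp_id].se)
    mvmr = mvmr_ivw(bx, bm, by, sy, trait_ids=(exposure.trait_id, mediator.trait_id))
    my = mvmr.coefficients[mediator.trait_id]

    indirect = indirect_effect(step1.beta, step1.se, my.beta, my.se)
    proportion = proportion_mediated(
        indirect.beta,
        total.beta,
        indirect_ci=(indirect.ci_low, indirect.ci_high),
        suppress=config.suppress_proportion,
    )

    screen_reason = "none"
    if step1.pval >= config.screen_alpha:
        screen_reason = "step1_not_significant"
    elif my.pval >= config.screen_alpha:
        screen_reason = "mediator_outcome_not_significant"

    return MediationResult(
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        beta_total=total.beta,
        se_total=total.se,
        pval_total=total.pval,
        beta_xm=step1.beta,
        se_xm=step1.se,
        pval_xm=step1.pval,
        beta_my=my.beta,
        se_my=my.se,
        pval_my=my.pval,
        indirect=indirect,
        proportion=proportion,
        screen_passed=screen_reason == "none",
        screen_reason=screen_reason,
        n_snps_total=len(total_pairs),
        n_snps_step1=len(step1_pairs),
        n_snps_mvmr=mvmr.n_snps,
        aux={"mvmr": mvmr, "total_estimate": total, "step1_estimate": step1},
    )


def _auto_ivw(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Fixed-effect IVW, upgraded to multiplicative random effects when
    Cochran's Q at the fitted slope has p < 0.05."""
    est = ivw(pairs, mode="fixed")
    if est.n_snps >= 2:
        q, df = est.aux["q"], est.aux["q_df"]
        if float(stats.chi2.sf(q, df)) < 0.05:
            est = ivw(pairs, mode="multiplicative_random")
    return est
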