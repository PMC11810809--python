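"""Orchestration of the three analyses: forward univariable scan
(taxa / cytokines -> outcome), reverse scan (outcome -> taxa), and the
two-step mediation pipeline.

Each exposure runs through the same sequence: harmonize to the outcome,
association-threshold filter, LD clumping, confounder-list exclusion,
MR-PRESSO outlier removal, then the four estimators (IVW primary; MR-Egger,
weighted median, weighted mode secondary) with heterogeneity and pleiotropy
diagnostics. The primary IVW switches to multiplicative random effects when
Cochran's Q has p < 0.05. Multiple testing uses the per-rank Bonferroni rule
p < 0.05 / n with the effective numbers of distinct taxa per rank
(phylum 9, class 15, order 19, family 30, genus 117 by default).

Per-exposure failures (no overlap, no instruments) are logged and skipped;
only a fully empty run is an error. A run manifest capturing thresholds,
seeds and input digests makes reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diagnostics import (
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    presso_distortion,
)
from .errors import MrPathError
from .gwas_io import SummaryDataset
from .harmonize import harmonize_datasets
from .iv_select import LDMatrix, assemble_instruments
from .mr_estimators import egger, ivw, weighted_median, weighted_mode
from .mvmr_mediation import MediationConfig, MediationResult, two_step_mediation

__all__ = [
    "DEFAULT_BONFERRONI",
    "ScanConfig",
    "run_univariable_scan",
    "run_reverse_scan",
    "run_mediation_pipeline",
]

logger = logging.getLogger("mrpath")

#: Effective numbers of distinct taxa per rank for the Bonferroni criterion.
DEFAULT_BONFERRONI: dict[str, int] = {
    "phylum": 9,
    "class": 15,
    "order": 19,
    "family": 30,
    "genus": 117,
}

_SECONDARY_ORDER = ("egger", "weighted_median", "weighted_mode")


@dataclass
class ScanConfig:
    """Thresholds, estimator settings and seeds for a scan."""

    pval_threshold: float = 1e-5
    reverse_pval_threshold: float = 5e-8  # assumption: unstated for reverse runs
    window_kb: float = 1000.0
    r2_threshold: float = 0.001
    palindrome_policy: str = "drop"
    exclusion_list: Mapping[str, str] = field(default_factory=dict)
    ld: LDMatrix | None = None
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    bonferroni: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_BONFERRONI))
    presso_alpha: float = 0.05
    screen_alpha: float = 0.05

    def __post_init__(self) -> None:
        for rank, n in self.bonferroni.items():
            if n < 1:
                raise MrPathError(f"bonferroni n for rank {rank!r} must be >= 1")

    def derived_seed(self, index: int) -> int:
        # stable per-exposure stream, kept below 2**31
        return (self.seed * 100_003 + 7 * index + 13) % (2**31)


def _analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: ScanConfig,
    pval_threshold: float,
    rank: str | None,
    seed: int,
) -> list[dict]:
    """Instrument selection, estimation and diagnostics for one exposure."""
    harmonized = harmonize_datasets(
        exposure, outcome, palindrome_policy=config.palindrome_policy
    )
    instruments, iv_log = assemble_instruments(
        harmonized.pairs,
        ld=config.ld,
        pval_threshold=pval_threshold,
        window_kb=config.window_kb,
        r2_threshold=config.r2_threshold,
        exclusion_list=config.exclusion_list,
    )
    pairs = instruments.pairs
    if not pairs:
        raise MrPathError(
            f"no instruments for {exposure.trait_id!r} after selection"
        )

    presso = None
    n_outliers = 0
    distortion = None
    if len(pairs) >= 4:
        presso = mr_presso(
            pairs, n_sim=config.n_sim, seed=seed, outlier_alpha=config.presso_alpha
        )
        if presso.outlier_snp_ids:
            pre = ivw(pairs, mode="fixed")
            outliers = set(presso.outlier_snp_ids)
            pairs = [p for p in pairs if p.snp_id not in outliers]
            n_outliers = len(outliers)
            distortion = presso_distortion(pre, ivw(pairs, mode="fixed"))

    fixed = ivw(pairs, mode="fixed")
    het = None
    q_pval = None
    primary = fixed
    if fixed.n_snps >= 2:
        het = cochran_q(pairs, fixed.beta)
        q_pval = het.pval
        if het.pval < 0.05:
            primary = ivw(pairs, mode="multiplicative_random")

    intercept = None
    secondary = {}
    loo_flagged = None
    if len(pairs) >= 3:
        secondary["egger"] = egger(pairs)
        secondary["weighted_median"] = weighted_median(pairs, n_boot=config.n_boot, seed=seed)
        secondary["weighted_mode"] = weighted_mode(pairs, n_boot=config.n_boot, seed=seed)
        intercept = egger_intercept_test(pairs)
        loo_flagged = sum(e.flagged for e in leave_one_out(pairs))

    n_rank = config.bonferroni.get(rank) if rank else None
    passes = bool(primary.pval < 0.05 / n_rank) if n_rank else None
    discordant = any(
        est.beta * primary.beta < 0 for est in secondary.values()
    )

    shared = {
        "exposure": exposure.trait_id,
        "outcome": outcome.trait_id,
        "rank": rank,
        "q_pval": q_pval,
        "egger_intercept_pval": intercept.pval if intercept else None,
        "presso_global_pval": presso.global_pval if presso else None,
        "n_outliers_removed": n_outliers,
        "passes_bonferroni": passes,
        "sensitivity_discordant": discordant,
        "n_loo_flagged": loo_flagged,
        "mean_f": instruments.mean_f,
        "n_weak_instruments": len(instruments.weak_snp_ids),
    }
    if distortion is not None:
        shared["presso_distortion"] = distortion["difference"]

    rows = [dict(shared, **primary.to_row(), primary=True)]
    for name in _SECONDARY_ORDER:
        if name in secondary:
            rows.append(dict(shared, **secondary[name].to_row(), primary=False))
    return rows


def _run_scan(
    exposures: Sequence[tuple[SummaryDataset, str | None]],
    outcome: SummaryDataset,
    config: ScanConfig,
    pval_threshold: float,
) -> tuple[pd.DataFrame, dict]:
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    order: dict[str, float] = {}
    for i, (exposure, rank) in enumerate(exposures):
        try:
            exp_rows = _analyze_pair(
                exposure, outcome, config, pval_threshold, rank,
                seed=config.derived_seed(i),
            )
        except MrPathError as err:
            logger.warning("skipping exposure %s: %s", exposure.trait_id, err)
            skipped[exposure.trait_id] = str(err)
            continue
        order[exposure.trait_id] = next(
            r["pval"] for r in exp_rows if r["primary"]
        )
        rows.extend(exp_rows)
    if not rows:
        raise MrPathError("scan produced no results (all exposures failed)")
    frame = pd.DataFrame(rows)
    frame["_order"] = frame["exposure"].map(order)
    frame = frame.sort_values(
        ["_order", "exposure", "primary"], ascending=[True, True, False],
        kind="stable",
    ).drop(columns="_order").reset_index(drop=True)
    manifest = {
        "pval_threshold": pval_threshold,
        "window_kb": config.window_kb,
        "r2_threshold": config.r2_threshold,
        "palindrome_policy": config.palindrome_policy,
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
        "seed": config.seed,
        "bonferroni": dict(config.bonferroni),
        "n_exposures": len(exposures),
        "skipped": skipped,
        "outcome": outcome.trait_id,
    }
    return frame, manifest


def run_univariable_scan(
    exposures: Sequence[tuple[SummaryDataset, str | None]],
    outcome: SummaryDataset,
    config: ScanConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Forward scan: each exposure against the outcome.

    ``exposures`` is a sequence of (dataset, taxonomic rank or None) tuples;
    the rank keys the Bonferroni threshold. Returns the results table (rows
    sorted by primary IVW p, primary row first within each exposure) and the
    run manifest.
    """
    config = config or ScanConfig()
    return _run_scan(exposures, outcome, config, config.pval_threshold)


def run_reverse_scan(
    outcome_as_exposure: SummaryDataset,
    taxa_outcomes: Sequence[SummaryDataset],
    config: ScanConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Reverse scan: the disease as exposure against each taxon outcome.

    Uses the genome-wide instrument threshold (default 5e-8, configurable):
    disease GWAS are well powered, unlike the lenient forward threshold.
    """
    config = config or ScanConfig()
    manifest = None
    frames = []
    skipped: dict[str, str] = {}
    for taxon in taxa_outcomes:
        try:
            frame, manifest = _run_scan(
                [(outcome_as_exposure, None)], taxon, config,
                config.reverse_pval_threshold,
            )
        except MrPathError as err:
            logger.warning("skipping reverse outcome %s: %s", taxon.trait_id, err)
            skipped[taxon.trait_id] = str(err)
            continue
        frames.append(frame)
    if not frames:
        raise MrPathError("reverse scan produced no results (all outcomes failed)")
    combined = pd.concat(frames, ignore_index=True)
    manifest = dict(manifest or {}, direction="reverse",
                    n_outcomes=len(taxa_outcomes), skipped=skipped)
    return combined, manifest


def run_mediation_pipeline(
    exposures: Sequence[SummaryDataset],
    mediators: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    config: ScanConfig | None = None,
) -> tuple[list[MediationResult], dict]:
    """Screen every (exposure, mediator) pair and assemble mediation results.

    Pairs must pass the two-path significance screen (exposure -> mediator
    and mediator -> outcome conditional on the exposure, both at
    ``screen_alpha``); failing pairs are logged, not emitted. An empty result
    list is a valid outcome (the log says why).
    """
    config = config or ScanConfig()
    med_config = MediationConfig(
        pval_threshold=config.pval_threshold,
        window_kb=config.window_kb,
        r2_threshold=config.r2_threshold,
        palindrome_policy=config.palindrome_policy,
        screen_alpha=config.screen_alpha,
        ld=config.ld,
    )
    results: list[MediationResult] = []
    screened_out: dict[str, str] = {}
    for exposure in exposures:
        for mediator in mediators:
            key = f"{exposure.trait_id}->{mediator.trait_id}"
            try:
                res = two_step_mediation(exposure, mediator, outcome, med_config)
            except MrPathError as err:
                logger.warning("mediation pair %s failed: %s", key, err)
                screened_out[key] = str(err)
                continue
            if res.screen_passed:
                results.append(res)
            else:
                logger.info("pair %s screened out: %s", key, res.screen_reason)
                screened_out[key] = res.screen_reason
    manifest = {
        "pval_threshold": config.pval_threshold,
        "screen_alpha": config.screen_alpha,
        "seed": config.seed,
        "outcome": outcome.trait_id,
        "n_pairs_considered": len(exposures) * len(mediators),
        "n_pairs_reported": len(results),
        "screened_out": screened_out,
    }
    return results, manifest


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
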