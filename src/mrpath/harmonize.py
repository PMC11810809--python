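"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR combines effect estimates from two different GWAS, which may
report the same SNP with the alleles in either order or on opposite strands.
Harmonization aligns every outcome (or mediator) record to the exposure's
effect allele:

* same allele pair, same order — kept unchanged;
* same pair, swapped order — outcome beta sign-flipped, eaf complemented;
* pair matches after complementing both outcome alleles (A<->T, C<->G) — the
  outcome record is strand-complemented first, then the rule above applies;
* palindromic A/T or G/C SNPs — dropped under the default policy, because
  allele codes alone cannot distinguish a strand flip from an effect-allele
  swap; an opt-in ``infer`` policy keeps those whose allele frequency is far
  from 0.5 on both sides and orients them by frequency;
* anything irreconcilable (including indels and non-ACGT codes) — dropped as
  an allele mismatch.

SEs are never altered by harmonization, and |beta| is preserved by every
kept/flipped action.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .errors import EmptyOverlapError, UsageError
from .gwas_io import SummaryDataset, VariantAssociation

__all__ = [
    "HarmonizedPair",
    "HarmonizedSet",
    "harmonize_pair",
    "harmonize_datasets",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure-outcome effects for one SNP, aligned to one effect allele."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    pval_exp: float
    pval_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action: str  # kept | flipped | strand_complemented | dropped
    drop_reason: str = "none"  # none | allele_mismatch | palindromic | duplicate

    def __post_init__(self) -> None:
        if self.action == "dropped" and self.drop_reason == "none":
            raise UsageError("dropped pair requires a drop_reason")
        if self.action != "dropped" and self.drop_reason != "none":
            raise UsageError("retained pair must have drop_reason 'none'")

    @property
    def retained(self) -> bool:
        return self.action != "dropped"


def harmonize_pair(
    exp_rec: VariantAssociation,
    out_rec: VariantAssociation,
    palindrome_policy: str = "drop",
    maf_threshold: float = 0.42,
) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele.

    ``palindrome_policy`` is ``"drop"`` (default: discard all A/T and G/C
    SNPs) or ``"infer"`` (keep palindromic SNPs whose effect-allele frequency
    is below ``maf_threshold`` or above 1 - ``maf_threshold`` concordantly on
    both sides, orienting by frequency).
    """
    if exp_rec.snp_id != out_rec.snp_id:
        raise UsageError(
            f"snp_id mismatch: {exp_rec.snp_id!r} vs {out_rec.snp_id!r}"
        )
    if palindrome_policy not in ("drop", "infer"):
        raise UsageError(f"unknown palindrome policy {palindrome_policy!r}")

    def _pair(action, reason="none", beta_out=None, eaf_out=None):
        return HarmonizedPair(
            snp_id=exp_rec.snp_id,
            chrom=exp_rec.chrom,
            pos=exp_rec.pos,
            effect_allele=exp_rec.effect_allele,
            other_allele=exp_rec.other_allele,
            beta_exp=exp_rec.beta,
            se_exp=exp_rec.se,
            beta_out=out_rec.beta if beta_out is None else beta_out,
            se_out=out_rec.se,
            pval_exp=exp_rec.pval,
            pval_out=out_rec.pval,
            eaf_exp=exp_rec.eaf,
            eaf_out=out_rec.eaf if eaf_out is None else eaf_out,
            action=action,
            drop_reason=reason,
        )

    ea_x, oa_x = exp_rec.effect_allele, exp_rec.other_allele
    ea_y, oa_y = out_rec.effect_allele, out_rec.other_allele
    valid = all(a in _COMPLEMENT for a in (ea_x, oa_x, ea_y, oa_y))
    if not valid:
        return _pair("dropped", "allele_mismatch")

    if _is_palindromic(ea_x, oa_x):
        if palindrome_policy == "drop":
            return _pair("dropped", "palindromic")
        return _infer_palindrome(exp_rec, out_rec, maf_threshold, _pair)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return _pair("kept")
    if (ea_y, oa_y) == (oa_x, ea_x):
        return _pair("flipped", beta_out=-out_rec.beta, eaf_out=_complement_eaf(out_rec.eaf))
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return _pair("strand_complemented")
    if (cea, coa) == (oa_x, ea_x):
        return _pair(
            "strand_complemented",
            beta_out=-out_rec.beta,
            eaf_out=_complement_eaf(out_rec.eaf),
        )
    return _pair("dropped", "allele_mismatch")


def _complement_eaf(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def _infer_palindrome(exp_rec, out_rec, maf_threshold, _pair):
    """Frequency-based orientation of a palindromic SNP (infer policy).

    Requires both frequencies present and both MAFs below the threshold;
    the two records are oriented so their frequencies agree in direction.
    """
    fx, fy = exp_rec.eaf, out_rec.eaf
    if fx is None or fy is None:
        return _pair("dropped", "palindromic")
    if min(fx, 1 - fx) >= maf_threshold or min(fy, 1 - fy) >= maf_threshold:
        return _pair("dropped", "palindromic")
    if (fx < 0.5) == (fy < 0.5):
        return _pair("kept")
    return _pair("flipped", beta_out=-out_rec.beta, eaf_out=1.0 - fy)


@dataclass
class HarmonizedSet:
    """Result of harmonizing two datasets: retained pairs plus the QC log."""

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair]
    dropped: list[HarmonizedPair]
    drop_counts: dict[str, int]

    def qc_table(self):
        """QC dispositions as (snp_id, action, drop_reason) rows."""
        return [
            (p.snp_id, p.action, p.drop_reason)
            for p in sorted(self.pairs + self.dropped, key=lambda p: p.snp_id)
        ]


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def harmonize_datasets(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_policy: str = "drop",
    maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Harmonize every SNP shared between two datasets.

    Pairs are formed on shared snp_ids only and the retained set is ordered
    by (chromosome, position). Raises :class:`EmptyOverlapError` when the
    datasets share no SNPs.
    """
    exp_by_id = exposure.by_id()
    out_by_id = outcome.by_id()
    shared = set(exp_by_id) & set(out_by_id)
    if not shared:
        raise EmptyOverlapError(exposure.trait_id, outcome.trait_id)

    pairs: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []
    counts: dict[str, int] = {}
    for snp_id in sorted(shared):
        pair = harmonize_pair(
            exp_by_id[snp_id], out_by_id[snp_id], palindrome_policy, maf_threshold
        )
        if pair.retained:
            pairs.append(pair)
        else:
            dropped.append(pair)
            counts[pair.drop_reason] = counts.get(pair.drop_reason, 0) + 1
    pairs.sort(key=lambda p: (_chrom_key(p.chrom), p.pos, p.snp_id))
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        pairs=pairs,
        dropped=dropped,
        drop_counts=counts,
    )


def pairs_to_datasets(
    pairs: Sequence[HarmonizedPair],
    exposure: SummaryDataset,
    outcome: SummaryDataset,
) -> tuple[SummaryDataset, SummaryDataset]:
    """Rebuild aligned datasets from retained pairs (used for idempotence checks)."""
    exp_records, out_records = [], []
    for p in pairs:
        exp_records.append(
            VariantAssociation(
                snp_id=p.snp_id, chrom=p.chrom, pos=p.pos,
                effect_allele=p.effect_allele, other_allele=p.other_allele,
                beta=p.beta_exp, se=p.se_exp, pval=p.pval_exp, eaf=p.eaf_exp,
            )
        )
        out_records.append(
            VariantAssociation(
                snp_id=p.snp_id, chrom=p.chrom, pos=p.pos,
                effect_allele=p.effect_allele, other_allele=p.other_allele,
                beta=p.beta_out, se=p.se_out, pval=p.pval_out, eaf=p.eaf_out,
            )
        )
    exp_ds = replace(exposure, records=exp_records)
    out_ds = replace(outcome, records=out_records)
    return exp_ds, out_ds
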