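"""Data model and delimited-text I/O for GWAS summary statistics.

A GWAS summary-statistics file carries one row per SNP with the marginal
association of that variant with one trait: effect/other allele, effect-allele
frequency, effect size (per-SD units for continuous traits, log-odds for
binary ones), its standard error, p-value and sample size. This module
validates such files into :class:`SummaryDataset` objects, maintains the
bacterial-taxa registry with its known-group analysis filter, and writes the
result tables the downstream estimators produce.

Column names in the wild vary freely; readers take a ``column_map`` from
canonical field names to file column names, defaulting to
``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N``. Rows violating a field
invariant (non-positive SE, p outside (0, 1], identical or non-ACGT alleles,
frequency outside (0, 1)) are dropped and counted in a QC log rather than
aborting the read: real summary files routinely contain a few malformed rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    MrPathError,
    ValidationError,
)

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "RANKS",
    "VariantAssociation",
    "SummaryDataset",
    "TaxonMeta",
    "TaxaRegistry",
    "read_summary_tsv",
    "write_summary_tsv",
    "build_taxa_registry",
    "write_results_tsv",
]

#: Canonical field -> default file column name.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

#: Fields that must be mapped and present; eaf and n may be absent.
_MANDATORY_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)

_VALID_ALLELES = frozenset("ACGT")

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    Positions are 1-based; chromosome labels are opaque strings compared for
    equality. ``eaf`` is the effect-allele frequency and may be ``None`` when
    the source file does not report it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def invariant_violation(self) -> str | None:
        """Return a drop-reason string, or None if the record is valid."""
        ea, oa = self.effect_allele, self.other_allele
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            return "invalid_allele"
        if ea == oa:
            return "identical_alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "invalid_pval"
        if not math.isfinite(self.beta):
            return "invalid_beta"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "invalid_eaf"
        return None


@dataclass
class SummaryDataset:
    """A validated set of per-SNP associations for one trait.

    snp_ids are unique within a dataset (enforced on construction).
    """

    trait_id: str
    trait_role: str  # exposure | mediator | outcome
    effect_scale: str  # sd-units | log-odds
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_role not in ("exposure", "mediator", "outcome"):
            raise ValidationError(f"unknown trait_role {self.trait_role!r}")
        if self.effect_scale not in ("sd-units", "log-odds"):
            raise ValidationError(f"unknown effect_scale {self.effect_scale!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"duplicate snp_ids in dataset {self.trait_id!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass(frozen=True)
class TaxonMeta:
    """Registry entry for one bacterial taxon as printed in the source GWAS."""

    taxon_label: str
    rank: str
    known_group: bool = True

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValidationError(
                f"unknown rank {self.rank!r}; expected one of {RANKS}"
            )


@dataclass
class TaxaRegistry:
    """Per-rank totals plus, for each rank, the known-group analysis set.

    Taxa flagged ``known_group=False`` (e.g. unclassified "unknown genus"
    bins from 16S profiling) are excluded from the analysis set at their
    rank but still counted in the raw totals.
    """

    entries: list[TaxonMeta]
    rank_totals: dict[str, int]
    analysis_sets: dict[str, list[TaxonMeta]]

    @property
    def total(self) -> int:
        return sum(self.rank_totals.values())

    def analysis_count(self, rank: str) -> int:
        return len(self.analysis_sets.get(rank, []))


def build_taxa_registry(entries: Sequence[TaxonMeta]) -> TaxaRegistry:
    """Build the taxa registry with per-rank counts and analysis sets."""
    if not entries:
        raise ValidationError("taxa registry requires at least one entry")
    rank_totals: dict[str, int] = {}
    analysis_sets: dict[str, list[TaxonMeta]] = {}
    for entry in entries:  # TaxonMeta validates rank on construction
        rank_totals[entry.rank] = rank_totals.get(entry.rank, 0) + 1
        if entry.known_group:
            analysis_sets.setdefault(entry.rank, []).append(entry)
    return TaxaRegistry(list(entries), rank_totals, analysis_sets)


def _resolve_columns(
    columns: Iterable[str], column_map: Mapping[str, str]
) -> dict[str, str]:
    present = set(columns)
    resolved: dict[str, str] = {}
    for canonical in _MANDATORY_FIELDS:
        name = column_map.get(canonical)
        if name is None:
            raise ConfigurationError(
                f"column map does not define mandatory field {canonical!r}"
            )
        if name not in present:
            raise ConfigurationError(
                f"mandatory column {name!r} (field {canonical!r}) missing from file"
            )
        resolved[canonical] = name
    for optional in ("eaf", "n"):
        name = column_map.get(optional)
        if name is not None and name in present:
            resolved[optional] = name
    return resolved


def read_summary_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_role: str = "exposure",
    effect_scale: str = "sd-units",
    trait_id: str | None = None,
) -> tuple[SummaryDataset, dict[str, int]]:
    """Read a tab-separated summary-statistics file.

    Returns the validated dataset and a QC log counting dropped rows by
    reason. Alleles are upper-cased before validation. Duplicate snp_ids keep
    the record with the smallest p (reason ``duplicate``).

    Raises :class:`ConfigurationError` if a mandatory column is absent and
    :class:`EmptyDatasetError` if no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(frame.columns, cmap)

    qc: dict[str, int] = {}

    def _count(reason: str) -> None:
        qc[reason] = qc.get(reason, 0) + 1

    records: list[VariantAssociation] = []
    for row in frame.itertuples(index=False):
        raw = {k: getattr(row, v) for k, v in resolved.items()}
        try:
            rec = VariantAssociation(
                snp_id=str(raw["snp_id"]),
                chrom=str(raw["chrom"]),
                pos=int(float(raw["pos"])),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                eaf=_opt_float(raw.get("eaf")),
                n=_opt_float(raw.get("n")),
            )
        except (TypeError, ValueError):
            _count("unparseable_row")
            continue
        reason = rec.invariant_violation()
        if reason is not None:
            _count(reason)
            continue
        records.append(rec)

    # Keep the smallest-p record per snp_id; deterministic under ties.
    best: dict[str, VariantAssociation] = {}
    deduped: list[VariantAssociation] = []
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
            deduped.append(rec)
        else:
            _count("duplicate")
            if rec.pval < prev.pval:
                deduped[deduped.index(prev)] = rec
                best[rec.snp_id] = rec

    if not deduped:
        raise EmptyDatasetError(f"no valid rows in {path}")
    dataset = SummaryDataset(
        trait_id=trait_id if trait_id is not None else path.stem,
        trait_role=trait_role,
        effect_scale=effect_scale,
        records=deduped,
    )
    return dataset, qc


def _opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def write_summary_tsv(
    dataset: SummaryDataset,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a dataset in the same TSV dialect :func:`read_summary_tsv` reads."""
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    frame = dataset.to_frame()
    cols = [f for f in cmap if f in frame.columns]
    out = frame[cols].rename(columns={f: cmap[f] for f in cols})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "OR",
    "ci_low",
    "ci_high",
    "pval",
    "q_pval",
    "egger_intercept_pval",
    "passes_bonferroni",
]

MEDIATION_COLUMNS = [
    "exposure",
    "mediator",
    "outcome",
    "beta_indirect",
    "ci_low",
    "ci_high",
    "OR",
    "or_ci_low",
    "or_ci_high",
    "proportion_mediated",
]

#: Cell used where the mediation proportion is suppressed.
SUPPRESSED_CELL = "—"  # em dash, as in published mediation tables


def write_results_tsv(results: Sequence, path: str | Path) -> None:
    """Write MR or mediation results as a tab-separated table.

    ``results`` is a non-empty sequence of row mappings, or objects exposing
    ``to_row()`` (as :class:`~mrpath.mr_estimators.MREstimate` and
    :class:`~mrpath.mvmr_mediation.MediationResult` do). Odds ratios and CI
    bounds are formatted to 3 decimals; a suppressed mediation proportion is
    rendered as an em dash. The file is not created when the input is empty.
    """
    if not results:
        raise MrPathError("refusing to write an empty results table")
    rows = []
    for item in results:
        row = dict(item.to_row() if hasattr(item, "to_row") else item)
        rows.append(_format_row(row))
    frame = pd.DataFrame(rows)
    is_mediation = "beta_indirect" in frame.columns
    order = MEDIATION_COLUMNS if is_mediation else RESULT_COLUMNS
    cols = [c for c in order if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame[cols].to_csv(path, sep="\t", index=False)


_THREE_DP = ("OR", "ci_low", "ci_high", "or_ci_low", "or_ci_high")


def _format_row(row: dict) -> dict:
    out = dict(row)
    for key in _THREE_DP:
        if key in out and out[key] is not None and not _is_str(out[key]):
            out[key] = f"{float(out[key]):.3f}"
    pm = out.get("proportion_mediated")
    if "proportion_mediated" in out:
        if pm is None or (isinstance(pm, float) and np.isnan(pm)):
            out["proportion_mediated"] = SUPPRESSED_CELL
        elif not _is_str(pm):
            out["proportion_mediated"] = f"{float(pm):.3f}%"
    return out


def _is_str(x) -> bool:
    return isinstance(x, str)
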