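"""Instrument selection: p-value threshold, greedy LD clumping, confounder
exclusion, and per-SNP instrument-strength metrics.

A valid instrument must be robustly associated with the exposure (association
threshold, default p < 1e-5 as used for microbiome GWAS where genome-wide hits
are scarce), approximately independent of other instruments (LD clumping with
a 1000 kb window and r-squared < 0.001), and free of known confounder
associations (handled through a user-supplied exclusion list, replacing a
live PhenoScanner lookup).

Instrument strength is summarised per SNP by the variance explained
``R^2 = 2 * MAF * (1 - MAF) * beta^2`` and the F statistic
``F = beta^2 / se^2``; F < 10 conventionally flags a weak instrument, which
is reported but never used to drop SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .harmonize import HarmonizedPair

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "filter_by_pvalue",
    "clump",
    "exclude_snps",
    "instrument_strength",
    "assemble_instruments",
]


@dataclass
class LDMatrix:
    """Pairwise LD r-squared for an ordered set of SNPs.

    Square, symmetric, unit diagonal, entries in [0, 1]. SNPs absent from the
    matrix are treated as unlinked (r2 = 0) with a warning, since shipping a
    reference panel is out of scope.
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValidationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix must have unit diagonal")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float | None:
        """r2 between two SNPs, or None when either is not covered."""
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.columns), frame.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


def filter_by_pvalue(
    pairs: Sequence[HarmonizedPair], threshold: float = 1e-5
) -> list[HarmonizedPair]:
    """Retain pairs whose exposure p-value is strictly below ``threshold``."""
    if not (0 < threshold <= 1):
        raise ConfigurationError(
            f"p-value threshold must lie in (0, 1], got {threshold}"
        )
    return [p for p in pairs if p.pval_exp < threshold]


def clump(
    pairs: Sequence[HarmonizedPair],
    ld: LDMatrix | None,
    window_kb: float = 1000,
    r2_threshold: float = 0.001,
) -> list[HarmonizedPair]:
    """Greedy LD clumping: keep index SNPs, eliminate their LD partners.

    Repeatedly takes the remaining SNP with the smallest exposure p-value
    (ties broken by snp_id) as the index, then eliminates every other
    remaining SNP on the same chromosome within ``window_kb`` kilobases whose
    r2 with the index is at or above ``r2_threshold``. SNP pairs missing from
    the LD matrix (or the whole matrix, when ``ld`` is None) are treated as
    unlinked, with a warning.

    The retained set is independent of input order and is returned in the
    input's ordering.
    """
    if window_kb <= 0:
        raise ConfigurationError("clump window must be positive")
    if not (0 <= r2_threshold <= 1):
        raise ConfigurationError("clump r2 threshold must lie in [0, 1]")
    remaining = sorted(pairs, key=lambda p: (p.pval_exp, p.snp_id))
    window_bp = window_kb * 1000.0
    retained_ids: set[str] = set()
    warned_missing = False
    while remaining:
        index = remaining.pop(0)
        retained_ids.add(index.snp_id)
        survivors = []
        for other in remaining:
            if other.chrom == index.chrom and abs(other.pos - index.pos) <= window_bp:
                r2 = ld.lookup(index.snp_id, other.snp_id) if ld is not None else None
                if r2 is None:
                    if not warned_missing and ld is not None:
                        warnings.warn(
                            "LD matrix does not cover all candidate SNPs; "
                            "missing pairs treated as r2 = 0",
                            stacklevel=2,
                        )
                        warned_missing = True
                    r2 = 0.0
                if r2 >= r2_threshold:
                    continue  # eliminated by the index SNP
            survivors.append(other)
        remaining = survivors
    return [p for p in pairs if p.snp_id in retained_ids]


def exclude_snps(
    pairs: Sequence[HarmonizedPair],
    exclusion_list: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[list[HarmonizedPair], dict[str, int]]:
    """Remove listed SNPs (e.g. confounder-associated ones) from the set.

    ``exclusion_list`` maps snp_id -> reason. Listed ids absent from the set
    are logged under ``not_found``. Returns (retained pairs, per-reason log).
    """
    excl = dict(exclusion_list)
    present = {p.snp_id for p in pairs}
    log: dict[str, int] = {}
    for snp_id, reason in excl.items():
        key = reason if snp_id in present else "not_found"
        log[key] = log.get(key, 0) + 1
    return [p for p in pairs if p.snp_id not in excl], log


def read_exclusion_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (snp_id, reason) exclusion list."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ConfigurationError("exclusion list needs snp_id and reason columns")
    first, second = frame.columns[:2]
    return dict(zip(frame[first], frame[second]))


def instrument_strength(pair: HarmonizedPair) -> tuple[float | None, float]:
    """Per-SNP variance explained and F statistic on the exposure side.

    R^2 = 2 * MAF * (1 - MAF) * beta_exp^2 with MAF = min(eaf, 1 - eaf);
    F = beta_exp^2 / se_exp^2. R^2 is None when eaf is missing; F is always
    computed.
    """
    f_stat = pair.beta_exp**2 / pair.se_exp**2
    if pair.eaf_exp is None:
        return None, f_stat
    maf = min(pair.eaf_exp, 1.0 - pair.eaf_exp)
    r2 = 2.0 * maf * (1.0 - maf) * pair.beta_exp**2
    return r2, f_stat


@dataclass
class InstrumentSet:
    """Post-QC instruments with per-SNP strength metrics and provenance."""

    pairs: list[HarmonizedPair]
    r2_explained: list[float | None]
    f_stats: list[float]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def weak_snp_ids(self) -> list[str]:
        """SNPs with F < 10, reported but never dropped."""
        return [p.snp_id for p, f in zip(self.pairs, self.f_stats) if f < 10]

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if self.f_stats else float("nan")


def assemble_instruments(
    pairs: Sequence[HarmonizedPair],
    ld: LDMatrix | None = None,
    pval_threshold: float = 1e-5,
    window_kb: float = 1000,
    r2_threshold: float = 0.001,
    exclusion_list: Mapping[str, str] | None = None,
) -> tuple[InstrumentSet, dict]:
    """Full instrument-selection sequence: p filter, clump, exclude, score.

    Returns the instrument set plus a log with per-stage counts.
    """
    selected = filter_by_pvalue(pairs, pval_threshold)
    n_after_p = len(selected)
    selected = clump(selected, ld, window_kb, r2_threshold)
    n_after_clump = len(selected)
    excl_log: dict[str, int] = {}
    if exclusion_list:
        selected, excl_log = exclude_snps(selected, exclusion_list)
    strengths = [instrument_strength(p) for p in selected]
    instruments = InstrumentSet(
        pairs=list(selected),
        r2_explained=[s[0] for s in strengths],
        f_stats=[s[1] for s in strengths],
        provenance={
            "pval_threshold": pval_threshold,
            "window_kb": window_kb,
            "r2_threshold": r2_threshold,
            "n_excluded": len(exclusion_list or {}),
        },
    )
    log = {
        "n_input": len(pairs),
        "n_after_pvalue": n_after_p,
        "n_after_clump": n_after_clump,
        "n_final": len(instruments),
        "exclusions": excl_log,
        "n_weak": len(instruments.weak_snp_ids),
    }
    return instruments, log
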