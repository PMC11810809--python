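"""Seeded generator of two-sample GWAS summary statistics with a known
exposure -> mediator -> outcome causal structure.

The generator is summary-level: it never simulates genotypes. For SNP j with
minor-allele frequency p_j ~ Uniform(maf_range), the genotype variance is
v_j = 2 p_j (1 - p_j) and a GWAS of n individuals on a standardized trait
observes the true per-allele effect with standard error 1 / sqrt(v_j n)
exactly. The genetic architecture is sparse, as in real data: each SNP belongs to
one instrument class. Exposure instruments carry gamma_j ~ N(0,
sigma_gamma^2) on the exposure; mediator instruments carry eta_j ~ N(0,
sigma_eta^2) directly on the mediator (what real mediator-GWAS instruments
are, and what makes the mediator's conditional effect identifiable in a
multivariable fit); outcome instruments carry omega_j ~ N(0, sigma_omega^2)
on the outcome only (the disease's own risk loci, which a reverse-direction
analysis uses). The structural coefficients alpha (exposure -> mediator),
b (mediator -> outcome) and c_direct (exposure -> outcome) propagate them:

    beta_exp_j = gamma_j                       (+ sampling noise)
    beta_med_j = alpha gamma_j + eta_j         (+ sampling noise)
    beta_out_j = (c_direct + alpha b) gamma_j + b eta_j + omega_j
                 + s_j delta_j                 (+ sampling noise)

where delta_j is any horizontal-pleiotropy term and s_j = sign(gamma_j):
directional pleiotropy is defined on the exposure-increasing allele, the
orientation in which the MR-Egger intercept estimates its mean.

There is no outcome -> exposure path, but note that when the forward effect
is non-null the outcome GWAS hits include the exposure's instruments, so a
naive reverse analysis is contaminated exactly as it is with real data;
clean reverse-direction calibration checks therefore use a null forward
path. Association-threshold
selection on the relevant trait recovers each class: mediator instruments
have null exposure effects and vice versa.

Knobs map onto the three instrumental-variable assumptions: instrument
strength (sigma_gamma and the sample sizes set the F-statistic scale),
exchangeability/exclusion (balanced or directional pleiotropy with optional
correlation between delta_j and gamma_j, i.e. an InSIDE violation), and
independence between instruments (block LD realized as correlated effect
noise with block positions inside the clumping window).

Defaults encode the study conditions this package is exercised under:
MiBioGen-scale exposure GWAS (n = 18,340), a cytokine-scale mediator GWAS
(n = 15,000), an AF-scale outcome GWAS (n = 1,030,836), mean instrument
F of about 30, and the mediation pathway alpha = 0.2, b = 0.3,
c_direct = 0.1 (proportion mediated 37.5%).

Everything derives from the single config seed; identical configs produce
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import SummaryDataset, VariantAssociation
from .iv_select import LDMatrix

__all__ = [
    "PleiotropyConfig",
    "LDBlockConfig",
    "SimulationConfig",
    "TripletTruth",
    "SimulatedTriplet",
    "simulate_triplet",
    "make_ld_fixture",
]

_MIN_P = 1e-300  # p-values are clamped away from exact zero

_NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal-pleiotropy mechanism added to the outcome betas."""

    mode: str = "none"  # none | balanced | directional
    prob: float = 0.0  # fraction of SNPs carrying a pleiotropic effect
    mean: float = 0.0  # mean pleiotropic effect (directional mode)
    sd: float = 0.0

    def validate(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"invalid pleiotropy mode {self.mode!r}")
        if not (0 <= self.prob <= 1):
            raise ConfigurationError("pleiotropy prob must lie in [0, 1]")
        if self.sd < 0:
            raise ConfigurationError("pleiotropy sd must be non-negative")


@dataclass(frozen=True)
class LDBlockConfig:
    """Block LD: ``n_blocks`` blocks of ``block_size`` SNPs at ``within_r2``."""

    n_blocks: int
    block_size: int
    within_r2: float

    def validate(self) -> None:
        if self.block_size < 1 or self.n_blocks < 1:
            raise ConfigurationError("ld_blocks requires block_size, n_blocks >= 1")
        if not (0 <= self.within_r2 <= 1):
            raise ConfigurationError("within_r2 must lie in [0, 1]")


@dataclass
class SimulationConfig:
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 18_340
    n_med: int = 15_000
    n_out: int = 1_030_836
    sigma_gamma: float = 0.066
    sigma_eta: float = 0.073
    sigma_omega: float = 0.0088
    mediator_snp_fraction: float = 0.3
    outcome_snp_fraction: float = 0.2
    alpha: float = 0.2
    b: float = 0.3
    c_direct: float = 0.1
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    inside_violation: float = 0.0  # corr(delta_j, gamma_j) among pleiotropic SNPs
    ld_blocks: Optional[LDBlockConfig] = None
    palindrome_fraction: float = 0.15
    eaf_noise_sd: float = 0.0  # optional frequency noise for harmonization stress tests
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        if self.sigma_gamma <= 0:
            raise ConfigurationError("sigma_gamma must be positive")
        if self.sigma_eta < 0:
            raise ConfigurationError("sigma_eta must be non-negative")
        if self.sigma_omega < 0:
            raise ConfigurationError("sigma_omega must be non-negative")
        for name in ("mediator_snp_fraction", "outcome_snp_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.mediator_snp_fraction + self.outcome_snp_fraction > 1:
            raise ConfigurationError(
                "mediator_snp_fraction + outcome_snp_fraction must not exceed 1"
            )
        if not (0 <= self.palindrome_fraction <= 1):
            raise ConfigurationError("palindrome_fraction must lie in [0, 1]")
        if not (-1 <= self.inside_violation <= 1):
            raise ConfigurationError("inside_violation must lie in [-1, 1]")
        if self.eaf_noise_sd < 0:
            raise ConfigurationError("eaf_noise_sd must be non-negative")
        self.pleiotropy.validate()
        if self.ld_blocks is not None:
            self.ld_blocks.validate()


@dataclass
class TripletTruth:
    """Ground-truth estimands of the simulated mediation pathway."""

    alpha: float
    b: float
    c_direct: float
    gamma: np.ndarray
    eta: np.ndarray
    omega: np.ndarray
    delta: np.ndarray

    @property
    def beta_indirect(self) -> float:
        return self.alpha * self.b

    @property
    def beta_total(self) -> float:
        return self.c_direct + self.alpha * self.b

    @property
    def proportion(self) -> float:
        return self.beta_indirect / self.beta_total

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("alpha", self.alpha),
            ("b", self.b),
            ("c_direct", self.c_direct),
            ("beta_total", self.beta_total),
            ("beta_indirect", self.beta_indirect),
            ("proportion", self.proportion),
        ]
        pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SimulatedTriplet:
    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: TripletTruth


def _block_sizes(config: SimulationConfig) -> list[int]:
    if config.ld_blocks is None:
        return [1] * config.n_snps
    sizes = []
    remaining = config.n_snps
    n_blocks = config.ld_blocks.n_blocks
    size = config.ld_blocks.block_size
    for _ in range(n_blocks):
        take = min(size, remaining)
        if take == 0:
            break
        sizes.append(take)
        remaining -= take
    sizes.extend([1] * remaining)  # SNPs beyond the blocks are unlinked
    return sizes


def _block_noise(rng, sizes: list[int], r2: float, n_snps: int) -> np.ndarray:
    """Standard-normal vector with equicorrelation r2 inside each block."""
    z = rng.standard_normal(n_snps)
    if r2 <= 0:
        return z
    r = np.sqrt(r2)
    out = np.empty(n_snps)
    start = 0
    for size in sizes:
        shared = rng.standard_normal()
        out[start : start + size] = r * shared + np.sqrt(1 - r2) * z[start : start + size]
        start += size
    return out


def make_ld_fixture(ld_blocks: LDBlockConfig, n_snps: int | None = None,
                    snp_ids: list[str] | None = None) -> LDMatrix:
    """Block-diagonal r2 matrix: ``within_r2`` inside blocks, 0 between."""
    ld_blocks.validate()
    if n_snps is None:
        n_snps = ld_blocks.n_blocks * ld_blocks.block_size
    sizes = []
    remaining = n_snps
    for _ in range(ld_blocks.n_blocks):
        take = min(ld_blocks.block_size, remaining)
        if take == 0:
            break
        sizes.append(take)
        remaining -= take
    sizes.extend([1] * remaining)
    r2 = np.zeros((n_snps, n_snps))
    start = 0
    for size in sizes:
        r2[start : start + size, start : start + size] = ld_blocks.within_r2
        start += size
    np.fill_diagonal(r2, 1.0)
    if snp_ids is None:
        snp_ids = [f"rs{1000001 + i}" for i in range(n_snps)]
    return LDMatrix(snp_ids, r2)


def simulate_triplet(config: SimulationConfig) -> SimulatedTriplet:
    """Generate exposure, mediator and outcome summary datasets plus LD truth.

    See the module docstring for the generative model. The returned LD matrix
    matches the block structure used for the correlated effect noise (the
    identity when ``ld_blocks`` is None), and block members are placed within
    the 1000 kb clumping window while unlinked SNPs are separated by 10 Mb.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    sizes = _block_sizes(config)
    r2 = config.ld_blocks.within_r2 if config.ld_blocks is not None else 0.0

    maf = rng.uniform(*config.maf_range, size=k)
    v = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(v * config.n_exp)
    se_m = 1.0 / np.sqrt(v * config.n_med)
    se_y = 1.0 / np.sqrt(v * config.n_out)

    # Sparse architecture: contiguous segments [exposure | mediator | outcome]
    # so LD blocks stay within one instrument class.
    n_med_snps = int(round(config.mediator_snp_fraction * k))
    n_out_snps = int(round(config.outcome_snp_fraction * k))
    idx = np.arange(k)
    is_out = idx >= k - n_out_snps
    is_med = (idx >= k - n_out_snps - n_med_snps) & ~is_out
    is_exp = ~is_med & ~is_out
    gamma = config.sigma_gamma * _block_noise(rng, sizes, r2, k) * is_exp
    eta = config.sigma_eta * _block_noise(rng, sizes, r2, k) * is_med
    omega = config.sigma_omega * _block_noise(rng, sizes, r2, k) * is_out
    delta = _pleiotropy(rng, config, gamma)

    bx = gamma + se_x * _block_noise(rng, sizes, r2, k)
    bm = config.alpha * gamma + eta + se_m * _block_noise(rng, sizes, r2, k)
    theta = config.c_direct + config.alpha * config.b
    orient = np.where(gamma < 0, -1.0, 1.0)  # exposure-increasing allele frame
    by = (theta * gamma + config.b * eta + omega + orient * delta
          + se_y * _block_noise(rng, sizes, r2, k))

    chroms, positions = _positions(sizes)
    alleles = _alleles(rng, config.palindrome_fraction, k)
    eaf = maf.copy()
    if config.eaf_noise_sd > 0:
        eaf = np.clip(eaf + config.eaf_noise_sd * rng.standard_normal(k), 1e-4, 0.9999)
    snp_ids = [f"rs{1000001 + i}" for i in range(k)]

    def _dataset(trait_id, role, scale, beta, se, n):
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), _MIN_P, 1.0)
        records = [
            VariantAssociation(
                snp_id=snp_ids[j],
                chrom=chroms[j],
                pos=int(positions[j]),
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pvals[j]),
                eaf=float(eaf[j]),
                n=float(n),
            )
            for j in range(k)
        ]
        return SummaryDataset(trait_id, role, scale, records)

    exposure = _dataset("exposure", "exposure", "sd-units", bx, se_x, config.n_exp)
    mediator = _dataset("mediator", "mediator", "sd-units", bm, se_m, config.n_med)
    outcome = _dataset("outcome", "outcome", "log-odds", by, se_y, config.n_out)

    ld = _ld_from_sizes(snp_ids, sizes, r2)
    truth = TripletTruth(
        alpha=config.alpha, b=config.b, c_direct=config.c_direct,
        gamma=gamma, eta=eta, omega=omega, delta=delta,
    )
    return SimulatedTriplet(exposure, mediator, outcome, ld, truth)


def _pleiotropy(rng, config: SimulationConfig, gamma: np.ndarray) -> np.ndarray:
    k = len(gamma)
    plei = config.pleiotropy
    if plei.mode == "none":
        return np.zeros(k)
    mask = rng.random(k) < plei.prob
    mean = plei.mean if plei.mode == "directional" else 0.0
    rho = config.inside_violation
    z = rng.standard_normal(k)
    core = plei.sd * (rho * gamma / config.sigma_gamma + np.sqrt(1 - rho**2) * z)
    return mask * (mean + core)


def _positions(sizes: list[int]) -> tuple[list[str], list[int]]:
    """Block members 10 kb apart (inside the clumping window); blocks 10 Mb
    apart (outside it), cycling over chromosomes 1-22."""
    chroms: list[str] = []
    positions: list[int] = []
    for i_block, size in enumerate(sizes):
        chrom = str(i_block % 22 + 1)
        start = 1_000_000 + (i_block // 22) * 10_000_000
        for j in range(size):
            chroms.append(chrom)
            positions.append(start + j * 10_000)
    return chroms, positions


def _alleles(rng, palindrome_fraction: float, k: int) -> list[tuple[str, str]]:
    is_pal = rng.random(k) < palindrome_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    other_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=k)
    return [
        _PALINDROMIC_PAIRS[pal_idx[j]] if is_pal[j] else _NON_PALINDROMIC_PAIRS[other_idx[j]]
        for j in range(k)
    ]


def _ld_from_sizes(snp_ids, sizes, within_r2) -> LDMatrix:
    k = len(snp_ids)
    r2 = np.zeros((k, k))
    start = 0
    for size in sizes:
        r2[start : start + size, start : start + size] = within_r2
        start += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(list(snp_ids), r2)
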