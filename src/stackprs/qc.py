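"""Variant-level quality control.

The cascade applied before GWAS and scoring, in order: missing-call-rate
filter, minor-allele-frequency filter, Hardy–Weinberg exact-test filter,
removal of strand-ambiguous variants (A/T, C/G), deduplication by position,
and an imputation-quality (INFO) filter.  Default thresholds: missing rate
0.05, MAF 0.01, HWE p 1e-10, INFO 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "missing_rate",
    "filter_missing",
    "allele_freq",
    "filter_maf",
    "hwe_exact_p",
    "filter_hwe",
    "remove_ambiguous",
    "dedup_positions",
    "filter_info",
    "run_qc",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class QcThresholds:
    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-10
    min_info: float = 0.7


@dataclass
class QcReport:
    """Per-filter removal counts, in order of application."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_surviving: int = 0

    def check(self) -> None:
        if sum(self.removed.values()) != self.n_input - self.n_surviving:
            raise AssertionError("QC report does not account for every removal")

    def to_tsv(self) -> str:
        lines = ["filter\tremoved"]
        lines += [f"{k}\t{v}" for k, v in self.removed.items()]
        lines.append(f"surviving\t{self.n_surviving}")
        return "\n".join(lines) + "\n"


# -- per-variant statistics -------------------------------------------------


def _col(g: GenotypeMatrix, vid: str) -> np.ndarray:
    return g.genotypes[:, g.vid_index()[vid]]


def missing_rate(g: GenotypeMatrix, vid: str) -> float:
    x = _col(g, vid)
    return float(np.mean(x == MISSING))


def _missing_rates(g: GenotypeMatrix) -> np.ndarray:
    return np.mean(g.genotypes == MISSING, axis=0)


def allele_freq(g: GenotypeMatrix, vid: str) -> float:
    """Frequency of the counted allele (allele1) over non-missing genotypes."""
    x = _col(g, vid)
    obs = x != MISSING
    if not obs.any():
        return float("nan")
    return float(x[obs].mean() / 2.0)


def _allele_freqs(g: GenotypeMatrix) -> np.ndarray:
    x = g.genotypes.astype(float)
    obs = x != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_obs > 0, np.where(obs, x, 0.0).sum(axis=0) / (2.0 * n_obs), np.nan)


# -- Hardy-Weinberg exact test ---------------------------------------------


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count of the same parity whose exact probability does
    not exceed that of the observed table (two-sided, no mid-p correction).
    Computed in log space; a relative guard of 1e-12 absorbs rounding in the
    <= comparison.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)

    # P(het = h | allele counts) ∝ n! / (hom1! het! hom2!) * 2^h, h ≡ rare (mod 2)
    hs = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hs) // 2
    hom_common = (max(n_a, n_b) - rare) // 2 + hom_rare
    logw = (
        hs * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hs + 1)
        - gammaln(hom_common + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(x: np.ndarray) -> tuple[int, int, int]:
    return int(np.sum(x == 2)), int(np.sum(x == 1)), int(np.sum(x == 0))


# -- filters ----------------------------------------------------------------


def filter_missing(g: GenotypeMatrix, max_rate: float = 0.05) -> GenotypeMatrix:
    """Remove variants whose missing call rate is strictly over ``max_rate``."""
    if not (0.0 <= max_rate <= 1.0):
        raise ValueError(f"max_rate must be in [0, 1], got {max_rate}")
    keep = np.flatnonzero(_missing_rates(g) <= max_rate)
    return g.subset_variants(keep)


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Keep variants whose minor-allele frequency is at least ``min_maf``."""
    f = _allele_freqs(g)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= min_maf)
    return g.subset_variants(keep)


def filter_hwe(g: GenotypeMatrix, min_p: float = 1e-10, controls: np.ndarray | None = None) -> GenotypeMatrix:
    """Remove variants whose HWE exact p-value is strictly under ``min_p``.

    ``controls`` optionally restricts the test to a boolean control mask
    (cases and controls are pooled by default).
    """
    rows = np.flatnonzero(controls) if controls is not None else slice(None)
    keep = []
    for j in range(g.n_variants):
        x = g.genotypes[rows, j]
        x = x[x != MISSING]
        if x.size == 0 or hwe_exact_p(*_genotype_counts(x)) >= min_p:
            keep.append(j)
    return g.subset_variants(keep)


def remove_ambiguous(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop strand-ambiguous variants (allele pair A/T or C/G)."""
    keep = [
        j for j, v in enumerate(g.variants)
        if frozenset((v.allele1.upper(), v.allele2.upper())) not in _AMBIGUOUS
    ]
    return g.subset_variants(keep)


def dedup_positions(g: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse variants sharing (chrom, pos): keep the lowest missing rate,
    then the lexicographically smallest vid."""
    rates = _missing_rates(g)
    best: dict[tuple[str, int], int] = {}
    for j, v in enumerate(g.variants):
        key = (v.chrom, v.pos)
        if key not in best:
            best[key] = j
        else:
            k = best[key]
            if (rates[j], v.vid) < (rates[k], g.variants[k].vid):
                best[key] = j
    keep = sorted(best.values())
    return g.subset_variants(keep)


def filter_info(g: GenotypeMatrix, min_info: float = 0.7) -> GenotypeMatrix:
    """Remove imputed variants with INFO score strictly under ``min_info``.

    Variants without an INFO score (directly genotyped array variants) pass.
    """
    keep = [
        j for j, v in enumerate(g.variants)
        if v.info_score is None or v.info_score >= min_info
    ]
    return g.subset_variants(keep)


def run_qc(
    g: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    controls: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full QC cascade; raises if no variant survives."""
    report = QcReport(n_input=g.n_variants)
    stages = [
        ("missing_rate", lambda m: filter_missing(m, thresholds.max_missing_rate)),
        ("maf", lambda m: filter_maf(m, thresholds.min_maf)),
        ("hwe", lambda m: filter_hwe(m, thresholds.min_hwe_p, controls=controls)),
        ("ambiguous", remove_ambiguous),
        ("dup_position", dedup_positions),
        ("info", lambda m: filter_info(m, thresholds.min_info)),
    ]
    for name, fn in stages:
        before = g.n_variants
        g = fn(g)
        report.removed[name] = before - g.n_variants
    report.n_surviving = g.n_variants
    report.check()
    if g.n_variants == 0:
        raise ValueError("no variants survive quality control")
    return g, report
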