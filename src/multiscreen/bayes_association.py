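"""Bayes-factor case-control association testing on genotype count tables.

For each SNP the data are a 2x3 table of case/control counts over the
genotypes AA, AB, BB.  Under the null hypothesis H0 every individual has the
same probability theta of being a case; under the alternative H1 each
genotype class j has its own probability theta_j.  With independent uniform
priors on the thetas, both marginal likelihoods are products of Beta
functions and the (natural-log) Bayes factor is

    BFLn = sum_j ln B(n_jA + 1, n_jU + 1) - ln B(nA + 1, nU + 1)

where n_jA / n_jU are case/control counts in genotype class j and nA / nU
the case/control totals.  BFLn > 0 supports association (H1); BFLn < 0
supports the null.  No multiple-testing adjustment is applied — the screen
deliberately retains every SNP with nominal Bayesian support so that minor-
and modest-risk variants survive into the later structural and functional
screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCounts",
    "BfResult",
    "QcThresholds",
    "log_beta",
    "bfln",
    "hwe_chi_square",
    "qc_filter",
    "screen_snps",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control counts over the three genotypes AA, AB, BB at one SNP.

    ``n0a, n1a, n2a`` are case (affected) counts and ``n0u, n1u, n2u``
    control (unaffected) counts for genotype classes 0=AA, 1=AB, 2=BB.
    """

    snp_id: str
    n0a: int
    n1a: int
    n2a: int
    n0u: int
    n1u: int
    n2u: int

    def __post_init__(self) -> None:
        for name in ("n0a", "n1a", "n2a", "n0u", "n1u", "n2u"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(
                    f"{self.snp_id}: {name}={v} must be a non-negative integer"
                )

    @property
    def n_cases(self) -> int:
        return self.n0a + self.n1a + self.n2a

    @property
    def n_controls(self) -> int:
        return self.n0u + self.n1u + self.n2u

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def genotype_margins(self) -> tuple[int, int, int]:
        """Totals per genotype class (m0, m1, m2), cases + controls."""
        return (self.n0a + self.n0u, self.n1a + self.n1u, self.n2a + self.n2u)

    def allele_counts(self) -> tuple[int, int]:
        """Pooled (A, B) allele counts over cases and controls."""
        m0, m1, m2 = self.genotype_margins
        return 2 * m0 + m1, 2 * m2 + m1


@dataclass(frozen=True)
class BfResult:
    """Natural-log Bayes factor for one SNP; ``supports_h1`` iff bfln > 0."""

    snp_id: str
    bfln: float

    @property
    def supports_h1(self) -> bool:
        return self.bfln > 0.0


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds applied before association testing.

    min_maf
        Minimum minor-allele frequency, pooled over cases and controls.
    min_call_proxy
        Minimum total count relative to the cohort size (largest total in
        the batch, unless given explicitly) — a proxy for call rate.
    max_hwe_chi2_p
        SNPs whose control genotype counts depart from Hardy–Weinberg
        proportions with a 1-df chi-square p below this level are removed.
    """

    min_maf: float = 0.01
    min_call_proxy: float = 0.95
    max_hwe_chi2_p: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError(f"min_maf={self.min_maf} outside [0, 0.5]")
        if not 0.0 <= self.min_call_proxy <= 1.0:
            raise ValueError(f"min_call_proxy={self.min_call_proxy} outside [0, 1]")
        if not 0.0 <= self.max_hwe_chi2_p <= 1.0:
            raise ValueError(f"max_hwe_chi2_p={self.max_hwe_chi2_p} outside [0, 1]")


def log_beta(a: float, b: float) -> float:
    """ln B(a, b) = ln Γ(a) + ln Γ(b) − ln Γ(a+b), stable for large arguments.

    Raises ValueError for non-positive arguments.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"log_beta requires positive arguments, got ({a}, {b})")
    return float(betaln(a, b))


def bfln(counts: GenotypeCounts) -> BfResult:
    """Natural-log Bayes factor of H1 (per-genotype case probability) vs H0.

    Computed entirely in log space via the log-Beta function; exact for the
    uniform-prior model, deterministic, and well defined for any table
    including the all-zero one (BFLn = 0).
    """
    value = (
        log_beta(counts.n0a + 1, counts.n0u + 1)
        + log_beta(counts.n1a + 1, counts.n1u + 1)
        + log_beta(counts.n2a + 1, counts.n2u + 1)
        - log_beta(counts.n_cases + 1, counts.n_controls + 1)
    )
    return BfResult(snp_id=counts.snp_id, bfln=value)


def hwe_chi_square(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy–Weinberg proportions.

    Returns (chi2 statistic, p-value).  The allele frequency is estimated
    from the same counts; expected classes with zero expectation (fixed
    alleles) contribute nothing.  Total of zero -> (0.0, 1.0).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    mask = expected > 0
    stat = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    return stat, float(chi2.sf(stat, df=1))


def qc_filter(
    tables: list[GenotypeCounts],
    thresholds: QcThresholds | None = None,
    cohort_size: int | None = None,
) -> tuple[list[GenotypeCounts], list[tuple[str, str, float]]]:
    """Apply marker QC: call-rate proxy, minor-allele frequency, control HWE.

    Rules are checked in that order and the first failure is recorded in the
    rejection log as ``(snp_id, rule, offending value)``.  The HWE test uses
    control counts only; a SNP with zero controls skips that rule (logged).

    ``cohort_size`` defaults to the largest total count in the batch.
    Returns (passing tables, rejection log).  Raises on empty input.
    """
    if not tables:
        raise ValueError("qc_filter requires at least one genotype table")
    thr = thresholds if thresholds is not None else QcThresholds()
    if cohort_size is None:
        cohort_size = max(t.total for t in tables)

    passing: list[GenotypeCounts] = []
    rejections: list[tuple[str, str, float]] = []
    for t in tables:
        if cohort_size > 0 and t.total < thr.min_call_proxy * cohort_size:
            rejections.append((t.snp_id, "call_rate", t.total / cohort_size))
            continue
        a, b = t.allele_counts()
        maf = min(a, b) / (a + b) if (a + b) > 0 else 0.0
        if maf < thr.min_maf:
            rejections.append((t.snp_id, "maf", maf))
            continue
        if t.n_controls == 0:
            logger.warning("%s: zero controls, HWE rule skipped", t.snp_id)
        else:
            _, p = hwe_chi_square(t.n0u, t.n1u, t.n2u)
            if p < thr.max_hwe_chi2_p:
                rejections.append((t.snp_id, "hwe", p))
                continue
        passing.append(t)
    return passing, rejections


def screen_snps(
    tables: list[GenotypeCounts],
) -> tuple[set[str], list[BfResult]]:
    """Score every table and return the SNPs with strictly positive BFLn.

    Returns ``(significant ids, all results sorted by bfln descending)``.
    Ties in bfln are broken by snp_id for a deterministic ordering.
    """
    results = [bfln(t) for t in tables]
    results.sort(key=lambda r: (-r.bfln, r.snp_id))
    significant = {r.snp_id for r in results if r.supports_h1}
    return significant, results
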