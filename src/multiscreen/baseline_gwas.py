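"""Traditional GWAS baseline: allelic Fisher exact test with Bonferroni.

Each 2x3 genotype table is reduced to the 2x2 allelic table (allele counts
per phenotype), tested with the two-sided Fisher exact test, and screened
at a Bonferroni-corrected threshold alpha / n_tests.  This is the strict
"most significant SNPs" comparison arm: the report quantifies how little
it overlaps the inclusive multidimensional screen.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import fisher_exact as _scipy_fisher

from .bayes_association import GenotypeCounts

__all__ = [
    "AllelicTable",
    "to_allelic",
    "fisher_exact",
    "bonferroni_screen",
    "compare_methods",
]


@dataclass(frozen=True)
class AllelicTable:
    """2x2 allele-count table: rows case/control, columns allele A/B."""

    snp_id: str
    case_a: int
    case_b: int
    ctrl_a: int
    ctrl_b: int

    def __post_init__(self) -> None:
        for name in ("case_a", "case_b", "ctrl_a", "ctrl_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.snp_id}: {name} negative")


def to_allelic(counts: GenotypeCounts) -> AllelicTable:
    """Reduce a genotype table to allele counts (2 per homozygote, 1 per het)."""
    return AllelicTable(
        snp_id=counts.snp_id,
        case_a=2 * counts.n0a + counts.n1a,
        case_b=2 * counts.n2a + counts.n1a,
        ctrl_a=2 * counts.n0u + counts.n1u,
        ctrl_b=2 * counts.n2u + counts.n1u,
    )


def fisher_exact(table: AllelicTable) -> float:
    """Two-sided Fisher exact p-value for the allelic 2x2 table.

    Sums hypergeometric point probabilities no larger than the observed
    table's, with all margins fixed.  A zero margin gives p = 1.
    """
    p = _scipy_fisher(
        [[table.case_a, table.case_b], [table.ctrl_a, table.ctrl_b]],
        alternative="two-sided",
    ).pvalue
    return float(p)


def bonferroni_screen(
    pvalues: dict[str, float],
    alpha: float = 0.05,
    n_tests: int | None = None,
    threshold: float | None = None,
) -> tuple[set[str], float]:
    """SNPs significant at the Bonferroni-corrected level.

    The cutoff is ``alpha / n_tests`` (n_tests defaults to the number of
    p-values) unless a literal ``threshold`` is supplied, which mirrors a
    pre-computed study-wide cutoff.  Returns (significant ids, cutoff used);
    significance is strict: p < cutoff.
    """
    if threshold is None:
        n = n_tests if n_tests is not None else len(pvalues)
        if n < 1:
            return set(), float("nan")
        threshold = alpha / n
    return {s for s, p in pvalues.items() if p < threshold}, float(threshold)


def compare_methods(
    bayes_gene_set: set[str],
    gwas_gene_set: set[str],
) -> dict[str, object]:
    """Symmetric overlap summary between the two methods' gene sets."""
    inter = bayes_gene_set & gwas_gene_set
    union = bayes_gene_set | gwas_gene_set
    return {
        "n_multidimensional": len(bayes_gene_set),
        "n_gwas": len(gwas_gene_set),
        "n_intersection": len(inter),
        "n_union": len(union),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "intersection": sorted(inter),
    }
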