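"""Functional-annotation (third-dimensional) screen.

Known disease genes tend to co-occur in specific protein families (PIRSF),
GO terms, and KEGG pathways.  For each namespace the categories in which
the disease genes are statistically over-represented are found with a
one-sided hypergeometric tail test; a candidate gene earns the indicator
f_ns = 1 if it is annotated to at least one such enriched category, and the
overall indicator f = f_PIRSF OR f_GO OR f_KEGG.  Genes with f = 1 are the
final candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCatalog",
    "EnrichedCategorySet",
    "IndicatorResult",
    "enriched_categories",
    "indicator_f",
    "functional_screen",
    "NAMESPACES",
]

NAMESPACES = ("PIRSF", "GO", "KEGG")


@dataclass
class AnnotationCatalog:
    """Gene↔category maps for one namespace over a background universe."""

    namespace: str
    gene_to_categories: dict[str, set[str]]
    category_to_genes: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_category_map(
        cls,
        namespace: str,
        category_to_genes: dict[str, set[str]],
        universe: set[str] | None = None,
    ) -> "AnnotationCatalog":
        gene_to_categories: dict[str, set[str]] = {}
        for cat, genes in category_to_genes.items():
            for g in genes:
                gene_to_categories.setdefault(g, set()).add(cat)
        if universe is None:
            universe = set(gene_to_categories)
        missing = set(gene_to_categories) - universe
        if missing:
            raise ValueError(
                f"{namespace}: annotated genes outside universe: {sorted(missing)[:5]}"
            )
        return cls(
            namespace=namespace,
            gene_to_categories=gene_to_categories,
            category_to_genes={c: set(g) for c, g in category_to_genes.items()},
            universe=set(universe),
        )

    def categories_of(self, gene_id: str) -> set[str]:
        return self.gene_to_categories.get(gene_id, set())


@dataclass(frozen=True)
class EnrichedCategorySet:
    """Categories over-represented among disease genes, with the test table.

    ``table`` columns: category, k (disease genes in category), K (disease
    genes in universe), n (category size), N (universe size), p_value.
    """

    namespace: str
    categories: set[str]
    table: pd.DataFrame


@dataclass(frozen=True)
class IndicatorResult:
    """Per-gene namespace indicators; f is their logical OR."""

    gene_id: str
    f_pirsf: int
    f_go: int
    f_kegg: int

    @property
    def f(self) -> int:
        return int(bool(self.f_pirsf or self.f_go or self.f_kegg))


def enriched_categories(
    disease_genes: set[str],
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
    min_overlap: int = 2,
    correction: str | None = None,
) -> EnrichedCategorySet:
    """One-sided hypergeometric over-representation test per category.

    With N the universe size, K the number of disease genes in the universe,
    n the category size and k the disease genes inside it, the p-value is
    P(X >= k) for X ~ Hypergeom(N, K, n).  Categories pass with p <= alpha
    and k >= min_overlap.  ``correction="bh"`` applies Benjamini–Hochberg
    across the namespace before thresholding (off by default: the screen is
    deliberately inclusive).  Disease genes outside the universe are
    ignored with a log message.
    """
    if not catalog.universe:
        raise ValueError(f"{catalog.namespace}: empty universe")
    inside = disease_genes & catalog.universe
    dropped = len(disease_genes) - len(inside)
    if dropped:
        logger.info(
            "%s: %d disease genes outside the universe ignored",
            catalog.namespace,
            dropped,
        )
    N = len(catalog.universe)
    K = len(inside)
    rows = []
    for cat in sorted(catalog.category_to_genes):
        genes = catalog.category_to_genes[cat] & catalog.universe
        n = len(genes)
        k = len(genes & inside)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"category": cat, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    table = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p_value"])
    if correction == "bh" and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    passing = table[(table["p_value"] <= alpha) & (table["k"] >= min_overlap)]
    return EnrichedCategorySet(
        namespace=catalog.namespace,
        categories=set(passing["category"]),
        table=table,
    )


def indicator_f(
    gene_id: str,
    catalogs: dict[str, AnnotationCatalog],
    enriched: dict[str, EnrichedCategorySet],
) -> IndicatorResult:
    """f_ns = 1 iff the gene is annotated to >= 1 enriched category in ns."""
    flags = {}
    annotated_anywhere = False
    for ns in NAMESPACES:
        cat = catalogs.get(ns)
        if cat is None:
            flags[ns] = 0
            continue
        mine = cat.categories_of(gene_id)
        annotated_anywhere = annotated_anywhere or bool(mine)
        enr = enriched.get(ns)
        flags[ns] = int(bool(enr and (mine & enr.categories)))
    if not annotated_anywhere:
        logger.debug("%s: absent from all catalogs, f = 0", gene_id)
    return IndicatorResult(
        gene_id=gene_id,
        f_pirsf=flags["PIRSF"],
        f_go=flags["GO"],
        f_kegg=flags["KEGG"],
    )


def functional_screen(
    candidate_genes: set[str],
    disease_genes: set[str],
    catalogs: dict[str, AnnotationCatalog],
    alpha: float = 0.05,
    min_overlap: int = 2,
    correction: str | None = None,
) -> tuple[set[str], pd.DataFrame, dict[str, EnrichedCategorySet]]:
    """Keep candidates sharing >= 1 disease-enriched category (f = 1).

    Returns (final candidate set, full indicator table, enriched sets per
    namespace).  The indicator table has one row per candidate with columns
    gene_id, f_pirsf, f_go, f_kegg, f.
    """
    enriched = {
        ns: enriched_categories(
            disease_genes, cat, alpha=alpha, min_overlap=min_overlap, correction=correction
        )
        for ns, cat in catalogs.items()
    }
    rows = []
    final: set[str] = set()
    for g in sorted(candidate_genes):
        res = indicator_f(g, catalogs, enriched)
        rows.append(
            {
                "gene_id": g,
                "f_pirsf": res.f_pirsf,
                "f_go": res.f_go,
                "f_kegg": res.f_kegg,
                "f": res.f,
            }
        )
        if res.f:
            final.add(g)
    table = pd.DataFrame(rows, columns=["gene_id", "f_pirsf", "f_go", "f_kegg", "f"])
    return final, table, enriched
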