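"""Functional-annotation screen: the f indicator.

Builds annotation catalogs in which disease genes cluster in a few
categories, finds the disease-enriched categories per namespace with the
hypergeometric tail test, and keeps candidates annotated to at least one
enriched category (f = 1).
"""

from multiscreen import functional_screen
from multiscreen.synthetic_fixtures import simulate_annotations

genes = [f"g{i:03d}" for i in range(300)]
disease = set(genes[:25])
candidates = set(genes[25:45])

catalogs, truth = simulate_annotations(
    genes, disease, clustering_strength=0.9, seed=4,
    co_clustered_genes=set(genes[25:35]),  # 10 candidates share disease categories
)

final, table, enriched = functional_screen(candidates, disease, catalogs, alpha=0.05)
for ns, e in enriched.items():
    print(f"{ns}: {len(e.categories)} enriched categories "
          f"(planted: {sorted(truth.enriched_categories[ns])})")
print(f"\n{len(final)} of {len(candidates)} candidates keep f = 1")
print(table.head(10).to_string(index=False))
# f = f_PIRSF OR f_GO OR f_KEGG; genes sharing no enriched category are dropped
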