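"""SNP-to-gene assignment and the disease-locus genetic screen.

Builds a toy genome, assigns each SNP to its containing or nearest gene
(within 500 kb), and keeps genes that carry an associated SNP and overlap
a disease locus — the "test set" that feeds the structural SVM screen.
"""

from multiscreen.gene_mapping import assign_snps_to_genes, genetic_screen
from multiscreen.synthetic_fixtures import simulate_genome

genes, snps, loci, truth = simulate_genome(n_genes=30, n_snps=300, n_loci=8, seed=2)

assigned = assign_snps_to_genes(snps, genes)
n_inside = sum(1 for s, g in assigned.items() if g is not None)
print(f"{n_inside} of {len(snps)} SNPs assigned to a gene within 500 kb")

# pretend the SNPs landing in the first five locus-covered genes are significant
target_genes = sorted(truth.genes_in_loci)[:5]
significant = {s for s, g in assigned.items() if g in target_genes}
test_set = genetic_screen(significant, snps, genes, loci)
print(f"genetic screen keeps {len(test_set)} genes: {sorted(test_set)}")
# each kept gene has >= 1 significant SNP and interval overlap with a locus
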