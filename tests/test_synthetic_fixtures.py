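"""Synthetic-fixture generators: model laws, planted truth, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from multiscreen import io as msio
from multiscreen.bayes_association import bfln
from multiscreen.function_screen import enriched_categories
from multiscreen.gene_mapping import assign_snps_to_genes
from multiscreen.structure_features import compute_composition
from multiscreen.synthetic_fixtures import (
    PopulationModel,
    composition_to_sequence,
    sample_class_vectors,
    simulate_annotations,
    simulate_genome,
    simulate_genotype_counts,
    simulate_protein_features,
    write_endtoend_fixture,
)


class TestPopulationModel:
    def test_exactly_one_size_specification(self):
        with pytest.raises(ValueError):
            PopulationModel(n_individuals=100, genotype_margins=(10, 10, 10))
        with pytest.raises(ValueError):
            PopulationModel()

    def test_probability_ranges_validated(self):
        with pytest.raises(ValueError):
            PopulationModel(allele_freq=1.5, n_individuals=10)
        with pytest.raises(ValueError):
            PopulationModel(thetas=(0.5, 1.2, 0.5), n_individuals=10)

    def test_null_detection(self):
        assert PopulationModel(thetas=(0.3, 0.3, 0.3), n_individuals=10).is_null
        assert not PopulationModel(thetas=(0.3, 0.5, 0.7), n_individuals=10).is_null


class TestSimulateGenotypeCounts:
    def test_hwe_genotype_fractions(self):
        model = PopulationModel(allele_freq=0.5, n_individuals=10_000)
        tables, _ = simulate_genotype_counts(model, n_snps=1, seed=1)
        m = np.array(tables[0].genotype_margins) / 10_000
        se = 3 * np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert (np.abs(m - [0.25, 0.5, 0.25]) <= se).all()

    def test_case_fraction_tracks_theta(self):
        model = PopulationModel(
            allele_freq=0.5, thetas=(0.5, 0.5, 0.5), n_individuals=20_000
        )
        tables, _ = simulate_genotype_counts(model, n_snps=1, causal_fraction=1.0, seed=2)
        t = tables[0]
        frac = t.n_cases / t.total
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / t.total)

    def test_power_dominance_of_causal_design(self):
        margins = (300, 300, 300)
        alt = PopulationModel(thetas=(0.3, 0.5, 0.7), genotype_margins=margins)
        null = PopulationModel(thetas=(0.5, 0.5, 0.5), genotype_margins=margins)
        alt_tables, _ = simulate_genotype_counts(alt, 200, causal_fraction=1.0, seed=3)
        null_tables, _ = simulate_genotype_counts(null, 200, causal_fraction=1.0, seed=3)
        alt_rate = np.mean([bfln(t).supports_h1 for t in alt_tables])
        null_rate = np.mean([bfln(t).supports_h1 for t in null_tables])
        assert alt_rate > null_rate

    def test_truth_records_causal_fraction(self):
        model = PopulationModel(allele_freq=0.5, thetas=(0.4, 0.5, 0.6), n_individuals=100)
        tables, truth = simulate_genotype_counts(model, 40, causal_fraction=0.25, seed=4)
        assert len(truth.causal_snps) == 10
        assert truth.causal_snps <= {t.snp_id for t in tables}

    def test_seed_reproducibility(self):
        model = PopulationModel(allele_freq=0.3, thetas=(0.4, 0.5, 0.6), n_individuals=200)
        a, _ = simulate_genotype_counts(model, 20, causal_fraction=0.5, seed=5)
        b, _ = simulate_genotype_counts(model, 20, causal_fraction=0.5, seed=5)
        assert a == b


class TestSimulateGenome:
    def test_requested_locus_coverage_is_exact(self):
        genes, _, loci, truth = simulate_genome(10, 50, n_loci=5, seed=6)
        covered = {
            g.gene_id for g in genes
            for l in loci
            if g.chrom == l.chrom and g.start <= l.end and g.end >= l.start
        }
        assert covered == truth.genes_in_loci
        assert len(truth.genes_in_loci) == 5

    def test_all_far_snps_are_unassignable(self):
        genes, snps, _, _ = simulate_genome(
            10, 30, n_loci=0, seed=7, frac_inside=0.0, frac_near=0.0
        )
        assigned = assign_snps_to_genes(snps, genes)
        assert all(g is None for g in assigned.values())

    def test_genes_do_not_overlap(self):
        genes, _, _, _ = simulate_genome(50, 10, n_loci=0, seed=8)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end < b.start

    def test_truth_matches_module_assignment(self):
        genes, snps, _, truth = simulate_genome(20, 200, n_loci=3, seed=9)
        assigned = assign_snps_to_genes(snps, genes)
        assert assigned == truth.snp_to_gene

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            simulate_genome(1000, 10, n_loci=0, chrom_lengths={"chr1": 1_000_000}, seed=0)


class TestProteinFeatures:
    def test_compositions_on_simplex(self):
        feats, _ = simulate_protein_features(30, 30, separation=4.0, seed=10)
        comp = feats.iloc[:, :20].to_numpy()
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert (comp >= 0).all()

    def test_angles_and_fractions_in_range(self):
        feats, _ = simulate_protein_features(50, 50, separation=6.0, seed=11)
        angles = feats[["cell_alpha", "cell_beta", "cell_gamma"]].to_numpy()
        assert ((angles > 0) & (angles < 180)).all()
        hs = feats[["helix_frac", "sheet_frac"]].to_numpy()
        assert (hs >= 0).all() and (hs.sum(axis=1) <= 1 + 1e-9).all()

    def test_zero_separation_classes_indistinguishable(self):
        rng = np.random.default_rng(12)
        a = sample_class_vectors(400, True, 0.0, rng)
        b = sample_class_vectors(400, False, 0.0, rng)
        diff = a.mean(axis=0) - b.mean(axis=0)
        pooled_se = np.sqrt(a.var(axis=0) / 400 + b.var(axis=0) / 400)
        assert (np.abs(diff) <= 4 * pooled_se).all()

    def test_separation_shifts_class_means(self):
        rng = np.random.default_rng(13)
        a = sample_class_vectors(200, True, 8.0, rng)
        b = sample_class_vectors(200, False, 8.0, rng)
        assert np.abs(a.mean(axis=0) - b.mean(axis=0)).max() > 0.001

    def test_sequence_realises_composition(self):
        rng = np.random.default_rng(14)
        v = sample_class_vectors(1, True, 4.0, rng)[0]
        seq = composition_to_sequence(v[:20], length=500, rng=rng)
        comp, warn = compute_composition(seq)
        assert warn == 0 and len(seq) == 500
        np.testing.assert_allclose(comp, v[:20], atol=1 / 500 + 1e-12)


class TestSimulateAnnotations:
    genes = [f"g{i:04d}" for i in range(300)]
    disease = set(genes[:30])

    def test_every_annotated_gene_in_universe(self):
        catalogs, _ = simulate_annotations(self.genes, self.disease, seed=15)
        for cat in catalogs.values():
            assert set(cat.gene_to_categories) <= cat.universe

    def test_planted_categories_are_enriched(self):
        catalogs, truth = simulate_annotations(
            self.genes, self.disease, clustering_strength=0.95, seed=16
        )
        for ns, cat in catalogs.items():
            result = enriched_categories(self.disease, cat, alpha=0.05, min_overlap=2)
            assert truth.enriched_categories[ns] <= result.categories

    def test_null_pass_rate_matches_exact_hypergeometric_law(self):
        """With clustering off, the fraction of categories passing alpha
        equals the discrete null probability P(p(X) <= alpha) computed
        directly from the hypergeometric pmf."""
        genes = [f"g{i:04d}" for i in range(1000)]
        disease = set(genes[:50])
        catalogs, _ = simulate_annotations(
            genes, disease, n_categories_per_namespace=150,
            clustering_strength=0.0, seed=17, background_rate=40.0,
        )
        alpha = 0.05
        pvals, expected_rates = [], []
        for cat in catalogs.values():
            res = enriched_categories(disease, cat, alpha=alpha, min_overlap=0)
            for row in res.table.itertuples():
                pvals.append((row.p_value, row.n))
                support = np.arange(0, min(50, row.n) + 1)
                tail = hypergeom.sf(support - 1, 1000, 50, row.n)
                pmf = hypergeom.pmf(support, 1000, 50, row.n)
                expected_rates.append(pmf[tail <= alpha].sum())
        observed = np.mean([p <= alpha for p, _ in pvals])
        expected = float(np.mean(expected_rates))
        se = np.sqrt(expected * (1 - expected) / len(pvals))
        assert abs(observed - expected) <= 3 * se + 1e-12


class TestEndToEndFixture:
    def test_files_round_trip_and_truth_consistent(self, tmp_path):
        fx = write_endtoend_fixture(
            tmp_path, seed=3, n_snps=300, n_genes=40, n_causal=5,
            n_known_disease=8, n_extra_loci=3,
        )
        p = fx["paths"]
        truth = fx["truth"]
        tables, snps = msio.read_counts_tsv(p["counts"])
        assert len(tables) == 300
        genes = msio.read_genes_bed(p["genes"])
        assert len(genes) == 40
        assert truth.causal_genes <= {g.gene_id for g in genes}
        assert truth.causal_genes <= truth.genes_in_loci
        positives = msio.read_gene_list(p["positives"])
        assert len(positives) == 8 and not positives & truth.causal_genes
        sequences = msio.read_fasta(p["fasta"])
        assert set(sequences) == {g.gene_id for g in genes}
        for key, ns in (("pirsf", "PIRSF"), ("go", "GO"), ("kegg", "KEGG")):
            catalog = msio.read_gmt(p[key], ns)
            assert catalog.universe <= {g.gene_id for g in genes}

    def test_fixture_bytes_reproducible(self, tmp_path):
        kw = dict(seed=4, n_snps=100, n_genes=20, n_causal=3, n_known_disease=4,
                  n_extra_loci=2)
        fx1 = write_endtoend_fixture(tmp_path / "a", **kw)
        fx2 = write_endtoend_fixture(tmp_path / "b", **kw)
        for key in fx1["paths"]:
            a = open(fx1["paths"][key], "rb").read()
            b = open(fx2["paths"][key], "rb").read()
            assert a == b, f"{key} differs between identically seeded runs"
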