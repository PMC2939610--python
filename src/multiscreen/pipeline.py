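"""Pipeline orchestration: the three screens plus the GWAS baseline.

Stages, in order: genotype QC and Bayes-factor screening; SNP→gene mapping
and the disease-locus (genetic) screen producing the SVM test set;
feature building; the randomized-ensemble SVM screen; the functional-
annotation screen; then the Fisher/Bonferroni baseline and an overlap
report.  Every stage writes its intermediate TSV and the whole run is
summarised in a deterministic JSON report (the candidate "funnel").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import io as msio
from .baseline_gwas import bonferroni_screen, compare_methods, fisher_exact, to_allelic
from .bayes_association import QcThresholds, qc_filter, screen_snps
from .function_screen import functional_screen
from .gene_mapping import assign_snps_to_genes, genetic_screen
from .structure_features import FEATURE_NAMES, build_feature_vector
from .svm_screen import ensemble_predict, evaluate_feature_sets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ScreenReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat run configuration; every screening threshold is surfaced here."""

    counts: str
    genes: str
    loci: str
    fasta: str
    crystal: str
    positives: str
    pirsf: str
    go: str
    kegg: str
    # QC / association
    run_qc: bool = True
    min_maf: float = 0.01
    min_call_proxy: float = 0.95
    max_hwe_chi2_p: float = 1e-6
    # mapping
    max_distance: int = 500_000
    # SVM
    svm_c: float = 1.0
    svm_gamma: str | float = "auto"
    n_randomizations: int = 200
    keep_fraction: float = 1.0
    n_folds: int = 5
    evaluate_randomizations: int = 0  # 0 skips the Qa feature-set summary
    # functional screen
    alpha: float = 0.05
    min_overlap: int = 2
    correction: str | None = None
    # baseline
    gwas_alpha: float = 0.05
    gwas_threshold: float | None = None
    seed: int = 0

    _PATH_FIELDS = ("counts", "genes", "loci", "fasta", "crystal",
                    "positives", "pirsf", "go", "kegg")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        for key in cls._PATH_FIELDS:
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ScreenReport:
    """Stage-by-stage funnel of the multidimensional screen."""

    config: dict
    version: str
    n_snps_input: int = 0
    n_snps_qc: int = 0
    significant_snps: list[str] = field(default_factory=list)
    test_set_genes: list[str] = field(default_factory=list)
    svm_candidates: list[str] = field(default_factory=list)
    final_candidates: list[str] = field(default_factory=list)
    gwas_significant_snps: list[str] = field(default_factory=list)
    gwas_genes: list[str] = field(default_factory=list)
    gwas_threshold: float = 0.0
    overlap: dict = field(default_factory=dict)
    n_positive_pool: int = 0
    n_negative_pool: int = 0
    qa_summary: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    @property
    def funnel(self) -> dict[str, int]:
        return {
            "snps_input": self.n_snps_input,
            "snps_qc_passing": self.n_snps_qc,
            "snps_significant": len(self.significant_snps),
            "genes_test_set": len(self.test_set_genes),
            "genes_svm_candidates": len(self.svm_candidates),
            "genes_final_candidates": len(self.final_candidates),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["funnel"] = self.funnel
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; an empty list means the config is runnable."""
    problems = []
    for key in PipelineConfig._PATH_FIELDS:
        p = getattr(config, key)
        if not p:
            problems.append(f"{key}: no file given")
        elif not Path(p).exists():
            problems.append(f"{key}: file not found: {p}")
    for key, lo, hi in (
        ("min_maf", 0.0, 0.5),
        ("min_call_proxy", 0.0, 1.0),
        ("max_hwe_chi2_p", 0.0, 1.0),
        ("keep_fraction", 0.0, 1.0),
        ("alpha", 0.0, 1.0),
        ("gwas_alpha", 0.0, 1.0),
    ):
        v = getattr(config, key)
        if not lo <= v <= hi:
            problems.append(f"{key}: {v} outside [{lo}, {hi}]")
    if config.max_distance < 0:
        problems.append("max_distance: must be non-negative")
    if config.n_randomizations < 1:
        problems.append("n_randomizations: must be >= 1")
    if config.n_folds < 2:
        problems.append("n_folds: must be >= 2")
    if int(config.seed) != config.seed:
        problems.append("seed: must be an integer")
    return problems


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> ScreenReport:
    """Execute all screens; write intermediates and the JSON report.

    Raises on the first stage failure with the stage named; outputs of the
    completed stages remain on disk.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ScreenReport(config=asdict(config), version=__version__)

    # -- stage 1: QC + Bayes screen
    logger.info("stage bayes: reading %s", config.counts)
    tables, snps = msio.read_counts_tsv(config.counts)
    report.n_snps_input = len(tables)
    if config.run_qc:
        thr = QcThresholds(
            min_maf=config.min_maf,
            min_call_proxy=config.min_call_proxy,
            max_hwe_chi2_p=config.max_hwe_chi2_p,
        )
        tables, rejections = qc_filter(tables, thr)
        msio.write_rejections_tsv(outdir / "qc_rejections.tsv", rejections)
        report.outputs["qc_rejections"] = "qc_rejections.tsv"
    report.n_snps_qc = len(tables)
    significant, bf_results = screen_snps(tables)
    msio.write_bfln_tsv(outdir / "bfln.tsv", bf_results)
    report.outputs["bfln"] = "bfln.tsv"
    report.significant_snps = sorted(significant)

    # -- stage 2: gene mapping + genetic screen
    genes = msio.read_genes_bed(config.genes)
    loci = msio.read_loci_bed(config.loci)
    positives = msio.read_gene_list(config.positives)
    test_set = genetic_screen(significant, snps, genes, loci, config.max_distance)
    test_set -= positives  # known disease genes need no prediction
    report.test_set_genes = sorted(test_set)
    msio.write_gene_list(outdir / "test_set.txt", test_set)
    report.outputs["test_set"] = "test_set.txt"

    # -- stage 3: features
    sequences = msio.read_fasta(config.fasta)
    crystal = msio.read_crystal_tsv(config.crystal)
    records = msio.build_protein_records(sequences, crystal)
    import pandas as pd

    vectors = {r.gene_id: build_feature_vector(r).values for r in records}
    features = pd.DataFrame.from_dict(vectors, orient="index", columns=FEATURE_NAMES)
    features = features.sort_index()
    msio.write_features_tsv(outdir / "features.tsv", features)
    report.outputs["features"] = "features.tsv"

    # -- stage 4: SVM screen
    in_locus = {
        g.gene_id for g in genes
        for l in loci
        if g.chrom == l.chrom and g.start <= l.end and g.end >= l.start
    }
    featured = set(features.index)
    pos_ids = sorted(positives & featured)
    neg_ids = sorted(featured - in_locus - positives - test_set)
    test_ids = sorted(test_set & featured)
    if not pos_ids:
        raise RuntimeError("stage svm: no positive genes with features")
    report.n_positive_pool = len(pos_ids)
    report.n_negative_pool = len(neg_ids)
    pos_pool = features.loc[pos_ids]
    neg_pool = features.loc[neg_ids]
    if config.evaluate_randomizations > 0:
        qa = evaluate_feature_sets(
            pos_pool, neg_pool,
            n_randomizations=config.evaluate_randomizations,
            n_folds=config.n_folds, C=config.svm_c, gamma=config.svm_gamma,
            seed=config.seed,
        )
        qa.to_csv(outdir / "qa_summary.tsv", sep="\t", index=False)
        report.outputs["qa_summary"] = "qa_summary.tsv"
        report.qa_summary = qa.to_dict(orient="records")
    ens = ensemble_predict(
        pos_pool, neg_pool, features.loc[test_ids],
        n_randomizations=config.n_randomizations,
        keep_fraction=config.keep_fraction,
        C=config.svm_c, gamma=config.svm_gamma, seed=config.seed,
    )
    pred = pd.DataFrame(
        {
            "vote_fraction": ens.vote_fraction,
            "mean_margin": ens.mean_margin,
            "in_intersection": [g in ens.candidates for g in ens.vote_fraction.index],
        }
    )
    pred.sort_index().to_csv(outdir / "svm_predictions.tsv", sep="\t",
                             index_label="gene_id", float_format="%.6g")
    report.outputs["svm_predictions"] = "svm_predictions.tsv"
    report.svm_candidates = sorted(ens.candidates)

    # -- stage 5: functional screen
    catalogs = {
        "PIRSF": msio.read_gmt(config.pirsf, "PIRSF"),
        "GO": msio.read_gmt(config.go, "GO"),
        "KEGG": msio.read_gmt(config.kegg, "KEGG"),
    }
    final, indicators, enriched = functional_screen(
        ens.candidates, positives, catalogs,
        alpha=config.alpha, min_overlap=config.min_overlap,
        correction=config.correction,
    )
    indicators.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
    report.outputs["indicators"] = "indicators.tsv"
    enr_frames = [e.table.assign(namespace=ns) for ns, e in sorted(enriched.items())]
    pd.concat(enr_frames).to_csv(outdir / "enriched_categories.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    report.outputs["enriched_categories"] = "enriched_categories.tsv"
    report.final_candidates = sorted(final)
    msio.write_gene_list(outdir / "final_candidates.txt", final)
    report.outputs["final_candidates"] = "final_candidates.txt"

    # -- stage 6: GWAS baseline + comparison
    pvalues = {t.snp_id: fisher_exact(to_allelic(t)) for t in tables}
    gwas_sig, threshold = bonferroni_screen(
        pvalues, alpha=config.gwas_alpha, threshold=config.gwas_threshold
    )
    gwas_rows = pd.DataFrame(
        [(s, pvalues[s], s in gwas_sig) for s in sorted(pvalues)],
        columns=["snp_id", "p_value", "significant"],
    )
    gwas_rows.to_csv(outdir / "gwas.tsv", sep="\t", index=False, float_format="%.6g")
    report.outputs["gwas"] = "gwas.tsv"
    assigned = assign_snps_to_genes(
        [s for s in snps if s.snp_id in gwas_sig], genes, config.max_distance
    )
    gwas_genes = {g for g in assigned.values() if g is not None}
    report.gwas_significant_snps = sorted(gwas_sig)
    report.gwas_genes = sorted(gwas_genes)
    report.gwas_threshold = threshold
    report.overlap = compare_methods(final, gwas_genes)

    report.to_json(outdir / "report.json")
    report.outputs["report"] = "report.json"
    return report
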