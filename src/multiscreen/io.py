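"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: genotype-count TSV, BED (genes and disease loci; 0-based
half-open on disk, converted to 1-based inclusive in memory), FASTA
(Biopython), crystal-parameter TSV, GMT gene sets, gene-id lists, feature
and score TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bayes_association import BfResult, GenotypeCounts
from .function_screen import AnnotationCatalog
from .gene_mapping import DiseaseLocus, GeneRecord, SnpRecord
from .structure_features import FEATURE_NAMES, ProteinRecord

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = ["snp_id", "chrom", "pos", "n0A", "n1A", "n2A", "n0U", "n1U", "n2U"]
CRYSTAL_COLUMNS = ["gene_id", "a", "b", "c", "alpha", "beta", "gamma", "helix", "sheet"]


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(
    path: str | Path,
    tables: list[GenotypeCounts],
    snps: list[SnpRecord],
) -> None:
    pos = {s.snp_id: s for s in snps}
    rows = []
    for t in tables:
        s = pos[t.snp_id]
        rows.append([t.snp_id, s.chrom, s.pos, t.n0a, t.n1a, t.n2a, t.n0u, t.n1u, t.n2u])
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> tuple[list[GenotypeCounts], list[SnpRecord]]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables, snps = [], []
    for row in df.itertuples(index=False):
        tables.append(
            GenotypeCounts(
                snp_id=row.snp_id,
                n0a=int(row.n0A), n1a=int(row.n1A), n2a=int(row.n2A),
                n0u=int(row.n0U), n1u=int(row.n1U), n2u=int(row.n2U),
            )
        )
        snps.append(SnpRecord(snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos)))
    return tables, snps


# ----------------------------------------------------------------------- BED

def write_bed(path: str | Path, records: list[GeneRecord] | list[DiseaseLocus]) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for r in records:
            name = getattr(r, "gene_id", None) or getattr(r, "locus_id")
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def _read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append((chrom, int(start) + 1, int(end), name))  # -> 1-based inclusive
    return out


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    return [GeneRecord(gene_id=n, chrom=c, start=s, end=e) for c, s, e, n in _read_bed(path)]


def read_loci_bed(path: str | Path) -> list[DiseaseLocus]:
    return [DiseaseLocus(locus_id=n, chrom=c, start=s, end=e) for c, s, e, n in _read_bed(path)]


# --------------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """First record wins when a gene id repeats (logged)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            logger.warning("%s: duplicate FASTA record %s ignored", path, rec.id)
            continue
        out[rec.id] = str(rec.seq)
    return out


# --------------------------------------------------------------- crystal TSV

def write_crystal_tsv(path: str | Path, records: list[ProteinRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            [r.gene_id, r.cell_a, r.cell_b, r.cell_c,
             r.cell_alpha, r.cell_beta, r.cell_gamma, r.helix_frac, r.sheet_frac]
        )
    pd.DataFrame(rows, columns=CRYSTAL_COLUMNS).to_csv(path, sep="\t", index=False)


def _frac(value: float | None, field: str, gene_id: str) -> float | None:
    """Accept fraction or percent for helix/sheet; >1.5 is read as percent."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value > 1.5:
        logger.info("%s: %s=%s interpreted as percent", gene_id, field, value)
        return value / 100.0
    return float(value)


def read_crystal_tsv(path: str | Path) -> dict[str, dict[str, float | None]]:
    """Map gene_id -> crystal/secondary fields; empty cells are missing."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(CRYSTAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, dict[str, float | None]] = {}
    for row in df.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) else float(v)

        out[row.gene_id] = {
            "cell_a": opt(row.a), "cell_b": opt(row.b), "cell_c": opt(row.c),
            "cell_alpha": opt(row.alpha), "cell_beta": opt(row.beta),
            "cell_gamma": opt(row.gamma),
            "helix_frac": _frac(opt(row.helix), "helix", row.gene_id),
            "sheet_frac": _frac(opt(row.sheet), "sheet", row.gene_id),
        }
    return out


def build_protein_records(
    sequences: dict[str, str],
    crystal: dict[str, dict[str, float | None]] | None = None,
) -> list[ProteinRecord]:
    crystal = crystal or {}
    return [
        ProteinRecord(gene_id=gid, sequence=seq, **crystal.get(gid, {}))
        for gid, seq in sequences.items()
    ]


# ------------------------------------------------------------- feature table

def write_features_tsv(path: str | Path, features: pd.DataFrame) -> None:
    features.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if list(df.columns) != FEATURE_NAMES:
        raise ValueError(f"{path}: unexpected feature columns")
    return df


# ----------------------------------------------------------------- id lists

def write_gene_list(path: str | Path, genes: set[str] | list[str]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------- GMT

def write_gmt(path: str | Path, category_to_genes: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for cat in sorted(category_to_genes):
            genes = "\t".join(sorted(category_to_genes[cat]))
            fh.write(f"{cat}\t{cat}\t{genes}\n")


def read_gmt(
    path: str | Path,
    namespace: str,
    universe: set[str] | None = None,
) -> AnnotationCatalog:
    category_to_genes: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            category_to_genes[parts[0]] = {g for g in parts[2:] if g}
    return AnnotationCatalog.from_category_map(namespace, category_to_genes, universe)


# -------------------------------------------------------------- score tables

def write_bfln_tsv(path: str | Path, results: list[BfResult]) -> None:
    rows = [[r.snp_id, f"{r.bfln:.10g}", int(r.supports_h1)] for r in results]
    pd.DataFrame(rows, columns=["snp_id", "bfln", "supports_h1"]).to_csv(
        path, sep="\t", index=False
    )


def write_rejections_tsv(path: str | Path, rejections: list[tuple[str, str, float]]) -> None:
    pd.DataFrame(rejections, columns=["snp_id", "rule", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
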