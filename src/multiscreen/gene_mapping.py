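"""SNP-to-gene assignment and the genetic (first-dimensional) screen.

A SNP is assigned to the gene that contains it, or otherwise to the nearest
gene on the same chromosome within ``max_distance`` (default 500 kb — the
scale within which most enhancers/repressors and linkage-disequilibrium
blocks act).  SNPs farther than that from every gene are discarded.  The
genetic screen then keeps genes that received at least one associated SNP
(BFLn > 0) and whose interval overlaps at least one known disease locus.

Coordinates are 1-based inclusive throughout; BED input is converted on
read (see :mod:`multiscreen.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GeneRecord",
    "DiseaseLocus",
    "assign_snp_to_gene",
    "assign_snps_to_genes",
    "genetic_screen",
]

DEFAULT_MAX_DISTANCE = 500_000


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def distance_to(self, pos: int) -> int:
        """Distance from a position to the nearest interval boundary; 0 inside."""
        return max(0, self.start - pos, pos - self.end)

    def overlaps(self, other: "GeneRecord | DiseaseLocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )


@dataclass(frozen=True)
class DiseaseLocus:
    locus_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")


class _ChromIndex:
    """Vectorized per-chromosome interval arrays for nearest-gene queries."""

    def __init__(self, genes: list[GeneRecord]):
        order = sorted(range(len(genes)), key=lambda i: genes[i].gene_id)
        self.ids = [genes[i].gene_id for i in order]
        self.starts = np.array([genes[i].start for i in order], dtype=np.int64)
        self.ends = np.array([genes[i].end for i in order], dtype=np.int64)

    def nearest(self, pos: int, max_distance: int) -> str | None:
        d = np.maximum(0, np.maximum(self.starts - pos, pos - self.ends))
        i = int(np.argmin(d))  # argmin takes the first minimum = smallest id
        if d[i] > max_distance:
            return None
        return self.ids[i]


def _build_index(genes: list[GeneRecord]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {chrom: _ChromIndex(gs) for chrom, gs in by_chrom.items()}


def assign_snp_to_gene(
    snp: SnpRecord,
    genes: list[GeneRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> str | None:
    """Gene containing the SNP, else the nearest gene within ``max_distance``.

    Distance to a gene is the distance to the nearest boundary of its
    interval (0 if the SNP lies inside).  Ties are broken by the
    lexicographically smallest gene_id; result does not depend on the input
    ordering of ``genes``.  Returns None if no gene on the SNP's chromosome
    lies within range.
    """
    index = _build_index(genes)
    if snp.chrom not in index:
        return None
    return index[snp.chrom].nearest(snp.pos, max_distance)


def assign_snps_to_genes(
    snps: list[SnpRecord],
    genes: list[GeneRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> dict[str, str | None]:
    """Batch form of :func:`assign_snp_to_gene`; one shared index build."""
    index = _build_index(genes)
    out: dict[str, str | None] = {}
    for snp in snps:
        ci = index.get(snp.chrom)
        out[snp.snp_id] = None if ci is None else ci.nearest(snp.pos, max_distance)
    return out


def genetic_screen(
    significant_snps: set[str],
    snps: list[SnpRecord],
    genes: list[GeneRecord],
    loci: list[DiseaseLocus],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> set[str]:
    """First-dimensional screen: the SVM test set of candidate genes.

    Returns genes that (a) received at least one significant SNP via
    nearest-gene assignment and (b) overlap (share >= 1 base with) at least
    one disease locus on the same chromosome.
    """
    if not loci:
        logger.warning("genetic_screen: empty disease-locus collection")
        return set()
    sig = [s for s in snps if s.snp_id in significant_snps]
    assigned = assign_snps_to_genes(sig, genes, max_distance)
    hit_genes = {g for g in assigned.values() if g is not None}
    by_id = {g.gene_id: g for g in genes}
    result = set()
    for gid in hit_genes:
        g = by_id[gid]
        for locus in loci:
            if g.chrom == locus.chrom and g.start <= locus.end and g.end >= locus.start:
                result.add(gid)
                break
    return result
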