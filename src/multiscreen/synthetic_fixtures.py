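"""Synthetic study fixtures with known ground truth.

Every input the screening pipeline consumes can be generated here:

* genotype count tables under a prospective Hardy–Weinberg model in which
  an individual with genotype j is a case with probability theta_j (causal
  SNPs get distinct thetas; null SNPs share one theta; a marginal-null
  mode draws a common theta ~ Uniform(0,1) per SNP, the design under which
  the Bayes factor has expectation exactly 1);
* a toy genome of non-overlapping genes, SNPs placed inside/near/far from
  them, and disease loci covering designated genes;
* class-conditional protein feature vectors (and sequences realising their
  compositions) with a tunable between-class separation;
* PIRSF/GO/KEGG annotation catalogs in which disease genes (and any
  designated co-clustered genes) concentrate in a few categories.

Generators are seeded and bit-reproducible; each records its planted truth
in a :class:`FixtureTruth` so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .bayes_association import GenotypeCounts
from .function_screen import AnnotationCatalog, NAMESPACES
from .gene_mapping import DiseaseLocus, GeneRecord, SnpRecord
from .structure_features import AMINO_ACIDS, FEATURE_NAMES

__all__ = [
    "PopulationModel",
    "FixtureTruth",
    "simulate_genotype_counts",
    "simulate_genome",
    "build_loci",
    "simulate_protein_features",
    "composition_to_sequence",
    "simulate_annotations",
    "write_endtoend_fixture",
    "write_preset",
]


@dataclass(frozen=True)
class PopulationModel:
    """Prospective case-control genotype model.

    Genotypes follow Hardy–Weinberg proportions (p^2, 2p(1-p), (1-p)^2)
    for ``n_individuals``, or fixed per-genotype totals when
    ``genotype_margins`` is given.  In ``fixed-theta`` mode an individual
    with genotype j is a case with probability thetas[j]; in
    ``marginal-null`` mode a single theta ~ Uniform(0,1) is drawn per SNP
    and shared by all genotypes.
    """

    allele_freq: float = 0.5
    thetas: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_individuals: int | None = None
    genotype_margins: tuple[int, int, int] | None = None
    mode: str = "fixed-theta"

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must be in (0, 1)")
        if any(not 0 <= t <= 1 for t in self.thetas):
            raise ValueError("thetas must be in [0, 1]")
        if self.mode not in ("fixed-theta", "marginal-null"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.n_individuals is None) == (self.genotype_margins is None):
            raise ValueError("give exactly one of n_individuals / genotype_margins")
        if self.n_individuals is not None and self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.genotype_margins is not None and any(m < 0 for m in self.genotype_margins):
            raise ValueError("genotype margins must be non-negative")

    @property
    def is_null(self) -> bool:
        t0, t1, t2 = self.thetas
        return t0 == t1 == t2

    def hwe_probs(self) -> np.ndarray:
        p = self.allele_freq
        return np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])


@dataclass
class FixtureTruth:
    """Planted ground truth recorded by the generators."""

    causal_snps: set[str] = field(default_factory=set)
    causal_genes: set[str] = field(default_factory=set)
    enriched_categories: dict[str, set[str]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    snp_to_gene: dict[str, str | None] = field(default_factory=dict)
    genes_in_loci: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        d = {
            "causal_snps": sorted(self.causal_snps),
            "causal_genes": sorted(self.causal_genes),
            "enriched_categories": {k: sorted(v) for k, v in sorted(self.enriched_categories.items())},
            "effect_sizes": dict(sorted(self.effect_sizes.items())),
            "snp_to_gene": dict(sorted(self.snp_to_gene.items())),
            "genes_in_loci": sorted(self.genes_in_loci),
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            causal_snps=set(d["causal_snps"]),
            causal_genes=set(d["causal_genes"]),
            enriched_categories={k: set(v) for k, v in d["enriched_categories"].items()},
            effect_sizes=d["effect_sizes"],
            snp_to_gene=d["snp_to_gene"],
            genes_in_loci=set(d["genes_in_loci"]),
        )


# ------------------------------------------------------------ genotype data

def _draw_table(
    snp_id: str,
    margins: np.ndarray,
    thetas: np.ndarray,
    rng: np.random.Generator,
) -> GenotypeCounts:
    n_a = rng.binomial(margins, thetas)
    n_u = margins - n_a
    return GenotypeCounts(
        snp_id=snp_id,
        n0a=int(n_a[0]), n1a=int(n_a[1]), n2a=int(n_a[2]),
        n0u=int(n_u[0]), n1u=int(n_u[1]), n2u=int(n_u[2]),
    )


def simulate_genotype_counts(
    model: PopulationModel,
    n_snps: int,
    causal_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[GenotypeCounts], FixtureTruth]:
    """Genotype count tables with a seeded fraction of causal SNPs.

    Causal SNPs use the model's per-genotype thetas; null SNPs share the
    genotype-averaged theta so case/control totals stay comparable.  In
    marginal-null mode every SNP draws its own common theta ~ Uniform(0,1).
    """
    if not 0 <= causal_fraction <= 1:
        raise ValueError("causal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    n_causal = round(n_snps * causal_fraction)
    causal = set(rng.choice(ids, size=n_causal, replace=False)) if n_causal else set()

    probs = model.hwe_probs()
    if model.genotype_margins is not None:
        fixed_margins = np.array(model.genotype_margins, dtype=np.int64)
        weights = fixed_margins / fixed_margins.sum() if fixed_margins.sum() else probs
    else:
        fixed_margins = None
        weights = probs
    theta_bar = float(np.dot(weights, model.thetas))
    t0, t1, t2 = model.thetas
    delta = (t2 - t0) / 2

    tables = []
    truth = FixtureTruth(causal_snps=set(causal))
    for snp_id in ids:
        margins = (
            fixed_margins
            if fixed_margins is not None
            else rng.multinomial(model.n_individuals, probs)
        )
        if model.mode == "marginal-null":
            thetas = np.full(3, rng.uniform())
        elif snp_id in causal:
            thetas = np.array(model.thetas)
            truth.effect_sizes[snp_id] = delta
        else:
            thetas = np.full(3, theta_bar)
        tables.append(_draw_table(snp_id, np.asarray(margins), thetas, rng))
    return tables, truth


# ----------------------------------------------------------------- genome

def _brute_force_assign(
    snp: SnpRecord, genes: list[GeneRecord], max_distance: int
) -> str | None:
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        d = g.distance_to(snp.pos)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None or best[0] > max_distance:
        return None
    return best[1]


def build_loci(
    genes: list[GeneRecord],
    target_ids: set[str],
    padding: int = 100_000,
) -> list[DiseaseLocus]:
    """One disease locus per target gene, padded but clipped so that no
    non-target gene is touched."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)
    loci = []
    k = 0
    for chrom, gs in sorted(by_chrom.items()):
        for i, g in enumerate(gs):
            if g.gene_id not in target_ids:
                continue
            lo = g.start - padding
            hi = g.end + padding
            if i > 0:
                lo = max(lo, gs[i - 1].end + 1)
            if i + 1 < len(gs):
                hi = min(hi, gs[i + 1].start - 1)
            lo = max(lo, 1)
            k += 1
            loci.append(DiseaseLocus(locus_id=f"locus{k:03d}", chrom=chrom, start=lo, end=hi))
    return loci


def simulate_genome(
    n_genes: int,
    n_snps: int,
    n_loci: int,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
    frac_inside: float = 0.6,
    frac_near: float = 0.3,
    max_distance: int = 500_000,
    genes_in_loci: set[str] | None = None,
) -> tuple[list[GeneRecord], list[SnpRecord], list[DiseaseLocus], FixtureTruth]:
    """Toy genome: non-overlapping genes, placed SNPs, disease loci.

    Genes occupy the leading 80% of each chromosome in non-overlapping
    slots; the tail stays gene-free so "far" SNPs (> ``max_distance`` from
    every gene) exist.  SNP placement is controlled: ``frac_inside`` land
    inside genes (round-robin, so every gene is covered when
    n_snps*frac_inside >= n_genes), ``frac_near`` within ``max_distance``
    of a gene, and the remainder in the far tail.  Loci cover
    ``genes_in_loci`` if given, else ``n_loci`` randomly chosen genes.
    Truth records the brute-force SNP→gene assignment and the covered
    genes.  Raises if the genes cannot be packed.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 40_000_000, "chr2": 40_000_000}
    if frac_inside + frac_near > 1 + 1e-9:
        raise ValueError("frac_inside + frac_near must be <= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)

    # -- genes: per-chromosome slot packing in the leading 80%
    genes: list[GeneRecord] = []
    counts = np.full(len(chroms), n_genes // len(chroms))
    counts[: n_genes % len(chroms)] += 1
    gi = 0
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        usable = int(chrom_lengths[chrom] * 0.8)
        slot = usable // n_c
        max_len = min(50_000, slot // 2)
        if max_len < 2_000:
            raise ValueError(f"{chrom}: cannot pack {n_c} genes into {usable} bp")
        for j in range(n_c):
            gi += 1
            length = int(rng.integers(2_000, max_len + 1))
            start = slot * j + int(rng.integers(1, slot - length + 1))
            genes.append(
                GeneRecord(gene_id=f"gene{gi:04d}", chrom=chrom, start=start, end=start + length - 1)
            )

    # -- SNPs: inside / near / far, in controlled proportions
    n_inside = int(round(n_snps * frac_inside))
    n_near = int(round(n_snps * frac_near))
    n_far = n_snps - n_inside - n_near
    snps: list[SnpRecord] = []
    si = 0
    for k in range(n_inside):
        g = genes[k % len(genes)]  # round-robin coverage
        si += 1
        pos = int(rng.integers(g.start, g.end + 1))
        snps.append(SnpRecord(snp_id=f"snp{si:05d}", chrom=g.chrom, pos=pos))
    gene_set = [(g.chrom, g.start, g.end) for g in genes]

    def inside_any(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in gene_set)

    for _ in range(n_near):
        g = genes[int(rng.integers(len(genes)))]
        si += 1
        for _attempt in range(100):
            off = int(rng.integers(1, max_distance + 1))
            pos = g.end + off if rng.uniform() < 0.5 else g.start - off
            if pos >= 1 and pos <= chrom_lengths[g.chrom] and not inside_any(g.chrom, pos):
                break
        else:
            raise ValueError("could not place a near-gene SNP outside all genes")
        snps.append(SnpRecord(snp_id=f"snp{si:05d}", chrom=g.chrom, pos=pos))
    for _ in range(n_far):
        chrom = chroms[int(rng.integers(len(chroms)))]
        last_end = max((g.end for g in genes if g.chrom == chrom), default=0)
        lo = last_end + max_distance + 1
        hi = chrom_lengths[chrom]
        if lo >= hi:
            raise ValueError(f"{chrom}: no room for far SNPs beyond {lo}")
        si += 1
        snps.append(SnpRecord(snp_id=f"snp{si:05d}", chrom=chrom, pos=int(rng.integers(lo, hi + 1))))

    # -- loci
    if genes_in_loci is None:
        n_loci = min(n_loci, len(genes))
        genes_in_loci = set(rng.choice([g.gene_id for g in genes], size=n_loci, replace=False))
    loci = build_loci(genes, genes_in_loci)

    truth = FixtureTruth(
        snp_to_gene={s.snp_id: _brute_force_assign(s, genes, max_distance) for s in snps},
        genes_in_loci=set(genes_in_loci),
    )
    return genes, snps, loci, truth


# --------------------------------------------------------- protein features

_BASE_MEAN = np.concatenate(
    [np.full(20, 0.05), [70.0, 80.0, 90.0, 90.0, 95.0, 100.0, 0.32, 0.21]]
)
_BASE_SD = np.concatenate(
    [np.full(20, 0.01), [12.0, 12.0, 12.0, 12.0, 12.0, 12.0, 0.07, 0.06]]
)


def _class_means(separation: float, signal_dims: list[int] | None) -> tuple[np.ndarray, np.ndarray]:
    """Negative-class mean and positive-class mean at the given Mahalanobis
    separation, spread equally over the signal dims (1-based indices)."""
    if signal_dims is None:
        signal_dims = list(range(1, 29))
    idx = np.array(sorted(signal_dims)) - 1
    if idx.min() < 0 or idx.max() > 27:
        raise ValueError("signal_dims must be within 1..28")
    shift = np.zeros(28)
    per_dim = separation / np.sqrt(len(idx)) if len(idx) else 0.0
    sign = 1.0
    for i in idx:
        s = sign if i < 20 else 1.0  # alternate within composition to keep the simplex sum
        shift[i] = s * per_dim * _BASE_SD[i]
        if i < 20:
            sign = -sign
    return _BASE_MEAN.copy(), _BASE_MEAN + shift


def _postprocess(x: np.ndarray) -> np.ndarray:
    comp = np.clip(x[:, :20], 1e-4, None)
    x[:, :20] = comp / comp.sum(axis=1, keepdims=True)
    x[:, 20:23] = np.clip(x[:, 20:23], 1.0, None)  # cell lengths
    x[:, 23:26] = np.clip(x[:, 23:26], 1.0, 179.0)  # cell angles
    x[:, 26:28] = np.clip(x[:, 26:28], 0.0, 1.0)
    over = x[:, 26] + x[:, 27]
    bad = over > 1.0
    x[bad, 26:28] /= over[bad, None]
    return x


def sample_class_vectors(
    n: int,
    positive: bool,
    separation: float,
    rng: np.random.Generator,
    signal_dims: list[int] | None = None,
) -> np.ndarray:
    """Draw n 28-dim vectors from one class-conditional Gaussian, mapped
    back onto the feature constraints (simplex, angle and fraction ranges)."""
    neg_mean, pos_mean = _class_means(separation, signal_dims)
    mean = pos_mean if positive else neg_mean
    x = rng.normal(loc=mean, scale=_BASE_SD, size=(n, 28))
    return _postprocess(x)


def simulate_protein_features(
    n_pos: int,
    n_neg: int,
    n_test_pos: int = 0,
    n_test_neg: int = 0,
    separation: float = 4.0,
    seed: int = 0,
    signal_dims: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-conditional feature vectors for training pools and a test set.

    Separation is the Mahalanobis distance between class means (0 means the
    classes are identically distributed).  Returns (features, meta) where
    meta has columns ``label`` (1 positive / 0 negative) and ``role``
    (train_pos / train_neg / test_pos / test_neg).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    blocks = [
        ("POS", "train_pos", 1, True, n_pos),
        ("NEG", "train_neg", 0, False, n_neg),
        ("TPOS", "test_pos", 1, True, n_test_pos),
        ("TNEG", "test_neg", 0, False, n_test_neg),
    ]
    frames, meta_rows = [], []
    for prefix, role, label, positive, n in blocks:
        if n == 0:
            continue
        x = sample_class_vectors(n, positive, separation, rng, signal_dims)
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
        frames.append(pd.DataFrame(x, index=ids, columns=FEATURE_NAMES))
        meta_rows += [{"gene_id": g, "label": label, "role": role} for g in ids]
    features = pd.concat(frames) if frames else pd.DataFrame(columns=FEATURE_NAMES)
    meta = pd.DataFrame(meta_rows).set_index("gene_id") if meta_rows else pd.DataFrame()
    return features, meta


def composition_to_sequence(
    composition: np.ndarray,
    length: int = 500,
    rng: np.random.Generator | None = None,
) -> str:
    """A shuffled sequence whose residue counts realise the composition by
    largest-remainder rounding (composition error <= 1/length per residue)."""
    rng = rng or np.random.default_rng(0)
    target = np.asarray(composition, dtype=float) * length
    counts = np.floor(target).astype(int)
    short = length - counts.sum()
    if short > 0:
        order = np.argsort(-(target - counts))
        counts[order[:short]] += 1
    residues = [aa for aa, c in zip(AMINO_ACIDS, counts) for _ in range(c)]
    arr = np.array(residues)
    rng.shuffle(arr)
    return "".join(arr)


# ------------------------------------------------------------- annotations

def simulate_annotations(
    genes: list[str],
    disease_genes: set[str],
    n_categories_per_namespace: int = 30,
    clustering_strength: float = 0.9,
    seed: int = 0,
    co_clustered_genes: set[str] | None = None,
    n_disease_categories: int = 3,
    background_rate: float = 2.0,
) -> tuple[dict[str, AnnotationCatalog], FixtureTruth]:
    """PIRSF/GO/KEGG catalogs where disease genes co-cluster.

    A few designated "disease categories" per namespace receive each
    disease gene (and each co-clustered gene) independently with
    probability ``clustering_strength``; every gene additionally gets a
    Poisson(``background_rate``) number of uniformly chosen categories.
    Strength 0 removes the preferential assignment entirely (null).
    """
    if not set(disease_genes) <= set(genes):
        raise ValueError("disease_genes must be a subset of genes")
    co = co_clustered_genes or set()
    rng = np.random.default_rng(seed)
    catalogs: dict[str, AnnotationCatalog] = {}
    truth = FixtureTruth()
    universe = set(genes)
    for ns in NAMESPACES:
        cats = [f"{ns}_C{i + 1:03d}" for i in range(n_categories_per_namespace)]
        disease_cats = cats[:n_disease_categories]
        cat_map: dict[str, set[str]] = {c: set() for c in cats}
        for g in sorted(disease_genes | co):
            for c in disease_cats:
                if rng.uniform() < clustering_strength:
                    cat_map[c].add(g)
        for g in sorted(genes):
            k = rng.poisson(background_rate)
            for c in rng.choice(cats, size=min(k, len(cats)), replace=False):
                cat_map[c].add(g)
        catalogs[ns] = AnnotationCatalog.from_category_map(ns, cat_map, universe)
        truth.enriched_categories[ns] = set(disease_cats) if clustering_strength > 0 else set()
    return catalogs, truth


# ------------------------------------------------------------------ presets

def write_endtoend_fixture(
    outdir: str | Path,
    seed: int = 0,
    n_snps: int = 2_000,
    n_genes: int = 200,
    n_causal: int = 20,
    n_known_disease: int = 30,
    n_extra_loci: int = 10,
    n_individuals: int = 2_000,
    allele_freq: float = 0.3,
    thetas: tuple[float, float, float] = (0.35, 0.5, 0.65),
    separation: float = 4.0,
    clustering_strength: float = 0.9,
    sequence_length: int = 500,
) -> dict[str, object]:
    """Write the complete planted-truth input set for a full pipeline run.

    Causal genes carry SNPs generated under per-genotype case
    probabilities ``thetas`` and are covered by disease loci; known disease
    genes (the SVM positive pool) share the positive-class feature
    distribution with causal genes and co-cluster with them in the
    annotation catalogs.  Returns a dict with the file paths and the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # genome first, without loci; targets chosen below
    genes, snps, _, genome_truth = simulate_genome(
        n_genes=n_genes, n_snps=n_snps, n_loci=0, seed=seed, genes_in_loci=set()
    )
    gene_ids = [g.gene_id for g in genes]
    causal_genes = set(rng.choice(gene_ids, size=n_causal, replace=False))
    rest = [g for g in gene_ids if g not in causal_genes]
    extra_loci_genes = set(rng.choice(rest, size=n_extra_loci, replace=False))
    loci = build_loci(genes, causal_genes | extra_loci_genes)
    covered = causal_genes | extra_loci_genes
    outside = [g for g in rest if g not in covered]
    known_disease = set(rng.choice(outside, size=n_known_disease, replace=False))

    # genotype counts: SNPs inside causal genes are causal
    causal_snps = {
        s for s, g in genome_truth.snp_to_gene.items()
        if g in causal_genes and _inside(s, snps, genes, g)
    }
    probs = PopulationModel(allele_freq=allele_freq, n_individuals=n_individuals).hwe_probs()
    theta_bar = float(np.dot(probs, thetas))
    tables = []
    for s in snps:
        margins = rng.multinomial(n_individuals, probs)
        th = np.array(thetas) if s.snp_id in causal_snps else np.full(3, theta_bar)
        tables.append(_draw_table(s.snp_id, margins, th, rng))

    # features and sequences: positive class = causal + known disease genes
    positive_like = causal_genes | known_disease
    sequences: dict[str, str] = {}
    vectors = np.empty((len(gene_ids), 28))
    for i, gid in enumerate(gene_ids):
        v = sample_class_vectors(1, gid in positive_like, separation, rng)[0]
        vectors[i] = v
        sequences[gid] = composition_to_sequence(v[:20], length=sequence_length, rng=rng)
    from .structure_features import ProteinRecord

    protein_records = [
        ProteinRecord(
            gene_id=gid,
            sequence=sequences[gid],
            cell_a=vectors[i, 20], cell_b=vectors[i, 21], cell_c=vectors[i, 22],
            cell_alpha=vectors[i, 23], cell_beta=vectors[i, 24], cell_gamma=vectors[i, 25],
            helix_frac=vectors[i, 26], sheet_frac=vectors[i, 27],
        )
        for i, gid in enumerate(gene_ids)
    ]

    catalogs, ann_truth = simulate_annotations(
        genes=gene_ids,
        disease_genes=known_disease,
        clustering_strength=clustering_strength,
        seed=seed + 1,
        co_clustered_genes=causal_genes,
    )

    truth = FixtureTruth(
        causal_snps=causal_snps,
        causal_genes=causal_genes,
        enriched_categories=ann_truth.enriched_categories,
        effect_sizes={s: (thetas[2] - thetas[0]) / 2 for s in causal_snps},
        snp_to_gene=genome_truth.snp_to_gene,
        genes_in_loci=covered,
    )

    paths = {
        "counts": outdir / "counts.tsv",
        "genes": outdir / "genes.bed",
        "loci": outdir / "loci.bed",
        "fasta": outdir / "proteins.fasta",
        "crystal": outdir / "crystal.tsv",
        "positives": outdir / "positives.txt",
        "pirsf": outdir / "pirsf.gmt",
        "go": outdir / "go.gmt",
        "kegg": outdir / "kegg.gmt",
        "truth": outdir / "truth.json",
    }
    msio.write_counts_tsv(paths["counts"], tables, snps)
    msio.write_bed(paths["genes"], genes)
    msio.write_bed(paths["loci"], loci)
    msio.write_fasta(paths["fasta"], sequences)
    msio.write_crystal_tsv(paths["crystal"], protein_records)
    msio.write_gene_list(paths["positives"], known_disease)
    for ns, key in (("PIRSF", "pirsf"), ("GO", "go"), ("KEGG", "kegg")):
        msio.write_gmt(paths[key], catalogs[ns].category_to_genes)
    truth.to_json(paths["truth"])

    from .pipeline import PipelineConfig

    config = PipelineConfig(
        counts="counts.tsv", genes="genes.bed", loci="loci.bed",
        fasta="proteins.fasta", crystal="crystal.tsv", positives="positives.txt",
        pirsf="pirsf.gmt", go="go.gmt", kegg="kegg.gmt", seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth}


def _inside(snp_id: str, snps: list[SnpRecord], genes: list[GeneRecord], gene_id: str) -> bool:
    s = next(x for x in snps if x.snp_id == snp_id)
    g = next(x for x in genes if x.gene_id == gene_id)
    return g.chrom == s.chrom and g.start <= s.pos <= g.end


def write_preset(preset: str, outdir: str | Path, seed: int = 0) -> dict[str, object]:
    """Named fixture presets for the CLI: ``null``, ``power``, ``endtoend``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "endtoend":
        return write_endtoend_fixture(outdir, seed=seed)
    if preset == "null":
        model = PopulationModel(genotype_margins=(40, 40, 40), mode="marginal-null")
        tables, truth = simulate_genotype_counts(model, n_snps=10_000, seed=seed)
    elif preset == "power":
        model = PopulationModel(
            allele_freq=0.5, thetas=(0.4, 0.5, 0.6), genotype_margins=(300, 300, 300)
        )
        tables, truth = simulate_genotype_counts(model, n_snps=1_000, causal_fraction=0.5, seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    snps = [SnpRecord(snp_id=t.snp_id, chrom="chr1", pos=i + 1) for i, t in enumerate(tables)]
    msio.write_counts_tsv(outdir / "counts.tsv", tables, snps)
    truth.to_json(outdir / "truth.json")
    return {"paths": {"counts": str(outdir / "counts.tsv"), "truth": str(outdir / "truth.json")}, "truth": truth}
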