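"""Protein sequence/structure feature vectors for the structural screen.

Each gene's protein is summarised by a 28-dimension physicochemical vector:

* dims 1–20  — amino-acid composition (fractions, alphabetical one-letter
  order ``ACDEFGHIKLMNPQRSTVWY``),
* dims 21–26 — crystal unit-cell parameters a, b, c (Å) and alpha, beta,
  gamma (degrees),
* dims 27–28 — helical and beta-sheet fractions of the sequence.

Dims 21–28 together form the "secondary" feature subset used to train the
reduced classifier.  Structural fields may be missing (no crystal record);
missingness is tracked in a mask and handled by train-mean imputation at
standardization time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "FEATURE_NAMES",
    "SECONDARY_DIMS",
    "ProteinRecord",
    "ProteinFeatureVector",
    "compute_composition",
    "build_feature_vector",
    "standardize",
    "ScalerParams",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FEATURE_NAMES: list[str] = (
    [f"comp_{aa}" for aa in AMINO_ACIDS]
    + ["cell_a", "cell_b", "cell_c", "cell_alpha", "cell_beta", "cell_gamma"]
    + ["helix_frac", "sheet_frac"]
)

# 0-based column indices of the 8 "secondary" dims (21-28 in 1-based terms)
SECONDARY_DIMS = list(range(20, 28))

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ProteinRecord:
    """One gene's protein sequence plus optional crystal/secondary data.

    Fractions for helix/sheet are stored in [0, 1]; readers convert
    percent-style values (see :func:`multiscreen.io.read_crystal_tsv`).
    """

    gene_id: str
    sequence: str
    cell_a: float | None = None
    cell_b: float | None = None
    cell_c: float | None = None
    cell_alpha: float | None = None
    cell_beta: float | None = None
    cell_gamma: float | None = None
    helix_frac: float | None = None
    sheet_frac: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        for name in ("cell_a", "cell_b", "cell_c"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.gene_id}: {name}={v} must be positive")
        for name in ("cell_alpha", "cell_beta", "cell_gamma"):
            v = getattr(self, name)
            if v is not None and not 0 < v < 180:
                raise ValueError(f"{self.gene_id}: {name}={v} outside (0, 180)")
        for name in ("helix_frac", "sheet_frac"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{self.gene_id}: {name}={v} outside [0, 1]")
        if self.helix_frac is not None and self.sheet_frac is not None:
            if self.helix_frac + self.sheet_frac > 1 + 1e-9:
                raise ValueError(f"{self.gene_id}: helix_frac + sheet_frac > 1")


@dataclass(frozen=True)
class ProteinFeatureVector:
    """28-dim feature vector; missing entries are NaN and flagged in the mask."""

    gene_id: str
    values: np.ndarray  # shape (28,), float, NaN where missing
    missing_mask: np.ndarray  # shape (28,), bool

    @property
    def secondary(self) -> np.ndarray:
        """Dims 21–28: unit-cell parameters plus helix/sheet fractions."""
        return self.values[SECONDARY_DIMS]


def compute_composition(sequence: str) -> tuple[np.ndarray, int]:
    """Fraction of each of the 20 standard residues in a sequence.

    Non-standard letters (X, B, Z, ...) are excluded from both numerator and
    denominator; their count is returned as the second element.  Raises if
    no standard residue is present.
    """
    counts = np.zeros(20, dtype=np.int64)
    nonstandard = 0
    for ch in sequence.upper():
        i = _AA_INDEX.get(ch)
        if i is None:
            nonstandard += 1
        else:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard amino-acid residues")
    if nonstandard:
        logger.warning("%d non-standard residues excluded from composition", nonstandard)
    return counts / total, nonstandard


def build_feature_vector(record: ProteinRecord) -> ProteinFeatureVector:
    """Assemble the 28-dim vector (composition + crystal + helix/sheet)."""
    comp, _ = compute_composition(record.sequence)
    tail = [
        record.cell_a,
        record.cell_b,
        record.cell_c,
        record.cell_alpha,
        record.cell_beta,
        record.cell_gamma,
        record.helix_frac,
        record.sheet_frac,
    ]
    values = np.concatenate(
        [comp, np.array([np.nan if v is None else float(v) for v in tail])]
    )
    mask = np.isnan(values)
    return ProteinFeatureVector(gene_id=record.gene_id, values=values, missing_mask=mask)


@dataclass(frozen=True)
class ScalerParams:
    mean: np.ndarray
    sd: np.ndarray


def standardize(
    train: np.ndarray,
    apply: np.ndarray | None = None,
    impute_policy: str = "mean",
) -> tuple[np.ndarray, np.ndarray | None, ScalerParams]:
    """Per-dimension z-scaling with mean/sd estimated on the train rows only.

    Missing values (NaN) are imputed with the train mean of their dimension
    before scaling.  Zero-variance dimensions are mapped to 0 everywhere.
    Returns (scaled train, scaled apply or None, scaler parameters).
    """
    if impute_policy != "mean":
        raise ValueError(f"unknown impute_policy {impute_policy!r}")
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("standardize requires a non-empty train set")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(train, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)  # all-missing dim
    filled = np.where(np.isnan(train), mean, train)
    sd = filled.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d zero-variance dimensions scaled to 0", int(constant.sum()))
    safe_sd = np.where(constant, 1.0, sd)

    def _scale(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x = np.where(np.isnan(x), mean, x)
        z = (x - mean) / safe_sd
        z[:, constant] = 0.0
        return z

    out_apply = None if apply is None else _scale(np.atleast_2d(apply))
    return _scale(filled), out_apply, ScalerParams(mean=mean, sd=sd)
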