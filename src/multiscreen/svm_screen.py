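"""RBF-kernel SVM screen with randomized negative sets.

Known disease genes form a small positive class; the candidate negative
space (genes outside every disease locus) is large and heterogeneous, so a
single training set would sample it poorly.  Instead, many balanced
training sets are drawn — all positives plus an equal-size random subset of
negatives — and a classifier is trained per draw.  Model quality is
measured by pooled n-fold cross-validation sensitivity/specificity/accuracy
(Qp/Qn/Qa); test genes are finally labelled by every randomized classifier
and kept only if positive in (by default) all of them — the strict
intersection rule.

Features are z-standardized per training set (mean imputation for missing
values) before fitting; the classifier is libsvm's C-SVC via scikit-learn
with an RBF kernel, C = 1 and gamma = 1/n_features by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .structure_features import standardize

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "ClassifierPerformance",
    "EnsembleResult",
    "sample_training_set",
    "cross_validate",
    "evaluate_feature_sets",
    "ensemble_predict",
    "DEFAULT_C",
]

DEFAULT_C = 1.0


@dataclass(frozen=True)
class TrainingSet:
    """A balanced 1:1 positive/negative training draw (rows = genes)."""

    positives: pd.DataFrame
    negatives: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("training set must be balanced 1:1")
        overlap = set(self.positives.index) & set(self.negatives.index)
        if overlap:
            raise ValueError(f"positive/negative sets overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class ClassifierPerformance:
    """Pooled confusion counts with Qp (sensitivity), Qn (specificity), Qa."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def qp(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def qn(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def qa(self) -> float | None:
        d = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / d if d else None


@dataclass(frozen=True)
class EnsembleResult:
    """Votes over randomized trainings for each test gene.

    ``vote_fraction`` is the fraction of randomizations in which the gene
    was classified positive; ``mean_margin`` the mean signed distance to the
    separating hyperplane (disease-likeness score); ``candidates`` the genes
    positive in at least ``keep_fraction`` of randomizations.
    """

    vote_fraction: pd.Series
    mean_margin: pd.Series
    candidates: set[str]
    n_randomizations: int
    keep_fraction: float
    prediction_sets: list[set[str]] | None = None


def sample_training_set(
    positive_pool: pd.DataFrame,
    negative_pool: pd.DataFrame,
    seed: int,
) -> TrainingSet:
    """All positives plus an equal-size uniform draw (without replacement)
    from the negative pool; reproducible given the seed."""
    n = len(positive_pool)
    if len(negative_pool) < n:
        raise ValueError(
            f"negative pool ({len(negative_pool)}) smaller than positive set ({n})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_pool), size=n, replace=False)
    return TrainingSet(
        positives=positive_pool,
        negatives=negative_pool.iloc[np.sort(idx)],
        seed=seed,
    )


def _fit_svc(
    X_train: np.ndarray,
    y_train: np.ndarray,
    C: float,
    gamma: float | str,
) -> SVC:
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(X_train, y_train)
    return clf


def cross_validate(
    tset: TrainingSet,
    n_folds: int = 5,
    C: float = DEFAULT_C,
    gamma: float | str = "auto",
    seed: int = 0,
) -> ClassifierPerformance:
    """Seeded shuffle-and-split n-fold CV with confusion counts pooled
    over folds.

    The combined positive+negative rows are shuffled once, split into
    ``n_folds`` folds, and each fold is held out in turn.  If some training
    split ends up single-class the data are reshuffled once; a second
    failure raises.  ``gamma="auto"`` is 1/n_features.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.vstack([tset.positives.to_numpy(float), tset.negatives.to_numpy(float)])
    y = np.concatenate([np.ones(len(tset.positives)), np.zeros(len(tset.negatives))])
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")

    for attempt in range(2):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(len(y))
        folds = np.array_split(perm, n_folds)
        if all(len(np.unique(y[np.concatenate([f for j, f in enumerate(folds) if j != i])])) == 2
               for i in range(n_folds)):
            break
    else:
        raise ValueError("could not form folds with both classes after reshuffle")

    tp = tn = fp = fn = 0
    for i in range(n_folds):
        test_idx = folds[i]
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        Xtr, Xte, _ = standardize(X[train_idx], X[test_idx])
        clf = _fit_svc(Xtr, y[train_idx], C=C, gamma=gamma)
        pred = clf.predict(Xte)
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return ClassifierPerformance(tp=tp, tn=tn, fp=fp, fn=fn)


def evaluate_feature_sets(
    positive_pool: pd.DataFrame,
    negative_pool: pd.DataFrame,
    feature_subsets: dict[str, list[int]] | None = None,
    n_randomizations: int = 1000,
    n_folds: int = 5,
    C: float = DEFAULT_C,
    gamma: float | str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Qa summary (min/max/mean/sd) per feature subset over randomized draws.

    ``feature_subsets`` maps a label to 0-based column indices; default is
    the full 28-dim vector versus the 8 "secondary" dims (21–28).  Each
    randomization draws a fresh balanced training set (seed = master + i)
    and evaluates it by pooled n-fold CV.
    """
    if feature_subsets is None:
        ncol = positive_pool.shape[1]
        feature_subsets = {
            "full_28dim": list(range(ncol)),
            "secondary_8dim": list(range(max(0, ncol - 8), ncol)),
        }
    rows = []
    for label, cols in feature_subsets.items():
        qas = []
        for i in range(n_randomizations):
            tset = sample_training_set(positive_pool, negative_pool, seed=seed + i)
            sub = TrainingSet(
                positives=tset.positives.iloc[:, cols],
                negatives=tset.negatives.iloc[:, cols],
                seed=tset.seed,
            )
            perf = cross_validate(sub, n_folds=n_folds, C=C, gamma=gamma, seed=seed + i)
            qas.append(perf.qa)
        qas = np.array(qas, dtype=float)
        rows.append(
            {
                "feature_set": label,
                "n_randomizations": n_randomizations,
                "qa_min": float(qas.min()),
                "qa_max": float(qas.max()),
                "qa_mean": float(qas.mean()),
                "qa_sd": float(qas.std(ddof=1)) if len(qas) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def ensemble_predict(
    positive_pool: pd.DataFrame,
    negative_pool: pd.DataFrame,
    test_set: pd.DataFrame,
    n_randomizations: int = 10_000,
    keep_fraction: float = 1.0,
    C: float = DEFAULT_C,
    gamma: float | str = "auto",
    seed: int = 0,
    record_sets: bool = False,
) -> EnsembleResult:
    """Label every test gene under each randomized training; intersect.

    A gene is a candidate if classified positive in at least
    ``keep_fraction`` of the randomizations (1.0 = the strict intersection).
    Per-randomization seeds are ``seed + i``.  Raises if the test set shares
    genes with either pool.
    """
    overlap = (set(test_set.index) & set(positive_pool.index)) | (
        set(test_set.index) & set(negative_pool.index)
    )
    if overlap:
        raise ValueError(f"test set overlaps training pools: {sorted(overlap)[:5]}")
    ids = list(test_set.index)
    if not ids:
        return EnsembleResult(
            vote_fraction=pd.Series(dtype=float),
            mean_margin=pd.Series(dtype=float),
            candidates=set(),
            n_randomizations=n_randomizations,
            keep_fraction=keep_fraction,
            prediction_sets=[] if record_sets else None,
        )
    X_test_raw = test_set.to_numpy(float)
    votes = np.zeros(len(ids), dtype=np.int64)
    margin_sum = np.zeros(len(ids), dtype=float)
    sets: list[set[str]] | None = [] if record_sets else None
    for i in range(n_randomizations):
        tset = sample_training_set(positive_pool, negative_pool, seed=seed + i)
        X = np.vstack([tset.positives.to_numpy(float), tset.negatives.to_numpy(float)])
        y = np.concatenate([np.ones(len(tset.positives)), np.zeros(len(tset.negatives))])
        Xtr, Xte, _ = standardize(X, X_test_raw)
        clf = _fit_svc(Xtr, y, C=C, gamma=gamma)
        pos = clf.predict(Xte) == 1
        votes += pos
        margin_sum += clf.decision_function(Xte)
        if sets is not None:
            sets.append({ids[j] for j in np.nonzero(pos)[0]})
    vote_fraction = pd.Series(votes / n_randomizations, index=ids)
    mean_margin = pd.Series(margin_sum / n_randomizations, index=ids)
    threshold = keep_fraction * n_randomizations - 1e-9
    candidates = {ids[j] for j in range(len(ids)) if votes[j] >= threshold}
    return EnsembleResult(
        vote_fraction=vote_fraction,
        mean_margin=mean_margin,
        candidates=candidates,
        n_randomizations=n_randomizations,
        keep_fraction=keep_fraction,
        prediction_sets=sets,
    )
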