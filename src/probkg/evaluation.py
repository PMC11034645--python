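"""Cross-validation splits, ranking metrics, exposure-bias diagnostics, and
literature-support analyses for target-disease association prediction.

Two split schemes over the target-disease matrix: an entry-wise stratified
5-fold split, and a cluster-wise split in which disease columns are
agglomeratively clustered (average linkage, distance 1 - Jaccard) and whole
clusters are assigned to test folds, so that near-duplicate disease profiles
never straddle the train/test boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "Fold",
    "SplitPlan",
    "EvalReport",
    "entrywise_folds",
    "clusterwise_folds",
    "auroc",
    "aupr",
    "spearman",
    "degree_counts",
    "subset_performance",
    "maxscore_degree_correlation",
    "significant_entries",
    "novel_predictions",
    "literature_support_counts",
    "topk_cr_correlation",
    "evaluate_fold",
]

KT_THRESHOLDS = (100, 300, 500)
KD_THRESHOLDS = (10, 30, 50)
CR_THRESHOLDS = (0, 5, 25)
TOPK_GRID = (200, 500, 1000, 1500, 2000, 2500, 3000)


@dataclass
class Fold:
    """Flat-index masks over the TDA grid; the three arrays partition it."""

    test: np.ndarray
    val: np.ndarray
    train: np.ndarray


@dataclass
class SplitPlan:
    shape: tuple[int, int]
    folds: list[Fold]
    scheme: str
    seed: int

    def validate(self) -> None:
        n = self.shape[0] * self.shape[1]
        all_test = np.concatenate([f.test for f in self.folds])
        if len(np.unique(all_test)) != n or len(all_test) != n:
            raise ValueError("test folds do not partition the entry set")
        for f in self.folds:
            combined = np.concatenate([f.test, f.val, f.train])
            if len(combined) != n or len(np.unique(combined)) != n:
                raise ValueError("fold masks do not partition the entry set")

    def to_json(self, path: str) -> None:
        payload = {
            "shape": list(self.shape),
            "scheme": self.scheme,
            "seed": self.seed,
            "folds": [
                {
                    "test": f.test.tolist(),
                    "val": f.val.tolist(),
                    "train": f.train.tolist(),
                }
                for f in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        folds = [
            Fold(
                test=np.asarray(f["test"], dtype=np.int64),
                val=np.asarray(f["val"], dtype=np.int64),
                train=np.asarray(f["train"], dtype=np.int64),
            )
            for f in payload["folds"]
        ]
        return cls(
            shape=tuple(payload["shape"]),
            folds=folds,
            scheme=payload["scheme"],
            seed=payload["seed"],
        )


def _stratified_sample(
    idx: np.ndarray, labels: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``frac`` of ``idx``, separately within positives and negatives."""
    take = []
    for cls in (1, 0):
        pool = idx[labels == cls]
        n = int(round(frac * len(pool)))
        take.append(rng.permutation(pool)[:n])
    return np.sort(np.concatenate(take))


def entrywise_folds(
    tda: np.ndarray, k: int = 5, seed: int = 0, val_frac: float = 0.1
) -> SplitPlan:
    """Stratified k-fold split of individual matrix entries.

    Positives and negatives are shuffled separately and dealt round-robin, so
    per-fold positive counts differ by at most one from exact stratification.
    Validation entries are a stratified ``val_frac`` sample of each fold's
    non-test entries.
    """
    tda = np.asarray(tda)
    labels = (tda.ravel() > 0).astype(int)
    n_pos = int(labels.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positives for {k} folds; stratification degrades")
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    test_sets = [np.sort(np.concatenate([pos[i::k], neg[i::k]])) for i in range(k)]
    folds = []
    for i in range(k):
        test = test_sets[i]
        rest = np.sort(np.concatenate([test_sets[j] for j in range(k) if j != i]))
        val = _stratified_sample(rest, labels[rest], val_frac, rng)
        train = np.setdiff1d(rest, val, assume_unique=True)
        folds.append(Fold(test=test, val=val, train=train))
    plan = SplitPlan(shape=tda.shape, folds=folds, scheme="entry", seed=seed)
    plan.validate()
    return plan


def column_clusters(tda: np.ndarray, k: int = 5) -> np.ndarray:
    """Agglomerative clusters of disease columns (average linkage on
    1 - Jaccard), split until no cluster exceeds ``n_cols / k`` columns."""
    tda = np.asarray(tda) > 0
    n_cols = tda.shape[1]
    if n_cols < 2:
        return np.zeros(n_cols, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero column pairs
        dist = pdist(tda.T, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)
    Z = linkage(dist, method="average")
    limit = max(1, n_cols // k)
    t = k
    clusters = fcluster(Z, t, criterion="maxclust")
    while np.max(np.bincount(clusters)) > limit and t < n_cols:
        t += 1
        clusters = fcluster(Z, t, criterion="maxclust")
    if np.max(np.bincount(clusters)) > limit:
        warnings.warn("a column cluster exceeds 1/k of all columns; folds will be uneven")
    if t > k:
        warnings.warn(f"largest cluster split at a lower dendrogram level (cut={t})")
    return clusters


def clusterwise_folds(
    tda: np.ndarray, k: int = 5, seed: int = 0, val_frac: float = 0.1
) -> SplitPlan:
    """Cluster-wise k-fold split: whole column clusters are assigned to test
    folds (largest cluster first, into the currently smallest fold), then all
    entries of a fold's columns form its test set."""
    tda = np.asarray(tda)
    labels = (tda.ravel() > 0).astype(int)
    n_rows, n_cols = tda.shape
    clusters = column_clusters(tda, k)
    rng = np.random.default_rng(seed)
    ids, sizes = np.unique(clusters, return_counts=True)
    order = rng.permutation(len(ids))  # random tie order among equal sizes
    ids, sizes = ids[order], sizes[order]
    by_size = np.argsort(-sizes, kind="stable")
    fold_cols: list[list[int]] = [[] for _ in range(k)]
    for ci in by_size:
        target = min(range(k), key=lambda f: len(fold_cols[f]))
        fold_cols[target].extend(np.flatnonzero(clusters == ids[ci]).tolist())
    folds = []
    for i in range(k):
        cols = np.asarray(sorted(fold_cols[i]), dtype=np.int64)
        test = np.sort(
            (np.arange(n_rows)[:, None] * n_cols + cols[None, :]).ravel()
        ) if len(cols) else np.asarray([], dtype=np.int64)
        rest = np.setdiff1d(np.arange(n_rows * n_cols), test, assume_unique=False)
        val = _stratified_sample(rest, labels[rest], val_frac, rng)
        train = np.setdiff1d(rest, val, assume_unique=True)
        folds.append(Fold(test=test, val=val, train=train))
    plan = SplitPlan(shape=tda.shape, folds=folds, scheme="cluster", seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# ranking metrics


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined for single-class labels")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney with tie correction)."""
    return float(roc_auc_score(_check_labels(labels), np.asarray(scores)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-interpolated)."""
    return float(average_precision_score(_check_labels(labels), np.asarray(scores)))


def spearman(a, b) -> Optional[float]:
    """Spearman rank correlation with average ranks for ties; None when
    either input has zero variance (undefined, not 0)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    rho = spearmanr(a, b).statistic
    return None if np.isnan(rho) else float(rho)


def degree_counts(tda: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(k_t, k_d): observed associations per target (row sums) and per
    disease (column sums)."""
    tda = np.asarray(tda) > 0
    return tda.sum(axis=1), tda.sum(axis=0)


def subset_performance(
    pred: np.ndarray,
    tda: np.ndarray,
    kt_thresholds: Sequence[int] = KT_THRESHOLDS,
    kd_thresholds: Sequence[int] = KD_THRESHOLDS,
    entries: Optional[np.ndarray] = None,
) -> dict[str, Optional[float]]:
    """AUPR restricted to entries whose target (disease) has k_t (k_d)
    strictly below each threshold; None for empty or single-class subsets.

    ``entries`` optionally restricts the evaluation to a flat-index subset
    (e.g. a test fold) before thresholding.
    """
    pred, tda = np.asarray(pred), np.asarray(tda)
    k_t, k_d = degree_counts(tda)
    n_rows, n_cols = tda.shape
    flat = np.arange(n_rows * n_cols) if entries is None else np.asarray(entries)
    rows, cols = flat // n_cols, flat % n_cols
    out: dict[str, Optional[float]] = {}
    for name, degs, idx, thresholds in (
        ("k_t", k_t, rows, kt_thresholds),
        ("k_d", k_d, cols, kd_thresholds),
    ):
        for thr in thresholds:
            keep = flat[degs[idx] < thr]
            key = f"{name}<{thr}"
            try:
                out[key] = aupr(pred.ravel()[keep], (tda.ravel()[keep] > 0).astype(int))
            except ValueError:
                out[key] = None
    return out


def maxscore_degree_correlation(pred: np.ndarray, k_t: np.ndarray) -> Optional[float]:
    """Spearman correlation between each target's maximum prediction score
    and its number of observed associations."""
    return spearman(np.asarray(pred).max(axis=1), k_t)


def significant_entries(pred: np.ndarray) -> list[tuple[int, int]]:
    """Per-row selections: entries strictly above the row mean plus two row
    (population) standard deviations."""
    pred = np.asarray(pred, dtype=float)
    mu = pred.mean(axis=1, keepdims=True)
    sd = pred.std(axis=1, keepdims=True)  # population std
    rows, cols = np.nonzero(pred > mu + 2.0 * sd)
    return list(zip(rows.tolist(), cols.tolist()))


def novel_predictions(
    significant: Sequence[tuple[int, int]],
    observed_tda: np.ndarray,
    pred: np.ndarray,
) -> list[tuple[int, int, float]]:
    """Significant entries that are unobserved in the input networks, sorted
    by descending score with (row, column) tie-break."""
    observed = np.asarray(observed_tda) > 0
    pred = np.asarray(pred)
    kept = [(i, j, float(pred[i, j])) for i, j in significant if not observed[i, j]]
    kept.sort(key=lambda e: (-e[2], e[0], e[1]))
    return kept


def literature_support_counts(
    ranked: Sequence[tuple[int, int, float]],
    c_tda: np.ndarray,
    top_n: int = 200,
    thresholds: Sequence[int] = CR_THRESHOLDS,
) -> dict[int, int]:
    """Among the top-n ranked predictions, the number whose co-occurrence
    count strictly exceeds each threshold."""
    c_tda = np.asarray(c_tda)
    top = ranked[:top_n]
    return {
        thr: int(sum(c_tda[i, j] > thr for i, j, _ in top)) for thr in thresholds
    }


def topk_cr_correlation(
    ranked: Sequence[tuple[int, int, float]],
    c_tda: np.ndarray,
    ks: Sequence[int] = TOPK_GRID,
) -> dict[int, Optional[float]]:
    """Spearman correlation between the top-k prediction scores and their
    co-occurrence counts, for each k (truncated to the list length)."""
    c_tda = np.asarray(c_tda)
    out: dict[int, Optional[float]] = {}
    for k in ks:
        top = ranked[:k]
        if len(top) < 2:
            out[k] = None
            continue
        scores = [s for _, _, s in top]
        cs = [c_tda[i, j] for i, j, _ in top]
        out[k] = spearman(scores, cs)
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    """Metrics for one prediction grid against one ground truth."""

    auroc: Optional[float] = None
    aupr: Optional[float] = None
    subset_aupr: dict[str, Optional[float]] = field(default_factory=dict)
    maxscore_kt_spearman: Optional[float] = None
    literature_counts: dict[int, int] = field(default_factory=dict)
    topk_spearman: dict[int, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "subset_aupr": self.subset_aupr,
            "maxscore_kt_spearman": self.maxscore_kt_spearman,
            "literature_counts": {str(k): v for k, v in self.literature_counts.items()},
            "topk_spearman": {str(k): v for k, v in self.topk_spearman.items()},
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in self.to_dict().items():
                if isinstance(value, dict):
                    for k2, v2 in value.items():
                        fh.write(f"{key}[{k2}]\t{v2}\n")
                else:
                    fh.write(f"{key}\t{value}\n")


def evaluate_fold(
    pred: np.ndarray,
    truth: np.ndarray,
    entries: np.ndarray,
    observed_tda: Optional[np.ndarray] = None,
    c_tda: Optional[np.ndarray] = None,
    kt_thresholds: Sequence[int] = KT_THRESHOLDS,
    kd_thresholds: Sequence[int] = KD_THRESHOLDS,
) -> EvalReport:
    """Standard report for one fold: overall AUROC/AUPR on the given entries,
    degree-subset AUPRs, the exposure-bias correlation, and (when counts are
    given) the literature-support analyses of novel predictions."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    entries = np.asarray(entries)
    labels = (truth.ravel()[entries] > 0).astype(int)
    scores = pred.ravel()[entries]
    report = EvalReport()
    try:
        report.auroc = auroc(scores, labels)
        report.aupr = aupr(scores, labels)
    except ValueError:
        pass
    report.subset_aupr = subset_performance(
        pred, truth, kt_thresholds, kd_thresholds, entries=entries
    )
    k_t, _ = degree_counts(truth)
    report.maxscore_kt_spearman = maxscore_degree_correlation(pred, k_t)
    if c_tda is not None:
        observed = observed_tda if observed_tda is not None else truth
        ranked = novel_predictions(significant_entries(pred), observed, pred)
        report.literature_counts = literature_support_counts(ranked, c_tda)
        report.topk_spearman = topk_cr_correlation(ranked, c_tda)
    return report
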