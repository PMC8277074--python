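"""Clustering-quality metrics and the kernel two-sample separation statistic.

NMI and matched accuracy follow the deep-clustering benchmark
conventions; the population F-measure follows the flow-cytometry
benchmarking convention (size-weighted best-match F1 over true
populations). Latent-cluster separation is quantified with an unbiased
squared maximum-mean-discrepancy (MMD) estimate under an RBF kernel.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import confusion_matrix, normalized_mutual_info_score

__all__ = [
    "nmi",
    "matched_accuracy",
    "population_f_measure",
    "mmd_statistic",
    "mmd_permutation_test",
]


def _check_labels(labels_true, labels_pred) -> tuple[np.ndarray, np.ndarray]:
    lt = np.asarray(labels_true)
    lp = np.asarray(labels_pred)
    if lt.size == 0 or lp.size == 0:
        raise ValueError("labels must be non-empty")
    if lt.shape != lp.shape:
        raise ValueError("label vectors must have equal length")
    return lt, lp


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information, normalized by the arithmetic mean
    of the two label entropies. 1 for identical partitions (up to
    relabeling), 0 for independent ones."""
    lt, lp = _check_labels(labels_true, labels_pred)
    return float(normalized_mutual_info_score(lt, lp, average_method="arithmetic"))


def matched_accuracy(labels_true, labels_pred) -> float:
    """Classification accuracy after the optimal one-to-one matching of
    predicted clusters to true classes (exact bipartite assignment on
    the contingency table; extra clusters are matched to zero-count
    dummy classes)."""
    lt, lp = _check_labels(labels_true, labels_pred)
    cm = confusion_matrix(lt, lp)
    r, c = cm.shape
    if r != c:  # pad to square with zero-count dummies
        size = max(r, c)
        padded = np.zeros((size, size), dtype=cm.dtype)
        padded[:r, :c] = cm
        cm = padded
    row, col = linear_sum_assignment(cm, maximize=True)
    return float(cm[row, col].sum() / lt.size)


def population_f_measure(labels_true, labels_pred, weighted: bool = True) -> float:
    """Best-match F1 per true population, averaged with weights
    proportional to population sizes (``weighted=False`` for the plain
    mean). Predicted labels that are NaN or negative count as
    unassigned and are excluded with a warning."""
    lt, lp = _check_labels(labels_true, labels_pred)
    lp_float = np.asarray(lp, dtype=float) if np.issubdtype(
        np.asarray(lp).dtype, np.number) else None
    if lp_float is not None:
        assigned = np.isfinite(lp_float) & (lp_float >= 0)
    else:
        assigned = np.array([v is not None for v in lp])
    if not assigned.all():
        warnings.warn(f"excluding {int((~assigned).sum())} unassigned prediction(s)")
        lt, lp = lt[assigned], lp[assigned]
    if lt.size == 0:
        raise ValueError("no assigned predictions left")

    scores, weights = [], []
    pred_values = np.unique(lp)
    for pop in np.unique(lt):
        in_pop = lt == pop
        best = 0.0
        for cl in pred_values:
            in_cl = lp == cl
            tp = float(np.sum(in_pop & in_cl))
            if tp == 0.0:
                continue
            precision = tp / in_cl.sum()
            recall = tp / in_pop.sum()
            best = max(best, 2 * precision * recall / (precision + recall))
        scores.append(best)
        weights.append(in_pop.sum())
    scores = np.asarray(scores)
    weights = np.asarray(weights, dtype=float)
    if not weighted:
        weights = np.ones_like(weights)
    return float(np.sum(scores * weights) / weights.sum())


def _rbf_gamma(pooled: np.ndarray) -> float:
    """Median-pairwise-distance heuristic bandwidth for the RBF kernel."""
    med = np.median(pdist(pooled))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


def mmd_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Unbiased squared-MMD estimate, scaled by the pooled sample size.

    RBF kernel with median-heuristic bandwidth over the pooled sample.
    Near zero (possibly slightly negative — the estimator is unbiased)
    when both samples come from the same distribution; large and
    positive when they differ. Deterministic given the inputs.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(sample_b, dtype=np.float64))
    n, m = a.shape[0], b.shape[0]
    if n < 2 or m < 2:
        raise ValueError("unbiased MMD requires at least 2 samples per group")
    gamma = _rbf_gamma(np.vstack([a, b]))

    def k(x, y):
        return np.exp(-gamma * cdist(x, y, "sqeuclidean"))

    kaa = k(a, a)
    kbb = k(b, b)
    kab = k(a, b)
    term_a = (kaa.sum() - np.trace(kaa)) / (n * (n - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (m * (m - 1))
    mmd2 = term_a + term_b - 2.0 * kab.mean()
    return float((n + m) * mmd2)


def mmd_permutation_test(sample_a: np.ndarray, sample_b: np.ndarray,
                         n_permutations: int = 500, seed: int = 0
                         ) -> tuple[float, np.ndarray, float]:
    """Permutation null for the MMD statistic.

    Returns (observed statistic, null statistics under random
    relabeling, one-sided p-value with the +1 correction).
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(sample_b, dtype=np.float64))
    observed = mmd_statistic(a, b)
    pooled = np.vstack([a, b])
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        null[i] = mmd_statistic(pooled[perm[:n]], pooled[perm[n:]])
    p_value = (1 + np.sum(null >= observed)) / (1 + n_permutations)
    return observed, null, float(p_value)
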