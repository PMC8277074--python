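"""Construction of the binary batch similarity matrix S.

S encodes which sample pairs in a batch are considered alike; the
gating network is trained so that the co-membership matrix P P^T
approximates it. S can be derived without supervision (UMAP projection
followed by k-nearest-neighbors or distance thresholding), supplied by
the user, or built from prior-knowledge signature features (one marker
feature per expected group, as with organ-specific signature genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

__all__ = ["SimilaritySpec", "build_similarity", "signature_similarity"]

_METHODS = ("umap_knn", "umap_threshold", "precomputed", "signature")


@dataclass
class SimilaritySpec:
    """How to build S for a batch.

    method:
        ``umap_knn`` (default) — embed the batch with UMAP under
        ``metric`` and connect mutual-or k-nearest neighbors;
        ``umap_threshold`` — connect pairs within ``threshold`` in the
        embedding; ``precomputed`` — validate a user matrix;
        ``signature`` — prior-knowledge marker features.
    metric:
        Distance for the UMAP projection (``euclidean`` default,
        ``canberra`` for mass-cytometry marker panels, any metric UMAP
        accepts).
    n_neighbors:
        k for the kNN graph on the embedding; must be < batch size.
    threshold:
        Distance cutoff in the embedding for ``umap_threshold``.
    umap_dim:
        Embedding dimensionality (default 2).
    signature_features:
        Column indices of the signature features, one per expected
        group, for ``signature``.
    """

    method: str = "umap_knn"
    metric: str = "euclidean"
    n_neighbors: int = 10
    threshold: float = 1.0
    umap_dim: int = 2
    umap_n_neighbors: int = 15
    signature_features: list[int] | None = None
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")


def _assert_valid(S: np.ndarray) -> np.ndarray:
    assert S.shape[0] == S.shape[1]
    assert np.array_equal(S, S.T), "similarity matrix must be symmetric"
    assert np.isin(S, (0.0, 1.0)).all(), "similarity matrix must be binary"
    assert np.all(np.diag(S) == 1.0), "similarity matrix must have unit diagonal"
    return S


def _umap_embed(x: np.ndarray, spec: SimilaritySpec) -> np.ndarray:
    import umap  # deferred: numba-jitted import is expensive

    n = x.shape[0]
    reducer = umap.UMAP(
        n_components=spec.umap_dim,
        metric=spec.metric,
        n_neighbors=min(spec.umap_n_neighbors, n - 1),
        random_state=spec.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(x), dtype=np.float64)


def build_similarity(x_batch: np.ndarray, spec: SimilaritySpec,
                     precomputed: np.ndarray | None = None) -> np.ndarray:
    """Binary, symmetric, unit-diagonal N x N similarity matrix for a batch.

    ``umap_knn``: S_ij = 1 iff j is among i's k nearest neighbors in
    the UMAP embedding or vice versa (OR-symmetrized). ``umap_threshold``:
    S_ij = 1 iff the embedding distance is <= threshold. ``precomputed``:
    validated pass-through. A degenerate batch (all points identical)
    yields an all-ones S with a warning.
    """
    x = np.asarray(x_batch, dtype=np.float64)
    n = x.shape[0]

    if spec.method == "precomputed":
        if precomputed is None:
            raise ValueError("precomputed method requires a matrix")
        S = np.asarray(precomputed, dtype=np.float64).copy()
        if S.shape != (n, n):
            raise ValueError(f"precomputed S must be {n}x{n}, got {S.shape}")
        if not np.array_equal(S, S.T):
            raise ValueError("precomputed S must be symmetric")
        if not np.isin(S, (0.0, 1.0)).all():
            raise ValueError("precomputed S must be binary")
        np.fill_diagonal(S, 1.0)
        return _assert_valid(S)

    if spec.method == "signature":
        S, _ = signature_similarity(x, spec.signature_features)
        return S

    if np.allclose(x, x[0]):
        warnings.warn("degenerate batch (all points identical); S set to all ones")
        return _assert_valid(np.ones((n, n)))

    if spec.method == "umap_knn" and n < spec.n_neighbors + 1:
        raise ValueError("batch size must exceed n_neighbors")

    emb = _umap_embed(x, spec)

    if spec.method == "umap_knn":
        nn = NearestNeighbors(n_neighbors=spec.n_neighbors + 1).fit(emb)
        graph = nn.kneighbors_graph(emb).toarray()  # includes self
        S = np.where((graph + graph.T) > 0, 1.0, 0.0)
    else:  # umap_threshold
        dist = squareform(pdist(emb))
        S = (dist <= spec.threshold).astype(np.float64)
    np.fill_diagonal(S, 1.0)
    return _assert_valid(S)


def signature_similarity(x_batch: np.ndarray,
                         signature_features: list[int] | None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Prior-knowledge similarity from one marker feature per group.

    A sample is tagged with every signature whose feature value is
    strictly above that feature's batch mean; samples tagged by exactly
    one signature are kept (``keep_mask``), and S_ij = 1 iff i and j
    carry the same single tag. Rows for excluded samples have only the
    unit diagonal.
    """
    x = np.asarray(x_batch, dtype=np.float64)
    if not signature_features:
        raise ValueError("signature method requires signature_features")
    feats = list(signature_features)
    if len(set(feats)) != len(feats):
        raise ValueError("signature features must be distinct")
    if min(feats) < 0 or max(feats) >= x.shape[1]:
        raise ValueError("signature feature index out of range")

    vals = x[:, feats]  # (N, G)
    tags = vals > vals.mean(axis=0, keepdims=True)  # strictly above average
    n_tags = tags.sum(axis=1)
    keep_mask = n_tags == 1
    if not keep_mask.any():
        raise ValueError(
            "no sample is above average on exactly one signature feature; "
            "review the signature thresholds"
        )
    group = np.where(keep_mask, tags.argmax(axis=1), -1)
    same = (group[:, None] == group[None, :]) & keep_mask[:, None] & keep_mask[None, :]
    S = same.astype(np.float64)
    np.fill_diagonal(S, 1.0)
    return _assert_valid(S), keep_mask
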