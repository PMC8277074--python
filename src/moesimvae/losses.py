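"""Loss terms of the model and their weighted combination.

All terms accept either plain numpy arrays or autodiff tensors and
return a scalar :class:`~moesimvae._autodiff.Tensor`, so the same code
path serves both training (gradients) and diagnostics (call ``.item()``).

Reduction conventions (fixed so the loss-weight scales are
reproducible): reconstruction is summed over features and averaged over
samples; the similarity term is averaged over all N^2 matrix entries;
the KL term is an unweighted mean over non-empty clusters; the DEPICT
term is averaged over samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = [
    "LossBreakdown",
    "kl_loss",
    "reconstruction_loss",
    "similarity_loss",
    "depict_targets",
    "depict_loss",
    "total_loss",
]

logger = logging.getLogger(__name__)

EPS = 1e-7
VAR_FLOOR = 1e-6
_VAR_CEIL = 1e18


@dataclass
class LossBreakdown:
    """All scalar loss terms of one step, with the combination identities
    vae = reconst + pi1*kl, clustering = similarity + pi2*depict and
    total = vae + clustering holding exactly."""

    reconst: float
    kl: float
    similarity: float
    depict: float
    vae: float
    clustering: float
    total: float


def kl_loss(z, p=None, *, hard: np.ndarray | None = None,
            per_cluster: bool = True) -> Tensor:
    """Covariance penalty on the latent representation.

    For each cluster (hard assignment from ``p`` or given directly) the
    per-dimension latent variances sigma_j are estimated from its
    members and the Kullback-Leibler divergence between N(0, I) and
    N(0, diag(sigma_j)) is computed in closed form,
    ``0.5 * sum_j (1/sigma_j - 1 + ln sigma_j)``; the result is the
    unweighted mean over clusters with at least two members. With
    ``per_cluster=False`` a single global variance estimate is used.
    Variances are floored at 1e-6.
    """
    z = as_tensor(z)
    n, d_z = z.data.shape
    if hard is None:
        if p is None:
            hard = np.zeros(n, dtype=int)
        else:
            p_arr = p.data if isinstance(p, Tensor) else np.asarray(p)
            hard = p_arr.argmax(axis=1)
    if not per_cluster:
        hard = np.zeros(n, dtype=int)

    terms: list[Tensor] = []
    for k in np.unique(hard):
        idx = np.flatnonzero(hard == k)
        if idx.size < 2:
            continue
        zk = z.take_rows(idx)
        centered = zk - zk.mean(axis=0, keepdims=True)
        var = (centered * centered).mean(axis=0).clip(VAR_FLOOR, _VAR_CEIL)
        # KL(N(0,I) || N(0,diag(var))) per cluster
        terms.append((1.0 / var - 1.0 + var.log()).sum() * 0.5)
    if not terms:
        warnings.warn("no cluster with >= 2 members; KL term is 0")
        return Tensor(0.0)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def reconstruction_loss(x, x_reconst, truncated: bool = False) -> Tensor:
    """Binary cross-entropy between data in [0,1] and its reconstruction.

    Summed over features, averaged over samples. ``truncated=True``
    drops the complement term and the sign (the bare ``x log x_rec``
    form), kept only for ablation; reconstructions are clamped to
    [1e-7, 1 - 1e-7] in both variants.
    """
    x = as_tensor(x)
    xr = as_tensor(x_reconst)
    if x.data.shape != xr.data.shape:
        raise ValueError("x and x_reconst must share shape")
    if x.data.min() < 0 or x.data.max() > 1:
        raise ValueError("x must be scaled to [0, 1]")
    n = x.data.shape[0]
    xr = xr.clip(EPS, 1.0 - EPS)
    if truncated:
        return (x * xr.log()).sum() * (1.0 / n)
    per_elem = x * xr.log() + (1.0 - x) * (1.0 - xr).log()
    return -per_elem.sum() * (1.0 / n)


def _check_similarity(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.array_equal(S, S.T):
        raise ValueError("S must be symmetric")
    if not np.isin(S, (0.0, 1.0)).all():
        raise ValueError("S must be binary")
    return S


def similarity_loss(p, S, truncated: bool = False) -> Tensor:
    """Binary cross-entropy between the binary similarity matrix S and
    the cluster co-membership matrix G = P P^T, averaged over all N^2
    entries. G_ij is close to 1 only when samples i and j put their
    probability mass on the same cluster."""
    p = as_tensor(p)
    S = _check_similarity(S)
    n = p.data.shape[0]
    if S.shape[0] != n:
        raise ValueError("S size must match the batch size of p")
    g = (p @ p.T).clip(EPS, 1.0 - EPS)
    s = Tensor(S)
    if truncated:
        return (s * g.log()).sum() * (1.0 / (n * n))
    per_entry = s * g.log() + (1.0 - s) * (1.0 - g).log()
    return -per_entry.sum() * (1.0 / (n * n))


def depict_targets(p: np.ndarray) -> np.ndarray:
    """Sharpened target distribution q from clean probabilities p.

    q_ik is p_ik normalized by the square root of cluster k's total
    soft mass, renormalized per row. Columns with zero mass contribute
    nothing (skipped with a log message).
    """
    p = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    col_mass = p.sum(axis=0)
    zero_cols = col_mass <= 0.0
    if zero_cols.any():
        logger.info("depict_targets: skipping %d empty cluster column(s)",
                    int(zero_cols.sum()))
    denom = np.where(zero_cols, 1.0, np.sqrt(col_mass))
    num = np.where(zero_cols[None, :], 0.0, p / denom)
    return num / num.sum(axis=1, keepdims=True)


def depict_loss(p, p_noisy) -> Tensor:
    """Cross-entropy between targets q (computed from the clean p and
    treated as constants) and the dropout-noised probabilities,
    averaged over samples. Encourages noise-invariant cluster features."""
    p_noisy = as_tensor(p_noisy)
    q = depict_targets(p)
    if q.shape != p_noisy.data.shape:
        raise ValueError("p and p_noisy must share shape")
    n = q.shape[0]
    return -(Tensor(q) * p_noisy.clip(EPS, 1.0 - EPS).log()).sum() * (1.0 / n)


def _scalar(v, name: str) -> float:
    v = v.item() if isinstance(v, Tensor) else float(v)
    if not np.isfinite(v):
        raise FloatingPointError(f"non-finite loss component: {name} = {v}")
    return v


def total_loss(reconst, kl, similarity, depict,
               pi1: float, pi2: float) -> LossBreakdown:
    """Combine the four terms into the full objective.

    vae = reconst + pi1*kl regularizes the latent representation;
    clustering = similarity + pi2*depict trains the gating network;
    total = vae + clustering is optimized end-to-end.
    """
    r = _scalar(reconst, "reconst")
    k = _scalar(kl, "kl")
    s = _scalar(similarity, "similarity")
    d = _scalar(depict, "depict")
    vae = r + pi1 * k
    clustering = s + pi2 * d
    return LossBreakdown(
        reconst=r, kl=k, similarity=s, depict=d,
        vae=vae, clustering=clustering, total=vae + clustering,
    )
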