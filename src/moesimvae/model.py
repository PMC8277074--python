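"""Encoder, gating network and mixture-of-experts decoder.

The architecture: a shared fully connected encoder maps [0,1]-scaled
data to a Gaussian variational posterior in latent space; a gating
(clustering) network maps latent codes to soft cluster probabilities;
each sample is routed by hard argmax to one of K expert decoders, each
of which learns to reconstruct and generate a single data mode.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, scatter_rows
from ._nn import MLP
from .config import ModelConfig

__all__ = [
    "LatentBatch",
    "AssignmentMatrix",
    "MixtureState",
    "MoESimVAE",
    "cluster_means",
]

CHECKPOINT_VERSION = 1


@dataclass
class LatentBatch:
    """Variational posterior parameters and a reparameterized sample."""

    mean: np.ndarray
    log_var: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if not (self.mean.shape == self.log_var.shape == self.z.shape):
            raise ValueError("mean, log_var and z must share shape")


@dataclass
class AssignmentMatrix:
    """Soft cluster probabilities, their dropout-noised counterpart and
    the hard argmax assignment (ties broken to the lowest index)."""

    p: np.ndarray
    p_noisy: np.ndarray
    hard: np.ndarray

    def __post_init__(self):
        rowsum = self.p.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise ValueError("rows of p must sum to 1")


@dataclass
class MixtureState:
    """Per-cluster latent means, empirical weights and occupancies.

    Empty clusters (``n_k == 0``) carry NaN means and are flagged via
    :attr:`empty`; sampling from them is refused downstream.
    """

    mu: np.ndarray
    omega: np.ndarray
    n_k: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return self.n_k == 0

    @property
    def active(self) -> np.ndarray:
        """Indices of occupied clusters."""
        return np.flatnonzero(self.n_k > 0)


def cluster_means(z: np.ndarray, p: np.ndarray, soft: bool = False) -> MixtureState:
    """EM-style empirical mixture state from latent codes and assignments.

    The default estimator divides the probability-weighted sum of codes
    by the *hard* occupancy count of each cluster; ``soft=True`` uses
    the soft mass in the denominator (a true weighted mean) instead.
    """
    z = np.asarray(z, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if z.shape[0] != p.shape[0]:
        raise ValueError("z and p must have the same number of rows")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("p must be row-stochastic")
    n, k = p.shape
    hard = p.argmax(axis=1)
    n_k = np.bincount(hard, minlength=k).astype(np.float64)
    weighted = p.T @ z  # (K, D_z)
    denom = p.sum(axis=0) if soft else n_k
    mu = np.full((k, z.shape[1]), np.nan)
    nonzero = denom > 0
    mu[nonzero] = weighted[nonzero] / denom[nonzero, None]
    return MixtureState(mu=mu, omega=n_k / n, n_k=n_k)


class MoESimVAE:
    """The similarity-guided mixture-of-experts variational autoencoder.

    Parameters are initialized deterministically from ``cfg.seed``. The
    public numpy-facing methods (:meth:`encode`, :meth:`gate`,
    :meth:`decode_moe`) wrap differentiable tensor-level counterparts
    (suffixed ``_t``) used by the training loop.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
        enc_widths = list(cfg.encoder_layers)
        trunk_out = enc_widths[-1] if enc_widths else cfg.input_dim
        self.encoder = MLP(cfg.input_dim, enc_widths[:-1], trunk_out, rng) if enc_widths else None
        head_in = trunk_out
        self.mean_head = MLP(head_in, [], cfg.latent_dim, rng)
        self.logvar_head = MLP(head_in, [], cfg.latent_dim, rng)
        self.logvar_head.layers[-1].b.data += cfg.logvar_bias_init
        self.gating = MLP(cfg.latent_dim, list(cfg.gating_layers), cfg.n_experts, rng)
        self.experts = [
            MLP(cfg.latent_dim, list(cfg.expert_layers), cfg.input_dim, rng)
            for _ in range(cfg.n_experts)
        ]
        self.mixture: MixtureState | None = None
        self.scaling_meta: dict | None = None

    # -- parameters ----------------------------------------------------

    @property
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.encoder is not None:
            params += self.encoder.parameters
        params += self.mean_head.parameters + self.logvar_head.parameters
        params += self.gating.parameters
        for e in self.experts:
            params += e.parameters
        return params

    # -- validation ----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"expected (N, {self.cfg.input_dim}) input, got {x.shape}"
            )
        if not np.isfinite(x).all():
            raise ValueError("input contains non-finite values")
        if x.min() < -1e-9 or x.max() > 1 + 1e-9:
            raise ValueError("input must be scaled to [0, 1]")
        return x

    # -- tensor-level forward (differentiable) ---------------------------

    def _trunk_t(self, x: Tensor) -> Tensor:
        if self.encoder is None:
            return x
        return self.encoder(x).relu()

    def encode_t(self, x: Tensor, rng: np.random.Generator | None = None,
                 sample: bool = True, noise_scale: float = 1.0
                 ) -> tuple[Tensor, Tensor, Tensor]:
        h = self._trunk_t(x)
        mean = self.mean_head(h)
        if self.cfg.posterior_logvar is not None:
            log_var = Tensor(np.full(mean.data.shape, self.cfg.posterior_logvar))
        else:
            log_var = self.logvar_head(h)
        if not sample:
            return mean, log_var, mean
        rng = rng if rng is not None else np.random.default_rng(self.cfg.seed)
        eps = Tensor(noise_scale * rng.standard_normal(mean.data.shape))
        z = mean + (log_var * 0.5).exp() * eps
        return mean, log_var, z

    def gate_t(self, z: Tensor, dropout_rng: np.random.Generator | None = None) -> Tensor:
        rate = self.cfg.dropout_rate if dropout_rng is not None else 0.0
        return self.gating(z, dropout_rate=rate, rng=dropout_rng).softmax()

    def decode_t(self, z: Tensor, hard: np.ndarray) -> Tensor:
        hard = np.asarray(hard)
        if hard.shape[0] != z.data.shape[0]:
            raise ValueError("hard must have one entry per latent row")
        if hard.size and (hard.min() < 0 or hard.max() >= self.cfg.n_experts):
            raise IndexError("expert index out of range")
        n = z.data.shape[0]
        pieces = []
        for k in range(self.cfg.n_experts):
            idx = np.flatnonzero(hard == k)
            if idx.size == 0:
                continue
            out_k = self.experts[k](z.take_rows(idx)).sigmoid()
            pieces.append(scatter_rows(out_k, idx, n))
        if not pieces:
            return Tensor(np.zeros((n, self.cfg.input_dim)))
        out = pieces[0]
        for piece in pieces[1:]:
            out = out + piece
        return out

    # -- numpy-facing operations -----------------------------------------

    def encode(self, x: np.ndarray, rng: np.random.Generator | None = None) -> LatentBatch:
        """Variational posterior and reparameterized sample for a batch.

        With ``rng=None`` a fresh generator seeded from the config is
        used, so repeated calls return bit-identical samples.
        """
        x = self._check_input(x)
        mean, log_var, z = self.encode_t(Tensor(x), rng=rng)
        return LatentBatch(mean=mean.data, log_var=log_var.data, z=z.data)

    def gate(self, z: np.ndarray, rng: np.random.Generator | None = None) -> AssignmentMatrix:
        """Clean and dropout-noised cluster probabilities plus hard routing."""
        z = np.asarray(z, dtype=np.float64)
        if not np.isfinite(z).all():
            raise ValueError("latent codes must be finite")
        p = self.gate_t(Tensor(z)).data
        if self.cfg.dropout_rate > 0.0:
            rng = rng if rng is not None else np.random.default_rng(self.cfg.seed)
            p_noisy = self.gate_t(Tensor(z), dropout_rng=rng).data
        else:
            p_noisy = p.copy()
        return AssignmentMatrix(p=p, p_noisy=p_noisy, hard=p.argmax(axis=1))

    def decode_moe(self, z: np.ndarray, hard: np.ndarray) -> np.ndarray:
        """Reconstruction in (0,1): row i is produced by expert hard[i] only."""
        return self.decode_t(Tensor(np.asarray(z, dtype=np.float64)), hard).data

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic cluster probabilities (posterior mean, no noise)."""
        x = self._check_input(x)
        _, _, z = self.encode_t(Tensor(x), sample=False)
        return self.gate_t(z).data

    # -- checkpointing ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a versioned archive with config, parameters and metadata."""
        buf = io.BytesIO()
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters)}
        if self.mixture is not None:
            arrays["mixture_mu"] = self.mixture.mu
            arrays["mixture_omega"] = self.mixture.omega
            arrays["mixture_n_k"] = self.mixture.n_k
        np.savez(buf, **arrays)
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "config": self.cfg.to_dict(),
            "scaling": self.scaling_meta,
            "has_mixture": self.mixture is not None,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "MoESimVAE":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["format_version"] != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta['format_version']}"
                )
            with zf.open("arrays.npz") as fh:
                arrays = np.load(io.BytesIO(fh.read()))
                model = cls(ModelConfig.from_dict(meta["config"]))
                for i, p in enumerate(model.parameters):
                    p.data = arrays[f"param_{i}"]
                if meta["has_mixture"]:
                    model.mixture = MixtureState(
                        mu=arrays["mixture_mu"],
                        omega=arrays["mixture_omega"],
                        n_k=arrays["mixture_n_k"],
                    )
        model.scaling_meta = meta.get("scaling")
        return model
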