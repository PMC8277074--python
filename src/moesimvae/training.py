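"""End-to-end minibatch training of the joint objective.

Per batch: build (or reuse) the binary similarity matrix S, encode,
gate through the clustering network (clean and dropout-noised passes),
route each sample to its argmax expert, evaluate all loss terms and
take one Adam step on their weighted sum. Cluster means/weights are
refreshed once per epoch from a full deterministic pass, as in the
M-step of EM.

Batches are drawn once from a seeded permutation and kept fixed across
epochs (the last incomplete batch is dropped so S has a fixed size);
this lets S be computed once per batch and makes runs bit-for-bit
reproducible on one CPU thread.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._nn import Adam
from .config import ModelConfig
from .losses import (LossBreakdown, depict_loss, kl_loss, reconstruction_loss,
                     similarity_loss, total_loss)
from .model import MixtureState, MoESimVAE, cluster_means
from .similarity import SimilaritySpec, build_similarity

__all__ = ["TrainState", "train", "predict_clusters"]


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    mixture: MixtureState | None = None
    loss_history: list[LossBreakdown] = field(default_factory=list)
    active_experts: set[int] = field(default_factory=set)
    final_assignments: np.ndarray | None = None


def _make_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    if n <= batch_size:
        return [perm]
    batches = [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    if len(batches[-1]) < batch_size:
        batches = batches[:-1]  # drop incomplete batch: S has fixed size
    return batches


def train(data: np.ndarray,
          cfg: ModelConfig | None = None,
          sim_spec: SimilaritySpec | None = None,
          *,
          n_experts: int | None = None,
          latent_dim: int = 2,
          epochs: int = 150,
          batch_size: int = 200,
          lr: float = 1e-3,
          seed: int = 0,
          precomputed_similarity: np.ndarray | None = None,
          noise_warmup_epochs: int = 0,
          out_dir: str | Path | None = None,
          ) -> tuple[MoESimVAE, TrainState]:
    """Train a model on [0,1]-scaled data.

    Either pass a full :class:`ModelConfig` or just ``n_experts`` (a
    default architecture is then built around ``latent_dim``). With
    ``out_dir`` set, per-step losses are written to ``losses.tsv`` and
    ``metrics.jsonl`` under it.

    ``noise_warmup_epochs`` linearly ramps the reparameterization
    noise from 0 to its full scale over the first epochs: the gating
    first locks onto the similarity blocks on a near-deterministic
    latent, then the growing noise forces the clusters to separate at
    the prior's unit scale (which is what makes mixture sampling gate
    cleanly).

    Returns the trained model (its :attr:`mixture` holds the final
    cluster means/weights) and the :class:`TrainState`.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D sample x feature matrix")
    if data.min() < -1e-9 or data.max() > 1 + 1e-9:
        raise ValueError("data must be scaled to [0, 1]")

    if cfg is None:
        if n_experts is None:
            raise ValueError("pass cfg or n_experts")
        cfg = ModelConfig(n_experts=n_experts, latent_dim=latent_dim,
                          input_dim=data.shape[1], seed=seed)
    if cfg.input_dim != data.shape[1]:
        raise ValueError("cfg.input_dim does not match the data")
    sim_spec = sim_spec if sim_spec is not None else SimilaritySpec(seed=seed)
    if sim_spec.method == "umap_knn" and batch_size < sim_spec.n_neighbors + 1:
        raise ValueError("batch_size must be at least n_neighbors + 1")

    ss = np.random.SeedSequence(seed)
    shuffle_rng, eps_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    batches = _make_batches(data.shape[0], batch_size, shuffle_rng)

    # Per-batch similarity, computed once (batches are fixed).
    sim_matrices = []
    for idx in batches:
        if sim_spec.method == "precomputed":
            if precomputed_similarity is None:
                raise ValueError("precomputed similarity method needs the matrix")
            S = build_similarity(data[idx], sim_spec,
                                 precomputed=precomputed_similarity[np.ix_(idx, idx)])
        else:
            S = build_similarity(data[idx], sim_spec)
        sim_matrices.append(S)

    model = MoESimVAE(cfg)
    opt = Adam(model.parameters, lr=lr)
    state = TrainState()

    tsv_fh = jsonl_fh = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tsv_fh = open(out_dir / "losses.tsv", "w")
        tsv_fh.write("step\treconst\tkl\tsimilarity\tdepict\tvae\tclustering\ttotal\n")
        jsonl_fh = open(out_dir / "metrics.jsonl", "w")

    try:
        for epoch in range(epochs):
            if noise_warmup_epochs > 0:
                noise_scale = min(1.0, (epoch + 1) / noise_warmup_epochs)
            else:
                noise_scale = 1.0
            for idx, S in zip(batches, sim_matrices):
                x_t = Tensor(data[idx])
                _, _, z = model.encode_t(x_t, rng=eps_rng, noise_scale=noise_scale)
                p_t = model.gate_t(z)
                if cfg.dropout_rate > 0:
                    p_noisy_t = model.gate_t(z, dropout_rng=drop_rng)
                else:
                    p_noisy_t = p_t
                hard = p_t.data.argmax(axis=1)

                x_rec = model.decode_t(z, hard)
                l_rec = reconstruction_loss(x_t, x_rec)
                l_kl = kl_loss(z, hard=hard, per_cluster=cfg.kl_per_cluster)
                l_sim = similarity_loss(p_t, S) * cfg.similarity_weight
                l_dep = depict_loss(p_t.data, p_noisy_t)

                try:
                    breakdown = total_loss(l_rec, l_kl, l_sim, l_dep,
                                           cfg.pi1, cfg.pi2)
                except FloatingPointError as exc:
                    last = state.loss_history[-1] if state.loss_history else None
                    raise RuntimeError(
                        f"training aborted at step {state.step}: {exc}; "
                        f"last finite breakdown: {last}"
                    ) from exc

                total_t = l_rec + cfg.pi1 * l_kl + l_sim + cfg.pi2 * l_dep
                opt.zero_grad()
                total_t.backward()
                opt.step()

                state.step += 1
                state.loss_history.append(breakdown)
                if tsv_fh is not None:
                    b = breakdown
                    tsv_fh.write(f"{state.step}\t{b.reconst:.6g}\t{b.kl:.6g}\t"
                                 f"{b.similarity:.6g}\t{b.depict:.6g}\t{b.vae:.6g}\t"
                                 f"{b.clustering:.6g}\t{b.total:.6g}\n")
                    jsonl_fh.write(json.dumps({"step": state.step, **vars(b)}) + "\n")

            state.epoch = epoch + 1
            _refresh_mixture(model, data, state, cfg)

        if state.mixture is None:  # epochs == 0
            _refresh_mixture(model, data, state, cfg)
    finally:
        if tsv_fh is not None:
            tsv_fh.close()
            jsonl_fh.close()

    if len(state.active_experts) == 1 and cfg.n_experts > 1:
        warnings.warn("gating collapsed: all samples routed to one expert")
    model.mixture = state.mixture
    return model, state


def _refresh_mixture(model: MoESimVAE, data: np.ndarray,
                     state: TrainState, cfg: ModelConfig) -> None:
    """EM-style per-epoch refresh from a deterministic full pass."""
    _, _, z = model.encode_t(Tensor(data), sample=False)
    p = model.gate_t(z).data
    state.mixture = cluster_means(z.data, p, soft=cfg.soft_cluster_means)
    state.final_assignments = p.argmax(axis=1)
    state.active_experts = set(np.flatnonzero(state.mixture.n_k > 0).tolist())


def predict_clusters(model: MoESimVAE, x: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and soft probabilities for new data.

    Deterministic: the posterior mean is used, no sampling noise.
    """
    p = model.predict_proba(x)
    return p.argmax(axis=1), p
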