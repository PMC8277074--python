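"""Model configuration and its flat-file (JSON/YAML) serialization."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    """Architecture and loss-weight hyperparameters.

    Attributes
    ----------
    n_experts:
        Number of decoder experts K (upper bound on clusters the model
        can use; unused experts are silenced during training).
    latent_dim:
        Dimensionality of the Gaussian-mixture latent space.
    input_dim:
        Number of input features D; data must be scaled to [0, 1].
    encoder_layers / expert_layers / gating_layers:
        Hidden-layer widths of the respective fully connected stacks.
    dropout_rate:
        Dropout probability on the noisy gating pass used by the
        noise-robust clustering (DEPICT) loss; 0 disables it.
    pi1:
        Weight of the latent covariance KL penalty inside the VAE loss.
    pi2:
        Weight of the DEPICT term inside the clustering loss.
    similarity_weight:
        Coefficient on the similarity-reconstruction loss; set to 0 for
        the ablation that trains without the similarity matrix.
    soft_cluster_means:
        If True, cluster means are fully soft weighted averages; the
        default divides the soft-weighted sum by the hard-assignment
        count, matching the published estimator.
    kl_per_cluster:
        Estimate latent variances per cluster (default) or globally.
    logvar_bias_init:
        Initial bias of the posterior log-variance head. A negative
        value starts the posterior tight, so the covariance penalty
        inflates each cluster's spread of codes toward unit variance
        instead of drowning the codes in reparameterization noise.
    posterior_logvar:
        If set, the posterior log-variance is held at this constant
        instead of being learned (0.0 gives unit posterior noise, so
        each latent cluster is round at the prior scale and the
        similarity loss must carve unit-Gaussian-separable clusters —
        the regime that makes mixture sampling gate cleanly). None
        (default) learns it through the log-variance head.
    seed:
        Seed for parameter initialization and the reparameterization
        noise stream.
    """

    n_experts: int
    latent_dim: int
    input_dim: int
    encoder_layers: list[int] = field(default_factory=lambda: [64, 32])
    expert_layers: list[int] = field(default_factory=lambda: [32, 64])
    gating_layers: list[int] = field(default_factory=lambda: [32])
    dropout_rate: float = 0.1
    pi1: float = 0.01
    pi2: float = 1.0
    similarity_weight: float = 1.0
    soft_cluster_means: bool = False
    kl_per_cluster: bool = True
    logvar_bias_init: float = -3.0
    posterior_logvar: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pi1 < 0 or self.pi2 < 0 or self.similarity_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        for name in ("encoder_layers", "expert_layers", "gating_layers"):
            widths = getattr(self, name)
            if any(w < 1 for w in widths):
                raise ValueError(f"{name} must contain positive widths")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
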