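"""Mode-specific data generation.

Latent points are sampled from the learned mixture of standard
Gaussians N(mu_k, I); each sample is gated through the clustering
network to its argmax expert, which decodes it. No posterior
thresholding or rejection is applied — n requested samples cost
exactly n decoder evaluations.
"""

from __future__ import annotations

import numpy as np

from .model import MixtureState, MoESimVAE

__all__ = ["sample_latent", "generate"]


def sample_latent(mixture: MixtureState, component: int | None, n: int,
                  seed: int = 0, uniform: bool = False
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent points from N(mu_k, I).

    With ``component`` given, all points come from that component
    (refused if it is empty). Otherwise components are drawn from the
    empirical weights omega (or uniformly over non-empty components
    with ``uniform=True``).
    """
    rng = np.random.default_rng(seed)
    d_z = mixture.mu.shape[1]
    if n == 0:
        return np.empty((0, d_z)), np.empty(0, dtype=int)
    if component is not None:
        if mixture.empty[component]:
            raise ValueError(
                f"component {component} is empty (silenced expert); "
                "cannot sample from it"
            )
        labels = np.full(n, component, dtype=int)
    else:
        active = mixture.active
        if active.size == 0:
            raise ValueError("mixture has no occupied component")
        if uniform:
            weights = np.full(active.size, 1.0 / active.size)
        else:
            weights = mixture.omega[active] / mixture.omega[active].sum()
        labels = active[rng.choice(active.size, size=n, p=weights)]
    z = mixture.mu[labels] + rng.standard_normal((n, d_z))
    return z, labels


def generate(model: MoESimVAE, latent: np.ndarray,
             labels: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Decode latent points through the gated mixture-of-experts.

    Each latent point is assigned by the clustering network (argmax)
    and decoded by the selected expert. Returns the generated data in
    (0,1) and the realized gate per sample; ``labels`` (the components
    the latent points were drawn from) are accepted only for caller
    bookkeeping and do not influence the gating.
    """
    latent = np.asarray(latent, dtype=np.float64)
    if latent.ndim != 2 or latent.shape[1] != model.cfg.latent_dim:
        raise ValueError(f"latent must be (n, {model.cfg.latent_dim})")
    assignment = model.gate(latent)
    x_gen = model.decode_moe(latent, assignment.hard)
    return x_gen, assignment.hard
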