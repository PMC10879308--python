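"""Seeded synthetic drug-disease worlds for testing and benchmarking.

Real drug-disease data couples three observations: drugs similar to each
other tend to treat diseases similar to each other, and the observed
association matrix is a sparse, noisy shadow of that latent structure.
The generator plants exactly this: drugs and diseases are drawn around
shared cluster centres in a low-dimensional latent space, the true
affinity of a pair decays with latent distance (exp(-d^2)), the observed
binary associations are the top-affinity pairs at the requested density
with a fraction of entries flipped as noise, and the within-type
similarity matrices are latent-proximity kernels (exp(-d^2/2)) with unit
diagonal.

Defaults (60 drugs, 80 diseases, latent dimension 8, density 0.05,
noise 0.05) keep the end-to-end tests fast on one CPU while leaving the
planted signal clearly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import AssociationMatrix, SimilarityMatrix, ValidationError


@dataclass
class SyntheticWorld:
    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    associations: AssociationMatrix
    truth: np.ndarray              # M x N ground-truth affinity
    drug_latent: np.ndarray
    disease_latent: np.ndarray
    seed: int


def _similarity_from_latent(latent: np.ndarray, prefix: str) -> SimilarityMatrix:
    d2 = cdist(latent, latent, metric="sqeuclidean")
    S = np.exp(-d2 / 2.0)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    ids = [f"{prefix}{i:03d}" for i in range(latent.shape[0])]
    return SimilarityMatrix(ids=ids, values=S)


def generate_world(
    M: int = 60,
    N: int = 80,
    latent_dim: int = 8,
    density: float = 0.05,
    noise: float = 0.05,
    seed: int = 7,
    n_clusters: int = 5,
    cluster_spread: float = 0.4,
) -> SyntheticWorld:
    """Generate a seeded synthetic world with planted latent structure.

    ``density`` is the fraction of the M*N pairs that are observed
    positives; ``noise`` is the fraction of those positives swapped with
    random zero pairs after planting.
    """
    if not 0 < density < 1:
        raise ValidationError("density must be in (0, 1)")
    if not 0 <= noise <= 1:
        raise ValidationError("noise must be in [0, 1]")
    if latent_dim < 1:
        raise ValidationError("latent_dim must be at least 1")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, (n_clusters, latent_dim))
    drug_latent = (
        centers[rng.integers(n_clusters, size=M)]
        + rng.normal(0.0, cluster_spread, (M, latent_dim))
    )
    disease_latent = (
        centers[rng.integers(n_clusters, size=N)]
        + rng.normal(0.0, cluster_spread, (N, latent_dim))
    )
    truth = np.exp(-cdist(drug_latent, disease_latent, metric="sqeuclidean"))

    n_pos = int(round(density * M * N))
    if n_pos < 1 or n_pos >= M * N:
        raise ValidationError("density leaves no positives or no negatives")
    flat_order = np.argsort(-truth, axis=None, kind="stable")
    Y = np.zeros(M * N)
    Y[flat_order[:n_pos]] = 1.0

    n_flip = int(round(noise * n_pos))
    if n_flip > 0:
        pos_idx = np.flatnonzero(Y == 1)
        zero_idx = np.flatnonzero(Y == 0)
        drop = rng.choice(pos_idx, size=n_flip, replace=False)
        add = rng.choice(zero_idx, size=n_flip, replace=False)
        Y[drop] = 0.0
        Y[add] = 1.0
    Y = Y.reshape(M, N)

    drug_sim = _similarity_from_latent(drug_latent, "DR")
    disease_sim = _similarity_from_latent(disease_latent, "DI")
    assoc = AssociationMatrix(
        drug_ids=list(drug_sim.ids), disease_ids=list(disease_sim.ids), values=Y
    )
    return SyntheticWorld(
        drug_sim=drug_sim,
        disease_sim=disease_sim,
        associations=assoc,
        truth=truth,
        drug_latent=drug_latent,
        disease_latent=disease_latent,
        seed=seed,
    )


def holdout_positives(
    world: SyntheticWorld, fraction: float, seed: int
) -> tuple[AssociationMatrix, np.ndarray]:
    """Zero a uniform sample of positives in a training copy.

    Returns the training matrix and the held-out (drug, disease) index
    pairs; the world itself is untouched.
    """
    if not 0 < fraction < 1:
        raise ValidationError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = np.argwhere(world.associations.values > 0)
    n_out = int(round(fraction * len(pairs)))
    if n_out >= len(pairs):
        raise ValidationError("holdout fraction removes every positive")
    if n_out < 1:
        raise ValidationError("holdout fraction removes no positives")
    held = pairs[rng.choice(len(pairs), size=n_out, replace=False)]
    train_values = world.associations.values.copy()
    train_values[held[:, 0], held[:, 1]] = 0.0
    train = AssociationMatrix(
        drug_ids=list(world.associations.drug_ids),
        disease_ids=list(world.associations.disease_ids),
        values=train_values,
    )
    return train, held
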