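"""Similarity networks and the drug-disease heterogeneous adjacency.

Drugs and diseases form a two-type graph: within-type edges carry
similarity weights, cross-type edges carry known associations.  The
blocks are assembled as

    G = [[ mu * S'_r ,  Y      ],
         [ Y^T       ,  mu * S'_d ]]

where S' = E^{-1/2} S E^{-1/2} is the symmetric degree-normalization of a
similarity matrix (E its diagonal row-sum matrix) and mu is a penalty
factor controlling how much the similarity channels contribute relative
to the association channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AssociationMatrix,
    SimilarityMatrix,
    ValidationError,
    warn,
)


def jaccard_similarity(
    profiles: np.ndarray, ids: list[str] | None = None
) -> SimilarityMatrix:
    """Jaccard similarity between rows of a binary feature matrix.

    ``S[i, j] = |P_i & P_j| / |P_i | P_j|`` for feature sets P.  Entities
    with an all-zero profile get off-diagonal similarity 0 (with a
    warning) and diagonal 1.
    """
    P = np.asarray(profiles)
    if P.ndim != 2:
        raise ValidationError("profiles must be a 2-D binary matrix")
    if not np.all((P == 0) | (P == 1)):
        raise ValidationError("profiles must be binary")
    P = P.astype(float)
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    empty = sizes == 0
    if empty.any():
        warn(f"{int(empty.sum())} entity profile(s) are all-zero; their similarity is 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    if ids is None:
        ids = [f"e{i}" for i in range(P.shape[0])]
    return SimilarityMatrix(ids=list(ids), values=S)


def normalize_similarity(S: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric degree normalization S' = E^{-1/2} S E^{-1/2}.

    E = diag(row sums of S).  The result has S'_ij = S_ij / sqrt(d_i d_j)
    and spectral radius at most 1.  A zero row sum is an error: the caller
    should ensure unit self-similarity first.
    """
    d = S.values.sum(axis=1)
    zero = np.flatnonzero(d <= 0)
    if zero.size:
        raise ValidationError(
            f"zero row sum for entity {S.ids[zero[0]]!r}; add self-similarity 1 first"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    out = SimilarityMatrix.__new__(SimilarityMatrix)
    out.ids = list(S.ids)
    out.values = S.values * inv_sqrt[:, None] * inv_sqrt[None, :]
    return out


def apply_penalty(S: SimilarityMatrix, mu: float) -> SimilarityMatrix:
    """Scale every similarity entry by the penalty factor mu > 0."""
    if mu <= 0:
        raise ValidationError(f"penalty factor mu must be positive, got {mu}")
    out = SimilarityMatrix.__new__(SimilarityMatrix)
    out.ids = list(S.ids)
    out.values = mu * S.values
    return out


@dataclass
class HeteroGraph:
    """Block adjacency of the drug-disease heterogeneous network."""

    G: np.ndarray
    degree: np.ndarray
    M: int
    N: int
    drug_ids: list[str]
    disease_ids: list[str]

    @property
    def size(self) -> int:
        return self.M + self.N


def build_hetero_adjacency(
    Sr_hat: SimilarityMatrix, Sd_hat: SimilarityMatrix, Y: AssociationMatrix
) -> HeteroGraph:
    """Assemble G = [[Sr_hat, Y], [Y^T, Sd_hat]] with its degree vector.

    The similarity inputs are expected to be normalized-and-scaled
    already; Y may be raw binary or completed real-valued.
    """
    M, N = Y.shape
    if Sr_hat.n != M or Sd_hat.n != N:
        raise ValidationError(
            f"dimension mismatch: drug sim {Sr_hat.n}x{Sr_hat.n}, "
            f"disease sim {Sd_hat.n}x{Sd_hat.n}, associations {M}x{N}"
        )
    G = np.block([[Sr_hat.values, Y.values], [Y.values.T, Sd_hat.values]])
    if G.size and G.min() < 0:
        raise ValidationError("heterogeneous adjacency must be non-negative")
    return HeteroGraph(
        G=G,
        degree=G.sum(axis=1),
        M=M,
        N=N,
        drug_ids=list(Y.drug_ids),
        disease_ids=list(Y.disease_ids),
    )


def build_network(
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    Y: AssociationMatrix,
    mu: float,
) -> HeteroGraph:
    """Normalize both similarity matrices, apply the penalty, assemble G."""
    Sr = apply_penalty(normalize_similarity(drug_sim), mu)
    Sd = apply_penalty(normalize_similarity(disease_sim), mu)
    return build_hetero_adjacency(Sr, Sd, Y)
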