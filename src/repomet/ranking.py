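"""Scoring, top-k ranking and cold-start embedding of new entities.

After metric learning, every drug-disease pair is scored by the squared
Euclidean distance between the latent vectors; smaller distances mean
more likely indications.  Entities absent from training (a new drug or a
new disease) are placed in the metric space as a similarity-weighted
average of their h most-similar training entities' vectors, then clipped
onto the same l-ball.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import RankedPrediction, ValidationError
from .metric import MetricModel, clip_to_ball


def score_all(model: MetricModel) -> np.ndarray:
    """M x N matrix of squared distances ||alpha_i - beta_j||^2."""
    return cdist(model.drug_vectors, model.disease_vectors, metric="sqeuclidean")


def rank_candidates(
    distances: np.ndarray,
    partner_ids: list[str],
    exclude: set[int] | None = None,
    k: int | None = None,
) -> list[tuple[str, float, int]]:
    """Rank one anchor's partners by ascending distance.

    Excluded partner indices (known associations) are dropped; ties in
    distance break lexicographically by partner identifier; ranks are
    consecutive from 1.  At most ``k`` results are returned (all, if
    fewer candidates remain).
    """
    if k is not None and k < 1:
        raise ValidationError("k must be at least 1")
    exclude = exclude or set()
    order = sorted(
        (i for i in range(len(partner_ids)) if i not in exclude),
        key=lambda i: (distances[i], partner_ids[i]),
    )
    if k is not None:
        order = order[:k]
    return [(partner_ids[i], float(distances[i]), r + 1) for r, i in enumerate(order)]


def predictions_for_drug(
    model: MetricModel, drug_index: int, exclude: set[int] | None = None,
    k: int | None = None,
) -> list[RankedPrediction]:
    """Ranked disease predictions for one drug, as writable records."""
    distances = score_all(model)[drug_index]
    ranked = rank_candidates(distances, model.disease_ids, exclude, k)
    drug_id = model.drug_ids[drug_index]
    return [RankedPrediction(drug_id, pid, d, r) for pid, d, r in ranked]


def cold_start_embed(
    sim_row: np.ndarray,
    trained_vectors: np.ndarray,
    h: int,
    l: float = 1.0,
    weighted: bool = True,
) -> np.ndarray:
    """Embed an unseen entity from its similarities to training entities.

    The h most-similar training entities (similarity > 0) are averaged,
    weighted by similarity by default, and the result is clipped onto the
    l-ball so it satisfies the same norm invariant as trained vectors.
    """
    sim_row = np.asarray(sim_row, dtype=float)
    if h < 1:
        raise ValidationError("h must be at least 1")
    if sim_row.shape[0] != trained_vectors.shape[0]:
        raise ValidationError(
            f"{sim_row.shape[0]} similarities for {trained_vectors.shape[0]} entities"
        )
    if not (sim_row > 0).any():
        raise ValidationError("cold start impossible: all similarities are zero")
    # Top-h by similarity; stable tie-break on index for reproducibility.
    order = np.lexsort((np.arange(len(sim_row)), -sim_row))
    top = order[: min(h, len(order))]
    top = top[sim_row[top] > 0]
    weights = sim_row[top] if weighted else np.ones(len(top))
    vec = weights @ trained_vectors[top] / weights.sum()
    return clip_to_ball(vec[None, :], l)[0]
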