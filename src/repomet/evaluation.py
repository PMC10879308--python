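"""Evaluation protocols: repeated cross-validation, leave-one-entity-out
cold start, independent test sets, and the ranking metrics they report.

Known positives (not all zero pairs) are what cross-validation splits:
each repeat shuffles the positive pairs into near-equal folds, zeroes
one fold out of the training matrix, runs the full pipeline (completion,
metric learning, scoring) and ranks the held-out positives against all
pairs that were not training positives.  AUC and AUPR are computed
globally over that candidate set; precision@K and recall@K are computed
per drug and averaged, matching the top-k recommendation framing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .completion import complete_associations
from .datamodel import (
    AssociationMatrix,
    RunConfig,
    SimilarityMatrix,
    ValidationError,
    logger,
)
from .metric import MetricModel, train_metric
from .network import build_network
from .ranking import cold_start_embed, score_all


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative.

    Tie-aware (ties count 1/2), via the rank-sum identity
    AUC = (R_+ - P(P+1)/2) / (P * N) with midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Thresholds sweep the distinct score values in descending order; tied
    scores enter together.  Equals average precision:
    AP = sum_k (R_k - R_{k-1}) * P_k.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("AUPR needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order].astype(float)
    cum_tp = np.cumsum(l_sorted)
    npred = np.arange(1, labels.size + 1)
    # Keep only the last index of each tied block (threshold boundaries).
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = cum_tp[boundary]
    pred = npred[boundary]
    precision = tp / pred
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def precision_recall_at_k(
    ranked_hits: np.ndarray, n_test_positives: int, K: int
) -> tuple[float, float]:
    """precision@K and recall@K from a ranked 0/1 hit vector.

    ``ranked_hits[i]`` is 1 when the candidate at rank i+1 is a held-out
    positive.  p@K divides by K even when fewer candidates exist.
    """
    if K < 1:
        raise ValidationError("K must be at least 1")
    if n_test_positives < 1:
        raise ValidationError("recall@K undefined with zero test positives")
    hits = float(np.asarray(ranked_hits)[:K].sum())
    return hits / K, hits / n_test_positives


# ---------------------------------------------------------------------------
# Cross-validation splitting
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """One train/test split: the fold's positives are zeroed for training."""

    repeat: int
    fold: int
    train: AssociationMatrix
    test_pairs: np.ndarray  # (n_test, 2) drug/disease indices
    seed: int


def make_cv_splits(
    Y: AssociationMatrix, folds: int, repeats: int, seed: int
) -> list[FoldSplit]:
    """Partition the known positives into folds, repeated with reshuffling."""
    if folds < 2:
        raise ValidationError("folds must be at least 2")
    pairs = np.argwhere(Y.values > 0)
    if len(pairs) < folds:
        raise ValidationError(f"{len(pairs)} positives cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    splits: list[FoldSplit] = []
    for rep in range(repeats):
        perm = rng.permutation(len(pairs))
        groups = np.array_split(perm, folds)
        for fold, idx in enumerate(groups):
            test_pairs = pairs[idx]
            train_values = Y.values.copy()
            train_values[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
            train = AssociationMatrix(
                drug_ids=list(Y.drug_ids),
                disease_ids=list(Y.disease_ids),
                values=train_values,
            )
            splits.append(FoldSplit(rep, fold, train, test_pairs, seed))
    return splits


@dataclass
class MetricsReport:
    auc: float = np.nan
    aupr: float = np.nan
    p_at_k: dict[int, float] = field(default_factory=dict)
    r_at_k: dict[int, float] = field(default_factory=dict)
    per_fold: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pipeline helper
# ---------------------------------------------------------------------------

def fit_score_matrix(
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    Y: AssociationMatrix,
    config: RunConfig,
    seed: int,
    use_completion: bool = True,
) -> tuple[np.ndarray, MetricModel, AssociationMatrix]:
    """Run completion (optional) + metric learning; return the distance
    matrix, the metric model, and the (completed or raw) training matrix."""
    ss = np.random.SeedSequence(seed)
    rng_c, rng_m = (np.random.default_rng(s) for s in ss.spawn(2))
    if use_completion:
        graph = build_network(drug_sim, disease_sim, Y, config.completion.mu)
        _, Y_fit = complete_associations(graph, Y, config.completion, rng_c)
    else:
        Y_fit = AssociationMatrix(
            drug_ids=list(Y.drug_ids), disease_ids=list(Y.disease_ids),
            values=Y.values.copy(), completed=True,
        )
    model = train_metric(Y_fit, config.metric, rng_m)
    return score_all(model), model, Y_fit


def _ranking_metrics(
    distances: np.ndarray,
    train_positive: np.ndarray,
    test_positive: np.ndarray,
    k_list: list[int],
) -> dict:
    """Global AUC/AUPR and per-drug-averaged p@K, r@K on one split.

    Candidates are all pairs that are not training positives; held-out
    positives are the targets.  Scores are negated distances (higher =
    more associated).
    """
    candidate = ~train_positive
    scores = -distances[candidate]
    labels = test_positive[candidate]
    out = {
        "auc": auc_score(scores, labels),
        "aupr": aupr_score(scores, labels),
        "p_at_k": {},
        "r_at_k": {},
    }
    M = distances.shape[0]
    per_drug_p: dict[int, list[float]] = {K: [] for K in k_list}
    per_drug_r: dict[int, list[float]] = {K: [] for K in k_list}
    for i in range(M):
        n_test = int(test_positive[i].sum())
        if n_test == 0:
            continue
        cand = np.flatnonzero(candidate[i])
        order = cand[np.argsort(distances[i, cand], kind="stable")]
        hits = test_positive[i, order].astype(float)
        for K in k_list:
            p, r = precision_recall_at_k(hits, n_test, K)
            per_drug_p[K].append(p)
            per_drug_r[K].append(r)
    for K in k_list:
        out["p_at_k"][K] = float(np.mean(per_drug_p[K])) if per_drug_p[K] else np.nan
        out["r_at_k"][K] = float(np.mean(per_drug_r[K])) if per_drug_r[K] else np.nan
    return out


def _aggregate(per_fold: list[dict], k_list: list[int]) -> MetricsReport:
    report = MetricsReport(per_fold=per_fold)
    report.auc = float(np.mean([f["auc"] for f in per_fold]))
    report.aupr = float(np.mean([f["aupr"] for f in per_fold]))
    for K in k_list:
        report.p_at_k[K] = float(np.nanmean([f["p_at_k"][K] for f in per_fold]))
        report.r_at_k[K] = float(np.nanmean([f["r_at_k"][K] for f in per_fold]))
    return report


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def run_protocol(
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    assoc: AssociationMatrix,
    protocol: str,
    config: RunConfig,
    seed: int | None = None,
    independent: AssociationMatrix | None = None,
    use_completion: bool = True,
    max_entities: int | None = None,
) -> MetricsReport:
    """Run one of the evaluation protocols end to end.

    ``cv``           repeated k-fold cross-validation over known positives.
    ``new_drug``     leave one drug's associations out, cold-start re-embed
                     it from its h nearest neighbours, rank its diseases.
    ``new_disease``  the disease-side mirror of ``new_drug``.
    ``independent``  train on the full matrix, test on a second association
                     matrix over the same entities (training positives are
                     excluded from the candidate set).

    ``max_entities`` caps how many entities the leave-out protocols
    iterate over (in degree-descending order); ``seed`` defaults to the
    evaluation seed in ``config``.
    """
    if protocol not in ("cv", "new_drug", "new_disease", "independent"):
        raise ValueError(f"unknown protocol {protocol!r}")
    ev = config.evaluation
    seed = ev.seed if seed is None else seed
    k_list = ev.k_list

    if protocol == "cv":
        splits = make_cv_splits(assoc, ev.folds, ev.repeats, seed)
        per_fold = []
        for s in splits:
            distances, _, Y_fit = fit_score_matrix(
                drug_sim, disease_sim, s.train, config,
                seed + 7919 * s.repeat + s.fold, use_completion,
            )
            train_pos = s.train.values > 0
            test_pos = np.zeros_like(train_pos)
            test_pos[s.test_pairs[:, 0], s.test_pairs[:, 1]] = True
            m = _ranking_metrics(distances, train_pos, test_pos, k_list)
            m.update(repeat=s.repeat, fold=s.fold)
            logger.info("cv repeat %d fold %d auc %.4f aupr %.4f",
                        s.repeat, s.fold, m["auc"], m["aupr"])
            per_fold.append(m)
        return _aggregate(per_fold, k_list)

    if protocol == "independent":
        if independent is None:
            raise ValidationError("independent protocol requires a second association matrix")
        if (independent.drug_ids != assoc.drug_ids
                or independent.disease_ids != assoc.disease_ids):
            extra_drugs = sorted(set(independent.drug_ids) ^ set(assoc.drug_ids))
            extra_dis = sorted(set(independent.disease_ids) ^ set(assoc.disease_ids))
            raise ValidationError(
                "entity universe mismatch between training and independent sets; "
                f"offending drugs: {extra_drugs[:5]}, diseases: {extra_dis[:5]}"
            )
        distances, _, _ = fit_score_matrix(
            drug_sim, disease_sim, assoc, config, seed, use_completion
        )
        train_pos = assoc.values > 0
        test_pos = (independent.values > 0) & ~train_pos
        m = _ranking_metrics(distances, train_pos, test_pos, k_list)
        return _aggregate([m], k_list)

    # Leave-one-entity-out protocols.  The disease-side case runs the
    # drug-side logic on the transposed problem.
    if protocol == "new_disease":
        assoc_t = AssociationMatrix(
            drug_ids=list(assoc.disease_ids), disease_ids=list(assoc.drug_ids),
            values=assoc.values.T.copy(),
        )
        return run_protocol(
            disease_sim, drug_sim, assoc_t, "new_drug", config,
            seed=seed, use_completion=use_completion, max_entities=max_entities,
        )

    degrees = assoc.values.sum(axis=1)
    eligible = np.flatnonzero(degrees >= max(ev.min_positive_degree, 1))
    if eligible.size == 0:
        raise ValidationError("no drug meets min_positive_degree for the leave-out protocol")
    eligible = eligible[np.argsort(-degrees[eligible], kind="stable")]
    if max_entities is not None:
        eligible = eligible[:max_entities]
    per_fold = []
    for pos, drug in enumerate(eligible):
        train_values = assoc.values.copy()
        train_values[drug, :] = 0.0
        train = AssociationMatrix(
            drug_ids=list(assoc.drug_ids), disease_ids=list(assoc.disease_ids),
            values=train_values,
        )
        _, model, _ = fit_score_matrix(
            drug_sim, disease_sim, train, config, seed + pos, use_completion
        )
        sim_row = drug_sim.values[drug].copy()
        sim_row[drug] = 0.0  # the entity cannot neighbour itself
        vec = cold_start_embed(
            sim_row, model.drug_vectors, config.coldstart.h,
            config.metric.clip_bound_l, config.coldstart.weighted,
        )
        d = ((vec[None, :] - model.disease_vectors) ** 2).sum(axis=1)
        labels = assoc.values[drug] > 0
        scores = -d
        hits_order = np.argsort(d, kind="stable")
        hits = labels[hits_order].astype(float)
        m = {
            "auc": auc_score(scores, labels),
            "aupr": aupr_score(scores, labels),
            "p_at_k": {}, "r_at_k": {},
            "entity": assoc.drug_ids[drug],
        }
        for K in k_list:
            p, r = precision_recall_at_k(hits, int(labels.sum()), K)
            m["p_at_k"][K] = p
            m["r_at_k"][K] = r
        logger.info("new-entity leave-out %s auc %.4f", assoc.drug_ids[drug], m["auc"])
        per_fold.append(m)
    return _aggregate(per_fold, k_list)
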