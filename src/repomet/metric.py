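"""Symmetric collaborative metric learning with adaptive margins.

Drugs and diseases are embedded as points alpha_r, beta_d in one
n-dimensional metric space; association strength is the squared
Euclidean distance d(r, d) = ||alpha_r - beta_d||^2 (smaller = more
likely a treatment).  Training minimizes a symmetric triplet objective,

    L = L_R + L_D + gamma * L_AM

with a drug-centric hinge sum L_R = sum [d(r,d) - d(r,dbar) + m_r]_+
over triplets (r, d, dbar), the mirrored disease-centric sum L_D with
per-disease margins n_d, and an adaptive-margin reward
L_AM = -(mean_r m_r + mean_d n_d) that pushes margins wide.  Margins are
clamped to (0, l] and all latent vectors are projected back onto the
Euclidean ball of radius l after every update.  Optimization is AdaGrad
with per-parameter accumulated squared gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    AssociationMatrix,
    MetricConfig,
    NumericalError,
    ValidationError,
    logger,
    warn,
)

MARGIN_EPS = 1e-6


def squared_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Euclidean distance between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    return float(diff @ diff)


def clip_to_ball(vectors: np.ndarray, l: float) -> np.ndarray:
    """Project each row onto the Euclidean ball of radius l."""
    if l <= 0:
        raise ValidationError("clip bound l must be positive")
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    factor = np.where(norms > l, l / np.where(norms > 0, norms, 1.0), 1.0)
    out = v * factor
    return out.reshape(np.asarray(vectors).shape)


def clamp_margins(margins: np.ndarray, l: float) -> np.ndarray:
    """Project margins into [MARGIN_EPS, l] (the open interval (0, l])."""
    if l <= 0:
        raise ValidationError("clip bound l must be positive")
    return np.clip(np.asarray(margins, dtype=float), MARGIN_EPS, l)


@dataclass
class MetricModel:
    """Latent vectors and per-entity margins of the joint metric space."""

    drug_vectors: np.ndarray       # M x n   (alpha_r)
    disease_vectors: np.ndarray    # N x n   (beta_d)
    drug_margins: np.ndarray       # length M  (m_r)
    disease_margins: np.ndarray    # length N  (n_d)
    clip_bound: float = 1.0
    drug_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)

    def check_invariants(self, tol: float = 1e-9) -> None:
        l = self.clip_bound
        for name, vec in (("drug", self.drug_vectors), ("disease", self.disease_vectors)):
            norms = np.linalg.norm(vec, axis=1)
            if norms.size and norms.max() > l + tol:
                raise ValidationError(f"{name} vector norm {norms.max():.6g} exceeds l={l}")
        for name, m in (("drug", self.drug_margins), ("disease", self.disease_margins)):
            if m.size and (m.min() <= 0 or m.max() > l + tol):
                raise ValidationError(f"{name} margins outside (0, l]")


@dataclass
class TripletBatch:
    """Flat triplets (anchor, positive partner, negative partner).

    ``centric`` is ``"drug"`` when anchors are drugs ranking diseases,
    ``"disease"`` when anchors are diseases ranking drugs.  One row per
    sampled negative, so a positive pair with P negatives spans P rows.
    """

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    centric: str

    def __len__(self) -> int:
        return len(self.anchors)


def sample_triplets(
    Y_completed: np.ndarray,
    centric: str,
    P: int,
    rng: np.random.Generator,
    pairs: np.ndarray | None = None,
) -> TripletBatch:
    """Draw P negatives per positive pair, uniformly without replacement.

    Positives are entries of the completed matrix strictly greater than
    zero; negatives are zero entries of the anchor's row (drug-centric)
    or column (disease-centric).  ``pairs`` restricts sampling to a
    subset of positive (drug, disease) index pairs.  Anchors with no
    zero-entry partner contribute nothing (with a warning).
    """
    if centric not in ("drug", "disease"):
        raise ValueError(f"centric must be 'drug' or 'disease', got {centric!r}")
    Yc = np.asarray(Y_completed)
    if pairs is None:
        pairs = np.argwhere(Yc > 0)
    anchors_out, pos_out, neg_out = [], [], []
    axis = 1 if centric == "drug" else 0
    zero_partners: dict[int, np.ndarray] = {}
    skipped = 0
    for i, j in pairs:
        anchor, positive = (i, j) if centric == "drug" else (j, i)
        if anchor not in zero_partners:
            row = Yc[i, :] if centric == "drug" else Yc[:, j]
            zero_partners[anchor] = np.flatnonzero(row == 0)
        candidates = zero_partners[anchor]
        if candidates.size == 0:
            skipped += 1
            continue
        take = min(P, candidates.size)
        negs = rng.choice(candidates, size=take, replace=False)
        anchors_out.extend([anchor] * take)
        pos_out.extend([positive] * take)
        neg_out.extend(negs.tolist())
    if skipped:
        warn(f"{skipped} positive pair(s) skipped: anchor has no zero-entry partner")
    return TripletBatch(
        anchors=np.asarray(anchors_out, dtype=int),
        positives=np.asarray(pos_out, dtype=int),
        negatives=np.asarray(neg_out, dtype=int),
        centric=centric,
    )


def _pair_sq_dist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = A - B
    return np.einsum("ij,ij->i", d, d)


def drug_centric_loss(model: MetricModel, triplets: TripletBatch) -> float:
    """Hinge sum over drug-anchored triplets with the drug's margin m_r."""
    if triplets.centric != "drug":
        raise ValidationError("drug_centric_loss requires drug-centric triplets")
    if len(triplets) == 0:
        return 0.0
    a = model.drug_vectors[triplets.anchors]
    p = model.disease_vectors[triplets.positives]
    ng = model.disease_vectors[triplets.negatives]
    h = _pair_sq_dist(a, p) - _pair_sq_dist(a, ng) + model.drug_margins[triplets.anchors]
    return float(np.maximum(h, 0.0).sum())


def disease_centric_loss(model: MetricModel, triplets: TripletBatch) -> float:
    """Hinge sum over disease-anchored triplets with the disease's margin n_d."""
    if triplets.centric != "disease":
        raise ValidationError("disease_centric_loss requires disease-centric triplets")
    if len(triplets) == 0:
        return 0.0
    a = model.disease_vectors[triplets.anchors]
    p = model.drug_vectors[triplets.positives]
    ng = model.drug_vectors[triplets.negatives]
    h = _pair_sq_dist(a, p) - _pair_sq_dist(a, ng) + model.disease_margins[triplets.anchors]
    return float(np.maximum(h, 0.0).sum())


def adaptive_margin_loss(model: MetricModel) -> float:
    """Negative of (mean drug margin + mean disease margin); in [-2l, 0)."""
    return float(-(model.drug_margins.mean() + model.disease_margins.mean()))


def total_loss(
    model: MetricModel,
    drug_triplets: TripletBatch,
    disease_triplets: TripletBatch,
    gamma: float,
) -> float:
    """L = L_R + L_D + gamma * L_AM."""
    if gamma < 0:
        raise ValidationError("gamma must be non-negative")
    return (
        drug_centric_loss(model, drug_triplets)
        + disease_centric_loss(model, disease_triplets)
        + gamma * adaptive_margin_loss(model)
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _AdaGrad:
    def __init__(self, shapes: list[tuple], lr: float, eps: float = 1e-8):
        self.lr, self.eps = lr, eps
        self.accum = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, a in zip(params, grads, self.accum):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


def _accumulate_gradients(
    model: MetricModel,
    batch: TripletBatch,
    g_alpha: np.ndarray,
    g_beta: np.ndarray,
    g_m: np.ndarray,
    g_n: np.ndarray,
) -> None:
    """Add the hinge-loss gradients of one triplet batch in place.

    Only triplets with an active hinge contribute.  For a drug-centric
    triplet (r, d, dbar):  dL/dalpha_r = 2(beta_dbar - beta_d),
    dL/dbeta_d = -2(alpha_r - beta_d), dL/dbeta_dbar = 2(alpha_r -
    beta_dbar), dL/dm_r = 1; the disease-centric case mirrors it.
    """
    if len(batch) == 0:
        return
    if batch.centric == "drug":
        a = model.drug_vectors[batch.anchors]
        p = model.disease_vectors[batch.positives]
        ng = model.disease_vectors[batch.negatives]
        h = _pair_sq_dist(a, p) - _pair_sq_dist(a, ng) + model.drug_margins[batch.anchors]
        act = h > 0
        if not act.any():
            return
        ia, ip, ineg = batch.anchors[act], batch.positives[act], batch.negatives[act]
        av, pv, nv = a[act], p[act], ng[act]
        np.add.at(g_alpha, ia, 2.0 * (nv - pv))
        np.add.at(g_beta, ip, -2.0 * (av - pv))
        np.add.at(g_beta, ineg, 2.0 * (av - nv))
        np.add.at(g_m, ia, 1.0)
    else:
        a = model.disease_vectors[batch.anchors]
        p = model.drug_vectors[batch.positives]
        ng = model.drug_vectors[batch.negatives]
        h = _pair_sq_dist(a, p) - _pair_sq_dist(a, ng) + model.disease_margins[batch.anchors]
        act = h > 0
        if not act.any():
            return
        ia, ip, ineg = batch.anchors[act], batch.positives[act], batch.negatives[act]
        av, pv, nv = a[act], p[act], ng[act]
        np.add.at(g_beta, ia, 2.0 * (nv - pv))
        np.add.at(g_alpha, ip, -2.0 * (av - pv))
        np.add.at(g_alpha, ineg, 2.0 * (av - nv))
        np.add.at(g_n, ia, 1.0)


def initialize_metric_model(
    M: int,
    N: int,
    config: MetricConfig,
    rng: np.random.Generator,
    drug_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> MetricModel:
    """Latent vectors ~ Normal(0.1, spread); margins ~ Uniform(0, l]."""
    std = np.sqrt(0.03) if config.init_spread_is_variance else 0.03
    l = config.clip_bound_l
    model = MetricModel(
        drug_vectors=rng.normal(0.1, std, (M, config.n)),
        disease_vectors=rng.normal(0.1, std, (N, config.n)),
        drug_margins=l * (1.0 - rng.random(M)),
        disease_margins=l * (1.0 - rng.random(N)),
        clip_bound=l,
        drug_ids=list(drug_ids or []),
        disease_ids=list(disease_ids or []),
    )
    model.drug_vectors = clip_to_ball(model.drug_vectors, l)
    model.disease_vectors = clip_to_ball(model.disease_vectors, l)
    model.drug_margins = clamp_margins(model.drug_margins, l)
    model.disease_margins = clamp_margins(model.disease_margins, l)
    return model


def train_metric(
    Y_completed: AssociationMatrix,
    config: MetricConfig,
    rng: np.random.Generator,
    epoch_callback=None,
) -> MetricModel:
    """Train latent vectors and adaptive margins on a completed matrix.

    Per epoch, the positive entries (in shuffled order, batches of
    ``batch_size``) each receive P freshly sampled negatives for both the
    drug-centric and the disease-centric hinge; gradients are applied
    with AdaGrad, then vectors are clipped back onto the l-ball and
    margins clamped into (0, l].  A small validation split of positives
    monitors convergence: training stops early when the validation
    ranking AUC has not improved for ``patience`` consecutive epochs, and
    the best-validation parameters are restored.

    ``epoch_callback(epoch, model, train_loss, val_loss)`` is invoked
    after every epoch (used by invariant checks and progress reporting).
    """
    Yv = Y_completed.values
    M, N = Yv.shape
    pairs = np.argwhere(Yv > 0)
    if len(pairs) == 0:
        raise ValidationError("cannot train metric model without positive associations")
    P = config.P if config.P is not None else min(M, N)
    from scipy.stats import rankdata  # local import keeps module deps minimal

    model = initialize_metric_model(
        M, N, config, rng,
        drug_ids=Y_completed.drug_ids, disease_ids=Y_completed.disease_ids,
    )
    l = config.clip_bound_l

    # Hold out a small validation split of positives for the convergence check.
    n_val = int(round(config.val_fraction * len(pairs)))
    perm = rng.permutation(len(pairs))
    val_pairs = pairs[perm[:n_val]]
    train_pairs = pairs[perm[n_val:]]
    if len(train_pairs) == 0:
        raise ValidationError("validation split consumed every positive pair")

    params = [model.drug_vectors, model.disease_vectors,
              model.drug_margins, model.disease_margins]
    opt = _AdaGrad([p.shape for p in params], config.lr2)
    gamma = config.gamma

    # Convergence is monitored by how well the current embedding ranks the
    # held-out validation positives against the zero-entry pairs (AUC on
    # negated distances).  The raw validation triplet loss is unsuitable as
    # a stopping signal: growing margins inflate every hinge term even
    # while the ranking itself keeps improving.
    candidate_mask = Yv == 0
    val_label = np.zeros_like(candidate_mask)
    if len(val_pairs):
        val_label[val_pairs[:, 0], val_pairs[:, 1]] = True
    eval_mask = candidate_mask | val_label

    def validation_auc() -> float:
        if len(val_pairs) == 0:
            return np.nan
        diff = model.drug_vectors[:, None, :] - model.disease_vectors[None, :, :]
        dist = np.einsum("ijk,ijk->ij", diff, diff)
        scores = -dist[eval_mask]
        labels = val_label[eval_mask]
        n_pos = labels.sum()
        n_neg = labels.size - n_pos
        ranks = rankdata(scores)
        return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))

    best_val = -np.inf
    best_state = None
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            chunk = train_pairs[order[start:start + config.batch_size]]
            d_batch = sample_triplets(Yv, "drug", P, rng, pairs=chunk)
            s_batch = sample_triplets(Yv, "disease", P, rng, pairs=chunk)
            g_alpha = np.zeros_like(model.drug_vectors)
            g_beta = np.zeros_like(model.disease_vectors)
            g_m = np.zeros(M)
            g_n = np.zeros(N)
            _accumulate_gradients(model, d_batch, g_alpha, g_beta, g_m, g_n)
            _accumulate_gradients(model, s_batch, g_alpha, g_beta, g_m, g_n)
            # Adaptive-margin reward: dL_AM/dm_r = -1/M, dn_d likewise.
            g_m -= gamma / M
            g_n -= gamma / N
            batch_loss = total_loss(model, d_batch, s_batch, gamma)
            if not np.isfinite(batch_loss):
                raise NumericalError("metric-learning loss is not finite")
            epoch_loss += batch_loss
            opt.step(params, [g_alpha, g_beta, g_m, g_n])
            model.drug_vectors[:] = clip_to_ball(model.drug_vectors, l)
            model.disease_vectors[:] = clip_to_ball(model.disease_vectors, l)
            model.drug_margins[:] = clamp_margins(model.drug_margins, l)
            model.disease_margins[:] = clamp_margins(model.disease_margins, l)

        val = validation_auc()
        logger.info("metric epoch %d train_loss %.6f val_auc %.4f", epoch + 1, epoch_loss, val)
        if epoch_callback is not None:
            epoch_callback(epoch, model, epoch_loss, val)
        if np.isfinite(val):
            if val > best_val + 1e-6:
                best_val = val
                best_state = [p.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    logger.info("metric training converged at epoch %d", epoch + 1)
                    break
    if best_state is not None:
        model.drug_vectors[:], model.disease_vectors[:] = best_state[0], best_state[1]
        model.drug_margins[:], model.disease_margins[:] = best_state[2], best_state[3]
    return model
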