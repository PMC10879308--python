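"""Association-matrix completion with a GCN encoder and bilinear decoder.

The heterogeneous adjacency G is symmetrically renormalized by its own
degree, A = E^{-1/2} G E^{-1/2}, and a small graph-convolutional encoder
is trained on it:

    H^0     = G W_in                      (linear input projection)
    H^{l+1} = ReLU(A H^l W^{l+1})         for l = 0 .. L-1
    Z       = sum_l beta_l H^l            (layer attention, l = 0 .. L)
    Ytilde  = sigmoid(H_R W' H_D^T)       (bilinear decoder)

where H_R / H_D are the drug / disease rows of Z.  The loss is a
class-balanced binary cross-entropy in which each positive pair is
weighted by eta = |Y-| / |Y+|.  After training, predicted scores at or
above a threshold theta are kept as soft positives (known positives stay
pinned at 1), yielding the completed matrix used by metric learning.

Everything is plain numpy with explicit reverse-mode gradients and an
Adam update rule; the graphs involved are small enough that full-batch
dense training is the simplest correct choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    AssociationMatrix,
    CompletionConfig,
    NumericalError,
    ValidationError,
    logger,
    warn,
)
from .network import HeteroGraph

EPS_SIGMOID = 1e-7


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def sym_normalize_adjacency(G: np.ndarray) -> np.ndarray:
    """A = E^{-1/2} G E^{-1/2} with E = diag(row sums).

    Isolated nodes (zero degree) receive a self-loop of 1 before the
    degree is computed, otherwise the inverse square root is undefined.
    """
    G = np.asarray(G, dtype=float)
    d = G.sum(axis=1)
    isolated = d <= 0
    if isolated.any():
        warn(f"{int(isolated.sum())} isolated node(s) in G; adding unit self-loops")
        G = G.copy()
        idx = np.flatnonzero(isolated)
        G[idx, idx] = 1.0
        d = G.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return G * inv_sqrt[:, None] * inv_sqrt[None, :]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gcn_layer(G_norm: np.ndarray, H: np.ndarray, W: np.ndarray, activation=relu) -> np.ndarray:
    """One graph convolution: activation(A H W) on the normalized adjacency."""
    out = activation(G_norm @ H @ W)
    if not np.all(np.isfinite(out)):
        raise NumericalError("non-finite values in GCN layer output")
    return out


def layer_attention_combine(
    H_list: list[np.ndarray], attention: np.ndarray, M: int
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted sum of per-layer embeddings, split into drug and
    disease blocks (first M rows are drugs)."""
    shapes = {H.shape for H in H_list}
    if len(shapes) != 1:
        raise ValidationError(f"layer embeddings have mismatched shapes: {shapes}")
    if len(H_list) != len(attention):
        raise ValidationError("one attention weight per layer embedding is required")
    Z = sum(b * H for b, H in zip(attention, H_list))
    return Z[:M], Z[M:]


def init_attention(L: int) -> np.ndarray:
    """Attention weights beta_l = 1/(l+1) for layers l = 0..L."""
    return 1.0 / (np.arange(L + 1) + 1.0)


def bilinear_decode(H_R: np.ndarray, H_D: np.ndarray, W_dec: np.ndarray) -> np.ndarray:
    """Pairwise scores sigmoid(h_r^T W' h_d), strictly inside (0, 1)."""
    return sigmoid(H_R @ W_dec @ H_D.T)


def weighted_bce_loss(scores: np.ndarray, Y: np.ndarray) -> float:
    """Class-balanced binary cross-entropy over all drug-disease pairs.

    Positives are up-weighted by eta = (#negatives / #positives); the sum
    is divided by M*N.  Scores exactly 0 or 1 are clamped to avoid log(0).
    """
    Y = np.asarray(Y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = float((Y > 0).sum())
    if n_pos == 0:
        raise ValidationError("weighted BCE undefined without positive pairs")
    n_neg = float(Y.size - n_pos)
    eta = n_neg / n_pos
    if ((scores <= 0) | (scores >= 1)).any():
        warn("scores at 0 or 1 clamped inside the cross-entropy")
    p = np.clip(scores, EPS_SIGMOID, 1.0 - EPS_SIGMOID)
    pos = Y > 0
    total = eta * np.log(p[pos]).sum() + np.log(1.0 - p[~pos]).sum()
    return float(-total / Y.size)


def threshold_complete(
    scores: np.ndarray, Y: AssociationMatrix, theta: float
) -> AssociationMatrix:
    """Screen predicted scores at threshold theta into a completed matrix.

    Known positives are always kept (pinned to 1); a zero entry whose
    predicted score reaches theta keeps that score; everything else is 0.
    """
    if not 0 <= theta <= 1:
        raise ValidationError(f"theta must be in [0, 1], got {theta}")
    out = np.where(scores >= theta, scores, 0.0)
    out = np.where(Y.values > 0, 1.0, out)
    return AssociationMatrix(
        drug_ids=list(Y.drug_ids),
        disease_ids=list(Y.disease_ids),
        values=out,
        completed=True,
    )


# ---------------------------------------------------------------------------
# Model and training
# ---------------------------------------------------------------------------

@dataclass
class CompletionModel:
    """Trained parameters and final embeddings of the completion network."""

    input_weight: np.ndarray          # (M+N) x k
    layer_weights: list[np.ndarray]   # L matrices, k x k
    attention: np.ndarray             # length L+1
    decoder: np.ndarray               # k x k
    H_R: np.ndarray = field(default=None)  # M x k final drug embeddings
    H_D: np.ndarray = field(default=None)  # N x k final disease embeddings
    loss_history: list[float] = field(default_factory=list)


class _Adam:
    """Adam update rule on a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward(
    A: np.ndarray,
    X: np.ndarray,
    model: CompletionModel,
    M: int,
    *,
    node_mask: np.ndarray | None = None,
    act_masks: list[np.ndarray] | None = None,
):
    """Forward pass; returns intermediates needed for the backward pass.

    Node dropout masks rows of the input features; activation dropout
    masks each layer's embedding where it enters the attention combine.
    """
    Xd = X if node_mask is None else X * node_mask
    H = [Xd @ model.input_weight]
    U = [None]
    for W in model.layer_weights:
        U.append(A @ H[-1] @ W)
        H.append(relu(U[-1]))
    Hm = H if act_masks is None else [h * m for h, m in zip(H, act_masks)]
    H_R, H_D = layer_attention_combine(Hm, model.attention, M)
    logits = H_R @ model.decoder @ H_D.T
    scores = sigmoid(logits)
    return Xd, H, Hm, U, H_R, H_D, scores


def train_completion(
    graph: HeteroGraph,
    Y: AssociationMatrix,
    config: CompletionConfig,
    rng: np.random.Generator,
) -> tuple[CompletionModel, np.ndarray]:
    """Train the completion network by full-batch gradient descent (Adam).

    Returns the trained model (with final embeddings) and the M x N score
    matrix evaluated without dropout.  With ``epochs=0`` the initialized
    model is scored and returned unchanged.
    """
    M, N = graph.M, graph.N
    S = M + N
    k, L = config.k, config.L
    A = sym_normalize_adjacency(graph.G)
    X = graph.G
    Yv = Y.values
    if not (Yv > 0).any():
        raise ValidationError("cannot train completion without positive associations")

    # Weight variables drawn uniformly from [-0.01, 0.01].
    model = CompletionModel(
        input_weight=rng.uniform(-0.01, 0.01, (S, k)),
        layer_weights=[rng.uniform(-0.01, 0.01, (k, k)) for _ in range(L)],
        attention=init_attention(L),
        decoder=rng.uniform(-0.01, 0.01, (k, k)),
    )
    if not config.include_input_layer:
        model.attention = model.attention.copy()
        model.attention[0] = 0.0

    n_pos = float((Yv > 0).sum())
    eta = (Yv.size - n_pos) / n_pos
    C = np.where(Yv > 0, eta, 1.0)          # per-pair loss weights
    scale = 1.0 / Yv.size

    params = [model.input_weight, *model.layer_weights, model.decoder]
    opt = _Adam(params, config.lr1)
    opt_att = _Adam([model.attention], config.lr1) if config.train_attention else None

    def eval_scores() -> np.ndarray:
        return _forward(A, X, model, M)[-1]

    loss_history = [weighted_bce_loss(eval_scores(), Yv)]
    logger.info("completion epoch 0 loss %.6f", loss_history[0])

    # Dropout makes single-epoch score snapshots noisy; the returned score
    # matrix is averaged over a trailing window of evaluation-mode passes.
    from collections import deque

    window: deque[np.ndarray] = deque(maxlen=max(1, config.score_window))
    stall_epochs = 0
    for epoch in range(config.epochs):
        node_mask = None
        if config.node_dropout > 0:
            keep = rng.random((S, 1)) >= config.node_dropout
            node_mask = keep / (1.0 - config.node_dropout)
        act_masks = None
        if config.reg_dropout > 0:
            act_masks = [
                (rng.random((S, k)) >= config.reg_dropout) / (1.0 - config.reg_dropout)
                for _ in range(L + 1)
            ]

        Xd, H, Hm, U, H_R, H_D, P = _forward(
            A, X, model, M, node_mask=node_mask, act_masks=act_masks
        )

        # Backward pass.  dL/dlogit = C * (p - y) / (M N).
        Pc = np.clip(P, EPS_SIGMOID, 1.0 - EPS_SIGMOID)
        G_log = C * (Pc - (Yv > 0)) * scale
        dW_dec = H_R.T @ G_log @ H_D
        dH_R = G_log @ H_D @ model.decoder.T
        dH_D = G_log.T @ H_R @ model.decoder
        dZ = np.vstack([dH_R, dH_D])

        d_att = np.array([float((dZ * h).sum()) for h in Hm])
        # Gradients w.r.t. the raw H^l: the attention path goes through the
        # dropout mask; the next layer consumed the raw activation.
        gH = [b * dZ for b in model.attention]
        if act_masks is not None:
            gH = [g * m for g, m in zip(gH, act_masks)]

        dLW = [None] * L
        for l in range(L, 0, -1):
            dU = gH[l] * (U[l] > 0)
            AH = A @ H[l - 1]
            dLW[l - 1] = AH.T @ dU
            gH[l - 1] = gH[l - 1] + (A.T @ dU) @ model.layer_weights[l - 1].T
        dW_in = Xd.T @ gH[0]

        opt.step(params, [dW_in, *dLW, dW_dec])
        if opt_att is not None:
            if not config.include_input_layer:
                d_att[0] = 0.0
            opt_att.step([model.attention], [d_att])

        epoch_scores = eval_scores()
        window.append(epoch_scores)
        loss = weighted_bce_loss(epoch_scores, Yv)
        if not np.isfinite(loss):
            raise NumericalError(
                f"completion loss diverged at epoch {epoch + 1}; try a lower lr1"
            )
        loss_history.append(loss)
        logger.info("completion epoch %d loss %.6f", epoch + 1, loss)
        # The reconstruction loss is minimized until converged; epochs is a cap.
        rel = (loss_history[-2] - loss) / max(abs(loss_history[-2]), 1e-12)
        if rel < config.tol:
            stall_epochs += 1
            if stall_epochs >= 10:
                logger.info("completion converged at epoch %d", epoch + 1)
                break
        else:
            stall_epochs = 0

    _, _, _, _, model.H_R, model.H_D, scores = _forward(A, X, model, M)
    if window:
        scores = np.mean(window, axis=0)
    model.loss_history = loss_history
    return model, scores


def complete_associations(
    graph: HeteroGraph,
    Y: AssociationMatrix,
    config: CompletionConfig,
    rng: np.random.Generator,
) -> tuple[CompletionModel, AssociationMatrix]:
    """Train the completion network and screen its scores at theta."""
    model, scores = train_completion(graph, Y, config, rng)
    return model, threshold_complete(scores, Y, config.theta)
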