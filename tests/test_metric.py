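"""Triplet losses, adaptive margins, projections, and metric training."""

import numpy as np
import pytest

import repomet
from repomet import (
    AssociationMatrix,
    MetricConfig,
    MetricModel,
    TripletBatch,
    adaptive_margin_loss,
    clamp_margins,
    clip_to_ball,
    disease_centric_loss,
    drug_centric_loss,
    sample_triplets,
    squared_distance,
    total_loss,
    train_metric,
)
from repomet.metric import MARGIN_EPS


def make_model(alpha, beta, m=None, n=None, l=10.0):
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    return MetricModel(
        drug_vectors=alpha,
        disease_vectors=beta,
        drug_margins=np.asarray(m if m is not None else np.full(len(alpha), 0.5)),
        disease_margins=np.asarray(n if n is not None else np.full(len(beta), 0.5)),
        clip_bound=l,
    )


class TestSquaredDistance:
    def test_three_four_five(self):
        assert squared_distance(np.zeros(2), np.array([3.0, 4.0])) == 25.0

    def test_identity_and_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert squared_distance(a, a) == 0.0
        assert squared_distance(a, b) == pytest.approx(squared_distance(b, a), abs=1e-15)

    def test_dim_mismatch(self):
        with pytest.raises(repomet.ValidationError):
            squared_distance(np.zeros(2), np.zeros(3))


class TestHingeLosses:
    def test_satisfied_constraint_contributes_zero(self):
        # d(r,d)=0.3, d(r,dbar)=1.0, m_r=0.5 -> hinge 0.3-1.0+0.5 < 0
        model = make_model([[0.0]], [[np.sqrt(0.3)], [1.0]], m=[0.5])
        t = TripletBatch(np.array([0]), np.array([0]), np.array([1]), "drug")
        assert drug_centric_loss(model, t) == 0.0

    def test_violated_constraint_value(self):
        # d(r,d)=0.9, d(r,dbar)=0.4, m_r=0.2 -> hinge 0.7
        model = make_model([[0.0]], [[np.sqrt(0.9)], [np.sqrt(0.4)]], m=[0.2])
        t = TripletBatch(np.array([0]), np.array([0]), np.array([1]), "drug")
        assert drug_centric_loss(model, t) == pytest.approx(0.7, abs=1e-12)

    def test_batch_of_satisfied_triplets_is_exactly_zero(self, rng):
        alpha = rng.normal(size=(3, 4))
        beta = np.vstack([alpha + 0.01, alpha + 10.0])  # positives near, negatives far
        model = make_model(alpha, beta, m=np.full(3, 0.5), n=np.full(6, 0.5))
        anchors = np.array([0, 1, 2])
        t = TripletBatch(anchors, anchors, anchors + 3, "drug")
        assert drug_centric_loss(model, t) == 0.0
        s = TripletBatch(anchors, anchors, np.array([0, 1, 2]), "disease")
        # disease anchors 0..2 are near their positive drugs; negative drugs
        # are the same drugs, so build explicit far negatives instead
        model2 = make_model(
            np.vstack([alpha, alpha + 10.0]), beta[:3],
            m=np.full(6, 0.5), n=np.full(3, 0.5),
        )
        s = TripletBatch(anchors, anchors, anchors + 3, "disease")
        assert disease_centric_loss(model2, s) == 0.0

    def test_role_swap_symmetry(self, rng):
        """Transposing the roles (drugs <-> diseases) maps the disease-centric
        loss onto the drug-centric loss exactly."""
        alpha, beta = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        m, n = rng.uniform(0.1, 1.0, 4), rng.uniform(0.1, 1.0, 5)
        model = make_model(alpha, beta, m=m, n=n)
        anchors = np.array([0, 2, 4, 1])
        pos = np.array([1, 3, 0, 2])
        neg = np.array([2, 0, 3, 3])
        t_dis = TripletBatch(anchors, pos, neg, "disease")
        swapped = make_model(beta, alpha, m=n, n=m)
        t_drug = TripletBatch(anchors, pos, neg, "drug")
        assert disease_centric_loss(model, t_dis) == pytest.approx(
            drug_centric_loss(swapped, t_drug), abs=1e-12
        )


class TestAdaptiveMargin:
    def test_arithmetic(self):
        model = make_model(
            np.zeros((2, 1)), np.zeros((2, 1)), m=[0.5, 1.0], n=[1.0, 1.0]
        )
        assert adaptive_margin_loss(model) == pytest.approx(-1.75)

    def test_extremes(self):
        l = 2.0
        model = make_model(np.zeros((3, 1)), np.zeros((4, 1)),
                           m=np.full(3, l), n=np.full(4, l), l=l)
        assert adaptive_margin_loss(model) == pytest.approx(-2 * l)

    def test_total_loss_combination(self):
        model = make_model(np.zeros((2, 1)), np.zeros((2, 1)), m=[1.0, 1.0], n=[1.0, 1.0])
        empty_d = TripletBatch(np.array([]), np.array([]), np.array([]), "drug")
        empty_s = TripletBatch(np.array([]), np.array([]), np.array([]), "disease")
        assert total_loss(model, empty_d, empty_s, 0.1) == pytest.approx(-0.2)
        assert total_loss(model, empty_d, empty_s, 0.0) == 0.0


class TestProjections:
    def test_three_four_projection(self):
        out = clip_to_ball(np.array([[3.0, 4.0]]), 1.0)
        np.testing.assert_allclose(out, [[0.6, 0.8]])

    def test_interior_point_unchanged(self):
        np.testing.assert_array_equal(clip_to_ball(np.array([[0.1, 0.0]]), 1.0), [[0.1, 0.0]])

    def test_row_norm_invariant_and_idempotence(self, rng):
        V = rng.normal(size=(20, 6)) * 3
        out = clip_to_ball(V, 1.0)
        assert np.linalg.norm(out, axis=1).max() <= 1 + 1e-12
        np.testing.assert_allclose(clip_to_ball(out, 1.0), out, atol=1e-15)

    @pytest.mark.parametrize("value, expected", [(1.7, 1.0), (-0.2, MARGIN_EPS), (0.5, 0.5)])
    def test_margin_clamp(self, value, expected):
        assert clamp_margins(np.array([value]), 1.0)[0] == expected

    def test_margin_clamp_idempotent(self, rng):
        m = rng.normal(size=30)
        once = clamp_margins(m, 1.0)
        np.testing.assert_array_equal(clamp_margins(once, 1.0), once)


class TestSampleTriplets:
    def test_drug_with_all_positives_contributes_nothing(self, rng):
        Y = np.ones((2, 3))
        Y[1, 0] = 0.0
        with pytest.warns(UserWarning, match="skipped"):
            batch = sample_triplets(Y, "drug", 2, rng)
        assert np.all(batch.anchors == 1)

    def test_negatives_come_from_zero_entries(self, rng):
        Y = (rng.random((6, 7)) < 0.3).astype(float)
        Y[0, 0] = 1.0
        batch = sample_triplets(Y, "drug", 3, rng)
        assert np.all(Y[batch.anchors, batch.positives] > 0)
        assert np.all(Y[batch.anchors, batch.negatives] == 0)
        dis = sample_triplets(Y, "disease", 3, rng)
        assert np.all(Y[dis.positives, dis.anchors] > 0)
        assert np.all(Y[dis.negatives, dis.anchors] == 0)

    def test_fixed_seed_reproducible(self):
        Y = (np.random.default_rng(1).random((5, 9)) < 0.4).astype(float)
        b1 = sample_triplets(Y, "drug", 4, np.random.default_rng(7))
        b2 = sample_triplets(Y, "drug", 4, np.random.default_rng(7))
        np.testing.assert_array_equal(b1.negatives, b2.negatives)

    def test_default_negatives_per_anchor_is_min_dimension(self):
        cfg = MetricConfig()
        assert cfg.P is None  # resolved to min(M, N) inside training
        Y = np.zeros((7, 5))
        Y[0, 0] = 1.0
        batch = sample_triplets(Y, "drug", min(7, 5), np.random.default_rng(0))
        assert len(batch) == 4  # only 4 zero-entry diseases remain for drug 0


class TestTrainMetric:
    def _assoc(self, world):
        return AssociationMatrix(
            drug_ids=world.associations.drug_ids,
            disease_ids=world.associations.disease_ids,
            values=world.associations.values.copy(),
            completed=True,
        )

    def test_loss_decreases_and_invariants_hold_each_epoch(self, small_world):
        cfg = MetricConfig(n=16, epochs=12, patience=100)
        losses = []

        def cb(epoch, model, train_loss, val_loss):
            model.check_invariants()
            losses.append(train_loss)

        train_metric(self._assoc(small_world), cfg, np.random.default_rng(2), epoch_callback=cb)
        assert losses[-1] < losses[0]

    def test_identical_seeds_identical_embeddings(self, small_world):
        cfg = MetricConfig(n=8, epochs=6, patience=100)
        models = [
            train_metric(self._assoc(small_world), cfg, np.random.default_rng(11))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(models[0].drug_vectors, models[1].drug_vectors)
        np.testing.assert_array_equal(models[0].disease_margins, models[1].disease_margins)

    def test_no_positives_is_error(self):
        empty = AssociationMatrix(["r"], ["d"], np.zeros((1, 1)), completed=True)
        with pytest.raises(repomet.ValidationError):
            train_metric(empty, MetricConfig(n=4, epochs=1), np.random.default_rng(0))

    def test_parameter_recovery_ranks_heldout_positives(self):
        """Latent positions planted in 4 dimensions are recoverable: training
        on 70% of the threshold-defined positives ranks the held-out
        positives above matched random negatives with AUC >= 0.8."""
        rng = np.random.default_rng(21)
        M, N, dim = 40, 50, 4
        alpha = rng.normal(size=(M, dim)) * 0.5
        beta = rng.normal(size=(N, dim)) * 0.5
        d2 = ((alpha[:, None, :] - beta[None, :, :]) ** 2).sum(-1)
        tau = np.quantile(d2, 0.15)
        Y = (d2 < tau).astype(float)
        pairs = np.argwhere(Y > 0)
        perm = rng.permutation(len(pairs))
        held = pairs[perm[: int(0.3 * len(pairs))]]
        train_vals = Y.copy()
        train_vals[held[:, 0], held[:, 1]] = 0.0
        assoc = AssociationMatrix(
            [f"r{i}" for i in range(M)], [f"d{j}" for j in range(N)],
            train_vals, completed=True,
        )
        # Matched model capacity (n = generating dimension) recovers the
        # planted geometry; a heavily overparameterized model would instead
        # memorize the training positives.
        cfg = MetricConfig(n=dim, epochs=150, patience=1000)
        model = train_metric(assoc, cfg, np.random.default_rng(3))
        from repomet.evaluation import auc_score
        from repomet.ranking import score_all

        dist = score_all(model)
        zeros = np.argwhere((Y == 0))
        neg = zeros[rng.choice(len(zeros), size=len(held), replace=False)]
        scores = np.r_[-dist[held[:, 0], held[:, 1]], -dist[neg[:, 0], neg[:, 1]]]
        labels = np.r_[np.ones(len(held)), np.zeros(len(neg))]
        assert auc_score(scores, labels) >= 0.8
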