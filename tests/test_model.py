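import math

import numpy as np
import pytest

from probkg.graph import ProbAdjacency, RelationSpec, sigmoid
from probkg import model
from probkg.model import (
    ModelParams,
    TrainConfig,
    build_aggregation_adjacency,
    binarized_adjacency,
    aggregate,
    control_objective,
    embed,
    init_params,
    loss_weight_matrix,
    objective,
    predict_tda,
    randomized_edge_probability,
    randomized_weight_matrix,
    reconstruct,
    sample_randomized,
    save_params,
    load_params,
    train,
)


def ref_sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestAggregationAdjacency:
    def test_binarize_then_row_normalize(self):
        spec = RelationSpec("r", "drug", "protein")
        adj = ProbAdjacency(
            spec, np.array([[0.0, 0.7], [0.0, 0.0]]), np.array([[False, True], [False, False]])
        )
        np.testing.assert_allclose(
            build_aggregation_adjacency(adj), [[0.0, 1.0], [0.0, 0.0]]
        )

    def test_similarity_keeps_values_then_normalizes(self):
        spec = RelationSpec("s", "drug", "drug", in_similarity_set=True, symmetric=True)
        probs = np.array([[0.0, 0.5], [0.5, 0.0]])
        adj = ProbAdjacency(spec, probs, np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(
            build_aggregation_adjacency(adj), [[0.0, 1.0], [1.0, 0.0]]
        )

    def test_all_zero_stays_zero(self):
        spec = RelationSpec("r", "drug", "protein")
        adj = ProbAdjacency(spec, np.zeros((3, 2)), np.zeros((3, 2), dtype=bool))
        np.testing.assert_array_equal(build_aggregation_adjacency(adj), np.zeros((3, 2)))

    def test_unit_row_norms(self, toy_kg):
        for s in toy_kg.specs:
            ahat = build_aggregation_adjacency(toy_kg.adjacency[s.name])
            norms = np.linalg.norm(ahat, axis=1)
            nonzero = norms > 0
            np.testing.assert_allclose(norms[nonzero], 1.0, atol=1e-12)


class TestAggregate:
    def test_identity_adjacency_identity_weight(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, seed=0)
        params = init_params(toy_kg, cfg)
        # isolate one relation with identity pieces
        spec = toy_kg.spec_by_name("dpi")
        for s in toy_kg.specs:
            params.W[s.name][:] = 0.0
        params.W["dpi"] = np.eye(4)
        ahat = {s.name: np.zeros_like(toy_kg.adjacency[s.name].probs) for s in toy_kg.specs}
        ahat["dpi"] = np.eye(3, 4)
        Y = aggregate(toy_kg, params, ahat=ahat)
        np.testing.assert_allclose(Y["drug"], params.X["protein"][:3])

    def test_zero_weights_zero_output(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, seed=0)
        params = init_params(toy_kg, cfg)
        for s in toy_kg.specs:
            params.W[s.name][:] = 0.0
        Y = aggregate(toy_kg, params)
        for t in toy_kg.catalog.types:
            np.testing.assert_array_equal(Y[t], 0.0)

    def test_matches_explicit_loop(self, toy_kg):
        cfg = TrainConfig(d0=5, d1=3, k=3, seed=2)
        params = init_params(toy_kg, cfg)
        Y = aggregate(toy_kg, params)
        # oracle: explicit per-relation accumulation
        expect = {
            t: np.zeros((toy_kg.catalog.size(t), 5)) for t in toy_kg.catalog.types
        }
        for s in toy_kg.specs:
            ahat = build_aggregation_adjacency(toy_kg.adjacency[s.name])
            if s.source_type == s.target_type:
                expect[s.source_type] += ahat @ params.X[s.source_type] @ params.W[s.name]
            else:
                expect[s.source_type] += ahat @ params.X[s.target_type] @ params.W[s.name]
                expect[s.target_type] += ahat.T @ params.X[s.source_type] @ params.W[s.name]
        for t in expect:
            np.testing.assert_allclose(Y[t], expect[t], atol=1e-12)


class TestEmbed:
    def test_zero_projection_zero_embedding(self):
        Y, X = np.ones((3, 2)), np.ones((3, 2))
        Z = embed(Y, X, np.zeros((4, 3)))
        np.testing.assert_array_equal(Z, 0.0)

    def test_rows_unit_norm(self):
        rng = np.random.default_rng(0)
        Z = embed(rng.normal(size=(6, 4)), rng.normal(size=(6, 4)), rng.normal(size=(8, 5)))
        norms = np.linalg.norm(Z, axis=1)
        for n in norms:
            assert n == pytest.approx(1.0, abs=1e-6) or n == 0.0

    def test_step_by_step_recomputation(self):
        rng = np.random.default_rng(4)
        Y, X = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        W1 = rng.normal(size=(4, 3))
        Z = embed(Y, X, W1)
        for i in range(4):
            row = np.concatenate([Y[i], X[i]]) @ W1
            row = np.maximum(row, 0.0)
            norm = np.linalg.norm(row)
            expect = row / norm if norm > 0 else row
            np.testing.assert_allclose(Z[i], expect, atol=1e-12)


class TestReconstruct:
    def test_identity_chain(self):
        eye = np.eye(3)
        np.testing.assert_allclose(reconstruct(eye, eye, eye, eye), eye)

    def test_tied_projections_symmetric_output(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(5, 4))
        G = rng.normal(size=(4, 3))
        S = reconstruct(Z, G, G, Z)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_quadruple_loop_oracle(self):
        rng = np.random.default_rng(2)
        Za, Zb = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        G, H = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        S = reconstruct(Za, G, H, Zb)
        for i in range(3):
            for j in range(4):
                acc = 0.0
                for u in range(2):
                    for v in range(2):
                        for w in range(3):
                            acc += Za[i, u] * G[u, w] * H[v, w] * Zb[j, v]
                assert S[i, j] == pytest.approx(acc, abs=1e-10)


class TestLossWeightMatrix:
    def test_non_literature_all_ones(self):
        spec = RelationSpec("r", "drug", "protein")
        M = loss_weight_matrix(None, np.random.rand(3, 4), spec, 0.0, 0.0)
        np.testing.assert_array_equal(M, 1.0)

    def test_unobserved_entry_is_one(self):
        spec = RelationSpec("r", "drug", "protein", in_literature_set=True)
        C = np.array([[3.0]])
        P = np.array([[0.0]])  # unobserved
        assert loss_weight_matrix(C, P, spec, 0.0, 0.0)[0, 0] == 1.0

    def test_algebraic_identity_with_eq1_probability(self):
        """For observed entries with P = sigmoid(C + alpha), the weight
        simplifies to sigmoid(C + beta) exactly."""
        rng = np.random.default_rng(12)
        spec = RelationSpec("r", "drug", "protein", in_literature_set=True)
        for _ in range(1000):
            C = np.array([[float(rng.integers(0, 200))]])
            alpha = float(rng.uniform(-4, 4))
            beta = float(rng.uniform(-4, 4))
            P = sigmoid(C + alpha)
            M = loss_weight_matrix(C, P, spec, alpha, beta)
            assert M[0, 0] == pytest.approx(ref_sigmoid(C[0, 0] + beta), abs=1e-12)
            assert ref_sigmoid(beta) - 1e-15 <= M[0, 0] < 1.0


class TestRandomized:
    def test_non_literature_observed_is_one(self):
        spec = RelationSpec("r", "drug", "side_effect")
        assert randomized_edge_probability(spec, 0.0, np.random.default_rng(0)) == 1.0

    def test_draw_range(self):
        spec = RelationSpec("r", "drug", "protein", in_literature_set=True)
        rng = np.random.default_rng(1)
        draws = [randomized_edge_probability(spec, 0.0, rng) for _ in range(10_000)]
        assert all(0.5 <= d < 1.0 for d in draws)

    def test_seeded_reproducible(self, toy_kg):
        a = sample_randomized(toy_kg, np.random.default_rng(3))
        b = sample_randomized(toy_kg, np.random.default_rng(3))
        for name in a.p:
            np.testing.assert_array_equal(a.p[name], b.p[name])
            np.testing.assert_array_equal(a.m[name], b.m[name])

    def test_randomized_grids_ranges(self, toy_kg):
        rand = sample_randomized(toy_kg, np.random.default_rng(5))
        for s in toy_kg.specs:
            adj = toy_kg.adjacency[s.name]
            if s.in_literature_set:
                obs = adj.observed
                assert np.all(rand.p[s.name][obs] >= sigmoid(toy_kg.alpha))
                assert np.all(rand.p[s.name][obs] < 1.0)
                assert np.all(rand.p[s.name][~obs] == 0.0)
                assert np.all(rand.m[s.name][obs] >= sigmoid(toy_kg.beta))
                assert np.all(rand.m[s.name][obs] < 1.0)
                assert np.all(rand.m[s.name][~obs] == 1.0)
            else:
                np.testing.assert_array_equal(rand.p[s.name], adj.probs)
                np.testing.assert_array_equal(rand.m[s.name], 1.0)

    def test_weight_matrix_unobserved_one(self):
        spec = RelationSpec("r", "drug", "protein", in_literature_set=True)
        p_prime = np.array([[0.0, 0.7], [0.6, 0.0]])
        M = randomized_weight_matrix(p_prime, spec, 0.0, 0.0, np.random.default_rng(0))
        assert M[0, 0] == 1.0 and M[1, 1] == 1.0
        assert 0.5 <= M[0, 1] < 1.0 and 0.5 <= M[1, 0] < 1.0


def elementwise_loss_oracle(params, kg, cfg, targets, weights):
    """Oracle: explicit double-sum over entries plus the l2 terms."""
    from probkg.model import embeddings

    Z = embeddings(params, kg, cfg.norm_mode)
    total = 0.0
    for s in kg.specs:
        S = Z[s.source_type] @ params.G[s.name] @ params.H[s.name].T @ Z[s.target_type].T
        T, Wt = targets[s.name], weights[s.name]
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                total += ((S[i, j] - T[i, j]) * Wt[i, j]) ** 2
    for _, arr in params.named():
        total += cfg.l2 * np.sum(arr * arr)
    return total


class TestObjective:
    def test_perfect_reconstruction_zero_loss(self, catalog):
        # one relation whose target we can hit exactly: all-zero target, zero G
        spec = RelationSpec("r", "protein", "disease", in_literature_set=True)
        from probkg.graph import CooccurrenceMatrix, ProbKG

        shape = (4, 2)
        kg = ProbKG(
            catalog=catalog,
            specs=[spec],
            adjacency={"r": ProbAdjacency(spec, np.zeros(shape), np.zeros(shape, dtype=bool))},
            cooccurrence={"r": CooccurrenceMatrix(spec, np.zeros(shape, dtype=int))},
        )
        cfg = TrainConfig(d0=3, d1=2, k=2, l2=0.0, seed=0)
        params = init_params(kg, cfg)
        params.G["r"][:] = 0.0
        assert objective(params, kg, cfg) == 0.0

    def test_matches_elementwise_oracle_all_variants(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, l2=1e-3, seed=8)
        params = init_params(toy_kg, cfg)
        rand = sample_randomized(toy_kg, np.random.default_rng(2))
        for variant in ("full", "og", "rp", "rw", "rpw"):
            prob = model._Problem(toy_kg, cfg, variant, rand)
            got = objective(params, toy_kg, cfg, variant=variant, rand=rand)
            expect = elementwise_loss_oracle(params, toy_kg, cfg, prob.targets, prob.weights)
            assert got == pytest.approx(expect, rel=1e-10)

    def test_og_reconstructs_binarized_grid(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, l2=0.0, seed=8)
        params = init_params(toy_kg, cfg)
        prob = model._Problem(toy_kg, cfg, "og")
        for s in toy_kg.specs:
            np.testing.assert_array_equal(
                prob.targets[s.name], binarized_adjacency(toy_kg.adjacency[s.name])
            )
            np.testing.assert_array_equal(prob.weights[s.name], 1.0)

    def test_rp_swaps_in_cached_grids(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, seed=8)
        rand = sample_randomized(toy_kg, np.random.default_rng(2))
        prob_rp = model._Problem(toy_kg, cfg, "rp", rand)
        prob_full = model._Problem(toy_kg, cfg, "full")
        for s in toy_kg.specs:
            np.testing.assert_array_equal(prob_rp.targets[s.name], rand.p[s.name])
            np.testing.assert_array_equal(prob_rp.weights[s.name], prob_full.weights[s.name])

    def test_relation_order_invariance(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, l2=1e-3, seed=8)
        params = init_params(toy_kg, cfg)
        base = objective(params, toy_kg, cfg)
        import dataclasses

        shuffled = dataclasses.replace(toy_kg, specs=list(reversed(toy_kg.specs)))
        assert objective(params, shuffled, cfg) == pytest.approx(base, rel=1e-12)

    def test_unknown_variant_rejected(self, toy_kg):
        cfg = TrainConfig(d0=4, d1=3, k=3, seed=8)
        params = init_params(toy_kg, cfg)
        with pytest.raises(ValueError):
            objective(params, toy_kg, cfg, variant="nope")
        with pytest.raises(ValueError):
            control_objective("full", params, toy_kg, cfg)

    def test_masked_entries_carry_zero_weight(self, toy_kg):
        from probkg.graph import mask_entries

        cfg = TrainConfig(d0=4, d1=3, k=3, l2=0.0, seed=8)
        pairs = [tuple(map(int, p)) for p in np.argwhere(toy_kg.adjacency["tda"].observed)]
        masked = mask_entries(toy_kg, pairs)
        prob = model._Problem(masked, cfg, "full")
        assert not prob.weights["tda"][masked.loss_mask["tda"]].any()

    def test_closed_form_when_counts_zero_alpha_eq_beta(self, catalog):
        """With C == 0 and alpha == beta, observed literature weights equal
        sigmoid(beta) which equals the probability floor sigmoid(alpha)."""
        from probkg.graph import CooccurrenceMatrix, ProbKG, assign_edge_probabilities

        spec = RelationSpec("r", "protein", "disease", in_literature_set=True)
        shape = (4, 2)
        observed = np.ones(shape, dtype=bool)
        kg = ProbKG(
            catalog=catalog,
            specs=[spec],
            adjacency={"r": ProbAdjacency(spec, observed.astype(float), observed)},
            alpha=0.7,
            beta=0.7,
        )
        kg = assign_edge_probabilities(kg, {"r": CooccurrenceMatrix(spec, np.zeros(shape, dtype=int))})
        M = loss_weight_matrix(
            kg.cooccurrence["r"].counts, kg.adjacency["r"].probs, spec, 0.7, 0.7
        )
        np.testing.assert_allclose(M, ref_sigmoid(0.7), atol=1e-12)
        np.testing.assert_allclose(kg.adjacency["r"].probs, ref_sigmoid(0.7), atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["full", "og", "rp", "rw", "rpw"])
    def test_analytic_matches_central_difference(self, tiny_synthetic, variant):
        kg, _, _ = tiny_synthetic
        cfg = TrainConfig(d0=4, d1=3, k=3, l2=1e-3, seed=2)
        rand = sample_randomized(kg, np.random.default_rng(9))
        prob = model._Problem(kg, cfg, variant, rand)
        params = init_params(kg, cfg)
        _, grads = prob.loss_and_grads(params)
        rng = np.random.default_rng(0)
        for name, arr in params.named():
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in arr.shape)
                eps = 1e-6
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = prob.loss(params)
                arr[idx] = orig - eps
                lm = prob.loss(params)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestTraining:
    def test_zero_epochs_identity(self, tiny_synthetic):
        kg, _, _ = tiny_synthetic
        cfg = TrainConfig(d0=6, d1=4, k=4, epochs=0, seed=3)
        result = train(kg, cfg)
        init = init_params(kg, cfg)
        for (n1, a), (n2, b) in zip(result.params.named(), init.named()):
            assert n1 == n2
            np.testing.assert_array_equal(a, b)
        assert result.loss_history == []

    def test_same_seed_bit_identical(self, tiny_synthetic, tiny_config):
        kg, _, _ = tiny_synthetic
        r1 = train(kg, tiny_config)
        r2 = train(kg, tiny_config)
        assert r1.loss_history == r2.loss_history
        for (n1, a), (n2, b) in zip(r1.params.named(), r2.params.named()):
            np.testing.assert_array_equal(a, b)

    def test_loss_decreases(self, tiny_synthetic, tiny_config):
        kg, _, _ = tiny_synthetic
        result = train(kg, tiny_config)
        assert result.loss_history[-1] < result.loss_history[0]

    def test_validation_early_stopping_returns_best(self, tiny_synthetic):
        kg, truth, holdout = tiny_synthetic
        n_cols = truth.shape[1]
        val_entries = np.array([i * n_cols + j for i, j in holdout])
        val_labels = np.ones(len(holdout), dtype=int)
        # add some negatives
        negs = np.flatnonzero(~truth.ravel())[:20]
        val_entries = np.concatenate([val_entries, negs])
        val_labels = np.concatenate([val_labels, np.zeros(20, dtype=int)])
        cfg = TrainConfig(d0=6, d1=4, k=4, epochs=40, eval_every=5, patience=100, seed=1)
        result = train(kg, cfg, val_entries=val_entries, val_labels=val_labels)
        assert result.val_history
        best = max(result.val_history, key=lambda t: t[1])
        assert result.best_epoch == best[0]

    def test_symmetric_reconstruction_after_training(self, tiny_synthetic, tiny_config):
        kg, _, _ = tiny_synthetic
        result = train(kg, tiny_config)
        from probkg.model import embeddings

        Z = embeddings(result.params, kg)
        for s in kg.specs:
            if s.symmetric:
                S = reconstruct(
                    Z[s.source_type], result.params.G[s.name],
                    result.params.H[s.name], Z[s.target_type],
                )
                np.testing.assert_allclose(S, S.T, atol=1e-8)


class TestPredict:
    def test_shape_and_equality_with_reconstruct(self, tiny_synthetic, tiny_config):
        kg, _, _ = tiny_synthetic
        result = train(kg, tiny_config)
        pred = predict_tda(result.params, kg)
        n_p = kg.catalog.size("protein")
        n_d = kg.catalog.size("disease")
        assert pred.shape == (n_p, n_d)
        from probkg.model import embeddings

        Z = embeddings(result.params, kg)
        spec = kg.spec_by_name(kg.tda_name)
        np.testing.assert_array_equal(
            pred,
            reconstruct(Z["protein"], result.params.G[spec.name],
                        result.params.H[spec.name], Z["disease"]),
        )

    def test_planted_positives_outscore_negatives(self, tiny_synthetic):
        kg, truth, holdout = tiny_synthetic
        cfg = TrainConfig(d0=16, d1=12, k=12, epochs=250, learning_rate=1e-2, seed=0)
        result = train(kg, cfg)
        pred = predict_tda(result.params, kg)
        unobserved = ~kg.adjacency[kg.tda_name].observed
        pos = pred[unobserved & truth]
        neg = pred[unobserved & ~truth]
        assert pos.mean() > neg.mean()


class TestParamsIO:
    def test_round_trip(self, tiny_synthetic, tiny_config, tmp_path):
        kg, _, _ = tiny_synthetic
        result = train(kg, tiny_config)
        path = str(tmp_path / "params.npz")
        save_params(result.params, path, tiny_config)
        back = load_params(path)
        for (n1, a), (n2, b) in zip(result.params.named(), back.named()):
            assert n1 == n2
            np.testing.assert_array_equal(a, b)
        assert back.tied == result.params.tied
        # tied pairs stay tied (same object)
        for r in back.tied:
            assert back.G[r] is back.H[r]
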