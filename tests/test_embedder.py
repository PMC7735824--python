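import numpy as np
import pytest
from scipy.stats import chisquare

from pmdne import (
    BipartiteNetwork,
    EmbeddingModel,
    Hyperparams,
    WalkCorpus,
    embedded_proximity,
    explicit_loss,
    joint_proximity,
    sample_negatives,
    sgd_update_explicit,
    sgd_update_skipgram,
    sweep,
    train,
)


def make_model(u_ids, v_ids, d, seed=0):
    return EmbeddingModel.initialize(u_ids, v_ids, d, seed)


class TestProximities:
    def test_single_edge_probability_one(self):
        bn = BipartiteNetwork(["m1"], ["d1"], {("m1", "d1"): 3.0})
        assert joint_proximity(bn) == {("m1", "d1"): 1.0}

    def test_two_edges_normalize_to_weight_shares(self):
        bn = BipartiteNetwork(
            ["m1", "m2"], ["d1"], {("m1", "d1"): 2.0, ("m2", "d1"): 6.0}
        )
        p = joint_proximity(bn)
        assert p[("m1", "d1")] == pytest.approx(0.25)
        assert p[("m2", "d1")] == pytest.approx(0.75)

    def test_probabilities_sum_to_one(self, small_dataset):
        p = joint_proximity(small_dataset.network)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            joint_proximity(BipartiteNetwork(["m1"], ["d1"], {}))

    def test_embedded_proximity_closed_form(self):
        assert embedded_proximity(np.zeros(4), np.zeros(4)) == 0.5
        assert embedded_proximity(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == (
            pytest.approx(0.7310586, abs=1e-7)
        )

    def test_embedded_proximity_symmetric_and_checked(self):
        u, v = np.array([0.3, -0.2, 1.1]), np.array([0.5, 0.4, -0.9])
        assert embedded_proximity(u, v) == embedded_proximity(v, u)
        with pytest.raises(ValueError, match="mismatch"):
            embedded_proximity(np.zeros(2), np.zeros(3))


class TestExplicitTerm:
    def test_single_edge_loss_is_log_two(self):
        bn = BipartiteNetwork(["m1"], ["d1"], {("m1", "d1"): 1.0})
        model = make_model(["m1"], ["d1"], d=2)
        model.u_emb[0] = [1.0, 0.0]
        model.v_emb[0] = [0.0, 1.0]  # dot = 0 -> -log 0.5
        assert explicit_loss(bn, model) == pytest.approx(0.6931472, abs=1e-7)

    def test_loss_nonnegative_and_vanishes_when_aligned(self):
        bn = BipartiteNetwork(["m1"], ["d1"], {("m1", "d1"): 1.0})
        model = make_model(["m1"], ["d1"], d=2)
        model.u_emb[0] = [30.0, 0.0]
        model.v_emb[0] = [30.0, 0.0]
        assert 0.0 <= explicit_loss(bn, model) < 1e-6

    def test_hand_update(self):
        model = make_model(["m1"], ["d1"], d=2)
        model.u_emb[0] = [1.0, 0.0]
        model.v_emb[0] = [1.0, 0.0]
        sgd_update_explicit(model, ("m1", "d1", 1.0), lam=0.01, gamma=0.1)
        np.testing.assert_allclose(model.u_emb[0], [1.0002689, 0.0], atol=1e-7)
        np.testing.assert_allclose(model.v_emb[0], [1.0002689, 0.0], atol=1e-7)

    def test_zero_gamma_is_noop(self):
        model = make_model(["m1"], ["d1"], d=4, seed=1)
        before = model.u_emb.copy(), model.v_emb.copy()
        sgd_update_explicit(model, ("m1", "d1", 1.0), lam=0.5, gamma=0.0)
        np.testing.assert_array_equal(model.u_emb, before[0])
        np.testing.assert_array_equal(model.v_emb, before[1])

    def test_update_matches_finite_difference_gradient(self):
        # descent on f(u, v) = -gamma * w * log sigma(u.v)
        rng = np.random.default_rng(0)
        h, lam = 1e-5, 0.3
        for _ in range(30):
            d = int(rng.integers(2, 9))
            gamma, w = float(rng.random() + 0.1), float(rng.random() * 2 + 0.5)
            u0 = rng.normal(0, 0.7, d)
            v0 = rng.normal(0, 0.7, d)

            def f(u, v):
                return -gamma * w * np.log(1.0 / (1.0 + np.exp(-(u @ v))))

            model = make_model(["m"], ["d"], d)
            model.u_emb[0], model.v_emb[0] = u0.copy(), v0.copy()
            sgd_update_explicit(model, ("m", "d", w), lam=lam, gamma=gamma)
            grad_u = np.array(
                [
                    (f(u0 + h * e, v0) - f(u0 - h * e, v0)) / (2 * h)
                    for e in np.eye(d)
                ]
            )
            grad_v = np.array(
                [
                    (f(u0, v0 + h * e) - f(u0, v0 - h * e)) / (2 * h)
                    for e in np.eye(d)
                ]
            )
            np.testing.assert_allclose(model.u_emb[0], u0 - lam * grad_u, rtol=1e-6, atol=1e-10)
            np.testing.assert_allclose(model.v_emb[0], v0 - lam * grad_v, rtol=1e-6, atol=1e-10)


class TestNegativeSampling:
    def test_zero_requested_returns_empty(self):
        rng = np.random.default_rng(0)
        assert sample_negatives({"a": 5, "b": 3}, "a", [], 0, rng) == []

    def test_exclusions_respected(self):
        rng = np.random.default_rng(1)
        vocab = {f"n{i}": i + 1 for i in range(10)}
        for _ in range(50):
            negs = sample_negatives(vocab, "n0", ["n1", "n2"], 5, rng)
            assert len(negs) == 5
            assert not set(negs) & {"n0", "n1", "n2"}

    def test_empty_allowed_set_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="empty"):
            sample_negatives({"a": 5, "b": 3}, "a", ["b"], 2, rng)

    def test_draws_follow_smoothed_unigram_distribution(self):
        # frequencies ** 0.75 renormalized over the allowed vocabulary
        rng = np.random.default_rng(7)
        vocab = {"a": 1, "b": 8, "c": 27, "d": 64}
        draws = sample_negatives(vocab, "zzz", [], 30000, rng)
        # center "zzz" is outside the vocabulary: nothing excluded
        observed = np.array([draws.count(k) for k in vocab])
        expected = np.array([v**0.75 for v in vocab.values()], dtype=float)
        expected = expected / expected.sum() * len(draws)
        assert chisquare(observed, expected).pvalue > 0.01


class TestSkipgramUpdate:
    def test_hand_update_one_dimensional(self):
        model = make_model(["c", "x"], [], d=1)
        model.u_emb[0] = [0.5]
        model.u_ctx[1] = [0.2]
        sgd_update_skipgram(model, "U", "c", ["x"], [], lam=0.1, coef=1.0)
        assert model.u_ctx[1, 0] == pytest.approx(0.2237510, abs=1e-7)
        assert model.u_emb[0, 0] == pytest.approx(0.5095004, abs=1e-7)

    def test_zero_coef_is_noop(self):
        model = make_model(["c", "x", "y"], [], d=3, seed=2)
        model.u_ctx += 0.1
        before = model.u_emb.copy(), model.u_ctx.copy()
        sgd_update_skipgram(model, "U", "c", ["x"], ["y"], lam=0.5, coef=0.0)
        np.testing.assert_array_equal(model.u_emb, before[0])
        np.testing.assert_array_equal(model.u_ctx, before[1])

    def test_missing_node_rejected(self):
        model = make_model(["c"], [], d=2)
        with pytest.raises(KeyError, match="missing"):
            sgd_update_skipgram(model, "U", "c", ["nope"], [], lam=0.1, coef=1.0)

    def test_update_matches_finite_difference_gradient(self):
        # ascent on g = coef * [sum_ctx log sig(c.t_z) + sum_neg log(1 - sig(c.t_z))]
        rng = np.random.default_rng(5)
        h, lam = 1e-5, 0.2
        for _ in range(30):
            d = int(rng.integers(2, 9))
            n_ctx, n_neg = int(rng.integers(1, 4)), int(rng.integers(0, 4))
            coef = float(rng.random() + 0.1)
            ids = ["c"] + [f"z{k}" for k in range(n_ctx + n_neg)]
            model = make_model(ids, [], d)
            model.u_emb[0] = rng.normal(0, 0.7, d)
            model.u_ctx[1:] = rng.normal(0, 0.7, (n_ctx + n_neg, d))
            c0 = model.u_emb[0].copy()
            t0 = model.u_ctx[1:].copy()
            ctx_ids = ids[1 : 1 + n_ctx]
            neg_ids = ids[1 + n_ctx :]

            def g(c, t):
                s = 1.0 / (1.0 + np.exp(-(t @ c)))
                return coef * (
                    np.log(s[:n_ctx]).sum() + np.log(1 - s[n_ctx:]).sum()
                )

            sgd_update_skipgram(model, "U", "c", ctx_ids, neg_ids, lam=lam, coef=coef)
            grad_c = np.array(
                [(g(c0 + h * e, t0) - g(c0 - h * e, t0)) / (2 * h) for e in np.eye(d)]
            )
            np.testing.assert_allclose(model.u_emb[0], c0 + lam * grad_c, rtol=1e-6, atol=1e-10)
            for z in range(n_ctx + n_neg):
                grad_t = np.zeros_like(t0)
                got = model.u_ctx[1 + z]
                for dim in range(d):
                    tp, tm = t0.copy(), t0.copy()
                    tp[z, dim] += h
                    tm[z, dim] -= h
                    grad_t[z, dim] = (g(c0, tp) - g(c0, tm)) / (2 * h)
                np.testing.assert_allclose(got, t0[z] + lam * grad_t[z], rtol=1e-6, atol=1e-10)


class TestTrain:
    def _corpora(self, data, hp):
        from pmdne import (
            allocate_walks,
            generate_walks,
            node_importance,
            project_homogeneous,
        )

        out = []
        for tag, (side, sim, coeff) in enumerate(
            (("U", data.sim_u, hp.e), ("V", data.sim_v, hp.c))
        ):
            proj = project_homogeneous(data.network, side, sim, coeff)
            imp = node_importance(proj, "degree")
            counts = allocate_walks(imp, hp.walks_per_node * proj.n_nodes)
            out.append(
                generate_walks(proj, counts, hp.max_t, hp.min_t, hp.stop_prob, rng_seed=tag)
            )
        return out

    def test_zero_epochs_returns_seeded_initialization(self, small_dataset, small_hp):
        hp = Hyperparams(d=8, epochs=0, seed=3)
        cu, cv = self._corpora(small_dataset, hp)
        model = train(small_dataset.network, cu, cv, hp)
        init = EmbeddingModel.initialize(
            small_dataset.network.u_nodes, small_dataset.network.v_nodes, 8, seed=[3, 0]
        )
        np.testing.assert_array_equal(model.u_emb, init.u_emb)
        assert model.loss_history == []

    def test_same_seed_is_bitwise_identical(self, small_dataset):
        hp = Hyperparams(d=8, epochs=3, seed=9)
        cu, cv = self._corpora(small_dataset, hp)
        m1 = train(small_dataset.network, cu, cv, hp)
        m2 = train(small_dataset.network, cu, cv, hp)
        np.testing.assert_array_equal(m1.u_emb, m2.u_emb)
        np.testing.assert_array_equal(m1.v_emb, m2.v_emb)
        assert m1.loss_history == m2.loss_history

    def test_explicit_loss_decreases_over_training(self, small_dataset, small_hp):
        cu, cv = self._corpora(small_dataset, small_hp)
        model = train(small_dataset.network, cu, cv, small_hp)
        o1_per_epoch = [row[0] for row in model.loss_history]
        assert o1_per_epoch[-1] < o1_per_epoch[0]

    def test_tracked_objective_nearly_monotone(self, small_dataset, small_hp):
        # gamma*O1 - alpha*O2 - beta*O3 may fluctuate by sampling noise only
        cu, cv = self._corpora(small_dataset, small_hp)
        model = train(small_dataset.network, cu, cv, small_hp)
        losses = [-row[3] for row in model.loss_history]
        for prev, cur in zip(losses, losses[1:]):
            assert cur <= prev + 0.01 * abs(prev)

    def test_embeddings_finite_across_seeds(self):
        from pmdne import make_synthetic

        for seed in range(20):
            data = make_synthetic(n_u=12, n_v=12, n_blocks=2, p_in=0.5, p_out=0.1, seed=seed)
            hp = Hyperparams(d=8, epochs=3, seed=seed, walks_per_node=3)
            cu = WalkCorpus(walks=[], params=(32, 1, 0.15))
            model = train(data.network, cu, cu, hp)
            assert np.isfinite(model.u_emb).all() and np.isfinite(model.v_emb).all()

    def test_equal_weight_neighbors_converge_to_equal_proximity(self):
        # pure explicit term: v1 and v2 both linked to m with weight 1
        bn = BipartiteNetwork(["m"], ["v1", "v2"], {("m", "v1"): 1.0, ("m", "v2"): 1.0})
        hp = Hyperparams(d=8, epochs=300, alpha=0.0, beta=0.0, gamma=0.1, seed=4, tol=0.0)
        empty = WalkCorpus(walks=[], params=(32, 1, 0.15))
        model = train(bn, empty, empty, hp)
        d1 = float(model.u_emb[0] @ model.v_emb[model.v_index["v1"]])
        d2 = float(model.u_emb[0] @ model.v_emb[model.v_index["v2"]])
        assert abs(d1 - d2) / max(abs(d1), abs(d2)) < 0.05

    def test_nothing_to_optimize_rejected(self):
        bn = BipartiteNetwork(["m"], ["d"], {("m", "d"): 1.0})
        empty = WalkCorpus(walks=[], params=(32, 1, 0.15))
        with pytest.raises(ValueError, match="optimize"):
            train(bn, empty, empty, Hyperparams(d=4, gamma=0.0))


class TestSweep:
    def test_single_point_grid(self):
        table = sweep({"d": [16]}, lambda hp: (0.9, 0.8))
        assert len(table) == 1
        assert table.loc[0, "parameter"] == "d"
        assert table.loc[0, "roc_auc"] == 0.9

    def test_grid_order_preserved_and_rows_populated(self):
        calls = []

        def fake_eval(hp):
            calls.append((hp.d, hp.ws))
            return (0.5 + 0.001 * len(calls), 0.5)

        table = sweep({"d": [8, 128], "ws": [2]}, fake_eval)
        assert list(table["value"]) == [8, 128, 2]
        assert table["roc_auc"].notna().all()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sweep({"learning_rate_warmup": [1]}, lambda hp: (0.5, 0.5))
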