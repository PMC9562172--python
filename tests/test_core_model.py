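"""Architecture unit tests: Q/K/V projections, attention normalization,
layer forward, full forward against the loop oracle, and checkpointing."""

import numpy as np
import pytest

from tgem.functional import (
    attention_weights,
    backward_batch,
    compute_qkv,
    forward,
    forward_batch,
    head_representation,
    layer_forward,
    nll_loss_and_grad,
)
from tgem.params import (
    HeadParams,
    LayerParams,
    TGEMParams,
    flatten_params,
    init_params,
    parameter_count,
)

from conftest import oracle_forward, random_model


class TestComputeQKV:
    @pytest.mark.parametrize(
        "x, wq, expected_q",
        [
            ([0.0, 0.0, 0.0], [1.0, -2.0, 5.0], [0.0, 0.0, 0.0]),
            ([1.0, 1.0, 1.0], [2.0, 3.0, 4.0], [2.0, 3.0, 4.0]),
            ([0.5, 2.0, 1.0], [2.0, 1.0, 3.0], [1.0, 2.0, 3.0]),
        ],
    )
    def test_elementwise_products(self, x, wq, expected_q):
        head = HeadParams(wq=np.array(wq), wk=np.ones(3), wv=np.full(3, 2.0))
        q, k, v = compute_qkv(np.array(x), head)
        np.testing.assert_allclose(q, expected_q)
        np.testing.assert_allclose(k, x)
        np.testing.assert_allclose(v, np.asarray(x) * 2.0)

    def test_length_mismatch_raises(self):
        head = HeadParams(wq=np.ones(3), wk=np.ones(3), wv=np.ones(3))
        with pytest.raises(ValueError, match="length"):
            compute_qkv(np.ones(4), head)


class TestAttentionWeights:
    def test_identical_logits_are_uniform(self):
        a = attention_weights(q=np.ones(4), k=np.full(4, 0.7), g=0)
        np.testing.assert_allclose(a, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_zero_logits(self):
        a = attention_weights(q=np.array([1.0, 5.0, 5.0]), k=np.array([9.0, 0.0, 0.0]), g=0)
        np.testing.assert_allclose(a, [0.5, 0.5], atol=1e-12)

    def test_log3_logit_gives_three_quarters(self):
        a = attention_weights(
            q=np.array([1.0, 0.0, 0.0]), k=np.array([0.0, np.log(3.0), 0.0]), g=0
        )
        np.testing.assert_allclose(a, [0.75, 0.25], atol=1e-12)

    def test_single_gene_is_hard_error(self):
        with pytest.raises(ValueError, match="at least 2 genes"):
            attention_weights(np.ones(1), np.ones(1), 0)

    def test_sums_to_one(self, rng):
        q = rng.normal(size=7)
        k = rng.normal(size=7)
        for g in range(7):
            assert attention_weights(q, k, g).sum() == pytest.approx(1.0, abs=1e-12)


class TestHeadRepresentation:
    @pytest.mark.parametrize(
        "a, v, expected",
        [
            ([0.5, 0.5], [2.0, 4.0], 3.0),
            ([0.3, 0.7], [0.0, 0.0], 0.0),
            ([0.75, 0.25], [1.0, -1.0], 0.5),
        ],
    )
    def test_dot_product(self, a, v, expected):
        assert head_representation(np.array(a), np.array(v)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            head_representation(np.ones(2) / 2, np.ones(3))


class TestLayerForward:
    def test_zero_head_mix_is_identity(self, rng):
        G = 5
        lp = LayerParams(
            wq=rng.normal(size=(2, G)), wk=rng.normal(size=(2, G)),
            wv=rng.normal(size=(2, G)), head_mix=np.zeros(2),
            ln_gain=np.ones(G), ln_bias=np.zeros(G),
        )
        x = rng.uniform(size=G)
        z, _ = layer_forward(x, lp)
        np.testing.assert_array_equal(z, x)

    def test_matches_loop_reference(self, rng):
        """Hand-set single-head layer equals an explicit-loop computation."""
        G = 3
        lp = LayerParams(
            wq=np.array([[1.0, 2.0, -1.0]]), wk=np.array([[0.5, 1.0, 2.0]]),
            wv=np.array([[1.0, -1.0, 0.5]]), head_mix=np.array([1.0]),
            ln_gain=np.ones(G), ln_bias=np.zeros(G),
        )
        x = np.array([0.2, 0.9, 0.4])
        z, A = layer_forward(x, lp)
        # explicit loops
        q, k, v = lp.wq[0] * x, lp.wk[0] * x, lp.wv[0] * x
        m = np.zeros(G)
        for g in range(G):
            idx = [i for i in range(G) if i != g]
            logits = np.array([q[g] * k[i] for i in idx])
            e = np.exp(logits - logits.max())
            a = e / e.sum()
            m[g] = sum(ai * v[i] for ai, i in zip(a, idx))
        mu, var = m.mean(), m.var()
        expected = x + (m - mu) / np.sqrt(var + 1e-5)
        np.testing.assert_allclose(z, expected, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        G = 6
        lp = LayerParams(
            wq=rng.normal(size=(2, G)), wk=rng.normal(size=(2, G)),
            wv=rng.normal(size=(2, G)), head_mix=rng.normal(size=2),
            ln_gain=rng.uniform(0.5, 1.5, G), ln_bias=rng.normal(size=G),
        )
        x = rng.uniform(size=G)
        z, _ = layer_forward(x, lp)
        perm = rng.permutation(G)
        lp_p = LayerParams(
            wq=lp.wq[:, perm], wk=lp.wk[:, perm], wv=lp.wv[:, perm],
            head_mix=lp.head_mix, ln_gain=lp.ln_gain[perm], ln_bias=lp.ln_bias[perm],
        )
        z_p, _ = layer_forward(x[perm], lp_p)
        np.testing.assert_allclose(z_p, z[perm], atol=1e-6)


class TestForward:
    def test_zero_classifier_gives_uniform(self, rng):
        params = random_model(rng, G=5, C=4)
        params.classifier.weight[:] = 0.0
        params.classifier.bias[:] = 0.0
        probs, _ = forward(rng.uniform(size=5), params)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_pruned_model_is_linear_classifier(self, rng):
        params = random_model(rng, G=5, C=3, L=1)
        params.layers[0].head_mix[:] = 0.0
        params.layers[0].ln_bias[:] = 0.0
        params.classifier.bias[:] = 0.0
        x = rng.uniform(size=5)
        probs, _ = forward(x, params)
        logits = params.classifier.weight @ x
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(probs, e / e.sum(), atol=1e-12)

    def test_matches_oracle_on_random_models(self, rng):
        for _ in range(10):
            G = int(rng.integers(3, 9))
            L = int(rng.integers(1, 4))
            H = int(rng.integers(1, 4))
            act = ("none", "relu", "gelu")[int(rng.integers(3))]
            params = random_model(rng, G=G, C=3, L=L, H=H, activation=act)
            x = rng.uniform(size=G)
            probs, _ = forward(x, params)
            np.testing.assert_allclose(probs, oracle_forward(params, x), atol=1e-6)

    def test_gene_name_mismatch_names_offender(self, rng):
        params = random_model(rng, G=3)
        with pytest.raises(ValueError, match="g1"):
            forward(np.ones(3), params, gene_names=["g0", "BAD", "g2"])

    def test_attention_rows_stochastic_with_zero_diagonal(self, rng):
        params = random_model(rng, G=6, L=2, H=2)
        _, attention = forward(rng.uniform(size=6), params)
        for A in attention:  # (H, G, G)
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)
            np.testing.assert_array_equal(np.diagonal(A, axis1=-2, axis2=-1), 0.0)
            assert A.min() >= 0.0 and A.max() <= 1.0

    def test_batched_equals_per_sample(self, rng):
        params = random_model(rng, G=7, L=2, H=3)
        X = rng.uniform(size=(5, 7))
        probs_batch, _, _ = forward_batch(X, params)
        for i in range(5):
            probs_i, _ = forward(X[i], params)
            np.testing.assert_allclose(probs_batch[i], probs_i, atol=1e-6)


class TestExpressionSample:
    def test_forward_accepts_sample_with_matching_names(self, rng):
        from tgem.data import ExpressionSample

        params = random_model(rng, G=3)
        sample = ExpressionSample(values=rng.uniform(size=3), gene_names=["g0", "g1", "g2"])
        probs, _ = forward(sample, params)
        probs_plain, _ = forward(sample.values, params)
        np.testing.assert_array_equal(probs, probs_plain)

    @pytest.mark.parametrize(
        "values, names, match",
        [
            ([1.0, 2.0], ["a"], "equal length"),
            ([1.0, 2.0], ["a", "a"], "unique"),
            ([1.0, np.nan], ["a", "b"], "finite"),
        ],
    )
    def test_invariants_enforced(self, values, names, match):
        from tgem.data import ExpressionSample

        with pytest.raises(ValueError, match=match):
            ExpressionSample(values=np.array(values), gene_names=names)


class TestParameterCount:
    def test_enumerated_example(self):
        params = init_params([f"g{i}" for i in range(10)], ["a", "b"], n_layers=1, n_heads=1)
        assert parameter_count(params) == 73

    def test_zero_heads_disallowed(self):
        with pytest.raises(ValueError):
            init_params(["g0", "g1"], ["a", "b"], n_heads=0)

    def test_doubling_heads_adds_linear_term(self):
        genes = [f"g{i}" for i in range(12)]
        p1 = init_params(genes, ["a", "b", "c"], n_layers=2, n_heads=2)
        p2 = init_params(genes, ["a", "b", "c"], n_layers=2, n_heads=4)
        assert parameter_count(p2) - parameter_count(p1) == 2 * (3 * 12 * 2 + 2)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        params = random_model(rng, G=5, C=3, L=2, H=2, activation="gelu")
        X = rng.uniform(size=(3, 5))
        y = rng.integers(0, 3, size=3)

        def loss_of():
            probs, logits, caches = forward_batch(X, params)
            return nll_loss_and_grad(logits, probs, y) + (caches,)

        loss, dlogits, caches = loss_of()
        layer_grads, clf_grads, _ = backward_batch(params, caches, dlogits)
        arrays = flatten_params(params)
        grads = []
        for g in layer_grads:
            grads.extend([g["wq"], g["wk"], g["wv"], g["head_mix"], g["ln_gain"], g["ln_bias"]])
        grads.extend([clf_grads["weight"], clf_grads["bias"]])
        eps = 1e-6
        check = rng.choice(len(arrays), size=4, replace=False)
        for ai in check:
            arr, grad = arrays[ai], grads[ai]
            flat_i = int(rng.integers(arr.size))
            idx = np.unravel_index(flat_i, arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss_of()[0]
            arr[idx] = orig - eps
            lm = loss_of()[0]
            arr[idx] = orig
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


class TestCheckpoint:
    def test_roundtrip_reproduces_forward_bit_identically(self, rng, tmp_path):
        from tgem.io import load_checkpoint, save_checkpoint
        from tgem.preprocess import PreprocessStats

        params = random_model(rng, G=6, C=3, L=2, H=2, activation="relu")
        stats = PreprocessStats(
            per_gene_min=rng.uniform(size=6), per_gene_max=rng.uniform(1, 2, size=6)
        )
        save_checkpoint(params, tmp_path / "ckpt", stats=stats, train_config={"epochs": 5})
        loaded, loaded_stats, meta = load_checkpoint(tmp_path / "ckpt")
        X = rng.uniform(size=(4, 6))
        p0, l0, _ = forward_batch(X, params)
        p1, l1, _ = forward_batch(X, loaded)
        np.testing.assert_array_equal(p0, p1)
        np.testing.assert_array_equal(l0, l1)
        np.testing.assert_array_equal(loaded_stats.per_gene_min, stats.per_gene_min)
        assert meta["train_config"] == {"epochs": 5}
        assert loaded.gene_names == params.gene_names
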