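"""Entropy profiling, integrated-gradients axioms, pruning and probes."""

import numpy as np
import pytest

from tgem.functional import forward_batch
from tgem.interpret import (
    attention_entropy,
    entropy_profile,
    head_representations,
    ig_attribution,
    ig_completeness_gap,
    layer_representations,
    probe_classifier,
    prune_head,
    prune_layer,
    prune_scan,
)
from tgem.params import ClassifierParams, LayerParams, TGEMParams, init_params

from conftest import random_model


def uniform_attention_model(G=6, H=2, L=1, C=3):
    """Equal per-gene weights: every Query gene attends uniformly."""
    layers = [
        LayerParams(
            wq=np.full((H, G), 0.3), wk=np.full((H, G), 0.2), wv=np.full((H, G), 0.5),
            head_mix=np.full(H, 1.0 / H), ln_gain=np.ones(G), ln_bias=np.zeros(G),
        )
        for _ in range(L)
    ]
    clf = ClassifierParams(weight=np.zeros((C, G)), bias=np.zeros(C))
    return TGEMParams(
        layers=layers, classifier=clf,
        gene_names=[f"g{i}" for i in range(G)], class_names=[f"c{i}" for i in range(C)],
    )


class TestAttentionEntropy:
    def test_uniform_two_keys(self):
        assert attention_entropy(np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_point_mass_is_zero(self):
        assert attention_entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_skewed_distribution(self):
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert attention_entropy(np.array([0.75, 0.25])) == pytest.approx(expected)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            attention_entropy(np.array([1.2, -0.2]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            attention_entropy(np.array([0.4, 0.4]))


class TestEntropyProfile:
    def test_uniform_model_attains_max_entropy(self):
        G = 6
        params = uniform_attention_model(G=G)
        X = np.full((3, G), 0.8)  # equal inputs: identical logits
        profile = entropy_profile(params, X)
        np.testing.assert_allclose(profile.values, np.log(G - 1), atol=1e-12)
        assert profile.max_entropy() == pytest.approx(np.log(G - 1))

    def test_single_sample_profile_is_that_sample(self, rng):
        params = random_model(rng, G=5, L=2, H=2)
        x = rng.uniform(size=5)
        single = entropy_profile(params, x[None, :])
        _, attention = __import__("tgem.functional", fromlist=["forward"]).forward(x, params)
        for li, A in enumerate(attention):
            for h in range(A.shape[0]):
                for g in range(A.shape[1]):
                    expected = attention_entropy(A[h, g][np.arange(5) != g])
                    assert single.values[li, h, g] == pytest.approx(expected, abs=1e-12)

    def test_two_samples_average(self, rng):
        params = random_model(rng, G=5, L=1, H=2)
        X = rng.uniform(size=(2, 5))
        both = entropy_profile(params, X)
        first = entropy_profile(params, X[:1])
        second = entropy_profile(params, X[1:])
        np.testing.assert_allclose(both.values, (first.values + second.values) / 2, atol=1e-12)

    def test_bounds(self, rng):
        params = random_model(rng, G=7, L=2, H=3, scale=1.5)
        profile = entropy_profile(params, rng.uniform(size=(4, 7)))
        assert profile.values.min() >= 0.0
        assert profile.values.max() <= np.log(6) + 1e-12


def linear_attention_model(rng, G=5, C=3, H=2):
    """No layer norm + linear readout: the class logit is exactly linear
    in the attention weights."""
    params = random_model(rng, G=G, C=C, H=H, L=1, activation="none", layer_norm=False)
    return params


class TestIntegratedGradients:
    def test_linear_model_exact_at_any_step_count(self, rng):
        params = linear_attention_model(rng, G=5)
        x = rng.uniform(0.1, 1.0, size=5)
        _, _, caches = forward_batch(x[None, :], params)
        A = caches["layers"][0]["A"][0]  # (H, G, G)
        V = caches["layers"][0]["V"][0]
        W = params.classifier.weight
        mix = params.layers[0].head_mix
        # logit_c = W[c] @ (x + sum_h mix_h A_h V_h): gradient is constant
        target = 1
        expected = np.zeros((5, 5))
        for h in range(params.n_heads):
            grad_h = mix[h] * np.outer(W[target], V[h])
            expected += (A[h] * grad_h) / params.n_heads
        for n_steps, rule in [(2, "left"), (3, "gausslegendre"), (5, "trapezoid")]:
            attrib = ig_attribution(params, x[None, :], 0, target, n_steps=n_steps, rule=rule)
            np.testing.assert_allclose(attrib.scores, expected, atol=1e-12)

    def test_completeness_on_random_models(self, rng):
        for _ in range(8):
            G = int(rng.integers(4, 8))
            L = int(rng.integers(1, 4))
            params = random_model(rng, G=G, L=L, H=int(rng.integers(1, 4)), scale=0.3)
            x = rng.uniform(size=G)
            layer = int(rng.integers(0, L))
            total, delta = ig_completeness_gap(params, x, layer, target_class=0, n_steps=200)
            assert abs(total - delta) <= 0.01 * abs(delta) + 1e-12

    def test_zero_attention_input_gives_zero_attribution(self, rng):
        params = linear_attention_model(rng, G=4)
        x = np.zeros(4)  # all Q/K logits 0 -> uniform attention but V=0
        attrib = ig_attribution(params, x[None, :], 0, 0, n_steps=4)
        np.testing.assert_allclose(attrib.scores, 0.0, atol=1e-12)

    def test_diagonal_always_zero(self, rng):
        params = random_model(rng, G=6, L=2, H=2)
        attrib = ig_attribution(params, rng.uniform(size=(3, 6)), 1, 2, n_steps=8)
        np.testing.assert_array_equal(np.diag(attrib.scores), 0.0)

    def test_requires_two_steps(self, rng):
        params = random_model(rng, G=4)
        with pytest.raises(ValueError, match="n_steps"):
            ig_attribution(params, np.ones((1, 4)) / 2, 0, 0, n_steps=1)


class TestPruning:
    def test_pruned_single_head_layer_is_identity(self, rng):
        params = random_model(rng, G=5, L=1, H=1)
        params.layers[0].ln_bias[:] = 0.0
        pruned = prune_head(params, 0, 0)
        X = rng.uniform(size=(3, 5))
        _, _, caches = forward_batch(X, pruned)
        np.testing.assert_array_equal(caches["Z_last"], X)
        # original untouched
        assert params.layers[0].head_mix[0] != 0.0

    def test_pruning_zero_head_changes_nothing(self, rng):
        params = random_model(rng, G=5, L=1, H=2)
        params.layers[0].head_mix[1] = 0.0
        X = rng.uniform(size=(4, 5))
        p0, _, _ = forward_batch(X, params)
        p1, _, _ = forward_batch(X, prune_head(params, 0, 1))
        np.testing.assert_array_equal(p0, p1)

    def test_prune_layer_equals_all_heads_jointly(self, rng):
        params = random_model(rng, G=5, L=2, H=3)
        pruned = prune_layer(params, 1)
        np.testing.assert_array_equal(pruned.layers[1].head_mix, 0.0)
        # pruning heads one at a time on separate copies leaves the model intact
        for h in range(3):
            prune_head(params, 1, h)
        assert np.all(params.layers[1].head_mix != 0.0)

    def test_prune_all_layers_reduces_to_linear_model(self, rng):
        params = random_model(rng, G=6, L=3, H=2, activation="relu")
        for lp in params.layers:
            lp.ln_bias[:] = 0.0
        pruned = params
        for li in range(3):
            pruned = prune_layer(pruned, li)
        X = rng.uniform(size=(4, 6))
        probs, _, _ = forward_batch(X, pruned)
        clf = params.classifier
        logits = np.maximum(X, 0.0) @ clf.weight.T + clf.bias
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        np.testing.assert_allclose(probs, e / e.sum(axis=1, keepdims=True), atol=1e-12)

    def test_index_errors(self, rng):
        params = random_model(rng, G=4, L=1, H=2)
        with pytest.raises(IndexError):
            prune_head(params, 0, 5)
        with pytest.raises(IndexError):
            prune_layer(params, 3)

    def test_scan_bookkeeping(self, rng):
        params = random_model(rng, G=5, L=2, H=2)
        X = rng.uniform(size=(10, 5))
        y = rng.integers(0, 3, size=10)
        reference, results = prune_scan(params, X, y)
        assert len(results) == 2 + 2 * 2
        for r in results:
            assert r.accuracy_drop == pytest.approx(reference - r.accuracy_after)
            assert 0.0 <= r.accuracy_after <= 1.0


def signal_through_head_model():
    """A model correct only via head 1's attention path.

    Two classes differ in genes 0/1 while gene 2 is constant; the readout
    looks only at gene 2, whose layer-normalized attention output carries
    the class difference, so pruning head 1 collapses accuracy to chance.
    """
    G = 3
    lp = LayerParams(
        wq=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]]),
        wk=np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0]]),
        wv=np.array([[4.0, -4.0, 0.0], [0.0, 0.0, 0.0]]),
        head_mix=np.array([1.0, 0.0]),
        ln_gain=np.ones(G), ln_bias=np.zeros(G),
    )
    # bias recenters the readout at the anchor's skip value (x3 = 1), so
    # only the attention contribution decides the class
    clf = ClassifierParams(weight=np.array([[0.0, 0.0, 8.0], [0.0, 0.0, -8.0]]),
                           bias=np.array([-8.0, 8.0]))
    return TGEMParams(
        layers=[lp], classifier=clf,
        gene_names=["m0", "m1", "anchor"], class_names=["a", "b"],
    )


class TestHeadSignalPruning:
    def test_head_one_carries_all_signal(self, rng):
        params = signal_through_head_model()
        n = 30
        X = np.zeros((2 * n, 3))
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        X[:n] = [1.0, 0.1, 1.0] + rng.normal(scale=0.02, size=(n, 3))
        X[n:] = [0.1, 1.0, 1.0] + rng.normal(scale=0.02, size=(n, 3))
        reference, results = prune_scan(params, X, y)
        assert reference == 1.0
        by_target = {(r.layer, r.head): r for r in results}
        assert by_target[(0, 1)].accuracy_drop == 0.0  # head 2 mixes with weight 0
        drops = [r.accuracy_drop for r in results]
        assert by_target[(0, 0)].accuracy_drop == max(drops)
        assert by_target[(0, 0)].accuracy_drop >= 0.4


class TestProbes:
    def test_separable_representations_give_perfect_probe(self, rng):
        train = np.vstack([rng.normal(-3, 0.2, (20, 4)), rng.normal(3, 0.2, (20, 4))])
        y = np.repeat([0, 1], 20)
        acc = probe_classifier(train, y, train, y)
        assert acc == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            probe_classifier(X, np.zeros(10, int), X, np.zeros(10, int))

    def test_probe_invariant_to_gene_permutation(self, rng):
        params = random_model(rng, G=6, L=1, H=2)
        X = rng.uniform(size=(30, 6))
        y = rng.integers(0, 2, size=30)
        reps = head_representations(params, X, 0)[:, 0]
        perm = rng.permutation(6)
        acc = probe_classifier(reps, y, reps, y)
        acc_p = probe_classifier(reps[:, perm], y, reps[:, perm], y)
        assert acc == pytest.approx(acc_p)

    def test_layer_representations_shapes(self, rng):
        params = random_model(rng, G=5, L=2, H=3)
        X = rng.uniform(size=(7, 5))
        reps = layer_representations(params, X)
        assert len(reps) == 2 and all(r.shape == (7, 5) for r in reps)
        zh = head_representations(params, X, 1)
        assert zh.shape == (7, 3, 5)
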