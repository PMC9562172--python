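"""Interpretation of trained attention models.

Four probes into what the network has learned:

* attention entropy per Query gene (broad vs focused attention),
* integrated-gradients attribution of the class logit to the attention
  weights of a layer, relative to a zero-attention baseline,
* head/layer pruning (zeroing head-mix weights) with accuracy bookkeeping,
* linear max-margin probe classifiers on intermediate representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .functional import forward_batch, logit_grad_wrt_attention
from .params import TGEMParams
from .train import accuracy_of


# ---------------------------------------------------------------------------
# entropy

def attention_entropy(a_g: np.ndarray) -> float:
    """Shannon entropy (nats) of one attention distribution; 0*log 0 := 0."""
    a = np.asarray(a_g, dtype=float)
    if np.any(a < 0):
        raise ValueError("attention weights must be non-negative")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"attention weights sum to {a.sum()}, expected 1")
    nz = a[a > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class EntropyProfile:
    """Mean attention entropy per (layer, head, query gene), in nats."""

    values: np.ndarray  # (L, H, G)
    gene_names: list[str]

    def max_entropy(self) -> float:
        return float(np.log(len(self.gene_names) - 1))


def entropy_profile(params: TGEMParams, X: np.ndarray, chunk: int = 64) -> EntropyProfile:
    """Forward all samples and average per-query-gene attention entropies."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    L, H, G = params.n_layers, params.n_heads, params.n_genes
    totals = np.zeros((L, H, G))
    for start in range(0, X.shape[0], chunk):
        _, _, caches = forward_batch(X[start : start + chunk], params)
        for li, cache in enumerate(caches["layers"]):
            A = cache["A"]  # (n, H, G, G)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(A > 0, A * np.log(A), 0.0)
            totals[li] += -term.sum(axis=-1).sum(axis=0)
    return EntropyProfile(values=totals / X.shape[0], gene_names=list(params.gene_names))


# ---------------------------------------------------------------------------
# integrated gradients over attention weights

@dataclass
class AttributionMatrix:
    """Integrated-gradients scores of attention weights for one layer/class.

    ``scores[g, i]`` attributes the class logit to the attention that
    Query gene ``g`` pays Key gene ``i``, averaged over heads and samples;
    the baseline is zero attention, so the diagonal is exactly 0.
    """

    scores: np.ndarray  # (G, G)
    layer: int
    class_label: int
    n_ig_steps: int
    gene_names: list[str]
    baseline: float = 0.0


def _quadrature(n_steps: int, rule: str) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights integrating over the path parameter on [0, 1]."""
    if rule == "gausslegendre":
        x, w = np.polynomial.legendre.leggauss(n_steps)
        return 0.5 * (x + 1.0), 0.5 * w
    if rule == "left":
        return np.arange(n_steps) / n_steps, np.full(n_steps, 1.0 / n_steps)
    if rule == "trapezoid":
        alphas = np.linspace(0.0, 1.0, n_steps + 1)
        weights = np.full(n_steps + 1, 1.0 / n_steps)
        weights[0] = weights[-1] = 0.5 / n_steps
        return alphas, weights
    raise ValueError("rule must be 'gausslegendre', 'left' or 'trapezoid'")


def ig_attribution(
    params: TGEMParams,
    X_class: np.ndarray,
    layer: int,
    target_class: int,
    n_steps: int = 50,
    rule: str = "gausslegendre",
    chunk: int = 16,
) -> AttributionMatrix:
    """Attribute the target-class logit to a layer's attention weights.

    The attention tensor computed at the true input is scaled by alpha
    along the straight line from the zero baseline, with Values and all
    other quantities fixed; the path integral of the logit gradient is
    approximated by an ``n_steps``-point quadrature and multiplied
    elementwise by the attention weights.  Scores are averaged over
    heads, then over samples.

    ``rule`` selects the quadrature: "gausslegendre" (default; the layer
    norm applied to the mixed head output makes the integrand steep near
    the zero-attention baseline, which fixed-step Riemann sums resolve
    poorly), "left", or "trapezoid".
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not 0 <= layer < params.n_layers:
        raise IndexError(f"layer {layer} out of range")
    X_class = np.asarray(X_class, dtype=float)
    if X_class.shape[0] < 1:
        raise ValueError("need at least one sample of the target class")
    G = params.n_genes
    total = np.zeros((G, G))
    n_total = 0
    alphas, weights = _quadrature(n_steps, rule)
    for start in range(0, X_class.shape[0], chunk):
        Xb = X_class[start : start + chunk]
        _, _, caches = forward_batch(Xb, params)
        A = caches["layers"][layer]["A"]  # (n, H, G, G)
        grad_sum = np.zeros_like(A)
        for alpha, w in zip(alphas, weights):
            _, _, c_alpha = forward_batch(
                Xb, params, attention_override=(layer, alpha * A)
            )
            dA = logit_grad_wrt_attention(params, c_alpha, target_class, layer)
            if not np.all(np.isfinite(dA)):
                raise FloatingPointError(
                    f"non-finite attribution gradient at alpha={alpha:.4f}"
                )
            grad_sum += w * dA
        ig = A * grad_sum  # (n, H, G, G)
        total += ig.mean(axis=1).sum(axis=0)
        n_total += Xb.shape[0]
    return AttributionMatrix(
        scores=total / n_total,
        layer=layer,
        class_label=target_class,
        n_ig_steps=n_steps,
        gene_names=list(params.gene_names),
    )


def ig_completeness_gap(
    params: TGEMParams, x: np.ndarray, layer: int, target_class: int, n_steps: int = 200,
    rule: str = "gausslegendre",
) -> tuple[float, float]:
    """(sum of attributions, F(a) - F(0)) for one sample; diagnostic for
    the quality of the path-integral approximation."""
    x = np.asarray(x, dtype=float)[None, :]
    attr = ig_attribution(params, x, layer, target_class, n_steps=n_steps, rule=rule)
    _, logits_a, caches = forward_batch(x, params)
    A = caches["layers"][layer]["A"]
    _, logits_0, _ = forward_batch(x, params, attention_override=(layer, 0.0 * A))
    # attribution matrix averaged over heads: total = mean over heads of sums,
    # so multiply back by H to compare with the logit difference
    total = attr.scores.sum() * params.n_heads
    delta = float(logits_a[0, target_class] - logits_0[0, target_class])
    return float(total), delta


# ---------------------------------------------------------------------------
# pruning

@dataclass
class PruneResult:
    layer: int
    head: int | None  # None = whole layer
    accuracy_after: float
    accuracy_drop: float


def prune_head(params: TGEMParams, layer: int, head: int) -> TGEMParams:
    """Copy of the model with one head's mixing weight zeroed."""
    if not 0 <= layer < params.n_layers:
        raise IndexError(f"layer {layer} out of range")
    if not 0 <= head < params.layers[layer].n_heads:
        raise IndexError(f"head {head} out of range for layer {layer}")
    pruned = params.copy()
    pruned.layers[layer].head_mix[head] = 0.0
    return pruned


def prune_layer(params: TGEMParams, layer: int) -> TGEMParams:
    """Copy of the model with every head of one layer zeroed out."""
    if not 0 <= layer < params.n_layers:
        raise IndexError(f"layer {layer} out of range")
    pruned = params.copy()
    pruned.layers[layer].head_mix[:] = 0.0
    return pruned


def prune_scan(
    params: TGEMParams, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, list[PruneResult]]:
    """Accuracy after pruning each layer and each (layer, head) in turn.

    Returns the unpruned reference accuracy and L + L*H prune results with
    ``accuracy_drop = reference - accuracy_after``.
    """
    if X_test.shape[0] < 1:
        raise ValueError("empty test set")
    reference = accuracy_of(params, X_test, y_test)
    results: list[PruneResult] = []
    for li in range(params.n_layers):
        acc = accuracy_of(prune_layer(params, li), X_test, y_test)
        results.append(PruneResult(li, None, acc, reference - acc))
        for h in range(params.layers[li].n_heads):
            acc = accuracy_of(prune_head(params, li, h), X_test, y_test)
            results.append(PruneResult(li, h, acc, reference - acc))
    return reference, results


# ---------------------------------------------------------------------------
# representations and probe classifiers

def layer_representations(params: TGEMParams, X: np.ndarray) -> list[np.ndarray]:
    """Per-layer outputs z_l (after skip connection) for each sample."""
    _, _, caches = forward_batch(np.asarray(X, dtype=float), params)
    reps = []
    for li, cache in enumerate(caches["layers"]):
        if li + 1 < len(caches["layers"]):
            reps.append(caches["layers"][li + 1]["X"])
        else:
            reps.append(caches["Z_last"])
    return reps


def head_representations(params: TGEMParams, X: np.ndarray, layer: int) -> np.ndarray:
    """Head outputs before the skip connection: (N, H, G) tensor."""
    _, _, caches = forward_batch(np.asarray(X, dtype=float), params)
    return caches["layers"][layer]["Zh"]


def probe_classifier(
    train_repr: np.ndarray,
    y_train: np.ndarray,
    test_repr: np.ndarray,
    y_test: np.ndarray,
    C: float = 1.0,
    seed: int = 0,
) -> float:
    """Linear max-margin probe (one-vs-rest) on fixed representations."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("probe training set contains a single class")
    clf = LinearSVC(C=C, random_state=seed)
    clf.fit(train_repr, y_train)
    return float(np.mean(clf.predict(test_repr) == y_test))


def probe_scan(
    params: TGEMParams,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> list[dict]:
    """Probe accuracy for every layer output and every head output."""
    rows: list[dict] = []
    train_layers = layer_representations(params, X_train)
    test_layers = layer_representations(params, X_test)
    for li in range(params.n_layers):
        acc = probe_classifier(train_layers[li], y_train, test_layers[li], y_test, seed=seed)
        rows.append({"layer": li, "head": None, "probe_acc": acc})
        zh_train = head_representations(params, X_train, li)
        zh_test = head_representations(params, X_test, li)
        for h in range(params.layers[li].n_heads):
            acc = probe_classifier(zh_train[:, h], y_train, zh_test[:, h], y_test, seed=seed)
            rows.append({"layer": li, "head": h, "probe_acc": acc})
    return rows
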