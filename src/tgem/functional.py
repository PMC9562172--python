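"""Forward and backward computation for gene-wise scalar self-attention.

The batched routines are the workhorses: inputs are ``(N, G)`` matrices of
normalized log expression, attention is materialized as ``(N, H, G, G)``
row-stochastic tensors with an exactly-zero diagonal (a gene never attends
to itself), and the analytic backward pass supplies gradients for Adam
training and for attributing class logits to attention weights.  The
scalar/single-sample functions mirror the same algebra one gene at a time
and serve as the readable reference for the vectorized code.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .params import HeadParams, LayerParams, TGEMParams

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# activations

def activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "gelu":
        return 0.5 * z * (1.0 + erf(z / _SQRT2))
    raise ValueError(f"unknown activation {kind!r}")


def activate_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "gelu":
        return 0.5 * (1.0 + erf(z / _SQRT2)) + z * np.exp(-0.5 * z * z) * _INV_SQRT2PI
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# single-sample / single-gene reference operations

def compute_qkv(x: np.ndarray, head: HeadParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar Query/Key/Value projections: elementwise products with x."""
    x = np.asarray(x, dtype=float)
    if x.shape != head.wq.shape:
        raise ValueError(
            f"expression vector has length {x.shape[0] if x.ndim == 1 else x.shape}, "
            f"head weights have length {head.wq.shape[0]}"
        )
    return head.wq * x, head.wk * x, head.wv * x


def attention_weights(q: np.ndarray, k: np.ndarray, g: int) -> np.ndarray:
    """Attention of Query gene ``g`` over the other ``G-1`` Key genes.

    Logits are the products ``q_g * k_i`` for ``i != g``; the result is
    their softmax (max-subtracted for stability), a length ``G-1``
    probability vector.
    """
    q = np.asarray(q, dtype=float)
    k = np.asarray(k, dtype=float)
    G = q.shape[0]
    if G < 2:
        raise ValueError("attention needs at least 2 genes (no Key genes to attend to)")
    if not 0 <= g < G:
        raise IndexError(f"query gene index {g} out of range for G={G}")
    logits = q[g] * np.delete(k, g)
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def head_representation(a_g: np.ndarray, v_minus_g: np.ndarray) -> float:
    """Attention-weighted combination of the other genes' Values."""
    a_g = np.asarray(a_g, dtype=float)
    v_minus_g = np.asarray(v_minus_g, dtype=float)
    if a_g.shape != v_minus_g.shape:
        raise ValueError("attention vector and value vector lengths differ")
    return float(a_g @ v_minus_g)


def layer_norm(m: np.ndarray, gain: np.ndarray, bias: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Layer normalization over the gene (last) dimension."""
    mu = m.mean(axis=-1, keepdims=True)
    var = m.var(axis=-1, keepdims=True)
    return gain * (m - mu) / np.sqrt(var + eps) + bias


def layer_forward(
    x_in: np.ndarray, layer: LayerParams, layer_norm_on: bool = True, eps: float = 1e-5
) -> tuple[np.ndarray, np.ndarray]:
    """One attention layer on a single sample.

    Returns the layer output (input plus layer-normalized head mixture)
    and the per-head ``(H, G, G)`` attention tensor.
    """
    out, cache = _layer_forward_batch(
        np.asarray(x_in, dtype=float)[None, :], layer, layer_norm_on=layer_norm_on, eps=eps
    )
    return out[0], cache["A"][0]


def forward(
    x, params: TGEMParams, gene_names: list[str] | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Class probabilities and per-layer attention for one sample.

    ``x`` may be a plain vector or an :class:`~tgem.data.ExpressionSample`;
    gene names, when available, must match the model's order and the first
    mismatch is named in the error.
    """
    if hasattr(x, "gene_names") and gene_names is None:
        gene_names = list(x.gene_names)
        x = x.values
    if gene_names is not None:
        check_gene_alignment(gene_names, params.gene_names)
    probs, _, caches = forward_batch(np.asarray(x, dtype=float)[None, :], params)
    attention = [c["A"][0] for c in caches["layers"]]
    return probs[0], attention


def check_gene_alignment(given: list[str], expected: list[str]) -> None:
    if list(given) == list(expected):
        return
    if len(given) != len(expected):
        raise ValueError(
            f"gene list length {len(given)} does not match model's {len(expected)}"
        )
    for i, (a, b) in enumerate(zip(given, expected)):
        if a != b:
            raise ValueError(
                f"gene name mismatch at position {i}: got {a!r}, model expects {b!r}"
            )


# ---------------------------------------------------------------------------
# batched forward / backward

def _layer_forward_batch(
    X: np.ndarray,
    lp: LayerParams,
    attention_override: np.ndarray | None = None,
    layer_norm_on: bool = True,
    eps: float = 1e-5,
) -> tuple[np.ndarray, dict]:
    """One layer on an ``(N, G)`` batch; caches intermediates for backward.

    ``attention_override`` replaces the computed attention tensor (used for
    integrated-gradients paths, where scaled sub-stochastic attention is
    fed through the otherwise-fixed downstream computation).
    """
    N, G = X.shape
    if G < 2:
        raise ValueError("attention needs at least 2 genes")
    Q = np.einsum("ng,hg->nhg", X, lp.wq)
    K = np.einsum("ng,hg->nhg", X, lp.wk)
    V = np.einsum("ng,hg->nhg", X, lp.wv)
    logits = Q[:, :, :, None] * K[:, :, None, :]
    ii = np.arange(G)
    logits[:, :, ii, ii] = -np.inf
    logits -= logits.max(axis=-1, keepdims=True)
    E = np.exp(logits)
    A = E / E.sum(axis=-1, keepdims=True)  # (N, H, G, G), zero diagonal
    A_used = A if attention_override is None else attention_override
    Zh = np.einsum("nhgi,nhi->nhg", A_used, V)
    M = np.einsum("nhg,h->ng", Zh, lp.head_mix)
    if layer_norm_on:
        mu = M.mean(axis=-1, keepdims=True)
        var = M.var(axis=-1, keepdims=True)
        s = np.sqrt(var + eps)
        Mhat = (M - mu) / s
        Y = lp.ln_gain * Mhat + lp.ln_bias
    else:
        s = Mhat = None
        Y = M
    out = X + Y
    cache = {
        "X": X, "Q": Q, "K": K, "V": V, "A": A, "A_used": A_used,
        "Zh": Zh, "M": M, "s": s, "Mhat": Mhat,
        "override": attention_override is not None, "ln": layer_norm_on,
    }
    return out, cache


def _layer_backward_batch(
    dout: np.ndarray, lp: LayerParams, cache: dict, stop_at_attention: bool = False
) -> tuple[np.ndarray | None, dict | None, np.ndarray | None]:
    """Backward through one layer.

    Returns ``(dX, grads, dA)``.  With ``stop_at_attention`` the gradient
    is taken with respect to the attention tensor actually used (treating
    Values and everything upstream as fixed) and ``dX``/``grads`` are None.
    """
    X, V, A_used, Zh = cache["X"], cache["V"], cache["A_used"], cache["Zh"]
    # layer norm backward (over gene axis)
    dY = dout
    if cache["ln"]:
        Mhat, s = cache["Mhat"], cache["s"]
        dgain = np.sum(dY * Mhat, axis=0)
        dbias = np.sum(dY, axis=0)
        dMhat = dY * lp.ln_gain
        dM = (
            dMhat
            - dMhat.mean(axis=-1, keepdims=True)
            - Mhat * (dMhat * Mhat).mean(axis=-1, keepdims=True)
        ) / s
    else:
        dgain = np.zeros_like(lp.ln_gain)
        dbias = np.zeros_like(lp.ln_bias)
        dM = dY
    dZh = dM[:, None, :] * lp.head_mix[None, :, None]
    dA = np.einsum("nhg,nhi->nhgi", dZh, V)
    if stop_at_attention:
        return None, None, dA
    dmix = np.einsum("nhg,ng->h", Zh, dM)
    dV = np.einsum("nhgi,nhg->nhi", A_used, dZh)
    if cache["override"]:
        dL = None
        dQ = np.zeros_like(cache["Q"])
        dK = np.zeros_like(cache["K"])
    else:
        A = cache["A"]
        dL = A * (dA - np.sum(A * dA, axis=-1, keepdims=True))
        dQ = np.einsum("nhgi,nhi->nhg", dL, cache["K"])
        dK = np.einsum("nhgi,nhg->nhi", dL, cache["Q"])
    dwq = np.einsum("nhg,ng->hg", dQ, X)
    dwk = np.einsum("nhg,ng->hg", dK, X)
    dwv = np.einsum("nhg,ng->hg", dV, X)
    # skip connection contributes dout once; Q/K/V paths once per head
    dX = (
        dout
        + np.einsum("nhg,hg->ng", dQ, lp.wq)
        + np.einsum("nhg,hg->ng", dK, lp.wk)
        + np.einsum("nhg,hg->ng", dV, lp.wv)
    )
    grads = {"wq": dwq, "wk": dwk, "wv": dwv, "head_mix": dmix, "ln_gain": dgain, "ln_bias": dbias}
    return dX, grads, None


def forward_batch(
    X: np.ndarray,
    params: TGEMParams,
    attention_override: tuple[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Full forward pass on an ``(N, G)`` batch.

    Returns ``(class_probs, logits, caches)``.  ``attention_override`` is a
    ``(layer_index, tensor)`` pair substituting that layer's attention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (N, G)")
    if X.shape[1] != params.n_genes:
        raise ValueError(f"X has {X.shape[1]} genes, model expects {params.n_genes}")
    caches: dict = {"layers": []}
    Z = X
    for li, lp in enumerate(params.layers):
        override = None
        if attention_override is not None and attention_override[0] == li:
            override = attention_override[1]
        Z, cache = _layer_forward_batch(
            Z, lp, attention_override=override,
            layer_norm_on=params.layer_norm, eps=params.ln_eps,
        )
        caches["layers"].append(cache)
    clf = params.classifier
    Zact = activate(Z, clf.activation)
    logits = Zact @ clf.weight.T + clf.bias
    shifted = logits - logits.max(axis=-1, keepdims=True)
    E = np.exp(shifted)
    probs = E / E.sum(axis=-1, keepdims=True)
    caches["Z_last"] = Z
    caches["Zact"] = Zact
    caches["probs"] = probs
    return probs, logits, caches


def backward_batch(
    params: TGEMParams, caches: dict, dlogits: np.ndarray
) -> tuple[list[dict], dict, np.ndarray]:
    """Gradients of a scalar objective given its gradient w.r.t. the logits.

    Returns per-layer gradient dicts (input to output order), classifier
    gradients, and the gradient w.r.t. the input batch.
    """
    clf = params.classifier
    Zact, Z_last = caches["Zact"], caches["Z_last"]
    dW = dlogits.T @ Zact
    db = dlogits.sum(axis=0)
    dZact = dlogits @ clf.weight
    dZ = dZact * activate_grad(Z_last, clf.activation)
    layer_grads: list[dict | None] = [None] * len(params.layers)
    for li in range(len(params.layers) - 1, -1, -1):
        dZ, grads, _ = _layer_backward_batch(dZ, params.layers[li], caches["layers"][li])
        layer_grads[li] = grads
    return layer_grads, {"weight": dW, "bias": db}, dZ


def logit_grad_wrt_attention(
    params: TGEMParams,
    caches: dict,
    target_class: int,
    layer: int,
) -> np.ndarray:
    """Gradient of the target-class logit w.r.t. ``layer``'s attention tensor.

    Backpropagates through the classifier and all layers above ``layer``,
    then stops at the attention weights themselves (Values fixed).
    """
    dlogits = np.zeros_like(caches["probs"])
    dlogits[:, target_class] = 1.0
    clf = params.classifier
    dZact = dlogits @ clf.weight
    dZ = dZact * activate_grad(caches["Z_last"], clf.activation)
    for li in range(len(params.layers) - 1, layer, -1):
        dZ, _, _ = _layer_backward_batch(dZ, params.layers[li], caches["layers"][li])
    _, _, dA = _layer_backward_batch(
        dZ, params.layers[layer], caches["layers"][layer], stop_at_attention=True
    )
    return dA


def nll_loss_and_grad(
    logits: np.ndarray, probs: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood of the true class and its logit gradient."""
    N = logits.shape[0]
    shifted = logits - logits.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=-1))
    loss = float(np.mean(logZ - shifted[np.arange(N), labels]))
    dlogits = probs.copy()
    dlogits[np.arange(N), labels] -= 1.0
    dlogits /= N
    return loss, dlogits


def predict_proba(params: TGEMParams, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Class probabilities in memory-bounded chunks."""
    X = np.asarray(X, dtype=float)
    out = np.empty((X.shape[0], params.n_classes))
    for start in range(0, X.shape[0], chunk):
        probs, _, _ = forward_batch(X[start : start + chunk], params)
        out[start : start + chunk] = probs
    return out
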