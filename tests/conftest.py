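"""Shared fixtures and an independent explicit-loop reference model.

The oracle below recomputes the forward pass with plain Python loops and
``math`` scalars, sharing no code with the vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tgem.params import TGEMParams, init_params


def oracle_forward(params: TGEMParams, x: np.ndarray) -> np.ndarray:
    """Triple-loop forward pass: returns class probabilities."""
    G = params.n_genes
    z = [float(v) for v in x]
    for lp in params.layers:
        H = lp.n_heads
        Z = [[0.0] * G for _ in range(H)]
        for h in range(H):
            q = [lp.wq[h][g] * z[g] for g in range(G)]
            k = [lp.wk[h][g] * z[g] for g in range(G)]
            v = [lp.wv[h][g] * z[g] for g in range(G)]
            for g in range(G):
                logits = [q[g] * k[i] for i in range(G) if i != g]
                mx = max(logits)
                exps = [math.exp(l - mx) for l in logits]
                s = sum(exps)
                a = [e / s for e in exps]
                others = [v[i] for i in range(G) if i != g]
                Z[h][g] = sum(ai * vi for ai, vi in zip(a, others))
        m = [sum(lp.head_mix[h] * Z[h][g] for h in range(H)) for g in range(G)]
        if params.layer_norm:
            mu = sum(m) / G
            var = sum((mi - mu) ** 2 for mi in m) / G
            sd = math.sqrt(var + params.ln_eps)
            y = [lp.ln_gain[g] * (m[g] - mu) / sd + lp.ln_bias[g] for g in range(G)]
        else:
            y = m
        z = [z[g] + y[g] for g in range(G)]
    act = params.classifier.activation
    if act == "relu":
        phi = [max(zi, 0.0) for zi in z]
    elif act == "gelu":
        phi = [0.5 * zi * (1.0 + math.erf(zi / math.sqrt(2))) for zi in z]
    else:
        phi = z
    W, b = params.classifier.weight, params.classifier.bias
    logits = [sum(W[c][g] * phi[g] for g in range(len(phi))) + b[c] for c in range(len(b))]
    mx = max(logits)
    exps = [math.exp(l - mx) for l in logits]
    s = sum(exps)
    return np.array([e / s for e in exps])


def random_model(
    rng: np.ndarray, G: int, C: int = 3, L: int = 1, H: int = 2,
    activation: str = "none", scale: float = 0.4, layer_norm: bool = True,
) -> TGEMParams:
    """Randomly perturbed initialized model (non-trivial attention)."""
    params = init_params(
        [f"g{i}" for i in range(G)], [f"c{i}" for i in range(C)],
        n_layers=L, n_heads=H, activation=activation, layer_norm=layer_norm,
        seed=int(rng.integers(0, 2**31)),
    )
    for lp in params.layers:
        for name in ("wq", "wk", "wv", "head_mix", "ln_gain"):
            arr = getattr(lp, name)
            arr += rng.normal(scale=scale, size=arr.shape)
    params.classifier.weight += rng.normal(scale=scale, size=params.classifier.weight.shape)
    params.classifier.bias += rng.normal(scale=scale, size=params.classifier.bias.shape)
    return params


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, quickly trainable 3-class dataset with strong markers."""
    from tgem import SimulationSpec, simulate

    spec = SimulationSpec(
        n_classes=3, n_genes=40, n_samples_per_class=60,
        n_markers_per_class=6, marker_effect=3.0, seed=11,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def trained_tiny(tiny_dataset):
    """A model fitted on the tiny dataset (shared across tests)."""
    from tgem import TGEM

    ds, gt = tiny_dataset
    res = TGEM(ds, n_layers=1, n_heads=2, seed=3).fit(epochs=30, learning_rate=1e-3)
    return res, gt
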