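"""Parameter containers for gene-wise scalar self-attention models.

Every gene carries its own scalar Query/Key/Value weight per head, so a
layer with ``H`` heads over ``G`` genes holds three ``(H, G)`` weight
matrices, an ``H``-vector mixing the heads, and a gene-wise layer-norm
gain/bias pair.  A dense ``C x G`` affine readout maps the last layer's
representation to class logits.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

ACTIVATIONS = ("none", "relu", "gelu")


@dataclass
class HeadParams:
    """Per-gene scalar Query/Key/Value weights of one attention head."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray

    def __post_init__(self) -> None:
        self.wq = np.asarray(self.wq, dtype=float)
        self.wk = np.asarray(self.wk, dtype=float)
        self.wv = np.asarray(self.wv, dtype=float)
        if not (self.wq.shape == self.wk.shape == self.wv.shape) or self.wq.ndim != 1:
            raise ValueError("wq, wk, wv must be 1-D vectors of equal length")
        for name in ("wq", "wk", "wv"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_genes(self) -> int:
        return self.wq.shape[0]


@dataclass
class LayerParams:
    """One attention layer: stacked head weights plus mixing and layer norm.

    ``wq``, ``wk``, ``wv`` are ``(H, G)``; ``head_mix`` is the length-``H``
    vector combining head outputs; ``ln_gain``/``ln_bias`` parameterize the
    layer normalization over the gene dimension.
    """

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    head_mix: np.ndarray
    ln_gain: np.ndarray
    ln_bias: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wq", "wk", "wv", "head_mix", "ln_gain", "ln_bias"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.wq.ndim != 2 or self.wq.shape != self.wk.shape or self.wq.shape != self.wv.shape:
            raise ValueError("wq, wk, wv must be (H, G) arrays of equal shape")
        h, g = self.wq.shape
        if h < 1:
            raise ValueError("a layer needs at least one head")
        if self.head_mix.shape != (h,):
            raise ValueError(f"head_mix must have length H={h}")
        if self.ln_gain.shape != (g,) or self.ln_bias.shape != (g,):
            raise ValueError(f"ln_gain/ln_bias must have length G={g}")

    @classmethod
    def from_heads(
        cls,
        heads: list[HeadParams],
        head_mix: np.ndarray,
        ln_gain: np.ndarray,
        ln_bias: np.ndarray,
    ) -> "LayerParams":
        return cls(
            wq=np.stack([h.wq for h in heads]),
            wk=np.stack([h.wk for h in heads]),
            wv=np.stack([h.wv for h in heads]),
            head_mix=head_mix,
            ln_gain=ln_gain,
            ln_bias=ln_bias,
        )

    @property
    def heads(self) -> list[HeadParams]:
        return [HeadParams(self.wq[h], self.wk[h], self.wv[h]) for h in range(self.n_heads)]

    @property
    def n_heads(self) -> int:
        return self.wq.shape[0]

    @property
    def n_genes(self) -> int:
        return self.wq.shape[1]


@dataclass
class ClassifierParams:
    """Dense affine readout applied after the activation ``phi``."""

    weight: np.ndarray
    bias: np.ndarray
    activation: str = "none"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weight.ndim != 2:
            raise ValueError("classifier weight must be (C, G)")
        c = self.weight.shape[0]
        if c < 2:
            raise ValueError("classifier needs at least 2 classes")
        if self.bias.shape != (c,):
            raise ValueError("classifier bias must have length C")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")

    @property
    def n_classes(self) -> int:
        return self.weight.shape[0]


@dataclass
class TGEMParams:
    """Full parameter set: attention layers, classifier, and name metadata."""

    layers: list[LayerParams]
    classifier: ClassifierParams
    gene_names: list[str]
    class_names: list[str]
    layer_norm: bool = True
    ln_eps: float = 1e-5

    def __post_init__(self) -> None:
        g = len(self.gene_names)
        if len(set(self.gene_names)) != g:
            raise ValueError("gene names must be unique")
        for i, lp in enumerate(self.layers):
            if lp.n_genes != g:
                raise ValueError(f"layer {i} has {lp.n_genes} genes, expected {g}")
        if self.classifier.weight.shape[1] != g:
            raise ValueError("classifier weight width must equal G")
        if len(self.class_names) != self.classifier.n_classes:
            raise ValueError("class_names length must equal number of classes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_heads(self) -> int:
        return self.layers[0].n_heads if self.layers else 0

    def copy(self) -> "TGEMParams":
        return copy.deepcopy(self)


def parameter_count(params: TGEMParams) -> int:
    """Total number of learnable scalars in the model.

    Each layer contributes ``3*G*H`` attention weights, ``H`` mixing
    weights, and ``2*G`` layer-norm parameters; the readout adds ``C*G + C``.
    """
    n = 0
    for lp in params.layers:
        h, g = lp.n_heads, lp.n_genes
        if h < 1:
            raise ValueError("layer with zero heads")
        n += 3 * g * h + h + 2 * g
    c, g = params.classifier.weight.shape
    n += c * g + c
    return n


def init_params(
    gene_names: list[str],
    class_names: list[str],
    n_layers: int = 1,
    n_heads: int = 2,
    activation: str = "none",
    layer_norm: bool = True,
    seed: int = 0,
) -> TGEMParams:
    """Seeded random initialization.

    Per-gene Q/K/V weights are uniform on ``[-1/sqrt(G), 1/sqrt(G)]``,
    head-mixing weights start at ``1/H`` so heads contribute equally, layer
    norm starts as the identity (gain 1, bias 0), and the readout uses the
    same fan-in scaling with zero bias.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if n_heads < 1:
        raise ValueError("need at least one head")
    rng = np.random.default_rng(seed)
    g, c = len(gene_names), len(class_names)
    scale = 1.0 / np.sqrt(g)
    layers = []
    for _ in range(n_layers):
        layers.append(
            LayerParams(
                wq=rng.uniform(-scale, scale, size=(n_heads, g)),
                wk=rng.uniform(-scale, scale, size=(n_heads, g)),
                wv=rng.uniform(-scale, scale, size=(n_heads, g)),
                head_mix=np.full(n_heads, 1.0 / n_heads),
                ln_gain=np.ones(g),
                ln_bias=np.zeros(g),
            )
        )
    classifier = ClassifierParams(
        weight=rng.uniform(-scale, scale, size=(c, g)),
        bias=np.zeros(c),
        activation=activation,
    )
    return TGEMParams(
        layers=layers,
        classifier=classifier,
        gene_names=list(gene_names),
        class_names=list(class_names),
        layer_norm=layer_norm,
    )


def flatten_params(params: TGEMParams) -> list[np.ndarray]:
    """Ordered list of the parameter arrays (views, not copies)."""
    arrays: list[np.ndarray] = []
    for lp in params.layers:
        arrays.extend([lp.wq, lp.wk, lp.wv, lp.head_mix, lp.ln_gain, lp.ln_bias])
    arrays.extend([params.classifier.weight, params.classifier.bias])
    return arrays
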