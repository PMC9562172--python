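"""Synthetic multi-class expression data with planted ground truth.

The generator emulates the situation the model is built for: a samples x
genes matrix of non-negative continuous expression where each class is
distinguished by a disjoint set of marker genes (a mean shift in log
space) and genes belong to correlated co-expression modules (a shared
latent factor per module).  Expression is produced on a log-normal scale
so the standard log + min-max preprocessing is exercised end to end.

Defaults: 3 classes of 300 samples over 200 genes, 20 markers per class
shifted by 2 noise standard deviations, one rho=0.5 module per marker set
plus two neutral modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset, GeneSetCollection


@dataclass
class SimulationSpec:
    n_classes: int = 3
    n_genes: int = 200
    n_samples_per_class: int = 300
    n_markers_per_class: int = 20
    marker_effect: float = 2.0  # mean shift in units of noise_sd, log scale
    module_spec: list[tuple[str, list[str], float]] | None = None
    noise_sd: float = 0.5  # log2-scale within-gene standard deviation
    baseline_mean: float = 3.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("marker sets exceed the gene universe")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def marker_map(self) -> dict[int, list[str]]:
        """Class -> planted marker genes (disjoint blocks at the front)."""
        names = self.gene_names
        k = self.n_markers_per_class
        return {c: names[c * k : (c + 1) * k] for c in range(self.n_classes)}

    def modules(self) -> list[tuple[str, list[str], float]]:
        """Module spec; by default one rho=0.5 module per marker set plus
        two neutral modules over non-marker genes."""
        if self.module_spec is not None:
            return self.module_spec
        names = self.gene_names
        markers = self.marker_map()
        mods = [
            (f"module_markers_c{c}", list(markers[c]), 0.5) for c in markers
        ]
        free = names[self.n_classes * self.n_markers_per_class :]
        size = min(15, max(2, len(free) // 2))
        for j in range(2):
            chunk = free[j * size : (j + 1) * size]
            if len(chunk) >= 2:
                mods.append((f"module_neutral_{j}", chunk, 0.5))
        return mods


def simulate(spec: SimulationSpec) -> tuple[ExpressionDataset, dict]:
    """Draw a dataset from the spec; returns (dataset, ground_truth).

    Log2 expression is baseline + module factor + class marker shift +
    noise; raw expression is 2**log2, strictly positive.  Ground truth
    maps classes to marker genes and modules to members/correlation.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.gene_names
    gene_index = {g: i for i, g in enumerate(names)}
    markers = spec.marker_map()
    all_markers = [g for c in sorted(markers) for g in markers[c]]
    if len(set(all_markers)) != len(all_markers):
        raise ValueError("marker sets overlap across classes")
    modules = spec.modules()
    for _, members, rho in modules:
        unknown = set(members) - set(names)
        if unknown:
            raise ValueError(f"module members outside gene universe: {sorted(unknown)}")
        if not 0 <= rho < 1:
            raise ValueError("module correlation must be in [0, 1)")

    n = spec.n_classes * spec.n_samples_per_class
    g = spec.n_genes
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=g)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_samples_per_class)

    log_expr = np.tile(baseline, (n, 1))
    # shared latent factor per module: corr(rho) between members
    load = np.zeros(g)
    factor_of = np.full(g, -1)
    for mi, (_, members, rho) in enumerate(modules):
        idx = [gene_index[m] for m in members]
        load[idx] = np.sqrt(rho)
        factor_of[idx] = mi
    factors = rng.normal(size=(n, len(modules)))
    eps = rng.normal(size=(n, g))
    shared = np.where(factor_of >= 0, load, 0.0)
    resid = np.sqrt(1.0 - shared**2)
    noise = eps * resid
    noise[:, factor_of >= 0] += factors[:, factor_of[factor_of >= 0]] * load[factor_of >= 0]
    log_expr += spec.noise_sd * noise
    for c, genes in markers.items():
        idx = [gene_index[m] for m in genes]
        log_expr[np.ix_(labels == c, idx)] += spec.marker_effect * spec.noise_sd

    matrix = np.exp2(log_expr)
    dataset = ExpressionDataset(
        matrix=matrix,
        gene_names=names,
        sample_ids=[f"S{i:05d}" for i in range(n)],
        labels=labels,
        class_names=[f"class{c}" for c in range(spec.n_classes)],
    )
    ground_truth = {
        "markers": {int(c): list(v) for c, v in markers.items()},
        "modules": [
            {"name": name, "members": list(members), "rho": float(rho)}
            for name, members, rho in modules
        ],
        "marker_shift_log2": spec.marker_effect * spec.noise_sd,
        "seed": spec.seed,
    }
    return dataset, ground_truth


def make_geneset_collection(
    ground_truth: dict,
    universe: list[str],
    n_decoys: int = 5,
    seed: int = 0,
) -> GeneSetCollection:
    """Genesets from the planted structure plus size-matched random decoys.

    One set per marker class and per module, then ``n_decoys`` sets drawn
    without replacement from non-marker genes with sizes cycling through
    the real sets' sizes.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for c, genes in sorted(ground_truth["markers"].items()):
        sets[f"markers_class{c}"] = list(genes)
    for mod in ground_truth["modules"]:
        sets[mod["name"]] = list(mod["members"])
    marker_genes = {g for genes in ground_truth["markers"].values() for g in genes}
    pool = [g for g in universe if g not in marker_genes]
    sizes = [len(v) for v in sets.values()]
    for j in range(n_decoys):
        size = sizes[j % len(sizes)]
        size = min(size, len(pool))
        pick = rng.choice(len(pool), size=size, replace=False)
        sets[f"decoy_{j}"] = sorted(pool[i] for i in pick)
    return GeneSetCollection(sets=sets, universe=list(universe))
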