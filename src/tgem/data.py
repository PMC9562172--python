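"""Core in-memory containers: labeled expression matrices and geneset collections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionSample:
    """One sample's normalized log expression vector with gene names."""

    values: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != len(self.gene_names):
            raise ValueError("values and gene_names must have equal length")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")


@dataclass
class ExpressionDataset:
    """Samples x genes expression with per-sample integer class labels.

    ``matrix`` holds raw non-negative expression (before log/min-max
    preprocessing); ``labels`` are integers in ``[0, C)`` indexing
    ``class_names``.
    """

    matrix: np.ndarray
    gene_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, g = self.matrix.shape
        if len(self.gene_names) != g:
            raise ValueError("gene_names length does not match matrix width")
        if len(self.sample_ids) != n or self.labels.shape != (n,):
            raise ValueError("sample_ids/labels length does not match matrix height")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_names)) != g:
            raise ValueError("duplicate gene names")
        c = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ValueError("labels out of range for class_names")
        counts = np.bincount(self.labels, minlength=c)
        if np.any(counts == 0):
            missing = [self.class_names[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"classes with no samples: {missing}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_names=list(self.gene_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            gene_names=[self.gene_names[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            class_names=list(self.class_names),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.gene_names)


@dataclass
class GeneSetCollection:
    """Named genesets over a gene universe.

    Set members need not all lie in the universe; enrichment statistics use
    the intersection with the universe.
    """

    sets: dict[str, list[str]]
    universe: list[str]

    def restricted(self, name: str) -> list[str]:
        """Members of a set intersected with the universe, universe order."""
        members = set(self.sets[name])
        return [g for g in self.universe if g in members]

    def __len__(self) -> int:
        return len(self.sets)
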