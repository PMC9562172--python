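"""Expression preprocessing: log transform, per-gene min-max scaling,
highly-variable-gene selection, and stratified data splitting.

The scaling statistics are fit on the training split only and reused
(with clipping) for validation and test data, so no information leaks
across splits; a strict-replication flag allows fitting on the full
matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset

LOG_BASES = ("log2p1", "ln1p")


@dataclass
class PreprocessStats:
    """Per-gene minima/maxima of log expression, fit on training data."""

    per_gene_min: np.ndarray
    per_gene_max: np.ndarray
    log_base: str = "log2p1"

    def __post_init__(self) -> None:
        self.per_gene_min = np.asarray(self.per_gene_min, dtype=float)
        self.per_gene_max = np.asarray(self.per_gene_max, dtype=float)
        if self.per_gene_min.shape != self.per_gene_max.shape:
            raise ValueError("min/max length mismatch")
        if np.any(self.per_gene_max < self.per_gene_min):
            raise ValueError("per-gene max below min")
        if self.log_base not in LOG_BASES:
            raise ValueError(f"log_base must be one of {LOG_BASES}")


@dataclass
class SplitSpec:
    """Stratified 70/10/20 train/validation/test split specification."""

    train_frac: float = 0.7
    val_frac: float = 0.1
    test_frac: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, expected 1")


def log_transform(matrix: np.ndarray, log_base: str = "log2p1") -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        bad = np.argwhere(matrix < 0)[0]
        raise ValueError(
            f"negative expression value at sample {bad[0]}, gene {bad[1]}; "
            "raw expression must be non-negative"
        )
    if log_base == "log2p1":
        return np.log2(matrix + 1.0)
    if log_base == "ln1p":
        return np.log1p(matrix)
    raise ValueError(f"log_base must be one of {LOG_BASES}")


def log_minmax_normalize(
    matrix: np.ndarray,
    stats: PreprocessStats | None = None,
    log_base: str = "log2p1",
) -> tuple[np.ndarray, PreprocessStats]:
    """Log-transform then scale each gene to [0, 1].

    Without ``stats`` the per-gene min/max are computed from this matrix
    (training mode).  With ``stats`` (validation/test mode) the stored
    training extremes are reused and the result is clipped to [0, 1].
    Constant genes (max == min) map to 0.
    """
    if stats is not None:
        log_base = stats.log_base
    logged = log_transform(matrix, log_base)
    if stats is None:
        stats = PreprocessStats(
            per_gene_min=logged.min(axis=0),
            per_gene_max=logged.max(axis=0),
            log_base=log_base,
        )
    rng_span = stats.per_gene_max - stats.per_gene_min
    safe = np.where(rng_span > 0, rng_span, 1.0)
    normalized = (logged - stats.per_gene_min) / safe
    normalized[:, rng_span == 0] = 0.0
    return np.clip(normalized, 0.0, 1.0), stats


def select_hvg(dataset: ExpressionDataset, n_top: int, log_base: str = "log2p1") -> np.ndarray:
    """Indices of the ``n_top`` most variable genes (variance of log expression).

    Ties are broken in favor of the lexicographically smaller gene name;
    the returned indices preserve the input gene order.
    """
    if n_top > dataset.n_genes:
        raise ValueError(f"n_top={n_top} exceeds number of genes {dataset.n_genes}")
    variances = log_transform(dataset.matrix, log_base).var(axis=0)
    order = sorted(
        range(dataset.n_genes),
        key=lambda i: (-variances[i], dataset.gene_names[i]),
    )
    keep = sorted(order[:n_top])
    return np.asarray(keep, dtype=int)


def stratified_split(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class shuffled 70/10/20 partition (floor for train/val, rest test).

    Returns (train, val, test) index arrays; partitions are disjoint and
    exhaustive.  Classes with fewer than 3 samples cannot populate all
    three splits and raise an error naming the class index.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    groups = (
        [(c, np.flatnonzero(labels == c)) for c in np.unique(labels)]
        if spec.stratified
        else [(None, np.arange(labels.shape[0]))]
    )
    for c, idx in groups:
        if idx.size < 3:
            raise ValueError(
                f"class {c} has only {idx.size} sample(s); need at least 3 to stratify"
            )
        idx = rng.permutation(idx)
        n_train = int(np.floor(spec.train_frac * idx.size))
        n_val = int(np.floor(spec.val_frac * idx.size))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )
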