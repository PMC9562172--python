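"""Model and results objects tying the pipeline together.

``TGEM`` is constructed from an :class:`~tgem.data.ExpressionDataset` plus
architecture choices; ``fit()`` splits the data (stratified 70/10/20),
fits the preprocessing on the training split, trains with Adam, and
returns a :class:`TGEMResults` carrying the best-validation-epoch
parameters, the training log, test-set metrics, and the interpretation
methods (entropy profile, attention attribution, pruning and probe scans,
regulatory-network extraction).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import interpret, io, metrics as metrics_mod, network as network_mod
from .data import ExpressionDataset, GeneSetCollection
from .functional import check_gene_alignment, predict_proba
from .params import TGEMParams, parameter_count
from .preprocess import PreprocessStats, SplitSpec, log_minmax_normalize, stratified_split
from .train import TrainConfig, grid_search, train


class TGEM:
    """Gene-wise scalar self-attention classifier for expression data."""

    def __init__(
        self,
        dataset: ExpressionDataset,
        n_layers: int = 1,
        n_heads: int = 2,
        activation: str = "none",
        layer_norm: bool = True,
        split: SplitSpec | None = None,
        log_base: str = "log2p1",
        normalize_full_matrix: bool = False,
        seed: int = 0,
    ):
        self.dataset = dataset
        self.config = TrainConfig(
            n_layers=n_layers, n_heads=n_heads, activation=activation,
            layer_norm=layer_norm, seed=seed,
        )
        self.split_spec = split or SplitSpec(seed=seed)
        self.log_base = log_base
        # strict-replication switch: fit min/max on the full matrix before
        # splitting instead of on the training split only
        self.normalize_full_matrix = normalize_full_matrix
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls, expr: pd.DataFrame, labels: pd.Series, **kwargs
    ) -> "TGEM":
        return cls(io.dataset_from_frames(expr, labels), **kwargs)

    # -- data preparation ---------------------------------------------------

    def _prepare(self) -> dict:
        ds = self.dataset
        train_idx, val_idx, test_idx = stratified_split(ds.labels, self.split_spec)
        if self.normalize_full_matrix:
            _, stats = log_minmax_normalize(ds.matrix, log_base=self.log_base)
            X_train, _ = log_minmax_normalize(ds.matrix[train_idx], stats)
        else:
            X_train, stats = log_minmax_normalize(
                ds.matrix[train_idx], log_base=self.log_base
            )
        X_val, _ = log_minmax_normalize(ds.matrix[val_idx], stats)
        X_test, _ = log_minmax_normalize(ds.matrix[test_idx], stats)
        return {
            "train_idx": train_idx, "val_idx": val_idx, "test_idx": test_idx,
            "X_train": X_train, "X_val": X_val, "X_test": X_test,
            "y_train": ds.labels[train_idx], "y_val": ds.labels[val_idx],
            "y_test": ds.labels[test_idx], "stats": stats,
        }

    # -- fitting ------------------------------------------------------------

    def fit(self, **config_overrides) -> "TGEMResults":
        cfg = replace(self.config, **config_overrides) if config_overrides else self.config
        prep = self._prepare()
        params, log = train(
            prep["X_train"], prep["y_train"], prep["X_val"], prep["y_val"],
            cfg, self.dataset.gene_names, self.dataset.class_names,
        )
        return TGEMResults(self, cfg, params, log, prep)

    def fit_grid(self, grid: dict | None = None, **config_overrides) -> "TGEMResults":
        """Hyperparameter search over layers x heads x activation."""
        cfg = replace(self.config, **config_overrides) if config_overrides else self.config
        prep = self._prepare()
        best_cfg, params, log, table = grid_search(
            prep["X_train"], prep["y_train"], prep["X_val"], prep["y_val"],
            cfg, self.dataset.gene_names, self.dataset.class_names, grid=grid,
        )
        res = TGEMResults(self, best_cfg, params, log, prep)
        res.grid_table = table
        return res


class TGEMResults:
    """Fitted model: parameters, diagnostics, and interpretation methods."""

    def __init__(
        self,
        model: TGEM,
        config: TrainConfig,
        params: TGEMParams,
        training_log: list[dict],
        prep: dict,
    ):
        self.model = model
        self.config = config
        self.params = params
        self.training_log = training_log
        self.split = {k: prep[k] for k in ("train_idx", "val_idx", "test_idx")}
        self._prep = prep
        self.preprocess_stats: PreprocessStats = prep["stats"]
        self.grid_table: list[dict] | None = None
        self._test_metrics: dict | None = None

    # -- prediction ---------------------------------------------------------

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        """Apply the fitted log + min-max preprocessing to raw expression."""
        out, _ = log_minmax_normalize(np.asarray(raw, dtype=float), self.preprocess_stats)
        return out

    def predict_proba(
        self, raw: np.ndarray, gene_names: list[str] | None = None
    ) -> np.ndarray:
        if gene_names is not None:
            check_gene_alignment(gene_names, self.params.gene_names)
        return predict_proba(self.params, self.normalize(raw))

    def predict(self, raw: np.ndarray, gene_names: list[str] | None = None) -> np.ndarray:
        return self.predict_proba(raw, gene_names).argmax(axis=1)

    # -- diagnostics --------------------------------------------------------

    @property
    def best_epoch(self) -> int:
        accs = [r["val_acc"] for r in self.training_log]
        return int(np.argmax(accs)) + 1

    @property
    def validation_accuracy(self) -> float:
        return max(r["val_acc"] for r in self.training_log)

    def test_metrics(self) -> dict:
        """ACC / MCC / AUC and confusion matrix on the held-out test split."""
        if self._test_metrics is None:
            probs = predict_proba(self.params, self._prep["X_test"])
            self._test_metrics = metrics_mod.evaluate(
                self._prep["y_test"], probs, self.params.n_classes
            )
        return self._test_metrics

    def summary(self) -> str:
        m = self.test_metrics()
        cfg = self.config
        lines = [
            "Gene-wise self-attention classifier",
            "=" * 51,
            f"{'Genes':<28}{self.params.n_genes:>23}",
            f"{'Classes':<28}{self.params.n_classes:>23}",
            f"{'Layers':<28}{cfg.n_layers:>23}",
            f"{'Heads per layer':<28}{cfg.n_heads:>23}",
            f"{'Readout activation':<28}{cfg.activation:>23}",
            f"{'Parameters':<28}{parameter_count(self.params):>23}",
            f"{'Epochs (batch size)':<28}{f'{cfg.epochs} ({cfg.batch_size})':>23}",
            f"{'Best epoch':<28}{self.best_epoch:>23}",
            f"{'Validation accuracy':<28}{self.validation_accuracy:>23.4f}",
            "-" * 51,
            f"{'Test accuracy':<28}{m['acc']:>23.4f}",
            f"{'Test MCC':<28}{m['mcc']:>23.4f}",
            f"{'Test macro AUC':<28}{m['auc']:>23.4f}",
            "=" * 51,
        ]
        return "\n".join(lines)

    # -- interpretation -----------------------------------------------------

    def entropy_profile(self, which: str = "test") -> interpret.EntropyProfile:
        return interpret.entropy_profile(self.params, self._split_X(which))

    def prune_scan(self) -> tuple[float, list[interpret.PruneResult]]:
        return interpret.prune_scan(
            self.params, self._prep["X_test"], self._prep["y_test"]
        )

    def probe_scan(self) -> list[dict]:
        return interpret.probe_scan(
            self.params,
            self._prep["X_train"], self._prep["y_train"],
            self._prep["X_test"], self._prep["y_test"],
            seed=self.config.seed,
        )

    def attribution(
        self, target_class: int, layer: int | None = None, n_steps: int = 50,
        which: str = "test",
    ) -> interpret.AttributionMatrix:
        """Integrated-gradients attention attribution from the samples of
        one class (held-out test samples by default)."""
        layer = self.params.n_layers - 1 if layer is None else layer
        X = self._class_X(target_class, which)
        return interpret.ig_attribution(
            self.params, X, layer, target_class, n_steps=n_steps
        )

    def extract_network(
        self,
        target_class: int,
        layer: int | None = None,
        rule: network_mod.ThresholdRule | None = None,
        n_steps: int = 50,
        n_hubs: int = 20,
        which: str = "test",
    ) -> network_mod.RegulatoryNetwork:
        X = self._class_X(target_class, which)
        return network_mod.extract_network(
            self.params, X, target_class, layer=layer, rule=rule,
            n_steps=n_steps, n_hubs=n_hubs,
        )

    def enrich(
        self, informative: list[str], collection: GeneSetCollection
    ) -> network_mod.EnrichmentResult:
        return network_mod.hypergeometric_enrichment(informative, collection)

    # -- plotting -----------------------------------------------------------

    def plot_training(self, ax=None):
        """Training loss and validation accuracy per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [r["epoch"] for r in self.training_log]
        ax.plot(epochs, [r["train_loss"] for r in self.training_log], label="train loss")
        ax2 = ax.twinx()
        ax2.plot(
            epochs, [r["val_acc"] for r in self.training_log],
            color="C1", label="validation accuracy",
        )
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean NLL")
        ax2.set_ylabel("validation accuracy")
        return ax

    def plot_entropy(self, profile: interpret.EntropyProfile | None = None, ax=None):
        """Strip plot of per-query-gene mean attention entropy by layer/head."""
        import matplotlib.pyplot as plt

        profile = profile or self.entropy_profile()
        if ax is None:
            _, ax = plt.subplots()
        L, H, _ = profile.values.shape
        pos = 0
        ticks, labels = [], []
        rng = np.random.default_rng(0)
        for li in range(L):
            for h in range(H):
                vals = profile.values[li, h]
                ax.scatter(
                    pos + rng.uniform(-0.25, 0.25, size=vals.size), vals, s=4, alpha=0.4
                )
                ticks.append(pos)
                labels.append(f"L{li+1}H{h+1}")
                pos += 1
        ax.axhline(profile.max_entropy(), ls="--", c="grey", lw=0.8)
        ax.set_xticks(ticks, labels)
        ax.set_ylabel("mean attention entropy (nats)")
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        io.save_checkpoint(
            self.params, path, stats=self.preprocess_stats,
            train_config=asdict(self.config), seed=self.config.seed,
        )

    # -- helpers ------------------------------------------------------------

    def _split_X(self, which: str) -> np.ndarray:
        key = {"train": "X_train", "val": "X_val", "test": "X_test"}[which]
        return self._prep[key]

    def _class_X(self, target_class: int, which: str) -> np.ndarray:
        X = self._split_X(which)
        y = self._prep[{"train": "y_train", "val": "y_val", "test": "y_test"}[which]]
        mask = y == target_class
        if not mask.any():
            raise ValueError(
                f"no {which} samples of class "
                f"{self.params.class_names[target_class]!r}"
            )
        return X[mask]
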