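"""Readers and writers for the standard formats around the model.

Expression comes in as a samples x genes TSV/CSV (first column sample ID,
header gene symbols) or an MTX triplet (genes x cells, transposed on
load); labels as a two-column TSV; genesets as GMT.  Model checkpoints
are an .npz parameter archive plus a JSON sidecar describing names,
architecture, preprocessing statistics and training config, and loading
reproduces forward outputs bit-identically.  Networks export as SIF and
GraphML for Cytoscape.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread

from .data import ExpressionDataset, GeneSetCollection
from .interpret import EntropyProfile, PruneResult
from .network import EnrichmentResult, RegulatoryNetwork
from .params import ClassifierParams, LayerParams, TGEMParams
from .preprocess import PreprocessStats


# ---------------------------------------------------------------------------
# expression and labels

def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    df = dataset.to_frame()
    df.index.name = "sample_id"
    # 17 significant digits keep the round-trip lossless for float64
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Samples x genes table from TSV/CSV (delimiter by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for g in header:
        if g in seen:
            raise ValueError(f"duplicate gene symbol in header: {g!r}")
        seen.add(g)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r}")
    return df


def read_expression_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> pd.DataFrame:
    """MTX triplet (genes x cells) to a dense cells x genes frame."""
    m = mmread(str(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    dense = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
    if dense.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    return pd.DataFrame(dense.T, index=barcodes, columns=features)


def write_labels_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class_label": [dataset.class_names[c] for c in dataset.labels],
        }
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels file must have two columns: sample_id, class_label")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))


def dataset_from_frames(expr: pd.DataFrame, labels: pd.Series) -> ExpressionDataset:
    """Join an expression frame with a label series into a dataset.

    Sample IDs present in one input but not the other are reported.
    """
    missing = [s for s in expr.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing[:10]}")
    lab = labels.loc[expr.index]
    class_names = sorted(set(lab.astype(str)))
    class_idx = {c: i for i, c in enumerate(class_names)}
    return ExpressionDataset(
        matrix=expr.values,
        gene_names=[str(c) for c in expr.columns],
        sample_ids=[str(s) for s in expr.index],
        labels=np.array([class_idx[str(v)] for v in lab]),
        class_names=class_names,
    )


# ---------------------------------------------------------------------------
# GMT genesets

def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, universe=universe or [])


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(
    params: TGEMParams,
    path: str | Path,
    stats: PreprocessStats | None = None,
    train_config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write <path>.npz (arrays) and <path>.json (metadata)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for li, lp in enumerate(params.layers):
        for name in ("wq", "wk", "wv", "head_mix", "ln_gain", "ln_bias"):
            arrays[f"layer{li}_{name}"] = getattr(lp, name)
    arrays["clf_weight"] = params.classifier.weight
    arrays["clf_bias"] = params.classifier.bias
    if stats is not None:
        arrays["pp_min"] = stats.per_gene_min
        arrays["pp_max"] = stats.per_gene_max
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "gene_names": params.gene_names,
        "class_names": params.class_names,
        "n_layers": params.n_layers,
        "n_heads": params.n_heads,
        "activation": params.classifier.activation,
        "layer_norm": params.layer_norm,
        "ln_eps": params.ln_eps,
        "log_base": stats.log_base if stats is not None else None,
        "train_config": train_config,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[TGEMParams, PreprocessStats | None, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        layers = [
            LayerParams(
                wq=z[f"layer{li}_wq"],
                wk=z[f"layer{li}_wk"],
                wv=z[f"layer{li}_wv"],
                head_mix=z[f"layer{li}_head_mix"],
                ln_gain=z[f"layer{li}_ln_gain"],
                ln_bias=z[f"layer{li}_ln_bias"],
            )
            for li in range(meta["n_layers"])
        ]
        classifier = ClassifierParams(
            weight=z["clf_weight"], bias=z["clf_bias"], activation=meta["activation"]
        )
        stats = None
        if "pp_min" in z:
            stats = PreprocessStats(
                per_gene_min=z["pp_min"],
                per_gene_max=z["pp_max"],
                log_base=meta.get("log_base") or "log2p1",
            )
    params = TGEMParams(
        layers=layers,
        classifier=classifier,
        gene_names=meta["gene_names"],
        class_names=meta["class_names"],
        layer_norm=meta.get("layer_norm", True),
        ln_eps=meta.get("ln_eps", 1e-5),
    )
    return params, stats, meta


# ---------------------------------------------------------------------------
# report and network exports

def write_network_sif(network: RegulatoryNetwork, path: str | Path) -> None:
    lines = [f"{k}\tregulates\t{q}" for k, q, _ in network.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_network_sif(path: str | Path) -> list[tuple[str, str, str]]:
    triples = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            src, rel, dst = line.split("\t")
            triples.append((src, rel, dst))
    return triples


def write_network_graphml(network: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(path))


def write_entropy_tsv(profile: EntropyProfile, path: str | Path) -> None:
    L, H, G = profile.values.shape
    rows = [
        {"layer": li, "head": h, "query_gene": profile.gene_names[g],
         "entropy": profile.values[li, h, g]}
        for li in range(L) for h in range(H) for g in range(G)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_prune_tsv(
    reference: float, results: list[PruneResult], path: str | Path
) -> None:
    """Table-style layout: one row per layer, columns LAYER, HEAD 1..H."""
    layers = sorted({r.layer for r in results})
    heads = sorted({r.head for r in results if r.head is not None})
    rows = []
    for li in layers:
        row: dict = {"layer": li + 1}
        for r in results:
            if r.layer != li:
                continue
            col = "LAYER" if r.head is None else f"HEAD {r.head + 1}"
            row[col] = r.accuracy_after
        rows.append(row)
    df = pd.DataFrame(rows, columns=["layer", "LAYER", *[f"HEAD {h+1}" for h in heads]])
    with open(path, "w") as fh:
        fh.write(f"# reference accuracy: {reference:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_attribution_tsv(attrib, path: str | Path) -> None:
    """Long-format (layer, query_gene, key_gene, score) off-diagonal dump."""
    names = attrib.gene_names
    G = len(names)
    recs = []
    for g in range(G):
        for i in range(G):
            if i != g:
                recs.append(
                    (attrib.layer, names[g], names[i], attrib.scores[g, i])
                )
    pd.DataFrame(
        recs, columns=["layer", "query_gene", "key_gene", "score"]
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(result: EnrichmentResult, path: str | Path) -> None:
    pd.DataFrame(result.table).to_csv(path, sep="\t", index=False)


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    out = {k: v for k, v in metrics.items() if k != "confusion"}
    Path(path).write_text(json.dumps(out, indent=2, default=float))


def write_confusion_tsv(confusion: np.ndarray, class_names: list[str], path: str | Path) -> None:
    pd.DataFrame(confusion, index=class_names, columns=class_names).to_csv(path, sep="\t")


def write_training_log(log: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# run manifests

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    seed: int,
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = Path(outdir) / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
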