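"""Regulatory-network extraction from attention attributions and geneset
enrichment of the informative genes.

Thresholding the attribution matrix of the last attention layer for one
class's samples leaves a directed graph of Key -> Query edges: a Query
gene keeping at least one edge is "informative", high-degree nodes are
hub candidates, and the informative set is tested for geneset enrichment
with the hypergeometric upper tail and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import GeneSetCollection
from .interpret import AttributionMatrix, ig_attribution
from .params import TGEMParams


@dataclass
class ThresholdRule:
    """How to turn attribution scores into retained edges.

    ``kind='percentile'`` keeps pairs scoring at or above the given
    percentile of the off-diagonal score distribution (on absolute values
    when ``absolute``); ``kind='value'`` uses a fixed cutoff;
    ``kind='top_k_per_query'`` keeps each Query gene's k highest-scoring
    Key partners.
    """

    kind: str = "percentile"
    percentile: float = 99.5
    value: float = 0.0
    top_k: int = 5
    absolute: bool = False

    def cutoff(self, scores: np.ndarray) -> float:
        off = scores[~np.eye(scores.shape[0], dtype=bool)]
        vals = np.abs(off) if self.absolute else off
        if self.kind == "percentile":
            return float(np.percentile(vals, self.percentile))
        if self.kind == "value":
            return self.value
        raise ValueError(f"no scalar cutoff for rule kind {self.kind!r}")


@dataclass
class RegulatoryNetwork:
    """Directed Key -> Query graph of above-threshold attribution edges."""

    edges: list[tuple[str, str, float]]  # (key_gene, query_gene, score)
    class_label: int
    layer: int
    threshold: float
    gene_names: list[str]
    hubs: list[tuple[str, int]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for k, q, _ in self.edges:
            seen.setdefault(k)
            seen.setdefault(q)
        return list(seen)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        hub_set = {h for h, _ in self.hubs}
        for k, q, s in self.edges:
            g.add_edge(k, q, score=float(s), interaction="regulates")
        for n in g.nodes:
            g.nodes[n]["hub"] = n in hub_set
        return g


def threshold_informative(
    attrib: AttributionMatrix, rule: ThresholdRule | float
) -> tuple[list[tuple[str, str, float]], list[str], list[str]]:
    """Apply the threshold rule; split Query genes into informative
    (at least one retained edge) and non-informative.

    Returns ``(edges, informative, non_informative)`` with edges as
    (key_gene, query_gene, score) triples.
    """
    scores = np.asarray(attrib.scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("attribution scores must be finite")
    names = attrib.gene_names
    G = scores.shape[0]
    offdiag = ~np.eye(G, dtype=bool)
    if isinstance(rule, (int, float)):
        rule = ThresholdRule(kind="value", value=float(rule))
    if rule.kind == "top_k_per_query":
        vals = np.abs(scores) if rule.absolute else scores
        keep = np.zeros_like(offdiag)
        for g in range(G):
            row = np.where(offdiag[g], vals[g], -np.inf)
            k = min(rule.top_k, G - 1)
            top = np.argpartition(row, -k)[-k:]
            keep[g, top] = True
        keep &= offdiag
    else:
        cut = rule.cutoff(scores)
        vals = np.abs(scores) if rule.absolute else scores
        keep = (vals >= cut) & offdiag
    edges = [
        (names[i], names[g], float(scores[g, i]))
        for g, i in zip(*np.nonzero(keep))
    ]
    informative = sorted({q for _, q, _ in edges}, key=names.index)
    non_informative = [n for n in names if n not in set(informative)]
    if not edges:
        warnings.warn("threshold retained no edges; network is empty", stacklevel=2)
    return edges, informative, non_informative


def extract_network(
    params: TGEMParams,
    X_class: np.ndarray,
    target_class: int,
    layer: int | None = None,
    rule: ThresholdRule | None = None,
    n_steps: int = 50,
    n_hubs: int = 20,
    ig_rule: str = "left",
) -> RegulatoryNetwork:
    """Attribution -> thresholding -> directed Key->Query network with hubs.

    By default the last attention layer is used, matching the idea that
    the top layer's attention is the most phenotype-specific.
    """
    if layer is None:
        layer = params.n_layers - 1
    rule = rule or ThresholdRule()
    attrib = ig_attribution(
        params, X_class, layer, target_class, n_steps=n_steps, rule=ig_rule
    )
    if rule.kind == "top_k_per_query":
        threshold = float("nan")
    else:
        threshold = rule.cutoff(attrib.scores)
    edges, informative, _ = threshold_informative(attrib, rule)
    net = RegulatoryNetwork(
        edges=edges,
        class_label=target_class,
        layer=layer,
        threshold=threshold,
        gene_names=list(params.gene_names),
    )
    if edges:
        net.hubs = find_hubs(net, n_hubs)
    return net


def find_hubs(network: RegulatoryNetwork, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by total degree (in + out).

    Ties prefer the larger summed incident edge score, then the
    lexicographically smaller name.  Returns (gene, degree) pairs.
    """
    if not network.edges:
        raise ValueError("cannot rank hubs of an empty network")
    degree: dict[str, int] = {}
    score_sum: dict[str, float] = {}
    for key, query, s in network.edges:
        for node in (key, query):
            degree[node] = degree.get(node, 0) + 1
            score_sum[node] = score_sum.get(node, 0.0) + s
    ranked = sorted(degree, key=lambda n: (-degree[n], -score_sum[n], n))
    return [(n, degree[n]) for n in ranked[:k]]


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of a gene list against a collection."""

    table: list[dict]  # per set: name, overlap, set_size, n_informative, p, fdr

    def significant(self, fdr: float = 0.05) -> list[str]:
        return [r["set"] for r in self.table if r["fdr"] < fdr]


def hypergeometric_enrichment(
    informative: list[str], collection: GeneSetCollection
) -> EnrichmentResult:
    """Upper-tail hypergeometric test per geneset with BH correction.

    With universe size N, set size K (within the universe), n informative
    genes and overlap m, p = P(X >= m) for X ~ Hypergeom(N, K, n).
    """
    universe = set(collection.universe)
    info = set(informative)
    if not info <= universe:
        raise ValueError("informative genes must lie within the universe")
    N = len(universe)
    n = len(info)
    rows = []
    for name in collection.sets:
        members = set(collection.restricted(name))
        K = len(members)
        m = len(info & members)
        # P(X >= m); survival function is P(X > m-1)
        p = 1.0 if n == 0 else float(hypergeom.sf(m - 1, N, K, n))
        rows.append(
            {"set": name, "overlap": m, "set_size": K, "n_informative": n, "p": min(p, 1.0)}
        )
    if rows:
        _, fdr, _, _ = multipletests([r["p"] for r in rows], method="fdr_bh")
        for r, q in zip(rows, fdr):
            r["fdr"] = float(q)
    rows.sort(key=lambda r: (r["fdr"], r["p"], r["set"]))
    return EnrichmentResult(table=rows)


def link_layers(
    query_enrichment_by_layer: dict[int, EnrichmentResult],
    informative_by_layer: dict[int, list[str]],
    edges_by_layer: dict[int, list[tuple[str, str, float]]],
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> list[tuple[int, str, str]]:
    """Cross-layer pathway links.

    For each pathway P enriched at layer l, collect the Key genes feeding
    P's informative Query genes at layer l, enrich that Key-gene list, and
    link P to every pathway enriched both in the Key genes and at layer
    l-1.  Returns (layer, pathway_at_l, pathway_at_l_minus_1) triples.
    """
    links: list[tuple[int, str, str]] = []
    layers = sorted(query_enrichment_by_layer)
    for l in layers:
        if l - 1 not in query_enrichment_by_layer:
            continue
        prev_enriched = set(query_enrichment_by_layer[l - 1].significant(fdr))
        if not prev_enriched:
            continue
        for pathway in query_enrichment_by_layer[l].significant(fdr):
            members = set(collection.restricted(pathway))
            queries = set(informative_by_layer[l]) & members
            keys = sorted({k for k, q, _ in edges_by_layer[l] if q in queries})
            if not keys:
                continue
            key_enrich = hypergeometric_enrichment(keys, collection)
            for target in key_enrich.significant(fdr):
                if target in prev_enriched:
                    links.append((l, pathway, target))
    return links
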