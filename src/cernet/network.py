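"""Condition-specific co-expression networks with typed edges.

Nodes are differentially expressed probes of three RNA classes (mRNA,
lncRNA, miRNA); edges come from three mechanisms and keep their type:

* ``lncRNA-mRNA`` — expression correlation (|r| at or above a threshold);
* ``miRNA-mRNA``  — seed-based target prediction, after filtering;
* ``mRNA-mRNA``   — shared pathway membership, by default additionally
  requiring a passing correlation so the graph stays expression-driven.

lncRNA–lncRNA, miRNA–miRNA and lncRNA–miRNA edges are never drawn. Hub
structure is summarized per node by degree, clustering coefficient and
k-core number; candidate core regulatory factors are ranked by the
absolute degree difference between the two condition-specific networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSet
from .matrix import ExpressionMatrix
from .targets import TargetRelation

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
EDGE_CORRELATION = "lncRNA-mRNA"
EDGE_TARGET = "miRNA-mRNA"
EDGE_PATHWAY = "mRNA-mRNA"
_FORBIDDEN = {
    frozenset(["lncRNA"]),
    frozenset(["miRNA"]),
    frozenset(["lncRNA", "miRNA"]),
}


@dataclass(frozen=True)
class CorrelationPair:
    """Unordered significant correlation between two probes (a < b)."""

    id_a: str
    id_b: str
    class_a: str
    class_b: str
    r: float
    p_corr: float  # NaN when n < 4 (t transform undefined)
    n_samples: int


@dataclass
class GeneNetwork:
    """Typed-edge graph over DE probes with per-node topology statistics."""

    condition_label: str
    graph: nx.Graph

    @property
    def node_table(self) -> pd.DataFrame:
        g = self.graph
        clustering = nx.clustering(g)
        core = nx.core_number(g) if g.number_of_nodes() else {}
        rows = [
            {
                "node": node,
                "rna_class": g.nodes[node].get("rna_class", "unknown"),
                "direction": g.nodes[node].get("direction", "null"),
                "degree": g.degree[node],
                "clustering_coefficient": clustering[node],
                "core_number": core.get(node, 0),
            }
            for node in sorted(g.nodes)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        g = self.graph
        by_class = {c: 0 for c in RNA_CLASSES}
        for _, data in g.nodes(data=True):
            by_class[data["rna_class"]] = by_class.get(data["rna_class"], 0) + 1
        by_type: dict[str, int] = {}
        for _, _, data in g.edges(data=True):
            by_type[data["edge_type"]] = by_type.get(data["edge_type"], 0) + 1
        return {
            "condition": self.condition_label,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "nodes_by_class": by_class,
            "edges_by_type": by_type,
        }


# ----------------------------------------------------------------------
# correlation screening
# ----------------------------------------------------------------------

def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt((n-2)/(1-r^2)), n-2 df."""
    if n < 4:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlation_pairs(
    matrices: Mapping[str, ExpressionMatrix],
    sample_subset: Sequence[str] | None = None,
    r_min: float = 0.99,
    p_max: float = 0.05,
) -> list[CorrelationPair]:
    """Screen all cross-class and mRNA–mRNA probe pairs for |r| >= r_min.

    ``matrices`` maps RNA class ("mRNA", "lncRNA", "miRNA") to its
    expression matrix; correlations are computed over ``sample_subset``
    (default: all shared samples). With n >= 4 samples the correlation
    p-value must also pass ``p_max``; at n < 4 the magnitude screen alone
    applies. Zero-variance probes are skipped with a warning.
    """
    classes = [c for c in RNA_CLASSES if c in matrices]
    if not classes:
        raise ValueError("no expression matrices supplied")
    ref = matrices[classes[0]]
    samples = list(sample_subset) if sample_subset is not None else ref.sample_ids
    n = len(samples)
    if n < 2:
        raise ValueError("need >= 2 samples for correlation")

    ids: list[str] = []
    klass: list[str] = []
    blocks = []
    for c in classes:
        m = matrices[c].subset_samples(samples)
        blocks.append(m.values.to_numpy(dtype=float))
        ids.extend(m.probe_ids)
        klass.extend([c] * len(m.probe_ids))
    x = np.vstack(blocks)

    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance probes skipped in correlation screen"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)

    pairs: list[CorrelationPair] = []
    k = len(ids)
    for i in range(k):
        if degenerate[i]:
            continue
        for j in range(i + 1, k):
            if degenerate[j]:
                continue
            ci, cj = klass[i], klass[j]
            if ci == cj and ci != "mRNA":
                continue  # lncRNA-lncRNA / miRNA-miRNA never screened
            r = float(corr[i, j])
            if abs(r) < r_min:
                continue
            p = correlation_p(r, n)
            if n >= 4 and not (p <= p_max):
                continue
            a, b = sorted([(ids[i], ci), (ids[j], cj)])
            pairs.append(
                CorrelationPair(a[0], b[0], a[1], b[1], r, p, n)
            )
    pairs.sort(key=lambda pr: (pr.id_a, pr.id_b))
    return pairs


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------

def build_network(
    pairs: Iterable[CorrelationPair],
    relations: Iterable[TargetRelation],
    sets: Sequence[GeneSet],
    condition_label: str,
    directions: Mapping[str, str] | None = None,
    mrna_edges: str = "pathway_and_correlation",
) -> GeneNetwork:
    """Assemble the typed-edge graph for one condition.

    * lncRNA–mRNA edges from correlation pairs (weight |r|);
    * miRNA–mRNA edges from (filtered) target relations (weight 1);
    * mRNA–mRNA edges for correlated pairs sharing >= 1 gene set
      (``mrna_edges="pathway_and_correlation"``, default) or for any two
      mRNA nodes sharing a set (``"pathway_only"``).

    Forbidden class pairs in ``pairs`` are ignored; duplicate edges
    collapse; self-loops are rejected.
    """
    if mrna_edges not in ("pathway_and_correlation", "pathway_only"):
        raise ValueError("unknown mRNA-mRNA edge rule")
    directions = directions or {}
    g = nx.Graph()

    def add_node(node: str, rna_class: str) -> None:
        g.add_node(node, rna_class=rna_class, direction=directions.get(node, "null"))

    membership: dict[str, set[str]] = {}
    for gs in sets:
        for m in gs.member_ids:
            membership.setdefault(m, set()).add(gs.set_id)

    def share_set(a: str, b: str) -> bool:
        return bool(membership.get(a, set()) & membership.get(b, set()))

    for pr in pairs:
        if pr.id_a == pr.id_b:
            raise ValueError("self-loop in correlation pairs")
        kinds = frozenset([pr.class_a, pr.class_b])
        if kinds == frozenset(["lncRNA", "mRNA"]):
            add_node(pr.id_a, pr.class_a)
            add_node(pr.id_b, pr.class_b)
            g.add_edge(pr.id_a, pr.id_b, edge_type=EDGE_CORRELATION, weight=abs(pr.r))
        elif kinds == frozenset(["mRNA"]):
            if mrna_edges == "pathway_and_correlation" and share_set(pr.id_a, pr.id_b):
                add_node(pr.id_a, "mRNA")
                add_node(pr.id_b, "mRNA")
                g.add_edge(pr.id_a, pr.id_b, edge_type=EDGE_PATHWAY, weight=abs(pr.r))
        # any other class combination is not a drawable edge

    for rel in relations:
        if rel.mirna_id == rel.mrna_id:
            raise ValueError("self-loop in target relations")
        add_node(rel.mirna_id, "miRNA")
        add_node(rel.mrna_id, "mRNA")
        g.add_edge(rel.mirna_id, rel.mrna_id, edge_type=EDGE_TARGET, weight=1.0)

    if mrna_edges == "pathway_only":
        mrnas = sorted(n for n, d in g.nodes(data=True) if d["rna_class"] == "mRNA")
        for i, a in enumerate(mrnas):
            for b in mrnas[i + 1 :]:
                if share_set(a, b) and not g.has_edge(a, b):
                    g.add_edge(a, b, edge_type=EDGE_PATHWAY, weight=1.0)

    _assert_edge_types(g)
    return GeneNetwork(condition_label=condition_label, graph=g)


def _assert_edge_types(g: nx.Graph) -> None:
    for a, b, data in g.edges(data=True):
        kinds = frozenset([g.nodes[a]["rna_class"], g.nodes[b]["rna_class"]])
        if kinds in _FORBIDDEN:
            raise AssertionError(f"forbidden edge class between {a} and {b}")
        expected = {
            frozenset(["lncRNA", "mRNA"]): EDGE_CORRELATION,
            frozenset(["miRNA", "mRNA"]): EDGE_TARGET,
            frozenset(["mRNA"]): EDGE_PATHWAY,
        }[kinds]
        if data["edge_type"] != expected:
            raise AssertionError(
                f"edge type {data['edge_type']} inconsistent with classes of {a}-{b}"
            )


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

def clustering_coefficient(network: GeneNetwork, node: str) -> float:
    """2*triangles / (deg*(deg-1)); 0 for degree < 2."""
    if node not in network.graph:
        raise KeyError(f"unknown node {node!r}")
    return float(nx.clustering(network.graph, node))


def average_clustering(network: GeneNetwork) -> float:
    """Subnetwork-average clustering coefficient (0 for an empty graph)."""
    if network.graph.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(network.graph))


def k_core(network: GeneNetwork, k: int) -> set[str]:
    """Maximal subgraph in which every node keeps degree >= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    g = network.graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    return set(nx.k_core(g, k).nodes)


def core_regulatory_factors(
    network_a: GeneNetwork, network_b: GeneNetwork, top_n: int = 10
) -> pd.DataFrame:
    """Rank nodes by |degree(A) - degree(B)| across two condition networks.

    Nodes absent from a network count degree 0 there. Ties break
    lexicographically on the node id.
    """
    deg_a = dict(network_a.graph.degree)
    deg_b = dict(network_b.graph.degree)
    nodes = sorted(set(deg_a) | set(deg_b))
    rows = [
        {
            "node": node,
            "rna_class": (
                network_a.graph.nodes[node]["rna_class"]
                if node in network_a.graph
                else network_b.graph.nodes[node]["rna_class"]
            ),
            "degree_a": deg_a.get(node, 0),
            "degree_b": deg_b.get(node, 0),
            "degree_diff": abs(deg_a.get(node, 0) - deg_b.get(node, 0)),
        }
        for node in nodes
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(
            ["degree_diff", "node"], ascending=[False, True]
        ).head(top_n)
        frame = frame.reset_index(drop=True)
    return frame


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def write_sif(network: GeneNetwork, path: str | Path) -> None:
    """Simple interaction format: node <TAB> edge_type <TAB> node."""
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{data['edge_type']}\t{b}\n")


def write_graphml(network: GeneNetwork, path: str | Path) -> None:
    g = network.graph.copy()
    clustering = nx.clustering(g)
    core = nx.core_number(g) if g.number_of_nodes() else {}
    for node in g.nodes:
        g.nodes[node]["degree"] = int(g.degree[node])
        g.nodes[node]["clustering_coefficient"] = float(clustering[node])
        g.nodes[node]["core_number"] = int(core.get(node, 0))
    nx.write_graphml(g, path)


def write_node_metrics(network: GeneNetwork, path: str | Path) -> None:
    network.node_table.to_csv(path, sep="\t", index=False)


def write_summary(networks: Sequence[GeneNetwork], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([n.summary() for n in networks], fh, indent=2, sort_keys=True)
        fh.write("\n")
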