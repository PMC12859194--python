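"""Tripartite ceRNA network assembly, expression filtering, statistics,
subnetwork extraction and Cytoscape-ready serialization.

The network is a directed graph over three disjoint node layers — circRNA,
miRNA, mRNA — with sponge edges (circRNA -> miRNA) and target edges
(miRNA -> mRNA) only. Nodes are differentially expressed features that are
incident to at least one retained edge whose other endpoint is also
differentially expressed; isolated nodes are dropped. Cell-type expression
filtering keeps only nodes present in the layer's expressed set and
re-drops anything newly isolated; filtering commutes with network
construction (a property promoted to a hard test).
"""

from __future__ import annotations

import difflib
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

LAYERS = ("circRNA", "miRNA", "mRNA")


def build_network(sig_circ: Iterable[str], sig_mirna: Iterable[str],
                  sig_mrna: Iterable[str], sponge_edges: pd.DataFrame,
                  target_edges: pd.DataFrame, contrast: str = "",
                  retained_only: bool = True) -> nx.DiGraph:
    """Assemble the tripartite network over significant features.

    ``sponge_edges``/``target_edges`` are the interaction tables
    (source_id, target_id, retained, ...). Multi-edges are already collapsed
    there; edge attributes carry best class/score, site count and
    junction-spanning flags.
    """
    sig_circ, sig_mirna, sig_mrna = set(sig_circ), set(sig_mirna), set(sig_mrna)
    g = nx.DiGraph(contrast=contrast)
    for edges, src_set, dst_set, src_layer, dst_layer, kind in (
            (sponge_edges, sig_circ, sig_mirna, "circRNA", "miRNA", "sponge"),
            (target_edges, sig_mirna, sig_mrna, "miRNA", "mRNA", "target")):
        if edges is None or edges.empty:
            continue
        sel = edges
        if retained_only and "retained" in sel.columns:
            sel = sel[sel["retained"]]
        for row in sel.itertuples():
            if row.source_id in src_set and row.target_id in dst_set:
                g.add_node(row.source_id, layer=src_layer)
                g.add_node(row.target_id, layer=dst_layer)
                g.add_edge(row.source_id, row.target_id, kind=kind,
                           best_class=getattr(row, "best_class", ""),
                           best_score=float(getattr(row, "best_score", 0.0)),
                           n_sites=int(getattr(row, "n_sites", 1)),
                           junction_spanning=bool(getattr(row, "junction_spanning", False)))
    _drop_isolated(g)
    return g


def _drop_isolated(g: nx.DiGraph) -> None:
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])


def filter_by_expression(g: nx.DiGraph, expressed_sets: Mapping[str, Iterable[str]],
                         allow_missing: bool = False) -> nx.DiGraph:
    """Restrict the network to nodes in each layer's expression set
    (e.g. endothelial-expressed features); newly isolated nodes are dropped.
    """
    sets = {k: set(v) for k, v in expressed_sets.items()}
    for layer in LAYERS:
        if layer not in sets and not allow_missing:
            raise ValueError(f"missing expression set for layer {layer!r} "
                             "(pass allow_missing=True to skip)")
    out = g.copy()
    drop = [n for n, d in out.nodes(data=True)
            if d["layer"] in sets and n not in sets[d["layer"]]]
    out.remove_nodes_from(drop)
    _drop_isolated(out)
    return out


def network_stats(g: nx.DiGraph) -> dict:
    """Node totals per layer, edge totals per kind, and a degree table."""
    nodes_by_layer = {layer: 0 for layer in LAYERS}
    for _, d in g.nodes(data=True):
        nodes_by_layer[d["layer"]] += 1
    edges_by_kind = {"sponge": 0, "target": 0}
    for _, _, d in g.edges(data=True):
        edges_by_kind[d["kind"]] += 1
    degree = pd.DataFrame(
        [(n, g.nodes[n]["layer"], g.degree(n)) for n in sorted(g)],
        columns=["node", "layer", "degree"])
    return dict(
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
        nodes_by_layer=nodes_by_layer, edges_by_kind=edges_by_kind,
        degree=degree)


def extract_subnetwork(g: nx.DiGraph, focal_circ_id: str, hops: int = 2) -> nx.DiGraph:
    """Directed 2-hop ego subnetwork of a focal circRNA: its sponged miRNAs
    and, at hops=2, those miRNAs' target mRNAs. The returned graph carries
    ``n_mirnas``/``n_mrnas`` counts in its graph attributes."""
    if focal_circ_id not in g:
        near = difflib.get_close_matches(focal_circ_id, list(g), n=5)
        raise KeyError(f"focal circRNA {focal_circ_id!r} not in network; "
                       f"nearest ids: {near}")
    keep = {focal_circ_id}
    mirnas = set(g.successors(focal_circ_id))
    keep |= mirnas
    mrnas: set[str] = set()
    if hops >= 2:
        for m in mirnas:
            mrnas |= set(g.successors(m))
        keep |= mrnas
    sub = g.subgraph(keep).copy()
    _drop_isolated(sub)
    sub.graph["focal"] = focal_circ_id
    sub.graph["n_mirnas"] = len(mirnas & set(sub))
    sub.graph["n_mrnas"] = len(mrnas & set(sub))
    return sub


def _canonical(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph(**g.graph)
    for n in sorted(g.nodes):
        out.add_node(n, **g.nodes[n])
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def write_graphml(g: nx.DiGraph, path) -> None:
    """GraphML with canonical node/edge ordering (byte-stable across runs)."""
    nx.write_graphml(_canonical(g), str(path), infer_numeric_types=False)


def write_sif(g: nx.DiGraph, path) -> None:
    """Cytoscape SIF: 'source<TAB>relation<TAB>target' per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{g.edges[u, v]['kind']}\t{v}\n")


def node_table(g: nx.DiGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(node=n, layer=g.nodes[n]["layer"]) for n in sorted(g)],
        columns=["node", "layer"])


def edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = []
    for u, v in sorted(g.edges):
        d = g.edges[u, v]
        rows.append(dict(source=u, target=v, kind=d["kind"],
                         best_class=d.get("best_class", ""),
                         best_score=d.get("best_score", float("nan")),
                         n_sites=d.get("n_sites", 1),
                         junction_spanning=d.get("junction_spanning", False)))
    return pd.DataFrame(rows, columns=["source", "target", "kind", "best_class",
                                       "best_score", "n_sites", "junction_spanning"])
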