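"""Hypergeometric over-representation analysis of network mRNAs and
pathway-to-network mapping.

The test is the one-sided upper-tail hypergeometric: with a universe of N
genes of which K belong to a set, and a query of n genes of which k belong,
p = P(X >= k) for X ~ Hypergeometric(N, K, n) — identical to one-sided
Fisher's exact on the 2x2 table. Adjustment is Benjamini-Hochberg across
tested sets; sets with no universe overlap are skipped. The default
significance gate is FDR < 0.05.

Pathway mapping propagates upstream through the ceRNA logic: an mRNA maps to
a set by membership, a miRNA maps iff at least one of its network targets
maps, and a circRNA maps iff at least one of its sponged miRNAs maps.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

logger = logging.getLogger(__name__)


def hypergeom_enrich(query: Iterable[str], gene_sets: Mapping[str, Iterable[str]],
                     universe: Iterable[str], fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each gene set.

    Query genes outside the universe are dropped with a notice; sets are
    intersected with the universe and empty intersections skipped.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("dropping %d query genes outside the universe", len(outside))
        query &= universe
    n = len(query)
    big_n = len(universe)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(dict(set_name=name, k=k, n=n, K=big_k, N=big_n, p_hyper=min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "k", "n", "K", "N", "p_hyper"])
    if not out.empty:
        out["fdr_bh"] = bh_fdr(out["p_hyper"].to_numpy())
        out["significant"] = out["fdr_bh"] < fdr_threshold
    else:
        out["fdr_bh"] = []
        out["significant"] = []
    return out.sort_values(["p_hyper", "set_name"], kind="mergesort").reset_index(drop=True)


def map_pathways_to_network(g: nx.DiGraph, gene_sets: Mapping[str, Iterable[str]],
                            selected_sets: Iterable[str],
                            enrichment: pd.DataFrame | None = None,
                            force: bool = False):
    """Annotate network nodes with the selected pathways and return the
    pathway-restricted sub-section.

    Returns ``(node_to_sets, subsection)``: a mapping node -> sorted list of
    selected sets it maps to (by membership for mRNAs, by propagation for
    miRNAs and circRNAs) and the induced subgraph on mapped nodes. Selecting
    a set that is not significant in ``enrichment`` warns (or raises unless
    ``force`` when the set is absent from the enrichment table).
    """
    selected = list(selected_sets)
    if enrichment is not None and not enrichment.empty:
        sig = set(enrichment.loc[enrichment["significant"], "set_name"])
        for name in selected:
            if name not in sig:
                warnings.warn(f"selected set {name!r} is not significant", stacklevel=2)
    node_to_sets: dict[str, set[str]] = {}
    for name in selected:
        if name not in gene_sets:
            if not force:
                raise KeyError(f"unknown gene set {name!r}")
            continue
        members = set(gene_sets[name])
        mapped_mrna = {n for n, d in g.nodes(data=True)
                       if d["layer"] == "mRNA" and n in members}
        mapped_mirna = {n for n, d in g.nodes(data=True)
                        if d["layer"] == "miRNA"
                        and any(t in mapped_mrna for t in g.successors(n))}
        mapped_circ = {n for n, d in g.nodes(data=True)
                       if d["layer"] == "circRNA"
                       and any(m in mapped_mirna for m in g.successors(n))}
        for node in mapped_mrna | mapped_mirna | mapped_circ:
            node_to_sets.setdefault(node, set()).add(name)
    mapped_nodes = set(node_to_sets)
    subsection = g.subgraph(mapped_nodes).copy()
    return {n: sorted(s) for n, s in node_to_sets.items()}, subsection
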