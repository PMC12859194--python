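"""End-to-end discovery pipeline on a simulated study, with truth scoring.

Composes the full chain the package implements: simulate -> back-splice
detection -> per-layer differential expression -> interaction prediction ->
tripartite network -> endothelial-expression filtering -> enrichment ->
focal subnetworks, and scores recovery of the planted sponging circuits.

The circRNA expression matrix entering DE is the *detected* per-sample
junction support from :func:`cernaforge.circdetect.call_backsplice`, so the
detection stage genuinely feeds the statistics downstream. circRNA counts
are normalized as fragments per million over the sample's total aligned
reads; miRNA and mRNA count matrices are TMM-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import circdetect, diffexp, enrich, interact, network
from .simulate import SimConfig, SimulatedDataset, simulate_dataset


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    junctions: pd.DataFrame
    records: pd.DataFrame
    circ_counts: pd.DataFrame          # detected junction support, tx ids
    de_circ: pd.DataFrame
    de_mirna: pd.DataFrame
    de_mrna: pd.DataFrame
    sponge_edges: pd.DataFrame
    target_edges: pd.DataFrame
    net: nx.DiGraph
    net_ec: nx.DiGraph                 # endothelial-expression filtered
    enrichment: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def detected_circ_counts(junctions: pd.DataFrame, truth_junctions: pd.DataFrame) -> pd.DataFrame:
    """Junction-support matrix (features x samples), with coordinates mapped
    back to simulator circRNA ids where they match."""
    coord_to_id = {
        f"{r.chrom}:{r.start}-{r.end}:{r.strand}": r.circ_id
        for r in truth_junctions.itertuples()}
    sup_cols = [c for c in junctions.columns if c.startswith("support_")]
    mat = junctions.copy()
    mat.index = [
        coord_to_id.get(f"{r.chrom}:{r.start}-{r.end}:{r.strand}",
                        f"{r.chrom}:{r.start}-{r.end}:{r.strand}")
        for r in junctions.itertuples()]
    mat = mat[sup_cols]
    mat.columns = [c.removeprefix("support_") for c in sup_cols]
    mat.index.name = "feature_id"
    return mat


def run_pipeline(config: SimConfig, contrast: tuple[str, str] | None = None,
                 selected_sets: tuple[str, ...] = ("angiogenesis", "VEGF_signaling"),
                 ) -> PipelineResult:
    """Run simulate -> detect -> DE -> predict -> network -> enrich and score
    recovery of the planted circuits against ground truth."""
    ds = simulate_dataset(config)
    if contrast is None:
        contrast = (config.groups[-1][0], config.reference_group)

    # --- detection ---------------------------------------------------------
    junctions = circdetect.call_backsplice(ds.segments)
    records = circdetect.annotate(junctions, ds.models)
    circ_counts = detected_circ_counts(junctions, ds.truth_junctions())

    # --- differential expression ------------------------------------------
    lib = ds.segments.groupby("sample")["read_id"].nunique().astype(float)
    _, circ_kept = circdetect.presence_filter(circ_counts, ds.design)
    circ_log = np.log2(circdetect.fpm_normalize(circ_kept, lib[circ_kept.columns]) + 1.0)
    de_circ = diffexp.de_test(circ_log, ds.design, contrast)

    de_mirna = _count_layer_de(ds.counts_mirna, ds.design, contrast)
    de_mrna = _count_layer_de(ds.counts_mrna, ds.design, contrast)

    # --- interactions ------------------------------------------------------
    sponge = interact.predict_sponge_edges(ds.circ_sequences, ds.mirna_seqs)
    target = interact.predict_target_edges(ds.mirna_seqs, ds.utr_seqs)

    # --- network -----------------------------------------------------------
    sig_circ = diffexp.significant_features(de_circ)
    sig_mir = diffexp.significant_features(de_mirna)
    sig_mrna = diffexp.significant_features(de_mrna)
    net = network.build_network(sig_circ, sig_mir, sig_mrna, sponge, target,
                                contrast=f"{contrast[0]}:{contrast[1]}")
    net_ec = network.filter_by_expression(net, ds.expressed_sets)

    # --- enrichment --------------------------------------------------------
    universe = list(circdetect.presence_filter(ds.counts_mrna, ds.design)[1].index)
    query = [n for n, d in net_ec.nodes(data=True) if d["layer"] == "mRNA"]
    enrichment = enrich.hypergeom_enrich(query, ds.gene_sets, universe)

    metrics = score_against_truth(ds, junctions, records, circ_counts, net_ec)
    metrics["enriched_sets"] = list(
        enrichment.loc[enrichment["significant"], "set_name"])
    return PipelineResult(
        dataset=ds, junctions=junctions, records=records, circ_counts=circ_counts,
        de_circ=de_circ, de_mirna=de_mirna, de_mrna=de_mrna,
        sponge_edges=sponge, target_edges=target, net=net, net_ec=net_ec,
        enrichment=enrichment, metrics=metrics)


def _count_layer_de(counts: pd.DataFrame, design: pd.DataFrame, contrast):
    _, kept = circdetect.presence_filter(counts, design)
    norm = diffexp.tmm_normalize(kept)
    return diffexp.de_test(np.log2(norm + 1.0), design, contrast)


def score_against_truth(ds: SimulatedDataset, junctions: pd.DataFrame,
                        records: pd.DataFrame, circ_counts: pd.DataFrame,
                        net_ec: nx.DiGraph) -> dict:
    """Recovery metrics against the generator's ground truth."""
    truth_j = ds.truth_junctions()
    truth_coords = {(r.chrom, r.start, r.end, r.strand) for r in truth_j.itertuples()}
    called = {(r.chrom, r.start, r.end, r.strand) for r in junctions.itertuples()}
    # support exactness over truth cells with >= 1 crossing
    sup = ds.truth_support.set_index(["circ_id", "sample"])["crossings"]
    n_cells = 0
    n_exact = 0
    for (cid, sample), cross in sup.items():
        detected = (circ_counts.loc[cid, sample]
                    if cid in circ_counts.index else 0)
        if cross > 0:
            n_cells += 1
            n_exact += int(detected == cross)
        elif cid in circ_counts.index:
            n_cells += 1
            n_exact += int(detected == 0)
    truth_edges = set()
    for c in ds.circuits:
        truth_edges.add((c.circ_id, c.mirna_id))
        for m in c.mrna_ids:
            truth_edges.add((c.mirna_id, m))
    net_edges = set(net_ec.edges)
    tp = len(net_edges & truth_edges)
    recovered = 0
    for c in ds.circuits:
        has_sponge = net_ec.has_edge(c.circ_id, c.mirna_id)
        has_target = any(net_ec.has_edge(c.mirna_id, m) for m in c.mrna_ids)
        recovered += int(has_sponge and has_target)
    annotated = records[records["status"] == "annotated"]
    host_truth = dict(zip(truth_j.circ_id, truth_j.host_gene))
    coord_to_id = {f"{r.chrom}:{r.start}-{r.end}:{r.strand}": r.circ_id
                   for r in truth_j.itertuples()}
    n_host_ok = sum(
        host_truth.get(coord_to_id.get(r.circ_id)) == r.host_gene
        for r in annotated.itertuples())
    return dict(
        n_planted_circuits=len(ds.circuits),
        n_circuits_recovered=recovered,
        path_recovery_rate=recovered / max(1, len(ds.circuits)),
        edge_precision=tp / max(1, len(net_edges)),
        edge_recall=tp / max(1, len(truth_edges)),
        n_network_edges=len(net_edges),
        n_network_nodes=net_ec.number_of_nodes(),
        junction_false_calls=len(called - truth_coords),
        junction_recall=len(called & truth_coords) / max(1, len(truth_coords)),
        support_exact_fraction=n_exact / max(1, n_cells),
        annotation_host_accuracy=n_host_ok / max(1, len(annotated)),
    )
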