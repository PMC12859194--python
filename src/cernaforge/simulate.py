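"""Synthetic ceRNA study generator.

Builds every input the discovery pipeline consumes — a genome, gene models,
linear and circular transcripts, junction-spanning segment alignments,
three-group count matrices with planted fold changes, planted miRNA response
elements (MREs), endothelial-expression lists, pathway gene sets, and qPCR Ct
tables — together with ground-truth tables sufficient to score recovery.

The default study design mirrors a three-group left-ventricle cohort:
non-ischemic controls (n=12), ischemic heart disease (n=12), and ischemic
heart disease with type-2 diabetes (n=11), sequenced at 100-nt read length.
Counts are negative-binomial (gamma-Poisson); a fixed seed gives
byte-identical outputs (numpy PCG64 generator, single sequential stream).

Planted "circuits" are sponging motifs: a circRNA carrying a seed-match site
for one miRNA (optionally straddling the back-splice junction), whose
expression change is mirrored inversely by the miRNA and positively by the
miRNA's planted mRNA targets — the pattern the network stage should recover
as a circRNA -> miRNA -> mRNA path.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from ._seq import complement, normalize, revcomp, to_rna

_BASES = np.frombuffer(b"ACGT", dtype="S1")

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class PlantedCircuit:
    """Ground-truth sponging circuit planted into the simulation.

    ``circ_log2fc`` maps group name -> log2 fold change versus the reference
    (first) group. The miRNA and mRNA effects default to the ceRNA
    expectation: miRNA moves opposite to the circRNA, targets move with it.
    """

    circ_id: str
    mirna_id: str
    mrna_ids: tuple[str, ...]
    circ_log2fc: Mapping[str, float]
    mre_on_junction: bool = True
    mrna_site_class: Mapping[str, str] | None = None
    mirna_log2fc: Mapping[str, float] | None = None
    mrna_log2fc: Mapping[str, float] | None = None

    def site_class_for(self, mrna_id: str) -> str:
        if self.mrna_site_class is None:
            return "8mer"
        return self.mrna_site_class[mrna_id]

    def effective_mirna_log2fc(self) -> dict[str, float]:
        if self.mirna_log2fc is not None:
            return dict(self.mirna_log2fc)
        return {g: -v for g, v in self.circ_log2fc.items()}

    def effective_mrna_log2fc(self) -> dict[str, float]:
        if self.mrna_log2fc is not None:
            return dict(self.mrna_log2fc)
        return dict(self.circ_log2fc)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and scale parameters for the generator."""

    seed: int = 0
    n_genes: int = 300
    n_circ: int = 50
    n_mirnas: int = 30
    groups: tuple[tuple[str, int], ...] = (("nonIHD", 12), ("IHD", 12), ("IHD_T2DM", 11))
    depth: float = 1e5
    dispersion: float = 0.1
    planted_circuits: tuple[PlantedCircuit, ...] | None = None
    utr_len: int = 300
    read_len: int = 100
    flank: int = 100
    mirna_len: int = 22
    circ_reads_mean: float = 150.0
    linear_reads_mean: float = 10.0
    chrom_len: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_circ", "n_mirnas", "utr_len", "read_len", "flank", "mirna_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth <= 0 or self.circ_reads_mean <= 0 or self.linear_reads_mean < 0:
            raise ValueError("depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, n in self.groups:
            if n < 2:
                raise ValueError(f"group {name!r} needs >= 2 samples")
        if self.n_circ > self.n_genes:
            raise ValueError("n_circ cannot exceed n_genes")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)

    @property
    def reference_group(self) -> str:
        return self.groups[0][0]


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate one chromosome of i.i.d. A/C/G/T and multi-exon gene models.

    Returns ``(genome, models)`` where genome maps chromosome name to
    sequence and models has one row per gene with 0-based half-open,
    non-overlapping exon intervals.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom = "chr1"
    cursor = 300
    rows = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(2, 6))
        ex_lens = rng.integers(120, 301, n_ex)
        introns = rng.integers(60, 201, n_ex - 1)
        starts, ends = [], []
        pos = cursor
        for i in range(n_ex):
            starts.append(pos)
            pos += int(ex_lens[i])
            ends.append(pos)
            if i < n_ex - 1:
                pos += int(introns[i])
        cursor = pos + int(rng.integers(200, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            dict(gene_id=f"g{gi:04d}", chrom=chrom, strand=strand,
                 exon_starts=tuple(starts), exon_ends=tuple(ends))
        )
    length = cursor + 300
    if config.chrom_len is not None:
        if length > config.chrom_len:
            raise ValueError(
                f"gene layout ({length} nt) exceeds configured chromosome length {config.chrom_len}"
            )
        length = config.chrom_len
    seq = _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")
    models = pd.DataFrame(rows)
    return {chrom: seq}, models


def spliced_sequence(genome: Mapping[str, str], chrom: str,
                     exon_starts: Sequence[int], exon_ends: Sequence[int],
                     strand: str) -> str:
    """Spliced transcript sequence in transcription (5'->3') orientation."""
    concat = "".join(genome[chrom][s:e] for s, e in zip(exon_starts, exon_ends))
    return concat if strand == "+" else revcomp(concat)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def simulate_transcripts(models: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One linear isoform per gene plus circular isoforms on random hosts.

    Each circle covers a contiguous exon run of its host gene ("exons i..j"
    style). Donor = 3' end of the last exon in the circle, acceptor = 5' end
    of the first, both strand-aware; stored coordinates are the
    genomic-leftmost ``start`` and rightmost ``end`` of the circle span.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    rows = []
    for row in models.itertuples():
        rows.append(_tx_row(f"tx_{row.gene_id}", row, "linear", 0, len(row.exon_starts) - 1, config))
    host_idx = rng.choice(len(models), size=config.n_circ, replace=False)
    for ci, gi in enumerate(host_idx):
        row = models.iloc[int(gi)]
        n_ex = len(row.exon_starts)
        span = int(rng.integers(2, min(3, n_ex) + 1)) if n_ex >= 2 else 1
        first = int(rng.integers(0, n_ex - span + 1))
        rows.append(_tx_row(f"circ_{ci:04d}", row, "circular", first, first + span - 1, config))
    return pd.DataFrame(rows)


def _tx_row(tx_id, gene_row, kind, first, last, config):
    starts = gene_row.exon_starts[first:last + 1]
    ends = gene_row.exon_ends[first:last + 1]
    length = sum(e - s for s, e in zip(starts, ends))
    if kind == "circular" and first == last and length < 2 * config.flank:
        warnings.warn(
            f"{tx_id}: single-exon circle shorter than 2*flank; junction sequence wraps",
            stacklevel=2,
        )
    if gene_row.strand == "+":
        acceptor, donor = starts[0], ends[-1]
    else:
        acceptor, donor = ends[-1], starts[0]
    return dict(
        tx_id=tx_id, gene_id=gene_row.gene_id, kind=kind, chrom=gene_row.chrom,
        strand=gene_row.strand, first_exon=first, last_exon=last,
        start=starts[0], end=ends[-1], donor=donor, acceptor=acceptor,
        exon_starts=tuple(starts), exon_ends=tuple(ends), length=length,
    )


def transcript_sequence(genome: Mapping[str, str], tx) -> str:
    """Spliced sequence of a transcript-table row (namedtuple or Series)."""
    return spliced_sequence(genome, tx.chrom, tx.exon_starts, tx.exon_ends, tx.strand)


def _spliced_pos_to_genomic(tx, pos: int) -> int:
    """Genomic coordinate of spliced position ``pos`` (transcription order)."""
    lens = [e - s for s, e in zip(tx.exon_starts, tx.exon_ends)]
    if tx.strand == "+":
        order = range(len(lens))
    else:
        order = range(len(lens) - 1, -1, -1)
    for i in order:
        if pos < lens[i]:
            if tx.strand == "+":
                return tx.exon_starts[i] + pos
            return tx.exon_ends[i] - 1 - pos
        pos -= lens[i]
    raise IndexError("spliced position beyond transcript length")


def _spliced_interval_to_segments(tx, s: int, e: int) -> list[tuple[int, int]]:
    """Map non-wrapping spliced interval [s, e) to genomic (start, end) pairs
    in read order (strand-aware)."""
    lens = [ln_e - ln_s for ln_s, ln_e in zip(tx.exon_starts, tx.exon_ends)]
    idx = range(len(lens)) if tx.strand == "+" else range(len(lens) - 1, -1, -1)
    out: list[tuple[int, int]] = []
    cum = 0
    for i in idx:
        lo, hi = cum, cum + lens[i]
        cum = hi
        a, b = max(s, lo), min(e, hi)
        if a >= b:
            continue
        if tx.strand == "+":
            out.append((tx.exon_starts[i] + (a - lo), tx.exon_starts[i] + (b - lo)))
        else:
            out.append((tx.exon_ends[i] - (b - lo), tx.exon_ends[i] - (a - lo)))
    return out


# ---------------------------------------------------------------------------
# miRNAs, UTRs and MRE planting
# ---------------------------------------------------------------------------

def simulate_mirnas(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random mature miRNA sequences (RNA alphabet)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    out = {}
    for i in range(config.n_mirnas):
        seq = _BASES[rng.integers(0, 4, config.mirna_len)].tobytes().decode("ascii")
        out[f"mir_{i:03d}"] = to_rna(seq)
    return out


def simulate_utrs(models: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random 3'UTR sequence per gene (DNA alphabet)."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    return {
        row.gene_id: _BASES[rng.integers(0, 4, config.utr_len)].tobytes().decode("ascii")
        for row in models.itertuples()
    }


def _site_payload(mirna_seq: str, site_class: str) -> tuple[str, int, int]:
    """Planted string with guard bases forcing exactly ``site_class``.

    Returns (payload, site_offset_within_payload, site_length). The site
    itself is the reverse complement of miRNA seed positions 2-8 (or 2-7)
    with the target-side adenine rules of the canonical site classes.
    """
    m = normalize(mirna_seq)
    core7 = revcomp(m[1:8])        # complement of m8 followed by match to 2-7
    match6 = core7[1:]
    not_m8 = "C" if core7[0] != "C" else "G"
    if site_class == "8mer":
        return core7 + "A", 0, 8
    if site_class == "7mer-m8":
        return core7 + "C", 0, 7
    if site_class == "7mer-A1":
        return not_m8 + match6 + "A", 1, 7
    if site_class == "6mer":
        return not_m8 + match6 + "C", 1, 6
    raise ValueError(f"unknown site class {site_class!r}")


def plant_mres(genome: Mapping[str, str], transcripts: pd.DataFrame,
               mirnas: Mapping[str, str], utrs: Mapping[str, str],
               circuits: Sequence[PlantedCircuit], config: SimConfig,
               rng: np.random.Generator | None = None,
               max_retries: int = 50):
    """Write seed-match sites into the genome (circRNA bodies/junctions) and
    3'UTRs; returns (genome', utrs', truth_sites table).

    Junction-spanning sites straddle circular position 0: in
    junction-centered coordinates the site starts before and ends after the
    back-splice point.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    g_edit = {c: bytearray(s, "ascii") for c, s in genome.items()}
    utr_edit = {k: v for k, v in utrs.items()}
    tx_by_id = {t.tx_id: t for t in transcripts.itertuples()}
    truth = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    for circuit in circuits:
        _validate_circuit(circuit, tx_by_id, mirnas, utr_edit)
        tx = tx_by_id[circuit.circ_id]
        L = tx.length
        payload, off, site_len = _site_payload(mirnas[circuit.mirna_id], "8mer")
        if circuit.mre_on_junction:
            start = L - site_len // 2  # straddles circular position 0
        else:
            start = min(L // 3, L - site_len)
        for i, base in enumerate(payload):
            pos = (start + i) % L
            gpos = _spliced_pos_to_genomic(tx, pos)
            b = base if tx.strand == "+" else complement(base)
            g_edit[tx.chrom][gpos] = ord(b)
        truth.append(dict(
            target_id=circuit.circ_id, target_kind="circRNA",
            mirna_id=circuit.mirna_id, position=start % L, site_class="8mer",
            junction_spanning=bool(circuit.mre_on_junction and start + site_len > L),
        ))
        for mrna_id in circuit.mrna_ids:
            cls = circuit.site_class_for(mrna_id)
            payload, off, site_len = _site_payload(mirnas[circuit.mirna_id], cls)
            seq = utr_edit[mrna_id]
            taken = occupied.setdefault(mrna_id, [])
            for _ in range(max_retries):
                p = int(rng.integers(0, len(seq) - len(payload) + 1))
                if all(p + len(payload) + 1 <= a or p >= b + 1 for a, b in taken):
                    break
            else:
                raise RuntimeError(f"could not place site in UTR of {mrna_id}")
            utr_edit[mrna_id] = seq[:p] + payload + seq[p + len(payload):]
            taken.append((p, p + len(payload)))
            truth.append(dict(
                target_id=mrna_id, target_kind="mRNA_3UTR",
                mirna_id=circuit.mirna_id, position=p + off, site_class=cls,
                junction_spanning=False,
            ))

    genome_out = {c: b.decode("ascii") for c, b in g_edit.items()}
    truth_df = pd.DataFrame(
        truth, columns=["target_id", "target_kind", "mirna_id", "position",
                        "site_class", "junction_spanning"])
    return genome_out, utr_edit, truth_df


def _validate_circuit(circuit, tx_by_id, mirnas, utrs):
    if circuit.circ_id not in tx_by_id or tx_by_id[circuit.circ_id].kind != "circular":
        raise ValueError(f"planted circuit references unknown circRNA {circuit.circ_id!r}")
    if circuit.mirna_id not in mirnas:
        raise ValueError(f"planted circuit references unknown miRNA {circuit.mirna_id!r}")
    for m in circuit.mrna_ids:
        if m not in utrs:
            raise ValueError(f"planted circuit references unknown mRNA {m!r}")


# ---------------------------------------------------------------------------
# segment alignments
# ---------------------------------------------------------------------------

def make_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for gname, n in config.groups:
        for i in range(n):
            rows.append(dict(sample=f"{gname}_{i + 1:02d}", group=gname))
    return pd.DataFrame(rows)


def simulate_segment_alignments(transcripts: pd.DataFrame, config: SimConfig,
                                rng: np.random.Generator | None = None,
                                circ_log2fc: Mapping[tuple[str, str], float] | None = None):
    """Simulate read->genome segment alignments for every sample.

    Reads start uniformly along each transcript. A read crossing the
    back-splice junction of a circular transcript is emitted as consecutive
    segments whose genomic order is inverted relative to read order — the
    detection criterion downstream. Reads from circular transcripts are drawn
    negative-binomially around ``circ_reads_mean`` scaled by any planted
    log2 fold change, so detected junction support carries the planted
    effects.

    Returns ``(segments, truth_support)``: the segment table
    (read_id, segment_index, chrom, start, end, strand, sample) and the
    ground-truth junction-crossing count per (circ, sample).
    """
    rng = np.random.default_rng(config.seed + 5) if rng is None else rng
    circ_log2fc = circ_log2fc or {}
    design = make_design(config)
    circ_txs = [t for t in transcripts.itertuples() if t.kind == "circular"]
    lin_txs = [t for t in transcripts.itertuples() if t.kind == "linear"]
    rl = config.read_len
    recs: list[tuple] = []
    support: dict[tuple[str, str], int] = {}

    for srow in design.itertuples():
        sample, group = srow.sample, srow.group
        counter = 0
        for tx in circ_txs:
            mean = config.circ_reads_mean * 2.0 ** circ_log2fc.get((tx.tx_id, group), 0.0)
            n_reads = _nb_draw(rng, np.array([mean]), config.dispersion)[0]
            L = tx.length
            starts = rng.integers(0, L, int(n_reads))
            n_cross = 0
            for s in starts:
                s = int(s)
                read_id = f"{sample}:r{counter:07d}"
                counter += 1
                seg_i = 0
                pos = s
                remaining = rl
                while remaining > 0:
                    take = min(remaining, L - pos)
                    for gs, ge in _spliced_interval_to_segments(tx, pos, pos + take):
                        recs.append((read_id, seg_i, tx.chrom, gs, ge, tx.strand, sample))
                        seg_i += 1
                    remaining -= take
                    pos = (pos + take) % L
                    if remaining > 0:
                        n_cross += 1  # wrapped across the back-splice point
            support[(tx.tx_id, sample)] = n_cross
        for tx in lin_txs:
            n_reads = rng.poisson(config.linear_reads_mean)
            L = tx.length
            hi = max(1, L - rl + 1)
            starts = rng.integers(0, hi, int(n_reads))
            for s in starts:
                s = int(s)
                read_id = f"{sample}:r{counter:07d}"
                counter += 1
                for seg_i, (gs, ge) in enumerate(
                        _spliced_interval_to_segments(tx, s, min(s + rl, L))):
                    recs.append((read_id, seg_i, tx.chrom, gs, ge, tx.strand, sample))

    segments = pd.DataFrame(
        recs, columns=["read_id", "segment_index", "chrom", "start", "end", "strand", "sample"])
    sup_rows = [dict(circ_id=k[0], sample=k[1], crossings=v) for k, v in support.items()]
    truth_support = pd.DataFrame(sup_rows, columns=["circ_id", "sample", "crossings"])
    return segments, truth_support


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw; dispersion 0 degenerates to Poisson."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def simulate_counts(feature_ids: Sequence[str], config: SimConfig,
                    rng: np.random.Generator | None = None,
                    effects: Mapping[tuple[str, str], float] | None = None,
                    design: pd.DataFrame | None = None):
    """Negative-binomial count matrix (features x samples) with planted
    log2 fold changes applied to group means.

    ``effects`` maps (feature_id, group) -> log2FC vs the reference group.
    Returns (counts DataFrame, truth_effects DataFrame).
    """
    rng = np.random.default_rng(config.seed + 6) if rng is None else rng
    effects = effects or {}
    design = make_design(config) if design is None else design
    n_feat = len(feature_ids)
    w = rng.lognormal(0.0, 1.0, n_feat)
    base = config.depth * w / w.sum()
    cols = {}
    for srow in design.itertuples():
        mult = np.array([2.0 ** effects.get((f, srow.group), 0.0) for f in feature_ids])
        size_factor = rng.lognormal(0.0, 0.15)
        cols[srow.sample] = _nb_draw(rng, base * mult * size_factor, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    truth = pd.DataFrame(
        [dict(feature_id=f, group=g, log2fc=v) for (f, g), v in effects.items()],
        columns=["feature_id", "group", "log2fc"])
    return counts, truth


# ---------------------------------------------------------------------------
# default circuits, expression lists, gene sets, Ct tables
# ---------------------------------------------------------------------------

def default_planted_circuits(transcripts: pd.DataFrame, mirnas: Mapping[str, str],
                             config: SimConfig, n_circuits: int = 5,
                             mrnas_per_circuit: int = 4,
                             target_group: str | None = None) -> tuple[PlantedCircuit, ...]:
    """Five-circuit default: |log2FC| >= 1.5 circRNA effects in the disease
    contrast, 8mer/7mer sites, first circuit's MRE on the junction (the rest
    alternate junction/body placement)."""
    target_group = target_group or config.groups[-1][0]
    circ_ids = [t.tx_id for t in transcripts.itertuples() if t.kind == "circular"]
    host = {t.tx_id: t.gene_id for t in transcripts.itertuples() if t.kind == "circular"}
    gene_ids = sorted({t.gene_id for t in transcripts.itertuples() if t.kind == "linear"})
    lfcs = [2.0, -1.8, 1.6, 1.7, -1.5, 1.9, -1.6, 1.5][:n_circuits]
    classes = ["8mer", "7mer-m8", "8mer", "7mer-A1"]
    circuits = []
    used_mrnas: set[str] = set()
    host_genes = set(host.values())
    pool = [g for g in gene_ids if g not in host_genes]
    k = 0
    for i in range(n_circuits):
        mrnas = []
        while len(mrnas) < mrnas_per_circuit:
            g = pool[k % len(pool)]
            k += 1
            if g not in used_mrnas:
                mrnas.append(g)
                used_mrnas.add(g)
        circuits.append(PlantedCircuit(
            circ_id=circ_ids[i],
            mirna_id=f"mir_{i:03d}",
            mrna_ids=tuple(mrnas),
            circ_log2fc={target_group: lfcs[i]},
            mre_on_junction=(i % 2 == 0),
            mrna_site_class={m: classes[j % len(classes)] for j, m in enumerate(mrnas)},
        ))
    return tuple(circuits)


def build_effect_maps(circuits: Sequence[PlantedCircuit]):
    """Flatten circuits into per-layer (feature, group) -> log2FC maps."""
    circ_fx: dict[tuple[str, str], float] = {}
    mir_fx: dict[tuple[str, str], float] = {}
    mrna_fx: dict[tuple[str, str], float] = {}
    for c in circuits:
        for g, v in c.circ_log2fc.items():
            circ_fx[(c.circ_id, g)] = v
        for g, v in c.effective_mirna_log2fc().items():
            mir_fx[(c.mirna_id, g)] = v
        for g, v in c.effective_mrna_log2fc().items():
            for m in c.mrna_ids:
                mrna_fx[(m, g)] = v
    return circ_fx, mir_fx, mrna_fx


def simulate_expressed_sets(circ_ids: Sequence[str], mirna_ids: Sequence[str],
                            mrna_ids: Sequence[str], circuits: Sequence[PlantedCircuit],
                            rng: np.random.Generator, frac: float = 0.75):
    """Cell-type (endothelial) expression lists per layer: every planted
    circuit member plus a random majority of the remaining features."""
    must_circ = {c.circ_id for c in circuits}
    must_mir = {c.mirna_id for c in circuits}
    must_mrna = {m for c in circuits for m in c.mrna_ids}

    def pick(ids, must):
        rest = [i for i in ids if i not in must]
        n = int(round(frac * len(rest)))
        chosen = set(rng.choice(rest, size=n, replace=False)) if n else set()
        return set(must) | chosen

    return {
        "circRNA": pick(list(circ_ids), must_circ),
        "miRNA": pick(list(mirna_ids), must_mir),
        "mRNA": pick(list(mrna_ids), must_mrna),
    }


def simulate_gene_sets(mrna_ids: Sequence[str], circuits: Sequence[PlantedCircuit],
                       rng: np.random.Generator, n_random_sets: int = 6) -> dict[str, list[str]]:
    """GMT-style pathway sets; 'angiogenesis' contains the planted targets."""
    planted = sorted({m for c in circuits for m in c.mrna_ids})
    ids = list(mrna_ids)
    sets: dict[str, list[str]] = {}
    extra = [g for g in ids if g not in planted]
    sets["angiogenesis"] = planted + sorted(rng.choice(extra, size=min(10, len(extra)), replace=False))
    half = planted[: max(1, len(planted) // 2)]
    sets["VEGF_signaling"] = half + sorted(rng.choice(extra, size=min(8, len(extra)), replace=False))
    for i in range(n_random_sets):
        size = int(rng.integers(15, 31))
        sets[f"random_set_{i:02d}"] = sorted(rng.choice(ids, size=min(size, len(ids)), replace=False))
    return sets


def simulate_ct_table(rng: np.random.Generator | None = None,
                      conditions: Mapping[str, float] | None = None,
                      calibrator: str = "control", target_gene: str = "circNPHP1",
                      reference_gene: str = "18S", n_replicates: int = 3,
                      noise_sd: float = 0.05, base_dct: float = 8.0,
                      ref_ct: float = 14.0) -> pd.DataFrame:
    """Ct table implying known fold changes per condition vs the calibrator.

    ``conditions`` maps condition name -> true fold change (calibrator 1.0).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    conditions = dict(conditions) if conditions else {"control": 1.0, "hypoxia": 4.0}
    conditions.setdefault(calibrator, 1.0)
    rows = []
    for cond, fold in conditions.items():
        dct = base_dct - math.log2(fold)
        for rep in range(1, n_replicates + 1):
            ref = ref_ct + rng.normal(0.0, noise_sd)
            rows.append(dict(
                sample_id=f"{cond}_{rep}", condition=cond, target_gene=target_gene,
                reference_gene=reference_gene,
                ct_target=round(ref + dct + rng.normal(0.0, noise_sd), 3),
                ct_reference=round(ref, 3), replicate=rep,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    models: pd.DataFrame
    transcripts: pd.DataFrame
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    circuits: tuple[PlantedCircuit, ...]
    design: pd.DataFrame
    segments: pd.DataFrame
    truth_support: pd.DataFrame
    counts_circ: pd.DataFrame
    counts_mirna: pd.DataFrame
    counts_mrna: pd.DataFrame
    truth_effects: pd.DataFrame
    truth_sites: pd.DataFrame
    expressed_sets: dict[str, set[str]]
    gene_sets: dict[str, list[str]]
    ct_table: pd.DataFrame

    @property
    def circ_sequences(self) -> dict[str, str]:
        """Spliced circular sequences (post MRE planting)."""
        return {
            t.tx_id: transcript_sequence(self.genome, t)
            for t in self.transcripts.itertuples() if t.kind == "circular"
        }

    def truth_junctions(self) -> pd.DataFrame:
        rows = [
            dict(circ_id=t.tx_id, chrom=t.chrom, start=t.start, end=t.end,
                 strand=t.strand, host_gene=t.gene_id)
            for t in self.transcripts.itertuples() if t.kind == "circular"
        ]
        return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator with a single sequential RNG stream."""
    rng = np.random.default_rng(config.seed)
    genome, models = simulate_genome(config, rng)
    transcripts = simulate_transcripts(models, config, rng)
    mirnas = simulate_mirnas(config, rng)
    utrs = simulate_utrs(models, config, rng)
    circuits = (config.planted_circuits if config.planted_circuits is not None
                else default_planted_circuits(transcripts, mirnas, config))
    genome, utrs, truth_sites = plant_mres(
        genome, transcripts, mirnas, utrs, circuits, config, rng)
    circ_fx, mir_fx, mrna_fx = build_effect_maps(circuits)
    design = make_design(config)
    segments, truth_support = simulate_segment_alignments(
        transcripts, config, rng, circ_log2fc=circ_fx)
    circ_ids = [t.tx_id for t in transcripts.itertuples() if t.kind == "circular"]
    mrna_ids = sorted({t.gene_id for t in transcripts.itertuples() if t.kind == "linear"})
    counts_circ, fx_c = simulate_counts(circ_ids, config, rng, circ_fx, design)
    counts_mirna, fx_m = simulate_counts(sorted(mirnas), config, rng, mir_fx, design)
    counts_mrna, fx_g = simulate_counts(mrna_ids, config, rng, mrna_fx, design)
    fx_c["layer"], fx_m["layer"], fx_g["layer"] = "circRNA", "miRNA", "mRNA"
    truth_effects = pd.concat([fx_c, fx_m, fx_g], ignore_index=True)
    expressed = simulate_expressed_sets(circ_ids, sorted(mirnas), mrna_ids, circuits, rng)
    gene_sets = simulate_gene_sets(mrna_ids, circuits, rng)
    ct_table = simulate_ct_table(rng)
    return SimulatedDataset(
        config=config, genome=genome, models=models, transcripts=transcripts,
        mirna_seqs=mirnas, utr_seqs=utrs, circuits=circuits, design=design,
        segments=segments, truth_support=truth_support, counts_circ=counts_circ,
        counts_mirna=counts_mirna, counts_mrna=counts_mrna,
        truth_effects=truth_effects, truth_sites=truth_sites,
        expressed_sets=expressed, gene_sets=gene_sets, ct_table=ct_table,
    )


def write_all(ds: SimulatedDataset, outdir: str | os.PathLike) -> None:
    """Write every external artifact of the generator into ``outdir``."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    io.write_fasta(ds.genome, j("genome.fa"))
    io.write_gtf(ds.models, j("models.gtf"))
    io.write_bed12(ds.models, j("models.bed"))
    io.write_tsv(ds.segments, j("segments.tsv"))
    io.write_tsv(ds.counts_circ.reset_index(), j("counts_circ.tsv"))
    io.write_tsv(ds.counts_mirna.reset_index(), j("counts_mirna.tsv"))
    io.write_tsv(ds.counts_mrna.reset_index(), j("counts_mrna.tsv"))
    io.write_tsv(ds.truth_effects, j("truth_effects.tsv"))
    io.write_tsv(ds.truth_sites, j("truth_sites.tsv"))
    io.write_tsv(ds.truth_support, j("truth_support.tsv"))
    io.write_fasta(ds.mirna_seqs, j("mirnas.fa"))
    io.write_fasta(ds.utr_seqs, j("utrs.fa"))
    io.write_fasta(ds.circ_sequences, j("circ_seqs.fa"))
    io.write_tsv(ds.design, j("design.tsv"))
    io.write_gmt(ds.gene_sets, j("pathways.gmt"))
    ds.ct_table.to_csv(j("ct.csv"), index=False, lineterminator="\n")
    for layer, fname in (("circRNA", "expressed_EC_circ.txt"),
                         ("miRNA", "expressed_EC_mirna.txt"),
                         ("mRNA", "expressed_EC_mrna.txt")):
        with open(j(fname), "w") as fh:
            for name in sorted(ds.expressed_sets[layer]):
                fh.write(name + "\n")
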