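"""Back-splice junction calling, annotation, presence filtering, FPM
normalization and junction-sequence construction.

The detection criterion is inverted exon order: two consecutive aligned
segments of one read, on one chromosome and strand, whose genomic order is
reversed relative to read order indicate a back-splice. On the plus strand
the second segment starts upstream of the first; mirrored on the minus
strand. Junction coordinates are stored 0-based half-open with ``start`` the
genomic-leftmost position (acceptor side on '+', donor side on '-') and
``end`` the rightmost.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import spliced_sequence

_SEGMENT_COLS = ("read_id", "segment_index", "chrom", "start", "end", "strand")


def call_backsplice(segments: pd.DataFrame) -> pd.DataFrame:
    """Call back-splice junctions from a read-segment table.

    Parameters
    ----------
    segments
        One row per aligned segment with columns read_id, segment_index,
        chrom, start, end, strand and optionally sample. Segments of a read
        are taken in ``segment_index`` (read) order.

    Returns
    -------
    DataFrame with one row per junction (chrom, start, end, strand) and one
    support column per sample (``support_<sample>``), sorted canonically.
    A read wrapping the junction twice contributes two crossings.
    """
    missing = [c for c in _SEGMENT_COLS if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    bad = ~(
        (segments["start"] < segments["end"])
        & (segments["start"] >= 0)
        & segments["strand"].isin(["+", "-"])
    )
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"malformed segment row at line {line}: "
                         f"{segments.iloc[line].to_dict()}")
    has_sample = "sample" in segments.columns
    seg = segments.sort_values(["read_id", "segment_index"], kind="mergesort").reset_index(drop=True)
    if len(seg) < 2:
        return _empty_junction_table(sorted(seg["sample"].unique()) if has_sample else ["all"])

    rid = seg["read_id"].to_numpy()
    chrom = seg["chrom"].to_numpy()
    strand = seg["strand"].to_numpy()
    start = seg["start"].to_numpy()
    end = seg["end"].to_numpy()
    pair = (rid[:-1] == rid[1:]) & (chrom[:-1] == chrom[1:]) & (strand[:-1] == strand[1:])
    plus = pair & (strand[:-1] == "+") & (start[1:] < start[:-1])
    minus = pair & (strand[:-1] == "-") & (start[1:] > start[:-1])
    hit = plus | minus
    j_start = np.where(plus[hit], start[1:][hit], start[:-1][hit])
    j_end = np.where(plus[hit], end[:-1][hit], end[1:][hit])
    sample = (seg["sample"].to_numpy()[:-1][hit] if has_sample
              else np.repeat("all", int(hit.sum())))
    calls = pd.DataFrame(dict(
        chrom=chrom[:-1][hit], start=j_start, end=j_end, strand=strand[:-1][hit],
        sample=sample))
    all_samples = sorted(seg["sample"].unique()) if has_sample else ["all"]
    if calls.empty:
        return _empty_junction_table(all_samples)
    wide = (calls.groupby(["chrom", "start", "end", "strand", "sample"])
            .size().unstack("sample", fill_value=0))
    for s in all_samples:
        if s not in wide.columns:
            wide[s] = 0
    wide = wide[all_samples]
    wide.columns = [f"support_{s}" for s in all_samples]
    out = wide.reset_index().sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)
    return out


def _empty_junction_table(samples: Sequence[str]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "strand"] + [f"support_{s}" for s in samples]
    return pd.DataFrame(columns=cols)


def annotate(junctions: pd.DataFrame, models: pd.DataFrame) -> pd.DataFrame:
    """Annotate junctions against gene models by exact exon-boundary match.

    A junction is assigned to a gene when its start coincides with an
    annotated exon start and its end with an exon end of the same gene on
    the same chromosome and strand. A junction matching two genes is flagged
    ``ambiguous`` (one row per candidate); no match yields ``unannotated``.
    Exon indices are reported 1-based in transcription order.
    """
    by_loc: dict[tuple[str, str], list] = {}
    for g in models.itertuples():
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    rows = []
    for j in junctions.itertuples():
        candidates = []
        for g in by_loc.get((j.chrom, j.strand), []):
            if j.start in g.exon_starts and j.end in g.exon_ends:
                gi_first = g.exon_starts.index(j.start)
                gi_last = g.exon_ends.index(j.end)
                if gi_first <= gi_last:
                    candidates.append((g, gi_first, gi_last))
        circ_id = f"{j.chrom}:{j.start}-{j.end}:{j.strand}"
        base = dict(circ_id=circ_id, chrom=j.chrom, start=j.start, end=j.end, strand=j.strand)
        if not candidates:
            rows.append(dict(base, host_gene=None, exon_first=None, exon_last=None,
                             spliced_length=None, exon_starts=None, exon_ends=None,
                             status="unannotated"))
            continue
        status = "annotated" if len(candidates) == 1 else "ambiguous"
        for g, gi_first, gi_last in candidates:
            n_ex = len(g.exon_starts)
            if j.strand == "+":
                first_tx, last_tx = gi_first + 1, gi_last + 1
            else:
                first_tx, last_tx = n_ex - gi_last, n_ex - gi_first
            starts = g.exon_starts[gi_first:gi_last + 1]
            ends = g.exon_ends[gi_first:gi_last + 1]
            rows.append(dict(
                base, host_gene=g.gene_id, exon_first=first_tx, exon_last=last_tx,
                spliced_length=sum(e - s for s, e in zip(starts, ends)),
                exon_starts=starts, exon_ends=ends, status=status))
    return pd.DataFrame(rows, columns=[
        "circ_id", "chrom", "start", "end", "strand", "host_gene", "exon_first",
        "exon_last", "spliced_length", "exon_starts", "exon_ends", "status"])


def presence_filter(counts: pd.DataFrame, design: pd.DataFrame, min_frac: float = 0.5):
    """Per-group presence filter: a feature is expressed in group g iff it is
    nonzero in at least ceil(min_frac * n_g) of g's samples; a feature is kept
    overall iff expressed in at least one group.

    Returns ``(mask, kept)``: the feature-by-group boolean mask (enables
    per-group detection Venn counts) and the retained count matrix.
    """
    if not {"sample", "group"} <= set(design.columns):
        raise ValueError("design requires 'sample' and 'group' columns")
    missing = set(design["sample"]) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples absent from counts: {sorted(missing)}")
    mask = {}
    for group, sub in design.groupby("group", sort=False):
        samples = list(sub["sample"])
        if not samples:
            raise ValueError(f"empty group {group!r}")
        need = math.ceil(min_frac * len(samples))
        mask[group] = counts[samples].gt(0).sum(axis=1) >= need
    mask_df = pd.DataFrame(mask)
    kept = counts.loc[mask_df.any(axis=1)]
    return mask_df, kept


def fpm_normalize(counts: pd.DataFrame,
                  library_sizes: pd.Series | Mapping[str, float] | None = None) -> pd.DataFrame:
    """Fragments-per-million: count / library size * 1e6.

    Library size defaults to the column sum, in which case each normalized
    column sums to 1e6.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if lib.isna().any():
        raise ValueError("library size missing for some samples")
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    return counts.div(lib, axis=1) * 1e6


def junction_sequence(spliced_seq: str, flank: int = 100) -> str:
    """The 2*flank-nt junction sequence: the last ``flank`` nt of the spliced
    circular sequence followed by its first ``flank`` nt. The circle is
    periodic, so flanks longer than the circle wrap around.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    L = len(spliced_seq)
    if L == 0:
        raise ValueError("empty circular sequence")
    return "".join(spliced_seq[(L - flank + i) % L] for i in range(2 * flank))


def circ_spliced_sequence(genome: Mapping[str, str], record) -> str:
    """Reconstruct the spliced circular sequence of an annotated CircRecord
    row from the genome (transcription orientation)."""
    if record.exon_starts is None:
        raise ValueError(f"{record.circ_id}: unannotated junction has no exon model")
    return spliced_sequence(genome, record.chrom, record.exon_starts,
                            record.exon_ends, record.strand)
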