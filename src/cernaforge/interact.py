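"""Seed-match prediction of sponging (circRNA-miRNA) and targeting
(miRNA-mRNA) interactions.

Sites are canonical seed matches to miRNA positions 2-8 with perfect
Watson-Crick pairing (no G:U wobble): 6mer (match to 2-7), 7mer-A1 (6mer
followed by an A in the target), 7mer-m8 (match to 2-8) and 8mer (7mer-m8
followed by an A). Each occurrence is assigned its most specific class.

Binding "probability" is a transparent surrogate score per class —
{8mer: 0.99, 7mer-m8: 0.97, 7mer-A1: 0.96, 6mer: 0.90} — calibrated so the
conventional >0.95 retention cutoff keeps 7mer/8mer sites and drops 6mers.
It stands in for database-derived binding probabilities and is swappable.

Circular targets are scanned on the spliced circular sequence concatenated
with its own first 7 nt so a junction-spanning site is found exactly once;
positions are reported modulo the circle length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from ._seq import VALID, normalize, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SITE_SCORES: dict[str, float] = {
    "8mer": 0.99, "7mer-m8": 0.97, "7mer-A1": 0.96, "6mer": 0.90,
}
DEFAULT_CUTOFF = 0.95

_EDGE_COLUMNS = ["source_id", "target_id", "edge_kind", "best_class", "best_score",
                 "best_position", "n_sites", "junction_spanning", "retained"]


@dataclass(frozen=True)
class SeedSite:
    """One seed-match occurrence on a target sequence.

    ``position`` is 0-based on the target; for circular targets it is given
    in the circle's own coordinates (modulo length), and ``junction_spanning``
    marks sites whose interval crosses circular position 0.
    """

    target_id: str
    target_kind: str          # "circRNA" or "mRNA_3UTR"
    position: int
    site_class: str
    score: float
    junction_spanning: bool = False
    length: int = 0


def find_seed_sites(mirna_seq: str, target_seq: str, circular: bool = False,
                    target_id: str = "", target_kind: str = "",
                    scores: Mapping[str, float] | None = None) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one target sequence.

    U and T are treated identically. Windows containing ambiguous
    nucleotides are skipped with a log notice.
    """
    scores = DEFAULT_SITE_SCORES if scores is None else scores
    m = normalize(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    t = normalize(target_seq)
    L = len(t)
    if L < 6:
        return []
    seed = m[1:8]                       # positions 2-8
    if not set(seed) <= VALID:
        logger.info("ambiguous nucleotides in miRNA seed; no sites reported")
        return []
    core7 = revcomp(seed)               # complement of m8, then match to 2-7
    match6 = core7[1:]
    m8_base = core7[0]
    scan = t + t[:7] if circular else t
    sites: list[SeedSite] = []
    p = scan.find(match6)
    while p != -1 and p < L:
        window = scan[max(0, p - 1):p + 7]
        if set(window) <= VALID:
            if circular:
                prev = scan[(p - 1) % L] if p == 0 else scan[p - 1]
            else:
                prev = scan[p - 1] if p > 0 else ""
            nxt = scan[p + 6] if p + 6 < len(scan) else ""
            has_m8 = prev == m8_base
            has_a1 = nxt == "A"
            if has_m8 and has_a1:
                cls, start, length = "8mer", p - 1, 8
            elif has_m8:
                cls, start, length = "7mer-m8", p - 1, 7
            elif has_a1:
                cls, start, length = "7mer-A1", p, 7
            else:
                cls, start, length = "6mer", p, 6
            pos = start % L if circular else start
            sites.append(SeedSite(
                target_id=target_id, target_kind=target_kind, position=pos,
                site_class=cls, score=float(scores[cls]),
                junction_spanning=bool(circular and pos + length > L),
                length=length))
        else:
            logger.info("site at %d skipped: ambiguous nucleotides", p)
        p = scan.find(match6, p + 1)
    return sites


def score_sites(sites: list[SeedSite], scores: Mapping[str, float] | None = None) -> list[SeedSite]:
    """Re-score sites under a (possibly custom) class->score map."""
    scores = DEFAULT_SITE_SCORES if scores is None else scores
    return [SeedSite(s.target_id, s.target_kind, s.position, s.site_class,
                     float(scores[s.site_class]), s.junction_spanning, s.length)
            for s in sites]


def _predict_edges(targets: Mapping[str, str], mirnas: Mapping[str, str],
                   circular: bool, edge_kind: str, target_kind: str,
                   cutoff: float, scores: Mapping[str, float] | None,
                   source_is_target: bool) -> pd.DataFrame:
    rows = []
    for t_id in sorted(targets):
        t_seq = targets[t_id]
        if not t_seq:
            logger.warning("missing sequence for %s; skipped", t_id)
            continue
        for m_id in sorted(mirnas):
            sites = find_seed_sites(mirnas[m_id], t_seq, circular=circular,
                                    target_id=t_id, target_kind=target_kind,
                                    scores=scores)
            if not sites:
                continue
            best = max(sites, key=lambda s: (s.score, -s.position))
            retained = best.score > cutoff
            relevant = [s for s in sites if s.score > cutoff] if retained else sites
            source, target = (t_id, m_id) if source_is_target else (m_id, t_id)
            rows.append(dict(
                source_id=source, target_id=target, edge_kind=edge_kind,
                best_class=best.site_class, best_score=best.score,
                best_position=best.position, n_sites=len(sites),
                junction_spanning=any(s.junction_spanning for s in relevant),
                retained=retained))
    df = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    return df.sort_values(["source_id", "target_id"], kind="mergesort").reset_index(drop=True)


def predict_sponge_edges(circ_seqs: Mapping[str, str], mirnas: Mapping[str, str],
                         cutoff: float = DEFAULT_CUTOFF,
                         scores: Mapping[str, float] | None = None) -> pd.DataFrame:
    """circRNA -> miRNA sponging edges from full spliced circular sequences.

    One row per (circRNA, miRNA) pair with at least one site; ``retained``
    is True iff the best site's score exceeds ``cutoff``. ``n_sites``
    distinguishes single-MRE from multi-MRE sponges, and
    ``junction_spanning`` marks pairs whose site straddles the back-splice.
    """
    return _predict_edges(circ_seqs, mirnas, circular=True, edge_kind="sponge",
                          target_kind="circRNA", cutoff=cutoff, scores=scores,
                          source_is_target=True)


def predict_target_edges(mirnas: Mapping[str, str], utrs: Mapping[str, str],
                         cutoff: float = DEFAULT_CUTOFF,
                         scores: Mapping[str, float] | None = None) -> pd.DataFrame:
    """miRNA -> mRNA targeting edges from linear 3'UTR scans."""
    return _predict_edges(utrs, mirnas, circular=False, edge_kind="target",
                          target_kind="mRNA_3UTR", cutoff=cutoff, scores=scores,
                          source_is_target=False)
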