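"""Between-sample normalization and two-group differential expression.

Normalization is trimmed-mean-of-M-values (TMM): pairwise log ratios against
a reference sample are double-trimmed (by M and by average abundance A) and
combined by inverse-asymptotic-variance weights; factors are renormalized to
geometric mean 1. The DE statistic is a moderated t: the per-feature pooled
variance is shrunk toward the feature-wide mean variance with a configurable
prior degrees of freedom (0 gives the ordinary pooled t; an unequal-variance
Welch t is available via ``stat="welch"``). Volcano classes follow the
conventional two-threshold scheme (|log2FC| >= 0.58, P < 0.05 by default),
with the fold-change boundary inclusive and the P boundary strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

VOLCANO_CLASSES = ("both", "fc_only", "p_only", "ns")


@dataclass
class TMMFactors:
    factors: pd.Series           # per-sample scaling factor, geometric mean 1
    reference: str               # reference sample id
    m_trim: float
    a_trim: float


def tmm_factors(counts: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05) -> TMMFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference is the sample whose 75th percentile of count/library-size
    is closest to the mean across samples. For each sample, features with a
    zero in either member of the pair are excluded; the top and bottom
    ``m_trim`` of M values and ``a_trim`` of A values are trimmed; the factor
    is 2 to the weighted mean of the remaining M values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    frac = counts.div(lib, axis=1)
    uq = frac.quantile(0.75, axis=0)
    ref = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref].to_numpy(dtype=float)
    nr = lib[ref]
    raw = {}
    for s in counts.columns:
        yk = counts[s].to_numpy(dtype=float)
        nk = lib[s]
        raw[s] = _pair_factor(yk, nk, yr, nr, m_trim, a_trim)
    f = pd.Series(raw, dtype=float)
    f = f / np.exp(np.log(f).mean())
    return TMMFactors(factors=f, reference=ref, m_trim=m_trim, a_trim=a_trim)


def _pair_factor(yk, nk, yr, nr, m_trim, a_trim) -> float:
    ok = (yk > 0) & (yr > 0)
    if not ok.any():
        return 1.0
    yk, yr = yk[ok], yr[ok]
    pk, pr = yk / nk, yr / nr
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    # inverse asymptotic variance of M on the fraction scale: evaluating the
    # binomial variance at a common nominal depth keeps the factor exactly
    # invariant to rescaling a single library (the constant cancels in the
    # weighted mean)
    w = 1.0 / ((1.0 - pk) / pk + (1.0 - pr) / pr)
    n = len(m)
    lo_m = math.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    mean_m = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    if not np.isfinite(mean_m):
        return 1.0
    return 2.0 ** mean_m


def tmm_normalize(counts: pd.DataFrame, factors: TMMFactors | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    factors = tmm_factors(counts) if factors is None else factors
    eff = counts.sum(axis=0).astype(float) * factors.factors
    return counts.div(eff, axis=1) * 1e6


def _parse_contrast(contrast) -> tuple[str, str]:
    if isinstance(contrast, str):
        test, ref = contrast.split(":")
        return test, ref
    test, ref = contrast
    return test, ref


def de_test(log_expr: pd.DataFrame, design: pd.DataFrame, contrast,
            stat: str = "moderated", prior_df: float = 4.0,
            lfc_threshold: float = 0.58, p_threshold: float = 0.05) -> pd.DataFrame:
    """Two-group differential expression on log2 expression values.

    ``contrast`` is ``(test_group, ref_group)`` or ``"test:ref"``; log2FC is
    the test-minus-reference mean difference. ``stat="moderated"`` shrinks
    the pooled variance toward the feature-wide mean variance with
    ``prior_df`` prior degrees of freedom; ``prior_df=0`` is the ordinary
    pooled t; ``stat="welch"`` uses the unequal-variance t.
    """
    test, ref = _parse_contrast(contrast)
    groups = dict(design.groupby("group")["sample"].apply(list))
    for g in (test, ref):
        if g not in groups:
            raise ValueError(f"group {g!r} not in design")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    xb = log_expr[groups[test]].to_numpy(dtype=float)
    xa = log_expr[groups[ref]].to_numpy(dtype=float)
    nb, na = xb.shape[1], xa.shape[1]
    mb, ma = xb.mean(axis=1), xa.mean(axis=1)
    lfc = mb - ma
    if stat == "welch":
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
        tstat = np.asarray(res.statistic)
        dof = np.full(len(lfc), np.nan)
    elif stat == "moderated":
        vb = xb.var(axis=1, ddof=1)
        va = xa.var(axis=1, ddof=1)
        dfg = na + nb - 2
        s2 = ((nb - 1) * vb + (na - 1) * va) / dfg
        s2_0 = float(s2.mean())
        s2_t = (prior_df * s2_0 + dfg * s2) / (prior_df + dfg)
        se = np.sqrt(s2_t * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / np.where(se > 0, se, np.nan)
            tstat = np.where(se > 0, tstat,
                             np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
        dof = np.full(len(lfc), dfg + prior_df)
        p = 2.0 * stats.t.sf(np.abs(tstat), dfg + prior_df)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(dict(
        feature_id=log_expr.index, log2fc=lfc, t=tstat, df=dof, p_raw=p,
        fdr_bh=bh_fdr(p)))
    return classify_volcano(out, lfc=lfc_threshold, p=p_threshold)


def classify_volcano(de: pd.DataFrame, lfc: float = 0.58, p: float = 0.05) -> pd.DataFrame:
    """Assign volcano classes: ``both`` (|log2FC| >= lfc and P < p),
    ``fc_only``, ``p_only``, ``ns``. FC boundary inclusive, P strict."""
    out = de.copy()
    fc_pass = out["log2fc"].abs() >= lfc
    p_pass = out["p_raw"] < p
    cls = np.where(fc_pass & p_pass, "both",
                   np.where(fc_pass, "fc_only", np.where(p_pass, "p_only", "ns")))
    out["volcano_class"] = cls
    return out


def volcano_counts(de: pd.DataFrame) -> pd.Series:
    return de["volcano_class"].value_counts().reindex(VOLCANO_CLASSES, fill_value=0)


def significant_features(de: pd.DataFrame) -> set[str]:
    """Features in the ``both`` volcano class (the network-admission set)."""
    return set(de.loc[de["volcano_class"] == "both", "feature_id"])


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pseudobulk_cpm(counts: pd.DataFrame, cell_types, donors):
    """Pseudobulk counts-per-million from a cell-by-gene UMI matrix.

    UMIs are summed over all cells of one cell type from one donor, then each
    (donor, cell_type) profile is normalized to counts per million. Returns
    ``(cpm, log2cpm)`` indexed by (donor, cell_type); strata with no cells do
    not appear, and all-zero strata are dropped with a log notice.
    """
    cell_types = pd.Series(list(cell_types), index=counts.index, name="cell_type")
    donors = pd.Series(list(donors), index=counts.index, name="donor")
    pseudo = counts.groupby([donors, cell_types], observed=True).sum()
    totals = pseudo.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.info("dropping all-zero pseudobulk strata: %s", list(pseudo.index[empty]))
        pseudo = pseudo.loc[~empty]
        totals = totals.loc[~empty]
    cpm = pseudo.div(totals, axis=0) * 1e6
    return cpm, np.log2(cpm + 1.0)
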