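"""qRT-PCR quantification arithmetic: Livak relative expression and the
pulldown/digestion fold-enrichment formulas.

All folds are pure-Livak, i.e. amplification efficiency fixed at 2:
dCt = Ct(target) - Ct(reference), ddCt = dCt - mean dCt(calibrator),
fold = 2^(-ddCt). Rows with Ct above the detectability threshold (35 cycles
by default) in either the target or reference channel are excluded before
any averaging and reported, never silently zeroed. Replicates are aggregated
by the geometric mean of per-replicate folds (equivalently, the arithmetic
mean of ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_DETECTION_LIMIT = 35.0

_REQUIRED = ("sample_id", "condition", "target_gene", "reference_gene",
             "ct_target", "ct_reference")


@dataclass
class DdctResult:
    """Per-row folds plus per-(condition, target) aggregates and the rows
    excluded as undetectable."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    excluded: pd.DataFrame


def _check_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct_target"] <= 0).any() or (ct["ct_reference"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct.copy()


def ddct(ct: pd.DataFrame, calibrator_condition: str,
         detection_limit: float = CT_DETECTION_LIMIT) -> DdctResult:
    """Livak relative expression 2^(-ddCt) against a calibrator condition.

    The calibrator's mean relative expression is 1 by construction (its mean
    dCt defines the baseline). Undetectable rows (target or reference Ct
    above ``detection_limit``) are excluded and returned separately.
    """
    ct = _check_table(ct)
    undet = (ct["ct_target"] > detection_limit) | (ct["ct_reference"] > detection_limit)
    excluded = ct[undet].copy()
    excluded["reason"] = "undetectable"
    ct = ct[~undet].copy()
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    out_rows = []
    for target, sub in ct.groupby("target_gene", sort=False):
        cal = sub[sub["condition"] == calibrator_condition]
        if cal.empty:
            raise ValueError(
                f"no detectable calibrator ({calibrator_condition!r}) replicate "
                f"for target {target!r}")
        base = cal["dct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - base
        sub["fold"] = 2.0 ** (-sub["ddct"])
        out_rows.append(sub)
    per_sample = pd.concat(out_rows, ignore_index=True)
    summary = (per_sample.groupby(["target_gene", "condition"], sort=False)
               .agg(mean_ddct=("ddct", "mean"), n=("ddct", "size"))
               .reset_index())
    summary["fold"] = 2.0 ** (-summary["mean_ddct"])  # geometric mean of folds
    return DdctResult(per_sample=per_sample, summary=summary, excluded=excluded)


def pulldown_fold_enrichment_ddct(ct: pd.DataFrame, control_probe: str = "control_probe",
                                  detection_limit: float = CT_DETECTION_LIMIT) -> pd.DataFrame:
    """Probe-versus-control-probe fold enrichment for affinity pulldowns.

    ``condition`` holds the probe name; the calibrator is the control probe.
    Targets undetectable in a probe's pulldown are reported with status
    ``below_detection`` and no fold (never a silent zero).
    """
    res = ddct(ct, calibrator_condition=control_probe, detection_limit=detection_limit)
    out = res.summary.rename(columns={"condition": "probe", "fold": "fold_enrichment"})
    out["status"] = "ok"
    if not res.excluded.empty:
        miss = (res.excluded.groupby(["target_gene", "condition"]).size()
                .reset_index(name="n_undetectable")
                .rename(columns={"condition": "probe"}))
        miss["mean_ddct"] = np.nan
        miss["fold_enrichment"] = np.nan
        miss["status"] = "below_detection"
        miss["n"] = 0
        out = pd.concat([out, miss[["target_gene", "probe", "mean_ddct", "n",
                                    "fold_enrichment", "status"]]],
                        ignore_index=True)
    return out


def mirna_pulldown_enrichment(pd_mirna: float, pd_control: float,
                              input_mirna: float, input_control: float) -> float:
    """Biotin-miRNA pulldown fold enrichment X/Y.

    X = pulldown(miRNA)/pulldown(control), Y = input(miRNA)/input(control);
    the input ratio corrects the pulldown ratio for starting abundance.
    """
    for name, v in (("pd_mirna", pd_mirna), ("pd_control", pd_control),
                    ("input_mirna", input_mirna), ("input_control", input_control)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    x = pd_mirna / pd_control
    y = input_mirna / input_control
    return x / y


def rnase_r_resistance(ct: pd.DataFrame, undigested_condition: str = "undigested",
                       detection_limit: float = CT_DETECTION_LIMIT) -> pd.DataFrame:
    """Fold RNA remaining after exonuclease digestion, relative to undigested.

    A circular (exonuclease-resistant) species gives ~1; a degraded linear
    species gives << 1. Species undetectable after digestion are reported as
    ``below_detection``.
    """
    res = ddct(ct, calibrator_condition=undigested_condition,
               detection_limit=detection_limit)
    out = res.summary.rename(columns={"fold": "fold_remaining"})
    out["status"] = "ok"
    if not res.excluded.empty:
        miss = (res.excluded.groupby(["target_gene", "condition"]).size()
                .reset_index(name="n_undetectable"))
        miss["mean_ddct"] = np.nan
        miss["fold_remaining"] = np.nan
        miss["status"] = "below_detection"
        miss["n"] = 0
        out = pd.concat([out, miss[["target_gene", "condition", "mean_ddct", "n",
                                    "fold_remaining", "status"]]], ignore_index=True)
    return out


def spike_in_normalize(ct: pd.DataFrame, calibrator_condition: str,
                       spike_column: str = "ct_spike",
                       detection_limit: float = CT_DETECTION_LIMIT) -> DdctResult:
    """Livak quantification with an external spike-in as the reference term.

    For plasma samples without a reliable endogenous reference, the spike-in
    Ct (e.g. cel-miR-39 added at fixed amount during extraction) replaces the
    reference-gene Ct; otherwise identical to :func:`ddct`. A +1 cycle shift
    of the spike in one sample doubles that sample's corrected fold.
    """
    ct = ct.copy()
    if spike_column not in ct.columns:
        raise ValueError(f"missing spike-in column {spike_column!r}")
    if ct[spike_column].isna().any():
        bad = ct.loc[ct[spike_column].isna(), "sample_id"].tolist()
        raise ValueError(f"missing spike-in Ct for samples: {bad}")
    ct["ct_reference"] = ct[spike_column]
    ct["reference_gene"] = "spike_in"
    return ddct(ct, calibrator_condition=calibrator_condition,
                detection_limit=detection_limit)
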