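"""Relative expression: 2^-ddCt qPCR analysis and Western densitometry.

qPCR: each sample carries duplicate-well Ct values per gene; two
housekeeping genes (Rplp0 and Gapdh in the study) normalise the target.
The reference Ct is the arithmetic mean of the two housekeeper mean Cts
(equivalent to geometric-mean normalisation on the linear scale),
dCt = Ct_target - Ct_ref, ddCt subtracts the control-group mean dCt,
and the fold change is 2^-ddCt with amplification efficiency fixed at 2.

Densitometry: band intensities are divided by the loading control
(HSP70) and expressed as fold change versus the control-group mean.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
REPLICATE_RANGE_QC = 0.5  # cycles; duplicate wells further apart are flagged


def collapse_replicates(
    ct_values: Sequence[float], qc_range: float = REPLICATE_RANGE_QC
) -> tuple[float, bool]:
    """Mean Ct over replicate wells and a QC flag for discordant duplicates.

    Returns (mean_ct, flagged); flagged when max-min exceeds ``qc_range``.
    """
    vals = [float(v) for v in ct_values]
    if not vals:
        raise ValueError("no replicate Ct values")
    if any(v <= 0 for v in vals):
        raise ValueError("Ct values must be positive")
    flagged = (max(vals) - min(vals)) > qc_range
    return sum(vals) / len(vals), flagged


def collapse_ct_table(
    ct: pd.DataFrame, qc_range: float = REPLICATE_RANGE_QC
) -> pd.DataFrame:
    """Collapse a well-level table (sample_id, group, gene, ct) to one mean
    Ct per sample x gene, carrying the duplicate-spread QC flag."""
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (sample, group, gene), sub in ct.groupby(
        ["sample_id", "group", "gene"], sort=False
    ):
        mean_ct, flagged = collapse_replicates(sub["ct"].tolist(), qc_range)
        rows.append(
            {"sample_id": sample, "group": group, "gene": gene,
             "ct": mean_ct, "qc_flag": flagged}
        )
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_genes: Sequence[str] = ("Rplp0", "Gapdh"),
    control_group: str = CONTROL,
    qc_range: float = REPLICATE_RANGE_QC,
) -> pd.DataFrame:
    """Per-sample fold changes by the 2^-ddCt method with dual references.

    ``ct`` is well-level (sample_id, group, gene, ct); wells are first
    collapsed to per-sample mean Cts. Samples missing either reference
    gene are excluded with a warning. The control baseline is the
    arithmetic mean of control-sample dCts per target gene, so the
    geometric mean of control fold changes is exactly 1.

    Returns a tidy frame: sample_id, group, gene, delta_ct,
    delta_delta_ct, fold_change.
    """
    collapsed = collapse_ct_table(ct, qc_range)
    refs = list(reference_genes)
    wide = collapsed.pivot_table(index=["sample_id", "group"], columns="gene",
                                 values="ct", aggfunc="first")
    have_refs = wide[refs].notna().all(axis=1) if set(refs) <= set(wide.columns) \
        else pd.Series(False, index=wide.index)
    dropped = wide.index[~have_refs].get_level_values("sample_id").tolist()
    if dropped:
        warnings.warn(
            f"samples missing a reference gene, excluded: {dropped}", stacklevel=2
        )
    wide = wide[have_refs]
    if wide.empty:
        raise ValueError("no sample has both reference genes")
    ref_ct = wide[refs].mean(axis=1)

    targets = [g for g in wide.columns if g not in refs]
    rows = []
    for gene in targets:
        dct = wide[gene] - ref_ct
        ctrl = dct[dct.index.get_level_values("group") == control_group].dropna()
        if ctrl.empty:
            raise ValueError(f"no control-group dCt for gene {gene!r}")
        baseline = float(ctrl.mean())
        for (sample, group), value in dct.dropna().items():
            ddct = float(value) - baseline
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "gene": gene,
                    "delta_ct": float(value),
                    "delta_delta_ct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                }
            )
    return pd.DataFrame(rows)


def group_fold_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean fold change and s.e.m. per gene x group."""
    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    return (
        folds.groupby(["gene", "group"])["fold_change"]
        .agg(mean="mean", sem=sem, n="count")
        .reset_index()
    )


def densitometry_fold_change(
    bands: pd.DataFrame, control_group: str = CONTROL
) -> pd.DataFrame:
    """Loading-normalised band intensities as fold change vs the control mean.

    ``bands``: sample_id, group, protein, intensity, hsp70_intensity.
    normalised = intensity / hsp70_intensity; fold = normalised divided
    by the mean normalised value over control samples of that protein.
    """
    required = {"sample_id", "group", "protein", "intensity", "hsp70_intensity"}
    missing = required - set(bands.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (bands["hsp70_intensity"] <= 0).any():
        raise ValueError("loading-control intensity must be positive")
    if (bands["intensity"] <= 0).any():
        raise ValueError("band intensity must be positive")
    df = bands.copy()
    df["normalized"] = df["intensity"] / df["hsp70_intensity"]
    out = []
    for protein, sub in df.groupby("protein", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "normalized"]
        if ctrl.empty:
            raise ValueError(f"no control samples for protein {protein!r}")
        baseline = float(ctrl.mean())
        sub = sub.copy()
        sub["fold_change"] = sub["normalized"] / baseline
        out.append(sub)
    return pd.concat(out, ignore_index=True)
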