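"""Relative gene expression by the 2^-dCt method, with fold changes.

Given a long-format qPCR table (sample_id, condition, gene, ct), replicate
Ct values are averaged per sample and gene, dCt = Ct(target) -
Ct(reference) is computed against a reference gene (RPLP0 in the
motivating experiments), and relative expression is 2^-dCt.  Fold changes
divide each sample's relative expression by the mean relative expression
of a basal condition, so the basal group's mean fold is 1 by construction
(equivalently 2^-ddCt).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["relative_expression", "fold_change"]

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "ct")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    bad = ~np.isfinite(table["ct"]) | (table["ct"] <= 0)
    if bad.any():
        log.warning("excluding %d rows with non-finite or non-positive Ct", int(bad.sum()))
        table = table[~bad]
    return table


def relative_expression(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-sample, per-target dCt and 2^-dCt.

    Replicate Ct rows (same sample and gene) are averaged first.  Samples
    without a reference-gene measurement are excluded with a warning.

    Returns a frame with columns sample_id, condition, gene, mean_ct,
    reference_ct, delta_ct, rel_expr.
    """
    table = _validate(pd.DataFrame(table))
    mean_ct = (
        table.groupby(["sample_id", "condition", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
        .rename(columns={"ct": "mean_ct"})
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene][["sample_id", "mean_ct"]].rename(
        columns={"mean_ct": "reference_ct"}
    )
    if len(ref) == 0:
        raise ValueError(f"reference gene {reference_gene!r} not found in table")
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    merged = targets.merge(ref, on="sample_id", how="left")
    no_ref = merged["reference_ct"].isna()
    if no_ref.any():
        excluded = sorted(merged.loc[no_ref, "sample_id"].unique())
        log.warning("samples without reference gene excluded: %s", excluded)
        merged = merged[~no_ref]
    merged["delta_ct"] = merged["mean_ct"] - merged["reference_ct"]
    merged["rel_expr"] = 2.0 ** (-merged["delta_ct"])
    return merged.reset_index(drop=True)


def fold_change(
    rel: pd.DataFrame, basal_condition: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold change of relative expression versus a basal condition.

    Per gene, each sample's ``rel_expr`` is divided by the mean
    ``rel_expr`` of the basal group, so basal folds average to 1.

    Returns (per-sample frame with a ``fold`` column, per-condition
    summary with mean and SE of fold by gene and condition).
    """
    rel = pd.DataFrame(rel)
    if basal_condition not in set(rel["condition"]):
        raise ValueError(f"basal condition {basal_condition!r} not present")
    out = []
    for gene, sub in rel.groupby("gene", sort=True):
        basal_mean = sub.loc[sub["condition"] == basal_condition, "rel_expr"].mean()
        if not np.isfinite(basal_mean) or basal_mean == 0:
            raise ValueError(f"basal mean expression for gene {gene!r} is zero or undefined")
        sub = sub.copy()
        sub["fold"] = sub["rel_expr"] / basal_mean
        out.append(sub)
    per_sample = pd.concat(out, ignore_index=True)
    summary = (
        per_sample.groupby(["gene", "condition"], sort=True)["fold"]
        .agg(
            mean_fold="mean",
            se_fold=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    return per_sample, summary
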