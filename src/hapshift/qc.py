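"""Replicate-consistency filtering, decontamination and normalisation.

The order used by the pipeline mirrors the study workflow:
replicate filter -> negative-control subtraction -> relative proportions
-> replicate averaging (site-level vectors).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import ASVTable


def replicate_filter(table: ASVTable, min_replicates: int = 2, scope: str = "site") -> ASVTable:
    """Retain ASVs observed in more than one replicate sample.

    With ``scope="site"`` (default) an ASV must be present in
    ``min_replicates`` replicates of at least one site; ``scope="global"``
    counts replicates across all sites.  Retained ASVs keep all their
    counts.  Negative controls never count toward replication.
    """
    if scope not in ("site", "global"):
        raise ValueError("scope must be 'site' or 'global'")
    exp_cols = table.experimental_columns()
    meta = table.samples.loc[exp_cols]
    for site, group in meta.groupby("site_id"):
        if len(group) < min_replicates:
            warnings.warn(
                f"site {site} has fewer than {min_replicates} replicates; "
                "replicate filter cannot apply there",
                stacklevel=2,
            )
    present = table.counts[exp_cols] > 0
    if scope == "global":
        keep = present.sum(axis=1) >= min_replicates
    else:
        by_site = present.T.groupby(meta["site_id"]).sum().T  # asv x site
        keep = (by_site >= min_replicates).any(axis=1)
    kept = table.counts.loc[keep[keep].index]
    return ASVTable(
        counts=kept.copy(),
        sequences={a: table.sequences[a] for a in kept.index},
        samples=table.samples,
        log={**table.log, "replicate_filter_removed": int((~keep).sum())},
    )


def subtract_negative_controls(table: ASVTable) -> ASVTable:
    """Subtract the maximum negative-control count per ASV, flooring at zero.

    Negative-control columns are dropped afterwards, and ASVs reduced to
    all-zero are removed.
    """
    neg_cols = table.negative_columns()
    if not neg_cols:
        raise ValueError("no negative-control samples present")
    exp_cols = table.experimental_columns()
    max_neg = table.counts[neg_cols].max(axis=1)
    adjusted = table.counts[exp_cols].sub(max_neg, axis=0).clip(lower=0)
    n_floored = int(((table.counts[exp_cols].sub(max_neg, axis=0)) < 0).to_numpy().sum())
    out = ASVTable(
        counts=adjusted,
        sequences=dict(table.sequences),
        samples=table.samples,
        log={
            **table.log,
            "negatives_subtracted": {a: int(m) for a, m in max_neg.items() if m > 0},
            "floored_cells": n_floored,
        },
    )
    return out.drop_empty_asvs()


def to_relative_abundance(table: ASVTable) -> tuple[pd.DataFrame, list[str]]:
    """Divide each sample column by its total; returns (proportions, excluded).

    All-zero samples cannot be normalised; they are excluded and returned
    in the second element with a warning.
    """
    totals = table.counts.sum(axis=0)
    excluded = [s for s in table.counts.columns if totals[s] == 0]
    if excluded:
        warnings.warn(f"excluding all-zero samples: {excluded}", stacklevel=2)
    kept = [s for s in table.counts.columns if totals[s] > 0]
    if not kept:
        raise ValueError("no non-zero samples to normalise")
    props = table.counts[kept].div(totals[kept], axis=1)
    return props, excluded


def average_replicates(props: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate proportion vectors per site (ASV x site)."""
    meta = samples.loc[list(props.columns)]
    sites_with_samples = set(meta["site_id"])
    all_sites = set(samples.loc[~samples["is_negative_control"], "site_id"])
    for site in sorted(all_sites - sites_with_samples):
        warnings.warn(f"site {site} has no surviving replicates", stacklevel=2)
    return props.T.groupby(meta["site_id"]).mean().T


def qc_pipeline(
    table: ASVTable, min_replicates: int = 2, scope: str = "site"
) -> tuple[pd.DataFrame, ASVTable]:
    """Full QC chain; returns (site-level proportion table, filtered count table)."""
    filtered = replicate_filter(table, min_replicates=min_replicates, scope=scope)
    if filtered.negative_columns():
        filtered = subtract_negative_controls(filtered)
    if filtered.counts.empty:
        return pd.DataFrame(), filtered
    props, _ = to_relative_abundance(filtered)
    site_props = average_replicates(props, filtered.samples)
    return site_props, filtered
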