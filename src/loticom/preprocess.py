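"""Table-level preprocessing of OTU abundance tables.

The pipeline mirrors a standard 16S workflow once an OTU table exists:

1. within each (site, habitat) replicate group, keep a taxon only if it is
   present in at least a given fraction of the replicates (prevalence filter),
2. average replicate counts into one sample per (site, habitat),
3. round averaged counts to integers and rarefy every sample to a common
   depth by sampling without replacement,
4. remove low-abundance taxa (global relative-abundance cutoff) and taxa
   whose taxonomy matches an unwanted lineage (e.g. chloroplasts).

Defaults follow common practice for catchment-scale surveys: 75% replicate
prevalence, rarefaction to 24 007 reads, and a 0.01% abundance floor.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .core import HABITATS, SampleMetadata, TaxaTable

__all__ = [
    "remove_taxa_by_label",
    "replicate_prevalence_filter",
    "average_replicates",
    "averaged_metadata",
    "rarefy",
    "low_abundance_filter",
    "preprocess_pipeline",
]


def remove_taxa_by_label(
    table: TaxaTable, taxonomy: Mapping[str, str], pattern: str
) -> TaxaTable:
    """Drop taxa whose lineage string contains ``pattern`` (case-insensitive).

    Taxa missing from ``taxonomy`` are treated as non-matching and kept.
    """
    pat = pattern.lower()
    keep = [
        t for t in table.taxon_ids if pat not in str(taxonomy.get(t, "")).lower()
    ]
    if not keep:
        warnings.warn(
            f"pattern {pattern!r} matched every taxon; returning an empty table",
            stacklevel=2,
        )
    return TaxaTable(table.data.loc[keep].copy())


def _groups_for(table: TaxaTable, meta: SampleMetadata) -> dict[tuple[str, str], list[str]]:
    in_table = set(table.sample_ids)
    groups: dict[tuple[str, str], list[str]] = {}
    for key, members in meta.replicate_groups().items():
        present = [s for s in members if s in in_table]
        if not present:
            raise ValueError(
                f"replicate group (site={key[0]!r}, habitat={key[1]!r}) has no "
                "samples in the table"
            )
        groups[key] = present
    return groups


def replicate_prevalence_filter(
    table: TaxaTable, meta: SampleMetadata, threshold: float = 0.75
) -> TaxaTable:
    """Zero out taxa that occur in fewer than ``threshold`` of a group's replicates.

    Prevalence is evaluated per (site, habitat) replicate group; the rule is
    inclusive (a taxon present in exactly 75% of replicates passes at 0.75).
    Counts are zeroed within the failing group only — the same taxon may be
    perfectly real at another site.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    data = table.data.copy()
    for _, members in _groups_for(table, meta).items():
        block = data[members]
        prevalence = (block > 0).sum(axis=1) / len(members)
        failing = prevalence < threshold
        data.loc[failing, members] = 0.0
    return TaxaTable(data)


def average_replicates(table: TaxaTable, meta: SampleMetadata) -> TaxaTable:
    """Collapse each (site, habitat) replicate group to its arithmetic mean.

    Output samples are named ``{site}_{habitat}`` and ordered by site (order
    of first appearance in the metadata) then habitat (FL, PA, BF, SE).
    """
    groups = _groups_for(table, meta)
    site_order = list(dict.fromkeys(meta.data["site"]))
    ordered = sorted(
        groups, key=lambda k: (site_order.index(k[0]), HABITATS.index(k[1]))
    )
    cols = {}
    for site, habitat in ordered:
        cols[f"{site}_{habitat}"] = table.data[groups[(site, habitat)]].mean(axis=1)
    return TaxaTable(pd.DataFrame(cols))


def averaged_metadata(meta: SampleMetadata) -> SampleMetadata:
    """Metadata matching :func:`average_replicates` output (one row per group)."""
    site_order = list(dict.fromkeys(meta.data["site"]))
    keys = sorted(
        meta.replicate_groups(),
        key=lambda k: (site_order.index(k[0]), HABITATS.index(k[1])),
    )
    rows = [
        {"sample_id": f"{site}_{habitat}", "site": site, "habitat": habitat, "replicate": 1}
        for site, habitat in keys
    ]
    return SampleMetadata(pd.DataFrame(rows))


def rarefy(table: TaxaTable, depth: int, seed: int) -> TaxaTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Non-integer counts (e.g. replicate means) are rounded half-to-even first.
    Each column is then a multivariate-hypergeometric draw, so for a fixed
    seed the output is reproducible and column sums equal ``depth`` exactly.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = np.rint(table.values).astype(np.int64)
    totals = counts.sum(axis=0)
    short = np.nonzero(totals < depth)[0]
    if short.size:
        sid = table.sample_ids[short[0]]
        raise ValueError(
            f"sample {sid!r} has only {totals[short[0]]} reads after rounding; "
            f"cannot rarefy to {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return TaxaTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns, dtype=float)
    )


def low_abundance_filter(table: TaxaTable, threshold: float = 1e-4) -> TaxaTable:
    """Remove taxa whose total abundance is below ``threshold`` of the grand total.

    The cutoff is strict ("below"): a taxon sitting exactly at the cutoff is
    kept.  The fraction is taken of the whole-table grand total.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    row_sums = table.data.sum(axis=1)
    cutoff = threshold * row_sums.sum()
    return TaxaTable(table.data.loc[row_sums >= cutoff].copy())


def preprocess_pipeline(
    table: TaxaTable,
    meta: SampleMetadata,
    taxonomy: Mapping[str, str] | None = None,
    remove_pattern: str = "chloroplast",
    prevalence: float = 0.75,
    depth: int = 24_007,
    min_frac: float = 1e-4,
    seed: int = 0,
) -> tuple[TaxaTable, SampleMetadata, dict]:
    """Run the full preprocessing chain and return (table, metadata, log).

    Order: prevalence filter -> replicate averaging -> rounding + rarefaction
    -> low-abundance filter -> lineage-pattern removal.  The log records taxon
    and sample counts surviving each stage plus every parameter used.
    """
    log: dict = {
        "prevalence": prevalence,
        "depth": depth,
        "min_frac": min_frac,
        "seed": seed,
        "input_taxa": table.shape[0],
        "input_samples": table.shape[1],
    }
    t = replicate_prevalence_filter(table, meta, prevalence)
    log["taxa_after_prevalence"] = t.drop_empty_taxa().shape[0]
    t = average_replicates(t, meta)
    out_meta = averaged_metadata(meta)
    log["samples_after_averaging"] = t.shape[1]
    t = rarefy(t, depth, seed)
    t = low_abundance_filter(t, min_frac)
    log["taxa_after_low_abundance"] = t.shape[0]
    if taxonomy is not None:
        t = remove_taxa_by_label(t, taxonomy, remove_pattern)
    t = t.drop_empty_taxa()
    log["taxa_final"] = t.shape[0]
    return t, out_meta, log
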