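"""Habitat specificity, occupancy, specialist calling, and habitat overlap.

For taxon S and habitat H:

* specificity = (mean abundance of S over H's samples) / (sum of those
  habitat means over all habitats) — 1.0 means S occurs only in H;
* occupancy (fidelity) = fraction of H's samples in which S is present.

Specialists are taxa with both quantities at or above a threshold (0.7 by
default) within a habitat, evaluated over that habitat's most abundant taxa.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .core import HABITATS, SampleMetadata, TaxaTable

__all__ = [
    "top_n_by_abundance",
    "specificity",
    "occupancy",
    "habitat_mean_table",
    "spec_occu_table",
    "call_specialists",
    "habitat_overlap",
]


def _habitat_samples(table: TaxaTable, meta: SampleMetadata, habitat: str) -> list[str]:
    samples = [s for s in meta.samples_of_habitat(habitat) if s in set(table.sample_ids)]
    if not samples:
        raise ValueError(f"habitat {habitat!r} has no samples in the table")
    return samples


def top_n_by_abundance(table: TaxaTable, meta: SampleMetadata, habitat: str,
                       n: int = 500) -> list[str]:
    """The ``n`` taxa with the largest summed abundance across a habitat's samples.

    Ties at the boundary break deterministically toward the lexicographically
    smaller taxon id.  If ``n`` exceeds the taxon count, all taxa are returned.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    totals = table.data[_habitat_samples(table, meta, habitat)].sum(axis=1)
    order = sorted(totals.index, key=lambda t: (-totals[t], str(t)))
    return order[: min(n, len(order))]


def habitat_mean_table(table: TaxaTable, meta: SampleMetadata) -> pd.DataFrame:
    """Mean abundance of every taxon in every habitat present (taxa x habitats)."""
    cols = {}
    for h in meta.habitats_present():
        cols[h] = table.data[_habitat_samples(table, meta, h)].mean(axis=1)
    return pd.DataFrame(cols)


def specificity(table: TaxaTable, meta: SampleMetadata, taxon: str, habitat: str) -> float:
    """Specificity of one taxon for one habitat; NaN if the taxon is absent everywhere."""
    means = habitat_mean_table(table, meta)
    if taxon not in means.index:
        raise KeyError(f"unknown taxon {taxon!r}")
    if habitat not in means.columns:
        raise ValueError(f"habitat {habitat!r} has no samples")
    total = means.loc[taxon].sum()
    if total == 0:
        return float("nan")
    return float(means.loc[taxon, habitat] / total)


def occupancy(table: TaxaTable, meta: SampleMetadata, taxon: str, habitat: str) -> float:
    """Fraction of the habitat's samples in which the taxon is present (> 0)."""
    samples = _habitat_samples(table, meta, habitat)
    if taxon not in table.data.index:
        raise KeyError(f"unknown taxon {taxon!r}")
    row = table.data.loc[taxon, samples]
    return float((row > 0).sum() / len(samples))


def spec_occu_table(table: TaxaTable, meta: SampleMetadata, top_n: int = 500,
                    threshold: float = 0.7) -> pd.DataFrame:
    """Specificity and occupancy for each habitat's ``top_n`` most abundant taxa.

    Returns one row per (taxon, habitat) with columns ``taxon``, ``habitat``,
    ``specificity``, ``occupancy`` and ``specialist``.
    """
    means = habitat_mean_table(table, meta)
    mean_sums = means.sum(axis=1)
    frames = []
    for h in meta.habitats_present():
        taxa = top_n_by_abundance(table, meta, h, top_n)
        samples = _habitat_samples(table, meta, h)
        block = table.data.loc[taxa, samples]
        occ = (block > 0).sum(axis=1) / len(samples)
        with np.errstate(invalid="ignore"):
            spec = means.loc[taxa, h] / mean_sums.loc[taxa].replace(0, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "taxon": taxa,
                    "habitat": h,
                    "specificity": spec.to_numpy(),
                    "occupancy": occ.to_numpy(),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return call_specialists(records, threshold)


def call_specialists(records: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Flag records with specificity AND occupancy >= threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = records.copy()
    out["specialist"] = (
        (out["specificity"] >= threshold) & (out["occupancy"] >= threshold)
    ).fillna(False)
    return out


def habitat_overlap(table: TaxaTable, meta: SampleMetadata) -> dict[tuple[str, ...], int]:
    """Count taxa present in exactly each non-empty subset of habitats.

    Presence means abundance > 0 in at least one sample of the habitat.  The
    counts partition the observed taxa: summed over all subsets they equal the
    number of taxa present in >= 1 sample.  All non-empty subsets of the
    habitats present in the metadata are reported, including zero counts.
    """
    habitats = meta.habitats_present()
    presence = pd.DataFrame(
        {h: (table.data[_habitat_samples(table, meta, h)] > 0).any(axis=1)
         for h in habitats}
    )
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(habitats) + 1):
        for subset in combinations(habitats, r):
            in_subset = presence[list(subset)].all(axis=1)
            out_subset = ~presence[[h for h in habitats if h not in subset]].any(axis=1) \
                if len(subset) < len(habitats) else pd.Series(True, index=presence.index)
            counts[subset] = int((in_subset & out_subset).sum())
    return counts
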