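"""Domain containers and I/O: abundance tables, sample metadata, trees, distances.

The package works on three aligned objects: a taxa x samples abundance table
(:class:`TaxaTable`), per-sample metadata (:class:`SampleMetadata`) and a rooted
phylogeny whose tip labels match the table's taxon ids.  Distances between
samples or taxa are carried as :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "HABITATS",
    "TaxaTable",
    "SampleMetadata",
    "read_taxa_table",
    "write_taxa_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "DistanceMatrix",
]

#: The four habitat types: free-living plankton, particle-associated plankton,
#: benthic stone biofilm, and sediment.
HABITATS = ("FL", "PA", "BF", "SE")


class TaxaTable:
    """Abundance matrix with taxa as rows and samples as columns.

    Values are non-negative counts (or replicate-averaged counts).  Labels are
    unique; orientation is fixed — every operation in the package expects
    taxa-rows x sample-columns.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nt, ns = self.shape
        return f"<TaxaTable: {nt} taxa x {ns} samples>"

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxaTable) and self.data.equals(other.data)

    # -- convenience ---------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "TaxaTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return TaxaTable(self.data[list(sample_ids)].copy())

    def select_taxa(self, taxon_ids: Sequence[str]) -> "TaxaTable":
        missing = [t for t in taxon_ids if t not in self.data.index]
        if missing:
            raise KeyError(f"unknown taxon id(s): {missing}")
        return TaxaTable(self.data.loc[list(taxon_ids)].copy())

    def drop_empty_taxa(self) -> "TaxaTable":
        """Remove taxa with zero total abundance across all samples."""
        keep = self.data.sum(axis=1) > 0
        return TaxaTable(self.data.loc[keep].copy())

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.data.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise ValueError(f"sample {empty!r} has zero total abundance")
        return self.data / totals


class SampleMetadata:
    """Per-sample site, habitat and replicate labels.

    Habitat is restricted to the closed four-level set ``{FL, PA, BF, SE}``.
    Replicate groups — the unit of prevalence filtering and averaging — are
    defined by ``(site, habitat)``.
    """

    COLUMNS = ("sample_id", "site", "habitat", "replicate")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"metadata missing column(s): {missing}")
        data = data.loc[:, list(self.COLUMNS)].copy()
        if data["sample_id"].duplicated().any():
            dup = data.loc[data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        bad = set(data["habitat"]) - set(HABITATS)
        if bad:
            raise ValueError(
                f"unknown habitat label(s) {sorted(bad)}; expected one of {HABITATS}"
            )
        data["replicate"] = data["replicate"].astype(int)
        if (data["replicate"] < 1).any():
            raise ValueError("replicate numbers must be >= 1")
        data["sample_id"] = data["sample_id"].astype(str)
        data["site"] = data["site"].astype(str)
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def habitats_present(self) -> list[str]:
        return [h for h in HABITATS if h in set(self.data["habitat"])]

    def samples_of_habitat(self, habitat: str) -> list[str]:
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat {habitat!r}; expected one of {HABITATS}")
        sel = self.data["habitat"] == habitat
        return list(self.data.loc[sel, "sample_id"])

    def replicate_groups(self) -> dict[tuple[str, str], list[str]]:
        """Map (site, habitat) -> list of member sample ids."""
        groups: dict[tuple[str, str], list[str]] = {}
        for row in self.data.itertuples(index=False):
            groups.setdefault((row.site, row.habitat), []).append(row.sample_id)
        return groups

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SampleMetadata: {len(self.data)} samples>"


# ---------------------------------------------------------------------------
# table / metadata I/O (TSV is the contract)
# ---------------------------------------------------------------------------

def read_taxa_table(path: str | os.PathLike | io.TextIOBase) -> TaxaTable:
    """Read a tab-separated abundance table (first column ``taxon_id``).

    Duplicated ids and negative or non-numeric cells are hard errors.
    Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    try:
        values = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at taxon {df.index[i]!r} "
                        f"(row {i + 1}), sample {col!r} (column {j + 1})"
                    ) from None
        raise
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return TaxaTable(values)


def write_taxa_table(table: TaxaTable, path, header_comment: str | None = None) -> None:
    """Write a TaxaTable as TSV; values keep full repr precision."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("taxon_id\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        for taxon, row in table.data.iterrows():
            fh.write(str(taxon) + "\t" + "\t".join(repr(v) for v in row) + "\n")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        meta.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees and patristic distances
# ---------------------------------------------------------------------------

def read_newick(source) -> TreeNode:
    """Read a rooted newick tree; every edge must carry a branch length.

    ``source`` may be a path or a newick string.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(io.StringIO(source), format="newick")
    else:
        tree = TreeNode.read(str(source), format="newick")
    tips = list(tree.tips())
    labels = [t.name for t in tips]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))
        raise ValueError(f"duplicate tip label: {dup!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            where = node.name or "an internal node"
            raise ValueError(f"missing branch length on edge above {where}")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode, taxa: Iterable[str] | None = None) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between the requested tips.

    The distance between two tips is the sum of branch lengths along the path
    connecting them; ``d(i, i) = 0``.  Unknown taxa are a hard error — taxa in
    a table but absent from the tree must never be dropped silently.
    """
    tip_names = {t.name for t in tree.tips()}
    if taxa is None:
        taxa = sorted(tip_names)
    else:
        taxa = list(taxa)
        unknown = [t for t in taxa if t not in tip_names]
        if unknown:
            raise KeyError(f"taxa not found as tree tips: {unknown}")
    endpoints = {t.name: t for t in tree.tips() if t.name in set(taxa)}
    dm = tree.tip_tip_distances(endpoints=[endpoints[t] for t in taxa])
    return DistanceMatrix(dm.data, ids=list(dm.ids))
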