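"""Diversity, beta-diversity, dispersion and significance testing.

Alpha diversity (Shannon, Pielou), Whittaker's beta, Bray-Curtis
dissimilarities, principal-coordinates embedding, Anderson-style multivariate
dispersion (distance to group centroid), one-way PERMANOVA, one-way ANOVA
with Tukey HSD, and Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .core import SampleMetadata, TaxaTable

__all__ = [
    "shannon",
    "pielou",
    "whittaker_beta",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "distance_to_centroid",
    "DispersionResult",
    "permanova",
    "PermanovaResult",
    "anova_tukey",
    "AnovaTukeyResult",
    "bonferroni",
    "alpha_diversity_table",
]


def _clean_abundances(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValueError("abundances must be finite and non-negative")
    return x


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive relative abundances.

    Natural logarithm by default; pass ``base=2`` for bits.
    """
    x = _clean_abundances(abundances)
    if x.sum() == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    p = x[x > 0] / x.sum()
    h = float(scipy.stats.entropy(p))
    if base is not None:
        h /= np.log(base)
    return h


def pielou(abundances) -> float:
    """Pielou's evenness J = H / ln S, with S the number of positive taxa."""
    x = _clean_abundances(abundances)
    s = int((x > 0).sum())
    if s < 2:
        raise ValueError("Pielou's evenness requires >= 2 taxa with positive abundance")
    return shannon(x) / np.log(s)


def whittaker_beta(table: TaxaTable, samples: Sequence[str] | None = None) -> float:
    """Whittaker's beta = gamma / mean(alpha) - 1 on presence/absence.

    ``gamma`` is the richness of the pooled group; ``alpha`` the per-sample
    richness.  Always >= 0, and 0 iff all samples share one composition.
    """
    sub = table if samples is None else table.select_samples(list(samples))
    presence = sub.values > 0
    if presence.shape[1] < 2:
        raise ValueError("Whittaker's beta requires >= 2 samples")
    alphas = presence.sum(axis=0)
    if (alphas == 0).any():
        empty = sub.sample_ids[int(np.argmin(alphas))]
        raise ValueError(f"sample {empty!r} has zero richness")
    gamma = int(presence.any(axis=1).sum())
    return gamma / float(alphas.mean()) - 1.0


def bray_curtis(table: TaxaTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples on relative abundances."""
    rel = table.relative_abundance().to_numpy().T  # samples x taxa
    return DistanceMatrix(squareform(pdist(rel, metric="braycurtis")),
                          ids=table.sample_ids)


@dataclass
class PcoaResult:
    """Principal-coordinates embedding with negative eigenvalues retained.

    ``coords`` spans the positive-eigenvalue (real) axes, ``imag_coords`` the
    negative-eigenvalue axes (their squared contributions subtract); both are
    scaled by sqrt(|eigenvalue|).  Axes are ordered by decreasing eigenvalue.
    """

    ids: list[str]
    eigenvalues: np.ndarray
    coords: np.ndarray
    imag_coords: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical scaling (Gower centring + eigendecomposition) of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    centered = (centered + centered.T) / 2.0
    evals, evecs = scipy.linalg.eigh(centered)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos, neg = evals > tol, evals < -tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    imag_coords = evecs[:, neg] * np.sqrt(-evals[neg])
    return PcoaResult(list(dm.ids), evals, coords, imag_coords)


@dataclass
class DispersionResult:
    """Per-sample distance to the group centroid in principal-coordinates space."""

    distances: pd.Series  # indexed by sample id
    groups: pd.Series
    group_means: pd.Series

    def mean(self, group: str) -> float:
        return float(self.group_means[group])


def _as_group_series(groups, ids: Sequence[str]) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups.reindex(ids)
    groups = list(groups)
    if len(groups) != len(ids):
        raise ValueError("group labels must align with the distance-matrix ids")
    return pd.Series(groups, index=list(ids))


def distance_to_centroid(dm: DistanceMatrix, groups) -> DispersionResult:
    """Multivariate dispersion: distance of each sample to its group centroid.

    Follows the homogeneity-of-dispersions construction for semi-metric
    distances: the squared centroid distance is the contribution from the
    positive-eigenvalue axes minus the contribution from the
    negative-eigenvalue axes, clamped at zero before the square root.
    """
    grp = _as_group_series(groups, dm.ids)
    res = pcoa(dm)
    dist = pd.Series(np.nan, index=list(dm.ids), dtype=float)
    for g in grp.unique():
        members = np.asarray(grp.values == g)
        if members.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        c_pos = res.coords[members].mean(axis=0)
        c_neg = res.imag_coords[members].mean(axis=0)
        d2 = ((res.coords[members] - c_pos) ** 2).sum(axis=1) - (
            (res.imag_coords[members] - c_neg) ** 2
        ).sum(axis=1)
        dist.iloc[np.nonzero(members)[0]] = np.sqrt(np.clip(d2, 0.0, None))
    means = dist.groupby(grp).mean()
    return DispersionResult(dist, grp, means)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int

    def __post_init__(self):
        assert 0.0 <= self.r_squared <= 1.0
        assert 0.0 < self.p_value <= 1.0


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        if idx.size == 0:
            raise ValueError("every group must have at least one member")
        block = d2[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_total <= 0:
        raise ValueError("all distances are zero; PERMANOVA is undefined")
    with np.errstate(divide="ignore"):  # F = inf under complete separation
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, groups, permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA with free permutation of group labels.

    pseudo-F is computed from within/between sums of squared distances;
    ``p = (1 + #{F_perm >= F_obs}) / (1 + permutations)``.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    grp = _as_group_series(groups, dm.ids)
    codes, uniques = pd.factorize(grp.values)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _permanova_f(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, len(uniques))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PermanovaResult(f_obs, r2, p, permutations)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    df_between: int = 0
    df_within: int = 0


def anova_tukey(values, groups) -> AnovaTukeyResult:
    """One-way ANOVA plus all pairwise Tukey HSD comparisons.

    Tukey-adjusted p-values come from the studentized range distribution.
    """
    values = np.asarray(values, dtype=float)
    grp = np.asarray(list(groups))
    if values.shape[0] != grp.shape[0]:
        raise ValueError("values and groups must align")
    levels = pd.unique(grp)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [values[grp == g] for g in levels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 members")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f, p = scipy.stats.f_oneway(*arrays)
    hsd = pairwise_tukeyhsd(values, grp)
    frame = pd.DataFrame(
        hsd.summary().data[1:], columns=[c.lower() for c in hsd.summary().data[0]]
    )
    tukey = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(hsd.pvalues, dtype=float),
        }
    )
    return AnovaTukeyResult(
        float(f), float(p), tukey,
        df_between=len(levels) - 1, df_within=values.size - len(levels),
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def alpha_diversity_table(table: TaxaTable, meta: SampleMetadata) -> pd.DataFrame:
    """Per-sample Shannon diversity and Pielou evenness with habitat labels."""
    rows = []
    meta_idx = meta.data.set_index("sample_id")
    for sid in table.sample_ids:
        x = table.data[sid].to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "habitat": meta_idx.loc[sid, "habitat"],
                "site": meta_idx.loc[sid, "site"],
                "shannon": shannon(x),
                "pielou": pielou(x),
                "richness": int((x > 0).sum()),
            }
        )
    return pd.DataFrame(rows)
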