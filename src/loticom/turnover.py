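"""Phylogenetic turnover: betaMNTD, the independent-swap null, and betaNTI.

betaMNTD (between-community mean nearest taxon distance) measures, for each
taxon in one community, the patristic distance to its closest relative in the
other community, averaged with relative-abundance weights (or uniformly).

betaNTI standardizes the observed betaMNTD of a sample pair against a null
distribution obtained by independent-swap randomization of the community
matrix — repeated 2x2 checkerboard swaps that preserve each sample's richness,
each taxon's occurrence frequency, and each taxon's multiset of abundance
values.  |betaNTI| > 2 for the habitat mean indicates deterministic assembly
(negative: homogeneous selection; positive: variable selection); values in
[-2, +2] indicate stochastic assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .core import SampleMetadata, TaxaTable, patristic_distances

__all__ = [
    "NullModelConfig",
    "BNTIResult",
    "beta_mntd",
    "independent_swap",
    "beta_nti",
    "classify_assembly",
]

STOCHASTIC = "stochastic"
DET_HOMOGENEOUS = "deterministic-homogeneous"
DET_VARIABLE = "deterministic-variable"


@dataclass
class NullModelConfig:
    """Settings for the independent-swap null model.

    ``swap_factor`` scales the number of successful swaps per randomization
    (swap_factor x filled cells), ``attempt_factor`` caps the attempts.  One
    randomized matrix per permutation serves all sample pairs of a habitat;
    a burn-in of one full swap effort precedes the first saved null.
    """

    permutations: int = 999
    swap_factor: int = 10
    attempt_factor: int = 100
    seed: int = 0
    abundance_weighted: bool = True

    def __post_init__(self):
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.swap_factor < 1 or self.attempt_factor < self.swap_factor:
            raise ValueError("need attempt_factor >= swap_factor >= 1")


@dataclass
class BNTIResult:
    """Per-pair betaNTI for one habitat plus the habitat-level summary."""

    habitat: str
    pairs: pd.DataFrame  # sample_i, sample_j, beta_mntd_obs, null_mean, null_sd, bnti
    permutations: int
    abundance_weighted: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_bnti(self) -> float:
        """Mean betaNTI over pairs with a defined (non-degenerate) null."""
        return float(self.pairs["bnti"].mean(skipna=True))

    @property
    def assembly_class(self) -> str:
        return classify_assembly(self.mean_bnti)

    @property
    def fraction_deterministic(self) -> float:
        """Fraction of defined pairs with |betaNTI| > 2."""
        b = self.pairs["bnti"].dropna()
        return float((b.abs() > 2).mean()) if len(b) else float("nan")


def classify_assembly(mean_bnti: float) -> str:
    """Two-sided +/-2 rule on the habitat-mean betaNTI."""
    if not np.isfinite(mean_bnti):
        raise ValueError("mean betaNTI must be finite")
    if mean_bnti < -2:
        return DET_HOMOGENEOUS
    if mean_bnti > 2:
        return DET_VARIABLE
    return STOCHASTIC


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------

def _bmntd_arrays(x: np.ndarray, y: np.ndarray, d: np.ndarray, weighted: bool) -> float:
    ix = np.nonzero(x > 0)[0]
    iy = np.nonzero(y > 0)[0]
    if ix.size == 0 or iy.size == 0:
        raise ValueError("betaMNTD is undefined for an empty community")
    dmin_x = d[np.ix_(ix, iy)].min(axis=1)
    dmin_y = d[np.ix_(iy, ix)].min(axis=1)
    if weighted:
        fx = x[ix] / x[ix].sum()
        fy = y[iy] / y[iy].sum()
    else:
        fx = np.full(ix.size, 1.0 / ix.size)
        fy = np.full(iy.size, 1.0 / iy.size)
    return 0.5 * (float(fx @ dmin_x) + float(fy @ dmin_y))


def beta_mntd(x, y, dm: DistanceMatrix, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance for one sample pair.

    ``x`` and ``y`` are abundance vectors: pandas Series indexed by taxon id,
    or plain arrays aligned with ``dm.ids``.  Taxa shared by both samples
    contribute zero nearest-taxon distance (their nearest relative is
    themselves), so identical communities score 0.
    """
    d = np.asarray(dm.data, dtype=float)
    if isinstance(x, pd.Series) or isinstance(y, pd.Series):
        ids = list(dm.ids)
        x = pd.Series(x).reindex(ids, fill_value=0.0).to_numpy(dtype=float)
        y = pd.Series(y).reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if x.shape[0] != d.shape[0] or y.shape[0] != d.shape[0]:
        raise ValueError("abundance vectors must align with the distance matrix")
    return _bmntd_arrays(x, y, d, abundance_weighted)


@njit(cache=True)
def _pairwise_bmntd(mat, d, weighted):  # pragma: no cover - compiled
    """betaMNTD for all sample pairs of a taxa x samples matrix."""
    n_taxa, n_samp = mat.shape
    n_pairs = n_samp * (n_samp - 1) // 2
    out = np.empty(n_pairs)
    k = 0
    for a in range(n_samp):
        for b in range(a + 1, n_samp):
            half_a = 0.0
            tot_a = 0.0
            na = 0
            for i in range(n_taxa):
                if mat[i, a] > 0.0:
                    dmin = np.inf
                    for j in range(n_taxa):
                        if mat[j, b] > 0.0 and d[i, j] < dmin:
                            dmin = d[i, j]
                    if weighted:
                        half_a += mat[i, a] * dmin
                        tot_a += mat[i, a]
                    else:
                        half_a += dmin
                        na += 1
            half_b = 0.0
            tot_b = 0.0
            nb = 0
            for j in range(n_taxa):
                if mat[j, b] > 0.0:
                    dmin = np.inf
                    for i in range(n_taxa):
                        if mat[i, a] > 0.0 and d[j, i] < dmin:
                            dmin = d[j, i]
                    if weighted:
                        half_b += mat[j, b] * dmin
                        tot_b += mat[j, b]
                    else:
                        half_b += dmin
                        nb += 1
            if weighted:
                out[k] = 0.5 * (half_a / tot_a + half_b / tot_b)
            else:
                out[k] = 0.5 * (half_a / na + half_b / nb)
            k += 1
    return out


# ---------------------------------------------------------------------------
# independent swap
# ---------------------------------------------------------------------------

@njit(cache=True)
def _swap_chain(mat, effort, max_attempts, seed):  # pragma: no cover - compiled
    """Run checkerboard swaps in place; returns the number of successful swaps.

    A checkerboard is a 2x2 submatrix with non-zeros in exactly one diagonal;
    a swap moves each value to the empty cell in its own row, preserving row
    value multisets and row/column occupancy counts.
    """
    np.random.seed(seed)
    n, m = mat.shape
    successes = 0
    attempts = 0
    while successes < effort and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(0, n)
        r2 = np.random.randint(0, n)
        c1 = np.random.randint(0, m)
        c2 = np.random.randint(0, m)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        dd = mat[r2, c2]
        if a > 0.0 and dd > 0.0 and b == 0.0 and c == 0.0:
            mat[r1, c2] = a
            mat[r1, c1] = 0.0
            mat[r2, c1] = dd
            mat[r2, c2] = 0.0
            successes += 1
        elif a == 0.0 and dd == 0.0 and b > 0.0 and c > 0.0:
            mat[r1, c1] = b
            mat[r1, c2] = 0.0
            mat[r2, c2] = c
            mat[r2, c1] = 0.0
            successes += 1
    return successes


def _swap_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic 32-bit seed stream for the per-permutation swap chains."""
    return np.random.SeedSequence(master_seed).generate_state(n).astype(np.uint32)


def independent_swap(matrix: np.ndarray, effort: int | None = None,
                     max_attempts: int | None = None, seed: int = 0,
                     swap_factor: int = 10, attempt_factor: int = 100) -> np.ndarray:
    """One independent-swap randomization of an abundance (or presence) matrix.

    Performs ``effort`` successful checkerboard swaps (default: swap_factor x
    filled cells, attempts capped at attempt_factor x filled cells) and
    returns a new matrix.  Row and column non-zero counts, each row's multiset
    of non-zero values, and the grand total are preserved exactly.  If no swap
    can be found the input is returned unchanged with a warning.
    """
    mat = np.ascontiguousarray(np.asarray(matrix, dtype=float).copy())
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("matrix must be 2-D with >= 2 rows and >= 2 columns")
    filled = int((mat > 0).sum())
    if effort is None:
        effort = max(1, swap_factor * filled)
    if max_attempts is None:
        max_attempts = max(effort, attempt_factor * filled)
    done = _swap_chain(mat, effort, max_attempts, _swap_seeds(seed, 1)[0])
    if done == 0:
        warnings.warn(
            "no checkerboard submatrix found; matrix returned unchanged "
            "(degenerate for null-model use)",
            stacklevel=2,
        )
    return mat


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

def beta_nti(table: TaxaTable, meta: SampleMetadata, tree: TreeNode | DistanceMatrix,
             habitat: str, config: NullModelConfig | None = None) -> BNTIResult:
    """betaNTI for every within-habitat sample pair, with assembly classification.

    The habitat's samples are extracted from the table, taxa absent from all
    of them are dropped, and patristic distances are taken over the remaining
    taxa (``tree`` may be a phylogeny or a precomputed taxon distance matrix).
    The null distribution for each pair comes from ``config.permutations``
    independent-swap randomizations of the within-habitat matrix; each
    randomized matrix serves all pairs.  Pairs whose null standard deviation
    is zero are reported with betaNTI = NaN and excluded from the mean.
    """
    if config is None:
        config = NullModelConfig()
    samples = meta.samples_of_habitat(habitat)
    samples = [s for s in samples if s in set(table.sample_ids)]
    if len(samples) < 2:
        raise ValueError(f"habitat {habitat!r} needs >= 2 samples, found {len(samples)}")
    sub = table.select_samples(samples).drop_empty_taxa()
    if isinstance(tree, DistanceMatrix):
        missing = [t for t in sub.taxon_ids if t not in set(tree.ids)]
        if missing:
            raise KeyError(f"taxa missing from the distance matrix: {missing[:5]}")
        dm = tree.filter(sub.taxon_ids)
    else:
        dm = patristic_distances(tree, sub.taxon_ids)
    d = np.ascontiguousarray(dm.data)
    mat = np.ascontiguousarray(sub.values)
    weighted = bool(config.abundance_weighted)

    obs = _pairwise_bmntd(mat, d, weighted)

    filled = int((mat > 0).sum())
    effort = max(1, config.swap_factor * filled)
    cap = max(effort, config.attempt_factor * filled)
    seeds = _swap_seeds(config.seed, config.permutations + 1)

    null_mat = mat.copy()
    _swap_chain(null_mat, effort, cap, seeds[0])  # burn-in
    nulls = np.empty((config.permutations, obs.size))
    for k in range(config.permutations):
        done = _swap_chain(null_mat, effort, cap, seeds[k + 1])
        if done == 0 and k == 0:
            warnings.warn(
                f"independent swap found no checkerboard in habitat {habitat!r}; "
                "null distribution is degenerate",
                stacklevel=2,
            )
        nulls[k] = _pairwise_bmntd(null_mat, d, weighted)

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    if np.isnan(bnti).any():
        warnings.warn(
            f"{int(np.isnan(bnti).sum())} pair(s) in habitat {habitat!r} have "
            "zero null variance; reported as NaN and excluded from the mean",
            stacklevel=2,
        )

    idx = [(a, b) for i, a in enumerate(samples) for b in samples[i + 1:]]
    pairs = pd.DataFrame(
        {
            "sample_i": [a for a, _ in idx],
            "sample_j": [b for _, b in idx],
            "beta_mntd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "bnti": bnti,
        }
    )
    return BNTIResult(habitat, pairs, config.permutations, weighted)


def beta_nti_all_habitats(table: TaxaTable, meta: SampleMetadata, tree,
                          config: NullModelConfig | None = None) -> dict[str, BNTIResult]:
    """Run :func:`beta_nti` for every habitat with >= 2 samples."""
    out = {}
    for h in meta.habitats_present():
        in_table = [s for s in meta.samples_of_habitat(h) if s in set(table.sample_ids)]
        if len(in_table) >= 2:
            cfg = config if config is None else NullModelConfig(
                permutations=config.permutations, swap_factor=config.swap_factor,
                attempt_factor=config.attempt_factor,
                seed=config.seed + sum(map(ord, h)),  # distinct stream per habitat
                abundance_weighted=config.abundance_weighted,
            )
            out[h] = beta_nti(table, meta, tree, h, cfg)
    return out
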