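"""Synthetic metacommunities with a known assembly regime.

The generator builds (i) a Yule (pure-birth) phylogeny, (ii) a Brownian trait
on that phylogeny — so niches are phylogenetically conserved, (iii) log-normal
regional-pool abundances with the strong rank-abundance skew typical of 16S
surveys, and (iv) per-site community samples drawn multinomially with
Gaussian environmental filtering on the trait:

    w_ij = A_i * exp(-(t_i - e_j)^2 / (2 * sigma_filt^2))

where A_i is taxon i's pool abundance, t_i its trait, e_j site j's
environment and sigma_filt the filtering width.  sigma_filt = inf turns
filtering off (neutral sampling from the pool).  Three regimes follow:

* neutral            — sigma_filt = inf;
* homogeneous-filtering — finite sigma_filt, identical e_j at every site;
* variable-filtering — finite sigma_filt, e_j spread widely across sites.

Replicate samples are independent multinomial draws from the same site
weights, which gives the replicate prevalence filter realistic work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import SampleMetadata, TaxaTable

__all__ = [
    "SimulationConfig",
    "Metacommunity",
    "simulate_tree",
    "evolve_trait",
    "assemble",
    "benchmark_suite",
    "simulate_study",
    "NEUTRAL",
    "HOMOGENEOUS",
    "VARIABLE",
]

NEUTRAL = "neutral"
HOMOGENEOUS = "homogeneous-filtering"
VARIABLE = "variable-filtering"


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a catchment-scale 16S survey.

    ``filt_sigma`` is in trait units (same scale as the Brownian trait);
    ``math.inf`` disables filtering.  ``env`` holds one environment value per
    site; ``None`` means all zero.
    """

    n_taxa: int = 150
    n_sites: int = 12
    replicates: int = 1
    depth: int = 2000
    bm_rate: float = 1.0          # Brownian-motion rate sigma^2 per unit branch length
    pool_mu: float = 0.0          # log-normal location of pool abundances
    pool_sigma: float = 1.5       # log-normal shape: right-skewed rank-abundance curve
    env: np.ndarray | None = None
    filt_sigma: float = math.inf
    habitat: str = "BF"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2 or self.n_sites < 1 or self.replicates < 1 or self.depth < 1:
            raise ValueError("counts must be positive (n_taxa >= 2)")
        if not (self.filt_sigma > 0):
            raise ValueError("filt_sigma must be > 0 (or inf for neutral)")
        if self.env is not None and len(self.env) != self.n_sites:
            raise ValueError("env must provide one value per site")


@dataclass
class Metacommunity:
    """A simulated metacommunity with its ground-truth assembly regime."""

    table: TaxaTable
    meta: SampleMetadata
    tree: TreeNode
    traits: pd.Series
    regime: str
    env: np.ndarray
    config: SimulationConfig


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Yule (pure-birth, unit-rate) tree with ``n_taxa`` tips; ultrametric.

    Lineages split at exponential waiting times with total rate equal to the
    current lineage count; after the last split the clock runs one more
    exponential interval so terminal branches are positive.  Tips are named
    ``t0001 ...`` in birth order.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.extend([first, second])
    active = [first, second]
    start = {id(first): 0.0, id(second): 0.0}
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.length = t - start.pop(id(parent))
        kids = [TreeNode(), TreeNode()]
        parent.extend(kids)
        for k in kids:
            start[id(k)] = t
            active.append(k)
    t += rng.exponential(1.0 / len(active))
    for tip in active:
        tip.length = t - start[id(tip)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:04d}"
    return root


def evolve_trait(tree: TreeNode, rate: float = 1.0, seed: int = 0) -> pd.Series:
    """Brownian trait: child = parent + Normal(0, rate x branch length).

    Returns tip values (root value 0); variance accumulates linearly with
    path length, so closely related tips have similar niches.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, math.sqrt(rate * node.length))
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})


def _infer_regime(config: SimulationConfig, env: np.ndarray) -> str:
    if math.isinf(config.filt_sigma):
        return NEUTRAL
    if np.ptp(env) == 0:
        return HOMOGENEOUS
    return VARIABLE


def assemble(config: SimulationConfig, tree: TreeNode | None = None,
             traits: pd.Series | None = None) -> Metacommunity:
    """Draw a metacommunity under ``config``; deterministic for a fixed seed.

    ``tree`` and ``traits`` may be supplied to share one phylogeny across
    several regimes; by default they are simulated from the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, trait_seed, pool_seed, draw_seed = ss.generate_state(4)
    if tree is None:
        tree = simulate_tree(config.n_taxa, int(tree_seed))
    if traits is None:
        traits = evolve_trait(tree, config.bm_rate, int(trait_seed))
    taxa = list(traits.index)
    t = traits.to_numpy()

    pool_rng = np.random.default_rng(int(pool_seed))
    pool = pool_rng.lognormal(config.pool_mu, config.pool_sigma, size=len(taxa))

    env = np.zeros(config.n_sites) if config.env is None else np.asarray(config.env, float)
    if math.isinf(config.filt_sigma):
        weights = np.tile(pool[:, None], (1, config.n_sites))
    else:
        kernel = np.exp(-((t[:, None] - env[None, :]) ** 2)
                        / (2.0 * config.filt_sigma**2))
        weights = pool[:, None] * kernel
    dead = weights.sum(axis=0) == 0
    if dead.any():
        raise ValueError(
            f"all sampling weights are zero at site index {int(np.nonzero(dead)[0][0])}; "
            "filt_sigma is too small for the trait range"
        )
    probs = weights / weights.sum(axis=0)

    draw_rng = np.random.default_rng(int(draw_seed))
    cols, rows = {}, []
    for j in range(config.n_sites):
        site = f"site{j + 1:02d}"
        for r in range(1, config.replicates + 1):
            sid = f"{site}_{config.habitat}_r{r}"
            cols[sid] = draw_rng.multinomial(config.depth, probs[:, j])
            rows.append({"sample_id": sid, "site": site,
                         "habitat": config.habitat, "replicate": r})
    table = TaxaTable(pd.DataFrame(cols, index=taxa, dtype=float))
    meta = SampleMetadata(pd.DataFrame(rows))
    return Metacommunity(table, meta, tree, traits, _infer_regime(config, env),
                         env, config)


def benchmark_suite(seed: int = 0) -> dict[str, Metacommunity]:
    """Three fixed-setting metacommunities, one per assembly regime.

    Settings: 150 taxa, 10 sites, depth 2000, Brownian rate 1, pool
    log-normal sigma 1; one shared tree and trait set.  Filtering width is
    0.2 trait standard deviations; the homogeneous regime puts every site at
    the pool trait median, the variable regime spreads sites evenly over
    +/- 2 trait standard deviations.
    """
    base = SimulationConfig(n_taxa=150, n_sites=10, replicates=1, depth=2000,
                            bm_rate=1.0, pool_sigma=1.0, seed=seed)
    ss = np.random.SeedSequence(seed)
    tree_seed, trait_seed = ss.generate_state(2)
    tree = simulate_tree(base.n_taxa, int(tree_seed))
    traits = evolve_trait(tree, base.bm_rate, int(trait_seed))
    t_med, t_sd = float(traits.median()), float(traits.std())
    sigma = 0.2 * t_sd
    configs = {
        NEUTRAL: replace(base, filt_sigma=math.inf, seed=seed + 11),
        HOMOGENEOUS: replace(base, filt_sigma=sigma,
                             env=np.full(base.n_sites, t_med), seed=seed + 22),
        VARIABLE: replace(base, filt_sigma=sigma,
                          env=float(traits.mean()) + np.linspace(-2, 2, base.n_sites) * t_sd,
                          seed=seed + 33),
    }
    return {name: assemble(cfg, tree=tree, traits=traits)
            for name, cfg in configs.items()}


def simulate_study(seed: int = 0, n_taxa: int = 150, n_sites: int = 12,
                   depth: int = 2000) -> Metacommunity:
    """A full 12-site x 4-habitat survey with replicated benthic habitats.

    All habitats share one phylogeny, trait set and regional pool.  The
    planktonic habitats (FL, PA) are sampled neutrally or with weak
    filtering; the benthic habitats (BF, SE) are strongly filtered toward
    habitat-specific trait optima and carry replicate samples per site
    (3 biofilm, 3 sediment), mimicking the design of a catchment survey
    where water samples are single but benthic samples are replicated.
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, trait_seed = ss.generate_state(2)
    tree = simulate_tree(n_taxa, int(tree_seed))
    traits = evolve_trait(tree, 1.0, int(trait_seed))
    t_sd, t_mean = float(traits.std()), float(traits.mean())
    habitat_cfg = {
        "FL": dict(filt_sigma=math.inf, env=None, replicates=1),
        "PA": dict(filt_sigma=2.0 * t_sd, env=np.full(n_sites, t_mean), replicates=1),
        "BF": dict(filt_sigma=0.3 * t_sd,
                   env=np.full(n_sites, t_mean + 0.5 * t_sd), replicates=3),
        "SE": dict(filt_sigma=0.3 * t_sd,
                   env=np.full(n_sites, t_mean - 0.5 * t_sd), replicates=3),
    }
    tables, metas = [], []
    for k, (hab, cfg) in enumerate(habitat_cfg.items()):
        mc = assemble(
            SimulationConfig(n_taxa=n_taxa, n_sites=n_sites, depth=depth,
                             habitat=hab, seed=seed + 101 * (k + 1), **cfg),
            tree=tree, traits=traits,
        )
        tables.append(mc.table.data)
        metas.append(mc.meta.data)
    table = TaxaTable(pd.concat(tables, axis=1))
    meta = SampleMetadata(pd.concat(metas, ignore_index=True))
    cfg = SimulationConfig(n_taxa=n_taxa, n_sites=n_sites, depth=depth, seed=seed)
    return Metacommunity(table, meta, tree, traits, "mixed", np.zeros(n_sites), cfg)
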