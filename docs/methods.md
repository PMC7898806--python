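# Methods

## Scope and data model

`loticom` analyses a taxa × samples abundance table (`TaxaTable`), per-sample
metadata (site, habitat ∈ {FL, PA, BF, SE}, replicate) and a rooted
phylogeny whose tips match the table's taxon ids. Orientation is fixed
(taxa rows, sample columns); tip-label matching is exact string equality —
a taxon in the table but missing from the tree is a hard error in
phylogenetic operations, never silently dropped, because silent fuzzy
matching hides data errors. All tabular I/O is plain TSV.

## Preprocessing

Stage order: replicate prevalence filter → replicate averaging → rounding →
rarefaction → low-abundance filter → lineage-pattern removal.

* **Prevalence filter** (default 0.75, inclusive): within each
  (site, habitat) replicate group, a taxon present in fewer than 75% of the
  group's replicates is zeroed *within that group only* — the same taxon
  may be real at another site. The rule keeps a taxon at exactly 75%.
* **Averaging** takes the arithmetic mean over a group's replicates,
  yielding one sample per (site, habitat).
* **Rarefaction** (default depth 24 007 reads): averaged abundances are
  rounded half-to-even to integers (subsampling without replacement needs
  integer counts), then each sample is a multivariate-hypergeometric draw of
  exactly `depth` reads. For a fixed seed the output is byte-identical; the
  per-taxon expected count is depth × (count / sample total).
* **Low-abundance filter** (default 0.01%): taxa whose summed abundance is
  *strictly below* the threshold fraction of the whole-table grand total
  are removed (a global, not per-sample, cutoff; taxa exactly at the cutoff
  are kept). A per-sample variant was considered and rejected to keep the
  filter's meaning independent of sample count.
* **Lineage removal** drops taxa whose taxonomy string contains a pattern
  (case-insensitive), e.g. `chloroplast`; taxa without taxonomy are kept.

## Community statistics

Shannon diversity uses the natural logarithm (nats) by default with a
`base` flag; Pielou's evenness is H/ln S over taxa with positive abundance
(undefined for S < 2 and raised as an error rather than returned as 0/0).
Whittaker's beta is γ/ᾱ − 1 on presence/absence, so identical samples give
0. Bray–Curtis dissimilarities are computed on per-sample relative
abundances.

Principal-coordinates analysis is classical scaling: Gower-centre
−½d², eigendecompose, order axes by eigenvalue. Negative eigenvalues —
routine for Bray–Curtis — are retained: samples get real coordinates on
positive-eigenvalue axes and "imaginary" coordinates on negative ones.
Multivariate dispersion (distance to group centroid) follows the standard
semi-metric construction: squared distance = contribution from real axes −
contribution from imaginary axes, clamped at zero before the square root;
on Euclidean-embeddable inputs this reduces exactly to the direct Euclidean
distance to the centroid (verified to 1e-10 in the tests).

PERMANOVA is one-way with free permutation of labels (no strata):
pseudo-F from within/between sums of squared distances and
p = (1 + #{F_perm ≥ F_obs}) / (1 + permutations), so the smallest
attainable p is 1/(permutations + 1). Under complete separation the
within-group sum of squares is 0 and F is reported as infinity with R² = 1.
ANOVA/Tukey-HSD use scipy and statsmodels (studentized-range adjusted
p-values); Bonferroni is min(1, m·p).

## Specificity and occupancy

For taxon S and habitat H with habitat-mean abundances N̄(S,H):
specificity(S,H) = N̄(S,H) / Σ_H' N̄(S,H'), occupancy(S,H) = fraction of H's
samples containing S. Both are evaluated on the post-preprocessing table,
so "samples of H" are the 12 site-level (replicate-averaged) samples;
presence is strictly > 0 (no pseudo-count). Specificity of an observed
taxon sums to exactly 1 across habitats; for a taxon absent everywhere it
is NaN, never 0/0. Specialist calling (both quantities ≥ threshold,
default 0.7, inclusive) is evaluated within each habitat's top-500 taxa,
ranked by summed abundance with lexicographic tie-breaks (summed and mean
ranking coincide when habitats have equal sample counts). Habitat-overlap
counts assign each observed taxon to exactly one of the 15 non-empty
habitat subsets, so they partition the observed taxon set.

## betaMNTD, the independent-swap null, and betaNTI

Abundance-weighted βMNTD between samples x and y is
½[Σ_i f_i·min_{j∈y} d(i,j) + Σ_j g_j·min_{i∈x} d(j,i)] with f, g the
within-sample relative abundances over present taxa and d patristic
distances; the unweighted form replaces f, g with 1/richness. Shared taxa
contribute 0 (their nearest relative is themselves), so βMNTD is zero iff
the present-taxon sets coincide. Weighted mode is the default, following
the convention of the null-model literature this statistic comes from; both
modes are exposed because published workflows differ.

The independent-swap null randomizes the within-habitat taxa × samples
matrix by repeated 2×2 checkerboard swaps: a submatrix with non-zeros in
exactly one diagonal has each value moved to the empty cell of its own row.
This preserves, exactly: per-sample richness, per-taxon occurrence
frequency, each taxon's multiset of abundance values, and the grand total.
Per randomization the chain performs 10 × (filled cells) successful swaps
(attempts capped at 100 ×), with one additional full effort run as burn-in
before the first saved null; the chain is sequential, so consecutive nulls
are consecutive states of one long random walk. One randomized matrix per
permutation serves all sample pairs of the habitat (consistent nulls and a
large speed-up). Matrices with no checkerboard at all (e.g. fully filled)
are returned unchanged with a warning. The swap kernel and the all-pairs
βMNTD kernel are numba-compiled; per-permutation seeds derive
deterministically from one master seed, so results are reproducible.

βNTI per pair is (βMNTD_obs − null mean)/null sd (sd with ddof = 1, default
999 permutations); pairs with zero null sd are flagged NaN, excluded from
the habitat mean, and warned about. Classification applies the ±2 rule to
the habitat mean: < −2 homogeneous (deterministic) selection, > +2 variable
(deterministic) selection, otherwise stochastic; the per-pair fraction
beyond ±2 is also reported. The boundary is strict (a mean of exactly −2
reads stochastic).

### What the within-habitat swap null can and cannot detect

A point that matters when interpreting βNTI from this package: the null
conditions on the observed occurrence margins of the *within-habitat*
matrix. If every site applies the same filter (sites exchangeable), the
observed matrix is itself — conditional on those margins — a typical member
of the null ensemble, so the expected βNTI is 0 *regardless of how strong
the filtering is*. Site-invariant ("homogeneous") filtering is therefore
invisible to this null; what drives the habitat mean away from 0 is
*between-site structure*: sites selecting different clades push βNTI
positive (variable selection), while excess segregation of close relatives
across sites would push it negative. The benchmark results reflect this:
the variable-filtering regime is recovered (> +2) and the neutral regime
sits near 0, while the site-invariant filtering regime also sits near 0.
Detecting site-invariant selection requires a null that breaks the
taxon–phylogeny pairing (e.g. shuffling tip labels) or a randomization pool
wider than the habitat (e.g. the full multi-habitat matrix); both are
deliberate extensions, not defaults, and neither is implemented here.

## Synthetic metacommunities

The generator emulates a catchment survey: a Yule (pure-birth, unit-rate)
ultrametric phylogeny; a Brownian trait along it (child = parent +
Normal(0, σ²_BM × branch length)), giving phylogenetically conserved
niches; log-normal regional-pool abundances (default σ_pool = 1.5 — the
strong rank-abundance skew typical of 16S surveys, Gini > 0.5); and
per-site sampling weights w_ij = A_i·exp(−(t_i − e_j)²/(2σ²_filt)), drawn
multinomially to a fixed depth. σ_filt = ∞ gives neutral sampling from the
pool. Replicates are independent multinomial draws from the same site
weights. Regime labels follow the configuration: neutral (σ_filt = ∞),
homogeneous-filtering (finite σ_filt, all e_j equal), variable-filtering
(e_j spread widely relative to σ_filt).

`benchmark_suite` fixes the validation settings — 150 taxa, 10 sites,
depth 2000, σ²_BM = 1, σ_pool = 1, σ_filt = 0.2 trait standard deviations;
homogeneous puts every site at the pool trait median, variable spreads
sites evenly over ±2 trait standard deviations — with one shared tree and
trait set per master seed so the regimes differ only in filtering.
`simulate_study` builds the full 12-site × 4-habitat design (single water
samples; 3 replicates per site for each benthic habitat) with
habitat-specific optima so habitats differ compositionally.

What the generator does **not** emulate: species interactions, dispersal
limitation and mass effects between habitats, temporal dynamics,
sequencing error and chimeras, and the lottery/priority-effect dynamics
that segregate close relatives across sites. Consequently, passing the
regime-recovery benchmark shows the estimator chain is correct for
filtering-vs-neutral contrasts with conserved niches; it does not show
that every deterministic process in real rivers is detectable (see the
null-model caveat above).

## Numerical choices and degenerate inputs

* Averaged counts are rounded half-to-even before rarefaction; rarefying a
  sample whose total is below the target depth is a hard error naming the
  sample.
* PCoA treats eigenvalues within 1e-9 (relative) of zero as zero.
* All-zero abundance vectors, singleton dispersion groups, habitats with
  fewer than two samples, and zero-richness samples in Whittaker's beta are
  hard errors, not NaNs.
* Randomness: every stochastic operation takes an explicit seed;
  per-permutation and per-stage streams derive from it via seed sequences,
  so parallel or re-ordered execution cannot change results.
* Benchmark problem sizes (150 taxa, 10 sites, depth 2000, 99-permutation
  nulls, 10 seeds) are the package's validation settings: large enough for
  the variable-regime effect size to clear +2 by a wide margin, small
  enough to run routinely.

## Known limitations

* One-way PERMANOVA only (no strata or nested designs); NMDS ordination is
  out of scope — group differences are carried by PERMANOVA + dispersion.
* βNTI is computed within habitats only; between-habitat turnover and
  Raup–Crick partitioning of the stochastic fraction are not implemented.
* The swap chain's mixing is effort-based, not diagnosed; the default
  10×/100× effort follows common practice and the tests verify the chain
  reaches the full marginal-preserving set on small instances.
* BIOM import is not implemented; TSV is the contract.
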