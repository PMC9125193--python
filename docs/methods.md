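# Methods

`cycadiv` reconstructs, as tested reusable code, the inference that the
two cycads *Cycas revoluta* (CR, Ryukyu Archipelago and southern Kyushu)
and *C. taitungensis* (CT, Taiwan) diverged **non-allopatrically** —
with continuous but decreasing gene flow — together with the supporting
population-structure and morphometric analyses.  All data are synthetic:
the generators emit pseudo-observed datasets with the statistical
structure the analyses assume, so the full chain runs with no download.

## Demographic model

Two diploid demes evolve under a structured coalescent observed backward
in time.  Thirteen parameters describe the history:

| symbol | meaning | units |
|---|---|---|
| `N_CR2`, `N_CT2` | extant effective sizes | diploids |
| `N_CR_REL`, `N_CT_REL` | pre-bottleneck multipliers: `N_CR1 = N_CR_REL x N_CR2`, `N_CT1 = N_CT_REL x N_CT2` | — |
| `N_anc_REL` | ancestral multiplier: `N_anc = N_anc_REL x N_CT1` | — |
| `t1` | bottleneck / migration-change time | generations |
| `t2` | species divergence | generations |
| `t3` | stem divergence of the section (ghost split) | generations |
| `m_CT1`, `m_CR1` | migration before `t1` (CT→CR, CR→CT) | fraction/generation |
| `m_CT2`, `m_CR2` | migration after `t1` | fraction/generation |
| `mu` | mutation rate | per site per generation |

Backward from the present: sizes are (`N_CR2`, `N_CT2`) on `[0, t1)`,
(`N_CR1`, `N_CT1`) on `[t1, t2)` (the bottleneck, present in all four
scenarios), and the demes merge at `t2` into one deme of size `N_anc`.
The deeper split `t3` involves only an unsampled ghost lineage with no
migration; it is genealogically inert for the sampled demes and is
identified only through its prior — which is why its posterior interval
is expected to be very wide.  `N_anc` is anchored to the CT side
(`N_anc_REL x N_CT1`); the package treats the product identities
`N_CR1 = 5.9 x 5835.7 = 34,430.6`, `N_CT1 = 4.52 x 2669.8 = 12,067.5`
and `N_anc = 3.1 x 4.52 x 2669.8 = 37,409.2` as required tests at the
fitted medians.

The four speciation scenarios differ only in which migration epochs are
switched on: CG (continuous gene flow) both; PC (primary contact) only
the older epoch `[t1, t2)`; SC (secondary contact) only the recent epoch
`[0, t1)`; CI (complete isolation) none.  Migration rates are
forward-time fractions of the receiving species' gene pool ("CT to CR"
affects CR); backward in time a lineage sampled in CR jumps to CT at
exactly that rate.

Generation time is 30 years; at that value the fitted medians convert to
a species divergence of ~0.14 Mya and a stem divergence of ~4.8 Mya, and
a 9-Mya ceiling equals 3 x 10^5 generations, the default upper prior
bound on times.

## Coalescent simulator

Loci are independent ~238-bp fragments without intralocus recombination
(RAD-scale), with infinite-sites mutation at rate `mu x length` on the
total branch length.  Waiting times are exponential (continuous-time
coalescent); coalescence in a deme of diploid size N occurs at rate
`k(k-1)/(4N)` for `k` lineages.  Diploid genotypes pair consecutive
haplotypes, which is distribution-free because haplotypes are
exchangeable.  One root seed yields deterministic per-locus child seeds,
so results are reproducible regardless of how loci are batched.  The
per-locus kernel is compiled with numba.

**Strong-migration limit.**  The migration priors extend to 1 per
generation; event-by-event simulation of such draws would require
millions of migration events per locus.  When the per-epoch backward
migration rate exceeds 50x the pairwise coalescence rate
(`m01 + m10 > 50 [1/(2N0) + 1/(2N1)]`), the simulator switches to the
collecting-phase limit: the demes behave as one pool whose
pair-coalescence rate is `pi0^2/(2N0) + pi1^2/(2N1)` at the stationary
occupancy `pi` of the backward migration chain, and deme labels are
redrawn from `pi` when a slow epoch resumes.  At the switching threshold
the approximation error is within Monte-Carlo noise of the exact
simulation (verified against event-by-event runs and against msprime in
the test suite).

The simulator is cross-validated against msprime (two-sample
Kolmogorov–Smirnov on per-species S and pi distributions at three
parameter sets, 500 loci, alpha = 0.01) and against Watterson's
`E[S] = 4 N mu L sum_{i<2n} 1/i` in the panmictic limit.  msprime is
used only as an oracle in tests, never by the package itself.

## Summary statistics

Seventeen named statistics feed the ABC: per-species segregating sites,
panel-total pairwise differences, per-site expected heterozygosity
mean/sd; per-locus global (all individuals pooled) mean/sd of S, pi,
Fst and Fit; and the multilocus interspecific Fst.  Private-allele
counts are carried for diversity reporting only.  The published method
names 20 statistics but enumerates 17; the registry implements the 17
enumerated and exposes `register_stat` so further statistics can be
plugged in.  Conventions:

- unphased genotype-based estimators throughout; per-site gene diversity
  uses the unbiased `2n/(2n-1)` correction (Arlequin convention), and
  the per-site pairwise-difference estimator equals the exact mean
  Hamming distance over haplotype pairs (asserted by enumeration);
- missing data are handled by per-site pairwise deletion; sites with
  fewer than two usable diploids in a group are skipped for pi/He;
- Fst and Fit are Weir & Cockerham (1984) variance-component estimators;
  multilocus values are ratios of summed components; with a single group
  the among-group component is zero and Fit reduces to the within-group
  inbreeding estimator;
- per-locus statistics aggregate over loci carrying at least one SNP
  (after filtering the observed panel is one SNP per locus, so this is
  the natural universe); a panel with no segregating sites yields the
  all-zero vector;
- "global" Fst/Fit group by population labels; "interspecific Fst" by
  the two species.

## SNP panel filtering

Fixed order: (1) mean allele depth < 5 (only when depth is recorded —
simulated data carry none), (2) site missing rate > 0.55, (3) minor
allele frequency < 0.01, (4) observed heterozygosity > 0.8,
(5) individual missing rate > 0.5, (6) one SNP per RAD locus, keeping
the highest-MAF SNP with ties broken by smallest position (the tie rule
is the package's determinism choice).  The published pipeline applies
two site-missingness cutoffs at different stages (0.4, then 0.55); the
package exposes one configurable cutoff, default 0.55, because only the
final panel matters downstream.  Because site rules are evaluated on the
retained individuals and the individual rule on the retained sites, a
single pass is not a fixed point; the pass is repeated until nothing
changes, which makes filtering idempotent (removal counts accumulate per
rule across passes).  Idempotence and input-order insensitivity are
tested properties.

## ABC

Rejection ABC with Epanechnikov weights: statistics are standardized by
the median absolute deviation over the reference table (robust to the
heavy-tailed statistics the migration priors produce), distance is
Euclidean, the best `k` rows are retained **jointly across models**, and
weights are `w_i = 1 - (d_i/d_(k))^2`.

- *Model choice*: posterior probability of a model is its share of
  retained weight; the Bayes factor versus the equal-prior composite of
  the other G-1 models is `(G-1) P / (1-P)`.  This
  weighted-acceptance-odds estimator is simpler than GLM-based marginal
  densities; the difference is documented as a deliberate design choice.
- *Goodness of fit*: observed statistic = mean distance to the k nearest
  rows of the selected model's table; the null re-computes it for table
  rows treated as pseudo-observations with leave-one-out; p = fraction
  of null >= observed.  Under self-simulation the p-values are uniform
  (KS-tested).
- *Parameter estimation*: parameters are log-transformed, then either
  summarized directly from the retained weighted draws ("rejection"),
  corrected by a weighted local-linear regression on the standardized
  retained statistics (Beaumont-style, the tested default), or by
  averaged single-hidden-layer networks (15 hidden units, 50 restarts) —
  the "15 hidden layers / 50 networks" wording in the source method is
  read with the R `abc` package semantics of `sizenet`/`numnet`.
  Summaries are weighted mean/median/95% interval by cumulative-weight
  interpolation (equal weights on {10,20,30,40} give median 25) and are
  back-transformed.
- *Priors*: the published supplement with exact priors is unavailable;
  the defaults (uniform sizes, `t ~ U(10, 3x10^5)` with `t1<=t2<=t3`
  enforced by conditional sampling, log-uniform migration on
  `[1e-8, 1]`, `mu ~ U(1e-8, 2e-7)`) are reconstructions chosen to be
  consistent with the reported posterior intervals, flagged
  `reconstructed: true` in config exports, and fully configurable.
- *Statistic pruning*: greedy scan in declared order dropping any
  statistic with |Pearson r| >= 0.95 against one already retained;
  constant columns drop first.

Calibration at desk scale (20+10 diploids; 100-locus tables with 2,000
rows/model for model choice, a 500-locus 5,000-row CG table for
estimation) is part of the acceptance suite: the confusion matrix beats
chance with CI-vs-CG discrimination >= 0.6, and the weighted 95%
intervals cover the generating log(N_CR2) and log(t2) in >= 80% of
seeded replicates.  The published analysis used 10^6 simulations per
model; that is configuration, not architecture — `n_per_model` scales
freely.

## Population structure

- *Nei (1972) standard distance* `D = -ln(J_xy / sqrt(J_x J_y))` on
  biallelic frequencies, loci with undefined frequencies excluded
  pairwise; the 1972 variant is the package's documented choice where
  the upstream library offers several.
- *PCoA* by double-centering `-D^2/2` and eigendecomposition; negative
  eigenvalues are reported but get no coordinates.
- *Connection networks*: Delaunay triangulation (dense), K-nearest
  neighbours (moderate, default K = 7 = 28/4, a quarter of the sampling
  localities), minimum spanning tree (sparse).  Geographic coordinates
  are projected equirectangularly about the mean latitude; at island
  scale the projection error is negligible against edge-length
  differences.
- *Monmonier barriers*: the barrier walks through the network's
  triangles, entering through the starting edge (largest associated
  distance; run r of the 20 restarts starts at the r-th largest) and
  exiting each triangle across the uncrossed edge with the larger
  distance above the threshold (default 0).  A direction stops at the
  network boundary, on revisiting a triangle, or when no candidate
  clears the threshold; on triangle-free networks (paths, spanning
  trees) every edge is a bridge and a barrier is a single edge.  Ties
  break by lowest edge index, making results deterministic.  The best
  run maximizes the cumulative crossed distance.  With the threshold at
  zero a barrier legitimately extends to the boundary, so it may
  fragment the network beyond the main split; "separates the demes"
  therefore means no post-removal component mixes the two demes.
- *NJ tree* via scikit-bio's Saitou–Nei implementation, with bootstrap
  support from resampling loci (not individuals) with replacement,
  recomputing Nei distances and counting bipartitions of the full-data
  tree.

## Morphometrics

Two-sided Mann–Whitney U tests per continuous trait (exact enumeration
when n1+n2 <= 12 without ties, otherwise normal approximation with tie
and continuity corrections), at alpha = 0.05 with no multiple-testing
correction — matching the comparison being reproduced; both are
configurable.  Female-cone compactness is excluded by design (it cannot
be standardized across developmental stages).  The four significant
leaflet traits (width, length/width ratio, basal width, spacing) drive
an island/region-level clustering: group trait means are standardized,
embedded by Euclidean distance, and clustered by UPGMA, complete,
single, and Ward linkage; the method with the largest agglomerative
coefficient — mean over items of `1 - h_first/h_final` — wins.
Recurvation of the leaflet margin is an ordinal class 1–4 summarized as
per-group proportions.

## Synthetic data

- *SNP panels*: coalescent simulation under a chosen scenario at the
  fitted parameter medians by default (209 + 30 diploids, 907 loci),
  MCAR missingness at 35.4% (optionally Beta-heterogeneous per
  individual), then the standard QC filters.  An optional north/south
  substructure inside CR adds a third deme (two CR halves joined by
  symmetric migration that merge at an internal split time <= t2),
  emulating the strong intraspecific structure of the real system.
  Every generator writes a truth record (parameters, seeds, model)
  sufficient to score downstream recovery.
- *Traits*: truncated normals per species with the published mean and
  (min, max) per trait and sd = range/6 — a reconstruction, since only
  mean/range summaries are published.  Recurvation-class mixes (CR
  mostly recurved with ~15% flat; CT mostly flat) are likewise
  reconstructed from the reported class proportions.
- *Island fixtures*: localities along an arc with a planted
  allele-frequency discontinuity, for barrier-detection tests.

What passing tests show — and do not show: the generators reproduce the
panel's dimensions, missingness, and filtering behaviour and the
coalescent's distributional properties, but not sequencing error,
depth-dependent genotyping bias, linked selection, or spatially
autocorrelated sampling; conclusions about real data quality control
are out of scope.

## Numerical choices and problem sizes

Desk-scale defaults keep every stage tractable on one CPU: ABC
calibration uses 20+10 diploids with 100-locus tables (2,000 rows/model)
for model choice and a 500-locus, 5,000-row table for parameter
estimation; simulator calibration uses 2,000 loci (Watterson), 1,000
loci per grid point (Fst monotonicity) and 500 loci per parameter set
(cross-simulator KS).  Degenerate inputs are defined rather than
rejected: empty panels give all-zero statistics, identical items give
agglomerative coefficient 0, zero-weight posterior draws are dropped
before quantile interpolation, and a locus whose mutation count exceeds
its length still gets unique positions.

## Known limitations

- The Bayes factor is an acceptance-odds estimator, not a GLM marginal
  density; values are comparable within a run, not to the published
  table.
- The strong-migration limit introduces a small (sub-Monte-Carlo) bias
  near the switching threshold.
- The neural-network adjustment is stochastic across library versions;
  local-linear is the tested default.
- Nei distances of fixed-difference pairs are unbounded; `J_xy = 0`
  yields an infinity sentinel that downstream PCoA cannot embed.
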