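# Methods

This note documents the models and procedures implemented in `tilokit`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a user auditing results should know.

## Synthetic chromosomes

`synthio.simulate_chromosome` draws a symmetric count matrix whose expected
intensity factorizes as

```
lambda(i, j) = d(|i−j|) · beta^[same TAD] · gamma^[different TADs, same cluster] · delta^[loop window]
d(s) = (1 + s)^(−alpha)
```

scaled so the upper-triangle expectation sums to `depth`, then samples each
upper-triangle cell independently from a Poisson and mirrors it. The
diagonal is zero by default and excluded from depth accounting: self-bin
contacts carry no information for any downstream stage. Poisson (rather
than negative-binomial) noise is the simplest model consistent with
shallow Hi-C; an overdispersion knob is deliberately deferred.

Default study conditions, fixed once: **40 TADs × 10 bins at 25-kb bins**
(250-kb TADs — mid-range for mammalian chromosomes), **alpha = 1.0** (the
classic contact-probability decay `~s^-1`), **beta = 3** (intra-TAD
enrichment of the order seen in block-structured Hi-C), **gamma = 2**,
**depth = 5·10⁵** read pairs for one 10-Mb chromosome (shallow but
realistic per-chromosome coverage). Loops are per-experiment inputs.

Cluster labels are a *balanced seeded-random* assignment, not round-robin.
With equal TAD sizes, any periodic assignment aliases genomic distance with
cluster identity: certain separations become dominated by same-cluster
pairs, which inflates the distance-decay expectation at those separations
and silently shrinks the observed same/different O/E contrast below the
planted fold. Random balanced labels keep the enrichment mixture uniform in
distance, so the observed same-cluster / different-cluster O/E ratio equals
`gamma` (verified in the tests to within sampling error).

What the generator does **not** emulate: mappability and GC bias (the
planted rank-1 bias in the balancing tests stands in for these),
overdispersion, trans-chromosomal contacts, unequal TAD sizes by default,
A/B compartment checkerboards, and resolution-dependent artifacts. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under a clean generative model, not performance on real libraries.

## Contact-map conventions, balancing, O/E

Coordinates are 0-based half-open (BED); bin `b` covers
`[b·bin_size, (b+1)·bin_size)`. Bins with a zero marginal are masked and
excluded from balancing, decay estimation, insulation, and network edges;
the mask travels as a boolean vector, never as NaNs.

`balance_ice` is standard iterative correction: divide by the outer product
of row-sum ratios until the coefficient of variation of unmasked row sums
falls below `tol` (default 1e-6, max 200 iterations), preserving total
signal. Note the identifiability caveat: iterative correction recovers a
planted factorizable bias exactly only when the unbiased matrix itself has
constant row sums; the validation fixtures use circulant matrices for this
reason.

`expected_by_distance` is the arithmetic mean of values at each separation
over unmasked pairs; `oe_transform` divides by it (0 where the expected
value is 0). O/E is used everywhere a statistic would otherwise be
dominated by distance decay.

## Insulation and boundaries

The insulation statistic at bin `i` is the mean contact value in the square
`[i−w, i−1] × [i, i+w−1]` — the contacts *crossing the left edge of bin
`i`* — with `w = 8` bins (200 kb at 25-kb bins) by default. The
edge-crossing form is chosen deliberately: the symmetric variant that
excludes bin `i` on both sides attains its minimum on a *two-bin plateau*
around a sharp boundary, so called boundaries would sit one bin left of TAD
start bins; the edge-crossing square has a unique minimum exactly at the
first bin of the downstream block, making boundary bins and TAD start bins
the same coordinate with no half-bin bookkeeping.

Scores are `log2 raw − mean(log2 raw)` over valid bins — the log-ratio to
the chromosome-wide *geometric* mean — so valid finite scores average to
exactly zero and boundary calls are invariant under global rescaling. A bin
whose square sums to zero (possible only in noiseless fixtures) scores
`−inf`: excluded from the normalization mean, but still a legal boundary
minimum.

`call_boundaries` takes strict local minima within `±delta_bins` (default
3; plateau ties resolve to the leftmost bin) that sit at least `min_depth`
(default 0.1 log2 units) below the lower of their flanking maxima, the
maxima being taken between neighboring candidate minima or the valid track
ends. The window `w`, `delta_bins` and `min_depth` are exposed flags; there
is no canonical published value for this combination, and boundary sets
shift with them — treat them as analysis parameters, not constants.

## Peak annotation

A peak belongs to the TAD containing its midpoint (half-open, so a midpoint
on a junction goes right); this makes per-TAD counts well-defined for
grouping. Occupancy groups are `non`/`low`/`medium`/`high` for 0 / 1–2 /
3–4 / ≥5 peaks. Boundary co-location uses a slack of 1 bin by default
(boundary-bin granularity); loop-anchor overlap uses interval intersection
with a bp slack. Scaled-domain profiles linearly interpolate each TAD's
internal signal onto `n_meta_bins` positions and append fixed-width
unscaled flanks; TADs shorter than 2 bins are skipped and counted.

## Aggregate maps (loop-o-gram / APA)

Both operations sum `(2h+1)²` O/E submatrices centered on anchor pairs
(all eligible peak pairs within a separation band for the loop-o-gram,
default `h = 10` giving a 21×21 window of 25-kb bins; loop anchor pairs for
APA, default `h = 5`), drop clipped windows, and normalize the sum to its
median. Aggregating O/E rather than raw counts is essential — raw pileups
are dominated by decay. Aggregation over *pairs* (rather than single-anchor
rows) is the design choice here because the output is interpreted alongside
loop heatmaps; it is exposed, not hidden, in the API (`loopogram` takes
peak lists and a separation band).

The pass/fail flag operationalizes a quartile filter: the aggregate passes
when its global maximum lies inside the central 3×3 block *and* exceeds the
75th percentile of all cells. Requiring centrality matters: the maximum of
the central 3×3 alone exceeds Q3 for most *null* aggregates (nine
near-independent cells against a 75% threshold), whereas the global-maximum
position is uniform under the null, giving a ~2% false-pass rate at
`h = 10` — consistent with shuffled-anchor aggregates failing ≥95% of the
time, which the tests enforce.

Center enrichment is center/median for loop-o-grams and center over the
mean of the four corner 3×3 blocks for APA (the conventional APA score).

## TAD-network clustering

`build_tad_network` weights the edge between two TADs as the mean O/E over
their unmasked inter-TAD bin pairs (raw-mean available); diagonal zero;
fully masked TADs are dropped with a warning.

**Ordering.** The objective is the weighted linear-arrangement cost
`sum w(a,b)·|pi(a)−pi(b)|`. Exact minimization is NP-hard, so `order_nodes`
runs steepest-descent local search from the genomic order plus seeded
random restarts (default 10). The move set is segment reversal (which
subsumes adjacent transposition) and single-node reinsertion; a state where
no move improves the cost is the termination condition. Move deltas are
evaluated in closed form — O(n²) for all reinsertions, O(n³) streamed for
all reversals per sweep — and are property-tested against full cost
recomputation. Orderings are equivalent modulo reversal; the canonical form
places the genomically first TAD in the left half. On random 7-node
networks the search with 10 restarts finds the exhaustive-search optimum
essentially always (validated in the tests against `oracle_best_ordering`).

**Slicing.** `cut_profile` gives `C(i)`, the weight crossing each position;
`pinch_ratios` scores each interior local minimum (plateaus resolve
leftmost) as `C(i)/min(Lmax, Rmax)` with flanking maxima taken up to
neighboring minima or the profile ends, undefined where both flanks are
zero. `slice_network` accepts cuts with `rho <= tau` (default 0.5) greedily
from the smallest ratio, skipping cuts that would create a segment smaller
than `min_size` (default 2 — singleton clusters are indistinguishable from
noise).

**Background subtraction.** Before ordering and slicing, `tilo_cluster`
reduces edge weights to enrichment above background:
`w_eff = max(0, w − median(off-diagonal w))`. This step is load-bearing.
With raw O/E edges the background level is ~1 between *every* pair, so the
cut profile of any arrangement is dominated by the quadratic
`i·(n−i)` envelope of the baseline; cluster borders are then not even local
minima. After subtraction, borders carry only clipped noise, interior cuts
carry cluster signal, and planted borders score pinch ratios around 0.3.
The median is the right location estimate because most TAD pairs belong to
no common cluster. The behavior is controlled by the `baseline` parameter
(`"median"`, `"none"`, or an explicit float).

**Recursion and robustness.** The pipeline re-orders and re-slices inside
each segment until no segment admits a cut, with recursion capped at
`max_rounds = 10` to guarantee termination. `tilo_cluster` runs `restarts`
(default 10) independently seeded replicates of the whole pipeline; each
replicate uses a smaller number of local-search starts (`order_restarts`,
default 3) since replicates already diversify the search. Robustness is the
mean pairwise adjusted Rand index across replicates; reported labels come
from the replicate with the median top-level cost, renumbered 0..K−1 by
genomic first appearance. A zero or block-diagonal network yields
robustness exactly 1.

## 3D bead models

`write_gtrack` emits one bead per TAD in a strict, documented gtrack
dialect (`##gtrack version: 1.0`, declared columns `seqid start end id
radius periphery edges`, optional extras such as per-bead peak counts;
edges `id=weight;...` and symmetric). Bead radii scale as (TAD length)^⅓ so
total bead volume is `vol_frac` of the nucleus volume. Beads overlapping a
LAD are flagged `periphery`. Gaps between TADs carry no bead — the
convention of filling gaps with single-base beads and then removing them
reduces, for edge construction, to ignoring gaps. Diploid mode duplicates
records with `_A`/`_B` suffixes.

`embed` is a deliberately simplified Metropolis simulated-annealing
embedder, not a reimplementation of Chrom3D's likelihood (which also models
inter-chromosomal contacts); the exported gtrack keeps interoperability
with the real tool. Energy:

```
E = w_chain·Σ max(0, d − r_a − r_b)²   over consecutive chain beads
  + w_int  ·Σ d²                       over interaction-pair beads
  + w_lad  ·Σ (R − |x|)²               over periphery beads
  + w_excl ·Σ max(0, r_a + r_b − d)²   over all bead pairs
```

with defaults `w_chain = w_int = 1`, `w_lad = 0.5`, `w_excl = 20` — these
weights have no counterpart in the data and are exposed configuration. The
nucleus (`R = 5` model units) is a hard wall: proposals violating
`|x| + r <= R` are rejected, so the returned model always satisfies the
constraint. Proposals are single-bead Gaussian displacements with a step
size annealed alongside a geometric temperature schedule (1.0 → 1e-3) over
`iterations` (default 200,000). The best-visited configuration is returned,
so the final energy never exceeds the initial one. Runs are deterministic
given the seed.

`group_distances` compares, for each group with ≥2 beads, its within-group
pairwise center distances against the distances from its beads to all other
beads, via `mann_whitney_u`: midrank-based U, exact enumeration of all
group assignments when `n_x + n_y <= 12` (two-sided p as the probability of
a |U − mean| at least as extreme), otherwise a normal approximation with
tie-corrected variance and 0.5 continuity correction. The normal
approximation is good to roughly ±0.02 against exact enumeration at
n = 6+6; for smaller samples the exact path is always taken.

## Numerical choices and degenerate inputs

- Local-search acceptance threshold: a move must improve the cost by more
  than `1e-9·(1+|cost|)` — guards against float-tie cycling.
- Ties: boundary and pinch-ratio plateau minima resolve to the leftmost
  bin; equal-cost orderings resolve to the first found (restart order).
- A flat cut profile has no minima: one cluster, no error.
- Fewer than 2 TADs: trivial single cluster, robustness 1.
- `profile_around` and `scaled_domain_profile` reject flank widths that are
  not whole bins rather than silently rounding.
- Empty peak sets are rejected where a fraction would be reported (a
  fraction of nothing is a silent bug); empty boundary lists give 0.
- ICE non-convergence raises with the final CV rather than returning a
  half-balanced matrix.

## Problem sizes

The validation experiments run at the study conditions above: 10 simulated
chromosomes of 400 bins for recovery and null experiments, 100 random
7-node networks for the ordering oracle, 100 anchor shuffles for the
aggregation null, and 10 embeddings of 40 beads at 200,000 iterations.
These sizes give stable pass/fail behavior at the stated thresholds while
keeping a full validation run in the minutes range on a single core.

## Known limitations

- The pinch-ratio formulation here (arrangement cost + greedy slicing) is a
  declared, testable operationalization; the original lexicographic
  formulation from knot theory is not fully specified in accessible
  sources, and no claim of exact equivalence is made.
- Single chromosome per simulation; trans contacts and inter-chromosomal
  clustering are out of scope.
- The balancing utility is plain iterative correction, not a full
  bias-model pipeline.
- The embedder's weights are heuristic; distances between groups are
  meaningful relative to each other within one embedding, not in physical
  units.
- Hierarchical (nested) cluster output is collapsed: recursion depth is
  recorded only through the final flat labels.
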