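# tilokit

Tools for asking how the topological domains (TADs) of a chromosome associate
with one another in space, from nothing but a binned Hi-C contact map — and
for validating every step of that analysis on synthetic chromosomes with
planted ground truth.

Hi-C readily shows *local* structure: TADs as blocks on the diagonal,
boundaries as insulation minima, loops as focal dots. Higher-order structure
— which TADs co-associate in *cis*, forming "metaTAD"-like clusters enriched
for particular chromatin marks — is harder to see. `tilokit` implements a
graph-theoretic route to it, together with the supporting computations such
a study needs (insulation scores and boundary calls, peak-to-TAD/boundary/
loop-anchor annotation, aggregate peak analysis, and Chrom3D-compatible 3D
bead models), for computational chromatin biologists who want each stage as
a tested, seedable library function.

## The core method

TADs are the nodes of a weighted network; the edge weight between TADs *a*
and *b* is the mean observed/expected (O/E) Hi-C contact over their
inter-TAD bin pairs, so edges measure enrichment over distance decay rather
than genomic adjacency. The pipeline then:

1. **Orders** the nodes by minimizing the weighted linear-arrangement cost
   `sum_{a<b} w(a,b) |pi(a) − pi(b)|` with steepest-descent local search
   (segment reversals and single-node reinsertions, closed-form move deltas,
   seeded random restarts), stopping when no move improves the cost.
2. **Slices** the arrangement via the **pinch ratio**: with `C(i)` the total
   edge weight crossing position `i`, each interior local minimum of `C`
   scores `rho(i) = C(i) / min(Lmax, Rmax)` against its flanking maxima.
   Cuts with `rho <= tau` (default 0.5) are accepted greedily, smallest
   first, never creating a segment below `min_size`.
3. **Recurses** inside each segment until no segment admits a cut, and
   **scores robustness** as the mean pairwise adjusted Rand index across
   independently seeded replicates of the whole pipeline.

Clusters can then be annotated by ChIP peak content (groups `non`/`low`/
`medium`/`high` for 0 / 1–2 / 3–4 / ≥5 peaks per TAD), exported as Chrom3D
gtrack bead models ("1 TAD = 1 bead"), embedded in a spherical nucleus by
simulated annealing, and compared by within- vs between-group 3D distances
with a Wilcoxon–Mann–Whitney rank-sum test.

The synthetic generator (`tilokit.synthio`) produces Poisson-sampled contact
maps with power-law distance decay `(1+s)^(-alpha)`, planted TAD blocks,
planted inter-TAD cluster enrichment, focal loops, and peak tracks — all
with full ground truth, so recovery is measurable.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from tilokit import (study_params, simulate_chromosome, tilo_cluster,
                     insulation_score, call_boundaries)

params = study_params(n_tads=40, tad_bins=10, n_clusters=4,
                      cluster_fold=2.0, depth=5e5, seed=42)
cmap, truth = simulate_chromosome(params)

track = insulation_score(cmap, window_bins=8)
boundaries = call_boundaries(track)
print(f"called {len(boundaries)} boundaries, planted {len(truth.boundaries)}")

result = tilo_cluster(cmap, truth.tads, tau=0.5, restarts=10, seed=42)
ari = adjusted_rand_score(truth.cluster_labels, result.labels)
print(f"clusters: {result.n_clusters}, robustness: {result.robustness:.3f}, "
      f"ARI vs truth: {ari:.3f}")
```

prints

```
called 39 boundaries, planted 39
clusters: 4, robustness: 1.000, ARI vs truth: 1.000
```

i.e. on a 400-bin chromosome (40 TADs of 250 kb at 25-kb bins, four planted
clusters scattered along the chromosome, 2-fold inter-TAD enrichment,
500,000 read pairs), every planted boundary is recovered, and the clustering
reproduces the planted partition exactly (adjusted Rand index 1.0) with
perfect agreement across the 10 internal replicates (robustness 1.0).
Cluster labels are renumbered by genomic first appearance, so they match the
planted labels up to that renaming.

The same stages are available from the shell:

```sh
tilokit simulate --out fixture --seed 42
tilokit tilo --matrix fixture/matrix.coo.tsv --tads fixture/tads.bed \
       --n-bins 400 --out tilo-run --seed 42
tilokit gtrack --tads fixture/tads.bed --clusters tilo-run/clusters.bed \
       --peaks fixture/peaks.bed --out gt
tilokit embed --gtrack gt/model.gtrack --out model --seed 42
```

Every run writes a JSON provenance record (version, parameters, seed, input
hashes); identical configs and seeds give byte-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `tilokit.synthio` | synthetic chromosomes with planted truth; fixture writer |
| `tilokit.hicio` | COO/dense/BED/BEDPE I/O, ICE balancing, distance decay, O/E |
| `tilokit.insulation` | sliding-square insulation, boundary calling, anchor profiles |
| `tilokit.annotate` | peak-to-TAD counts and groups, boundary/anchor overlap, meta-profiles |
| `tilokit.aggregate` | loop-o-grams over peak pairs, APA over loop anchors |
| `tilokit.tilo` | TAD network, ordering, pinch-ratio slicing, clustering |
| `tilokit.model3d` | gtrack export/parsing, Monte-Carlo embedding, rank-sum statistics |
| `tilokit.cli` | `tilokit` command with one subcommand per stage |

See `docs/methods.md` for the model, parameter choices and limitations.
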