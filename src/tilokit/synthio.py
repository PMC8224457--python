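"""Synthetic Hi-C chromosomes with planted ground truth.

The generator emulates the statistical structure a binned single-chromosome
Hi-C matrix presents to the downstream stages:

* power-law distance decay ``d(s) = (1 + s)**(-alpha)``,
* topological domains (TADs) as diagonal blocks with fold enrichment ``beta``,
* inter-TAD *cluster* enrichment: pairs of bins in different TADs that carry
  the same planted cluster label are enriched by ``gamma`` — this is the
  structure the TAD-network clustering stage is designed to recover,
* focal loops as ``delta``-fold enrichment on single bin pairs,
* Poisson count noise at a controlled total sequencing depth.

Everything is deterministic given ``seed``; the planted truth travels with
the matrix as a :class:`SyntheticTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hicio import (
    BinnedContactMap,
    GenomicInterval,
    LoopSet,
    write_bed,
    write_bedpe,
    write_contact_map,
)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "study_params",
    "simulate_chromosome",
    "expected_intensity",
    "plant_peaks",
    "plant_boundary_peaks",
    "write_fixture",
]

PEAK_GROUPS = ("non", "low", "medium", "high")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated chromosome."""

    n_bins: int
    tad_lengths: tuple[int, ...]
    cluster_labels: tuple[int, ...]
    bin_size: int = 25_000
    alpha: float = 1.0                # distance-decay exponent, > 0
    intra_tad_fold: float = 3.0       # beta >= 1
    cluster_fold: float = 2.0         # gamma >= 1, inter-TAD same-cluster
    loops: tuple[tuple[int, int], ...] = ()
    loop_fold: float = 1.0            # delta >= 1, focal 1-bin square
    depth: float = 5e5                # expected off-diagonal read pairs
    seed: int = 0
    sample_diagonal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "tad_lengths", tuple(int(x) for x in self.tad_lengths))
        object.__setattr__(self, "cluster_labels", tuple(int(x) for x in self.cluster_labels))
        object.__setattr__(self, "loops", tuple((int(i), int(j)) for i, j in self.loops))
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if min(self.intra_tad_fold, self.cluster_fold, self.loop_fold) < 1:
            raise ValueError("fold enrichments must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if any(l <= 0 for l in self.tad_lengths):
            k = next(i for i, l in enumerate(self.tad_lengths) if l <= 0)
            raise ValueError(f"TAD {k} has non-positive length {self.tad_lengths[k]}")
        cum = np.cumsum(self.tad_lengths)
        if cum[-1] != self.n_bins:
            # name the first TAD at which the partition goes wrong
            over = np.flatnonzero(cum > self.n_bins)
            k = int(over[0]) if len(over) else len(self.tad_lengths) - 1
            raise ValueError(
                f"tad_lengths must sum to n_bins={self.n_bins}, got {cum[-1]} "
                f"(offending TAD index {k})"
            )
        if len(self.cluster_labels) != len(self.tad_lengths):
            raise ValueError(
                f"cluster_labels length {len(self.cluster_labels)} != "
                f"TAD count {len(self.tad_lengths)}"
            )
        for k, (i, j) in enumerate(self.loops):
            if not (0 <= i < j < self.n_bins):
                raise ValueError(f"loop {k} has invalid bin pair ({i}, {j})")

    @property
    def n_tads(self) -> int:
        return len(self.tad_lengths)

    @property
    def boundaries(self) -> np.ndarray:
        """Interior TAD boundary bins (start bin of every TAD but the first)."""
        return np.cumsum(self.tad_lengths)[:-1]

    def tad_bin_spans(self) -> list[tuple[int, int]]:
        edges = np.concatenate([[0], np.cumsum(self.tad_lengths)])
        return [(int(edges[k]), int(edges[k + 1])) for k in range(self.n_tads)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated chromosome."""

    boundaries: np.ndarray                      # interior boundary bins, increasing
    tads: list[GenomicInterval]                 # bp intervals tiling the chromosome
    cluster_labels: np.ndarray                  # per TAD
    loop_pairs: list[tuple[int, int]]           # bin pairs
    peak_intervals: list[GenomicInterval]       # filled by plant_peaks
    params: SimParams

    def __post_init__(self):
        b = np.asarray(self.boundaries)
        if len(b) and np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.cluster_labels) != len(self.tads):
            raise ValueError("cluster_labels length must equal TAD count")


def study_params(
    n_tads: int = 40,
    tad_bins: int = 10,
    n_clusters: int = 4,
    cluster_fold: float = 2.0,
    intra_tad_fold: float = 3.0,
    alpha: float = 1.0,
    depth: float = 5e5,
    bin_size: int = 25_000,
    loops: tuple[tuple[int, int], ...] = (),
    loop_fold: float = 1.0,
    seed: int = 0,
) -> SimParams:
    """Default study conditions: equal-sized TADs, balanced random labels.

    Each cluster gets ``n_tads / n_clusters`` TADs (up to remainder) at
    seeded random positions, so planted clusters are scattered along the
    chromosome — *not* genomically contiguous — and no genomic distance is
    systematically enriched for one cluster. Recovering them requires the
    ordering step, not mere segmentation.
    """
    base = np.array([k % n_clusters for k in range(n_tads)])
    labels = np.random.default_rng(seed + 101_159).permutation(base)
    return SimParams(
        n_bins=n_tads * tad_bins,
        tad_lengths=tuple([tad_bins] * n_tads),
        cluster_labels=tuple(int(x) for x in labels),
        bin_size=bin_size,
        alpha=alpha,
        intra_tad_fold=intra_tad_fold,
        cluster_fold=cluster_fold,
        loops=loops,
        loop_fold=loop_fold,
        depth=depth,
        seed=seed,
    )


def expected_intensity(params: SimParams) -> np.ndarray:
    """Expected count matrix lambda(i, j), scaled so the off-diagonal
    expectation (upper triangle) sums to ``depth``.

    lambda(i,j) = d(|i-j|) * beta^[same TAD] * gamma^[different TAD, same
    cluster] * delta^[loop pair], with d(s) = (1+s)^(-alpha).
    """
    n = params.n_bins
    idx = np.arange(n)
    sep = np.abs(np.subtract.outer(idx, idx))
    lam = (1.0 + sep) ** (-params.alpha)

    tad_of = np.repeat(np.arange(params.n_tads), params.tad_lengths)
    same_tad = np.equal.outer(tad_of, tad_of)
    lam = np.where(same_tad, lam * params.intra_tad_fold, lam)

    clus_of = np.asarray(params.cluster_labels)[tad_of]
    same_clus = np.equal.outer(clus_of, clus_of) & ~same_tad
    lam = np.where(same_clus, lam * params.cluster_fold, lam)

    for i, j in params.loops:
        lam[i, j] *= params.loop_fold
        lam[j, i] *= params.loop_fold

    off = np.triu(lam, 1).sum()
    lam *= params.depth / off
    return lam


def simulate_chromosome(params: SimParams) -> tuple[BinnedContactMap, SyntheticTruth]:
    """Draw a Poisson-sampled symmetric contact map with planted structure."""
    lam = expected_intensity(params)
    rng = np.random.default_rng(params.seed)
    n = params.n_bins
    iu, ju = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    counts[iu, ju] = rng.poisson(lam[iu, ju])
    counts += counts.T
    if params.sample_diagonal:
        counts[np.diag_indices(n)] = rng.poisson(np.diag(lam))

    cmap = BinnedContactMap(
        chrom="chrS", bin_size=params.bin_size, values=counts
    )
    tads = [
        GenomicInterval("chrS", sb * params.bin_size, eb * params.bin_size, name=f"tad_{k}")
        for k, (sb, eb) in enumerate(params.tad_bin_spans())
    ]
    truth = SyntheticTruth(
        boundaries=params.boundaries,
        tads=tads,
        cluster_labels=np.asarray(params.cluster_labels),
        loop_pairs=list(params.loops),
        peak_intervals=[],
        params=params,
    )
    return cmap, truth


# ---------------------------------------------------------------------------
# peak planting
# ---------------------------------------------------------------------------

def plant_peaks(
    truth: SyntheticTruth,
    group_spec: dict[str, int],
    tad_groups: list[str] | None = None,
    peak_width: int | None = None,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Place non-overlapping peaks uniformly, strictly inside each TAD.

    ``group_spec`` maps a group name (subset of {non, low, medium, high}) to
    the number of peaks every TAD of that group receives; ``tad_groups``
    assigns each TAD to a group (default: cycle through group_spec's keys).
    Raises if a TAD cannot hold the requested number of peaks. The placements
    are recorded on ``truth.peak_intervals`` and returned sorted by start.
    """
    bad = set(group_spec) - set(PEAK_GROUPS)
    if bad:
        raise ValueError(f"unknown peak groups {sorted(bad)}; allowed: {PEAK_GROUPS}")
    keys = list(group_spec)
    if tad_groups is None:
        tad_groups = [keys[k % len(keys)] for k in range(len(truth.tads))]
    if len(tad_groups) != len(truth.tads):
        raise ValueError("tad_groups length must equal TAD count")
    width = peak_width if peak_width is not None else max(200, truth.params.bin_size // 5)
    rng = np.random.default_rng(seed)
    peaks: list[GenomicInterval] = []
    for k, tad in enumerate(truth.tads):
        n_peaks = group_spec[tad_groups[k]]
        if n_peaks == 0:
            continue
        inner_start, inner_end = tad.start + 1, tad.end - 1
        free = (inner_end - inner_start) - n_peaks * width
        if free < 0:
            raise ValueError(
                f"TAD {k} ({tad.start}-{tad.end}) cannot hold {n_peaks} peaks of width {width}"
            )
        # uniform non-overlapping placement: distribute the free space
        gaps = np.sort(rng.integers(0, free + 1, size=n_peaks))
        for p in range(n_peaks):
            s = inner_start + gaps[p] + p * width
            peaks.append(GenomicInterval(tad.chrom, int(s), int(s + width), name=f"peak_t{k}_{p}"))
    peaks.sort(key=lambda iv: iv.start)
    truth.peak_intervals = peaks
    return peaks


def plant_boundary_peaks(
    truth: SyntheticTruth,
    n_peaks: int,
    peak_width: int | None = None,
    seed: int = 0,
    slack_bins: int = 1,
) -> list[GenomicInterval]:
    """Place peaks centered within ``slack_bins`` bins of interior boundaries.

    Boundaries are sampled without replacement while available, then with
    replacement (offsetting within the slack window keeps peaks distinct).
    """
    if len(truth.boundaries) == 0:
        raise ValueError("truth has no interior boundaries")
    width = peak_width if peak_width is not None else max(200, truth.params.bin_size // 5)
    bs = truth.params.bin_size
    rng = np.random.default_rng(seed)
    chrom = truth.tads[0].chrom
    chrom_end = truth.tads[-1].end
    peaks = []
    bset = np.asarray(truth.boundaries)
    for p in range(n_peaks):
        b = int(bset[p % len(bset)]) if n_peaks <= len(bset) else int(rng.choice(bset))
        off = int(rng.integers(-slack_bins, slack_bins + 1))
        center = (b + off) * bs + bs // 2
        s = int(np.clip(center - width // 2, 0, chrom_end - width))
        peaks.append(GenomicInterval(chrom, s, s + width, name=f"bpeak_{p}"))
    peaks.sort(key=lambda iv: iv.start)
    return peaks


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(
    dir_path: str | Path,
    cmap: BinnedContactMap,
    truth: SyntheticTruth,
    peaks: list[GenomicInterval] | None = None,
    lads: list[GenomicInterval] | None = None,
) -> dict:
    """Write a complete text fixture and return its manifest.

    Files: COO matrix, TAD BED, peak BED, loop BEDPE, LAD BED and a JSON
    manifest recording per-file row counts plus the simulation parameters.
    All files round-trip losslessly through the :mod:`tilokit.hicio` readers.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    peaks = peaks if peaks is not None else truth.peak_intervals
    lads = lads or []

    write_contact_map(cmap, d / "matrix.coo.tsv", fmt="coo")
    write_bed(truth.tads, d / "tads.bed")
    write_bed(peaks, d / "peaks.bed")
    write_bed(lads, d / "lads.bed")
    chrom = truth.tads[0].chrom
    loop_ivs = []
    for i, j in truth.loop_pairs:
        bs = cmap.bin_size
        loop_ivs.append(
            (GenomicInterval(chrom, i * bs, (i + 1) * bs), GenomicInterval(chrom, j * bs, (j + 1) * bs))
        )
    write_bedpe(LoopSet(anchors=loop_ivs), d / "loops.bedpe")

    n_coo = int(np.count_nonzero(np.triu(cmap.values)))
    manifest = {
        "chrom": chrom,
        "n_bins": cmap.n_bins,
        "bin_size": cmap.bin_size,
        "files": {
            "matrix.coo.tsv": n_coo,
            "tads.bed": len(truth.tads),
            "peaks.bed": len(peaks),
            "lads.bed": len(lads),
            "loops.bedpe": len(truth.loop_pairs),
        },
        "boundaries": [int(b) for b in truth.boundaries],
        "cluster_labels": [int(c) for c in truth.cluster_labels],
        "params": _params_json(truth.params),
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _params_json(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    d["tad_lengths"] = list(d["tad_lengths"])
    d["cluster_labels"] = list(d["cluster_labels"])
    d["loops"] = [list(p) for p in d["loops"]]
    return d
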