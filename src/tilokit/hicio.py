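"""Contact-map and interval I/O, matrix balancing, distance decay and O/E.

Conventions used throughout the package:

* Genomic coordinates are 0-based, half-open (BED convention). Bin ``b`` of a
  map with bin size ``s`` covers ``[b*s, (b+1)*s)``.
* Contact matrices are dense, symmetric, nonnegative ``float64`` arrays.
* Bins with a zero marginal are *masked*: they are excluded from balancing,
  distance decay, insulation and TAD-network edges. The mask travels with the
  map as a boolean array (``True`` = masked), never as NaNs.

On disk a map is either sparse COO text (``bin_i<TAB>bin_j<TAB>count``,
0-based, upper triangle only) or a dense TSV with ``n_bins`` columns; the
dialect is auto-detected from the column count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BinnedContactMap",
    "GenomicInterval",
    "LoopSet",
    "ConvergenceError",
    "read_contact_map",
    "write_contact_map",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "balance_ice",
    "expected_by_distance",
    "oe_transform",
]


class ConvergenceError(RuntimeError):
    """Raised when iterative correction fails to reach the tolerance."""

    def __init__(self, message: str, final_cv: float):
        super().__init__(message)
        self.final_cv = final_cv


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def midpoint_bin(self, bin_size: int) -> int:
        return self.midpoint // bin_size

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LoopSet:
    """Chromatin loops as (left anchor, right anchor) pairs on one chromosome.

    Anchor A lies strictly left of anchor B; pairs are kept sorted by A.start.
    """

    anchors: list[tuple[GenomicInterval, GenomicInterval]]

    def __post_init__(self):
        for a, b in self.anchors:
            if a.chrom != b.chrom:
                raise ValueError(f"loop anchors on different chromosomes: {a.chrom} vs {b.chrom}")
            if a.end > b.start:
                raise ValueError(
                    f"loop anchors overlap or are unordered: {a.start}-{a.end} vs {b.start}-{b.end}"
                )
        self.anchors = sorted(self.anchors, key=lambda ab: (ab[0].start, ab[1].start))

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)


@dataclass
class BinnedContactMap:
    """Symmetric binned Hi-C contact matrix for a single chromosome."""

    chrom: str
    bin_size: int
    values: np.ndarray
    balanced: bool = False
    mask: np.ndarray = field(default=None)  # True = masked-out bin

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix contains non-finite values")
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(f"negative count at bin pair ({i}, {j})")
        if not np.array_equal(v, v.T):
            i, j = np.argwhere(v != v.T)[0]
            raise ValueError(f"asymmetric matrix at cell ({i}, {j}): {v[i, j]} != {v[j, i]}")
        self.values = v
        if self.mask is None:
            self.mask = self._zero_marginal_mask()
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (v.shape[0],):
                raise ValueError("mask length must equal n_bins")

    def _zero_marginal_mask(self) -> np.ndarray:
        return self.values.sum(axis=0) == 0

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, *, balanced: bool | None = None) -> "BinnedContactMap":
        return BinnedContactMap(
            chrom=self.chrom,
            bin_size=self.bin_size,
            values=values,
            balanced=self.balanced if balanced is None else balanced,
            mask=self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# contact-map I/O
# ---------------------------------------------------------------------------

def read_contact_map(
    path: str | Path,
    n_bins: int,
    bin_size: int,
    chrom: str = "chr1",
) -> BinnedContactMap:
    """Read a contact map from COO triple text or dense TSV (auto-detected).

    A file whose rows have exactly three columns is parsed as COO
    (``bin_i  bin_j  count``, upper triangle, 0-based); anything else must be
    a dense ``n_bins`` x ``n_bins`` TSV, which is required to be symmetric.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3 and n_bins != 3:
        i = df[0].to_numpy(dtype=np.int64)
        j = df[1].to_numpy(dtype=np.int64)
        c = df[2].to_numpy(dtype=float)
        if np.any((i < 0) | (i >= n_bins) | (j < 0) | (j >= n_bins)):
            k = int(np.flatnonzero((i < 0) | (i >= n_bins) | (j < 0) | (j >= n_bins))[0])
            raise ValueError(
                f"{path}: bin index out of range at row {k}: ({i[k]}, {j[k]}) with n_bins={n_bins}"
            )
        if np.any(i > j):
            k = int(np.flatnonzero(i > j)[0])
            raise ValueError(
                f"{path}: lower-triangle entry at row {k}: ({i[k]}, {j[k]}); COO must be upper triangle"
            )
        if np.any(c < 0):
            k = int(np.flatnonzero(c < 0)[0])
            raise ValueError(f"{path}: negative count at row {k}")
        m = np.zeros((n_bins, n_bins), dtype=float)
        np.add.at(m, (i, j), c)
        # mirror the upper triangle
        upper = np.triu(m, 1)
        m = np.diag(np.diag(m)) + upper + upper.T
    else:
        m = df.to_numpy(dtype=float)
        if m.shape != (n_bins, n_bins):
            raise ValueError(f"{path}: dense matrix shape {m.shape} != ({n_bins}, {n_bins})")
        if not np.array_equal(m, m.T):
            a, b = np.argwhere(m != m.T)[0]
            raise ValueError(
                f"{path}: dense matrix is asymmetric at cell ({a}, {b}): {m[a, b]} != {m[b, a]}"
            )
    return BinnedContactMap(chrom=chrom, bin_size=bin_size, values=m)


def write_contact_map(cmap: BinnedContactMap, path: str | Path, fmt: str = "coo") -> None:
    """Write a map as COO text (upper triangle, nonzero entries) or dense TSV."""
    path = Path(path)
    if fmt == "coo":
        i, j = np.nonzero(np.triu(cmap.values))
        c = cmap.values[i, j]
        # integers stay integers so round trips are lossless
        if np.allclose(c, np.round(c)):
            col = pd.Series(np.round(c).astype(np.int64))
        else:
            col = pd.Series(c)
        pd.DataFrame({0: i, 1: j, 2: col}).to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "dense":
        pd.DataFrame(cmap.values).to_csv(
            path, sep="\t", header=False, index=False, float_format="%.9g"
        )
    else:
        raise ValueError(f"unknown contact-map format {fmt!r}")


# ---------------------------------------------------------------------------
# interval I/O (BED / BEDPE)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into a list of intervals (empty file allowed)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    out = []
    for row in df.itertuples(index=False):
        fields = list(row) + ["."] * (6 - len(row))
        out.append(
            GenomicInterval(
                chrom=str(fields[0]),
                start=int(fields[1]),
                end=int(fields[2]),
                name=str(fields[3]) if len(row) > 3 else ".",
                score=float(fields[4]) if len(row) > 4 and fields[4] != "." else 0.0,
                strand=str(fields[5]) if len(row) > 5 else ".",
            )
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, n_cols: int = 6) -> None:
    rows = []
    for iv in intervals:
        row = [iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand][:n_cols]
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> LoopSet:
    """Read BEDPE (chromA startA endA chromB startB endB [name score])."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return LoopSet(anchors=[])
    pairs = []
    for row in df.itertuples(index=False):
        a = GenomicInterval(chrom=str(row[0]), start=int(row[1]), end=int(row[2]))
        b = GenomicInterval(chrom=str(row[3]), start=int(row[4]), end=int(row[5]))
        pairs.append((a, b))
    return LoopSet(anchors=pairs)


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    rows = [
        [a.chrom, a.start, a.end, b.chrom, b.start, b.end, f"loop_{k}", 0]
        for k, (a, b) in enumerate(loops)
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# balancing and expected/observed
# ---------------------------------------------------------------------------

def balance_ice(
    cmap: BinnedContactMap, max_iter: int = 200, tol: float = 1e-6
) -> BinnedContactMap:
    """Iterative correction (ICE): equalize row sums over unmasked bins.

    Bins with an all-zero marginal are masked and excluded. The total signal
    of the unmasked submatrix is preserved. Raises :class:`ConvergenceError`
    (carrying the final CV) if the coefficient of variation of unmasked row
    sums does not fall below ``tol`` within ``max_iter`` iterations.
    """
    mask = cmap.values.sum(axis=0) == 0
    keep = ~mask
    if keep.sum() < 2:
        raise ValueError("fewer than two unmasked bins; nothing to balance")
    w = cmap.values[np.ix_(keep, keep)].astype(float)
    total = w.sum()
    cv = np.inf
    for _ in range(max_iter):
        s = w.sum(axis=0)
        mean_s = s.mean()
        cv = s.std() / mean_s
        if cv <= tol:
            break
        b = s / mean_s
        w /= np.outer(b, b)
    else:
        raise ConvergenceError(
            f"ICE did not converge in {max_iter} iterations (final CV {cv:.3g} > tol {tol:g})",
            final_cv=float(cv),
        )
    w *= total / w.sum()
    out = np.zeros_like(cmap.values)
    out[np.ix_(keep, keep)] = w
    # exact symmetry despite float division order
    out = (out + out.T) / 2.0
    result = BinnedContactMap(
        chrom=cmap.chrom, bin_size=cmap.bin_size, values=out, balanced=True, mask=mask
    )
    return result


def expected_by_distance(cmap: BinnedContactMap) -> np.ndarray:
    """Mean contact value at each genomic separation over unmasked bin pairs.

    Returns a vector of length ``n_bins``; entry ``s`` covers pairs with
    ``|i - j| == s`` (``s = 0`` is the diagonal). Separations with no unmasked
    pair get 0.
    """
    n = cmap.n_bins
    keep = ~cmap.mask
    decay = np.zeros(n)
    for s in range(n):
        vals = np.diagonal(cmap.values, offset=s)
        ok = keep[: n - s] & keep[s:]
        if ok.any():
            decay[s] = vals[ok].mean()
    return decay


def oe_transform(cmap: BinnedContactMap) -> BinnedContactMap:
    """Observed/expected transform: divide by the distance-decay mean.

    Cells at separations whose expected value is 0 (and all masked bins) map
    to 0. Symmetry is preserved.
    """
    n = cmap.n_bins
    decay = expected_by_distance(cmap)
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = decay[sep]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, cmap.values / denom, 0.0)
    keep = ~cmap.mask
    oe[~keep, :] = 0.0
    oe[:, ~keep] = 0.0
    return BinnedContactMap(
        chrom=cmap.chrom, bin_size=cmap.bin_size, values=oe,
        balanced=cmap.balanced, mask=cmap.mask.copy(),
    )
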