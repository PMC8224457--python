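"""Relate ChIP peaks to TADs, boundaries and loop anchors.

A peak belongs to exactly one TAD — the one containing its midpoint (half-open
intervals, so a midpoint sitting exactly on a junction goes to the right-hand
TAD). Per-TAD peak counts translate into the four occupancy groups used to
color TAD clusters: "non" (0 peaks), "low" (1-2), "medium" (3-4), "high"
(5 or more).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hicio import GenomicInterval, LoopSet

__all__ = [
    "TadPeakAnnotation",
    "peak_group_label",
    "peaks_at_boundaries",
    "count_peaks_per_tad",
    "anchor_overlap",
    "scaled_domain_profile",
]


def peak_group_label(count: int) -> str:
    """Occupancy group for a per-TAD peak count: 0 / 1-2 / 3-4 / >=5."""
    if count < 0:
        raise ValueError("peak count cannot be negative")
    if count == 0:
        return "non"
    if count <= 2:
        return "low"
    if count <= 4:
        return "medium"
    return "high"


@dataclass
class TadPeakAnnotation:
    """Per-TAD peak counts and group labels, plus each peak's TAD index."""

    counts: np.ndarray              # per TAD
    labels: list[str]               # per TAD, one of non/low/medium/high
    peak_tad_index: np.ndarray      # per peak; -1 if midpoint outside all TADs

    @property
    def n_tads(self) -> int:
        return len(self.counts)


def peaks_at_boundaries(
    peaks: list[GenomicInterval],
    boundaries: list[int] | np.ndarray,
    bin_size: int,
    slack_bins: int = 1,
) -> tuple[list[str], float]:
    """Classify each peak as ``boundary`` or ``intra-TAD``.

    A peak is at a boundary iff its midpoint bin lies within ``slack_bins``
    of some boundary bin. Returns the per-peak classes and the boundary
    fraction. Raises on an empty peak set (a fraction of nothing is
    meaningless); an empty boundary list simply yields fraction 0.
    """
    if not peaks:
        raise ValueError("empty peak set")
    b = np.asarray(sorted(int(x) for x in boundaries))
    classes = []
    for p in peaks:
        mb = p.midpoint // bin_size
        at = len(b) > 0 and np.min(np.abs(b - mb)) <= slack_bins
        classes.append("boundary" if at else "intra-TAD")
    frac = classes.count("boundary") / len(classes)
    return classes, frac


def count_peaks_per_tad(
    peaks: list[GenomicInterval], tads: list[GenomicInterval]
) -> TadPeakAnnotation:
    """Assign peaks to TADs by midpoint and label TADs by occupancy group.

    TADs must be disjoint; they are processed in sorted genomic order.
    """
    order = sorted(range(len(tads)), key=lambda k: tads[k].start)
    starts = np.array([tads[k].start for k in order])
    ends = np.array([tads[k].end for k in order])
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("TADs overlap; midpoint assignment requires disjoint TADs")
    counts = np.zeros(len(tads), dtype=int)
    peak_tad = np.full(len(peaks), -1, dtype=int)
    for pi, p in enumerate(peaks):
        m = p.midpoint
        k = int(np.searchsorted(starts, m, side="right")) - 1
        if k >= 0 and m < ends[k]:
            orig = order[k]
            counts[orig] += 1
            peak_tad[pi] = orig
    labels = [peak_group_label(int(c)) for c in counts]
    return TadPeakAnnotation(counts=counts, labels=labels, peak_tad_index=peak_tad)


def anchor_overlap(
    peaks: list[GenomicInterval], loops: LoopSet, slack_bp: int = 0
) -> dict:
    """Fraction of peaks whose +-slack-extended interval hits a loop anchor.

    Returns ``{"fraction", "n_overlap", "n_total"}``. An empty loop set is
    rejected; an empty peak set yields fraction 0 over 0 — rejected too.
    """
    if len(loops) == 0:
        raise ValueError("empty loop set")
    if not peaks:
        raise ValueError("empty peak set")
    anchors = [iv for pair in loops for iv in pair]
    a_start = np.array([a.start for a in anchors])
    a_end = np.array([a.end for a in anchors])
    n_over = 0
    for p in peaks:
        s, e = p.start - slack_bp, p.end + slack_bp
        if np.any((a_start < e) & (s < a_end)):
            n_over += 1
    return {
        "fraction": n_over / len(peaks),
        "n_overlap": n_over,
        "n_total": len(peaks),
    }


def scaled_domain_profile(
    signal: np.ndarray,
    tads: list[GenomicInterval],
    bin_size: int,
    n_meta_bins: int = 100,
    flank_bp: int = 20_000,
) -> tuple[np.ndarray, int]:
    """Average a per-bin signal along TADs rescaled to a common length.

    Each TAD's internal signal is linearly interpolated onto ``n_meta_bins``
    positions; fixed-width flanks (``flank_bp`` each side) are appended
    unscaled. Returns ``(profile, n_skipped)`` where the profile has
    ``flank + n_meta_bins + flank`` entries and ``n_skipped`` counts TADs
    shorter than 2 bins (skipped with a warning). Out-of-range flank bins are
    ignored via NaN-mean.
    """
    if flank_bp % bin_size != 0:
        raise ValueError(f"flank_bp={flank_bp} must be a multiple of bin_size={bin_size}")
    sig = np.asarray(signal, dtype=float)
    f = flank_bp // bin_size
    width = f + n_meta_bins + f
    rows = []
    n_skipped = 0
    for tad in tads:
        sb, eb = tad.start // bin_size, tad.end // bin_size
        nb = eb - sb
        if nb < 2:
            n_skipped += 1
            continue
        row = np.full(width, np.nan)
        inner = sig[sb:eb]
        row[f : f + n_meta_bins] = np.interp(
            np.linspace(0, nb - 1, n_meta_bins), np.arange(nb), inner
        )
        for k in range(f):
            left = sb - f + k
            if 0 <= left < len(sig):
                row[k] = sig[left]
            right = eb + k
            if 0 <= right < len(sig):
                row[f + n_meta_bins + k] = sig[right]
        rows.append(row)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} TADs shorter than 2 bins")
    if not rows:
        raise ValueError("no TAD long enough for a scaled profile")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN flank columns
        profile = np.nanmean(np.vstack(rows), axis=0)
    return profile, n_skipped
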