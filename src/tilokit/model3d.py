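"""Chrom3D-compatible gtrack export, a lightweight bead embedder, and
group-distance statistics.

The gtrack dialect written (and strictly re-parsed) here is:

.. code-block:: text

    ##gtrack version: 1.0
    ###seqid	start	end	id	radius	periphery	edges
    chrS	0	250000	chrS:0-250000	0.42	0	chrS:250000-500000=1.0;...

* one record per TAD ("1 TAD = 1 bead"), tab-separated;
* ``periphery`` is 1 when the bead overlaps a lamina-associated domain;
* ``edges`` lists interaction partners as ``id=weight`` joined by ``;``,
  or ``.`` when the bead has none; every edge must be symmetric;
* optional extra columns (e.g. ``peaks``) are declared in the ``###`` header.

Beads of the same cluster are pairwise edge-connected, so the embedder pulls
each cluster together inside a spherical nucleus. The embedder itself is a
deliberately simple Metropolis annealer (Chrom3D's full likelihood —
inter-chromosomal contacts, LAD statistics — is out of scope; the exported
gtrack keeps interoperability with the real tool). Default embedding
parameters: 200,000 iterations, nuclear radius 5 model units, total bead
volume 0.15 of the nucleus volume.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm, rankdata

from .hicio import GenomicInterval

__all__ = [
    "GTrackRecord",
    "BeadModel",
    "GroupDistanceReport",
    "bead_radii",
    "write_gtrack",
    "read_gtrack",
    "embed",
    "group_distances",
    "mann_whitney_u",
]

GTRACK_VERSION_LINE = "##gtrack version: 1.0"
GTRACK_CORE_COLUMNS = ("seqid", "start", "end", "id", "radius", "periphery", "edges")


@dataclass
class GTrackRecord:
    seqid: str
    start: int
    end: int
    rid: str
    radius: float
    periphery: bool = False
    edges: dict[str, float] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gtrack record {self.rid}: start {self.start} >= end {self.end}")
        if self.radius <= 0:
            raise ValueError(f"gtrack record {self.rid}: radius must be positive")


@dataclass
class BeadModel:
    coords: np.ndarray          # (n, 3) bead centers, model units
    radii: np.ndarray
    nucleus_radius: float
    chain_breaks: list[int]     # indices where a new chromosome chain starts
    seed: int
    iterations: int
    energy_initial: float
    energy_final: float

    @property
    def n_beads(self) -> int:
        return len(self.radii)


def bead_radii(lengths_bp: np.ndarray, nucleus_radius: float, vol_frac: float) -> np.ndarray:
    """Radii proportional to (TAD length)^(1/3), scaled so the summed bead
    volume is ``vol_frac`` of the nucleus volume."""
    lengths = np.asarray(lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("TAD lengths must be positive")
    r = lengths ** (1.0 / 3.0)
    scale = (vol_frac * nucleus_radius**3 / (r**3).sum()) ** (1.0 / 3.0)
    return r * scale


# ---------------------------------------------------------------------------
# gtrack I/O
# ---------------------------------------------------------------------------

def _interval_overlaps(iv: GenomicInterval, others: list[GenomicInterval]) -> bool:
    return any(o.chrom == iv.chrom and o.start < iv.end and iv.start < o.end for o in others)


def write_gtrack(
    path: str | Path,
    tads: list[GenomicInterval],
    cluster_labels: np.ndarray | list[int],
    lads: list[GenomicInterval] | None = None,
    peaks: list[GenomicInterval] | None = None,
    diploid: bool = False,
    nucleus_radius: float = 5.0,
    vol_frac: float = 0.15,
    edge_weight: float = 1.0,
) -> list[GTrackRecord]:
    """Write one bead per TAD with intra-cluster interaction edges.

    TADs must not overlap. Gaps between consecutive TADs simply carry no
    bead: the Chrom3D convention of filling gaps with single-base beads and
    then removing them reduces, for edge construction, to ignoring the gaps,
    which is what is done here. ``diploid=True`` duplicates every record with
    ``_A``/``_B`` haplotype suffixes (edges stay within a haplotype).
    """
    tads = sorted(tads, key=lambda t: (t.chrom, t.start))
    for a, b in zip(tads, tads[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping TADs: {a.chrom}:{a.start}-{a.end} and {b.start}-{b.end}")
    labels = np.asarray(cluster_labels, dtype=int)
    if len(labels) != len(tads):
        raise ValueError("cluster_labels length must equal TAD count")
    lads = lads or []
    lengths = np.array([len(t) for t in tads], dtype=float)
    radii = bead_radii(lengths, nucleus_radius, vol_frac)

    peak_counts = None
    if peaks is not None:
        from .annotate import count_peaks_per_tad

        peak_counts = count_peaks_per_tad(peaks, tads).counts

    records: list[GTrackRecord] = []
    ids = [f"{t.chrom}:{t.start}-{t.end}" for t in tads]
    for k, t in enumerate(tads):
        edges = {
            ids[j]: edge_weight
            for j in range(len(tads))
            if j != k and labels[j] == labels[k] and tads[j].chrom == t.chrom
        }
        extras = {}
        if peak_counts is not None:
            extras["peaks"] = str(int(peak_counts[k]))
        records.append(
            GTrackRecord(
                seqid=t.chrom, start=t.start, end=t.end, rid=ids[k],
                radius=float(radii[k]), periphery=_interval_overlaps(t, lads),
                edges=edges, extras=extras,
            )
        )
    if diploid:
        dip = []
        for hap in ("A", "B"):
            for r in records:
                dip.append(
                    GTrackRecord(
                        seqid=f"{r.seqid}_{hap}", start=r.start, end=r.end,
                        rid=f"{r.rid}_{hap}", radius=r.radius, periphery=r.periphery,
                        edges={f"{pid}_{hap}": w for pid, w in r.edges.items()},
                        extras=dict(r.extras),
                    )
                )
        records = dip

    extra_cols = sorted({c for r in records for c in r.extras})
    cols = list(GTRACK_CORE_COLUMNS) + extra_cols
    lines = [GTRACK_VERSION_LINE, "###" + "\t".join(cols)]
    for r in records:
        edge_str = ";".join(f"{pid}={w:g}" for pid, w in sorted(r.edges.items())) or "."
        row = [r.seqid, str(r.start), str(r.end), r.rid, f"{r.radius:.6g}",
               "1" if r.periphery else "0", edge_str]
        row += [r.extras.get(c, ".") for c in extra_cols]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
    return records


def read_gtrack(path: str | Path) -> list[GTrackRecord]:
    """Strict parser for the dialect documented in this module.

    Validates the header lines, column declaration, unique ids, positive
    radii, start < end, and that every edge references an existing id with a
    symmetric counterpart of equal weight.
    """
    lines = Path(path).read_text().rstrip("\n").split("\n")
    if not lines or lines[0].strip() != GTRACK_VERSION_LINE:
        raise ValueError(f"missing or malformed version line; expected {GTRACK_VERSION_LINE!r}")
    if len(lines) < 2 or not lines[1].startswith("###"):
        raise ValueError("missing '###' column-declaration line")
    cols = lines[1][3:].split("\t")
    if tuple(cols[:7]) != GTRACK_CORE_COLUMNS:
        raise ValueError(f"first seven columns must be {GTRACK_CORE_COLUMNS}, got {tuple(cols[:7])}")
    extra_cols = cols[7:]
    records = []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != len(cols):
            raise ValueError(f"line {ln}: expected {len(cols)} columns, got {len(f)}")
        edges = {}
        if f[6] != ".":
            for part in f[6].split(";"):
                pid, _, w = part.partition("=")
                if not _:
                    raise ValueError(f"line {ln}: malformed edge {part!r}")
                edges[pid] = float(w)
        records.append(
            GTrackRecord(
                seqid=f[0], start=int(f[1]), end=int(f[2]), rid=f[3],
                radius=float(f[4]), periphery={"0": False, "1": True}[f[5]],
                edges=edges, extras=dict(zip(extra_cols, f[7:])),
            )
        )
    ids = [r.rid for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate bead id {dup!r}")
    by_id = {r.rid: r for r in records}
    for r in records:
        for pid, w in r.edges.items():
            if pid not in by_id:
                raise ValueError(f"edge from {r.rid} references unknown id {pid!r}")
            back = by_id[pid].edges.get(r.rid)
            if back is None or not math.isclose(back, w, rel_tol=1e-9):
                raise ValueError(f"asymmetric edge {r.rid} <-> {pid}")
    return records


# ---------------------------------------------------------------------------
# Monte-Carlo embedding
# ---------------------------------------------------------------------------

def embed(
    records: list[GTrackRecord],
    iterations: int = 200_000,
    nucleus_radius: float = 5.0,
    vol_frac: float = 0.15,
    seed: int = 0,
    w_chain: float = 1.0,
    w_int: float = 1.0,
    w_lad: float = 0.5,
    w_excl: float = 20.0,
    t_start: float = 1.0,
    t_end: float = 1e-3,
) -> BeadModel:
    """Metropolis simulated annealing of a bead-on-a-string chromosome model.

    Energy terms: squared stretch of consecutive chain beads beyond contact,
    squared distance of interaction-pair beads, squared distance of periphery
    (LAD) beads from the nuclear envelope, and a soft excluded-volume
    penalty. The nucleus is a hard wall: proposals placing a bead outside
    ``|x| + r <= R`` are rejected outright, so the returned configuration
    always satisfies the constraint. The best configuration ever visited is
    returned; its energy never exceeds the initial one.
    """
    if vol_frac > 0.5:
        raise ValueError(f"vol_frac={vol_frac} is infeasible (> 0.5)")
    n = len(records)
    if n == 0:
        raise ValueError("no beads to embed")
    R = float(nucleus_radius)
    radii = np.array([r.radius for r in records])
    # rescale radii to the requested volume fraction of this nucleus
    radii *= (vol_frac * R**3 / (radii**3).sum()) ** (1.0 / 3.0)
    periphery = np.array([r.periphery for r in records], dtype=bool)
    id_index = {r.rid: k for k, r in enumerate(records)}
    pairs = sorted(
        {(min(id_index[r.rid], id_index[p]), max(id_index[r.rid], id_index[p]))
         for r in records for p in r.edges}
    )
    partners = [[] for _ in range(n)]
    for a, b in pairs:
        partners[a].append(b)
        partners[b].append(a)
    partners = [np.array(p, dtype=int) for p in partners]

    chain_breaks = [0] + [k for k in range(1, n) if records[k].seqid != records[k - 1].seqid]
    chain_prev = np.full(n, -1, dtype=int)
    for k in range(1, n):
        if records[k].seqid == records[k - 1].seqid:
            chain_prev[k] = k - 1

    rng = np.random.default_rng(seed)
    # initial chain: a bounded random walk from a random interior point
    coords = np.zeros((n, 3))
    lim = max(1e-3, 0.6 * (R - radii.max()))
    for k in range(n):
        if chain_prev[k] < 0:
            coords[k] = rng.uniform(-lim / 2, lim / 2, 3)
        else:
            step = rng.standard_normal(3)
            step *= (radii[k] + radii[chain_prev[k]]) / np.linalg.norm(step)
            cand = coords[chain_prev[k]] + step
            coords[k] = np.clip(cand, -lim, lim)
        # project into the nucleus if the walk drifted out
        norm_k = np.linalg.norm(coords[k])
        if norm_k + radii[k] > R:
            coords[k] *= (R - radii[k]) * 0.95 / norm_k

    def bead_energy(k: int, x: np.ndarray, pos: np.ndarray) -> float:
        e = 0.0
        for nb in (chain_prev[k], k + 1 if k + 1 < n and chain_prev[k + 1] == k else -1):
            if nb >= 0:
                d = np.linalg.norm(x - pos[nb])
                stretch = d - (radii[k] + radii[nb])
                if stretch > 0:
                    e += w_chain * stretch**2
        if len(partners[k]):
            dd = np.linalg.norm(pos[partners[k]] - x, axis=1)
            e += w_int * float((dd**2).sum())
        if periphery[k]:
            e += w_lad * (R - np.linalg.norm(x)) ** 2
        d_all = np.linalg.norm(pos - x, axis=1)
        d_all[k] = np.inf
        overlap = (radii[k] + radii) - d_all
        ov = overlap[overlap > 0]
        if len(ov):
            e += w_excl * float((ov**2).sum())
        return e

    def total_energy(pos: np.ndarray) -> float:
        e = 0.0
        for k in range(n):
            if chain_prev[k] >= 0:
                d = np.linalg.norm(pos[k] - pos[chain_prev[k]])
                stretch = d - (radii[k] + radii[chain_prev[k]])
                if stretch > 0:
                    e += w_chain * stretch**2
        for a, b in pairs:
            e += w_int * float(((pos[a] - pos[b]) ** 2).sum())
        for k in np.flatnonzero(periphery):
            e += w_lad * (R - np.linalg.norm(pos[k])) ** 2
        for a in range(n):
            for b in range(a + 1, n):
                ov = (radii[a] + radii[b]) - np.linalg.norm(pos[a] - pos[b])
                if ov > 0:
                    e += w_excl * ov**2
        return e

    e_init = total_energy(coords)
    e_curr = e_init
    best = coords.copy()
    e_best = e_curr

    beads = rng.integers(0, n, size=iterations)
    disp = rng.standard_normal((iterations, 3))
    us = rng.random(iterations)
    temps = t_start * (t_end / t_start) ** (np.arange(iterations) / max(1, iterations - 1))
    for it in range(iterations):
        k = int(beads[it])
        T = temps[it]
        sigma = 0.1 + 0.4 * T
        x_new = coords[k] + sigma * disp[it]
        if np.linalg.norm(x_new) + radii[k] > R:
            continue  # hard nuclear wall
        e_old = bead_energy(k, coords[k], coords)
        e_new = bead_energy(k, x_new, coords)
        de = e_new - e_old
        if de <= 0 or us[it] < math.exp(-de / T):
            coords[k] = x_new
            e_curr += de
            if e_curr < e_best:
                e_best = e_curr
                best = coords.copy()
    e_final = total_energy(best)  # recompute: incremental sums drift in float
    return BeadModel(
        coords=best, radii=radii, nucleus_radius=R, chain_breaks=chain_breaks,
        seed=seed, iterations=iterations,
        energy_initial=float(e_init), energy_final=float(e_final),
    )


# ---------------------------------------------------------------------------
# group distances and the rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceReport:
    label: str                   # e.g. "high-high vs high-other"
    within: np.ndarray           # pairwise distances, first sample
    between: np.ndarray          # pairwise distances, second sample
    u_statistic: float
    p_value: float
    n_within: int
    n_between: int


def _pair_distances(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray | None) -> np.ndarray:
    if idx_b is None:
        pts = coords[idx_a]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        iu = np.triu_indices(len(idx_a), k=1)
        return d[iu]
    d = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=2)
    return d.ravel()


def group_distances(
    model: BeadModel | np.ndarray, groups: list | np.ndarray
) -> list[GroupDistanceReport]:
    """Within- vs between-group 3D center distances, with rank-sum tests.

    For every group with >= 2 beads, compares its within-group pairwise
    distances against the distances from its beads to all other beads
    (groups with fewer than 2 beads are skipped with a warning).
    """
    coords = model.coords if isinstance(model, BeadModel) else np.asarray(model, float)
    groups = np.asarray(groups)
    reports = []
    for g in pd_unique(groups):
        idx = np.flatnonzero(groups == g)
        rest = np.flatnonzero(groups != g)
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 beads; skipped")
            continue
        within = _pair_distances(coords, idx, None)
        if len(rest) == 0:
            continue
        between = _pair_distances(coords, idx, rest)
        u, p = mann_whitney_u(within, between)
        reports.append(
            GroupDistanceReport(
                label=f"{g}-{g} vs {g}-other", within=within, between=between,
                u_statistic=u, p_value=p, n_within=len(within), n_between=len(between),
            )
        )
    return reports


def pd_unique(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for v in values.tolist():
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test, two-sided.

    U is computed from midrank sums (ties allowed). The p-value comes from
    exact enumeration of all group assignments when ``n_x + n_y <= 12``, and
    otherwise from the normal approximation with tie-corrected variance and
    a 0.5 continuity correction. ``method`` may force ``"exact"`` or
    ``"normal"``.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0

    if method == "exact" or (method == "auto" and nx + ny <= 12):
        stat_obs = abs(u - mu)
        hits = total = 0
        idx_all = range(nx + ny)
        for comb in itertools.combinations(idx_all, nx):
            r = sum(ranks[list(comb)])
            u_perm = r - nx * (nx + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= stat_obs - 1e-12:
                hits += 1
        return u, hits / total

    nn = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (nn * (nn - 1)))
    var = nx * ny / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * norm.sf(z))
    return u, p
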