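import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from tilokit import model3d, synthio
from tilokit.hicio import GenomicInterval
from tilokit.model3d import (
    bead_radii,
    embed,
    group_distances,
    mann_whitney_u,
    read_gtrack,
    write_gtrack,
)


@pytest.fixture(scope="module")
def tads12():
    return [GenomicInterval("chrS", k * 250_000, (k + 1) * 250_000) for k in range(12)]


@pytest.fixture(scope="module")
def two_cluster_gtrack(tmp_path_factory, tads12):
    path = tmp_path_factory.mktemp("gt") / "m.gtrack"
    labels = [0, 1] * 6  # interleaved clusters
    write_gtrack(path, tads12, labels)
    return read_gtrack(path)


class TestGtrack:
    def test_three_tads_one_cluster(self, tmp_path):
        tads = [GenomicInterval("chr1", k * 1000, (k + 1) * 1000) for k in range(3)]
        recs = write_gtrack(tmp_path / "x.gtrack", tads, [0, 0, 0])
        assert len(recs) == 3
        assert sum(len(r.edges) for r in recs) == 6  # 3 pairs, both directions

    def test_round_trip_field_for_field(self, tmp_path, tads12):
        lads = [GenomicInterval("chrS", 0, 600_000)]
        peaks = [GenomicInterval("chrS", 100_000 + k * 10, 100_200 + k * 10) for k in range(5)]
        path = tmp_path / "m.gtrack"
        out = write_gtrack(path, tads12, [0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 1, 2],
                           lads=lads, peaks=peaks)
        back = read_gtrack(path)
        assert len(back) == len(out)
        for a, b in zip(out, back):
            assert (a.seqid, a.start, a.end, a.rid) == (b.seqid, b.start, b.end, b.rid)
            assert a.radius == pytest.approx(b.radius, rel=1e-5)
            assert a.periphery == b.periphery
            assert set(a.edges) == set(b.edges)
            assert a.extras == b.extras

    def test_no_lads_no_periphery_flags(self, two_cluster_gtrack):
        assert not any(r.periphery for r in two_cluster_gtrack)

    def test_lad_overlap_sets_periphery(self, tmp_path, tads12):
        lads = [GenomicInterval("chrS", 0, 300_000)]
        recs = write_gtrack(tmp_path / "m.gtrack", tads12, [0] * 12, lads=lads)
        assert recs[0].periphery and recs[1].periphery and not recs[2].periphery

    def test_overlapping_tads_rejected(self, tmp_path):
        tads = [GenomicInterval("chr1", 0, 2000), GenomicInterval("chr1", 1000, 3000)]
        with pytest.raises(ValueError, match="overlap"):
            write_gtrack(tmp_path / "x.gtrack", tads, [0, 0])

    def test_diploid_duplicates_with_suffixes(self, tmp_path, tads12):
        recs = write_gtrack(tmp_path / "d.gtrack", tads12, [0] * 12, diploid=True)
        assert len(recs) == 24
        assert {r.rid[-2:] for r in recs} == {"_A", "_B"}
        back = read_gtrack(tmp_path / "d.gtrack")  # still passes the strict parser
        assert len(back) == 24

    @pytest.mark.parametrize(
        "mutation,msg",
        [
            (lambda t: t.replace("##gtrack version: 1.0", "#gtrack"), "version"),
            (lambda t: t.replace("###seqid", "###chrom"), "columns"),
            (lambda t: t + t.splitlines()[2] + "\n", "duplicate"),
        ],
    )
    def test_strict_parser_rejects_corruption(self, tmp_path, tads12, mutation, msg):
        path = tmp_path / "m.gtrack"
        write_gtrack(path, tads12, [0] * 12)
        path.write_text(mutation(path.read_text()))
        with pytest.raises(ValueError, match=msg):
            read_gtrack(path)

    def test_bead_volume_sums_to_vol_frac(self, tads12):
        r = bead_radii(np.array([len(t) for t in tads12]), nucleus_radius=5.0, vol_frac=0.15)
        assert (r**3).sum() == pytest.approx(0.15 * 5.0**3)


class TestEmbed:
    def test_single_bead_inside_nucleus_zero_energy(self, tmp_path):
        tads = [GenomicInterval("chr1", 0, 1000)]
        recs = write_gtrack(tmp_path / "x.gtrack", tads, [0])
        m = embed(recs, iterations=1000, seed=0)
        assert np.linalg.norm(m.coords[0]) + m.radii[0] <= m.nucleus_radius + 1e-9
        assert m.energy_final == 0.0

    def test_infeasible_volume_fraction_rejected(self, two_cluster_gtrack):
        with pytest.raises(ValueError, match="infeasible"):
            embed(two_cluster_gtrack, vol_frac=0.6)

    def test_deterministic_given_seed(self, two_cluster_gtrack):
        a = embed(two_cluster_gtrack, iterations=5000, seed=4)
        b = embed(two_cluster_gtrack, iterations=5000, seed=4)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_energy_decreases_and_constraints_hold(self, two_cluster_gtrack):
        m = embed(two_cluster_gtrack, iterations=20_000, seed=1)
        assert m.energy_final < m.energy_initial
        assert np.all(np.linalg.norm(m.coords, axis=1) + m.radii <= m.nucleus_radius + 1e-9)

    def test_two_clusters_separate_in_space(self, two_cluster_gtrack):
        hits = 0
        for s in range(3):
            m = embed(two_cluster_gtrack, iterations=30_000, seed=s)
            labels = np.array([0, 1] * 6)
            d_within, d_between = [], []
            for a, b in itertools.combinations(range(12), 2):
                d = np.linalg.norm(m.coords[a] - m.coords[b])
                (d_within if labels[a] == labels[b] else d_between).append(d)
            hits += np.mean(d_within) < np.mean(d_between)
        assert hits >= 2


class TestGroupDistances:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        coords = rng.random((30, 3))
        groups = ["a", "b"] * 15  # random split, no structure
        reps = group_distances(coords, groups)
        assert all(r.p_value > 0.01 for r in reps)

    def test_small_group_skipped_with_warning(self):
        coords = np.random.default_rng(1).random((5, 3))
        with pytest.warns(UserWarning, match="fewer than 2"):
            reps = group_distances(coords, ["a", "a", "a", "a", "b"])
        assert [r.label for r in reps] == ["a-a vs a-other"]

    def test_distances_positive(self, two_cluster_gtrack):
        m = embed(two_cluster_gtrack, iterations=10_000, seed=2)
        reps = group_distances(m, ["x", "y"] * 6)
        for r in reps:
            assert np.all(r.within > 0) and np.all(r.between > 0)


class TestMannWhitneyU:
    def test_extreme_separation_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # two-sided; one-sided would be 1/20

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_symmetry_u_and_p(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(8), rng.random(5)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))
        assert px == pytest.approx(py)

    def test_exact_agrees_with_scipy_all_small_sizes(self):
        rng = np.random.default_rng(8)
        for nx in range(1, 7):
            for ny in range(1, 7):
                if nx + ny > 12:
                    continue
                x = rng.normal(size=nx)
                y = rng.normal(size=ny)
                u, p = mann_whitney_u(x, y)
                ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_6_plus_6(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(0.5, 1.0, size=6)
            _, p_exact = mann_whitney_u(x, y, method="exact")
            _, p_norm = mann_whitney_u(x, y, method="normal")
            assert abs(p_exact - p_norm) < 0.05

    def test_ties_normal_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(10)
        x = np.round(rng.normal(size=20), 1)
        y = np.round(rng.normal(0.3, 1.0, size=15), 1)
        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])
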