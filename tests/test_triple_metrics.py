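import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from multiport.triple_metrics import (
    InsufficientTrajectoriesError,
    RegionLabeling,
    azimuthal_sector_labeling,
    cumulative_angle,
    make_triple,
    merge_length,
    pairwise_angle,
    score_triple,
    select_best_triple,
    summarize_by_region,
)

from conftest import icosphere_mesh, make_traj


def triple_from_directions(dirs, clearances=(1.0, 1.0, 1.0), length=20.0):
    trajs = [
        make_traj(np.asarray(d) / np.linalg.norm(d) * length, clearance=c)
        for d, c in zip(dirs, clearances)
    ]
    return make_triple(*trajs)


class TestPairwiseAngle:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_known_angles(self, d1, d2, expected):
        t1 = make_traj(np.array(d1, float) * 10)
        t2 = make_traj(np.array(d2, float) * 10)
        assert pairwise_angle(t1, t2) == pytest.approx(expected, abs=1e-9)

    def test_different_targets_rejected(self):
        t1 = make_traj((10, 0, 0), target=(0, 0, 0))
        t2 = make_traj((10, 0, 0), target=(0, 0, 1))
        with pytest.raises(ValueError):
            pairwise_angle(t1, t2)


class TestCumulativeAngle:
    def test_orthogonal_triple_is_270(self):
        triple = triple_from_directions([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert cumulative_angle(triple) == pytest.approx(270.0, abs=1e-9)

    def test_identical_triple_is_zero(self):
        triple = triple_from_directions([(1, 0, 0)] * 3)
        assert cumulative_angle(triple) == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_recomputation(self, rng):
        for _ in range(20):
            dirs = rng.normal(size=(3, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            triple = triple_from_directions(dirs)
            expected = sum(
                np.degrees(
                    np.arccos(np.clip(np.dot(dirs[i], dirs[j]), -1, 1))
                )
                for i, j in ((0, 1), (0, 2), (1, 2))
            )
            assert cumulative_angle(triple) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_shared_rotation(self, rng):
        for seed in range(100):
            gen = np.random.default_rng(seed)
            dirs = gen.normal(size=(3, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            rot = Rotation.random(rng=gen).as_matrix()
            ca0 = cumulative_angle(triple_from_directions(dirs))
            ca1 = cumulative_angle(triple_from_directions(dirs @ rot.T))
            assert abs(ca0 - ca1) <= 1e-9

    def test_bounded_by_540(self, rng):
        for _ in range(50):
            dirs = rng.normal(size=(3, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            assert cumulative_angle(triple_from_directions(dirs)) <= 540.0


class TestMergeLength:
    def traj_pair(self, alpha_deg):
        a = np.radians(alpha_deg)
        return (
            make_traj((20.0, 0, 0)),
            make_traj((20 * np.cos(a), 20 * np.sin(a), 0)),
        )

    def test_sixty_degrees_unit_radii(self):
        t1, t2 = self.traj_pair(60.0)
        assert merge_length(t1, t2, 1.0, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_antipodal_limit(self):
        t1, t2 = self.traj_pair(180.0)
        assert merge_length(t1, t2, 1.0, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_radii(self):
        t1, t2 = self.traj_pair(47.0)
        assert merge_length(t1, t2, 2.0, 2.0) == pytest.approx(
            2 * merge_length(t1, t2, 1.0, 1.0), abs=1e-12
        )

    def test_parallel_gives_infinite_overlap_flag(self):
        t1, t2 = self.traj_pair(0.0)
        assert np.isinf(merge_length(t1, t2, 1.0, 1.0))

    def test_antitone_in_angle(self):
        alphas = np.linspace(5, 180, 30)
        lengths = [
            merge_length(*self.traj_pair(a), 1.0, 1.0) for a in alphas
        ]
        assert np.all(np.diff(lengths) < 0)

    def test_matches_numeric_overlap_search(self, rng):
        # oracle: bisection for the largest depth x at which the axis points
        # are closer than r1 + r2 (their separation is 2 x sin(alpha/2))
        for _ in range(20):
            alpha = rng.uniform(5.0, 179.0)
            r1, r2 = rng.uniform(0.3, 2.0, 2)
            t1, t2 = self.traj_pair(alpha)
            lo, hi = 0.0, 1e6
            s = np.sin(np.radians(alpha) / 2)
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if 2 * mid * s < r1 + r2:
                    lo = mid
                else:
                    hi = mid
            assert merge_length(t1, t2, r1, r2) == pytest.approx(lo, abs=1e-4)


class TestScoreTriple:
    def test_monotone_in_min_clearance(self):
        dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        lo = triple_from_directions(dirs, clearances=(1.0, 2.0, 3.0))
        hi = triple_from_directions(dirs, clearances=(2.0, 2.0, 3.0))
        scale = 3.0
        assert score_triple(hi, clearance_scale=scale) > score_triple(
            lo, clearance_scale=scale
        )

    def test_monotone_in_cumulative_angle(self):
        small = triple_from_directions([(1, 0, 0), (1, 0.1, 0), (1, 0, 0.1)])
        large = triple_from_directions([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert score_triple(large, clearance_scale=1.0) > score_triple(
            small, clearance_scale=1.0
        )

    def test_zero_angle_weight_ranks_by_clearance(self, rng):
        triples = []
        for _ in range(10):
            dirs = rng.normal(size=(3, 3))
            cls = tuple(rng.uniform(0.5, 4.0, 3))
            triples.append(triple_from_directions(dirs, clearances=cls))
        scores = [
            score_triple(t, w_clearance=1.0, w_angle=0.0, clearance_scale=4.0)
            for t in triples
        ]
        mins = [min(tt.clearance for tt in t.trajectories) for t in triples]
        assert np.argsort(scores).tolist() == np.argsort(mins).tolist()

    def test_invalid_weights_rejected(self):
        triple = triple_from_directions([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        with pytest.raises(ValueError):
            score_triple(triple, w_clearance=0.0, w_angle=0.0)


class TestSelectBestTriple:
    def brute_force(self, cfts, w_clearance=1.0, w_angle=1.0):
        """Independent exhaustive reference: recompute angles and scores
        from the raw directions."""
        scale = max(t.clearance for t in cfts)
        best, best_key = None, None
        for combo in itertools.combinations(cfts, 3):
            ca = sum(
                np.degrees(
                    np.arccos(
                        np.clip(np.dot(a.direction, b.direction), -1, 1)
                    )
                )
                for a, b in itertools.combinations(combo, 2)
            )
            score = w_clearance * min(t.clearance for t in combo) / scale + (
                w_angle * ca / 540.0
            )
            entry_key = sorted(tuple(t.entry) for t in combo)
            key = (-score, -ca, entry_key)
            if best_key is None or key < best_key:
                best, best_key = combo, key
        return best, best_key

    def random_cfts(self, rng, n):
        out = []
        for _ in range(n):
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d) * rng.uniform(15, 30)
            d[2] = abs(d[2])
            out.append(make_traj(d, clearance=rng.uniform(0.5, 5.0)))
        return out

    def test_exactly_three_returns_unique_triple(self, rng):
        cfts = self.random_cfts(rng, 3)
        triple = select_best_triple(cfts)
        assert set(map(id, triple.trajectories)) == set(map(id, cfts))

    def test_fewer_than_three_rejected(self, rng):
        with pytest.raises(InsufficientTrajectoriesError):
            select_best_triple(self.random_cfts(rng, 2))

    @pytest.mark.parametrize("n", [6, 10, 12])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        cfts = self.random_cfts(rng, n)
        triple = select_best_triple(cfts, m_cap=None)
        _, key = self.brute_force(cfts)
        assert -triple.score == pytest.approx(key[0], abs=1e-12)
        assert -triple.cumulative_angle == pytest.approx(key[1], abs=1e-12)
        got_entries = sorted(tuple(t.entry) for t in triple.trajectories)
        assert np.allclose(got_entries, key[2])

    def test_invariant_to_input_order(self, rng):
        cfts = self.random_cfts(rng, 8)
        t0 = select_best_triple(cfts)
        perm = list(np.random.default_rng(0).permutation(len(cfts)))
        t1 = select_best_triple([cfts[i] for i in perm])
        assert np.allclose(
            sorted(tuple(t.entry) for t in t0.trajectories),
            sorted(tuple(t.entry) for t in t1.trajectories),
        )
        assert t0.score == pytest.approx(t1.score, abs=1e-12)

    def test_cap_restricts_to_highest_clearance(self, rng):
        cfts = self.random_cfts(rng, 30)
        triple = select_best_triple(cfts, m_cap=5)
        top5 = sorted(cfts, key=lambda t: -t.clearance)[:5]
        allowed = {id(t) for t in top5}
        assert all(id(t) in allowed for t in triple.trajectories)


class TestSummarizeByRegion:
    def make_scene(self, diameters, region_count=1):
        skull = icosphere_mesh(radius=30.0, name="bone")
        names = [f"R{i}" for i in range(region_count)]
        labeling = azimuthal_sector_labeling(skull, names)
        centroids = skull.triangle_centroids()
        trajs = []
        for i, d in enumerate(diameters):
            trajs.append(
                make_traj(centroids[i * 7], clearance=d / 2, max_diameter=d)
            )
        return trajs, skull, labeling

    def test_quartiles_type7_no_outliers(self):
        trajs, skull, labeling = self.make_scene([1, 2, 3, 4, 5])
        df = summarize_by_region(trajs, skull, labeling)
        row = df[df.region == "all"].iloc[0]
        assert (row["median"], row.q1, row.q3) == (3.0, 2.0, 4.0)
        assert row.n_outliers == 0

    def test_degenerate_iqr_flags_outlier(self):
        trajs, skull, labeling = self.make_scene([1, 1, 1, 1, 10])
        df = summarize_by_region(trajs, skull, labeling)
        row = df[df.region == "all"].iloc[0]
        assert row.q1 == row.q3 == 1.0
        assert row.n_outliers == 1
        assert row.outliers == "10"

    def test_percentages_split_between_regions(self):
        skull = icosphere_mesh(radius=30.0, name="bone")
        labeling = azimuthal_sector_labeling(skull, ["A", "B"])
        centroids = skull.triangle_centroids()
        in_a = np.flatnonzero(labeling.triangle_regions == 1)[:30]
        in_b = np.flatnonzero(labeling.triangle_regions == 2)[:30]
        trajs = [make_traj(centroids[i], clearance=1.0) for i in in_a] + [
            make_traj(centroids[i], clearance=1.0) for i in in_b
        ]
        df = summarize_by_region(trajs, skull, labeling)
        by = df.set_index("region")
        assert by.loc["A", "percent"] == pytest.approx(50.0)
        assert by.loc["B", "percent"] == pytest.approx(50.0)

    def test_empty_input_gives_empty_table(self):
        skull = icosphere_mesh(radius=30.0, name="bone")
        labeling = azimuthal_sector_labeling(skull, ["A"])
        df = summarize_by_region([], skull, labeling)
        assert df.empty

    def test_duplicate_region_names_rejected(self):
        with pytest.raises(ValueError):
            RegionLabeling(triangle_regions=np.array([1, 2]), names={1: "A", 2: "A"})
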