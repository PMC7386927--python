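"""IBS similarity, Ward clustering, threshold calibration, clonal groups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop import (
    MISSING,
    CalibrationError,
    ClonalAssignment,
    Dendrogram,
    SampleMeta,
    SimulationConfig,
    assign_clonal_groups,
    calibrate_threshold,
    cut_tree,
    dedupe_by_district,
    district_sharing_summary,
    ibs_similarity,
    simulate_collection,
    to_dissimilarity,
    varieties_per_farmer,
    ward_cluster,
)
from conftest import make_matrix


def brute_force_ward_heights(D):
    """Reference Lance-Williams ward.D heights, independent of the package.

    Plain-dict clusters, exhaustive minimum search, explicit update formula.
    Returns heights in merge order (sorted ascending by construction).
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    members = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    d = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}
    nxt = n
    heights = []
    while len(members) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        si, sj = size[i], size[j]
        newd = {}
        for k in members:
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            newd[k] = ((si + size[k]) * dik + (sj + size[k]) * djk - size[k] * h) / (
                si + sj + size[k]
            )
        for key in list(d):
            if i in key or j in key:
                del d[key]
        members[nxt] = members.pop(i) | members.pop(j)
        size[nxt] = si + sj
        for k, v in newd.items():
            d[tuple(sorted((nxt, k)))] = v
        nxt += 1
    return heights


def random_distance_matrix(rng, n):
    D = rng.uniform(0.05, 1.0, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestIbsSimilarity:
    def test_identical_vectors_similarity_one(self):
        G = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1]])
        S = ibs_similarity(G)
        assert S.values[0, 1] == 1.0

    def test_opposite_homozygotes_zero(self):
        G = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert ibs_similarity(G).values[0, 1] == 0.0

    def test_hand_worked_pair(self):
        # per-locus shared-allele fractions: 1, 0.5, 0, 1 -> mean 0.625
        G = make_matrix([[0, 1, 2, 1], [0, 2, 0, 1]])
        assert ibs_similarity(G).values[0, 1] == pytest.approx(0.625)

    def test_missing_sites_excluded_from_denominator(self):
        G = make_matrix([[0, 1, MISSING], [0, MISSING, 2]])
        S = ibs_similarity(G)
        assert S.values[0, 1] == 1.0  # only site 1 shared
        assert S.n_shared[0, 1] == 1

    def test_no_shared_sites_flagged_then_error_downstream(self):
        G = make_matrix([[0, MISSING], [MISSING, 2]])
        S = ibs_similarity(G)
        assert np.isnan(S.values[0, 1])
        with pytest.raises(ValueError, match="share no genotyped sites"):
            to_dissimilarity(S)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_bounds_symmetry_and_site_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dosages = rng.choice([0, 1, 2, MISSING], size=(5, 30), p=[0.3, 0.3, 0.3, 0.1])
        G = make_matrix(dosages)
        S = ibs_similarity(G)
        vals = S.values[np.isfinite(S.values)]
        assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()
        assert np.allclose(S.values, S.values.T, equal_nan=True)
        perm = rng.permutation(30)
        S2 = ibs_similarity(make_matrix(dosages[:, perm]))
        assert np.allclose(S.values, S2.values, equal_nan=True)


class TestToDissimilarity:
    def test_complement(self):
        G = make_matrix([[0, 1, 2, 1], [0, 2, 0, 1]])
        D = to_dissimilarity(ibs_similarity(G))
        assert D[0, 1] == pytest.approx(0.375)
        assert D[0, 0] == 0.0

    def test_rows_euclidean_mode_runs(self):
        rng = np.random.default_rng(0)
        G = make_matrix(rng.choice([0, 1, 2], size=(4, 50)))
        D = to_dissimilarity(ibs_similarity(G), mode="rows-euclidean")
        assert D.shape == (4, 4)
        assert np.allclose(D, D.T)
        assert (np.diag(D) == 0).all()


class TestWardCluster:
    def test_two_points_merge_at_their_distance(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        T = ward_cluster(D)
        assert T.heights.tolist() == [0.4]

    def test_three_equidistant_points(self):
        # Lance-Williams update: (2d + 2d - d)/3 = d, so both merges at d
        D = np.full((3, 3), 0.3)
        np.fill_diagonal(D, 0.0)
        T = ward_cluster(D)
        assert np.allclose(T.heights, [0.3, 0.3])

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_brute_force_reference(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            D = random_distance_matrix(rng, n)
            T = ward_cluster(D)
            assert np.allclose(
                sorted(T.heights), brute_force_ward_heights(D), atol=1e-10
            )

    def test_matches_scipy_on_sqrt_distances(self):
        # scipy's ward applies Lance-Williams to squared inputs and returns
        # square roots, so feeding sqrt(D) and squaring heights reproduces
        # ward.D on D: an independent route through another implementation.
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(123)
        D = random_distance_matrix(rng, 12)
        T = ward_cluster(D)
        Z = linkage(squareform(np.sqrt(D)), method="ward")
        assert np.allclose(sorted(T.heights), sorted(Z[:, 2] ** 2), atol=1e-9)

    def test_ward_d2_variant_matches_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        D = random_distance_matrix(rng, 9)
        T = ward_cluster(D, variant="ward.D2")
        Z = linkage(squareform(D), method="ward")
        assert np.allclose(sorted(T.heights), sorted(Z[:, 2]), atol=1e-9)

    def test_rejects_nonfinite(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            ward_cluster(D)

    def test_tie_break_is_deterministic(self):
        D = np.full((4, 4), 0.2)
        np.fill_diagonal(D, 0.0)
        T1 = ward_cluster(D)
        T2 = ward_cluster(D)
        assert np.array_equal(T1.merges, T2.merges)
        # first merge takes the lexicographically smallest pair
        assert tuple(T1.merges[0, :2]) == (0.0, 1.0)


class TestCutTree:
    @pytest.fixture
    def toy_tree(self):
        merges = np.array(
            [[0, 1, 0.02, 2], [2, 3, 0.03, 2], [4, 5, 0.5, 4]], dtype=float
        )
        return Dendrogram(merges, ["A", "B", "C", "D"])

    def test_cut_between_levels(self, toy_tree):
        assert cut_tree(toy_tree, 0.075).tolist() == [0, 0, 1, 1]

    def test_cut_zero_gives_singletons(self, toy_tree):
        assert cut_tree(toy_tree, 0.0).tolist() == [0, 1, 2, 3]

    def test_cut_at_root_gives_one_group(self, toy_tree):
        assert cut_tree(toy_tree, 0.5).tolist() == [0, 0, 0, 0]

    def test_group_count_non_increasing_in_height(self):
        rng = np.random.default_rng(7)
        D = random_distance_matrix(rng, 10)
        T = ward_cluster(D)
        counts = [
            len(set(cut_tree(T, h).tolist()))
            for h in np.linspace(0, T.root_height, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCalibration:
    @pytest.fixture
    def toy_tree(self):
        merges = np.array(
            [[0, 1, 0.02, 2], [2, 3, 0.03, 2], [4, 5, 0.5, 4]], dtype=float
        )
        return Dendrogram(merges, ["A", "B", "C", "D"])

    def test_interval_and_midpoint_on_toy_tree(self, toy_tree):
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        cal = calibrate_threshold(toy_tree, groups, rule="midpoint")
        assert cal.h_min == pytest.approx(0.03)
        assert cal.h_max == pytest.approx(0.5)
        assert cal.threshold == pytest.approx(0.265)

    def test_geometric_rule_stays_inside_interval(self, toy_tree):
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        cal = calibrate_threshold(toy_tree, groups)
        assert cal.h_min <= cal.threshold < cal.h_max
        assert cal.threshold == pytest.approx(np.sqrt(0.03 * 0.5))

    def test_identical_replicates_span_zero_to_root(self):
        D = np.zeros((3, 3))
        D[0, 2] = D[2, 0] = D[1, 2] = D[2, 1] = 0.4
        T = ward_cluster(D, leaf_ids=["r1", "r2", "x"])
        cal = calibrate_threshold(T, {"r1": "g", "r2": "g"})
        assert cal.h_min == 0.0
        assert cal.h_max == pytest.approx(T.root_height)

    def test_inseparable_replicates_raise(self):
        # replicate partners are farther apart than the cross-group gap
        D = np.array(
            [
                [0.0, 0.9, 0.1, 0.9],
                [0.9, 0.0, 0.9, 0.1],
                [0.1, 0.9, 0.0, 0.9],
                [0.9, 0.1, 0.9, 0.0],
            ]
        )
        T = ward_cluster(D, leaf_ids=["a1", "a2", "b1", "b2"])
        with pytest.raises(CalibrationError, match="not separable"):
            calibrate_threshold(T, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})

    def test_interval_matches_exhaustive_threshold_scan(self):
        """The interval contains exactly the thresholds whose cut reproduces
        the replicate partition, verified by scanning all merge heights."""
        rng = np.random.default_rng(21)
        # two tight replicate pairs plus background samples
        base = rng.uniform(0.3, 0.8, size=(8, 8))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.02
        D[2, 3] = D[3, 2] = 0.05
        ids = [f"s{i}" for i in range(8)]
        groups = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        T = ward_cluster(D, leaf_ids=ids)
        cal = calibrate_threshold(T, groups)

        probes = sorted(
            set(T.heights.tolist())
            | {h + 1e-9 for h in T.heights}
            | {h - 1e-9 for h in T.heights}
        )
        for h in probes:
            labels = cut_tree(T, h)
            lab = dict(zip(ids, labels))
            ok = (
                lab["s0"] == lab["s1"]
                and lab["s2"] == lab["s3"]
                and lab["s0"] != lab["s2"]
            )
            assert ok == (cal.h_min <= h < cal.h_max), h


class TestAssignment:
    def test_exact_duplicates_always_grouped(self):
        G = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        A = assign_clonal_groups(G, threshold=1e-6)
        assert A.labels["s0"] == A.labels["s1"] != A.labels["s2"]

    def test_group_labels_use_first_member_index(self):
        G = make_matrix([[0, 1, 2], [2, 1, 0], [0, 1, 2]])
        A = assign_clonal_groups(G, threshold=1e-6)
        assert A.labels["s0"] == "C_1"
        assert A.labels["s1"] == "C_2"
        assert A.labels["s2"] == "C_1"

    def test_simulation_recovery_perfect_ari(self):
        from sklearn.metrics import adjusted_rand_score

        config = SimulationConfig(n_sites=5000, error_rate=0.005, seed=2)
        G, truth = simulate_collection(config)
        rep = {
            s.sample_id: s.replicate_group
            for s in G.samples
            if s.replicate_group is not None
        }
        checks = G.subset_ids(sorted(rep))
        T = ward_cluster(
            to_dissimilarity(ibs_similarity(checks)), leaf_ids=checks.sample_ids
        )
        cal = calibrate_threshold(T, rep)
        A = assign_clonal_groups(G, cal.threshold)
        ari = adjusted_rand_score(
            truth.clone_labels(G.sample_ids), [A.labels[s] for s in G.sample_ids]
        )
        assert ari == 1.0


class TestDedupe:
    def _assignment(self):
        labels = {
            "a1": "C_1", "a2": "C_1", "b1": "C_1",
            "b2": "C_2", "c1": "C_3", "c2": "C_3",
        }
        samples = [
            SampleMeta("a1", district="X", farmer_id="f1"),
            SampleMeta("a2", district="X", farmer_id="f1"),
            SampleMeta("b1", district="Y", farmer_id="f2"),
            SampleMeta("b2", district="Y", farmer_id="f2"),
            SampleMeta("c1", district="X", farmer_id="f1"),
            SampleMeta("c2", district="X", farmer_id="f2"),
        ]
        return ClonalAssignment(dict(labels), 0.1), samples

    def test_one_representative_per_group_district_cell(self):
        A, samples = self._assignment()
        reps = dedupe_by_district(A, samples, seed=0)
        assert set(reps) == {
            ("C_1", "X"), ("C_1", "Y"), ("C_2", "Y"), ("C_3", "X")
        }
        assert reps[("C_1", "X")] in {"a1", "a2"}

    def test_same_seed_same_choice(self):
        A1, samples = self._assignment()
        A2, _ = self._assignment()
        assert dedupe_by_district(A1, samples, seed=9) == dedupe_by_district(
            A2, samples, seed=9
        )

    def test_missing_district_raises(self):
        A, samples = self._assignment()
        samples[0] = SampleMeta("a1")
        with pytest.raises(ValueError, match="a1"):
            dedupe_by_district(A, samples, seed=0)

    def test_sharing_summary_counts(self):
        labels = {}
        samples = []
        district_sets = {"g1": "ABCD", "g2": "A", "g3": "AB"}
        for g, dists in district_sets.items():
            for d in dists:
                sid = f"{g}{d}"
                labels[sid] = g
                samples.append(SampleMeta(sid, district=d))
        A = ClonalAssignment(labels, 0.1)
        summary = district_sharing_summary(A, samples).set_index("k_districts")
        assert summary.loc[4, "exactly_k"] == 1
        assert summary.loc[2, "at_least_k"] == 2
        assert summary.loc[1, "exactly_k"] == 1

    def test_mean_varieties_per_farmer(self):
        labels = {f"s{i}": f"C_{i}" for i in range(6)}
        samples = [
            SampleMeta(f"s{i}", district="X", farmer_id="f1" if i < 2 else "f2")
            for i in range(6)
        ]
        counts = varieties_per_farmer(ClonalAssignment(labels, 0.1), samples)
        assert counts["f1"] == 2
        assert counts["f2"] == 4
        assert counts.mean() == pytest.approx(3.0)
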