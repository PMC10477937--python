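import numpy as np
import pytest

from clustannot import (
    ClusterProfile,
    CountsWithLabels,
    FormatError,
    JointClustering,
    MarkerRole,
    Species,
    WeightMatrix,
    aggregate_and_normalize,
    build_reference,
    compute_weight_matrix,
    correct_reference_expression,
    marker_score,
    refine_subclusters,
    select_markers,
)


def make_jc(assignments):
    """assignments: list of (cell, cluster, source, celltype-or-None)."""
    return JointClustering(
        combined_cluster_of={c: cl for c, cl, _, _ in assignments},
        source_of={c: s for c, _, s, _ in assignments},
        ref_celltype_of={
            c: t for c, _, s, t in assignments if s == "reference"
        },
    )


class TestWeightMatrix:
    def test_hand_counted_fractions(self):
        assignments = [
            (f"r{i}", "A" if i < 7 else "B", "reference", "T") for i in range(10)
        ]
        wb = compute_weight_matrix(make_jc(assignments))
        frame = wb.to_frame()
        assert frame.loc["A", "T"] == pytest.approx(0.7)
        assert frame.loc["B", "T"] == pytest.approx(0.3)

    def test_type_confined_to_one_cluster_gives_one_hot(self):
        assignments = [(f"r{i}", "A", "reference", "T") for i in range(5)] + [
            (f"b{i}", "B", "background", None) for i in range(5)
        ]
        wb = compute_weight_matrix(make_jc(assignments))
        frame = wb.to_frame()
        assert frame.loc["A", "T"] == 1.0
        assert frame.loc["B", "T"] == 0.0

    def test_random_assignment_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        types = [f"T{i}" for i in range(4)]
        clusters = [f"C{i}" for i in range(6)]
        assignments = [
            (
                f"r{i}",
                clusters[rng.integers(6)],
                "reference",
                types[rng.integers(4)],
            )
            for i in range(200)
        ]
        wb = compute_weight_matrix(make_jc(assignments)).to_frame()
        # Independent tally straight from the assignment list.
        for t in types:
            of_type = [a for a in assignments if a[3] == t]
            for c in clusters:
                expected = sum(1 for a in of_type if a[1] == c) / len(of_type)
                got = wb.loc[c, t] if c in wb.index else 0.0
                assert got == pytest.approx(expected)

    def test_columns_sum_to_one_for_random_partitions(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            n = int(rng.integers(5, 60))
            assignments = [
                (
                    f"r{i}",
                    f"C{rng.integers(1, 5)}",
                    "reference",
                    f"T{rng.integers(1, 4)}",
                )
                for i in range(n)
            ]
            wb = compute_weight_matrix(make_jc(assignments))
            np.testing.assert_allclose(wb.values.sum(axis=0), 1.0, atol=1e-9)


class TestCorrectedExpression:
    def _eb(self, values):
        values = np.asarray(values, dtype=float)
        return ClusterProfile(
            [f"g{i}" for i in range(values.shape[0])],
            [f"C{j}" for j in range(values.shape[1])],
            values,
        )

    def test_one_hot_weight_matrix_is_identity(self):
        eb = self._eb(np.array([[1.0, 5.0], [2.0, 6.0]]))
        wb = WeightMatrix(["C0", "C1"], ["T"], np.array([[0.0], [1.0]]))
        er = correct_reference_expression(eb, wb)
        np.testing.assert_array_equal(er.column("T"), eb.column("C1"))

    def test_half_half_weights_average_columns(self):
        eb = self._eb(np.array([[1.0, 3.0], [2.0, 6.0]]))
        wb = WeightMatrix(["C0", "C1"], ["T"], np.array([[0.5], [0.5]]))
        er = correct_reference_expression(eb, wb)
        np.testing.assert_allclose(er.column("T"), [2.0, 4.0])

    def test_matches_triple_loop_product(self):
        rng = np.random.default_rng(11)
        eb_values = rng.uniform(0, 5, (50, 8))
        raw = rng.uniform(0, 1, (8, 3))
        wb_values = raw / raw.sum(axis=0)
        eb = self._eb(eb_values)
        wb = WeightMatrix(eb.cluster_ids, ["T0", "T1", "T2"], wb_values)
        er = correct_reference_expression(eb, wb)
        expected = np.zeros((50, 3))
        for g in range(50):
            for t in range(3):
                for c in range(8):
                    expected[g, t] += eb_values[g, c] * wb_values[c, t]
        np.testing.assert_allclose(er.values, expected, atol=1e-10)

    def test_id_mismatch_rejected(self):
        eb = self._eb(np.ones((3, 2)))
        wb = WeightMatrix(["C0", "X"], ["T"], np.array([[0.5], [0.5]]))
        with pytest.raises(FormatError, match="X"):
            correct_reference_expression(eb, wb)


class TestMarkerScore:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return ClusterProfile(
            [f"g{i}" for i in range(values.shape[0])],
            [f"c{j}" for j in range(values.shape[1])],
            values,
        )

    def test_exclusive_gene_scores_one(self):
        profile = self._profile([[3.0, 0.0], [1.0, 1.0]])
        assert marker_score(profile, "c0")[0] == ("g0", pytest.approx(1.0))

    def test_uniform_gene_scores_inverse_sqrt_k(self):
        profile = self._profile([[2.0, 2.0, 2.0, 2.0]])
        for c in profile.cluster_ids:
            assert marker_score(profile, c)[0][1] == pytest.approx(0.5)

    def test_all_zero_gene_scores_zero_not_nan(self):
        profile = self._profile([[0.0, 0.0], [1.0, 2.0]])
        scores = dict(marker_score(profile, "c0"))
        assert scores["g0"] == 0.0

    def test_ranking_matches_direct_cosine_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 4, (100, 5))
        profile = self._profile(values)
        for j, c in enumerate(profile.cluster_ids):
            onehot = np.zeros(5)
            onehot[j] = 1.0
            expected = {}
            for i, g in enumerate(profile.gene_ids):
                norm = np.linalg.norm(values[i])
                expected[g] = float(values[i] @ onehot / norm) if norm else 0.0
            got = dict(marker_score(profile, c))
            for g in expected:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_scale_invariance_per_gene(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0.1, 4, (30, 4))
        profile = self._profile(values)
        scaled = self._profile(values * rng.uniform(0.5, 10, (30, 1)))
        for c in profile.cluster_ids:
            a = dict(marker_score(profile, c))
            b = dict(marker_score(scaled, c))
            for g in a:
                assert a[g] == pytest.approx(b[g], abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(FormatError):
            marker_score(self._profile([[1.0]]), "c0")


class TestSelectMarkers:
    def _profile(self):
        rng = np.random.default_rng(14)
        return ClusterProfile(
            [f"g{i}" for i in range(10)],
            ["c0", "c1"],
            rng.uniform(0, 3, (10, 2)),
        )

    def test_entry_count_and_rank_structure(self):
        mset = select_markers(self._profile(), n_per_cluster=3)
        assert len(mset.entries) == 6
        assert mset.cluster_ids == ["c0", "c1"]
        for cid in mset.cluster_ids:
            assert [
                e.rank for e in mset.entries if e.cluster_id == cid
            ] == [1, 2, 3]

    def test_n_larger_than_gene_count_takes_all(self):
        mset = select_markers(self._profile(), n_per_cluster=99)
        assert len(mset.entries) == 20

    def test_perfectly_specific_genes_win_at_n1(self):
        profile = ClusterProfile(
            ["spec0", "spec1", "junk"],
            ["c0", "c1"],
            np.array([[5.0, 0.0], [0.0, 5.0], [1.0, 1.0]]),
        )
        mset = select_markers(profile, n_per_cluster=1)
        assert mset.genes_for("c0") == ["spec0"]
        assert mset.genes_for("c1") == ["spec1"]

    def test_marker_genes_subset_of_profile_genes(self):
        profile = self._profile()
        mset = select_markers(profile, n_per_cluster=5)
        assert set(mset.all_genes()) <= set(profile.gene_ids)


class TestRefineSubclusters:
    def _blob_data(self, centers, n_per_blob, label="T"):
        rng = np.random.default_rng(15)
        cells, coords = [], {}
        for b, center in enumerate(centers):
            for i in range(n_per_blob):
                cid = f"cell{b}_{i}"
                cells.append(cid)
                coords[cid] = rng.normal(center, 1.0, size=2)
        counts = np.ones((3, len(cells)), dtype=int)
        data = CountsWithLabels(
            ["g0", "g1", "g2"], cells, counts, {c: label for c in cells}
        )
        return data, coords

    def test_separated_blobs_recovered(self):
        data, coords = self._blob_data([(0, 0), (10, 10)], 50)
        sub_of = refine_subclusters(data, coords)
        labels = {}
        for cell, sub in sub_of.items():
            blob = cell.split("_")[0]
            labels.setdefault(blob, []).append(sub)
        majority = {
            blob: max(set(subs), key=subs.count) for blob, subs in labels.items()
        }
        assert majority["cell0"] != majority["cell1"]
        agreement = sum(
            1
            for cell, sub in sub_of.items()
            if sub == majority[cell.split("_")[0]]
        ) / len(sub_of)
        assert agreement >= 0.99

    def test_tiny_type_kept_whole(self):
        data, coords = self._blob_data([(0, 0)], 5)
        sub_of = refine_subclusters(data, coords)
        assert set(sub_of.values()) == {"T::0"}

    def test_resolution_zero_gives_one_subcluster_per_type(self):
        data, coords = self._blob_data([(0, 0), (10, 10)], 50)
        sub_of = refine_subclusters(data, coords, resolution=0.0)
        assert set(sub_of.values()) == {"T::0"}


class TestBuildReference:
    def test_bundle_satisfies_invariants(self, small_pair, small_bundle):
        small_bundle.validate()
        assert set(small_bundle.er.cluster_ids) == set(small_pair.ref_types)
        assert set(small_bundle.sub_to_main.values()) <= set(
            small_pair.ref_types
        )
        assert small_bundle.meta["embedding"].startswith("joint-pca")

    def test_self_background_er_close_to_naive_per_type_averages(
        self, small_pair
    ):
        # With the reference serving as its own background, the corrected
        # profiles should essentially reproduce plain per-type averages.
        ref = small_pair.reference
        clone = CountsWithLabels(
            gene_ids=ref.gene_ids,
            cell_ids=[f"bgcopy:{c}" for c in ref.cell_ids],
            counts=ref.counts,
            cluster_of={
                f"bgcopy:{c}": ref.cluster_of[c] for c in ref.cell_ids
            },
        )
        bundle = build_reference(ref, clone, species=Species.HUMAN)
        naive = aggregate_and_normalize(small_pair.reference)
        for t in small_pair.ref_types:
            r = np.corrcoef(bundle.er.column(t), naive.column(t))[0, 1]
            assert r > 0.99

    def test_empty_background_rejected(self, small_pair):
        empty = CountsWithLabels(
            small_pair.reference.gene_ids, [], np.zeros((1200, 0)), {}
        )
        with pytest.raises(FormatError):
            build_reference(small_pair.reference, empty)
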