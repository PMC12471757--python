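"""Descriptors, z-scores, Tanimoto-distance clustering and MDS."""

import dataclasses
import math

import numpy as np
import pytest

from diazopred import (
    DescriptorVector,
    FingerprintConfig,
    assign_unknowns_to_clusters,
    compute_descriptors,
    compute_fingerprint,
    hierarchical_clusters,
    mds_embedding,
    tanimoto_distance_matrix,
    zscore_matrix,
)

from conftest import SMALL_FP


class TestDescriptors:
    def test_benzene(self):
        d = compute_descriptors("c1ccccc1")
        assert d.dbe == 4 and d.n_rings == 1 and d.n_nitrogen == 0

    def test_glycine(self):
        d = compute_descriptors("NCC(=O)O")
        assert d.n_nitrogen == 1 and d.n_carboxyl == 1
        assert d.n_amide == 0 and d.dbe == 1

    def test_chloroform(self):
        d = compute_descriptors("ClC(Cl)Cl")
        assert d.n_halogen == 3 and d.hetero_to_carbon == 3.0

    def test_diketopiperazine(self):
        d = compute_descriptors("O=C1CNC(=O)CN1")
        assert d.n_amide == 2 and d.n_rings == 1 and d.dbe == 3

    def test_no_carbon_gives_nan_ratios(self):
        d = compute_descriptors("O")  # water
        assert math.isnan(d.hetero_to_carbon) and math.isnan(d.n_to_carbon)

    def test_smiles_order_invariance(self):
        a = compute_descriptors("OC(=O)CN")  # glycine, reordered spelling
        b = compute_descriptors("NCC(=O)O")
        assert a == b


def _const_vector(value: float) -> DescriptorVector:
    return DescriptorVector(
        n_halogen=int(value), n_nitrogen=0, n_oxygen=0, n_rings=0,
        hetero_to_carbon=0.0, n_to_carbon=0.0, n_amide=0, n_carboxyl=0, dbe=0.0,
    )


class TestZscores:
    def test_identical_groups_give_zero(self):
        vectors = {f"M{i}": compute_descriptors("CCO") for i in range(4)}
        groups = {"M0": "a", "M1": "a", "M2": "b", "M3": "b"}
        with pytest.warns(UserWarning):  # all descriptors constant
            z = zscore_matrix(vectors, groups)
        assert np.allclose(z.values, 0.0)

    def test_two_level_split_gives_plus_minus_one(self):
        # one varying descriptor, values {0,0,10,10}, population SD
        vectors = {
            "A1": _const_vector(0), "A2": _const_vector(0),
            "B1": _const_vector(10), "B2": _const_vector(10),
        }
        groups = {"A1": "low", "A2": "low", "B1": "high", "B2": "high"}
        with pytest.warns(UserWarning):  # other descriptors are constant
            z = zscore_matrix(vectors, groups)
        assert z.loc["low", "n_halogen"] == pytest.approx(-1.0)
        assert z.loc["high", "n_halogen"] == pytest.approx(1.0)

    def test_global_zscores_have_mean_zero_sd_one(self):
        from diazopred.chemspace import descriptor_frame

        smiles = ["CCO", "NCC(=O)O", "c1ccccc1", "ClCCCl", "O=C1CNC(=O)CN1"]
        vectors = {f"M{i}": compute_descriptors(s) for i, s in enumerate(smiles)}
        frame = descriptor_frame(vectors)
        z = (frame - frame.mean()) / frame.std(ddof=0)
        varying = frame.std(ddof=0) > 0
        assert np.allclose(z.loc[:, varying].mean(), 0.0, atol=1e-12)
        assert np.allclose(z.loc[:, varying].std(ddof=0), 1.0, atol=1e-12)

    def test_median_variant_available(self):
        vectors = {
            "A1": _const_vector(0), "A2": _const_vector(1), "A3": _const_vector(10),
        }
        groups = {"A1": "g", "A2": "g", "A3": "g"}
        with pytest.warns(UserWarning):
            mean_z = zscore_matrix(vectors, groups, stat="mean")
            median_z = zscore_matrix(vectors, groups, stat="median")
        assert mean_z.loc["g", "n_halogen"] != median_z.loc["g", "n_halogen"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            zscore_matrix({}, {})


class TestDistanceMatrix:
    def _fps(self, smiles_by_id):
        return {
            cid: compute_fingerprint(s, SMALL_FP)
            for cid, s in smiles_by_id.items()
        }

    def test_identical_molecules_distance_zero(self):
        distances = tanimoto_distance_matrix(
            self._fps({"A": "CCO", "B": "OCC"})
        )
        assert distances.loc["A", "B"] == 0.0

    def test_disjoint_molecules_distance_one(self):
        distances = tanimoto_distance_matrix(self._fps({"A": "CCC", "B": "OO"}))
        assert distances.loc["A", "B"] == 1.0

    def test_symmetric_zero_diagonal_unit_range(self):
        distances = tanimoto_distance_matrix(
            self._fps({"A": "CCO", "B": "NCC(=O)O", "C": "c1ccccc1"})
        )
        values = distances.values
        assert np.array_equal(values, values.T)
        assert np.all(np.diag(values) == 0)
        assert np.all((values >= 0) & (values <= 1))


class TestHierarchicalClusters:
    @staticmethod
    def _two_pair_matrix():
        import pandas as pd

        ids = ["A1", "A2", "B1", "B2"]
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = 0.05
        m[2, 3] = m[3, 2] = 0.05
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_two_tight_pairs_recovered(self):
        assignments, _ = hierarchical_clusters(self._two_pair_matrix(), n_clusters=2)
        assert assignments["A1"] == assignments["A2"]
        assert assignments["B1"] == assignments["B2"]
        assert assignments["A1"] != assignments["B1"]

    def test_enrichment_percentages(self):
        labels = {"A1": 1, "A2": 1, "B1": 1, "B2": 0}
        _, enrichment = hierarchical_clusters(
            self._two_pair_matrix(), labels, n_clusters=2
        )
        assert sorted(enrichment.values()) == [50.0, 100.0]

    def test_singleton_clusters(self):
        labels = {"A1": 1, "A2": 0, "B1": 1, "B2": 0}
        assignments, enrichment = hierarchical_clusters(
            self._two_pair_matrix(), labels, n_clusters=4
        )
        assert sorted(assignments.values()) == [1, 2, 3, 4]
        assert set(enrichment.values()) <= {0.0, 100.0}

    def test_partition_invariant_to_id_permutation(self):
        frame = self._two_pair_matrix()
        permuted = frame.loc[["B2", "A1", "B1", "A2"], ["B2", "A1", "B1", "A2"]]
        a1, _ = hierarchical_clusters(frame, n_clusters=2)
        a2, _ = hierarchical_clusters(permuted, n_clusters=2)
        # compare partitions, not cluster ids
        part1 = {frozenset(k for k, v in a1.items() if v == c) for c in set(a1.values())}
        part2 = {frozenset(k for k, v in a2.items() if v == c) for c in set(a2.values())}
        assert part1 == part2

    def test_more_clusters_than_items_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(self._two_pair_matrix(), n_clusters=5)


class TestAssignUnknowns:
    def _setup(self):
        labeled = {
            "L1": compute_fingerprint("O=C1CNC(=O)CN1", SMALL_FP),
            "L2": compute_fingerprint("ClCCCCCl", SMALL_FP),
        }
        clusters = {"L1": 1, "L2": 2}
        return labeled, clusters

    def test_identical_unknown_joins_its_cluster_at_distance_zero(self):
        labeled, clusters = self._setup()
        unknowns = {"U1": compute_fingerprint("O=C1CNC(=O)CN1", SMALL_FP)}
        assignments, dists = assign_unknowns_to_clusters(unknowns, labeled, clusters)
        a = assignments["U1"]
        assert a.cluster_id == 1 and a.nearest_labeled_id == "L1"
        assert a.nearest_labeled_distance == 0.0
        assert dists[1] == [0.0]

    def test_tie_broken_by_smallest_labeled_id(self):
        from diazopred import Fingerprint

        cfg = FingerprintConfig(n_bits=64)
        labeled = {
            "LB": Fingerprint(frozenset({1, 2}), cfg),
            "LA": Fingerprint(frozenset({3, 4}), cfg),
        }
        unknowns = {"U": Fingerprint(frozenset({9, 10}), cfg)}
        assignments, _ = assign_unknowns_to_clusters(
            unknowns, labeled, {"LA": 1, "LB": 2}
        )
        assert assignments["U"].nearest_labeled_id == "LA"

    def test_distances_in_unit_interval(self, separable_dataset):
        from diazopred import fingerprint_dataset

        fps, _ = fingerprint_dataset(separable_dataset.records[:20], SMALL_FP)
        ids = sorted(fps)
        labeled = {c: fps[c] for c in ids[:10]}
        unknowns = {c: fps[c] for c in ids[10:]}
        clusters = {c: 1 + (i % 3) for i, c in enumerate(labeled)}
        assignments, _ = assign_unknowns_to_clusters(unknowns, labeled, clusters)
        assert all(
            0.0 <= a.nearest_labeled_distance <= 1.0 for a in assignments.values()
        )

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            assign_unknowns_to_clusters({}, {}, {})


class TestMds:
    @staticmethod
    def _frame(matrix, ids):
        import pandas as pd

        return pd.DataFrame(matrix, index=ids, columns=ids)

    def test_equilateral_triangle_distances_reproduced(self):
        d = 0.8
        matrix = np.array([[0, d, d], [d, 0, d], [d, d, 0]], dtype=float)
        coords = mds_embedding(self._frame(matrix, ["A", "B", "C"]), dims=2)
        for i in range(3):
            for j in range(i + 1, 3):
                embedded = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert embedded == pytest.approx(d, abs=1e-9)

    def test_two_points_embed_at_their_distance(self):
        matrix = np.array([[0.0, 0.37], [0.37, 0.0]])
        coords = mds_embedding(self._frame(matrix, ["A", "B"]), dims=1)
        assert np.linalg.norm(coords.iloc[0] - coords.iloc[1]) == pytest.approx(0.37)

    def test_duplicate_points_coincide(self):
        matrix = np.array(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        coords = mds_embedding(self._frame(matrix, ["A", "B", "C"]), dims=2)
        assert np.allclose(coords.loc["A"], coords.loc["B"], atol=1e-9)

    def test_euclidean_matrix_reproduced_within_tolerance(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(6, 2))
        matrix = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        ids = [f"P{i}" for i in range(6)]
        coords = mds_embedding(self._frame(matrix, ids), dims=2)
        embedded = np.linalg.norm(
            coords.values[:, None] - coords.values[None, :], axis=-1
        )
        assert np.allclose(embedded, matrix, atol=1e-9)

    def test_non_symmetric_rejected(self):
        matrix = np.array([[0.0, 0.3], [0.6, 0.0]])
        with pytest.raises(ValueError):
            mds_embedding(self._frame(matrix, ["A", "B"]))
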