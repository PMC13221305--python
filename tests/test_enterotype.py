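import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist, jensenshannon
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from conftest import make_config
from enterotyper.enterotype import (
    EnterotypeModel, assign_new, calinski_harabasz, jsd_matrix,
    label_enterotypes, pam, pcoa, select_k,
)
from enterotyper.synthetic_cohort import generate_cohort
from enterotyper.tables_io import to_relative


def profiles_from(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    rows = rows / rows.sum(axis=1, keepdims=True)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids)


def jsd_oracle(p, q):
    """Term-by-term sqrt Jensen-Shannon distance, natural log."""
    m = 0.5 * (np.asarray(p) + np.asarray(q))
    kl = lambda a: sum(ai * math.log(ai / mi) for ai, mi in zip(a, m) if ai > 0)
    return math.sqrt(0.5 * kl(p) + 0.5 * kl(q))


class TestJSD:
    def test_identical_profiles_distance_zero(self):
        D = jsd_matrix(profiles_from([[0.3, 0.7], [0.3, 0.7]]))
        assert D.data[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_support_limit(self):
        D = jsd_matrix(profiles_from([[1, 0], [0, 1]]), pseudocount=1e-15)
        assert D.data[0, 1] == pytest.approx(math.sqrt(math.log(2)), abs=1e-5)

    def test_matches_term_by_term_oracle(self):
        p, q = [0.5, 0.5], [0.9, 0.1]
        D = jsd_matrix(profiles_from([p, q]), pseudocount=1e-300)
        assert D.data[0, 1] == pytest.approx(jsd_oracle(p, q), abs=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(6), size=5)
        D = jsd_matrix(profiles_from(P), pseudocount=1e-300)
        for i, j in itertools.combinations(range(5), 2):
            assert D.data[i, j] == pytest.approx(
                jensenshannon(P[i], P[j], base=math.e), abs=1e-9)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            jsd_matrix(profiles_from([[1, 0], [0, 1]]), pseudocount=0.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.full(5, 0.7), size=3)
        D = jsd_matrix(profiles_from(P)).data
        assert np.allclose(D, D.T)
        assert D[0, 1] <= D[0, 2] + D[2, 1] + 1e-12
        assert (D <= math.sqrt(math.log(2)) + 1e-9).all()


class TestPAM:
    def test_separable_clouds_split_exactly(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)),
                         rng.normal(10, 0.05, (10, 2))])
        _, assignment, _ = pam(cdist(pts, pts), k=2)
        assert len(set(assignment[:10])) == 1
        assert len(set(assignment[10:])) == 1
        assert assignment[0] != assignment[-1]

    @pytest.mark.parametrize("k", [2, 3])
    def test_cost_equals_exhaustive_search_n7(self, k):
        rng = np.random.default_rng(2)
        for _ in range(20):
            M = rng.uniform(0, 1, (7, 7))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            _, _, cost = pam(D, k)
            best = min(D[list(S)].min(axis=0).sum()
                       for S in itertools.combinations(range(7), k))
            assert cost == pytest.approx(best, abs=1e-12)

    def test_duplicate_points_co_assigned(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0], [9.0]])
        _, assignment, _ = pam(cdist(pts, pts), k=2)
        assert assignment[0] == assignment[1]
        assert assignment[2] == assignment[3]

    def test_k_out_of_range_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pam(D, 1)
        with pytest.raises(ValueError):
            pam(D, 4)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0, 1, (20, 20))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        m1, a1, c1 = pam(D, 3)
        m2, a2, c2 = pam(D, 3)
        assert m1 == m2 and c1 == c2 and (a1 == a2).all()


class TestCalinskiHarabasz:
    def test_perfect_clusters_infinite(self):
        D = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        assert calinski_harabasz(D, [0, 0, 1, 1], 2) == math.inf

    def test_equals_centroid_formula_on_euclidean(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pts = rng.normal(size=(25, 3))
            labels = rng.integers(0, 3, 25)
            while len(np.unique(labels)) < 3:
                labels = rng.integers(0, 3, 25)
            ours = calinski_harabasz(cdist(pts, pts), labels, 3)
            ref = calinski_harabasz_score(pts, labels)
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_all_identical_degenerate(self):
        D = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            assert math.isnan(calinski_harabasz(D, [0, 0, 1, 1], 2))

    def test_empty_cluster_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="empty"):
            calinski_harabasz(D, [0, 0, 0], 2)


class TestSelectK:
    @pytest.mark.parametrize("K,expected", [(2, 2), (4, 4)])
    def test_recovers_archetype_count(self, K, expected):
        hits = 0
        for seed in range(10):
            table, _, _, _ = generate_cohort(
                make_config(K=K, n_subjects=15, seed=seed))
            D = jsd_matrix(to_relative(table))
            model = select_k(D, range(2, 7))
            hits += model.k == expected
        assert hits >= 9

    def test_ties_resolve_to_smallest_k(self):
        curve = {2: 5.0, 3: 5.0, 4: 4.0}
        best = max(sorted(curve), key=lambda k: (curve[k], -k))
        assert best == 2

    def test_empty_range_rejected(self):
        D = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            select_k(D, [])

    def test_model_json_round_trip(self, tmp_path):
        table, _, _, _ = generate_cohort(make_config(K=2, n_subjects=10))
        model = select_k(jsd_matrix(to_relative(table)), range(2, 5))
        path = tmp_path / "model.json"
        model.to_json(path)
        again = EnterotypeModel.from_json(path)
        assert again.k == model.k
        assert list(again.medoid_ids) == list(model.medoid_ids)
        assert again.assignment.equals(model.assignment)


class TestPCoA:
    def test_line_recovered_on_one_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        res = pcoa(DistanceMatrix(cdist(pts, pts), ids=list("abc")))
        coords = res.coordinates.to_numpy()
        rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(rec, cdist(pts, pts), atol=1e-9)

    def test_reconstructs_random_3d_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        D = cdist(pts, pts)
        res = pcoa(DistanceMatrix(D, ids=[str(i) for i in range(12)]))
        coords = res.coordinates.to_numpy()[:, :3]
        rec = cdist(coords, coords)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_duplicate_sample_same_coordinates(self):
        pts = np.array([[0.0, 0], [0, 0], [2, 1], [3, 4]])
        res = pcoa(DistanceMatrix(cdist(pts, pts), ids=list("abcd")))
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[1], atol=1e-9)

    def test_eigenvalues_sorted_positive(self, default_cohort):
        table = default_cohort[0]
        D = jsd_matrix(to_relative(table).iloc[:60])
        res = pcoa(D)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues > 0).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_agrees_with_skbio_reference(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 4))
        D = DistanceMatrix(cdist(pts, pts), ids=[str(i) for i in range(10)])
        ours = pcoa(D).coordinates.to_numpy()
        ref = skbio_pcoa(D).samples.to_numpy()[:, :ours.shape[1]]
        for axis in range(ours.shape[1]):
            sign = np.sign(np.dot(ours[:, axis], ref[:, axis])) or 1.0
            np.testing.assert_allclose(ours[:, axis], sign * ref[:, axis],
                                       atol=1e-6)


class TestLabelling:
    def make_model(self, assignment_values, ids):
        return EnterotypeModel(
            k=len(set(assignment_values)), medoid_ids=[],
            assignment=pd.Series(assignment_values, index=ids),
            ch_curve={}, cost=0.0)

    def test_dominant_genus_label(self):
        profiles = pd.DataFrame(
            [[0.8, 0.1, 0.1]] * 3 + [[0.05, 0.9, 0.05]] * 3,
            columns=["Bifidobacterium", "Streptococcus", "Bacteroides"],
            index=[f"s{i}" for i in range(6)])
        model = self.make_model([0] * 3 + [1] * 3, list(profiles.index))
        labels = label_enterotypes(model, profiles)
        assert labels[0] == "ET-Bifi"
        assert labels[1] == "ET-St"

    def test_margin_rule_gives_dual_label(self):
        profiles = pd.DataFrame(
            [[0.40, 0.35, 0.25]] * 4 + [[0.1, 0.1, 0.8]] * 2,
            columns=["Bifidobacterium", "Bacteroides", "Streptococcus"],
            index=[f"s{i}" for i in range(6)])
        model = self.make_model([0] * 4 + [1] * 2, list(profiles.index))
        labels = label_enterotypes(model, profiles)
        assert labels[0] == "ET-Bifi and Bact"

    def test_duplicate_names_suffixed_by_size(self):
        profiles = pd.DataFrame(
            [[0.9, 0.1]] * 4 + [[0.7, 0.3]] * 2,
            columns=["Bifidobacterium", "Bacteroides"],
            index=[f"s{i}" for i in range(6)])
        model = self.make_model([0] * 4 + [1] * 2, list(profiles.index))
        labels = label_enterotypes(model, profiles)
        assert labels[0] == "ET-Bifi 1"   # larger cluster
        assert labels[1] == "ET-Bifi 2"


class TestAssignNew:
    def make_model(self):
        return EnterotypeModel(
            k=3, medoid_ids=["m0", "m1", "m2"],
            assignment=pd.Series(dtype=int), ch_curve={}, cost=0.0)

    def test_medoid_assigns_to_own_cluster(self):
        model = self.make_model()
        d = pd.DataFrame([[0.0, 0.5, 0.9]], index=["new"],
                         columns=["m0", "m1", "m2"])
        assert assign_new(model, d)["new"] == 0

    def test_tie_goes_to_lowest_cluster(self):
        model = self.make_model()
        d = pd.DataFrame([[0.9, 0.4, 0.4]], index=["new"],
                         columns=["m0", "m1", "m2"])
        assert assign_new(model, d)["new"] == 1

    def test_missing_distance_rejected(self):
        model = self.make_model()
        d = pd.DataFrame([[0.1, 0.2]], index=["new"], columns=["m0", "m1"])
        with pytest.raises(ValueError, match="m2"):
            assign_new(model, d)

    def test_training_samples_reproduce_assignment(self):
        table, _, _, _ = generate_cohort(make_config(K=3, n_subjects=15, seed=4))
        D = jsd_matrix(to_relative(table))
        model = select_k(D, range(2, 5))
        Ddf = pd.DataFrame(D.data, index=list(D.ids), columns=list(D.ids))
        re_assigned = assign_new(model, Ddf[list(model.medoid_ids)])
        assert (re_assigned == model.assignment).all()


def test_full_recovery_ari(default_cohort):
    """On the default six-archetype cohort the fitted assignment matches the
    generator truth almost perfectly."""
    table, _, _, truth = default_cohort
    model = select_k(jsd_matrix(to_relative(table)), range(2, 11))
    true = [truth.true_enterotype[s] for s in model.assignment.index]
    assert model.k == 6
    assert adjusted_rand_score(true, model.assignment.to_numpy()) >= 0.90
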