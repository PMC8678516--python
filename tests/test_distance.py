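"""Distances, minimum spanning networks and PCoA against independent oracles."""

import itertools

import numpy as np
import pytest

from clonoscope.clonal import MLGTable, assign_mlg
from clonoscope.distance import (
    DistanceMatrix,
    bruvo_distance,
    build_msn,
    mismatch_distance,
    pcoa,
    repeat_count,
)
from clonoscope.types import LocusDef, MISSING

from .conftest import make_dataset


class TestMismatchDistance:
    def test_identical_isolates_distance_zero(self):
        ds = make_dataset([("a", "R", "P", 1, 2, 3), ("b", "R", "P", 1, 2, 3)])
        assert mismatch_distance(ds).d[0, 1] == 0.0

    def test_counts_differing_loci(self):
        ds = make_dataset(
            [("a", "R", "P", 1, 2, 3, 4, 5), ("b", "R", "P", 9, 2, 8, 4, 7)]
        )
        assert mismatch_distance(ds).d[0, 1] == 3.0

    def test_pairwise_deletion_of_missing(self):
        ds = make_dataset(
            [("a", "R", "P", 1, MISSING, 3), ("b", "R", "P", 2, 5, 3)]
        )
        assert mismatch_distance(ds).d[0, 1] == 1.0
        assert mismatch_distance(ds, rescale=True).d[0, 1] == pytest.approx(1.5)

    def test_no_shared_loci_is_error(self):
        ds = make_dataset(
            [("a", "R", "P", 1, MISSING), ("b", "R", "P", MISSING, 5)]
        )
        with pytest.raises(ValueError, match="share no scored loci"):
            mismatch_distance(ds)


class TestBruvoDistance:
    def test_closed_form_two_loci(self):
        # repeat counts 10 vs 12 at one locus, equal at the other
        ds = make_dataset([("a", "R", "P", 10, 7), ("b", "R", "P", 12, 7)])
        d = bruvo_distance(ds, alleles_are_repeats=True).d[0, 1]
        assert d == pytest.approx((1 - 2 ** (-2) + 0) / 2)  # 0.375

    def test_fragment_size_conversion(self):
        loci = [LocusDef("L1", motif_length=2, size_offset=100)]
        ds = make_dataset([("a", "R", "P", 120), ("b", "R", "P", 124)], loci)
        # repeats 10 vs 12
        assert bruvo_distance(ds).d[0, 1] == pytest.approx(1 - 2 ** (-2))

    def test_rounding_warning_beyond_tolerance(self):
        locus = LocusDef("L1", motif_length=3, size_offset=100)
        with pytest.warns(UserWarning, match="repeat units"):
            assert repeat_count(131, locus) == 10  # 31/3 = 10.33

    def test_matches_bruteforce_on_random_dataset(self):
        rng = np.random.default_rng(17)
        rows = [
            (f"i{k}", "R", "P", *rng.integers(5, 15, size=4).tolist())
            for k in range(6)
        ]
        ds = make_dataset(rows)
        dm = bruvo_distance(ds, alleles_are_repeats=True)
        for i, j in itertools.combinations(range(6), 2):
            expected = np.mean(
                [
                    1 - 2.0 ** (-abs(rows[i][3 + l] - rows[j][3 + l]))
                    for l in range(4)
                ]
            )
            assert dm.d[i, j] == pytest.approx(expected)

    def test_bounds_symmetry_and_zero_iff_equal(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"i{k}", "R", "P", *rng.integers(5, 12, size=5).tolist())
            for k in range(8)
        ]
        ds = make_dataset(rows)
        dm = bruvo_distance(ds, alleles_are_repeats=True)
        assert (dm.d >= 0).all() and (dm.d <= 1).all()
        np.testing.assert_allclose(dm.d, dm.d.T)
        for i, j in itertools.combinations(range(8), 2):
            equal = rows[i][3:] == rows[j][3:]
            assert (dm.d[i, j] == 0) == equal


def _mlg_of(n):
    labels = [f"MLG-{k + 1}" for k in range(n)]
    return MLGTable(
        labels=labels,
        keys={l: (k,) for k, l in enumerate(labels)},
        members={l: [l] for l in labels},
        assignment={l: l for l in labels},
    )


def _exhaustive_mst_weight(d):
    """Oracle: minimum total weight over all spanning trees (<= 6 nodes)."""
    n = d.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(d[u, v] for u, v in subset))
    return best


class TestBuildMsn:
    def test_two_nodes_single_edge(self):
        dm = DistanceMatrix(["MLG-1", "MLG-2"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        msn = build_msn(_mlg_of(2), dm)
        assert msn.graph.number_of_edges() == 1

    def test_three_nodes_keeps_two_cheapest(self):
        d = np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
        dm = DistanceMatrix(["MLG-1", "MLG-2", "MLG-3"], d)
        msn = build_msn(_mlg_of(3), dm)
        edges = {frozenset(e) for e in msn.graph.edges()}
        assert edges == {frozenset({"MLG-1", "MLG-2"}), frozenset({"MLG-2", "MLG-3"})}
        assert msn.total_weight == pytest.approx(_exhaustive_mst_weight(d))

    def test_equal_weight_alternatives_both_flagged_co_minimal(self):
        # MLG-1--MLG-2 fixed cheap edge; MLG-3 ties to both ends at 0.2
        d = np.array(
            [
                [0.0, 0.1, 0.2, 0.5],
                [0.1, 0.0, 0.2, 0.5],
                [0.2, 0.2, 0.0, 0.3],
                [0.5, 0.5, 0.3, 0.0],
            ]
        )
        dm = DistanceMatrix([f"MLG-{k}" for k in range(1, 5)], d)
        msn = build_msn(_mlg_of(4), dm, tie_policy="all_ties")
        tied = [
            (u, v) for u, v, attrs in msn.graph.edges(data=True) if attrs["co_minimal"]
        ]
        assert len(tied) == 2  # the 1-3 and 2-3 alternatives
        first = build_msn(_mlg_of(4), dm, tie_policy="first")
        assert first.graph.number_of_edges() == 3  # strict tree

    def test_total_weight_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            n = 6
            sq = rng.random((n, n))
            d = np.triu(sq, 1)
            d = d + d.T
            dm = DistanceMatrix([f"MLG-{k + 1}" for k in range(n)], d)
            msn = build_msn(_mlg_of(n), dm)
            assert msn.total_weight == pytest.approx(_exhaustive_mst_weight(d))
            assert msn.graph.number_of_edges() >= n - 1

    def test_matches_scipy_mst_weight(self):
        from scipy.sparse.csgraph import minimum_spanning_tree

        rng = np.random.default_rng(29)
        n = 12
        sq = rng.random((n, n))
        d = np.triu(sq, 1)
        d = d + d.T
        dm = DistanceMatrix([f"MLG-{k + 1}" for k in range(n)], d)
        msn = build_msn(_mlg_of(n), dm)
        scipy_weight = minimum_spanning_tree(d).sum()
        assert msn.total_weight == pytest.approx(scipy_weight)

    def test_infinite_distance_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        dm = DistanceMatrix(["MLG-1", "MLG-2"], d)
        with pytest.raises(ValueError, match="disconnected"):
            build_msn(_mlg_of(2), dm)


class TestPcoa:
    def test_collinear_points_put_all_variance_on_axis_one(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert len(res.percent_explained) == 1
        assert res.percent_explained[0] == pytest.approx(100.0)

    def test_identical_points_give_zero_coordinates(self):
        d = np.zeros((2, 2))
        res = pcoa(DistanceMatrix(["a", "b"], d))
        assert res.coordinates.size == 0 or np.allclose(res.coordinates, 0)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(10, 3))
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(X))
        res = pcoa(DistanceMatrix([f"p{k}" for k in range(10)], d))
        got = squareform(pdist(res.coordinates[:, :3]))
        np.testing.assert_allclose(got, d, atol=1e-8)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")

        rng = np.random.default_rng(37)
        X = rng.normal(size=(8, 4))
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(X))
        ours = pcoa(DistanceMatrix([f"p{k}" for k in range(8)], d))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-8])[::-1],
            np.sort(np.asarray(theirs.eigvals[theirs.eigvals > 1e-8]))[::-1],
            rtol=1e-6,
        )

    def test_percent_explained_sums_to_100(self, toy_dataset):
        res = pcoa(mismatch_distance(toy_dataset))
        assert res.percent_explained.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
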