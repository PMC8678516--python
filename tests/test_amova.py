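"""AMOVA components against an independent sums-of-squares oracle."""

import itertools

import numpy as np
import pytest

from clonoscope.amova import amova, pairwise_differentiation
from clonoscope.distance import DistanceMatrix, mismatch_distance

from .conftest import make_dataset


def _oracle_two_level(d2, pops):
    """Independent decomposition: direct SS sums per group, textbook coefficients."""
    N = sum(len(p) for p in pops)
    P = len(pops)
    all_idx = [i for p in pops for i in p]
    ss_total = sum(d2[i, j] for i, j in itertools.combinations(all_idx, 2)) / N
    ss_wp = sum(
        sum(d2[i, j] for i, j in itertools.combinations(p, 2)) / len(p) for p in pops
    )
    ss_ap = ss_total - ss_wp
    ms_wp = ss_wp / (N - P)
    ms_ap = ss_ap / (P - 1)
    n0 = (N - sum(len(p) ** 2 for p in pops) / N) / (P - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n0
    return ss_ap, ss_wp, sigma_a, sigma_w


def _random_structured(seed, n_regions=3, pops_per_region=2, n_per_pop=3, n_loci=5):
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_regions):
        base = rng.integers(1, 30, size=n_loci)
        for p in range(pops_per_region):
            for k in range(n_per_pop):
                alleles = base + rng.integers(0, 3, size=n_loci)
                rows.append(
                    (f"r{r}p{p}k{k}", f"R{r}", f"R{r}P{p}", *alleles.tolist())
                )
    return make_dataset(rows)


class TestAmovaTwoLevel:
    def test_fixed_differences_give_phi_one(self):
        ds = make_dataset(
            [
                ("a1", "R", "P1", 1, 1), ("a2", "R", "P1", 1, 1),
                ("b1", "R", "P2", 2, 2), ("b2", "R", "P2", 2, 2),
            ]
        )
        dm = mismatch_distance(ds)
        res = amova(dm, {r.isolate_id: r.population for r in ds.isolates})
        assert res.phi["phi_PT"] == pytest.approx(1.0)

    def test_all_identical_gives_sentinel(self):
        ds = make_dataset(
            [("a", "R", "P1", 1), ("b", "R", "P1", 1),
             ("c", "R", "P2", 1), ("d", "R", "P2", 1)]
        )
        dm = mismatch_distance(ds)
        res = amova(dm, {r.isolate_id: r.population for r in ds.isolates})
        assert all(l.ss == 0 for l in res.levels)
        assert np.isnan(res.phi["phi_PT"])

    def test_components_match_oracle(self):
        ds = _random_structured(51, n_regions=1, pops_per_region=4, n_per_pop=5)
        dm = mismatch_distance(ds)
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        res = amova(dm, pop_of)
        pops = {}
        for i, iid in enumerate(dm.ids):
            pops.setdefault(pop_of[iid], []).append(i)
        ss_ap, ss_wp, sigma_a, sigma_w = _oracle_two_level(dm.d**2, list(pops.values()))
        assert res.component("Among populations").ss == pytest.approx(ss_ap)
        assert res.component("Within populations").ss == pytest.approx(ss_wp)
        assert res.component("Among populations").sigma2 == pytest.approx(sigma_a)
        assert res.component("Within populations").sigma2 == pytest.approx(sigma_w)


class TestAmovaThreeLevel:
    def test_df_partition_and_percent_sum(self):
        ds = _random_structured(53)
        dm = mismatch_distance(ds)
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        region_of = {r.population: r.region for r in ds.isolates}
        res = amova(dm, pop_of, region_of)
        assert res.total_df == len(ds) - 1
        assert sum(l.percent for l in res.levels) == pytest.approx(100.0, abs=1e-9)

    def test_phi_identity(self):
        ds = _random_structured(57)
        dm = mismatch_distance(ds)
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        region_of = {r.population: r.region for r in ds.isolates}
        phi = amova(dm, pop_of, region_of).phi
        lhs = (1 - phi["phi_CT"]) * (1 - phi["phi_SC"])
        assert lhs == pytest.approx(1 - phi["phi_ST"], abs=1e-9)

    def test_ss_decomposition_matches_direct_sums(self):
        ds = _random_structured(59, n_regions=2, pops_per_region=3, n_per_pop=3)
        dm = mismatch_distance(ds)
        d2 = dm.d**2
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        region_of = {r.population: r.region for r in ds.isolates}
        res = amova(dm, pop_of, region_of)
        idx_of_pop, idx_of_region = {}, {}
        for i, iid in enumerate(dm.ids):
            idx_of_pop.setdefault(pop_of[iid], []).append(i)
            idx_of_region.setdefault(region_of[pop_of[iid]], []).append(i)
        N = len(dm.ids)
        ss_total = sum(d2[i, j] for i, j in itertools.combinations(range(N), 2)) / N
        ss_wp = sum(
            sum(d2[i, j] for i, j in itertools.combinations(p, 2)) / len(p)
            for p in idx_of_pop.values()
        )
        ss_wr = sum(
            sum(d2[i, j] for i, j in itertools.combinations(m, 2)) / len(m)
            for m in idx_of_region.values()
        )
        assert res.component("Within populations").ss == pytest.approx(ss_wp)
        assert res.component("Among populations within regions").ss == pytest.approx(
            ss_wr - ss_wp
        )
        assert res.component("Among regions").ss == pytest.approx(ss_total - ss_wr)

    def test_permutation_p_values_bounded_and_reproducible(self):
        ds = _random_structured(61)
        dm = mismatch_distance(ds)
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        region_of = {r.population: r.region for r in ds.isolates}
        r1 = amova(dm, pop_of, region_of, n_perm=49, seed=3)
        r2 = amova(dm, pop_of, region_of, n_perm=49, seed=3)
        assert r1.p_values == r2.p_values
        for p in r1.p_values.values():
            assert 1 / 50 <= p <= 1.0


class TestPairwiseDifferentiation:
    def test_identical_units_give_zero(self):
        # both populations hold the same genotype multiset
        block = [(1, 2), (3, 4), (5, 6), (1, 2), (3, 4)]
        ds = make_dataset(
            [(f"a{k}", "R", "P1", *g) for k, g in enumerate(block)]
            + [(f"b{k}", "R", "P2", *g) for k, g in enumerate(block)]
        )
        dm = mismatch_distance(ds)
        res = pairwise_differentiation(
            dm, {r.isolate_id: r.population for r in ds.isolates}, n_perm=19, seed=1
        )
        assert res.values[0, 1] <= 0.05  # zero within estimation rounding
        assert res.p_values[0, 1] >= 0.05

    def test_fixed_differences_give_one(self):
        ds = make_dataset(
            [(f"a{k}", "R", "P1", 1, 1) for k in range(5)]
            + [(f"b{k}", "R", "P2", 3, 3) for k in range(5)]
        )
        dm = mismatch_distance(ds)
        res = pairwise_differentiation(
            dm, {r.isolate_id: r.population for r in ds.isolates}
        )
        assert res.values[0, 1] == pytest.approx(1.0)

    def test_small_units_excluded_not_error(self):
        ds = make_dataset(
            [(f"a{k}", "R", "P1", k, 1) for k in range(6)]
            + [(f"b{k}", "R", "P2", k + 2, 3) for k in range(6)]
            + [("tiny", "R", "P3", 9, 9)]
        )
        dm = mismatch_distance(ds)
        res = pairwise_differentiation(
            dm, {r.isolate_id: r.population for r in ds.isolates},
            statistic="PhiPT", min_n=5,
        )
        assert res.excluded == ["P3"]
        assert res.unit_ids == ["P1", "P2"]

    def test_matches_two_level_amova(self):
        ds = _random_structured(67, n_regions=1, pops_per_region=2, n_per_pop=6)
        dm = mismatch_distance(ds)
        pop_of = {r.isolate_id: r.population for r in ds.isolates}
        res = pairwise_differentiation(dm, pop_of)
        direct = amova(dm, pop_of)
        assert res.values[0, 1] == pytest.approx(direct.phi["phi_PT"])


class TestNullBehaviour:
    def test_type_one_error_near_nominal(self):
        """Shuffled labels: rejection rate at alpha=0.05 within binomial 99% CI."""
        from scipy.stats import binom

        rng = np.random.default_rng(71)
        n_sims, alpha, n_perm = 120, 0.05, 39
        rejections = 0
        for _ in range(n_sims):
            rows = [
                (f"i{k}", "R", f"P{k % 2}", *rng.integers(1, 5, size=4).tolist())
                for k in range(12)
            ]
            ds = make_dataset(rows)
            dm = mismatch_distance(ds)
            res = amova(
                dm, {r.isolate_id: r.population for r in ds.isolates},
                n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
            )
            if res.p_values["phi_PT"] <= alpha:
                rejections += 1
        lo, hi = binom.ppf([0.005, 0.995], n_sims, alpha)
        assert lo <= rejections <= hi
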