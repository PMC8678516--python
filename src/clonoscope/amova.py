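"""Distance-based hierarchical AMOVA and Φ-statistics.

The analysis of molecular variance partitions the sum of squared pairwise
genetic distances across a sampling hierarchy (regions / populations /
individuals) and expresses each level as a variance component; the Φ
statistics are intraclass correlations built from those components
(Φ_CT among regions, Φ_SC among populations within regions, Φ_ST
individuals vs total; Φ_PT is the two-level form, the statistic usually
reported for binary marker profiles). Significance comes from
non-parametric permutation: individuals are permuted among populations for
the within/among-population components and whole populations among regions
for the among-region component.

Squared distances are the allele-mismatch count for SSR data (a one-locus
mismatch contributes 1 to d²) and the Hamming distance on state vectors for
binary marker profiles. Negative variance components are reported as
computed, without truncation, as the classical programs do.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .distance import DistanceMatrix

logger = logging.getLogger("clonoscope")


@dataclass
class AmovaLevel:
    source: str
    df: int
    ss: float
    sigma2: float
    percent: float


@dataclass
class AmovaResult:
    levels: List[AmovaLevel]
    phi: Dict[str, float]
    p_values: Dict[str, float] = field(default_factory=dict)
    n_perm: int = 0

    @property
    def total_df(self) -> int:
        return sum(l.df for l in self.levels)

    def component(self, source: str) -> AmovaLevel:
        for l in self.levels:
            if l.source == source:
                return l
        raise KeyError(source)


def _ss_within_groups(d2: np.ndarray, groups: Sequence[Sequence[int]]) -> float:
    """Distance form of a sum of squares: Σ_groups (1/n_g)·Σ_{i<j∈g} d²."""
    total = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return total


def _two_level_components(
    d2: np.ndarray, pops: Sequence[Sequence[int]]
) -> Tuple[List[AmovaLevel], float]:
    """SS decomposition and components for populations / individuals."""
    N = sum(len(p) for p in pops)
    P = len(pops)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_wp = _ss_within_groups(d2, pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    ms_ap = ss_ap / df_ap if df_ap > 0 else 0.0
    sizes = np.array([len(p) for p in pops], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (P - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n0 if n0 > 0 else 0.0
    total = sigma_a + sigma_w
    levels = [
        AmovaLevel("Among populations", df_ap, ss_ap, sigma_a,
                   100.0 * sigma_a / total if total != 0 else float("nan")),
        AmovaLevel("Within populations", df_wp, ss_wp, sigma_w,
                   100.0 * sigma_w / total if total != 0 else float("nan")),
    ]
    phi_pt = sigma_a / total if total != 0 else float("nan")
    return levels, phi_pt


def _three_level_components(
    d2: np.ndarray,
    region_pops: Sequence[Sequence[Sequence[int]]],
) -> Tuple[List[AmovaLevel], Dict[str, float]]:
    """Regions / populations-within-regions / individuals decomposition."""
    all_pops = [p for r in region_pops for p in r]
    region_members = [[i for p in r for i in p] for r in region_pops]
    N = sum(len(p) for p in all_pops)
    P = len(all_pops)
    G = len(region_pops)

    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_wp = _ss_within_groups(d2, all_pops)
    ss_wr = _ss_within_groups(d2, region_members)
    ss_ap_wr = ss_wr - ss_wp
    ss_ar = ss_total - ss_wr

    df_ar, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    ms_ap = ss_ap_wr / df_ap if df_ap else 0.0
    ms_ar = ss_ar / df_ar if df_ar else 0.0

    pop_sizes = [float(len(p)) for p in all_pops]
    region_sizes = [float(len(m)) for m in region_members]
    sum_np2_over_region = sum(
        sum(len(p) ** 2 for p in r) / len(m)
        for r, m in zip(region_pops, region_members)
        if len(m)
    )
    n1 = (N - sum_np2_over_region) / df_ap if df_ap else 0.0
    n2 = (
        (sum_np2_over_region - sum(s**2 for s in pop_sizes) / N) / df_ar
        if df_ar else 0.0
    )
    n3 = (N - sum(s**2 for s in region_sizes) / N) / df_ar if df_ar else 0.0

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if n1 else 0.0
    sigma_a = (ms_ar - sigma_c - n2 * sigma_b) / n3 if n3 else 0.0
    total = sigma_a + sigma_b + sigma_c

    def pct(x):
        return 100.0 * x / total if total != 0 else float("nan")

    levels = [
        AmovaLevel("Among regions", df_ar, ss_ar, sigma_a, pct(sigma_a)),
        AmovaLevel("Among populations within regions", df_ap, ss_ap_wr, sigma_b, pct(sigma_b)),
        AmovaLevel("Within populations", df_wp, ss_wp, sigma_c, pct(sigma_c)),
    ]
    phi = {
        "phi_CT": sigma_a / total if total != 0 else float("nan"),
        "phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else float("nan"),
        "phi_ST": (sigma_a + sigma_b) / total if total != 0 else float("nan"),
    }
    return levels, phi


def _hierarchy_indices(
    ids: Sequence[str],
    population_of: Dict[str, str],
    region_of: Optional[Dict[str, str]] = None,
):
    """Group index lists (in first-occurrence order of units)."""
    pops: Dict[str, List[int]] = {}
    for i, iid in enumerate(ids):
        pops.setdefault(population_of[iid], []).append(i)
    if region_of is None:
        return list(pops.values()), None
    regions: Dict[str, List[str]] = {}
    for pop in pops:
        region = region_of[pop]
        regions.setdefault(region, []).append(pop)
    nested = [[pops[p] for p in plist] for plist in regions.values()]
    return list(pops.values()), nested


def amova(
    distances: DistanceMatrix,
    population_of: Dict[str, str],
    region_of_population: Optional[Dict[str, str]] = None,
    n_perm: int = 0,
    seed: Optional[int] = None,
    squared: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on a distance matrix.

    ``population_of`` maps isolate id to population; adding
    ``region_of_population`` turns the design into three levels. Distances
    are squared internally unless ``squared`` marks the matrix as already
    squared. Permutation p-values (when ``n_perm > 0``): individuals among
    populations for Φ_ST/Φ_SC-type components, whole populations among
    regions for Φ_CT.
    """

    ids = distances.ids
    for iid in ids:
        if iid not in population_of:
            raise ValueError(f"no population for isolate {iid!r}")
    counts: Dict[str, int] = {}
    for iid in ids:
        counts[population_of[iid]] = counts.get(population_of[iid], 0) + 1
    if any(c == 0 for c in counts.values()):
        raise ValueError("empty population in design")
    if region_of_population is not None:
        region_pop_count: Dict[str, int] = {}
        for pop, region in region_of_population.items():
            if pop in counts:
                region_pop_count[region] = region_pop_count.get(region, 0) + 1
        for region, c in region_pop_count.items():
            if c == 1:
                logger.warning(
                    "region %s has a single population; its within-region "
                    "component is carried by the size coefficients", region
                )

    d2 = distances.d.astype(float) ** (1 if squared else 2)

    def fit(ids_order):
        pops, nested = _hierarchy_indices(ids_order, population_of, region_of_population)
        if nested is None:
            levels, phi_pt = _two_level_components(d2, pops)
            return levels, {"phi_PT": phi_pt}
        return _three_level_components(d2, nested)

    levels, phi = fit(ids)
    result = AmovaResult(levels=levels, phi=dict(phi), n_perm=int(n_perm))
    if n_perm <= 0:
        return result

    rng = np.random.default_rng(seed)
    n = len(ids)
    if region_of_population is None:
        observed = phi["phi_PT"]
        count = 0
        for _ in range(int(n_perm)):
            perm_ids = [ids[k] for k in rng.permutation(n)]
            # permuted ids reassign individuals to population slots
            perm_pop = {pid: population_of[iid] for pid, iid in zip(perm_ids, ids)}
            pops, _ = _hierarchy_indices(ids, perm_pop)
            _, phi_perm = _two_level_components(d2, pops)
            if phi_perm >= observed - 1e-12:
                count += 1
        result.p_values["phi_PT"] = (count + 1) / (n_perm + 1)
        return result

    # three-level: individuals among populations (phi_ST, phi_SC within regions),
    # whole populations among regions (phi_CT)
    observed = dict(phi)
    counts_extreme = {k: 0 for k in ("phi_CT", "phi_SC", "phi_ST")}
    pops_list = sorted({population_of[i] for i in ids})
    regions_list = sorted({region_of_population[p] for p in pops_list})
    region_assignment = [region_of_population[p] for p in pops_list]
    for _ in range(int(n_perm)):
        # phi_ST: individuals among populations, ignoring regions
        perm = rng.permutation(n)
        perm_pop = {ids[k]: population_of[ids[perm[k]]] for k in range(n)}
        _, nested = _hierarchy_indices(ids, perm_pop, region_of_population)
        _, phi_p = _three_level_components(d2, nested)
        if phi_p["phi_ST"] >= observed["phi_ST"] - 1e-12:
            counts_extreme["phi_ST"] += 1

        # phi_SC: individuals among populations within their region
        perm_pop_sc = {}
        by_region: Dict[str, List[str]] = {}
        for iid in ids:
            by_region.setdefault(
                region_of_population[population_of[iid]], []
            ).append(iid)
        for region, members in by_region.items():
            shuffled = [members[k] for k in rng.permutation(len(members))]
            for iid, donor in zip(members, shuffled):
                perm_pop_sc[iid] = population_of[donor]
        _, nested = _hierarchy_indices(ids, perm_pop_sc, region_of_population)
        _, phi_p = _three_level_components(d2, nested)
        if phi_p["phi_SC"] >= observed["phi_SC"] - 1e-12:
            counts_extreme["phi_SC"] += 1

        # phi_CT: whole populations among regions
        shuffled_regions = [
            region_assignment[k] for k in rng.permutation(len(region_assignment))
        ]
        perm_region_of = dict(zip(pops_list, shuffled_regions))
        _, nested = _hierarchy_indices(ids, population_of, perm_region_of)
        _, phi_p = _three_level_components(d2, nested)
        if phi_p["phi_CT"] >= observed["phi_CT"] - 1e-12:
            counts_extreme["phi_CT"] += 1

    for key, count in counts_extreme.items():
        result.p_values[key] = (count + 1) / (n_perm + 1)
    return result


@dataclass
class PairwiseDiffMatrix:
    unit_ids: List[str]
    statistic: str  # "Fst" or "PhiPT"
    values: np.ndarray
    p_values: np.ndarray
    excluded: List[str] = field(default_factory=list)


def pairwise_differentiation(
    distances: DistanceMatrix,
    unit_of: Dict[str, str],
    statistic: str = "Fst",
    n_perm: int = 0,
    seed: Optional[int] = None,
    min_n: int = 5,
    squared: bool = False,
) -> PairwiseDiffMatrix:
    """Pairwise unit differentiation via two-level AMOVA per unit pair.

    Units with fewer than ``min_n`` members are excluded (logged, not an
    error) when the statistic is the binary-profile Φ_PT; the same threshold
    is applied to Fst for symmetry. p-values permute individuals between
    the two units of each pair.
    """

    if statistic not in {"Fst", "PhiPT"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    members: Dict[str, List[str]] = {}
    for iid in distances.ids:
        members.setdefault(unit_of[iid], []).append(iid)
    excluded = [u for u, m in members.items() if len(m) < min_n]
    for u in excluded:
        logger.info("unit %s excluded from pairwise %s (n=%d < %d)",
                    u, statistic, len(members[u]), min_n)
    units = [u for u in members if u not in excluded]
    if len(units) < 2:
        raise ValueError("need at least two units after exclusion")

    k = len(units)
    values = np.zeros((k, k))
    p_values = np.ones((k, k))
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(range(k), 2):
        pair_ids = members[units[a]] + members[units[b]]
        sub = distances.submatrix(pair_ids)
        res = amova(
            sub,
            {i: unit_of[i] for i in pair_ids},
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)) if n_perm else None,
            squared=squared,
        )
        values[a, b] = values[b, a] = res.phi["phi_PT"]
        if n_perm:
            p_values[a, b] = p_values[b, a] = res.p_values["phi_PT"]
    return PairwiseDiffMatrix(
        unit_ids=units, statistic=statistic, values=values,
        p_values=p_values, excluded=excluded,
    )
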