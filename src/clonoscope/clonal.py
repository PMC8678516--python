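"""Multilocus genotype (MLG) assignment, clone correction and rarefaction.

In a partially clonal haploid population many isolates are exact copies of
one another. Statistics of reproductive mode therefore distinguish the
number of isolates sampled (n) from the number of distinct multilocus
genotypes (MLG), the expected number of genotypes at a common sample size
(eMLG, by hypergeometric rarefaction), and clone-corrected datasets that
keep one representative per genotype per hierarchy unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy.stats import hypergeom

from .types import SSRDataset


@dataclass
class MLGTable:
    """Partition of isolates into identical-genotype classes.

    ``labels`` are assigned in order of first occurrence (``MLG-1`` ...);
    ``members`` maps each label to the isolate ids carrying that genotype.
    """

    labels: List[str]
    keys: Dict[str, tuple]  # label -> genotype tuple
    members: Dict[str, List[str]]  # label -> isolate ids
    assignment: Dict[str, str]  # isolate id -> label
    group_of: Dict[str, str] = field(default_factory=dict)  # isolate id -> unit (optional)

    @property
    def n_mlg(self) -> int:
        return len(self.labels)

    @property
    def n_isolates(self) -> int:
        return len(self.assignment)

    def sizes(self) -> Dict[str, int]:
        return {label: len(ids) for label, ids in self.members.items()}

    def counts_by(self, unit_of: Dict[str, str]) -> Dict[str, Dict[str, int]]:
        """Per-label isolate counts within units (e.g. populations, regions)."""
        out: Dict[str, Dict[str, int]] = {}
        for label, ids in self.members.items():
            counts: Dict[str, int] = {}
            for iid in ids:
                unit = unit_of[iid]
                counts[unit] = counts.get(unit, 0) + 1
            out[label] = counts
        return out

    def representative_ids(self) -> List[str]:
        """First-occurrence isolate id of every MLG."""
        return [self.members[label][0] for label in self.labels]


def _group_by_key(items: Sequence[Tuple[str, tuple]]) -> MLGTable:
    labels: List[str] = []
    keys: Dict[str, tuple] = {}
    members: Dict[str, List[str]] = {}
    assignment: Dict[str, str] = {}
    seen: Dict[tuple, str] = {}
    for iid, key in items:
        label = seen.get(key)
        if label is None:
            label = f"MLG-{len(labels) + 1}"
            labels.append(label)
            seen[key] = label
            keys[label] = key
            members[label] = []
        members[label].append(iid)
        assignment[iid] = label
    return MLGTable(labels=labels, keys=keys, members=members, assignment=assignment)


def assign_mlg(dataset: SSRDataset, match_missing_policy: str = "strict") -> MLGTable:
    """Partition isolates by exact match of the full allele vector.

    Under the ``strict`` policy a missing allele is a distinct token: two
    isolates group together only if all scored loci match AND their missing
    patterns are identical. This prevents spurious clone merging when
    amplification fails at informative loci.
    """

    if match_missing_policy != "strict":
        raise ValueError(f"unknown match_missing_policy {match_missing_policy!r}")
    if not dataset.isolates:
        raise ValueError("cannot assign MLGs on an empty dataset")
    items = [(r.isolate_id, dataset.genotype_tuple(r)) for r in dataset.isolates]
    return _group_by_key(items)


_LEVELS = ("population", "region", "total")


def clone_correct(
    dataset: SSRDataset,
    level: str = "total",
    representative: str = "first",
    seed: Optional[int] = None,
) -> SSRDataset:
    """Keep one representative of each MLG within each unit at ``level``.

    ``level='population'`` keeps one copy of a genotype in every population
    where it occurs; ``'region'`` one per region; ``'total'`` one overall.
    The representative is the first occurrence in input order (determinism
    first); ``representative='random'`` draws it with ``seed``.
    """

    if level not in _LEVELS:
        raise ValueError(f"unknown clone-correction level {level!r}; use {_LEVELS}")
    if representative not in {"first", "random"}:
        raise ValueError(f"unknown representative policy {representative!r}")

    def unit(rec):
        if level == "population":
            return rec.population
        if level == "region":
            return rec.region
        return "__total__"

    groups: Dict[tuple, List] = {}
    for rec in dataset.isolates:
        key = (unit(rec), dataset.genotype_tuple(rec))
        groups.setdefault(key, []).append(rec)

    if representative == "first":
        keep = {recs[0].isolate_id for recs in groups.values()}
    else:
        import numpy as np

        rng = np.random.default_rng(seed)
        keep = {recs[int(rng.integers(len(recs)))].isolate_id for recs in groups.values()}
    return dataset.subset(keep)


@dataclass
class RarefactionResult:
    group_id: str
    n_rarefied: int
    emlg: float
    se: float


def _p_absent(N: int, n: int, size: int) -> float:
    """P(a class of ``size`` contributes no member to a subsample of n)."""
    if size > N - n:
        return 0.0
    # C(N - size, n) / C(N, n), via the hypergeometric pmf at 0
    return float(hypergeom.pmf(0, N, size, n))


def rarefy_emlg(
    mlg_counts: Sequence[int],
    n_rarefied: int,
    with_se: bool = True,
    group_id: str = "",
) -> RarefactionResult:
    """Expected number of MLGs in a random subsample of ``n_rarefied`` isolates.

    Hypergeometric rarefaction: ``eMLG = sum_g [1 - C(N-N_g, n)/C(N, n)]``
    with the classical rarefaction variance for the standard error. At
    ``n = N`` this returns the observed MLG count with zero SE.
    """

    counts = [int(c) for c in mlg_counts]
    if any(c < 1 for c in counts):
        raise ValueError("MLG counts must be positive integers")
    N = sum(counts)
    n = int(n_rarefied)
    if n < 1:
        raise ValueError("n_rarefied must be >= 1")
    if n > N:
        raise ValueError(f"n_rarefied={n} exceeds total sample size {N}")

    q = [_p_absent(N, n, c) for c in counts]
    emlg = sum(1.0 - qi for qi in q)
    se = 0.0
    if with_se:
        var = sum(qi * (1.0 - qi) for qi in q)
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                q_ij = _p_absent(N, n, counts[i] + counts[j])
                var += 2.0 * (q_ij - q[i] * q[j])
        se = math.sqrt(max(var, 0.0))
    return RarefactionResult(group_id=group_id, n_rarefied=n, emlg=emlg, se=se)


def rarefaction_depth(group_sizes: Sequence[int], minimum: int = 10) -> int:
    """Default rarefaction depth: the smallest group size that is >= minimum.

    Groups smaller than the returned depth report their observed MLG count
    instead of a rarefied value (see :func:`rarefy_groups`).
    """

    eligible = [s for s in group_sizes if s >= minimum]
    if not eligible:
        return max(group_sizes)
    return min(eligible)


def rarefy_groups(
    mlg_table: MLGTable,
    unit_of: Dict[str, str],
    depth: Optional[int] = None,
    minimum: int = 10,
) -> List[RarefactionResult]:
    """Rarefied eMLG per unit (population/region), sharing one depth.

    Units smaller than the depth report their observed MLG count with SE 0.
    """

    by_unit = mlg_table.counts_by(unit_of)
    unit_sizes: Dict[str, int] = {}
    unit_counts: Dict[str, List[int]] = {}
    for label, counts in by_unit.items():
        for unit, c in counts.items():
            unit_sizes[unit] = unit_sizes.get(unit, 0) + c
            unit_counts.setdefault(unit, []).append(c)
    if depth is None:
        depth = rarefaction_depth(list(unit_sizes.values()), minimum=minimum)
    out = []
    for unit in sorted(unit_counts):
        counts = unit_counts[unit]
        if unit_sizes[unit] < depth:
            out.append(
                RarefactionResult(group_id=unit, n_rarefied=unit_sizes[unit],
                                  emlg=float(len(counts)), se=0.0)
            )
        else:
            out.append(rarefy_emlg(counts, depth, group_id=unit))
    return out
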