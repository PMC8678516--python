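"""Pairwise genetic distances, minimum spanning networks and PCoA.

Two distances are provided for haploid multilocus genotypes: the plain
allele-mismatch count (the "haploid genetic distance" tradition of
spreadsheet population genetics, squared when fed to AMOVA) and the
stepwise-mutation-aware microsatellite distance ``1 - 2^(-|Δ repeats|)``
averaged over loci, used for minimum spanning networks. Because the
organism is haploid (one allele per locus), no genome-addition/loss model
is needed for the latter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .clonal import MLGTable
from .types import MISSING, LocusDef, SSRDataset


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered ids."""

    ids: List[str]
    d: np.ndarray
    metric_tag: str = "mismatch"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def index(self, isolate_id: str) -> int:
        return self.ids.index(isolate_id)

    def submatrix(self, wanted_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in wanted_ids]
        return DistanceMatrix(
            ids=list(wanted_ids), d=self.d[np.ix_(idx, idx)], metric_tag=self.metric_tag
        )


def mismatch_distance(
    dataset: SSRDataset, missing_policy: str = "pairwise", rescale: bool = False
) -> DistanceMatrix:
    """Number of loci with differing alleles, per isolate pair.

    Loci missing in either member of a pair are dropped (pairwise deletion);
    with ``rescale=True`` the count is rescaled to the full locus count
    (count * L / shared). A pair sharing zero scored loci is an error.
    """

    if missing_policy not in {"pairwise"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if len(dataset) < 2:
        raise ValueError("need at least two isolates")
    ids = dataset.isolate_ids
    L = len(dataset.loci)
    geno = [dataset.genotype_tuple(r) for r in dataset.isolates]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            diff = 0
            for a, b in zip(geno[i], geno[j]):
                if a is MISSING or b is MISSING:
                    continue
                shared += 1
                if a != b:
                    diff += 1
            if shared == 0:
                raise ValueError(
                    f"isolates {ids[i]!r} and {ids[j]!r} share no scored loci"
                )
            value = diff * (L / shared) if rescale else float(diff)
            d[i, j] = d[j, i] = value
    return DistanceMatrix(ids=ids, d=d, metric_tag="mismatch")


def repeat_count(size: int, locus: LocusDef, tolerance: float = 0.25) -> int:
    """Convert a fragment size (bp) to a repeat count for a locus.

    Residues beyond ``tolerance`` repeat units trigger a warning and are
    rounded to the nearest integer.
    """

    x = (size - locus.size_offset) / locus.motif_length
    nearest = round(x)
    if abs(x - nearest) > tolerance:
        warnings.warn(
            f"allele {size} at locus {locus.locus_id} is {x:.2f} repeat units; "
            f"rounding to {nearest}",
            stacklevel=2,
        )
    return int(nearest)


def bruvo_distance(
    dataset: SSRDataset, locus_defs: Optional[Sequence[LocusDef]] = None,
    alleles_are_repeats: bool = False,
) -> DistanceMatrix:
    """Stepwise-mutation distance, mean over shared loci of ``1 - 2^(-|Δ|)``.

    Alleles are converted to repeat counts via each locus's motif length and
    flank offset unless ``alleles_are_repeats`` is set. Bounded in [0, 1];
    zero iff the repeat vectors agree on every shared locus.
    """

    loci = list(locus_defs) if locus_defs is not None else list(dataset.loci)
    by_id = {l.locus_id: l for l in loci}
    for locus_id in dataset.locus_ids:
        if locus_id not in by_id:
            raise ValueError(f"no motif definition for locus {locus_id!r}")
    ids = dataset.isolate_ids
    reps = []
    for rec in dataset.isolates:
        row = []
        for locus_id in dataset.locus_ids:
            a = rec.allele(locus_id)
            if a is MISSING:
                row.append(None)
            elif alleles_are_repeats:
                row.append(int(a))
            else:
                row.append(repeat_count(int(a), by_id[locus_id]))
        reps.append(row)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            terms = [
                1.0 - 2.0 ** (-abs(x - y))
                for x, y in zip(reps[i], reps[j])
                if x is not None and y is not None
            ]
            if not terms:
                raise ValueError(
                    f"isolates {ids[i]!r} and {ids[j]!r} share no scored loci"
                )
            d[i, j] = d[j, i] = float(np.mean(terms))
    return DistanceMatrix(ids=ids, d=d, metric_tag="bruvo")


# ---------------------------------------------------------------------------
# Minimum spanning network
# ---------------------------------------------------------------------------


@dataclass
class MSNGraph:
    """Minimum spanning network over MLG nodes.

    Nodes carry clone size and per-population composition; edges carry the
    genetic distance, an ``in_tree`` flag (membership in the Kruskal-selected
    spanning tree) and a ``co_minimal`` flag set on every edge — selected or
    alternative — that participates in an equal-weight tie for a merge step.
    """

    graph: nx.Graph

    @property
    def total_weight(self) -> float:
        return sum(
            d["distance"] for _, _, d in self.graph.edges(data=True) if d["in_tree"]
        )


def build_msn(
    mlg_table: MLGTable,
    distances: DistanceMatrix,
    tie_policy: str = "all_ties",
    node_populations: Optional[Dict[str, Dict[str, int]]] = None,
) -> MSNGraph:
    """Kruskal minimum spanning tree over MLG representatives, plus ties.

    ``distances.ids`` must be the MLG labels (distances between clone
    representatives). With ``tie_policy='all_ties'`` every equal-weight edge
    joining the same two components at a merge step is added and flagged
    ``co_minimal``, turning the tree into a network as drawn in clonal
    population studies; ``'first'`` keeps a strict tree.
    """

    if tie_policy not in {"all_ties", "first"}:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    labels = distances.ids
    if not np.isfinite(distances.d).all():
        raise ValueError("non-finite distances: graph would be disconnected")
    sizes = mlg_table.sizes()

    g = nx.Graph()
    for label in labels:
        g.add_node(
            label,
            size=sizes.get(label, 1),
            populations=dict((node_populations or {}).get(label, {})),
        )
    if len(labels) == 1:
        return MSNGraph(graph=g)

    edges = sorted(
        (
            (distances.d[i, j], labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ),
        key=lambda e: e[0],
    )

    parent = {label: label for label in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    while k < len(edges):
        w = edges[k][0]
        block = []
        while k < len(edges) and edges[k][0] == w:
            block.append(edges[k])
            k += 1
        # components are frozen within an equal-weight block so that every
        # tie joining the same pair of components is recorded
        comp_before = {label: find(label) for label in labels}
        by_pair: Dict[frozenset, list] = {}
        pair_order = []
        for w_e, u, v in block:
            cu, cv = comp_before[u], comp_before[v]
            if cu == cv:
                continue  # redundant within a component even before this block
            pair = frozenset((cu, cv))
            if pair not in by_pair:
                by_pair[pair] = []
                pair_order.append(pair)
            by_pair[pair].append((u, v))
        for pair in pair_order:
            group = by_pair[pair]
            tied = len(group) > 1
            u0, v0 = group[0]
            if find(u0) != find(v0):
                parent[find(u0)] = find(v0)
                g.add_edge(u0, v0, distance=float(w), in_tree=True, co_minimal=tied)
                rest = group[1:]
            else:
                # distinct before-block components already joined transitively
                # at this same weight: every edge here is a co-minimal cycle edge
                rest = group
            if tie_policy == "all_ties":
                for u, v in rest:
                    g.add_edge(u, v, distance=float(w), in_tree=False, co_minimal=True)
    roots = {find(label) for label in labels}
    if len(roots) > 1:
        raise ValueError(f"distance matrix is disconnected into {len(roots)} components")
    return MSNGraph(graph=g)


# ---------------------------------------------------------------------------
# Principal coordinate analysis
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    ids: List[str]
    coordinates: np.ndarray  # n x k, axes ordered by eigenvalue descending
    eigenvalues: np.ndarray  # all n, descending
    percent_explained: np.ndarray  # over positive eigenvalues, sums to 100


def pcoa(distances: DistanceMatrix) -> PcoaResult:
    """Classical scaling (Gower) of a distance matrix.

    Double-centers ``-D²/2``, eigendecomposes, and scales eigenvectors by
    ``sqrt(λ)`` for positive eigenvalues. Negative eigenvalues (possible for
    non-Euclidean distances such as mismatch counts) are reported but
    excluded from the percent-explained normalisation.
    """

    D = distances.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    percent = (
        100.0 * eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(0)
    )
    return PcoaResult(
        ids=list(distances.ids),
        coordinates=coords,
        eigenvalues=eigval,
        percent_explained=percent,
    )
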