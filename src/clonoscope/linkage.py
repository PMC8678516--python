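"""Index of association I_A and its standardised form r̄d.

Multilocus linkage disequilibrium is the population-genetic signature of
clonal reproduction in haploids: under free recombination loci assort
independently and the variance of pairwise multilocus distances equals the
sum of the per-locus variances (I_A ≈ 0, r̄d ≈ 0); under clonality loci are
inherited together and the observed variance exceeds that sum.

For every pair of isolates the per-locus distance is 0/1 mismatch. With
``D = Σ_l d_l`` per pair, ``V_O = var(D)`` over pairs and
``V_E = Σ_l var(d_l)``:

    I_A  = V_O / V_E − 1
    r̄d  = (V_O − V_E) / (2 Σ_{j<k} sqrt(var_j · var_k))

Both ratios are invariant to the variance denominator convention. The
permutation null shuffles alleles among isolates independently per locus
(which preserves allele frequencies and hence V_E), with
``p = (#{perm ≥ observed} + 1)/(n_perm + 1)``; the test is identical
whether ranked on I_A, r̄d or V_O.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clonal import clone_correct, assign_mlg
from .types import MISSING, SSRDataset


@dataclass
class LinkageResult:
    group_id: str
    i_a: float
    r_d: float
    v_o: float
    v_e: float
    p_value: float
    n_perm: int
    n_mlg_used: int
    tested: bool = True  # False when below min_mlg ("nt" in reports)


def _encode(dataset: SSRDataset) -> np.ndarray:
    """Integer-coded allele matrix (n × L); missing = -1."""
    n, L = len(dataset), len(dataset.loci)
    codes = np.empty((n, L), dtype=np.int64)
    for l, locus_id in enumerate(dataset.locus_ids):
        mapping: dict = {}
        for i, rec in enumerate(dataset.isolates):
            a = rec.allele(locus_id)
            if a is MISSING:
                codes[i, l] = -1
            else:
                codes[i, l] = mapping.setdefault(a, len(mapping))
    return codes


def _pair_table(codes: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """0/1 mismatch per locus for every isolate pair: shape (n_pairs, L).

    Loci missing in either pair member contribute NaN and are dropped from
    that locus's variance (pairwise deletion).
    """

    a, b = codes[i_idx], codes[j_idx]
    table = (a != b).astype(float)
    table[(a == -1) | (b == -1)] = np.nan
    return table


def _ia_rd_from_pairs(per_locus: np.ndarray) -> tuple:
    """(I_A, r_d, V_O, V_E) from the per-pair per-locus 0/1 distance table."""
    D = np.nansum(per_locus, axis=1)
    v_o = float(np.var(D))  # population convention; the ratios are invariant
    var_l = np.array([
        float(np.var(col[~np.isnan(col)])) if np.any(~np.isnan(col)) else 0.0
        for col in per_locus.T
    ])
    v_e = float(var_l.sum())
    denom_cross = 0.0
    L = len(var_l)
    for j in range(L):
        for k in range(j + 1, L):
            denom_cross += math.sqrt(var_l[j] * var_l[k])
    i_a = v_o / v_e - 1.0 if v_e > 0 else float("nan")
    r_d = (v_o - v_e) / (2.0 * denom_cross) if denom_cross > 0 else float("nan")
    return i_a, r_d, v_o, v_e


def index_of_association(
    dataset: SSRDataset,
    n_perm: int = 999,
    seed: Optional[int] = None,
    clone_correct_level: Optional[str] = "region",
    min_mlg: int = 5,
    group_id: str = "",
) -> LinkageResult:
    """I_A and r̄d with a per-locus allele-shuffling permutation test.

    The statistics are computed on clone-corrected data by default
    (``clone_correct_level`` is forwarded to :func:`clone_correct`; pass
    ``None`` to analyse all isolates). Groups with fewer than ``min_mlg``
    distinct genotypes after correction are flagged not-tested, mirroring
    the "nt" convention of clonal-diversity tables.
    """

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(dataset.loci) < 2:
        raise ValueError("index of association needs at least two loci")
    data = (
        clone_correct(dataset, level=clone_correct_level)
        if clone_correct_level is not None
        else dataset
    )
    n_mlg = assign_mlg(data).n_mlg
    if n_mlg < min_mlg:
        return LinkageResult(
            group_id=group_id, i_a=float("nan"), r_d=float("nan"),
            v_o=float("nan"), v_e=float("nan"), p_value=float("nan"),
            n_perm=0, n_mlg_used=n_mlg, tested=False,
        )

    n = len(data)
    codes = _encode(data)
    pair_idx = np.array(list(itertools.combinations(range(n), 2)))
    i_idx, j_idx = pair_idx[:, 0], pair_idx[:, 1]
    i_a, r_d, v_o, v_e = _ia_rd_from_pairs(_pair_table(codes, i_idx, j_idx))

    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(int(n_perm)):
        permuted = np.empty_like(codes)
        for l in range(codes.shape[1]):
            permuted[:, l] = codes[rng.permutation(n), l]
        _, r_d_perm, _, _ = _ia_rd_from_pairs(_pair_table(permuted, i_idx, j_idx))
        if r_d_perm >= r_d - 1e-12:
            n_extreme += 1
    p = (n_extreme + 1) / (n_perm + 1)
    return LinkageResult(
        group_id=group_id, i_a=i_a, r_d=r_d, v_o=v_o, v_e=v_e,
        p_value=p, n_perm=int(n_perm), n_mlg_used=n_mlg,
    )
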