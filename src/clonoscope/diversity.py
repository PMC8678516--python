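"""Allele-frequency diversity indices for haploid multilocus data.

Per locus and per group: effective allele number ``Ne = 1/Σp²``, gene
diversity ``h = 1 − Σp²`` and its small-sample unbiased form
``uh = n/(n−1)·h``, percentage of polymorphic loci (≥2 observed alleles),
and private-allele counts (alleles absent from every other group). Group
summaries are means over loci, reported for both the full and the
clone-corrected dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .types import MISSING, SSRDataset

logger = logging.getLogger("clonoscope")

#: sentinel for indices undefined at n = 1
NOT_COMPUTABLE = float("nan")

_GROUPINGS = ("population", "region", "cluster_label", "total")


@dataclass
class AlleleFrequencyTable:
    """Long-format allele frequencies: one row per group × locus × allele."""

    table: pd.DataFrame  # columns: group_id, locus_id, allele, frequency, n

    def groups(self) -> List[str]:
        return list(self.table["group_id"].unique())

    def loci(self, group_id: str) -> List[str]:
        sub = self.table[self.table["group_id"] == group_id]
        return list(sub["locus_id"].unique())

    def freqs(self, group_id: str, locus_id: str) -> Dict:
        sub = self.table[
            (self.table["group_id"] == group_id) & (self.table["locus_id"] == locus_id)
        ]
        return dict(zip(sub["allele"], sub["frequency"]))

    def sample_size(self, group_id: str, locus_id: str) -> int:
        sub = self.table[
            (self.table["group_id"] == group_id) & (self.table["locus_id"] == locus_id)
        ]
        return int(sub["n"].iloc[0]) if len(sub) else 0


def allele_frequencies(
    dataset: SSRDataset,
    group_by: str = "total",
    cluster_of: Optional[Dict[str, str]] = None,
) -> AlleleFrequencyTable:
    """Allele frequencies per locus per group over non-missing alleles.

    ``group_by`` is one of population/region/cluster_label/total;
    ``cluster_of`` maps isolate ids to external cluster labels when grouping
    by an externally supplied partition (e.g. model-based clusters). A locus
    with zero scored isolates in a group is skipped with a warning.
    """

    if group_by not in _GROUPINGS:
        raise ValueError(f"unknown group_by {group_by!r}; use {_GROUPINGS}")
    if group_by == "cluster_label" and cluster_of is None:
        raise ValueError("cluster_label grouping requires cluster_of")

    def group(rec) -> str:
        if group_by == "population":
            return rec.population
        if group_by == "region":
            return rec.region
        if group_by == "cluster_label":
            return cluster_of[rec.isolate_id]
        return "total"

    rows = []
    groups: Dict[str, list] = {}
    for rec in dataset.isolates:
        groups.setdefault(group(rec), []).append(rec)
    for group_id, recs in groups.items():
        for locus_id in dataset.locus_ids:
            alleles = [r.allele(locus_id) for r in recs if r.allele(locus_id) is not MISSING]
            if not alleles:
                logger.warning(
                    "group %s has no scored isolates at locus %s; skipped",
                    group_id, locus_id,
                )
                continue
            n = len(alleles)
            counts: Dict = {}
            for a in alleles:
                counts[a] = counts.get(a, 0) + 1
            for allele, count in sorted(counts.items()):
                rows.append(
                    {
                        "group_id": group_id,
                        "locus_id": locus_id,
                        "allele": allele,
                        "frequency": count / n,
                        "n": n,
                    }
                )
    return AlleleFrequencyTable(table=pd.DataFrame(rows))


@dataclass
class DiversitySummary:
    group_id: str
    p_percent: float  # % of loci with >= 2 observed alleles
    ne: float  # mean effective allele number over loci
    np_mean: float  # mean private alleles per locus
    np_total: float  # total private alleles over loci
    uh: float  # mean unbiased gene diversity over loci
    n_loci: int


def diversity_summary(
    freq_table: AlleleFrequencyTable, clone_corrected: bool = False
) -> List[DiversitySummary]:
    """Per-group diversity summary from one allele-frequency table.

    Private alleles are counted against the other groups of the same table,
    so a table built from a single (total) grouping reports zero. The
    ``clone_corrected`` flag is carried for report labelling only; pass a
    frequency table built from a clone-corrected dataset to get the
    bracketed variants of a diversity table.
    """

    df = freq_table.table
    if df.empty:
        return []
    summaries = []
    all_groups = freq_table.groups()
    # which groups carry which alleles, per locus
    carriers: Dict = {}
    for row in df.itertuples():
        carriers.setdefault((row.locus_id, row.allele), set()).add(row.group_id)

    for group_id in all_groups:
        ne_vals, uh_vals, private_counts, poly = [], [], [], []
        loci = freq_table.loci(group_id)
        for locus_id in loci:
            p = freq_table.freqs(group_id, locus_id)
            n = freq_table.sample_size(group_id, locus_id)
            sum_p2 = sum(f * f for f in p.values())
            ne_vals.append(1.0 / sum_p2)
            h = 1.0 - sum_p2
            uh_vals.append(n / (n - 1) * h if n > 1 else NOT_COMPUTABLE)
            poly.append(len(p) >= 2)
            private_counts.append(
                sum(
                    1
                    for allele in p
                    if carriers[(locus_id, allele)] == {group_id}
                )
                if len(all_groups) > 1
                else 0
            )
        uh_defined = [u for u in uh_vals if not math.isnan(u)]
        summaries.append(
            DiversitySummary(
                group_id=group_id,
                p_percent=100.0 * sum(poly) / len(poly),
                ne=float(sum(ne_vals) / len(ne_vals)),
                np_mean=float(sum(private_counts) / len(private_counts)),
                np_total=float(sum(private_counts)),
                uh=float(sum(uh_defined) / len(uh_defined)) if uh_defined else NOT_COMPUTABLE,
                n_loci=len(loci),
            )
        )
    return summaries
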