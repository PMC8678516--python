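"""Rule-based prediction of alkaloid chemotypes from gene-marker states.

Alkaloid production in *Epichloë* endophytes is governed by gene clusters
(ergot alkaloids EAS, indole-diterpenes IDT, lolines LOL) and by domains of
the single perA gene (pyrrolopyrazines, PPZ). Because the clusters are
frequently eroded by transposon activity, the presence/absence pattern of a
few key genes predicts the terminal product of each pathway:

* EAS — ergovaline (ERV) needs all five scored genes (dmaW, easC, easA,
  cloA, lpsB); with only the early genes dmaW and easC the pathway stalls
  at chanoclavine (CC).
* PPZ — peramine (PER, a pyrrolopyrazine-1-one) needs all three perA
  markers; loss of the reductase domain (perAR) truncates the product to
  pyrrolopyrazine-1,4-diones (PPZA2).
* IDT — paspaline (PAS) is the first stable intermediate; terpendole I
  (TDI) needs idtG and idtQ; terpendole C (TDC) additionally needs idtP,
  idtK and a functional idtF (a first-exon deletion pseudogenises idtF and
  blocks the late pathway); lolitrem B (LTB), the end product, additionally
  needs idtJ.
* LOL — lolines (LOL) need all four scored genes (lolC, lolA, lolO, lolP).

Two rule sets are provided. ``table_consistent`` (default) keys paspaline
on idtG + idtP in the absence of idtQ and lets a pseudogene idtF carry
terpendole I — the reading that reproduces the published genotype panel.
``methods_text`` follows the prose wording instead: paspaline from
idtG + idtQ, terpendole I requiring functional idtF. An UNTESTED marker
never satisfies a positive requirement (conservative prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .clonal import MLGTable, _group_by_key
from .types import (
    ABSENT,
    AlkaloidProfile,
    DEFAULT_PANEL,
    MarkerPanel,
    MatingType,
    PRESENT,
    PSEUDOGENE,
)

RULE_SETS = ("table_consistent", "methods_text")

#: canonical within-class product order for report columns
EAS_PRODUCTS = ("ERV", "CC")
PPZ_PRODUCTS = ("PER", "PPZA2")
IDT_PRODUCTS = ("LTB", "TDC", "TDI", "PAS")
LOL_PRODUCTS = ("LOL",)


@dataclass(frozen=True)
class ChemotypePrediction:
    eas_product: str  # ERV | CC | NONE
    ppz_product: str  # PER | PPZA2 | NONE
    idt_product: str  # LTB | TDC | TDI | PAS | NONE
    lol_product: str  # LOL | NONE
    rule_set: str = "table_consistent"

    @property
    def label(self) -> str:
        """Products joined EAS/PPZ/IDT/LOL with "/"; empty when none."""
        parts = [
            p
            for p in (self.eas_product, self.ppz_product, self.idt_product, self.lol_product)
            if p != "NONE"
        ]
        return "/".join(parts)


def predict_chemotype(
    profile: AlkaloidProfile, rule_set: str = "table_consistent"
) -> ChemotypePrediction:
    """Predict the terminal product of each alkaloid class for one profile."""

    if rule_set not in RULE_SETS:
        raise ValueError(f"unknown rule_set {rule_set!r}; use {RULE_SETS}")

    def present(marker: str) -> bool:
        return profile.state(marker) is PRESENT

    def functional_idtF() -> bool:
        # a pseudogene copy still yields a PCR band but cannot carry the
        # late pathway; only a functional copy satisfies idtF requirements
        return profile.state("idtF") is PRESENT

    # EAS
    if all(present(g) for g in ("dmaW", "easC", "easA", "cloA", "lpsB")):
        eas = "ERV"
    elif present("dmaW") and present("easC"):
        eas = "CC"
    else:
        eas = "NONE"

    # PPZ (perA domains)
    if present("perA5") and present("perAT2"):
        ppz = "PER" if present("perAR") else "PPZA2"
    else:
        ppz = "NONE"

    # IDT ladder
    idt = "NONE"
    if rule_set == "table_consistent":
        if present("idtG") and present("idtQ"):
            idt = "TDI"
            if present("idtP") and functional_idtF() and present("idtK"):
                idt = "TDC"
                if present("idtJ"):
                    idt = "LTB"
        elif present("idtG") and present("idtP"):
            idt = "PAS"
    else:  # methods_text
        if present("idtG") and present("idtQ"):
            idt = "PAS"
            if functional_idtF():
                idt = "TDI"
                if present("idtP") and present("idtK"):
                    idt = "TDC"
                    if present("idtJ"):
                        idt = "LTB"

    # LOL
    lol = "LOL" if all(present(g) for g in ("lolC", "lolA", "lolO", "lolP")) else "NONE"

    return ChemotypePrediction(
        eas_product=eas, ppz_product=ppz, idt_product=idt, lol_product=lol,
        rule_set=rule_set,
    )


def assign_amlg(
    profiles: Sequence[AlkaloidProfile], panel: MarkerPanel = DEFAULT_PANEL
) -> MLGTable:
    """Group profiles by exact identity of the full marker-state vector.

    PSEUDOGENE and UNTESTED are distinct states, so two isolates differing
    only in idtF functionality (or in scoring coverage) form distinct
    alkaloid genotypes, as in the published panel.
    """

    items = [(p.isolate_id, p.state_tuple(panel)) for p in profiles]
    return _group_by_key(items)


@dataclass
class MatingSummary:
    group_id: str
    n_a: int
    n_b: int
    n_nd: int
    ratio_ab: Optional[float]  # None when no B isolates (not computable)

    @property
    def n(self) -> int:
        return self.n_a + self.n_b + self.n_nd


def mating_summary(
    profiles: Sequence[AlkaloidProfile], group_by: str = "region"
) -> List[MatingSummary]:
    """Counts of mating types A/B/ND and the A:B ratio per group.

    ND isolates are reported but excluded from the ratio; the ratio is
    recomputed from counts (None when no B isolates).
    """

    def group(p: AlkaloidProfile) -> str:
        if group_by == "population":
            return p.population
        if group_by == "region":
            return p.region
        if group_by == "total":
            return "total"
        raise ValueError(f"unknown group_by {group_by!r}")

    groups: Dict[str, List[AlkaloidProfile]] = {}
    for p in profiles:
        groups.setdefault(group(p), []).append(p)
    out = []
    for group_id, members in groups.items():
        n_a = sum(1 for p in members if p.mating_type is MatingType.A)
        n_b = sum(1 for p in members if p.mating_type is MatingType.B)
        n_nd = sum(1 for p in members if p.mating_type is MatingType.ND)
        out.append(
            MatingSummary(
                group_id=group_id, n_a=n_a, n_b=n_b, n_nd=n_nd,
                ratio_ab=(n_a / n_b) if n_b > 0 else None,
            )
        )
    return out


@dataclass
class ChemotypeReport:
    """Aggregated chemotype and aMLG statistics per group."""

    group_by: str
    product_counts: pd.DataFrame  # group, product, count, percent
    label_counts: pd.DataFrame  # group, label, count, percent
    n_chemotypes: int  # distinct labels overall (empty label counts as one)
    n_amlg: int
    amlg_region_occupancy: pd.DataFrame  # amlg label, regions present, single_region
    single_region_fraction: float
    largest_amlg: pd.DataFrame  # per group: label, size, fraction of group
    eas_complete: pd.DataFrame  # group, count, percent with all five EAS genes


def chemotype_report(
    profiles: Sequence[AlkaloidProfile],
    predictions: Optional[Sequence[ChemotypePrediction]] = None,
    group_by: str = "total",
    rule_set: str = "table_consistent",
) -> ChemotypeReport:
    """Per-group product and genotype aggregates of the chemotype engine."""

    profiles = list(profiles)
    if predictions is None:
        predictions = [predict_chemotype(p, rule_set) for p in profiles]
    if len(predictions) != len(profiles):
        raise ValueError("predictions must align with profiles")

    def group(p: AlkaloidProfile) -> str:
        if group_by == "population":
            return p.population
        if group_by == "region":
            return p.region
        return "total"

    df = pd.DataFrame(
        {
            "isolate_id": [p.isolate_id for p in profiles],
            "group": [group(p) for p in profiles],
            "region": [p.region for p in profiles],
            "label": [pred.label for pred in predictions],
            "eas": [pred.eas_product for pred in predictions],
            "ppz": [pred.ppz_product for pred in predictions],
            "idt": [pred.idt_product for pred in predictions],
            "lol": [pred.lol_product for pred in predictions],
            "eas_complete": [
                all(p.state(g) is PRESENT for g in DEFAULT_PANEL.eas) for p in profiles
            ],
        }
    )
    group_sizes = df.groupby("group").size()

    prod_rows = []
    for cls in ("eas", "ppz", "idt", "lol"):
        counts = df.groupby(["group", cls]).size()
        for (g, product), count in counts.items():
            if product == "NONE":
                continue
            prod_rows.append(
                {"group": g, "class": cls.upper(), "product": product,
                 "count": int(count), "percent": 100.0 * count / group_sizes[g]}
            )
    product_counts = pd.DataFrame(prod_rows)

    label_counts = (
        df.groupby(["group", "label"]).size().reset_index(name="count")
    )
    label_counts["percent"] = [
        100.0 * c / group_sizes[g] for g, c in zip(label_counts["group"], label_counts["count"])
    ]

    mlg = assign_amlg(profiles)
    region_of = {p.isolate_id: p.region for p in profiles}
    occupancy_rows = []
    for label in mlg.labels:
        regions = sorted({region_of[i] for i in mlg.members[label]})
        occupancy_rows.append(
            {"amlg": label, "size": len(mlg.members[label]),
             "regions": ";".join(regions), "n_regions": len(regions),
             "single_region": len(regions) == 1}
        )
    occupancy = pd.DataFrame(occupancy_rows)
    single_fraction = float(occupancy["single_region"].mean())

    group_of = {p.isolate_id: group(p) for p in profiles}
    largest_rows = []
    for g in group_sizes.index:
        best_label, best_size = None, 0
        for label in mlg.labels:
            size = sum(1 for i in mlg.members[label] if group_of[i] == g)
            if size > best_size:
                best_label, best_size = label, size
        largest_rows.append(
            {"group": g, "amlg": best_label, "size": best_size,
             "fraction": best_size / group_sizes[g]}
        )
    largest = pd.DataFrame(largest_rows)

    eas_rows = [
        {"group": g, "count": int(c), "percent": 100.0 * c / group_sizes[g]}
        for g, c in df[df["eas_complete"]].groupby("group").size().items()
    ]

    return ChemotypeReport(
        group_by=group_by,
        product_counts=product_counts,
        label_counts=label_counts,
        n_chemotypes=int(df["label"].nunique()),
        n_amlg=mlg.n_mlg,
        amlg_region_occupancy=occupancy,
        single_region_fraction=single_fraction,
        largest_amlg=largest,
        eas_complete=pd.DataFrame(eas_rows),
    )
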