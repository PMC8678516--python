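"""Core data model: loci, isolates, SSR datasets and alkaloid-marker profiles.

The organism is a haploid fungal endophyte: each isolate carries exactly one
allele per microsatellite (SSR) locus, and a single copy of each
secondary-metabolite gene cluster whose members are scored present/absent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class Missing(enum.Enum):
    """Singleton token for an unscored SSR allele."""

    MISSING = "MISSING"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = Missing.MISSING

#: Allele values are integer fragment sizes (bp) or repeat counts; MISSING
#: marks a locus that failed to amplify.
Allele = "int | Missing"


class MarkerState(enum.Enum):
    """Scored state of an alkaloid-pathway or mating-type gene marker."""

    PRESENT = "1"
    ABSENT = "0"
    PSEUDOGENE = "psi"  # idtF copy with the first-exon deletion (in-frame stop)
    UNTESTED = "nt"


PRESENT = MarkerState.PRESENT
ABSENT = MarkerState.ABSENT
PSEUDOGENE = MarkerState.PSEUDOGENE
UNTESTED = MarkerState.UNTESTED


@dataclass(frozen=True)
class LocusDef:
    """Definition of one SSR locus.

    Parameters
    ----------
    locus_id:
        Unique name of the marker.
    motif_length:
        Repeat-unit length in bp (>= 1); needed to convert fragment sizes to
        repeat counts for the stepwise-mutation (Bruvo) distance.
    size_offset:
        Length in bp of the non-repeat flanking sequence inside the amplicon
        (>= 0), i.e. ``repeat_count = (size - size_offset) / motif_length``.
    """

    locus_id: str
    motif_length: int = 1
    size_offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1 for locus {self.locus_id!r}")
        if self.size_offset < 0:
            raise ValueError(f"size_offset must be >= 0 for locus {self.locus_id!r}")


@dataclass
class IsolateRecord:
    """One haploid isolate: provenance plus its single allele per locus."""

    isolate_id: str
    region: str
    population: str
    alleles: dict  # locus_id -> int | MISSING
    habitat: Optional[str] = None
    flags: set = field(default_factory=set)

    def allele(self, locus_id: str):
        return self.alleles.get(locus_id, MISSING)


@dataclass
class SSRDataset:
    """Ordered collection of haploid isolates typed at a shared locus panel."""

    isolates: list  # of IsolateRecord
    loci: list  # of LocusDef

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.isolates:
            if rec.isolate_id in seen:
                raise ValueError(f"duplicate isolate_id {rec.isolate_id!r}")
            seen.add(rec.isolate_id)
        pop_region: dict = {}
        for rec in self.isolates:
            prev = pop_region.setdefault(rec.population, rec.region)
            if prev != rec.region:
                raise ValueError(
                    f"population {rec.population!r} assigned to two regions "
                    f"({prev!r}, {rec.region!r})"
                )
        locus_ids = {l.locus_id for l in self.loci}
        if len(locus_ids) != len(self.loci):
            raise ValueError("locus_ids not unique in panel")
        for rec in self.isolates:
            unknown = set(rec.alleles) - locus_ids
            if unknown:
                raise ValueError(
                    f"isolate {rec.isolate_id!r} carries alleles at loci not in "
                    f"the panel: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.isolates)

    @property
    def locus_ids(self) -> list:
        return [l.locus_id for l in self.loci]

    @property
    def isolate_ids(self) -> list:
        return [rec.isolate_id for rec in self.isolates]

    def hierarchy(self) -> dict:
        """region -> ordered list of populations (first-occurrence order)."""
        out: dict = {}
        for rec in self.isolates:
            pops = out.setdefault(rec.region, [])
            if rec.population not in pops:
                pops.append(rec.population)
        return out

    def regions(self) -> list:
        return list(self.hierarchy())

    def populations(self) -> list:
        return [p for pops in self.hierarchy().values() for p in pops]

    def subset(self, isolate_ids: Iterable[str]) -> "SSRDataset":
        wanted = set(isolate_ids)
        return SSRDataset(
            isolates=[r for r in self.isolates if r.isolate_id in wanted],
            loci=list(self.loci),
        )

    def subset_by(self, *, region: Optional[str] = None, population: Optional[str] = None) -> "SSRDataset":
        recs = self.isolates
        if region is not None:
            recs = [r for r in recs if r.region == region]
        if population is not None:
            recs = [r for r in recs if r.population == population]
        return SSRDataset(isolates=list(recs), loci=list(self.loci))

    def genotype_tuple(self, rec: IsolateRecord) -> tuple:
        """Full allele vector in canonical locus order (MISSING kept distinct)."""
        return tuple(rec.allele(l) for l in self.locus_ids)


# ---------------------------------------------------------------------------
# Alkaloid / mating-type marker panel
# ---------------------------------------------------------------------------

EAS_GENES = ("dmaW", "easC", "easA", "cloA", "lpsB")
PPZ_MARKERS = ("perA5", "perAT2", "perAR")
IDT_GENES = ("idtG", "idtQ", "idtP", "idtF", "idtK", "idtJ")
LOL_GENES = ("lolC", "lolA", "lolO", "lolP")
MT_GENES = ("mtAC", "mtBA")


@dataclass(frozen=True)
class MarkerPanel:
    """Canonical ordering of the alkaloid-gene and mating-type markers.

    idtF is the only marker allowed the PSEUDOGENE state (the first-exon
    deletion that truncates the protein but still yields a PCR band).
    """

    eas: tuple = EAS_GENES
    ppz: tuple = PPZ_MARKERS
    idt: tuple = IDT_GENES
    lol: tuple = LOL_GENES
    mt: tuple = MT_GENES

    @property
    def alkaloid_markers(self) -> tuple:
        return self.eas + self.ppz + self.idt + self.lol

    @property
    def all_markers(self) -> tuple:
        return self.alkaloid_markers + self.mt

    def validate_state(self, marker_id: str, state: MarkerState) -> None:
        if state is PSEUDOGENE and marker_id != "idtF":
            raise ValueError(
                f"PSEUDOGENE state is only legal for idtF, not {marker_id!r}"
            )


DEFAULT_PANEL = MarkerPanel()


class MatingType(enum.Enum):
    A = "A"
    B = "B"
    ND = "ND"  # mating-type genes not detected


@dataclass
class AlkaloidProfile:
    """Per-isolate presence/absence states of the alkaloid-gene markers."""

    isolate_id: str
    region: str
    population: str
    states: dict  # marker_id -> MarkerState
    mating_type: MatingType = MatingType.ND

    def state(self, marker_id: str) -> MarkerState:
        return self.states.get(marker_id, UNTESTED)

    def state_tuple(self, panel: MarkerPanel = DEFAULT_PANEL) -> tuple:
        """Full marker-state vector over the alkaloid markers, canonical order."""
        return tuple(self.state(m) for m in panel.alkaloid_markers)


def parse_marker_state(cell: str) -> MarkerState:
    """Map a table cell to a canonical marker state.

    Accepts ``1/+`` (present), ``0/-/–`` (absent), ``psi/ψ`` (pseudogene) and
    ``nt/NA/blank`` (untested), case-insensitively.
    """

    token = str(cell).strip().lower()
    if token in {"1", "+", "present"}:
        return PRESENT
    if token in {"0", "-", "–", "absent"}:
        return ABSENT
    if token in {"psi", "ψ", "pseudogene"}:
        return PSEUDOGENE
    if token in {"nt", "na", "", "untested", "nan"}:
        return UNTESTED
    raise ValueError(f"unrecognised marker state {cell!r}")


def parse_mating_type(cell: str) -> MatingType:
    token = str(cell).strip().upper()
    if token in {"A", "B"}:
        return MatingType[token]
    if token in {"ND", "NA", "", "NAN"}:
        return MatingType.ND
    raise ValueError(f"unrecognised mating type {cell!r}")
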