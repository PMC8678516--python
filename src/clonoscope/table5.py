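"""Published alkaloid-genotype panel: 38 aMLGs of *Epichloë festucae*.

The published study scored 198 isolates from the Faroe Islands, Finland and
Spain for 5 ergot-alkaloid (EAS) genes, 3 perA (PPZ) domains, 6
indole-diterpene (IDT) genes (idtF additionally scored for the first-exon
deletion that pseudogenises it) and 4 loline (LOL) genes, and printed the
resulting 38 distinct marker profiles with per-region isolate counts,
per-genotype mating-type tallies and the predicted chemotype string. This
module transcribes that panel and expands it back to an isolate-level list,
which serves as the golden fixture for the chemotype engine and the aMLG
statistics.

Transcription notes (verbatim-from-print, known inconsistencies preserved):

* the per-region count columns sum to 61 / 90 / 47 (Faroe / Finland / Spain)
  although the running text states 60 / 91 / 46-47;
* the gt-24 chemotype prints without a separator ("ERV/PPZA2LTB") and is
  stored with the slash restored;
* all four LOL genes are absent in every isolate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .types import (
    AlkaloidProfile,
    MatingType,
    DEFAULT_PANEL,
    parse_marker_state,
)

REGIONS = ("Faroe Islands", "Finland", "Spain")

# Columns: gt, mt (per-genotype tally: "a:b" counts, or letters per isolate),
# counts in Faroe/Finland/Spain, then the 14 scored alkaloid markers in panel
# order (dmaW easC easA cloA lpsB perA5 perAT2 perAR idtG idtQ idtP idtF idtK
# idtJ; LOL genes omitted here, all absent), then the printed chemotype.
_TABLE5 = """\
gt-1	B	1	0	0	+	-	-	-	+	+	+	-	+	-	nt	-	-	-	PPZA2
gt-2	A	1	0	0	+	+	+	+	-	+	+	-	-	-	nt	-	-	-	CC/PPZA2
gt-3	A	1	0	0	+	-	-	-	-	-	-	-	+	-	-	-	-	-
gt-4	A	1	0	0	+	+	+	+	+	+	+	-	-	-	nt	-	+	-	ERV/PPZA2
gt-5	B	1	0	0	-	-	-	-	-	+	+	-	-	-	-	+	+	-	PPZA2
gt-8	A	0	1	0	+	+	+	-	+	-	+	-	+	+	nt	psi	+	-	CC/TDI
gt-9	B	0	1	0	+	+	+	+	+	-	+	-	+	+	+	psi	+	-	ERV/TDI
gt-10	B	0	1	0	-	-	-	-	+	-	+	-	-	-	+	-	-	-
gt-11	A	0	1	0	+	+	+	+	-	+	+	-	+	-	nt	+	+	-	CC/PPZA2
gt-12	A	0	1	0	+	-	-	+	-	-	+	-	+	-	nt	+	+	-
gt-13	nd	0	1	0	+	-	-	-	-	-	+	-	+	-	+	+	+	-	PAS
gt-14	A	0	1	0	+	+	+	+	-	+	+	-	+	+	nt	-	-	-	PPZA2/TDI
gt-15	A	0	0	1	+	+	-	+	-	+	+	+	+	+	+	+	+	+	CC/PER/LTB
gt-16	B	0	0	1	+	+	+	+	+	+	+	+	+	+	+	psi	+	+	ERV/PER/TDI
gt-17	B	0	0	1	+	+	+	+	+	+	-	+	+	+	nt	-	-	-	ERV/TDI
gt-18	A	0	0	1	+	-	+	-	+	+	+	+	+	+	+	+	+	+	PER/LTB
gt-19	B	0	0	1	-	-	-	-	-	+	+	+	+	+	+	+	+	-	PER/TDC
gt-20	B	0	0	1	+	+	+	+	+	+	+	+	-	+	+	psi	+	-	ERV/PER
gt-21	B	0	0	1	+	+	+	+	-	+	+	+	-	-	nt	-	-	-	CC/PER
gt-22	B	0	0	1	+	+	+	+	+	+	-	-	+	+	+	+	+	-	ERV/TDC
gt-23	nd	0	0	1	+	+	+	+	+	+	+	+	+	-	-	-	-	-	ERV/PER
gt-24	B	0	0	1	+	+	+	+	+	+	+	-	+	+	+	+	+	+	ERV/PPZA2/LTB
gt-25	A,nd	0	2	0	+	-	-	-	-	-	+	-	+	-	+	-	-	-	PAS
gt-26	3:0	3	0	0	+	+	+	-	+	-	+	-	-	-	-	-	-	-	CC
gt-27	32:0	30	2	0	+	+	+	+	+	+	+	-	-	-	-	-	-	-	ERV/PPZA2
gt-28	4:0	0	0	4	+	+	+	+	+	+	+	+	-	-	-	-	-	-	ERV/PER
gt-29	7:0	6	1	0	+	+	+	+	+	+	+	-	-	-	-	+	+	-	ERV/PPZA2
gt-30	4:0	4	0	0	+	+	+	+	+	+	+	-	-	+	-	-	-	-	ERV/PPZA2
gt-31	2:0	0	0	2	+	+	+	+	+	+	+	+	-	+	-	-	-	-	ERV/PER
gt-32	2:0	2	0	0	+	+	+	+	+	+	+	-	-	+	-	+	+	-	ERV/PPZA2
gt-33	8:4	9	0	3	+	+	+	+	+	+	+	-	+	-	-	-	-	-	ERV/PPZA2
gt-34	2:0	0	0	2	+	+	+	+	+	+	+	-	+	-	nt	-	+	-	ERV/PPZA2
gt-35	7:0	0	2	5	+	+	+	+	+	+	+	-	+	-	nt	+	+	-	ERV/PPZA2
gt-36	0:2	0	0	2	+	+	+	+	+	+	+	+	+	-	+	+	+	-	ERV/PER/PAS
gt-37	1:6	1	6	0	+	+	+	+	+	+	+	-	+	+	+	-	-	-	ERV/PPZA2/TDI
gt-38	1:3	1	0	3	+	+	+	+	+	+	+	+	+	+	+	-	-	-	ERV/PER/TDI
gt-39	70:1	0	70	1	+	+	+	+	+	+	+	-	+	+	+	psi	+	-	ERV/PPZA2/TDI
gt-40	4:11	0	0	15	+	+	+	+	+	+	+	+	+	+	+	+	+	-	ERV/PER/TDC
"""

_SCORED_MARKERS = (
    "dmaW", "easC", "easA", "cloA", "lpsB",
    "perA5", "perAT2", "perAR",
    "idtG", "idtQ", "idtP", "idtF", "idtK", "idtJ",
)
_LOL = ("lolC", "lolA", "lolO", "lolP")


@dataclass(frozen=True)
class Table5Row:
    """One printed genotype row: states, per-region counts, chemotype string."""

    gt_id: str
    states: tuple  # MarkerState per marker in panel alkaloid order (18)
    counts: tuple  # (faroe, finland, spain)
    mating_types: tuple  # per-isolate MatingType, genotype-level order
    printed_chemotype: str


def _parse_mt(token: str, n_total: int) -> Tuple[MatingType, ...]:
    token = token.strip()
    if ":" in token:
        n_a, n_b = (int(x) for x in token.split(":"))
        types = (MatingType.A,) * n_a + (MatingType.B,) * n_b
    else:
        types = tuple(
            MatingType.ND if part.strip().lower() == "nd" else MatingType[part.strip()]
            for part in token.split(",")
        )
    if len(types) < n_total:  # pad undetected up to the row total
        types = types + (MatingType.ND,) * (n_total - len(types))
    return types


def table5_rows() -> List[Table5Row]:
    """Parse the transcribed panel into structured rows (deterministic)."""
    rows = []
    for line in _TABLE5.splitlines():
        fields = line.split("\t")
        gt_id, mt_token = fields[0], fields[1]
        counts = tuple(int(x) for x in fields[2:5])
        scored = tuple(parse_marker_state(x) for x in fields[5:19])
        # full panel order: EAS+PPZ+IDT scored, LOL all absent
        states = scored + tuple(parse_marker_state("-") for _ in _LOL)
        chemo = fields[19] if len(fields) > 19 else ""
        rows.append(
            Table5Row(
                gt_id=gt_id,
                states=states,
                counts=counts,
                mating_types=_parse_mt(mt_token, sum(counts)),
                printed_chemotype=chemo,
            )
        )
    return rows


def expand_table5_fixture() -> Tuple[List[AlkaloidProfile], List[Table5Row]]:
    """Expand the printed per-region counts into an isolate-level profile list.

    Isolate ids are deterministic (``<gt>-<region>-<k>``). The printed
    mating-type tally is per genotype, not per region, so types are assigned
    to isolates in region order (Faroe, Finland, Spain), A's first — an
    arbitrary but fixed convention; regional mating-type summaries derived
    from this fixture are therefore approximate for the few multi-region
    genotypes.
    """

    panel_markers = DEFAULT_PANEL.alkaloid_markers
    profiles: List[AlkaloidProfile] = []
    rows = table5_rows()
    for row in rows:
        states = dict(zip(panel_markers, row.states))
        mt_iter = iter(row.mating_types)
        for region, count in zip(REGIONS, row.counts):
            for k in range(1, count + 1):
                profiles.append(
                    AlkaloidProfile(
                        isolate_id=f"{row.gt_id}-{region.split()[0]}-{k}",
                        region=region,
                        population=region,
                        states=dict(states),
                        mating_type=next(mt_iter),
                    )
                )
    return profiles, rows
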