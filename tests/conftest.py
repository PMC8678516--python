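"""Shared fixtures: small hand-built datasets and builders."""

from __future__ import annotations

import pytest

from clonoscope.types import (
    AlkaloidProfile,
    IsolateRecord,
    LocusDef,
    MISSING,
    MarkerState,
    MatingType,
    DEFAULT_PANEL,
    SSRDataset,
)


def make_dataset(rows, loci=None):
    """Build an SSRDataset from (id, region, pop, alleles...) tuples.

    ``loci`` defaults to mononucleotide loci L1..Ln (repeat counts usable
    directly as allele values).
    """

    n_loci = len(rows[0]) - 3
    if loci is None:
        loci = [LocusDef(f"L{i + 1}", 1, 0) for i in range(n_loci)]
    isolates = [
        IsolateRecord(
            isolate_id=row[0],
            region=row[1],
            population=row[2],
            alleles={
                loci[i].locus_id: row[3 + i] for i in range(n_loci)
            },
        )
        for row in rows
    ]
    return SSRDataset(isolates=isolates, loci=loci)


def make_profile(isolate_id="iso", region="R", population="P",
                 mating_type=MatingType.ND, **marker_states):
    """Build an AlkaloidProfile; markers given as keyword states."""
    states = {
        marker: MarkerState(value) if not isinstance(value, MarkerState) else value
        for marker, value in marker_states.items()
    }
    return AlkaloidProfile(
        isolate_id=isolate_id, region=region, population=population,
        states=states, mating_type=mating_type,
    )


@pytest.fixture
def toy_dataset():
    """Six haploid isolates, two regions, four distinct genotypes."""
    return make_dataset(
        [
            ("i1", "north", "N1", 10, 20, 30),
            ("i2", "north", "N1", 10, 20, 30),  # clone of i1
            ("i3", "north", "N2", 10, 22, 30),
            ("i4", "south", "S1", 12, 24, 34),
            ("i5", "south", "S1", 12, 24, 36),
            ("i6", "south", "S1", 12, 24, 34),  # clone of i4
        ]
    )


@pytest.fixture
def table5():
    from clonoscope.table5 import expand_table5_fixture

    return expand_table5_fixture()
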