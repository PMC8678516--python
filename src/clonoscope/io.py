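"""Readers, writers and QC filters for the tabular inputs and outputs.

Input tables are plain delimited text (comma or tab, auto-detected from the
header line). The reserved leading columns of a genotype table are
``isolate_id, region, population[, habitat]``; every remaining column is a
locus. Blank cells and ``NA`` are missing; ``0`` is NOT treated as missing
(it is an implausible but legal size), so silent data loss is impossible.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
import os
from dataclasses import dataclass, field, asdict, is_dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    MISSING,
    AlkaloidProfile,
    IsolateRecord,
    LocusDef,
    MarkerPanel,
    DEFAULT_PANEL,
    PSEUDOGENE,
    SSRDataset,
    parse_marker_state,
    parse_mating_type,
)

logger = logging.getLogger("clonoscope")

_RESERVED = ("isolate_id", "region", "population")
_MISSING_TOKENS = {"", "na", "nan"}


def _sniff_sep(path: str) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_locus_defs(path: str) -> List[LocusDef]:
    """Read a locus-definition table: locus_id, motif_length, size_offset."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"locus_id", "motif_length", "size_offset"}
    if not required.issubset(df.columns):
        raise ValueError(f"locus table must have columns {sorted(required)}")
    return [
        LocusDef(str(r.locus_id), int(r.motif_length), int(r.size_offset))
        for r in df.itertuples()
    ]


def _parse_allele(cell, row_id: str, locus: str):
    token = str(cell).strip()
    if token.lower() in _MISSING_TOKENS:
        return MISSING
    try:
        value = float(token)
        if value != int(value):
            raise ValueError
        return int(value)
    except ValueError:
        raise ValueError(
            f"non-integer allele {cell!r} at isolate {row_id!r}, locus {locus!r}"
        ) from None


def read_ssr_table(
    path: str,
    locus_defs: Optional[Sequence[LocusDef]] = None,
    strict: bool = True,
) -> SSRDataset:
    """Read a haploid SSR genotype table into an :class:`SSRDataset`.

    When ``locus_defs`` is given, every non-reserved column must match a
    defined locus (error under ``strict``, warning otherwise); without it the
    loci are inferred from the header with mononucleotide defaults.
    """

    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = list(df.columns)
    for col in _RESERVED:
        if col not in cols:
            raise ValueError(f"genotype table missing required column {col!r}")
    meta_cols = [c for c in cols if c in _RESERVED + ("habitat",)]
    locus_cols = [c for c in cols if c not in meta_cols]

    if locus_defs is not None:
        known = {l.locus_id: l for l in locus_defs}
        unknown = [c for c in locus_cols if c not in known]
        if unknown:
            msg = f"unknown locus columns {unknown} not in locus definitions"
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
            locus_cols = [c for c in locus_cols if c in known]
        loci = [known[c] for c in locus_cols]
    else:
        loci = [LocusDef(c) for c in locus_cols]

    seen: set = set()
    isolates = []
    for _, row in df.iterrows():
        iid = str(row["isolate_id"]).strip()
        if iid in seen:
            raise ValueError(f"duplicate isolate_id {iid!r}")
        seen.add(iid)
        alleles = {c: _parse_allele(row[c], iid, c) for c in locus_cols}
        isolates.append(
            IsolateRecord(
                isolate_id=iid,
                region=str(row["region"]).strip(),
                population=str(row["population"]).strip(),
                habitat=(str(row["habitat"]).strip() or None) if "habitat" in df.columns else None,
                alleles=alleles,
            )
        )
    return SSRDataset(isolates=isolates, loci=loci)


def read_marker_table(path: str, panel: MarkerPanel = DEFAULT_PANEL) -> List[AlkaloidProfile]:
    """Read a per-isolate alkaloid/mating-type marker table.

    Cells are ``1/0/psi/nt`` with synonyms (``+``, ``-``, ``ψ``, ``NA``);
    mating type is ``A``, ``B`` or ``ND``. ``psi`` is only legal for idtF.
    """

    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("marker table %s is empty", path)
        return []
    for col in _RESERVED:
        if col not in df.columns:
            raise ValueError(f"marker table missing required column {col!r}")
    marker_cols = [
        c for c in df.columns if c not in _RESERVED + ("habitat", "mating_type")
    ]
    unknown = [c for c in marker_cols if c not in panel.all_markers]
    if unknown:
        raise ValueError(f"unknown marker columns {unknown}")

    profiles = []
    for _, row in df.iterrows():
        states = {}
        for marker in marker_cols:
            state = parse_marker_state(row[marker])
            if state is PSEUDOGENE and marker != "idtF":
                raise ValueError(
                    f"pseudogene state only legal for idtF, found on {marker!r} "
                    f"(isolate {row['isolate_id']!r})"
                )
            states[marker] = state
        profiles.append(
            AlkaloidProfile(
                isolate_id=str(row["isolate_id"]).strip(),
                region=str(row["region"]).strip(),
                population=str(row["population"]).strip(),
                states=states,
                mating_type=parse_mating_type(row.get("mating_type", "ND")),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class ExcludedRecord:
    isolate_id: str
    reason: str


def filter_multiallelic(
    raw_records: Sequence[IsolateRecord], loci: Sequence[LocusDef]
) -> Tuple[SSRDataset, List[ExcludedRecord]]:
    """Drop isolates showing more than one allele at any locus.

    A haploid genome yields one allele per locus; multiple peaks indicate a
    multi-strain infection or a somatic hybrid, and such samples are excluded
    from all analyses (exclusion is logged, not an error). Raw records may
    carry lists/tuples of alleles per locus.
    """

    kept, excluded = [], []
    for rec in raw_records:
        bad_loci = [
            locus
            for locus, value in rec.alleles.items()
            if isinstance(value, (list, tuple, set)) and len(set(value)) > 1
        ]
        if bad_loci:
            reason = f"multiple alleles at loci {sorted(bad_loci)}"
            excluded.append(ExcludedRecord(rec.isolate_id, reason))
            logger.info("excluded isolate %s: %s", rec.isolate_id, reason)
            continue
        alleles = {
            locus: (next(iter(value)) if isinstance(value, (list, tuple, set)) else value)
            for locus, value in rec.alleles.items()
        }
        kept.append(
            IsolateRecord(
                isolate_id=rec.isolate_id,
                region=rec.region,
                population=rec.population,
                habitat=rec.habitat,
                alleles=alleles,
                flags=set(rec.flags),
            )
        )
    return SSRDataset(isolates=kept, loci=list(loci)), excluded


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    import enum

    import numpy as np

    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(result, path: str, format: str = "csv") -> str:
    """Write a result object to ``path``.

    Tabular results (DataFrames, dataclasses, dicts) support csv/tsv/json;
    distance matrices additionally support ``square_csv`` and ``phylip``;
    MSN graphs support ``edgelist`` (TSV) and ``graphml``. Round-trip safe
    for tabular formats.
    """

    from .distance import DistanceMatrix, MSNGraph

    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)

    if isinstance(result, DistanceMatrix):
        if format in {"csv", "square_csv"}:
            df = pd.DataFrame(result.d, index=result.ids, columns=result.ids)
            df.to_csv(path)
        elif format == "phylip":
            with open(path, "w") as fh:
                fh.write(f"{len(result.ids)}\n")
                for i, name in enumerate(result.ids):
                    row = " ".join(f"{v:.6f}" for v in result.d[i])
                    fh.write(f"{name} {row}\n")
        else:
            raise ValueError(f"unsupported distance-matrix format {format!r}")
        return path

    if isinstance(result, MSNGraph):
        import networkx as nx

        if format == "graphml":
            g = result.graph.copy()
            for _, attrs in g.nodes(data=True):
                for key, value in list(attrs.items()):
                    if isinstance(value, dict):  # GraphML holds scalars only
                        attrs[key] = ";".join(f"{k}:{v}" for k, v in sorted(value.items()))
            nx.write_graphml(g, path)
        elif format in {"edgelist", "tsv"}:
            rows = [
                {"u": u, "v": v, "distance": d["distance"], "co_minimal": d["co_minimal"]}
                for u, v, d in result.graph.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unsupported MSN format {format!r}")
        return path

    if isinstance(result, pd.DataFrame):
        if format == "csv":
            result.to_csv(path, index=False)
        elif format == "tsv":
            result.to_csv(path, sep="\t", index=False)
        elif format == "json":
            result.to_json(path, orient="records", indent=1)
        else:
            raise ValueError(f"unsupported DataFrame format {format!r}")
        return path

    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(result), fh, indent=1, default=str)
        return path
    if format in {"csv", "tsv"}:
        payload = _to_jsonable(result)
        if isinstance(payload, dict):
            payload = [payload]
        pd.DataFrame(payload).to_csv(path, sep="," if format == "csv" else "\t", index=False)
        return path
    raise ValueError(f"unsupported format {format!r} for {type(result).__name__}")


def read_distance_matrix(path: str):
    from .distance import DistanceMatrix
    import numpy as np

    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(ids=[str(i) for i in df.index], d=df.to_numpy(dtype=float), metric_tag="loaded")
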