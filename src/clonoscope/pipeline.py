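"""One-shot orchestration: reproduce the full analysis from input tables or
from simulation, writing every summary table plus a manifest and run log."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .amova import amova, pairwise_differentiation
from .chemotype import chemotype_report, mating_summary, predict_chemotype, assign_amlg
from .clonal import assign_mlg, clone_correct, rarefy_groups
from .distance import bruvo_distance, build_msn, mismatch_distance, pcoa
from .diversity import allele_frequencies, diversity_summary
from .io import read_locus_defs, read_marker_table, read_ssr_table, write_results
from .linkage import index_of_association
from .simulate import SimulationParams, simulate

logger = logging.getLogger("clonoscope")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Every stochastic stage receives a child seed derived reproducibly from
    ``seed`` via a seed sequence, so reruns with the same config reproduce
    every permutation p-value exactly.
    """

    output_dir: str = "clonoscope_out"
    ssr_table: Optional[str] = None
    locus_table: Optional[str] = None
    marker_table: Optional[str] = None
    simulate: Optional[dict] = None  # SimulationParams overrides
    n_perm: int = 999
    seed: int = 1
    clone_correct_level: str = "region"
    rarefaction_depth: Optional[int] = None  # None = auto
    rule_set: str = "table_consistent"
    min_mlg: int = 5
    pairwise_min_n: int = 5
    skip: List[str] = field(default_factory=list)  # e.g. ["ssr"], ["markers"]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Run every enabled stage; returns the manifest (stage -> output path).

    Any stage failure aborts with the stage name and cause; outputs written
    before the failure are retained and the MANIFEST marks completeness.
    """

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: Dict[str, str] = {"_version": __version__, "_seed": str(config.seed)}
    seeds = _child_seeds(config.seed, 8)
    current_stage = "setup"

    def save(stage: str, obj, name: str, fmt: str = "csv") -> None:
        path = os.path.join(out, name)
        write_results(obj, path, fmt)
        manifest[stage] = path

    try:
        dataset = None
        profiles = None
        current_stage = "input"
        if config.simulate is not None:
            params = SimulationParams(**{**config.simulate, "seed": seeds[0]})
            dataset, profiles, _ = simulate(params)
            logger.info("simulated %d isolates under seed %d", len(dataset), seeds[0])
        else:
            if config.ssr_table and "ssr" not in config.skip:
                locus_defs = read_locus_defs(config.locus_table) if config.locus_table else None
                dataset = read_ssr_table(config.ssr_table, locus_defs)
            if config.marker_table and "markers" not in config.skip:
                profiles = read_marker_table(config.marker_table)

        if dataset is not None and "ssr" not in config.skip:
            current_stage = "mlg"
            mlg = assign_mlg(dataset)
            pop_of = {r.isolate_id: r.population for r in dataset.isolates}
            region_of_iso = {r.isolate_id: r.region for r in dataset.isolates}
            membership = pd.DataFrame(
                {
                    "isolate_id": list(mlg.assignment),
                    "mlg": [mlg.assignment[i] for i in mlg.assignment],
                    "population": [pop_of[i] for i in mlg.assignment],
                    "region": [region_of_iso[i] for i in mlg.assignment],
                }
            )
            save("mlg", membership, "mlg_membership.csv")

            current_stage = "rarefaction"
            rar = rarefy_groups(mlg, pop_of, depth=config.rarefaction_depth)
            save("rarefaction", pd.DataFrame([dataclasses.asdict(r) for r in rar]),
                 "rarefaction.csv")

            current_stage = "diversity"
            rows = []
            for group_by in ("population", "region", "total"):
                freq = allele_frequencies(dataset, group_by)
                for s in diversity_summary(freq):
                    rows.append({"group_by": group_by, **dataclasses.asdict(s),
                                 "clone_corrected": False})
                cc = clone_correct(dataset, level="region" if group_by != "population" else "population")
                for s in diversity_summary(allele_frequencies(cc, group_by)):
                    rows.append({"group_by": group_by, **dataclasses.asdict(s),
                                 "clone_corrected": True})
            save("diversity", pd.DataFrame(rows), "diversity.csv")

            current_stage = "linkage"
            link_rows = []
            for region in dataset.regions():
                res = index_of_association(
                    dataset.subset_by(region=region),
                    n_perm=config.n_perm, seed=seeds[1],
                    clone_correct_level=config.clone_correct_level,
                    min_mlg=config.min_mlg, group_id=region,
                )
                link_rows.append(dataclasses.asdict(res))
            res = index_of_association(
                dataset, n_perm=config.n_perm, seed=seeds[2],
                clone_correct_level="total", min_mlg=config.min_mlg, group_id="total",
            )
            link_rows.append(dataclasses.asdict(res))
            save("linkage", pd.DataFrame(link_rows), "linkage.csv")

            current_stage = "amova"
            dm = mismatch_distance(dataset)
            region_of_pop = {r.population: r.region for r in dataset.isolates}
            res = amova(dm, pop_of, region_of_pop, n_perm=config.n_perm, seed=seeds[3])
            save("amova", res, "amova.json", "json")

            current_stage = "pairwise"
            pw = pairwise_differentiation(
                dm, pop_of, statistic="Fst", n_perm=config.n_perm,
                seed=seeds[4], min_n=config.pairwise_min_n,
            )
            pw_df = pd.DataFrame(pw.values, index=pw.unit_ids, columns=pw.unit_ids)
            path = os.path.join(out, "pairwise_fst.csv")
            pw_df.to_csv(path)
            manifest["pairwise"] = path

            current_stage = "msn"
            reps = mlg.representative_ids()
            bruvo = bruvo_distance(dataset.subset(reps))
            rep_to_label = {mlg.members[l][0]: l for l in mlg.labels}
            bruvo.ids = [rep_to_label[i] for i in bruvo.ids]
            node_pops = mlg.counts_by(pop_of)
            msn = build_msn(mlg, bruvo, node_populations=node_pops)
            save("msn", msn, "msn.graphml", "graphml")

            current_stage = "pcoa"
            coords = pcoa(dm)
            k = coords.coordinates.shape[1]
            pcoa_df = pd.DataFrame(
                coords.coordinates, columns=[f"axis{i + 1}" for i in range(k)]
            )
            pcoa_df.insert(0, "isolate_id", coords.ids)
            save("pcoa", pcoa_df, "pcoa_coordinates.csv")
            save("pcoa_eig", pd.DataFrame({
                "eigenvalue": coords.eigenvalues[: len(coords.percent_explained)],
                "percent_explained": coords.percent_explained,
            }), "pcoa_eigenvalues.csv")

        if profiles is not None and "markers" not in config.skip:
            current_stage = "chemotype"
            preds = [predict_chemotype(p, config.rule_set) for p in profiles]
            per_isolate = pd.DataFrame(
                {
                    "isolate_id": [p.isolate_id for p in profiles],
                    "region": [p.region for p in profiles],
                    "population": [p.population for p in profiles],
                    "chemotype": [pr.label for pr in preds],
                }
            )
            save("chemotype_per_isolate", per_isolate, "chemotype_predictions.csv")
            report = chemotype_report(profiles, preds, group_by="region")
            save("chemotype_products", report.product_counts, "chemotype_products.csv")
            save("chemotype_labels", report.label_counts, "chemotype_labels.csv")
            amlg = assign_amlg(profiles)
            save("amlg", pd.DataFrame({
                "isolate_id": list(amlg.assignment),
                "amlg": list(amlg.assignment.values()),
            }), "amlg_membership.csv")

            current_stage = "mating"
            summaries = mating_summary(profiles, group_by="region")
            save("mating", pd.DataFrame([
                {"group": s.group_id, "n_A": s.n_a, "n_B": s.n_b, "n_ND": s.n_nd,
                 "ratio_AB": s.ratio_ab if s.ratio_ab is not None else "NC"}
                for s in summaries
            ]), "mating.csv")

        manifest["_complete"] = "true"
    except Exception as exc:
        manifest["_complete"] = "false"
        manifest["_failed_stage"] = current_stage
        with open(os.path.join(out, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(os.path.join(out, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
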