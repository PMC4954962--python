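"""End-to-end orchestration: simulate -> quantify -> call-hits -> enrich ->
network -> growth, from one TOML config, with a machine-readable summary."""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from inclusion_screen import enrichment, growth, network, quantify, screen_stats, synthetic

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "output_dir": "pipeline_out",
    "simulate": {
        "enabled": True,
        "seed": 0,
        "n_decreased": 3,
        "n_increased": 1,
        "n_confounded": 1,
        "n_null": 3,
        "replicates": 3,
        "wt_inclusion_prob": 0.4,
        "noise_sd": 10.0,
        "cell_intensity_cv": 0.1,
        "cells_per_image": [40, 80],
        "image_shape": [256, 256],
    },
    "quantify": {
        "cell_delta": 300.0,
        "inclusion_delta": 400.0,
        "min_cells_for_scoring": 20,
        "background_method": "tile_percentile",
    },
    "hits": {
        "wt_strain": "WT",
        "alpha": 0.05,
        "min_effect": 25.0,
        "effect_mode": "relative_to_wt",
    },
    "enrich": {"correction": "bonferroni", "min_term_hits": 2, "alpha": 0.05},
    "network": {},
    "growth": {"window_points": 9, "blank": 0.0},
}


def load_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _default_strains(sim: dict) -> list[synthetic.StrainSpec]:
    wt_p = sim["wt_inclusion_prob"]
    strains = [
        synthetic.StrainSpec("WT", "HIS3", construct="dsRed_SY1", true_inclusion_prob=wt_p)
    ]
    for i in range(sim["n_decreased"]):
        strains.append(
            synthetic.StrainSpec(
                f"dec{i + 1}", f"GDEC{i + 1}", construct="dsRed_SY1",
                true_inclusion_prob=wt_p * 0.25,
            )
        )
    for i in range(sim["n_increased"]):
        strains.append(
            synthetic.StrainSpec(
                f"inc{i + 1}", f"GINC{i + 1}", construct="dsRed_SY1",
                true_inclusion_prob=min(1.0, wt_p * 2.0),
            )
        )
    for i in range(sim["n_confounded"]):
        strains.append(
            synthetic.StrainSpec(
                f"conf{i + 1}", f"GCONF{i + 1}", construct="dsRed_SY1",
                true_inclusion_prob=wt_p * 0.25, true_expression_scale=0.6,
            )
        )
    for i in range(sim["n_null"]):
        strains.append(
            synthetic.StrainSpec(
                f"null{i + 1}", f"GNULL{i + 1}", construct="dsRed_SY1",
                true_inclusion_prob=wt_p,
            )
        )
    return strains


def stage_simulate(config: dict, out: Path) -> dict:
    sim = config["simulate"]
    seed = sim["seed"]
    strains = _default_strains(sim)
    cfg = synthetic.ImagingConfig(
        image_shape=tuple(sim["image_shape"]),
        cells_per_image=tuple(sim["cells_per_image"]),
        noise_sd=sim["noise_sd"],
        cell_intensity_cv=sim.get("cell_intensity_cv", 0.1),
    )
    images, truth = synthetic.generate_plate_images(
        strains, cfg, replicates=sim["replicates"], seed=seed
    )
    synthetic.write_plate(images, truth, out / "simulated")

    # annotation + interaction fixtures over the simulated gene ids
    genes = sorted({s.gene_id for s in strains})
    universe = genes + [f"GBG{i:04d}" for i in range(200)]
    dec_genes = [s.gene_id for s in strains if s.strain_id.startswith("dec")]
    annotation = synthetic.generate_annotation(
        universe,
        term_sizes={"GO:PLANT": max(4, len(dec_genes) + 2), "GO:OTHER1": 20, "GO:OTHER2": 35},
        planted=("GO:PLANT", len(dec_genes)),
        hits=dec_genes,
        seed=seed,
    )
    annotation.to_tsv(out / "simulated" / "annotation.tsv")
    pd.Series(universe, name="gene").to_csv(
        out / "simulated" / "universe.tsv", sep="\t", index=False
    )
    edges = synthetic.generate_interactions(
        dec_genes if len(dec_genes) >= 2 else genes,
        modules=[dec_genes] if len(dec_genes) >= 2 else [],
        extra_genetic_edges=2,
        seed=seed,
    )
    edges.to_csv(out / "simulated" / "edges.tsv", sep="\t", index=False)

    growth_strains = []
    for strain in strains[:3]:
        slow = 0.6 if strain.strain_id != "WT" else 0.2
        growth_strains.append(
            synthetic.StrainSpec(
                strain.strain_id, strain.gene_id, construct="dsRed_SY1",
                true_generation_time_h=2.0 + slow,
            )
        )
        growth_strains.append(
            synthetic.StrainSpec(
                strain.strain_id, strain.gene_id, construct="dsRed_only",
                true_generation_time_h=2.0,
            )
        )
    curves = synthetic.generate_growth_curves(growth_strains, noise_sd=0.005, seed=seed)
    od_frame, od_map = synthetic.growth_frame(curves)
    od_frame.to_csv(out / "simulated" / "growth.csv", index=False)
    od_map.to_csv(out / "simulated" / "growth_platemap.csv", index=False)

    config.setdefault("paths", {})
    config["paths"].update(
        {
            "images": str(out / "simulated" / "images"),
            "platemap": str(out / "simulated" / "platemap.csv"),
            "annotation": str(out / "simulated" / "annotation.tsv"),
            "universe": str(out / "simulated" / "universe.tsv"),
            "edges": str(out / "simulated" / "edges.tsv"),
            "growth": str(out / "simulated" / "growth.csv"),
            "growth_platemap": str(out / "simulated" / "growth_platemap.csv"),
        }
    )
    return {"n_strains": len(strains), "n_images": len(images)}


def stage_quantify(config: dict, out: Path) -> dict:
    paths = config["paths"]
    q = config["quantify"]
    images = quantify.load_plate(paths["images"], paths["platemap"])
    params = quantify.SegmentationParams(
        cell_delta=q["cell_delta"],
        inclusion_delta=q["inclusion_delta"],
        background_method=q["background_method"],
    )
    cells, wells = quantify.quantify_plate(
        images, params, min_cells_for_scoring=q["min_cells_for_scoring"]
    )
    # carry gene ids through for enrichment
    pm = pd.read_csv(paths["platemap"])
    gene_map = dict(zip(pm["strain_id"].astype(str), pm["gene_id"].astype(str)))
    wells["gene_id"] = wells["strain_id"].map(gene_map)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    wells.to_csv(out / "wells.tsv", sep="\t", index=False)
    return {"n_cells": len(cells), "n_wells": len(wells)}


def stage_call_hits(config: dict, out: Path) -> dict:
    h = config["hits"]
    wells = pd.read_csv(out / "wells.tsv", sep="\t")
    phenos = screen_stats.phenotypes_from_wells(wells)
    wt_strain = h["wt_strain"]
    if wt_strain not in phenos:
        raise ValueError(f"wild-type strain {wt_strain!r} not in wells table")
    wt = phenos.pop(wt_strain)
    criteria = screen_stats.HitCriteria(
        alpha_inclusion=h["alpha"],
        min_effect=h["min_effect"],
        effect_mode=h["effect_mode"],
        alpha_intensity=h["alpha"],
    )
    calls = screen_stats.call_hits(list(phenos.values()), wt, criteria)
    frame = screen_stats.hits_frame(calls)
    frame["gene_id"] = frame["strain_id"].map(
        {p.strain_id: p.gene_id for p in phenos.values()}
    )
    frame.to_csv(out / "hits.tsv", sep="\t", index=False)
    frame[frame["category"] == "expression_confounded"].to_csv(
        out / "confounded.tsv", sep="\t", index=False
    )
    counts = frame["category"].value_counts().to_dict()
    counts = {cat: int(counts.get(cat, 0)) for cat in screen_stats.CATEGORIES}
    return {
        "category_counts": counts,
        "wt_pct_mean": float(wt.pct_inclusion.mean()),
        "wt_replicates": int(wt.n_replicates),
    }


def _hit_genes(out: Path) -> set[str]:
    frame = pd.read_csv(out / "hits.tsv", sep="\t")
    mask = frame["category"].isin(["decreased", "increased"])
    return set(frame.loc[mask, "gene_id"].astype(str))


def stage_enrich(config: dict, out: Path) -> dict:
    paths = config["paths"]
    e = config["enrich"]
    universe = set(
        pd.read_csv(paths["universe"], sep="\t")["gene"].astype(str)
    )
    annotation = enrichment.AnnotationSet.from_tsv(paths["annotation"], universe)
    hits = _hit_genes(out)
    table = enrichment.enrich(
        hits,
        annotation,
        min_term_hits=e["min_term_hits"],
        correction=e["correction"],
        alpha=e["alpha"],
    )
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {
        "n_terms": int(len(table)),
        "significant_terms": table.loc[table["significant"], "term"].tolist(),
    }


def stage_network(config: dict, out: Path) -> dict:
    paths = config["paths"]
    edges = network.load_edges(paths["edges"])
    hits = _hit_genes(out)
    net = network.build_hit_network(hits, edges)
    network.write_graphml(net, out / "network.graphml")
    network.write_sif(net, out / "network.sif")
    network.modules_frame(net).to_csv(out / "modules.tsv", sep="\t", index=False)
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "module_sizes": [len(m) for m in net.modules],
    }


def stage_growth(config: dict, out: Path) -> dict:
    paths = config["paths"]
    g = config["growth"]
    curves = growth.read_growth_csv(paths["growth"], paths["growth_platemap"])
    gt_kwargs = {"window_points": g["window_points"], "blank": g["blank"]}
    growth.generation_times_frame(curves, **gt_kwargs).to_csv(
        out / "generation_times.tsv", sep="\t", index=False
    )
    wt_strain = config["hits"]["wt_strain"]
    tox = growth.toxicity_frame(curves, wt_strain=wt_strain, **gt_kwargs)
    tox.to_csv(out / "toxicity.tsv", sep="\t", index=False)
    return {
        "significant_toxicity_strains": tox.loc[tox["significant"], "strain_id"].tolist()
    }


STAGES = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "call-hits": stage_call_hits,
    "enrich": stage_enrich,
    "network": stage_network,
    "growth": stage_growth,
}


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order, writing summary.json at the end.

    Any stage failure raises StageError naming the stage; outputs written
    before the failure are retained.
    """
    out = Path(config.get("output_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)
    order = [s for s in STAGES if stages is None or s in stages]
    if not config.get("simulate", {}).get("enabled", True):
        order = [s for s in order if s != "simulate"]
    summary: dict = {"stages": {}, "config": config}
    try:
        for name in order:
            log.info("running stage %s", name)
            try:
                summary["stages"][name] = STAGES[name](config, out)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        summary["input_hashes"] = {
            key: _sha256(Path(p))
            for key, p in config.get("paths", {}).items()
            if Path(p).is_file()
        }
    finally:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        logging.getLogger().removeHandler(handler)
    return summary
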