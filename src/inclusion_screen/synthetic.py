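"""Synthetic screen fixtures with planted ground truth.

Generates fluorescence plate images (yeast-sized discs over a vignetted
background, diffuse vs punctate phenotype per cell), growth curves,
gene-term annotation tables, and interaction edge lists — all deterministic
in their seed, so every downstream stage can be validated against known
truth without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from inclusion_screen.enrichment import AnnotationSet
from inclusion_screen.growth import GrowthCurve
from inclusion_screen.quantify import FluorImage

log = logging.getLogger(__name__)

_CONSTRUCTS = ("dsRed_SY1", "dsRed_only")


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth parameters of one arrayed strain."""

    strain_id: str
    gene_id: str
    essential: bool = False
    construct: str = "dsRed_SY1"
    true_inclusion_prob: float = 0.0
    true_expression_scale: float = 1.0
    true_generation_time_h: float = 2.0

    def __post_init__(self) -> None:
        if self.construct not in _CONSTRUCTS:
            raise ValueError(f"construct must be one of {_CONSTRUCTS}")
        if not 0.0 <= self.true_inclusion_prob <= 1.0:
            raise ValueError("true_inclusion_prob must be in [0, 1]")
        if self.construct == "dsRed_only" and self.true_inclusion_prob != 0.0:
            raise ValueError("dsRed_only strains cannot form inclusions")
        if self.true_expression_scale <= 0:
            raise ValueError("true_expression_scale must be > 0")
        if self.true_generation_time_h <= 0:
            raise ValueError("true_generation_time_h must be > 0")


@dataclass
class ImagingConfig:
    """Rendering parameters for synthetic acquisitions.

    All intensities are grayscale units on the 16-bit scale; pixel values
    are clipped to [0, 65535] after noise.
    """

    image_shape: tuple[int, int] = (256, 256)
    bit_depth: int = 16
    background_level: float = 200.0
    vignette_amplitude: float = 60.0
    cells_per_image: tuple[int, int] = (40, 80)
    cell_radius_px: tuple[int, int] = (7, 10)
    diffuse_signal_delta: float = 500.0
    inclusion_delta: float = 800.0
    inclusions_per_cell: tuple[int, int] = (1, 3)
    inclusion_radius_px: tuple[int, int] = (1, 2)
    noise_sd: float = 0.0
    cell_intensity_cv: float = 0.0  # per-cell spread of the diffuse signal
    fields_per_well: int = 1

    def __post_init__(self) -> None:
        for name in (
            "background_level",
            "vignette_amplitude",
            "diffuse_signal_delta",
            "inclusion_delta",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit rendering is supported")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        for name in ("cells_per_image", "cell_radius_px", "inclusions_per_cell", "inclusion_radius_px"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be an increasing range of positive ints")


@dataclass
class GroundTruth:
    """Planted truth for a generated plate.

    ``cells``: one row per rendered cell (image, label, center_row,
    center_col, radius, has_inclusion).  ``wells``: per-well summary with
    the exact flagged-cell fraction.  ``inclusion_masks``/``cell_labels``:
    per-image pixel-level truth.
    """

    cells: pd.DataFrame
    wells: dict[str, dict]
    inclusion_masks: dict[str, np.ndarray] = field(default_factory=dict)
    cell_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def well_fraction(self, well: str) -> float:
        return self.wells[well]["true_fraction"]


def _vignette(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Radially symmetric quadratic falloff, brightest at the image center."""
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    r2 = (rr - (nr - 1) / 2.0) ** 2 + (cc - (nc - 1) / 2.0) ** 2
    rmax2 = ((nr - 1) / 2.0) ** 2 + ((nc - 1) / 2.0) ** 2
    return amplitude * (1.0 - r2 / rmax2)


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_cells: int,
    radius_range: tuple[int, int],
    max_tries: int = 200,
) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping discs fully inside the frame.

    Returns (row, col, radius) triples; gives up on a cell after
    ``max_tries`` placements, so crowded configurations may come back with
    fewer cells (logged by the caller).
    """
    nr, nc = shape
    placed: list[tuple[int, int, int]] = []
    for _ in range(n_cells):
        for _ in range(max_tries):
            radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
            margin = radius + 2
            if nr - margin <= margin or nc - margin <= margin:
                break
            row = int(rng.integers(margin, nr - margin))
            col = int(rng.integers(margin, nc - margin))
            ok = all(
                (row - r0) ** 2 + (col - c0) ** 2 > (radius + rad0 + 2) ** 2
                for r0, c0, rad0 in placed
            )
            if ok:
                placed.append((row, col, radius))
                break
    return placed


def _well_name(index: int) -> str:
    row = chr(ord("A") + index // 12)
    return f"{row}{index % 12 + 1:02d}"


def generate_plate_images(
    strains: list[StrainSpec],
    cfg: ImagingConfig | None = None,
    replicates: int = 1,
    seed: int = 0,
    plate: str = "plate1",
    keep_masks: bool = True,
) -> tuple[list[FluorImage], GroundTruth]:
    """Render one plate: each strain x replicate becomes a well.

    Every cell is a disc of diffuse signal ``background + vignette +
    diffuse_signal_delta * true_expression_scale``; cells drawn aggregated
    (Bernoulli ``true_inclusion_prob``) additionally carry 1+ puncta set to
    exactly ``inclusion_delta`` above the diffuse level.  Ground truth
    records every decision; identical arguments give bit-identical pixels.
    """
    cfg = cfg or ImagingConfig()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(strains) * replicates > 96:
        raise ValueError("at most 96 wells (strains x replicates) per plate")
    rng = np.random.default_rng(seed)
    vignette = _vignette(cfg.image_shape, cfg.vignette_amplitude)
    base = cfg.background_level + vignette

    nr, nc = cfg.image_shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")

    images: list[FluorImage] = []
    cell_rows: list[dict] = []
    wells: dict[str, dict] = {}
    inclusion_masks: dict[str, np.ndarray] = {}
    cell_label_maps: dict[str, np.ndarray] = {}

    well_idx = 0
    for strain in strains:
        for rep in range(replicates):
            well = _well_name(well_idx)
            well_idx += 1
            n_flagged = 0
            n_total = 0
            for fld in range(cfg.fields_per_well):
                n_request = int(
                    rng.integers(cfg.cells_per_image[0], cfg.cells_per_image[1] + 1)
                )
                placed = _place_cells(rng, cfg.image_shape, n_request, cfg.cell_radius_px)
                if len(placed) < n_request:
                    log.info(
                        "well %s field %d: placed %d of %d cells",
                        well,
                        fld,
                        len(placed),
                        n_request,
                    )
                pixels = base.copy()
                inc_mask = np.zeros(cfg.image_shape, dtype=bool)
                labels = np.zeros(cfg.image_shape, dtype=np.int32)
                diffuse = cfg.diffuse_signal_delta * strain.true_expression_scale
                image_id = f"{plate}_{well}_{fld}"
                for label, (row, col, radius) in enumerate(placed, start=1):
                    disc = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
                    diffuse_i = diffuse
                    if cfg.cell_intensity_cv > 0:
                        diffuse_i = diffuse * max(
                            0.2, rng.normal(1.0, cfg.cell_intensity_cv)
                        )
                    pixels[disc] = base[disc] + diffuse_i
                    labels[disc] = label
                    flagged = bool(rng.random() < strain.true_inclusion_prob)
                    if flagged:
                        cell_inc = np.zeros(cfg.image_shape, dtype=bool)
                        n_puncta = int(
                            rng.integers(
                                cfg.inclusions_per_cell[0],
                                cfg.inclusions_per_cell[1] + 1,
                            )
                        )
                        for _ in range(n_puncta):
                            prad = int(
                                rng.integers(
                                    cfg.inclusion_radius_px[0],
                                    cfg.inclusion_radius_px[1] + 1,
                                )
                            )
                            free = max(radius - prad - 1, 0)
                            angle = rng.uniform(0, 2 * np.pi)
                            dist = free * np.sqrt(rng.uniform())
                            prow = row + dist * np.cos(angle)
                            pcol = col + dist * np.sin(angle)
                            punct = (rr - prow) ** 2 + (cc - pcol) ** 2 <= prad**2
                            punct &= disc
                            cell_inc |= punct
                        pixels[cell_inc] = (
                            base[cell_inc] + diffuse_i + cfg.inclusion_delta
                        )
                        inc_mask |= cell_inc
                    n_total += 1
                    n_flagged += flagged
                    cell_rows.append(
                        {
                            "image": image_id,
                            "well": well,
                            "strain_id": strain.strain_id,
                            "label": label,
                            "center_row": row,
                            "center_col": col,
                            "radius": radius,
                            "has_inclusion": flagged,
                        }
                    )
                if cfg.noise_sd > 0:
                    pixels = pixels + rng.normal(0.0, cfg.noise_sd, size=pixels.shape)
                pixels = np.clip(pixels, 0.0, 2**16 - 1)
                images.append(
                    FluorImage(
                        pixels=pixels,
                        plate=plate,
                        well=well,
                        field=fld,
                        strain_id=strain.strain_id,
                        construct=strain.construct,
                    )
                )
                if keep_masks:
                    inclusion_masks[image_id] = inc_mask
                    cell_label_maps[image_id] = labels
            wells[well] = {
                "strain_id": strain.strain_id,
                "gene_id": strain.gene_id,
                "construct": strain.construct,
                "replicate": rep,
                "n_cells": n_total,
                "n_inclusion": n_flagged,
                "true_fraction": n_flagged / n_total if n_total else float("nan"),
            }

    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        wells=wells,
        inclusion_masks=inclusion_masks,
        cell_labels=cell_label_maps,
    )
    return images, truth


def platemap_frame(truth: GroundTruth, plate: str = "plate1") -> pd.DataFrame:
    """Plate-map CSV table for a generated plate."""
    rows = []
    for well, info in truth.wells.items():
        rows.append(
            {
                "plate": plate,
                "well": well,
                "strain_id": info["strain_id"],
                "gene_id": info["gene_id"],
                "construct": info["construct"],
                "replicate": info["replicate"],
            }
        )
    return pd.DataFrame(rows)


def write_plate(
    images: list[FluorImage],
    truth: GroundTruth,
    out_dir: str | Path,
    plate: str = "plate1",
) -> None:
    """Write TIFFs, plate map CSV, truth TSV and per-well JSON summary."""
    import tifffile

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img in images:
        tifffile.imwrite(
            img_dir / f"{img.image_id}.tif",
            np.round(img.pixels).astype(np.uint16),
        )
    platemap_frame(truth, plate).to_csv(out_dir / "platemap.csv", index=False)
    truth.cells.to_csv(out_dir / "truth_cells.tsv", sep="\t", index=False)
    with open(out_dir / "truth_wells.json", "w") as fh:
        json.dump(truth.wells, fh, indent=2)


# ---------------------------------------------------------------------------
# growth curves


def generate_growth_curves(
    strains: list[StrainSpec],
    sampling_interval_h: float = 0.5,
    duration_h: float = 72.0,
    lag_h: float = 2.0,
    carrying_capacity: float = 1.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    od0: float = 0.05,
    replicates: int = 3,
) -> list[GrowthCurve]:
    """Cultivation curves sampled every ``sampling_interval_h`` hours.

    The deterministic shape is a lag at ``od0`` followed by exponential
    growth capped at ``carrying_capacity``, so the exponential phase is
    exactly log2-linear with slope 1/true_generation_time_h — the doubling
    time a downstream log-linear estimator must recover.  Gaussian noise is
    added on top and the readings clipped at zero.
    """
    n_steps = duration_h / sampling_interval_h
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("duration_h must be an integer multiple of sampling_interval_h")
    rng = np.random.default_rng(seed)
    times = np.arange(round(n_steps) + 1) * sampling_interval_h
    curves: list[GrowthCurve] = []
    for strain in strains:
        g = strain.true_generation_time_h
        grown = np.where(
            times <= lag_h,
            od0,
            np.minimum(od0 * np.exp2((times - lag_h) / g), carrying_capacity),
        )
        for rep in range(replicates):
            od = grown.copy()
            if noise_sd > 0:
                od = od + rng.normal(0.0, noise_sd, size=od.shape)
            curves.append(
                GrowthCurve(
                    times=times.copy(),
                    od=np.clip(od, 0.0, None),
                    strain_id=strain.strain_id,
                    construct=strain.construct,
                    replicate=rep,
                )
            )
    return curves


def growth_frame(curves: list[GrowthCurve]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide-format OD table (time_h + one column per well) and its plate map."""
    data = {"time_h": curves[0].times}
    rows = []
    for i, curve in enumerate(curves):
        well = f"W{i + 1:03d}"
        data[well] = curve.od
        rows.append(
            {
                "well": well,
                "strain_id": curve.strain_id,
                "construct": curve.construct,
                "replicate": curve.replicate,
            }
        )
    return pd.DataFrame(data), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation and interaction fixtures


def generate_annotation(
    universe: list[str],
    term_sizes: dict[str, int],
    planted: tuple[str, int] | None = None,
    hits: list[str] | None = None,
    seed: int = 0,
) -> AnnotationSet:
    """Assign genes to terms uniformly, optionally planting an enriched term.

    ``planted=(term, overlap)`` forces that term to contain exactly
    ``overlap`` genes from ``hits`` (the designated hit list), with the
    remainder of the term drawn from outside the hit list.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    uset = set(universe)
    gene_to_terms: dict[str, set[str]] = {}
    for term, size in term_sizes.items():
        if size > len(universe):
            raise ValueError(f"term {term} larger than universe")
        if planted is not None and term == planted[0]:
            overlap = planted[1]
            if hits is None:
                raise ValueError("planted term requires a hit list")
            hit_pool = [g for g in hits if g in uset]
            if overlap > min(size, len(hit_pool)):
                raise ValueError("planted overlap exceeds term size or hit list")
            non_hits = [g for g in universe if g not in set(hits)]
            members = list(rng.choice(hit_pool, size=overlap, replace=False)) + list(
                rng.choice(non_hits, size=size - overlap, replace=False)
            )
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        for gene in members:
            gene_to_terms.setdefault(str(gene), set()).add(term)
    return AnnotationSet(gene_to_terms=gene_to_terms, universe=uset)


def generate_interactions(
    hits: list[str],
    modules: list[list[str]],
    extra_genetic_edges: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Edge table with planted physical modules plus genetic distractors.

    Each module is emitted as a randomized chain of physical edges (hence
    connected); ``extra_genetic_edges`` random hit pairs are added with
    kind "genetic" so the physical-only filter is exercised.
    """
    hit_set = set(hits)
    for module in modules:
        if not set(module) <= hit_set:
            raise ValueError("module genes must be a subset of hits")
        if len(module) < 2:
            raise ValueError("modules need at least 2 genes")
    rng = np.random.default_rng(seed)
    rows = []
    for module in modules:
        order = list(module)
        rng.shuffle(order)
        for a, b in zip(order[:-1], order[1:]):
            rows.append({"gene_a": a, "gene_b": b, "kind": "physical", "source": "planted_module"})
    n_added = 0
    attempts = 0
    while n_added < extra_genetic_edges and attempts < 100 * max(extra_genetic_edges, 1):
        attempts += 1
        a, b = rng.choice(list(hits), size=2, replace=False)
        rows.append({"gene_a": str(a), "gene_b": str(b), "kind": "genetic", "source": "distractor"})
        n_added += 1
    if extra_genetic_edges > 0 and len(hits) < 2:
        raise ValueError("genetic edges need at least 2 hit genes")
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "kind", "source"])
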