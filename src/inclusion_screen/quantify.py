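"""Intensity-threshold quantification of fluorescent inclusions.

The scoring chain mirrors a classic high-content-screening sub-program:
shade correction, background estimation, cell isolation by an intensity
difference of at least ``cell_delta`` (default 300 grayscale units) over
local background, inclusion isolation by a difference of at least
``inclusion_delta`` (default 400) over the per-cell diffuse signal, and
per-cell / per-well phenotype extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

_MAX_INTENSITY = 65535.0


@dataclass
class FluorImage:
    """A single-channel fluorescence acquisition with plate metadata.

    ``pixels`` is a rectangular 2-D float array in grayscale units
    (0..65535); metadata ties the image back to the plate map.
    """

    pixels: np.ndarray
    plate: str = ""
    well: str = ""
    field: int = 0
    strain_id: str = ""
    construct: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def image_id(self) -> str:
        return f"{self.plate}_{self.well}_{self.field}"


@dataclass
class SegmentationParams:
    """Thresholds and gates for the cell / inclusion masks.

    ``cell_delta`` and ``inclusion_delta`` are intensity *differences*
    (grayscale units), not absolute levels.  ``background_method`` selects
    how the local background map is estimated:

    - ``"tile_percentile"`` (default): low-percentile per tile, smoothly
      interpolated; robust to dense fields and fast.
    - ``"median"``: 2-D median filter of radius ``background_radius_px``.
    - ``"rolling_ball"``: morphological rolling-ball background.
    - ``"global"``: a single scalar (20th percentile of the image).
    """

    cell_delta: float = 300.0
    inclusion_delta: float = 400.0
    min_cell_area_px: int = 50
    max_cell_area_px: int = 2000
    min_inclusion_area_px: int = 2
    border_policy: str = "exclude"
    background_method: str = "tile_percentile"
    background_radius_px: int = 48

    def __post_init__(self) -> None:
        if self.cell_delta <= 0 or self.inclusion_delta <= 0:
            raise ValueError("cell_delta and inclusion_delta must be > 0")
        if self.min_cell_area_px < 1 or self.min_inclusion_area_px < 1:
            raise ValueError("minimum areas must be >= 1")
        if self.max_cell_area_px < self.min_cell_area_px:
            raise ValueError("max_cell_area_px < min_cell_area_px")
        if self.border_policy not in ("exclude", "include"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if self.background_method not in (
            "tile_percentile",
            "median",
            "rolling_ball",
            "global",
        ):
            raise ValueError(f"unknown background_method {self.background_method!r}")


@dataclass
class CellRecord:
    """Per-cell measurements from the combined cell + inclusion masks."""

    image: str
    label: int
    area_px: int
    mean_intensity: float
    inclusion_count: int
    inclusion_area_px: int
    has_inclusion: bool
    # expression proxy: mean over the cell's non-inclusion pixels, so bright
    # puncta do not couple the intensity readout to the phenotype itself
    mean_diffuse_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.has_inclusion != (self.inclusion_count >= 1):
            raise ValueError("has_inclusion must mirror inclusion_count >= 1")
        if self.inclusion_area_px > self.area_px:
            raise ValueError("inclusion area cannot exceed cell area")
        if self.mean_diffuse_intensity is None:
            self.mean_diffuse_intensity = self.mean_intensity


@dataclass
class WellPhenotype:
    """Per-well summary: cell count, % inclusion-carrying cells, intensity."""

    well: str
    strain_id: str
    construct: str
    n_cells: int
    pct_inclusion: float  # NaN when n_cells == 0
    mean_cell_intensity: float
    qc_pass: bool


# ---------------------------------------------------------------------------
# preprocessing


def _tile_stats(pixels: np.ndarray, tile: int, q: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tile percentile with tile-center coordinates (rows, cols, values)."""
    nr, nc = pixels.shape
    row_edges = np.linspace(0, nr, max(2, nr // tile + 1)).astype(int)
    col_edges = np.linspace(0, nc, max(2, nc // tile + 1)).astype(int)
    rows, cols, vals = [], [], []
    for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
        for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
            block = pixels[r0:r1, c0:c1]
            if block.size == 0:
                continue
            rows.append((r0 + r1 - 1) / 2.0)
            cols.append((c0 + c1 - 1) / 2.0)
            vals.append(np.percentile(block, q))
    return np.asarray(rows), np.asarray(cols), np.asarray(vals)


def _design(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(r), r, c, r * r, r * c, c * c])


def _poly2_surface(pixels: np.ndarray, tile: int = 32, q: float = 20.0) -> np.ndarray:
    """Least-squares quadratic background surface, robust to bright cells.

    Pass 1 fits through per-tile low percentiles to get a rough surface;
    pass 2 refits on the pixels consistent with that surface (within a
    MAD-based band), which is exact on noiseless backgrounds.
    """
    nr, nc = pixels.shape
    tile = max(4, min(tile, min(nr, nc) // 6 or 1))
    rows, cols, vals = _tile_stats(pixels, tile, q)
    # normalize coordinates for conditioning
    r = rows / max(nr - 1, 1)
    c = cols / max(nc - 1, 1)
    coef, *_ = np.linalg.lstsq(_design(r, c), vals, rcond=None)
    rr, cc = np.meshgrid(
        np.arange(nr) / max(nr - 1, 1), np.arange(nc) / max(nc - 1, 1), indexing="ij"
    )
    rough = _design(rr.ravel(), cc.ravel()) @ coef
    residual = pixels.ravel() - rough
    sigma = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    band = max(4.0 * sigma, 1e-6)
    mask = residual <= band
    if mask.sum() >= 6:
        coef, *_ = np.linalg.lstsq(
            _design(rr.ravel()[mask], cc.ravel()[mask]), pixels.ravel()[mask], rcond=None
        )
    surface = _design(rr.ravel(), cc.ravel()) @ coef
    return surface.reshape(nr, nc)


def shade_correct(
    img: FluorImage, model: str = "poly2", reference: np.ndarray | None = None
) -> FluorImage:
    """Remove the large-scale illumination trend from an image.

    ``model="poly2"`` fits a quadratic surface to robust per-tile background
    levels and subtracts its zero-mean part, so the image mean is preserved
    exactly.  ``model="flatfield_reference"`` divides by a reference flat
    field normalized to its own mean.  A degenerate (flat) fit returns the
    input unchanged.
    """
    if model == "poly2":
        surface = _poly2_surface(img.pixels)
        trend = surface - surface.mean()
        if np.ptp(trend) < 1e-9:
            log.info("shade_correct: flat fit for %s, returning input", img.image_id)
            return replace(img, pixels=img.pixels.copy())
        corrected = np.clip(img.pixels - trend, 0.0, None)
        return replace(img, pixels=corrected)
    if model == "flatfield_reference":
        if reference is None:
            raise ValueError("flatfield_reference requires a reference image")
        ref = np.asarray(reference, dtype=np.float64)
        if ref.shape != img.pixels.shape:
            raise ValueError("reference shape mismatch")
        if np.any(ref <= 0):
            raise ValueError("reference must be strictly positive")
        corrected = img.pixels * (ref.mean() / ref)
        return replace(img, pixels=corrected)
    raise ValueError(f"unknown shade model {model!r}")


def estimate_background(
    img: FluorImage, params: SegmentationParams
) -> tuple[float, np.ndarray]:
    """Estimate the non-cell background as (scalar level, per-pixel map).

    The scalar summary is the median of the map.  Raises if the image is
    saturated everywhere (unusable acquisition).
    """
    pixels = img.pixels
    if np.all(pixels >= _MAX_INTENSITY):
        raise ValueError("image saturated everywhere; acquisition unusable")

    method = params.background_method
    if method == "global":
        level = float(np.percentile(pixels, 20.0))
        bg_map = np.full_like(pixels, level)
    elif method == "tile_percentile":
        tile = max(8, int(params.background_radius_px))
        rows, cols, vals = _tile_stats(pixels, tile, 20.0)
        urows = np.unique(rows)
        ucols = np.unique(cols)
        grid = vals.reshape(len(urows), len(ucols))
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (urows, ucols), grid, bounds_error=False, fill_value=None
        )
        rr, cc = np.meshgrid(
            np.arange(pixels.shape[0]), np.arange(pixels.shape[1]), indexing="ij"
        )
        bg_map = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(pixels.shape)
    elif method == "median":
        size = 2 * int(params.background_radius_px) + 1
        bg_map = ndimage.median_filter(pixels, size=size, mode="nearest")
    elif method == "rolling_ball":
        from skimage.restoration import rolling_ball

        bg_map = rolling_ball(pixels, radius=params.background_radius_px)
    else:  # pragma: no cover - guarded by SegmentationParams
        raise ValueError(method)
    return float(np.median(bg_map)), bg_map


# ---------------------------------------------------------------------------
# segmentation


def segment_cells(
    img: FluorImage, background_map: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Label connected cellular regions by difference over local background.

    Foreground = pixels at least ``cell_delta`` above the background map;
    connected regions are gated to [min_cell_area_px, max_cell_area_px] and
    border-touching regions dropped under ``border_policy="exclude"``.
    Returns an integer label image (0 = background).
    """
    fg = (img.pixels - background_map) >= params.cell_delta
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = (areas[1:] >= params.min_cell_area_px) & (
        areas[1:] <= params.max_cell_area_px
    )
    if params.border_policy == "exclude":
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        keep[border[border > 0]] = False
    # relabel sequentially
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def segment_inclusions(
    img: FluorImage, cell_mask: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Isolate bright puncta within each cell.

    For every labeled cell the diffuse reference is estimated iteratively:
    the mean over the cell's pixels, recomputed once after excluding the
    first round of punctum candidates.  Pixels at least ``inclusion_delta``
    above the final reference and forming regions of
    ``min_inclusion_area_px`` or more are inclusion pixels.  The returned
    boolean mask is a subset of the cell mask.
    """
    out = np.zeros(cell_mask.shape, dtype=bool)
    n = int(cell_mask.max())
    if n == 0:
        return out
    structure = np.ones((3, 3), dtype=int)
    slices = ndimage.find_objects(cell_mask)
    for lbl in range(1, n + 1):
        sl = slices[lbl - 1]
        if sl is None:
            continue
        region = cell_mask[sl] == lbl
        values = img.pixels[sl]
        ref = values[region].mean()
        for _ in range(2):
            cand = region & ((values - ref) >= params.inclusion_delta)
            diffuse = region & ~cand
            if diffuse.any():
                ref = values[diffuse].mean()
        cand = region & ((values - ref) >= params.inclusion_delta)
        if not cand.any():
            continue
        cand_labels, m = ndimage.label(cand, structure=structure)
        areas = np.bincount(cand_labels.ravel())
        good = np.zeros(m + 1, dtype=bool)
        good[1:] = areas[1:] >= params.min_inclusion_area_px
        out[sl] |= good[cand_labels]
    return out


# ---------------------------------------------------------------------------
# scoring


def score_cells(
    img: FluorImage, cell_mask: np.ndarray, inclusion_mask: np.ndarray
) -> list[CellRecord]:
    """Combine cell and inclusion masks into one record per cell."""
    n = int(cell_mask.max())
    records: list[CellRecord] = []
    if n == 0:
        return records
    structure = np.ones((3, 3), dtype=int)
    slices = ndimage.find_objects(cell_mask)
    for lbl in range(1, n + 1):
        sl = slices[lbl - 1]
        if sl is None:
            continue
        region = cell_mask[sl] == lbl
        inc = inclusion_mask[sl] & region
        _, count = ndimage.label(inc, structure=structure)
        area = int(region.sum())
        inc_area = int(inc.sum())
        diffuse = region & ~inc
        values = img.pixels[sl]
        mean_all = float(values[region].mean())
        records.append(
            CellRecord(
                image=img.image_id,
                label=lbl,
                area_px=area,
                mean_intensity=mean_all,
                inclusion_count=int(count),
                inclusion_area_px=inc_area,
                has_inclusion=count >= 1,
                mean_diffuse_intensity=(
                    float(values[diffuse].mean()) if diffuse.any() else mean_all
                ),
            )
        )
    return records


def score_well(
    records: list[CellRecord],
    well: str = "",
    strain_id: str = "",
    construct: str = "",
    min_cells_for_scoring: int = 300,
    intensity_mode: str = "mean_of_means",
) -> WellPhenotype:
    """Pool cell records from one well into a phenotype.

    ``pct_inclusion`` is 100 x (cells with an inclusion) / (all cells).
    ``mean_cell_intensity`` summarizes the per-cell *diffuse* means (the
    expression-level proxy; inclusion pixels excluded so aggregation does
    not inflate it): by default the mean of per-cell means,
    ``intensity_mode="pooled"`` weights cells by area instead.  Zero cells
    yields NaN percentage and a QC failure.
    """
    n = len(records)
    if n == 0:
        return WellPhenotype(well, strain_id, construct, 0, float("nan"), float("nan"), False)
    n_inc = sum(r.has_inclusion for r in records)
    if intensity_mode == "mean_of_means":
        intensity = float(np.mean([r.mean_diffuse_intensity for r in records]))
    elif intensity_mode == "pooled":
        total = sum(r.mean_diffuse_intensity * r.area_px for r in records)
        intensity = float(total / sum(r.area_px for r in records))
    else:
        raise ValueError(f"unknown intensity_mode {intensity_mode!r}")
    return WellPhenotype(
        well=well,
        strain_id=strain_id,
        construct=construct,
        n_cells=n,
        pct_inclusion=100.0 * n_inc / n,
        mean_cell_intensity=intensity,
        qc_pass=n >= min_cells_for_scoring,
    )


# ---------------------------------------------------------------------------
# plate-level drivers and I/O


def quantify_image(
    img: FluorImage,
    params: SegmentationParams | None = None,
    shade_model: str = "poly2",
) -> list[CellRecord]:
    """Run the full per-image chain and return cell records."""
    params = params or SegmentationParams()
    corrected = shade_correct(img, model=shade_model) if shade_model else img
    _, bg_map = estimate_background(corrected, params)
    cell_mask = segment_cells(corrected, bg_map, params)
    inclusion_mask = segment_inclusions(corrected, cell_mask, params)
    return score_cells(corrected, cell_mask, inclusion_mask)


def quantify_plate(
    images: list[FluorImage],
    params: SegmentationParams | None = None,
    min_cells_for_scoring: int = 300,
    shade_model: str = "poly2",
    intensity_mode: str = "mean_of_means",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a collection of images, pooling fields per well.

    Returns (cells, wells) tables following the CellRecord / WellPhenotype
    schemas, with well rows carrying the metadata of their first image.
    """
    params = params or SegmentationParams()
    by_well: dict[str, list[CellRecord]] = {}
    meta: dict[str, FluorImage] = {}
    all_records: list[CellRecord] = []
    for img in images:
        records = quantify_image(img, params, shade_model)
        key = f"{img.plate}_{img.well}"
        by_well.setdefault(key, []).extend(records)
        meta.setdefault(key, img)
        all_records.extend(records)

    cells = pd.DataFrame([vars(r) for r in all_records])
    well_rows = []
    for key, records in by_well.items():
        img = meta[key]
        pheno = score_well(
            records,
            well=img.well,
            strain_id=img.strain_id,
            construct=img.construct,
            min_cells_for_scoring=min_cells_for_scoring,
            intensity_mode=intensity_mode,
        )
        row = vars(pheno).copy()
        row["plate"] = img.plate
        well_rows.append(row)
    wells = pd.DataFrame(well_rows)
    return cells, wells


def load_plate(images_dir: str | Path, platemap: str | Path) -> list[FluorImage]:
    """Read TIFF images listed in a plate-map CSV.

    The plate map must carry columns plate, well, strain_id, construct;
    image files are expected as ``<plate>_<well>_<field>.tif``.
    """
    import tifffile

    images_dir = Path(images_dir)
    pm = pd.read_csv(platemap)
    required = {"plate", "well", "strain_id", "construct"}
    if not required.issubset(pm.columns):
        raise ValueError(f"plate map missing columns: {sorted(required - set(pm.columns))}")
    images: list[FluorImage] = []
    for row in pm.itertuples(index=False):
        pattern = f"{row.plate}_{row.well}_*.tif"
        paths = sorted(images_dir.glob(pattern))
        if not paths:
            raise FileNotFoundError(f"no images matching {pattern} in {images_dir}")
        for path in paths:
            fld = int(path.stem.rsplit("_", 1)[1])
            images.append(
                FluorImage(
                    pixels=tifffile.imread(path).astype(np.float64),
                    plate=str(row.plate),
                    well=str(row.well),
                    field=fld,
                    strain_id=str(row.strain_id),
                    construct=str(row.construct),
                )
            )
    return images
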