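import numpy as np
import pytest

from inclusion_screen import quantify as q
from inclusion_screen import synthetic as syn


@pytest.fixture
def small_cfg() -> syn.ImagingConfig:
    """Compact rendering config used by most image tests."""
    return syn.ImagingConfig(image_shape=(160, 160), cells_per_image=(15, 25))


@pytest.fixture
def default_params() -> q.SegmentationParams:
    return q.SegmentationParams()


def disc_image(
    shape=(128, 128),
    background=200.0,
    discs=((64, 64, 10, 400.0),),
    puncta=(),
) -> q.FluorImage:
    """Hand-built image: flat background plus discs and puncta.

    ``discs``: (row, col, radius, delta-over-background) tuples.
    ``puncta``: (row, col, radius, delta-over-cell) tuples; the punctum is
    set relative to whatever value its center pixel already has.
    """
    px = np.full(shape, float(background))
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for row, col, radius, delta in discs:
        px[(rr - row) ** 2 + (cc - col) ** 2 <= radius**2] = background + delta
    for row, col, radius, delta in puncta:
        base = px[row, col]
        px[(rr - row) ** 2 + (cc - col) ** 2 <= radius**2] = base + delta
    return q.FluorImage(px)


def match_cells_to_truth(truth, img, cell_mask, records):
    """Pair detected cells with planted discs via the truth label map.

    Returns (n_truth, matched) where matched is a list of
    (truth_has_inclusion, detected_has_inclusion) pairs for 1-1 matches.
    """
    labels = truth.cell_labels[img.image_id]
    cells = truth.cells
    image_cells = cells[cells.image == img.image_id]
    matched = []
    used = set()
    for rec in records:
        mask = cell_mask == rec.label
        overlap = np.bincount(labels[mask])
        overlap[0] = 0
        if overlap.sum() == 0:
            continue
        tlab = int(overlap.argmax())
        if tlab in used:
            continue
        used.add(tlab)
        row = image_cells[image_cells.label == tlab]
        matched.append((bool(row.has_inclusion.iloc[0]), rec.has_inclusion))
    return len(image_cells), matched
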