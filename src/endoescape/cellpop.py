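"""Population-level per-cell image measurements.

Covers galectin-foci counts per cell, cytosolic dextran (vesicle-masked
median), chol-siRNA internalization (eroded-mask, best-plane mean), the
lysosomal colocalization fraction, and the flow-cytometry knockdown
normalization arithmetic. Cell, nucleus, focus, and marker-object
segmentations are accepted as label images produced elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion

from .exceptions import InputValidationError

__all__ = ["CellRecord", "count_foci_per_cell", "cytosolic_dextran",
           "sirna_internalization", "lysosomal_fraction",
           "knockdown_normalize", "records_to_frame"]

MARGIN_PX = 5   # eroded / dilated margin used by the uptake and dextran steps


@dataclass
class CellRecord:
    """Per-cell summary row."""

    cell_id: int
    foci_count: int | None = None
    cytosolic_dextran: float | None = None
    sirna_uptake: float | None = None
    lysosomal_fraction: float | None = None
    flags: tuple = ()


def count_foci_per_cell(cell_labels: np.ndarray, foci_labels: np.ndarray):
    """Assign each focus to the cell containing its centroid.

    Returns ``(counts, unassigned)`` where ``counts`` maps every cell id
    (including cells with zero foci) to its focus count and ``unassigned``
    lists foci whose centroid fell on background.
    """
    cell_labels = np.asarray(cell_labels)
    foci_labels = np.asarray(foci_labels)
    if cell_labels.shape != foci_labels.shape:
        raise InputValidationError(
            f"geometry mismatch: cells {cell_labels.shape} vs foci "
            f"{foci_labels.shape}")
    counts = {int(c): 0 for c in np.unique(cell_labels) if c != 0}
    unassigned = []
    for prop in regionprops(foci_labels):
        cy, cx = (int(round(v)) for v in prop.centroid)
        owner = int(cell_labels[cy, cx])
        if owner == 0:
            unassigned.append(int(prop.label))
        else:
            counts[owner] += 1
    return counts, unassigned


def cytosolic_dextran(image: np.ndarray, cell_labels: np.ndarray,
                      vesicle_threshold: float, control_mean: float = 0.0):
    """Median cytosolic dextran intensity per cell.

    Pixels above ``vesicle_threshold`` (dextran-containing endosomes) are
    masked together with a 5-pixel dilated margin; the median of the
    remaining cell pixels, minus the control-cell mean, is the per-cell
    value. A fully masked cell yields NaN and is flagged.
    """
    image = np.asarray(image, dtype=float)
    cell_labels = np.asarray(cell_labels)
    if image.shape != cell_labels.shape:
        raise InputValidationError("image and cell labels must share geometry")
    if vesicle_threshold <= 0:
        raise InputValidationError("vesicle_threshold must be positive")
    vesicles = dilation(image > vesicle_threshold, disk(MARGIN_PX))
    values, flagged = {}, []
    for c in (int(v) for v in np.unique(cell_labels) if v != 0):
        remaining = image[(cell_labels == c) & ~vesicles]
        if remaining.size == 0:
            values[c] = float("nan")
            flagged.append(c)
        else:
            values[c] = float(np.median(remaining)) - control_mean
    return values, flagged


def sirna_internalization(zstack: np.ndarray, cell_labels: np.ndarray):
    """Intracellular chol-siRNA per cell from a z-stack.

    The image background is the median pixel of the z-plane with the lowest
    mean intensity after masking all cells. Each cell mask is eroded by a
    5-pixel margin (excluding plasma-membrane signal); the mean of the
    remaining pixels in the z-plane where that mean is highest, minus the
    background, is the per-cell uptake. Cells emptied by the erosion are
    flagged and excluded (NaN).
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 2:
        raise InputValidationError("zstack must be 3D with >= 2 planes")
    cell_labels = np.asarray(cell_labels)
    if zstack.shape[1:] != cell_labels.shape:
        raise InputValidationError("zstack planes and cell labels must share geometry")

    outside = cell_labels == 0
    if not outside.any():
        raise InputValidationError("no background pixels left after masking cells")
    plane_means = zstack[:, outside].mean(axis=1)
    background = float(np.median(zstack[int(np.argmin(plane_means))][outside]))

    values, flagged = {}, []
    selem = disk(MARGIN_PX)
    for c in (int(v) for v in np.unique(cell_labels) if v != 0):
        eroded = erosion(cell_labels == c, selem)
        if not eroded.any():
            values[c] = float("nan")
            flagged.append(c)
            continue
        per_plane = zstack[:, eroded].mean(axis=1)
        values[c] = float(per_plane.max()) - background
    return values, flagged


def lysosomal_fraction(sirna_image: np.ndarray, lamp1_objects: np.ndarray,
                       cell_mask: np.ndarray, background: float = 0.0) -> float:
    """Fraction of a cell's siRNA intensity inside LAMP1-labeled objects.

    Background-subtracted intensities are clamped at zero before summing,
    so the result lies in [0, 1]. Returns NaN when the cell carries no
    signal above background.
    """
    sirna = np.asarray(sirna_image, dtype=float) - background
    np.clip(sirna, 0.0, None, out=sirna)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise InputValidationError("cell mask is empty")
    objects = (np.asarray(lamp1_objects) > 0) & cell_mask
    total = float(sirna[cell_mask].sum())
    if total == 0:
        return float("nan")
    return float(sirna[objects].sum() / total)


def knockdown_normalize(sample_mfi: float, wildtype_mfi: float,
                        control_sirna_mfi: float) -> float:
    """Knockdown fraction from flow-cytometry mean fluorescence intensities.

    Background fluorescence is removed by subtracting the wild-type cell
    measurement, non-specific effects by normalizing to cells treated with
    control siRNA: remaining = (sample - wt) / (control - wt), and the
    knockdown is 1 - remaining.
    """
    if control_sirna_mfi <= wildtype_mfi:
        raise InputValidationError(
            "control siRNA MFI must exceed the wild-type background "
            f"({control_sirna_mfi:g} <= {wildtype_mfi:g})")
    remaining = (sample_mfi - wildtype_mfi) / (control_sirna_mfi - wildtype_mfi)
    return 1.0 - remaining


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
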