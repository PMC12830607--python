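"""Nucleus counting and cell density per tissue compartment.

A nucleus is a connected component of the nucleus label whose centroid
lies inside the compartment; densities are reported as cells/mm**2.
Touching nuclei are not split (no watershed) — synthetic ground truth
controls overlap, and the limitation for real H&E is documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from .io_formats import (
    LABEL_EPITHELIUM,
    LABEL_NUCLEUS,
    LABEL_STROMA,
    LabeledHistologyImage,
)

logger = logging.getLogger(__name__)

COMPARTMENT_LABELS = {"stroma": LABEL_STROMA, "epithelium": LABEL_EPITHELIUM}

#: components smaller than this are discarded as segmentation noise
DEFAULT_MIN_NUCLEUS_AREA_PX = 4


@dataclass(frozen=True)
class CellDensityResult:
    """Cell count and density for one compartment of one image."""

    compartment: str
    area_mm2: float
    cell_count: int
    density_per_mm2: float


def _compartment_mask(image: LabeledHistologyImage, compartment: str) -> np.ndarray:
    """Compartment pixels including nuclei enclosed in the compartment."""
    try:
        label = COMPARTMENT_LABELS[compartment]
    except KeyError:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{sorted(COMPARTMENT_LABELS)}"
        ) from None
    mask = image.compartment_mask(label)
    if not mask.any():
        raise ValueError(f"image contains no {compartment} pixels")
    return mask


def count_nuclei(
    image: LabeledHistologyImage,
    compartment: str,
    min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
) -> int:
    """Number of nuclei whose centroid lies inside the compartment."""
    comp = _compartment_mask(image, compartment)
    nuclei = image.labels == LABEL_NUCLEUS
    if not nuclei.any():
        return 0
    # 4-connectivity: separately placed nuclei whose rasterized disks come
    # within a diagonal step stay distinct components
    lab = skmeasure.label(nuclei, connectivity=1)
    count = 0
    n_small = 0
    for region in skmeasure.regionprops(lab):
        if region.area < min_area_px:
            n_small += 1
            continue
        r, c = region.centroid
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), comp.shape[0] - 1)
        ci = min(max(ci, 0), comp.shape[1] - 1)
        if comp[ri, ci]:
            count += 1
        else:
            # centroid pixel on a compartment boundary: fall back to the
            # majority of the component's own pixels
            coords = region.coords
            if comp[coords[:, 0], coords[:, 1]].mean() > 0.5:
                count += 1
    if n_small:
        logger.info("discarded %d nucleus component(s) below %d px",
                    n_small, min_area_px)
    return count


def density(
    image: LabeledHistologyImage,
    compartment: str,
    min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
) -> CellDensityResult:
    """Cell density = nucleus count / compartment area (mm**2).

    The area is the hole-filled compartment mask, i.e. compartment pixels
    plus the nuclei embedded in them, times (um_per_px)**2 / 1e6.
    """
    comp = _compartment_mask(image, compartment)
    area_mm2 = float(comp.sum()) * image.um_per_px**2 / 1e6
    if area_mm2 <= 0:
        raise ValueError(f"{compartment} compartment has zero area")
    count = count_nuclei(image, compartment, min_area_px=min_area_px)
    return CellDensityResult(
        compartment=compartment,
        area_mm2=area_mm2,
        cell_count=count,
        density_per_mm2=count / area_mm2,
    )
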