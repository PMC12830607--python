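"""Thickness profiles from labeled histology rasters.

Replaces the manual slide-measurement step: the stroma/epithelium
interface (the basal contour) is traced and ordered, lightly smoothed to
suppress pixelation, and the epithelium is measured along the local
outward normal at regular arc-length steps — honoring curvature, so an
annulus of constant radial thickness reads as a flat profile.

Conventions: pixels are 0-based row-major; a pixel (r, c) covers the
half-open square [r - 0.5, r + 0.5) x [c - 0.5, c + 0.5), so a band that
is h pixels tall has physical thickness exactly h pixels.  Rays that
leave the image while still inside epithelium yield missing samples
(logged), never zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .io_formats import (
    LABEL_EPITHELIUM,
    LABEL_NUCLEUS,
    LABEL_STROMA,
    ConfigurationError,
    LabeledHistologyImage,
    ThicknessProfile,
)

logger = logging.getLogger(__name__)


class ExtractionError(ValueError):
    """The image does not contain a measurable epithelial band."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Sampling and smoothing choices for profile extraction.

    sampling_step_um
        Arc-length spacing of measurement sites along the basal contour.
    normal_window_um
        Half-width of the moving-average contour smoothing used to
        estimate stable local normals (raw pixel normals are too noisy).
    min_component_px
        Epithelium components smaller than this are discarded as debris.
    gap_tolerance_um
        Gaps in the epithelium along a ray (nuclei, keratin flakes) up to
        this length are bridged; thickness runs to the farthest
        epithelium pixel of the bridged run.
    """

    sampling_step_um: float = 5.0
    normal_window_um: float = 15.0
    min_component_px: int = 64
    gap_tolerance_um: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_step_um <= 0:
            raise ConfigurationError("sampling_step_um must be > 0")
        if self.normal_window_um < self.sampling_step_um:
            raise ConfigurationError(
                "normal_window_um must be >= sampling_step_um"
            )


def _filled_mask(labels: np.ndarray, value: int) -> np.ndarray:
    """Compartment mask with enclosed nuclei filled back in.

    Only nucleus pixels are reclaimed; an enclosed region of another
    tissue (e.g. the stroma disk inside an epithelial annulus) stays out.
    """
    base = labels == value
    filled = ndimage.binary_fill_holes(base)
    return base | (filled & (labels == LABEL_NUCLEUS))


def _epithelium_component(
    image: LabeledHistologyImage, min_component_px: int
) -> np.ndarray:
    epi = _filled_mask(image.labels, LABEL_EPITHELIUM)
    if not epi.any():
        raise ExtractionError("image contains no epithelium pixels")
    lab, n = skmeasure.label(epi, connectivity=2, return_num=True)
    sizes = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_component_px) + 1
    small = np.flatnonzero(sizes < min_component_px) + 1
    if small.size:
        logger.info(
            "discarded %d epithelium component(s) below %d px: sizes %s",
            small.size, min_component_px, sizes[small - 1].tolist(),
        )
    if keep.size == 0:
        raise ExtractionError(
            f"no epithelium component of at least {min_component_px} px"
        )
    if keep.size > 1:
        raise ExtractionError(
            "multiple large epithelium bands (section likely folded); "
            f"component sizes: {sorted(sizes[keep - 1].tolist(), reverse=True)}"
        )
    return lab == keep[0]


def extract_basal_contour(
    image: LabeledHistologyImage,
    config: ExtractionConfig = ExtractionConfig(),
) -> np.ndarray:
    """Ordered basal contour as an (n, 2) array of (x_um, y_um) points.

    The contour is the set of epithelium pixels 4-adjacent to stroma,
    ordered by angle around the stroma centroid (valid for the open bands
    and arcs this pipeline measures), cut at the largest angular gap so
    an open band starts at one end.
    """
    epi = _epithelium_component(image, config.min_component_px)
    stroma = _filled_mask(image.labels, LABEL_STROMA)
    if not stroma.any():
        raise ExtractionError("image contains no stroma pixels")
    stroma_neigh = ndimage.binary_dilation(
        stroma, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    interface = epi & stroma_neigh
    if not interface.any():
        raise ExtractionError("no stroma-epithelium interface found")

    rows, cols = np.nonzero(interface)
    cy, cx = ndimage.center_of_mass(stroma)
    theta = np.arctan2(rows - cy, cols - cx)
    order = np.argsort(theta, kind="stable")
    th_sorted = theta[order]
    gaps = np.diff(np.concatenate([th_sorted, [th_sorted[0] + 2 * np.pi]]))
    start = (int(np.argmax(gaps)) + 1) % order.size
    order = np.roll(order, -start)

    umpp = image.um_per_px
    pts = np.column_stack([cols[order] * umpp, rows[order] * umpp])
    return pts


def _smooth_contour(pts: np.ndarray, window_um: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    mean_step = float(np.mean(seg)) if seg.size else 1.0
    w = max(1, int(round(window_um / max(mean_step, 1e-9))))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return pts.copy()
    kernel = np.ones(w) / w
    out = np.empty_like(pts, dtype=float)
    half = w // 2
    for k in range(2):
        padded = np.pad(pts[:, k], half, mode="edge")
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


def _resample(pts: np.ndarray, step_um: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s[-1] + 1e-9, step_um)
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return np.column_stack([x, y])


def measure_thickness(
    image: LabeledHistologyImage,
    contour_um: np.ndarray,
    config: ExtractionConfig = ExtractionConfig(),
) -> ThicknessProfile:
    """Thickness along the outward basal normal at each arc-length step.

    At each sample the ray is marched in half-pixel steps; thickness is
    the distance from the stroma-side edge of the basal pixel to the far
    edge of the farthest epithelium pixel in the contiguous run (gaps up
    to ``gap_tolerance_um`` are bridged).  Positions are cumulative arc
    length in micrometres; rays leaving the image yield no sample.
    """
    if image.calibration is None:  # pragma: no cover - dataclass enforces it
        raise ConfigurationError("image calibration missing")
    umpp = image.um_per_px
    epi = _epithelium_component(image, config.min_component_px)
    h, w = epi.shape

    smoothed = _smooth_contour(np.asarray(contour_um, float),
                               config.normal_window_um)
    samples = _resample(smoothed, config.sampling_step_um)
    n = samples.shape[0]

    # outward orientation reference: away from the stroma bulk
    stroma = _filled_mask(image.labels, LABEL_STROMA)
    cy, cx = ndimage.center_of_mass(stroma)
    centroid_um = np.array([cx * umpp, cy * umpp])

    tangents = np.gradient(samples, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    norms[norms == 0] = 1.0
    tangents /= norms[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    flip = np.einsum("ij,ij->i", normals, samples - centroid_um) < 0
    normals[flip] *= -1.0

    tau = 0.5  # ray step, px
    gap_tol = config.gap_tolerance_um / umpp
    max_d = float(np.hypot(h, w))
    ds = (np.arange(int(np.ceil(max_d / tau))) + 0.5) * tau

    positions, thicknesses = [], []
    n_missing = 0
    for i in range(n):
        px, py = samples[i] / umpp  # (col, row) in px
        dx, dy = normals[i]
        first_in = last_in = None
        gap_len = 0.0
        out_of_bounds_in_band = False
        base_in = False
        c0, r0 = int(np.floor(px + 0.5)), int(np.floor(py + 0.5))
        if 0 <= r0 < h and 0 <= c0 < w:
            base_in = bool(epi[r0, c0])
        for d in ds:
            c = int(np.floor(px + dx * d + 0.5))
            r = int(np.floor(py + dy * d + 0.5))
            if not (0 <= r < h and 0 <= c < w):
                if last_in is not None and gap_len == 0.0:
                    out_of_bounds_in_band = True
                break
            if epi[r, c]:
                if first_in is None:
                    first_in = d
                last_in = d
                gap_len = 0.0
            elif first_in is not None:
                gap_len += tau
                if gap_len > gap_tol:
                    break
            elif d > 4.0:  # never entered the band near the base
                break
        if base_in and first_in is None:
            first_in = last_in = 0.0
        if last_in is None or out_of_bounds_in_band:
            n_missing += 1
            continue
        if base_in:
            t_px = last_in + tau / 2.0 + 0.5
        else:
            t_px = last_in - first_in + tau
        positions.append(i * config.sampling_step_um)
        thicknesses.append(t_px * umpp)

    if n_missing:
        logger.info("%d of %d rays yielded no sample (gaps logged)", n_missing, n)
    return ThicknessProfile(
        positions_um=np.asarray(positions, float),
        thickness_um=np.asarray(thicknesses, float),
    )


def extract_profile(
    image: LabeledHistologyImage,
    config: ExtractionConfig = ExtractionConfig(),
) -> ThicknessProfile:
    """Convenience: contour extraction followed by thickness measurement."""
    contour = extract_basal_contour(image, config)
    return measure_thickness(image, contour, config)
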