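"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Three generators, one per data stream:

* thickness profiles — control eyes are a constant baseline plus i.i.d.
  Gaussian noise; injured (study) eyes additionally carry a small number
  of smooth Gaussian-shaped "hot spots" of localized thickening or
  thinning, the signature the roughness metrics are designed to detect;
* labeled histology rasters — an epithelium band of prescribed local
  thickness over a stroma block, with nuclei placed by a hard-core
  Poisson process at a prescribed density and rasterized as disks;
* OCT series — baseline at day -1, a piecewise-linear rise to a swelling
  peak around days 7-9 and a monotone decline that does not return to
  baseline by day 28.

Every generator takes a single seed and is bit-reproducible: equal spec +
equal seed gives identical output.  Ground-truth parameters (bump
locations/amplitudes, nucleus counts, per-column thicknesses) are
returned alongside each artifact so recovery can be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DEFAULT_OCT_SCHEDULE,
    EYE_CONTROL,
    EYE_STUDY,
    GROUP_FOR_EYE,
    LABEL_BACKGROUND,
    LABEL_EPITHELIUM,
    LABEL_NUCLEUS,
    LABEL_STROMA,
    Calibration,
    LabeledHistologyImage,
    ThicknessProfile,
    write_measurements,
)

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    """A spec that cannot produce a valid artifact."""


# ---------------------------------------------------------------------------
# thickness-profile cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a synthetic thickness cohort.

    Defaults mirror the animal study being emulated: four animals, right
    eye injured and left eye control, a control epithelium near 78 um
    with roughly 190 measurements per eye, and hot spots of a few tens of
    micrometres amplitude in the injured eyes.  ``baseline_sd_um`` is the
    within-profile measurement noise; 4.6 um makes the control five-point
    rolling SD land near the observed control value (the expected sample
    SD of n=5 i.i.d. normals is c4(5) ~ 0.94 of sigma).
    """

    n_animals: int = 4
    baseline_mean_um: float = 77.7
    baseline_sd_um: float = 4.6
    n_points_per_eye: int = 190
    step_um: float = 10.0
    hotspot_count: int = 3
    hotspot_amplitude_um: float = 40.0
    hotspot_width_um: float = 40.0
    hotspot_sign: str = "both"  # "both" | "thickening" | "thinning"
    n_slides: int = 2
    floor_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points_per_eye < 5:
            raise GenerationError("n_points_per_eye must be >= 5")
        if self.hotspot_width_um <= 0 or self.step_um <= 0:
            raise GenerationError("widths and steps must be > 0")
        if self.baseline_mean_um <= self.floor_um:
            raise GenerationError("baseline must exceed the thickness floor")
        if self.hotspot_sign not in ("both", "thickening", "thinning"):
            raise GenerationError(f"unknown hotspot_sign {self.hotspot_sign!r}")
        if self.n_slides < 1:
            raise GenerationError("n_slides must be >= 1")


def _gaussian_bump(x: np.ndarray, center: float, amplitude: float,
                   width: float) -> np.ndarray:
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def generate_profile(
    spec: SyntheticCohortSpec,
    eye_role: str,
    rng: np.random.Generator | None = None,
    animal_id: str = "P1",
) -> tuple[ThicknessProfile, pd.DataFrame]:
    """One eye's profile plus the ground-truth hot-spot table.

    ``eye_role`` is ``"study"`` (hot spots injected) or ``"control"``
    (baseline + noise only).  Hot-spot centers are drawn on the sampling
    grid, away from the profile ends, so each bump's peak is sampled
    exactly.
    """
    if eye_role not in ("study", "control"):
        raise GenerationError(f"eye_role must be study or control, got {eye_role!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_points_per_eye
    positions = np.arange(n, dtype=float) * spec.step_um
    thick = np.full(n, spec.baseline_mean_um, dtype=float)
    if spec.baseline_sd_um > 0:
        thick = thick + rng.normal(0.0, spec.baseline_sd_um, size=n)

    bumps = []
    if eye_role == "study" and spec.hotspot_count > 0:
        margin = max(1, int(np.ceil(2.0 * spec.hotspot_width_um / spec.step_um)))
        margin = min(margin, (n - 1) // 2)
        lo, hi = margin, n - 1 - margin
        for _ in range(spec.hotspot_count):
            center = positions[int(rng.integers(lo, hi + 1))]
            if spec.hotspot_sign == "thickening":
                sign = 1.0
            elif spec.hotspot_sign == "thinning":
                sign = -1.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
            amp = sign * spec.hotspot_amplitude_um
            thick = thick + _gaussian_bump(positions, center, amp,
                                           spec.hotspot_width_um)
            bumps.append(
                {"center_um": center, "amplitude_um": amp,
                 "width_um": spec.hotspot_width_um}
            )

    if np.all(thick <= spec.floor_um):
        raise GenerationError(
            "generated profile is at or below the thickness floor everywhere; "
            "reduce the thinning amplitude or raise the baseline"
        )
    thick = np.clip(thick, spec.floor_um, None)

    eye = EYE_STUDY if eye_role == "study" else EYE_CONTROL
    profile = ThicknessProfile(
        positions_um=positions,
        thickness_um=thick,
        animal_id=animal_id,
        eye=eye,
        group=eye_role,
    )
    truth = pd.DataFrame(
        bumps, columns=["center_um", "amplitude_um", "width_um"]
    )
    truth.insert(0, "eye", eye)
    truth.insert(0, "animal_id", animal_id)
    return profile, truth


def generate_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full paired cohort: n_animals study (right) + control (left) eyes.

    Each eye is split into ``n_slides`` slide series (A, B, ...) with
    positions restarting at zero per slide, matching how sectioned strips
    are measured.  Returns (measurements, ground_truth); if ``out_dir``
    is given, both tables are also written there as CSV together with the
    spec parameters.
    """
    if spec.n_animals < 2:
        logger.warning(
            "n_animals=%d < 2: paired group tests downstream will fail",
            spec.n_animals,
        )
    rng = np.random.default_rng(spec.seed)
    frames, truths = [], []
    for i in range(spec.n_animals):
        animal = f"P{i + 1}"
        for role in ("study", "control"):
            profile, truth = generate_profile(spec, role, rng=rng,
                                              animal_id=animal)
            df = profile.to_frame()
            # split into slide strips; positions restart per slide
            edges = np.linspace(0, len(df), spec.n_slides + 1).astype(int)
            parts = []
            for s in range(spec.n_slides):
                part = df.iloc[edges[s]: edges[s + 1]].copy()
                part["slide_id"] = chr(ord("A") + s)
                part["position_um"] -= part["position_um"].iloc[0]
                parts.append(part)
            frames.append(pd.concat(parts, ignore_index=True))
            truths.append(truth)
    measurements = pd.concat(frames, ignore_index=True)
    nonempty = [t for t in truths if not t.empty]
    if nonempty:
        ground_truth = pd.concat(nonempty, ignore_index=True)
    else:
        ground_truth = truths[0]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measurements(measurements, out_dir / "measurements.csv")
        ground_truth.to_csv(out_dir / "ground_truth_hotspots.csv", index=False)
        pd.Series(spec.__dict__).to_json(out_dir / "cohort_spec.json")
    logger.info(
        "generated cohort: %d animals, %d rows, seed %d",
        spec.n_animals, len(measurements), spec.seed,
    )
    return measurements, ground_truth


# ---------------------------------------------------------------------------
# labeled histology rasters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Geometry and cellularity of a synthetic labeled histology raster.

    ``geometry`` is ``"flat"`` (horizontal basal contour; epithelium band
    above a stroma block) or ``"arc"`` (stroma disk of radius
    ``arc_radius_um`` centered in the image with an epithelial annulus on
    top).  ``thickness_um`` may be a scalar or a per-column array to
    imprint a known profile.  Nuclei are placed uniformly in the chosen
    compartment with a hard-core minimum separation (default: one
    diameter plus one pixel, so rasterized disks never touch) and their
    count is Poisson(density x compartment area).
    """

    width_px: int = 600
    height_px: int = 400
    um_per_px: float = 1.0
    geometry: str = "flat"
    arc_radius_um: float = 150.0
    thickness_um: float | tuple | np.ndarray = 80.0
    stroma_depth_um: float = 150.0
    nucleus_density_per_mm2: float = 0.0
    nucleus_compartment: str = "stroma"
    nucleus_radius_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise GenerationError("um_per_px must be > 0")
        if self.geometry not in ("flat", "arc"):
            raise GenerationError(f"unknown geometry {self.geometry!r}")
        if self.nucleus_density_per_mm2 < 0:
            raise GenerationError("nucleus density must be >= 0")
        tmax = float(np.max(np.asarray(self.thickness_um, dtype=float)))
        if tmax >= self.height_px * self.um_per_px:
            raise GenerationError("imprinted thickness exceeds the image height")


def _place_nuclei(
    rng: np.random.Generator,
    compartment_mask: np.ndarray,
    spec: SyntheticImageSpec,
) -> np.ndarray:
    """Hard-core uniform placement; returns (n, 2) float centers (row, col)."""
    umpp = spec.um_per_px
    area_mm2 = compartment_mask.sum() * umpp**2 / 1e6
    n = int(rng.poisson(spec.nucleus_density_per_mm2 * area_mm2))
    if n == 0:
        return np.empty((0, 2))
    r_px = spec.nucleus_radius_um / umpp
    # hard core: one diameter plus a pixel, so rasterized disks never touch
    min_sep = 2.0 * r_px + 2.0
    rows, cols = np.nonzero(compartment_mask)
    centers: list[tuple[float, float]] = []
    # occupancy grid with cell size >= min_sep: only 3x3 cells need checking
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    attempts = 0
    max_attempts = 200 * n
    while len(centers) < n and attempts < max_attempts:
        attempts += 1
        k = int(rng.integers(rows.size))
        cand = (rows[k] + rng.random() - 0.5, cols[k] + rng.random() - 0.5)
        gy, gx = int(cand[0] // min_sep), int(cand[1] // min_sep)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for c in grid.get((gy + dy, gx + dx), ()):
                    if (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 < min_sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers.append(cand)
            grid.setdefault((gy, gx), []).append(cand)
    if len(centers) < n:
        logger.warning(
            "placed only %d of %d nuclei before hitting the attempt budget "
            "(density too high for the hard-core constraint)", len(centers), n,
        )
    return np.asarray(centers, dtype=float)


def generate_histology_image(
    spec: SyntheticImageSpec,
) -> tuple[LabeledHistologyImage, dict]:
    """Labeled raster + ground truth (per-column thickness, nucleus count).

    Nucleus disks are clipped to their compartment so a disk near the
    boundary never leaks labels into the neighboring tissue; the ground
    truth count is the number of placed centers.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, umpp = spec.height_px, spec.width_px, spec.um_per_px
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)

    thick = np.asarray(spec.thickness_um, dtype=float)
    if thick.ndim == 0:
        thick = np.full(w, float(thick))
    if spec.geometry == "flat":
        if thick.size != w:
            raise GenerationError(
                f"per-column thickness length {thick.size} != width {w}"
            )
        t_px = np.maximum(np.rint(thick / umpp).astype(int), 0)
        stroma_px = int(round(spec.stroma_depth_um / umpp))
        basal_row = h - stroma_px  # first stroma row
        if basal_row <= 0 or np.any(basal_row - t_px < 0):
            raise GenerationError("band does not fit the image height")
        labels[basal_row:, :] = LABEL_STROMA
        for c in range(w):
            labels[basal_row - t_px[c]: basal_row, c] = LABEL_EPITHELIUM
        truth_thickness = t_px * umpp
    else:  # arc: stroma disk + epithelial annulus
        t0 = float(thick[0]) if thick.ndim else float(thick)
        r_in = spec.arc_radius_um / umpp
        t_px_f = float(np.mean(thick)) / umpp
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.hypot(yy - cy, xx - cx)
        labels[rr < r_in] = LABEL_STROMA
        labels[(rr >= r_in) & (rr < r_in + t_px_f)] = LABEL_EPITHELIUM
        truth_thickness = np.full(w, t_px_f * umpp)
        del t0

    nucleus_label = {
        "stroma": LABEL_STROMA, "epithelium": LABEL_EPITHELIUM
    }[spec.nucleus_compartment]
    comp_mask = labels == nucleus_label
    centers = np.empty((0, 2))
    if spec.nucleus_density_per_mm2 > 0:
        if not comp_mask.any():
            raise GenerationError(
                f"no {spec.nucleus_compartment} pixels to place nuclei in"
            )
        band = truth_thickness.min() if spec.nucleus_compartment == "epithelium" else np.inf
        if spec.nucleus_radius_um >= band / 2.0:
            logger.warning(
                "nucleus radius %.3g um >= half the band thickness; disks "
                "may overlap the compartment boundary", spec.nucleus_radius_um,
            )
        centers = _place_nuclei(rng, comp_mask, spec)
        r_px = spec.nucleus_radius_um / umpp
        for (cy_n, cx_n) in centers:
            y0, y1 = int(np.floor(cy_n - r_px)) - 1, int(np.ceil(cy_n + r_px)) + 2
            x0, x1 = int(np.floor(cx_n - r_px)) - 1, int(np.ceil(cx_n + r_px)) + 2
            y0, x0 = max(y0, 0), max(x0, 0)
            y1, x1 = min(y1, h), min(x1, w)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = (yy - cy_n) ** 2 + (xx - cx_n) ** 2 <= r_px**2
            disk &= comp_mask[y0:y1, x0:x1]  # clip to the compartment
            labels[y0:y1, x0:x1][disk] = LABEL_NUCLEUS

    image = LabeledHistologyImage(labels=labels,
                                  calibration=Calibration(um_per_px=umpp))
    truth = {
        "per_column_thickness_um": truth_thickness,
        "nucleus_count": int(len(centers)),
        "nucleus_centers_px": centers,
        "compartment_area_mm2": float(comp_mask.sum() * umpp**2 / 1e6),
        "seed": spec.seed,
    }
    return image, truth


# ---------------------------------------------------------------------------
# OCT series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticOCTSpec:
    """Post-injury corneal swelling curve for OCT pachymetry.

    Thickness starts at the regional baseline on day -1, rises linearly
    to ``peak_multiplier x baseline`` at ``peak_day`` and declines
    linearly to ``baseline + (1 - recovery_fraction) x excess`` at day
    28 — swelling that resolves only partially, as seen in the injured
    corneas.  The central cornea peaks later and swells more than the
    limbus by default.
    """

    baseline_um: float = 950.0
    peak_day: int = 8
    peak_multiplier: float = 1.5
    recovery_fraction: float = 0.8
    noise_sd_um: float = 0.0
    schedule: tuple = DEFAULT_OCT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_day not in self.schedule:
            raise GenerationError(
                f"peak_day {self.peak_day} not in the schedule {self.schedule}"
            )
        if self.peak_multiplier <= 1:
            raise GenerationError("peak_multiplier must be > 1")
        if not (0 < self.recovery_fraction < 1):
            raise GenerationError("recovery_fraction must be in (0, 1)")
        if self.baseline_um <= 0:
            raise GenerationError("baseline_um must be > 0")


def oct_curve(spec: SyntheticOCTSpec) -> pd.DataFrame:
    """Noise-free (day, thickness_um) curve for one eye."""
    days = np.asarray(sorted(spec.schedule), dtype=int)
    base = spec.baseline_um
    peak = spec.peak_multiplier * base
    end = base + (1.0 - spec.recovery_fraction) * (peak - base)
    last = int(days.max())
    vals = np.where(
        days <= spec.peak_day,
        base + (peak - base) * (days - (-1)) / (spec.peak_day + 1),
        peak + (end - peak) * (days - spec.peak_day) / (last - spec.peak_day),
    )
    return pd.DataFrame({"day": days, "thickness_um": vals})


def generate_oct_series(
    spec: SyntheticOCTSpec,
    animal_id: str = "P1",
    region: str = "central",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """OCT records for one animal/region; noise is added after the curve."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    curve = oct_curve(spec)
    vals = curve["thickness_um"].to_numpy().copy()
    if spec.noise_sd_um > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd_um, size=vals.size)
        vals = np.clip(vals, 1.0, None)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "region": region,
            "day": curve["day"],
            "thickness_um": vals,
        }
    )


def generate_oct_cohort(
    n_animals: int = 4,
    central: SyntheticOCTSpec | None = None,
    limbal: SyntheticOCTSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort OCT table for both regions; the limbus peaks earlier by default."""
    if central is None:
        central = SyntheticOCTSpec(baseline_um=950.0, peak_day=8,
                                   peak_multiplier=1.5, recovery_fraction=0.8,
                                   noise_sd_um=20.0)
    if limbal is None:
        limbal = SyntheticOCTSpec(baseline_um=850.0, peak_day=6,
                                  peak_multiplier=1.35, recovery_fraction=0.85,
                                  noise_sd_um=20.0)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_animals):
        animal = f"P{i + 1}"
        # animal-level baseline variation, then the regional curve + noise
        for region, spec in (("central", central), ("limbal", limbal)):
            jitter = rng.normal(0.0, 0.03 * spec.baseline_um)
            spec_i = replace(spec, baseline_um=spec.baseline_um + jitter,
                             seed=spec.seed)
            frames.append(
                generate_oct_series(spec_i, animal_id=animal, region=region,
                                    rng=rng)
            )
    return pd.concat(frames, ignore_index=True)
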