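"""Readers and writers for the pipeline's file formats.

All unit conventions live here: thickness and position are micrometres,
areas are mm**2, densities are cells/mm**2.  Measurement tables are plain
UTF-8 CSV with a header row; label masks are single-channel integer TIFF
or PNG; reports are CSV or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A required option or column is missing or inconsistent."""


class FormatError(ValueError):
    """A file's content violates the declared format contract."""


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

#: study design: the right eye is the injured (study) eye, the left the control
EYE_STUDY = "right"
EYE_CONTROL = "left"
EYES = (EYE_STUDY, EYE_CONTROL)
GROUPS = ("study", "control")
REGIONS = ("central", "limbal", "unspecified")
GROUP_FOR_EYE = {EYE_STUDY: "study", EYE_CONTROL: "control"}

#: label values in a labeled histology raster
LABEL_BACKGROUND = 0
LABEL_STROMA = 1
LABEL_EPITHELIUM = 2
LABEL_NUCLEUS = 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_STROMA, LABEL_EPITHELIUM, LABEL_NUCLEUS)

#: canonical measurement-table columns, also the default CSV header
MEASUREMENT_COLUMNS = (
    "animal_id",
    "eye",
    "group",
    "region",
    "slide_id",
    "position_um",
    "thickness_um",
)

#: OCT follow-up schedule; day -1 is the pre-procedure baseline, day 0 is
#: immediately after epithelial removal
DEFAULT_OCT_SCHEDULE = (-1, 0, 5, 6, 7, 8, 9, 10, 11, 17, 23, 28)
OCT_COLUMNS = ("animal_id", "region", "day", "thickness_um")


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size of a raster, micrometres per pixel."""

    um_per_px: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ConfigurationError(
                f"um_per_px must be positive and finite, got {self.um_per_px!r}"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """One epithelial thickness measurement along a sectioned profile."""

    animal_id: str
    eye: str
    group: str
    region: str
    slide_id: str
    position_um: float
    thickness_um: float


@dataclass
class ThicknessProfile:
    """Ordered thickness samples along one contour, with metadata.

    ``positions_um`` is the arc-length coordinate from the start of the
    profile; both arrays have equal length and positions are strictly
    increasing.
    """

    positions_um: np.ndarray
    thickness_um: np.ndarray
    animal_id: str = ""
    eye: str = ""
    group: str = ""
    region: str = "unspecified"
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if self.positions_um.shape != self.thickness_um.shape:
            raise ValueError("positions and thicknesses must have equal length")

    def __len__(self) -> int:
        return self.thickness_um.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "eye": self.eye,
                "group": self.group,
                "region": self.region,
                "slide_id": self.slide_id,
                "position_um": self.positions_um,
                "thickness_um": self.thickness_um,
            }
        )


@dataclass
class LabeledHistologyImage:
    """Calibrated label raster: 0=background, 1=stroma, 2=epithelium, 3=nucleus.

    Pixels are 0-based and row-major (``labels[row, col]``).
    """

    labels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"label raster must be 2-D, got {self.labels.ndim}-D")
        bad = np.setdiff1d(np.unique(self.labels), np.array(VALID_LABELS))
        if bad.size:
            raise FormatError(f"unknown label values: {bad.tolist()}")

    @property
    def um_per_px(self) -> float:
        return self.calibration.um_per_px

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def compartment_mask(self, label: int) -> np.ndarray:
        """Tissue mask including the nuclei embedded in that tissue.

        Each nucleus pixel is assigned to the tissue of its nearest
        non-nucleus pixel, so nuclei at image borders (which are not
        enclosed holes) are still reclaimed by their host compartment.
        """
        from scipy import ndimage

        base = self.labels == label
        nuc = self.labels == LABEL_NUCLEUS
        if not nuc.any():
            return base
        _, (ir, ic) = ndimage.distance_transform_edt(nuc, return_indices=True)
        owner = self.labels[ir, ic]
        return base | (nuc & (owner == label))


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def _apply_column_map(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename file columns to canonical names; missing columns raise."""
    cmap = {c: c for c in MEASUREMENT_COLUMNS}
    if column_map:
        cmap.update(column_map)
    required = [c for c in MEASUREMENT_COLUMNS if c not in ("group", "region")]
    missing = [cmap[c] for c in required if cmap[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found in file; "
            "configure a column map for this CSV dialect"
        )
    renamed = df.rename(columns={v: k for k, v in cmap.items() if v in df.columns})
    return renamed


def read_measurements(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an epithelial-thickness measurement CSV into canonical form.

    Parameters
    ----------
    path
        CSV file with a header row; one row per thickness measurement.
    column_map
        Optional mapping from canonical column names (``animal_id``, ``eye``,
        ``group``, ``region``, ``slide_id``, ``position_um``, ``thickness_um``)
        to the names used in the file, for foreign CSV dialects.

    Returns
    -------
    DataFrame with canonical columns, sorted by (animal, eye, slide,
    position).  ``group`` is derived from ``eye`` when absent; ``region``
    defaults to ``unspecified``.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    n_file_rows = len(raw)
    df = _apply_column_map(raw, column_map)

    if "group" not in df.columns:
        df["group"] = df["eye"].map(GROUP_FOR_EYE)
    if "region" not in df.columns:
        df["region"] = "unspecified"
    df = df[list(MEASUREMENT_COLUMNS)].copy()

    for col in ("position_um", "thickness_um"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise FormatError(
                f"non-numeric {col} in file rows {bad.tolist()[:10]}"
            )
        df[col] = parsed

    nonpos = df.index[~(df["thickness_um"] > 0)] + 2
    if len(nonpos):
        raise FormatError(
            f"thickness_um must be > 0; offending file rows {nonpos.tolist()[:10]}"
        )
    neg_pos = df.index[df["position_um"] < 0] + 2
    if len(neg_pos):
        raise FormatError(
            f"position_um must be >= 0; offending file rows {neg_pos.tolist()[:10]}"
        )

    bad_eye = sorted(set(df["eye"].unique()) - set(EYES))
    if bad_eye:
        raise FormatError(f"unknown eye value(s) {bad_eye}; expected {EYES}")
    inconsistent = df["group"] != df["eye"].map(GROUP_FOR_EYE)
    if inconsistent.any():
        logger.warning(
            "%d rows have group inconsistent with the right=study / left=control "
            "design", int(inconsistent.sum()),
        )

    df = df.sort_values(
        ["animal_id", "eye", "slide_id", "position_um"], kind="stable"
    ).reset_index(drop=True)

    for key, series in df.groupby(["animal_id", "eye", "slide_id"], sort=False):
        pos = series["position_um"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise FormatError(
                f"position_um must be strictly increasing within series {key}"
            )

    logger.info(
        "read %d measurement rows from %s (%d data rows in file, 0 rejected)",
        len(df), path, n_file_rows,
    )
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a canonical measurement table as CSV (lossless float repr)."""
    path = Path(path)
    df[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)
    return path


def profiles_from_measurements(df: pd.DataFrame) -> list[ThicknessProfile]:
    """Split a measurement table into one profile per (animal, eye, slide)."""
    out = []
    for (animal, eye, slide), sub in df.groupby(
        ["animal_id", "eye", "slide_id"], sort=True
    ):
        out.append(
            ThicknessProfile(
                positions_um=sub["position_um"].to_numpy(),
                thickness_um=sub["thickness_um"].to_numpy(),
                animal_id=str(animal),
                eye=str(eye),
                group=str(sub["group"].iloc[0]),
                region=str(sub["region"].iloc[0]),
                slide_id=str(slide),
            )
        )
    return out


# ---------------------------------------------------------------------------
# labeled rasters
# ---------------------------------------------------------------------------

def read_labeled_image(
    path: str | Path, calibration: Calibration
) -> LabeledHistologyImage:
    """Read a single-channel integer label raster (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    img = LabeledHistologyImage(labels=arr, calibration=calibration)
    values, counts = np.unique(img.labels, return_counts=True)
    logger.info(
        "read %s: %dx%d px at %.4g um/px, label histogram %s",
        path, img.shape[0], img.shape[1], calibration.um_per_px,
        dict(zip(values.tolist(), counts.tolist())),
    )
    return img


def write_labeled_image(image: LabeledHistologyImage, path: str | Path) -> Path:
    """Write a label raster as uint8 TIFF or PNG."""
    path = Path(path)
    data = image.labels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    return path


# ---------------------------------------------------------------------------
# OCT tables
# ---------------------------------------------------------------------------

def read_oct_series(path: str | Path) -> pd.DataFrame:
    """Read an OCT thickness table (animal_id, region, day, thickness_um)."""
    df = pd.read_csv(path)
    missing = [c for c in OCT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"OCT table missing column(s) {missing}")
    df = df[list(OCT_COLUMNS)].copy()
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    df["thickness_um"] = pd.to_numeric(df["thickness_um"], errors="raise")
    if not (df["thickness_um"] > 0).all():
        raise FormatError("OCT thickness_um must be > 0")
    dup = df.duplicated(["animal_id", "region", "day"])
    if dup.any():
        raise FormatError("duplicate (animal, region, day) rows in OCT table")
    return df.sort_values(["animal_id", "region", "day"]).reset_index(drop=True)


def write_oct_series(df: pd.DataFrame, path: str | Path) -> Path:
    df[list(OCT_COLUMNS)].to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# group-comparison reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "metric",
    "study_mean",
    "study_sd",
    "control_mean",
    "control_sd",
    "n_study",
    "n_control",
    "test",
    "t_stat",
    "p_value",
)


def comparisons_to_frame(comparisons: Sequence) -> pd.DataFrame:
    """Collect GroupComparison-like objects into a report table."""
    if not comparisons:
        raise ValueError("no comparisons to report")
    rows = []
    for c in comparisons:
        if dataclasses.is_dataclass(c):
            d = dataclasses.asdict(c)
        else:
            d = dict(c)
        rows.append({k: d.get(k) for k in REPORT_COLUMNS})
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def write_report(comparisons: Sequence, path: str | Path) -> Path:
    """Write group comparisons as CSV (default) or JSON by extension.

    Floats are written with full ``repr`` precision, so a read-back
    reproduces the values bit-for-bit.
    """
    path = Path(path)
    df = comparisons_to_frame(comparisons)
    if path.suffix.lower() == ".json":
        payload = df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    else:
        df.to_csv(path, index=False)
    logger.info("wrote report with %d metric rows to %s", len(df), path)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"report missing column(s) {missing}")
    return df[list(REPORT_COLUMNS)]
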