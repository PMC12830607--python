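"""Thickness-profile morphometry.

The metrics quantify how irregular an epithelial thickness profile is,
independent of the animal's baseline thickness:

* profiles are standardized to z-scores within a scope (default: per
  animal, pooling that animal's eye series) to remove individual baseline
  differences;
* arithmetic mean roughness Ra = mean(|z - mean(z)|) and maximum profile
  height Rz = max(z) - min(z) summarize surface irregularity on the
  standardized profile (this Rz is the plain max-min amplitude, not the
  ISO five-peak variant);
* a rolling standard deviation in windows of five consecutive
  measurements indexes local variability on the raw micrometre scale;
* the sigma-exceedance fractions (|z| > 1, 2, 3) and the Fisher-Pearson
  skewness g1 capture the burden and asymmetry of focal "hot spots" of
  thinning or thickening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ConfigurationError, ThicknessProfile

logger = logging.getLogger(__name__)

DEFAULT_ROLLING_WINDOW = 5
EXCEEDANCE_THRESHOLDS = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class MorphometryConfig:
    """Options controlling how the per-eye metrics are computed.

    standardize_scope
        ``"per_animal"`` pools the animal's measured eye series to set the
        z-score center and scale (removes between-animal baseline
        differences while keeping the between-eye contrast); ``"per_eye"``
        standardizes each eye on its own.
    z_ddof / rolling_ddof
        z-scores use the population SD (ddof 0, the usual z-score
        convention); the rolling SD uses the sample SD (ddof 1).
    rolling_on
        ``"raw"`` computes the rolling SD in micrometres on the raw
        profile (default); ``"z"`` on the standardized one.
    smooth_before_metrics
        Moving-average smoothing is a display aid; metrics are computed on
        unsmoothed values unless this sensitivity flag is set.
    break_at_slides
        If set, rolling windows do not span slide boundaries.
    rz_scope
        ``"per_eye"`` computes Ra/Rz on the eye-level standardized profile
        (slides concatenated); ``"per_slide_mean"`` averages per-slide
        values instead.
    """

    standardize_scope: str = "per_animal"
    rolling_window: int = DEFAULT_ROLLING_WINDOW
    rolling_on: str = "raw"
    z_ddof: int = 0
    rolling_ddof: int = 1
    smooth_before_metrics: bool = False
    smooth_window: int = 5
    break_at_slides: bool = False
    rz_scope: str = "per_eye"

    def __post_init__(self) -> None:
        if self.standardize_scope not in ("per_animal", "per_eye"):
            raise ConfigurationError(
                f"unknown standardize_scope {self.standardize_scope!r}"
            )
        if self.rolling_on not in ("raw", "z"):
            raise ConfigurationError(f"unknown rolling_on {self.rolling_on!r}")
        if self.rz_scope not in ("per_eye", "per_slide_mean"):
            raise ConfigurationError(f"unknown rz_scope {self.rz_scope!r}")
        if self.rolling_window < 2:
            raise ConfigurationError("rolling_window must be >= 2")


@dataclass
class StandardizedProfile:
    """z-scored thickness profile with the centering used to produce it."""

    z_values: np.ndarray
    center_um: float
    scale_um: float
    source: ThicknessProfile | None = None

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)


@dataclass
class MorphometrySummary:
    """All per-eye thickness-distribution metrics for one eye."""

    animal_id: str
    eye: str
    group: str
    n_measurements: int
    mean_um: float
    min_um: float
    max_um: float
    range_um: float
    ra: float
    rz: float
    skewness: float
    rolling_sd_um: float
    frac_exceed_1sd: float
    frac_exceed_2sd: float
    frac_exceed_3sd: float


def _values(profile) -> np.ndarray:
    if isinstance(profile, ThicknessProfile):
        return np.asarray(profile.thickness_um, dtype=float)
    if isinstance(profile, StandardizedProfile):
        return np.asarray(profile.z_values, dtype=float)
    return np.asarray(profile, dtype=float)


def standardize(
    profile,
    center: float | None = None,
    scale: float | None = None,
    ddof: int = 0,
) -> StandardizedProfile:
    """z-score a profile: z = (thickness - center) / scale.

    By default center and scale are the mean and population SD of the
    profile itself (per-eye scope); pass precomputed values to standardize
    within a wider scope such as one animal's pooled eye series.  A zero
    scale (constant data) maps every value to z = 0.
    """
    x = _values(profile)
    if x.size < 2 and center is None:
        raise ValueError("standardization needs at least 2 samples")
    c = float(np.mean(x)) if center is None else float(center)
    s = float(np.std(x, ddof=ddof)) if scale is None else float(scale)
    if s > 0:
        z = (x - c) / s
    else:
        z = np.zeros_like(x)
    return StandardizedProfile(
        z_values=z,
        center_um=c,
        scale_um=s,
        source=profile if isinstance(profile, ThicknessProfile) else None,
    )


def animal_scale_factors(
    df: pd.DataFrame, ddof: int = 0
) -> dict[str, tuple[float, float]]:
    """Per-animal (center, scale) over all of that animal's measurements."""
    out: dict[str, tuple[float, float]] = {}
    for animal, sub in df.groupby("animal_id"):
        x = sub["thickness_um"].to_numpy(dtype=float)
        out[str(animal)] = (float(np.mean(x)), float(np.std(x, ddof=ddof)))
    return out


def smooth(profile, window: int):
    """Centered moving average; edges use shrunken windows; window 1 is a no-op."""
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"smoothing window must be odd and >= 1, got {window}")
    x = _values(profile)
    if window == 1:
        return x.copy()
    sm = (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return sm


def roughness(z: StandardizedProfile | np.ndarray) -> tuple[float, float]:
    """(Ra, Rz) of a standardized profile.

    Ra is the mean absolute deviation from the profile mean; Rz is the
    max-min amplitude.  Both are unitless on z-scored input.
    """
    x = _values(z)
    if x.size < 2:
        raise ValueError("roughness needs at least 2 samples")
    ra = float(np.mean(np.abs(x - np.mean(x))))
    rz = float(np.max(x) - np.min(x))
    return ra, rz


def rolling_sd(
    profile, window: int = DEFAULT_ROLLING_WINDOW, ddof: int = 1
) -> tuple[np.ndarray, float]:
    """Sample SD in each full window of consecutive measurements.

    Returns the per-window values (length n - window + 1) and their mean.
    Units follow the input (micrometres on raw thickness).
    """
    x = _values(profile)
    if x.size < window:
        raise ValueError(
            f"rolling SD needs at least window={window} samples, got {x.size}"
        )
    vals = (
        pd.Series(x).rolling(window).std(ddof=ddof).to_numpy()[window - 1:]
    )
    return vals, float(np.mean(vals))


def skewness(profile) -> float:
    """Fisher-Pearson moment coefficient g1 (bias-uncorrected).

    Undefined (NaN) on zero-variance input, which is reported as missing
    rather than raised.
    """
    x = _values(profile)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 samples")
    if np.std(x) == 0:
        logger.warning("skewness undefined on zero-variance profile; reporting NaN")
        return float("nan")
    return float(stats.skew(x, bias=True))


def exceedance(
    z: StandardizedProfile | np.ndarray,
    thresholds: Sequence[float] = EXCEEDANCE_THRESHOLDS,
) -> tuple[float, ...]:
    """Fraction of samples with |z| strictly beyond each threshold."""
    x = _values(z)
    if x.size < 1:
        raise ValueError("exceedance needs at least 1 sample")
    a = np.abs(x)
    return tuple(float(np.mean(a > k)) for k in thresholds)


def _eye_series(eye_df: pd.DataFrame) -> np.ndarray:
    """Thicknesses of one eye, slides concatenated in slide order."""
    ordered = eye_df.sort_values(["slide_id", "position_um"], kind="stable")
    return ordered["thickness_um"].to_numpy(dtype=float)


def _slide_arrays(eye_df: pd.DataFrame) -> list[np.ndarray]:
    return [
        sub.sort_values("position_um")["thickness_um"].to_numpy(dtype=float)
        for _, sub in eye_df.groupby("slide_id", sort=True)
    ]


def summarize_eye(
    eye_df: pd.DataFrame,
    config: MorphometryConfig = MorphometryConfig(),
    center: float | None = None,
    scale: float | None = None,
) -> MorphometrySummary:
    """Compute every profile metric for one eye's measurement rows.

    ``center``/``scale`` inject a wider standardization scope (e.g. the
    per-animal pooled statistics); left as None, the eye is its own scope.
    """
    if eye_df.empty:
        raise ValueError("empty eye series")
    x = _eye_series(eye_df)
    if config.smooth_before_metrics:
        x = smooth(x, config.smooth_window)

    z = standardize(x, center=center, scale=scale, ddof=config.z_ddof)

    if config.rz_scope == "per_slide_mean" and eye_df["slide_id"].nunique() > 1:
        per_slide = [
            roughness(standardize(s, center=center, scale=scale,
                                  ddof=config.z_ddof).z_values)
            for s in _slide_arrays(eye_df)
            if s.size >= 2
        ]
        ra = float(np.mean([r[0] for r in per_slide]))
        rz = float(np.mean([r[1] for r in per_slide]))
    else:
        ra, rz = roughness(z.z_values)

    roll_src = x if config.rolling_on == "raw" else z.z_values
    if config.break_at_slides and eye_df["slide_id"].nunique() > 1:
        pieces = []
        offset = 0
        for s in _slide_arrays(eye_df):
            if s.size >= config.rolling_window:
                seg = roll_src[offset: offset + s.size]
                pieces.append(rolling_sd(seg, config.rolling_window,
                                         config.rolling_ddof)[0])
            offset += s.size
        if not pieces:
            raise ValueError("no slide long enough for the rolling window")
        roll_mean = float(np.mean(np.concatenate(pieces)))
    else:
        _, roll_mean = rolling_sd(roll_src, config.rolling_window,
                                  config.rolling_ddof)

    exc = exceedance(z.z_values)
    return MorphometrySummary(
        animal_id=str(eye_df["animal_id"].iloc[0]),
        eye=str(eye_df["eye"].iloc[0]),
        group=str(eye_df["group"].iloc[0]),
        n_measurements=int(x.size),
        mean_um=float(np.mean(x)),
        min_um=float(np.min(x)),
        max_um=float(np.max(x)),
        range_um=float(np.max(x) - np.min(x)),
        ra=ra,
        rz=rz,
        skewness=skewness(x),
        rolling_sd_um=roll_mean,
        frac_exceed_1sd=exc[0],
        frac_exceed_2sd=exc[1],
        frac_exceed_3sd=exc[2],
    )


def summarize_cohort(
    df: pd.DataFrame, config: MorphometryConfig = MorphometryConfig()
) -> pd.DataFrame:
    """Per-eye MorphometrySummary table for a whole measurement table.

    With the default per-animal standardization scope, each animal's
    z-score center/scale pool all of that animal's measurements (both
    eyes), so an irregular study eye shows up as large |z| against the
    animal's own baseline.
    """
    if df.empty:
        raise ValueError("empty measurement table")
    factors = (
        animal_scale_factors(df, ddof=config.z_ddof)
        if config.standardize_scope == "per_animal"
        else {}
    )
    rows = []
    for (animal, eye), eye_df in df.groupby(["animal_id", "eye"], sort=True):
        center, scale = factors.get(str(animal), (None, None))
        rows.append(
            summarize_eye(eye_df, config, center=center, scale=scale).__dict__
        )
    out = pd.DataFrame(rows)
    logger.info("summarized %d eyes (%s scope)", len(out), config.standardize_scope)
    return out
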