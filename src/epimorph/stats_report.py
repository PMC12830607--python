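"""Group comparison table and profile figure.

One row per morphometric metric, study vs control, with the test the
study design calls for: the pooled per-measurement thickness is compared
with an unpaired t-test (measurements as units), while every per-eye
metric (eye averages, Ra, Rz, exceedance, skewness, rolling SD, cell
density) is compared with a paired t-test matching the injured right eye
to the control left eye of the same animal.  Raw p-values are reported
without multiplicity correction; a Holm-adjusted column can be enabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cellularity import CellDensityResult
from .io_formats import write_report  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    """Per-metric study-vs-control summary with the test that produced p."""

    metric: str
    study_mean: float
    study_sd: float
    control_mean: float
    control_sd: float
    n_study: int
    n_control: int
    test: str  # "paired" | "unpaired" | "none"
    t_stat: float
    p_value: float
    degenerate: bool = False
    p_holm: float | None = None


def _group_stats(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def compare_metric(
    study: Sequence[float],
    control: Sequence[float],
    metric: str = "",
    test: str = "paired",
    study_ids: Sequence | None = None,
    control_ids: Sequence | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Two-sided t-test of one metric between the groups.

    ``test="paired"`` matches values by animal id (right vs left eye of
    the same animal) and tests the differences; ``"unpaired"`` uses the
    pooled-variance two-sample t (Welch by flag).  Zero-variance paired
    differences are flagged degenerate: t=0, p=1 when all differences
    are zero, otherwise p is pinned below machine resolution.
    """
    s = np.asarray(study, dtype=float)
    c = np.asarray(control, dtype=float)
    if s.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    degenerate = False
    if test == "paired":
        if study_ids is not None or control_ids is not None:
            sd_ = pd.Series(s, index=list(study_ids))
            cd_ = pd.Series(c, index=list(control_ids))
            missing = sorted(set(sd_.index) ^ set(cd_.index))
            if missing:
                raise ValueError(
                    f"paired test requires matched animals; unmatched: {missing}"
                )
            cd_ = cd_.reindex(sd_.index)
            s, c = sd_.to_numpy(), cd_.to_numpy()
        elif s.size != c.size:
            raise ValueError("paired test needs equal-length groups")
        diffs = s - c
        if np.std(diffs, ddof=1) == 0:
            degenerate = True
            if np.all(diffs == 0):
                t, p = 0.0, 1.0
            else:
                t = float(np.sign(diffs.mean())) * float("inf")
                p = float(np.finfo(float).tiny)
            logger.warning("metric %r: zero-variance paired differences", metric)
        else:
            t, p = stats.ttest_rel(s, c)
            t, p = float(t), float(p)
    elif test == "unpaired":
        t, p = stats.ttest_ind(s, c, equal_var=not welch)
        t, p = float(t), float(p)
        if np.isnan(t):
            degenerate = True
            t, p = 0.0, 1.0
    elif test == "none":
        t, p = float("nan"), float("nan")
    else:
        raise ValueError(f"unknown test {test!r}")
    sm, ss = _group_stats(s)
    cm, cs = _group_stats(c)
    return GroupComparison(
        metric=metric, study_mean=sm, study_sd=ss, control_mean=cm,
        control_sd=cs, n_study=int(s.size), n_control=int(c.size),
        test=test, t_stat=t, p_value=p, degenerate=degenerate,
    )


#: per-eye metrics compared paired, in report order: (column, row label)
PAIRED_EYE_METRICS = (
    ("n_measurements", "Number of measurements per eye (avg)"),
    ("mean_um", "Epithelium thickness (avg of avgs)"),
    ("min_um", "Minimal epithelium thickness (avg)"),
    ("max_um", "Maximum epithelium thickness (avg)"),
    ("range_um", "Max-min difference (avg)"),
    ("ra", "Arithmetic Mean Roughness (Ra)"),
    ("rz", "Maximum Height of Profile (Rz)"),
    ("frac_exceed_1sd", "Measurements exceeding 1 sigma (%)"),
    ("frac_exceed_2sd", "Measurements exceeding 2 sigma (%)"),
    ("frac_exceed_3sd", "Measurements exceeding 3 sigma (%)"),
    ("skewness", "Skewness"),
    ("rolling_sd_um", "Rolling Standard Deviation"),
)
PERCENT_METRICS = {"frac_exceed_1sd", "frac_exceed_2sd", "frac_exceed_3sd"}


def build_table(
    summaries: pd.DataFrame,
    measurements: pd.DataFrame | None = None,
    densities: Sequence[tuple[str, str, CellDensityResult]] = (),
    pooled_units: str = "measurements",
    holm: bool = False,
) -> list[GroupComparison]:
    """The full study-vs-control comparison table.

    Parameters
    ----------
    summaries
        Per-eye morphometry table (one row per eye) as produced by
        ``morphometry.summarize_cohort``.
    measurements
        Raw measurement table; enables the pooled "avg total" thickness
        row, tested unpaired with ``pooled_units`` ("measurements",
        treating every measurement as a unit, or "eyes").
    densities
        Optional (animal_id, group, CellDensityResult) triples, one per
        eye and compartment, for the cell-density rows (paired).
    holm
        Add Holm-adjusted p-values across the tested rows.
    """
    study = summaries[summaries["group"] == "study"]
    control = summaries[summaries["group"] == "control"]
    if study.empty or control.empty:
        raise ValueError("both groups must be present")

    rows: list[GroupComparison] = []
    rows.append(
        GroupComparison(
            metric="Number of samples (n)",
            study_mean=float(len(study)), study_sd=0.0,
            control_mean=float(len(control)), control_sd=0.0,
            n_study=len(study), n_control=len(control),
            test="none", t_stat=float("nan"), p_value=float("nan"),
        )
    )
    rows.append(
        GroupComparison(
            metric="Number of measurements (total)",
            study_mean=float(study["n_measurements"].sum()), study_sd=0.0,
            control_mean=float(control["n_measurements"].sum()), control_sd=0.0,
            n_study=len(study), n_control=len(control),
            test="none", t_stat=float("nan"), p_value=float("nan"),
        )
    )

    if measurements is not None:
        if pooled_units == "measurements":
            s = measurements.loc[measurements["group"] == "study",
                                 "thickness_um"].to_numpy()
            c = measurements.loc[measurements["group"] == "control",
                                 "thickness_um"].to_numpy()
            rows.append(compare_metric(
                s, c, metric="Epithelium thickness (avg total)",
                test="unpaired"))
        else:  # eyes as units: per-eye means, still unpaired per the plan
            rows.append(compare_metric(
                study["mean_um"], control["mean_um"],
                metric="Epithelium thickness (avg total)", test="unpaired"))

    for col, label in PAIRED_EYE_METRICS:
        if col not in summaries.columns:
            logger.warning("metric %r missing from summaries; row skipped", col)
            continue
        scale = 100.0 if col in PERCENT_METRICS else 1.0
        try:
            rows.append(compare_metric(
                study[col].to_numpy() * scale,
                control[col].to_numpy() * scale,
                metric=label, test="paired",
                study_ids=study["animal_id"], control_ids=control["animal_id"],
            ))
        except ValueError as exc:
            logger.warning("row %r skipped: %s", label, exc)

    if densities:
        ddf = pd.DataFrame(
            [
                {"animal_id": a, "group": g,
                 "compartment": r.compartment, "area_mm2": r.area_mm2,
                 "density": r.density_per_mm2}
                for a, g, r in densities
            ]
        )
        for comp in ("epithelium", "stroma"):
            sub = ddf[ddf["compartment"] == comp]
            if sub.empty:
                continue
            s = sub[sub["group"] == "study"]
            c = sub[sub["group"] == "control"]
            for col, label in (
                ("area_mm2", f"{comp.capitalize()} analyzed area per eye (mm^2)"),
                ("density", f"{comp.capitalize()} cell density (avg, cells/mm^2)"),
            ):
                try:
                    rows.append(compare_metric(
                        s[col].to_numpy(), c[col].to_numpy(), metric=label,
                        test="paired", study_ids=s["animal_id"],
                        control_ids=c["animal_id"],
                    ))
                except ValueError as exc:
                    logger.warning("row %r skipped: %s", label, exc)

    if holm:
        tested = [i for i, r in enumerate(rows) if r.test != "none"]
        pvals = np.array([rows[i].p_value for i in tested])
        adj = _holm(pvals)
        for i, p_adj in zip(tested, adj):
            rows[i] = replace(rows[i], p_holm=float(p_adj))
    return rows


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def render_profiles(
    measurements: pd.DataFrame,
    path: str | Path,
    standardized: bool = False,
    smooth_window: int = 5,
) -> Path:
    """Overlay per-eye thickness profiles, control in blue, study in red.

    Output is deterministic for fixed input and style (no timestamps are
    embedded), so repeated renders are byte-identical.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    from .morphometry import smooth, standardize

    if measurements.empty:
        raise ValueError("no profiles to render")
    fig = Figure(figsize=(9, 4.5), dpi=120)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    colors = {"study": "tab:red", "control": "tab:blue"}
    seen = set()
    for (animal, eye), sub in measurements.groupby(["animal_id", "eye"]):
        sub = sub.sort_values(["slide_id", "position_um"], kind="stable")
        y = sub["thickness_um"].to_numpy(dtype=float)
        if standardized:
            y = standardize(y).z_values
        if smooth_window > 1:
            y = smooth(y, smooth_window)
        group = str(sub["group"].iloc[0])
        label = group if group not in seen else None
        seen.add(group)
        ax.plot(np.arange(y.size), y, color=colors.get(group, "gray"),
                alpha=0.7, lw=1.0, label=label)
    ax.set_xlabel("measurement index along section")
    ax.set_ylabel("standardized thickness (z)" if standardized
                  else "epithelial thickness (um)")
    ax.legend(title="group")
    fig.tight_layout()
    path = Path(path)
    if path.suffix.lower() == ".png" or not path.suffix:
        fig.savefig(path, format="png", metadata={"Software": "epimorph"})
    else:
        fig.savefig(path)
    logger.info("wrote profile figure to %s", path)
    return path
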