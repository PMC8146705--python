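"""Matrix-calibration quantification, detection and repeatability statistics.

The measurement model is deliberately plain, because that is how targeted
food-authentication assays are evaluated in practice:

* **Calibration** — ordinary least squares of peak area on substitution
  level over matrix-matched standards (S1–S9 style ladders); R² is the
  squared Pearson correlation.
* **Quantification** — inverse prediction ``(area - intercept)/slope`` of
  unknowns measured under identical conditions.
* **Recovery** — ``100·estimated/true`` with an inclusive 80–120 % band.
* **Detection** — a marker is detected when all three of its monitored
  transitions have S/N ≥ 3; a species is confirmed when its markers satisfy
  the configured rule (default: all three).
* **Repeatability** — CV (sample SD over mean, in %) of peak areas and of
  the lowest-to-highest transition-area ratio across replicate preparations.

Peak-area tables are long-format DataFrames with columns
``sample_id, level, species, marker, transition, area, snr`` plus a
``role`` column ("standard" / "unknown" / "blank").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationResult",
    "QuantResult",
    "RepeatabilityReport",
    "DetectionCall",
    "normalize_to_max",
    "column_summary",
    "load_extraction_screen",
    "fit_calibration",
    "quantify",
    "recovery",
    "cv",
    "transition_ratio",
    "detect",
    "species_call",
    "lod_ladder",
    "snr",
    "boxplot_stats",
    "quantify_table",
    "plot_recoveries",
]

RECOVERY_BAND = (80.0, 120.0)
SNR_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# normalized peak-area summaries (extraction screening)

def normalize_to_max(area_matrix: pd.DataFrame) -> pd.DataFrame:
    """Express each row as a percentage of its maximum (row max -> 100)."""
    mat = area_matrix.astype(float)
    row_max = mat.max(axis=1)
    if (row_max <= 0).any():
        bad = list(mat.index[row_max <= 0])
        raise ValueError(f"rows without a positive maximum: {bad}")
    return mat.div(row_max, axis=0) * 100.0


def column_summary(percent_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean (rounded to integer %) and row-maximum counts.

    ``maxima`` counts, for each column, the rows whose row-maximum falls in
    that column; a row tied across k columns increments all k.
    """
    mat = percent_matrix.astype(float)
    means = mat.mean(axis=0).round().astype(int)
    row_max = mat.max(axis=1)
    maxima = mat.eq(row_max, axis=0).sum(axis=0).astype(int)
    return pd.DataFrame({"mean": means, "maxima": maxima})


def load_extraction_screen() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The shipped extraction-screen tables for the nine-legume panel.

    Returns ``(buffer_screen, time_screen)``: normalized mean peak areas
    (% of row maximum) of the 27 markers across eight extraction buffers and
    across six extraction times (minutes).
    """
    out = []
    for name in ("buffer_screen.csv", "time_screen.csv"):
        ref = resources.files("mrmkit.data").joinpath(name)
        with resources.as_file(ref) as p:
            out.append(pd.read_csv(p, index_col="marker"))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# calibration and quantification

@dataclass(frozen=True)
class CalibrationResult:
    """A per-marker standard curve."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    marker: str = ""
    low_n: bool = False  # 2-point curves have R^2 = 1 by construction


def fit_calibration(
    standards: Iterable[tuple[float, float]],
    marker: str = "",
    through_origin: bool = False,
) -> CalibrationResult:
    """OLS of area on substitution level over calibration standards."""
    pts = [(float(l), float(a)) for l, a in standards]
    levels = np.array([p[0] for p in pts])
    areas = np.array([p[1] for p in pts])
    if len(set(levels.tolist())) < 2:
        raise ValueError("calibration needs at least 2 distinct levels")
    if through_origin:
        slope = float(np.dot(levels, areas) / np.dot(levels, levels))
        intercept = 0.0
        pred = slope * levels
        ss_res = float(np.sum((areas - pred) ** 2))
        ss_tot = float(np.sum((areas - areas.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2 = min(max(r2, 0.0), 1.0)
    else:
        fit = stats.linregress(levels, areas)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2
    return CalibrationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(pts),
        marker=marker,
        low_n=len(pts) <= 2,
    )


def quantify(curve: CalibrationResult, area: float) -> float:
    """Inverse-predict the substitution level (%) from a peak area.

    Negative estimates (area below the fitted blank) are returned as-is;
    callers decide whether to clip or flag them.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration curve")
    return (float(area) - curve.intercept) / curve.slope


def recovery(estimated: float, true: float) -> tuple[float, bool]:
    """Recovery % and membership in the inclusive 80–120 % band."""
    if true <= 0:
        raise ValueError("recovery undefined for true level <= 0")
    pct = 100.0 * float(estimated) / float(true)
    lo, hi = RECOVERY_BAND
    return pct, lo <= pct <= hi


@dataclass
class QuantResult:
    """Quantification of one marker in one unknown sample."""

    marker: str
    sample: str
    estimated_level: float
    true_level: float | None = None
    recovery_pct: float | None = None
    in_band: bool | None = None
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# repeatability

def cv(values: Sequence[float]) -> float:
    """Coefficient of variation, %: 100 · sample SD (n−1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def transition_ratio(areas_by_rank: Sequence[float]) -> float:
    """Ratio of the lowest- to the highest-intense transition's area.

    ``areas_by_rank`` must follow the method's declared intensity order
    (rank 1 = most intense first); typically three areas per marker.
    """
    if len(areas_by_rank) < 2:
        raise ValueError("transition ratio needs at least 2 ranked areas")
    top = float(areas_by_rank[0])
    if top == 0:
        raise ValueError("highest-intensity transition area is zero")
    return float(areas_by_rank[-1]) / top


@dataclass
class RepeatabilityReport:
    """Per-marker repeatability across replicate preparations."""

    marker: str
    area_cv_pct: float
    ratio_cv_pct: float
    n: int


# ---------------------------------------------------------------------------
# detection and LOD

@dataclass
class DetectionCall:
    """Species-level detection decision from per-marker S/N tests."""

    species: str
    marker_detections: dict[str, bool]
    species_confirmed: bool
    rule: str = "all3"
    lod_level: float | None = None


def detect(
    marker_snr: Sequence[float],
    threshold: float = SNR_THRESHOLD,
    n_required: int = 3,
) -> bool:
    """Marker detected iff all monitored transitions reach S/N ≥ threshold."""
    if len(marker_snr) != n_required:
        raise ValueError(
            f"expected {n_required} S/N values per marker, got {len(marker_snr)}"
        )
    return all(float(s) >= threshold for s in marker_snr)


def species_call(
    species: str,
    marker_detections: Mapping[str, bool],
    rule: str = "all3",
) -> DetectionCall:
    """Combine marker detections into a species decision.

    ``all3`` (default, strict evidence) requires every marker detected;
    ``any1`` is a screening rule satisfied by a single marker.
    """
    if not marker_detections:
        raise ValueError("no marker detections supplied")
    flags = dict(marker_detections)
    if rule == "all3":
        confirmed = all(flags.values())
    elif rule == "any1":
        confirmed = any(flags.values())
    else:
        raise ValueError(f"unknown species rule {rule!r}")
    return DetectionCall(
        species=species, marker_detections=flags, species_confirmed=confirmed, rule=rule
    )


def lod_ladder(calls_by_level: Mapping[float, bool]) -> float | None:
    """Lowest tested level at which detection succeeds.

    Warns when the ladder is non-monotone (a detected level above an
    undetected one), which usually indicates noise near the threshold.
    Returns None when nothing is detected.
    """
    if not calls_by_level:
        raise ValueError("empty detection ladder")
    levels = sorted(calls_by_level)
    detected = [lvl for lvl in levels if calls_by_level[lvl]]
    if not detected:
        return None
    lod = detected[0]
    if any(not calls_by_level[lvl] for lvl in levels if lvl > lod):
        warnings.warn(
            "non-monotone detection ladder: a level above the LOD was not detected",
            stacklevel=2,
        )
    return lod


def snr(
    trace: Sequence[float],
    peak_window: tuple[int, int],
    noise_window: tuple[int, int],
    smooth_points: int | None = None,
) -> float:
    """Chromatographic signal-to-noise of a peak.

    Height is the maximum of the (lightly smoothed) trace in ``peak_window``
    above the baseline median of ``noise_window``; noise is the SD of the raw
    noise window.  The moving-average smoothing (default: ~1/8 of the peak
    window, odd) suppresses the upward bias of taking a pointwise maximum of
    noisy data while leaving the peak apex essentially untouched for peaks
    wider than the smoothing span.
    """
    y = np.asarray(trace, dtype=float)
    p0, p1 = peak_window
    n0, n1 = noise_window
    for lo, hi in ((p0, p1), (n0, n1)):
        if not (0 <= lo < hi <= len(y)):
            raise ValueError(f"window ({lo}, {hi}) out of bounds for trace")
    if not (p1 <= n0 or n1 <= p0):
        raise ValueError("peak and noise windows must be disjoint")
    if n1 - n0 < 10:
        raise ValueError("noise window must span at least 10 points")
    if smooth_points is None:
        smooth_points = max(3, ((p1 - p0) // 8) | 1)
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        ypad = np.pad(y, pad, mode="edge")
        ysm = np.convolve(ypad, kernel, mode="valid")
    else:
        ysm = y
    baseline = float(np.median(y[n0:n1]))
    noise_sd = float(np.std(y[n0:n1], ddof=1))
    if noise_sd == 0:
        raise ValueError("noise window has zero variance")
    height = float(ysm[p0:p1].max()) - baseline
    return height / noise_sd


# ---------------------------------------------------------------------------
# box-plot summaries

def boxplot_stats(values: Sequence[float]) -> dict:
    """Five-number box-plot summary with 1.5·IQR whiskers.

    Whiskers extend to the most extreme data point within 1.5 interquartile
    distances of the box; points beyond are returned as outliers.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whislo = float(inside.min()) if inside.size else float(q1)
    whishi = float(inside.max()) if inside.size else float(q3)
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whislo": whislo,
        "whishi": whishi,
        "outliers": outliers.tolist(),
    }


# ---------------------------------------------------------------------------
# table-level workflow

def _marker_signal(group: pd.DataFrame, mode: str) -> pd.Series:
    """Per-sample quantification signal for one marker's long-format rows."""
    pivot = group.pivot_table(
        index="sample_id", columns="transition", values="area", aggfunc="mean"
    )
    if mode == "sum":
        return pivot.sum(axis=1)
    if mode == "top":
        top = pivot.mean(axis=0).idxmax()
        return pivot[top]
    raise ValueError(f"unknown signal mode {mode!r}")


def quantify_table(
    table: pd.DataFrame,
    mode: str = "top",
    through_origin: bool = False,
) -> tuple[dict[str, CalibrationResult], pd.DataFrame]:
    """Calibrate and quantify a long-format peak-area table.

    Standards (``role == "standard"``) define one curve per marker using the
    most intense transition's area (``mode="top"``, default) or the summed
    areas (``mode="sum"``); unknowns are inverse-predicted and, where the
    true level is known and positive, scored for recovery against the
    inclusive 80–120 % band.

    Returns ``(curves, results)``: curves keyed by marker, results as one
    row per (marker, unknown sample).
    """
    required = {"sample_id", "level", "species", "marker", "transition", "area", "role"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    curves: dict[str, CalibrationResult] = {}
    rows: list[dict] = []
    for marker, group in table.groupby("marker", sort=False):
        std = group[group["role"] == "standard"]
        unk = group[group["role"] == "unknown"]
        if std.empty:
            continue
        signal = _marker_signal(std, mode)
        levels = std.groupby("sample_id")["level"].first().reindex(signal.index)
        curves[marker] = fit_calibration(
            zip(levels.to_numpy(), signal.to_numpy()), marker=marker,
            through_origin=through_origin,
        )
        if unk.empty:
            continue
        unk_signal = _marker_signal(unk, mode)
        unk_levels = unk.groupby("sample_id")["level"].first()
        species = group["species"].iloc[0]
        for sample_id, area in unk_signal.items():
            est = quantify(curves[marker], area)
            true = float(unk_levels.get(sample_id, np.nan))
            row = {
                "species": species,
                "marker": marker,
                "sample_id": sample_id,
                "true_level": true,
                "estimated_level": est,
                "recovery_pct": np.nan,
                "in_band": pd.NA,
                "flags": "negative_estimate" if est < 0 else "",
            }
            if np.isfinite(true) and true > 0:
                pct, ok = recovery(est, true)
                row["recovery_pct"] = pct
                row["in_band"] = ok
            rows.append(row)
    return curves, pd.DataFrame(rows)


def repeatability_report(table: pd.DataFrame) -> list[RepeatabilityReport]:
    """Per-marker CVs of areas and transition ratios across replicates.

    Expects one marker's transitions measured repeatedly on the same
    material; the most intense transition (by mean area) anchors both the
    area CV and the ratio denominator.
    """
    reports = []
    for marker, group in table.groupby("marker", sort=False):
        pivot = group.pivot_table(
            index="sample_id", columns="transition", values="area", aggfunc="mean"
        )
        order = pivot.mean(axis=0).sort_values(ascending=False).index
        top = pivot[order[0]]
        ratios = pivot[order[-1]] / pivot[order[0]]
        reports.append(
            RepeatabilityReport(
                marker=marker,
                area_cv_pct=cv(top.to_numpy()),
                ratio_cv_pct=cv(ratios.to_numpy()),
                n=len(pivot),
            )
        )
    return reports


def plot_recoveries(results: pd.DataFrame, path=None):
    """Box plots of recovery rates per marker with the 80–120 % band shaded.

    ``results`` is the output of :func:`quantify_table`.  Returns the
    matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = results.dropna(subset=["recovery_pct"])
    markers = list(dict.fromkeys(data["marker"]))
    groups = [data.loc[data["marker"] == m, "recovery_pct"].to_numpy() for m in markers]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(markers)), 4))
    ax.axhspan(*RECOVERY_BAND, color="0.85", zorder=0)
    ax.boxplot(groups, tick_labels=markers, whis=1.5)
    ax.set_ylabel("recovery [%]")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
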