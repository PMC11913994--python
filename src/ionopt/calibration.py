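"""Calibration curves, S/N, LOQ determination and method comparison.

Calibration follows common bioanalytical practice for LC-MS/MS panels:
linear least squares with 1/x weighting over a descending two-fold dilution
series, back-calculated accuracy per level, signal-to-noise against the
baseline-noise SD, and an LOQ rule requiring S/N >= 5 at the LOQ level and
back-calculated accuracy within 80-120% at that level and every level
above it (so the quantifiable range is contiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidValueError,
)

__all__ = [
    "CalibrationSeries",
    "CalibrationResult",
    "MethodComparison",
    "weighted_linear_fit",
    "snr",
    "determine_loq",
    "evaluate_series",
    "compare_methods",
    "comparison_from_table",
    "improvement_metrics",
    "load_table3",
]

SNR_THRESHOLD = 5.0  # boundary counts as passing
ACCURACY_BAND = (80.0, 120.0)  # back-calculated accuracy gate, percent


@dataclass
class CalibrationSeries:
    """Dilution series for one analyte under one instrument method.

    ``levels`` are pg-on-column amounts in strictly decreasing order;
    ``heights``/``aucs`` are (n_levels, n_replicates) arrays; ``noise_sd``
    is the baseline noise SD per level in the same detector units as the
    peak heights (the S/N denominator).
    """

    analyte: str
    levels: np.ndarray
    heights: np.ndarray
    noise_sd: np.ndarray
    aucs: Optional[np.ndarray] = None
    method: str = ""

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.heights = np.atleast_2d(np.asarray(self.heights, dtype=float))
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if np.any(np.diff(self.levels) >= 0):
            raise InvalidValueError("levels must be strictly decreasing")
        if np.any(self.levels <= 0):
            raise InvalidValueError("amounts must be positive")
        if self.heights.shape[0] != self.levels.size:
            raise InvalidValueError("heights must have one row per level")
        if self.noise_sd.size != self.levels.size:
            raise InvalidValueError("noise_sd must have one entry per level")
        if np.any(self.noise_sd <= 0):
            raise InvalidValueError("noise_sd must be positive")

    @property
    def mean_heights(self) -> np.ndarray:
        return self.heights.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, lv in enumerate(self.levels):
            for rep in range(self.heights.shape[1]):
                recs.append(
                    {
                        "analyte": self.analyte,
                        "level_pg": lv,
                        "replicate": rep + 1,
                        "height": self.heights[i, rep],
                        "auc": self.aucs[i, rep] if self.aucs is not None else np.nan,
                        "noise_sd": self.noise_sd[i],
                    }
                )
        return pd.DataFrame(recs)


@dataclass
class CalibrationResult:
    analyte: str
    slope: float
    intercept: float
    levels: np.ndarray
    accuracy: np.ndarray  # percent, per level
    snr: np.ndarray  # per level
    loq: Optional[float]  # pg on column, a member of levels, or None
    flags: list = field(default_factory=list)

    def snr_at(self, level: float) -> float:
        i = int(np.argmin(np.abs(self.levels - level)))
        if not np.isclose(self.levels[i], level, rtol=0.26):
            raise ConfigurationError(
                f"{self.analyte}: no calibration level near {level} pg"
            )
        return float(self.snr[i])


@dataclass
class MethodComparison:
    """Per-analyte LOQ and S/N before/after optimization.

    S/N values are compared at the pre-optimization LOQ level under both
    methods.  ``n_loq_improved`` counts strictly lower post LOQs;
    ``n_snr_improved`` counts strictly higher post S/N.
    """

    table: pd.DataFrame  # analyte, loq_pre, loq_post, snr_pre, snr_post

    @property
    def n_loq_improved(self) -> int:
        t = self.table.dropna(subset=["loq_pre", "loq_post"])
        return int((t["loq_post"] < t["loq_pre"]).sum())

    @property
    def n_snr_improved(self) -> int:
        t = self.table.dropna(subset=["snr_pre", "snr_post"])
        return int((t["snr_post"] > t["snr_pre"]).sum())


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def weighted_linear_fit(levels, responses, weighting: str = "1/x"):
    """Weighted least-squares line through calibration points.

    ``levels`` and ``responses`` are flat arrays (replicates repeated);
    weights are 1/x (default), 1/x^2, or uniform ("none").  Returns
    ``(slope, intercept)`` solving the weighted normal equations.
    """
    x = np.asarray(levels, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidValueError("levels and responses differ in length")
    if np.unique(x).size < 3:
        raise InsufficientDataError("need at least 3 distinct calibration levels")
    if weighting == "1/x":
        w = 1.0 / x
    elif weighting in ("1/x2", "1/x^2"):
        w = 1.0 / x**2
    elif weighting in ("none", None):
        w = np.ones_like(x)
    else:
        raise InvalidValueError(f"unknown weighting {weighting!r}")
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    A = np.array([[sw, swx], [swx, swxx]])
    b = np.array([swy, swxy])
    intercept, slope = np.linalg.solve(A, b)
    return float(slope), float(intercept)


def snr(height: float, noise_sd: float) -> float:
    """Signal-to-noise: peak height over baseline-noise SD."""
    if not np.all(np.asarray(noise_sd) > 0):
        raise InvalidValueError("noise_sd must be > 0")
    return height / noise_sd


def back_calculated_accuracy(series: CalibrationSeries, slope, intercept):
    """Per-level accuracy: 100 * back-calculated amount / nominal amount,
    using the replicate-mean height at each level."""
    back = (series.mean_heights - intercept) / slope
    return 100.0 * back / series.levels


def determine_loq(series: CalibrationSeries, fit=None) -> Optional[float]:
    """Lowest level passing the joint S/N and accuracy rule.

    The LOQ is the lowest level L with S/N >= 5 at L and back-calculated
    accuracy within 80-120% at L *and at every level above it* (the
    calibration range must be contiguous).  Returns None if no level
    qualifies.
    """
    if fit is None:
        x = np.repeat(series.levels, series.heights.shape[1])
        fit = weighted_linear_fit(x, series.heights.ravel())
    slope, intercept = fit
    acc = back_calculated_accuracy(series, slope, intercept)
    ratio = series.mean_heights / series.noise_sd
    lo, hi = ACCURACY_BAND
    acc_ok = (acc >= lo) & (acc <= hi)
    # levels are descending: level i passes the contiguity rule iff
    # all of 0..i pass accuracy
    contiguous_ok = np.cumprod(acc_ok).astype(bool)
    eligible = contiguous_ok & (ratio >= SNR_THRESHOLD)
    if not eligible.any():
        return None
    return float(series.levels[np.max(np.nonzero(eligible))])


def evaluate_series(series: CalibrationSeries, weighting: str = "1/x") -> CalibrationResult:
    """Fit, per-level diagnostics and LOQ for one calibration series."""
    x = np.repeat(series.levels, series.heights.shape[1])
    slope, intercept = weighted_linear_fit(x, series.heights.ravel(), weighting)
    acc = back_calculated_accuracy(series, slope, intercept)
    ratio = series.mean_heights / series.noise_sd
    loq = determine_loq(series, (slope, intercept))
    flags = [] if loq is not None else ["no-level-qualifies"]
    return CalibrationResult(
        analyte=series.analyte,
        slope=slope,
        intercept=intercept,
        levels=series.levels.copy(),
        accuracy=acc,
        snr=ratio,
        loq=loq,
        flags=flags,
    )


def compare_methods(pre: dict, post: dict) -> MethodComparison:
    """Pre/post-optimization comparison of calibration results.

    ``pre`` and ``post`` map analyte -> :class:`CalibrationResult` for the
    same analyte panel.  S/N is read at the pre-optimization LOQ level
    under both methods.
    """
    if set(pre) != set(post):
        raise ConfigurationError(
            f"analyte mismatch: {sorted(set(pre) ^ set(post))}"
        )
    recs = []
    for analyte in pre:
        rp, rq = pre[analyte], post[analyte]
        snr_pre = snr_post = np.nan
        if rp.loq is not None:
            snr_pre = rp.snr_at(rp.loq)
            snr_post = rq.snr_at(rp.loq)
        recs.append(
            {
                "analyte": analyte,
                "loq_pre": rp.loq,
                "loq_post": rq.loq,
                "snr_pre": snr_pre,
                "snr_post": snr_post,
            }
        )
    return MethodComparison(pd.DataFrame(recs).set_index("analyte").sort_index())


def comparison_from_table(table: pd.DataFrame) -> MethodComparison:
    """Build a :class:`MethodComparison` from a printed-style comparison
    table with columns analyte, loq_pre_pg, loq_post_pg, snr_pre, snr_post."""
    t = table.rename(
        columns={
            "loq_pre_pg": "loq_pre",
            "loq_post_pg": "loq_post",
        }
    )[["analyte", "loq_pre", "loq_post", "snr_pre", "snr_post"]]
    return MethodComparison(t.set_index("analyte"))


def load_table3() -> pd.DataFrame:
    """Reference LOQ / S/N comparison fixture for the 14-oxylipin panel."""
    with resources.files("ionopt.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Pre/post improvement metrics (peak height and AUC gains)
# ---------------------------------------------------------------------------


def improvement_metrics(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Percent change in mean peak height and mean AUC, per analyte.

    ``pre``/``post`` have columns analyte, replicate, height, auc with
    >= 3 replicates per analyte.  Returns per-analyte percent change
    100*(post/pre - 1) with a replicate-SD-propagated standard deviation.
    """
    recs = []
    for analyte in sorted(pre["analyte"].unique()):
        a = pre[pre["analyte"] == analyte]
        b = post[post["analyte"] == analyte]
        if len(a) < 3 or len(b) < 3:
            raise InsufficientDataError(f"{analyte}: need >= 3 replicates")
        rec = {"analyte": analyte}
        for metric in ("height", "auc"):
            if metric not in a or a[metric].isna().all():
                continue
            m0, m1 = a[metric].mean(), b[metric].mean()
            if m0 <= 0 or m1 <= 0:
                raise InvalidValueError(f"{analyte}: nonpositive mean {metric}")
            s0 = a[metric].std(ddof=1) / np.sqrt(len(a))
            s1 = b[metric].std(ddof=1) / np.sqrt(len(b))
            ratio = m1 / m0
            sd = 100.0 * ratio * np.sqrt((s0 / m0) ** 2 + (s1 / m1) ** 2)
            rec[f"{metric}_gain_pct"] = 100.0 * (ratio - 1.0)
            rec[f"{metric}_gain_sd"] = sd
        recs.append(rec)
    return pd.DataFrame(recs).set_index("analyte")
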