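"""Sensor quality-control pipeline for measurement streams.

Pre-scoring QC for wearable streams: EWMA control-chart drift detection
with a >10% baseline-shift rule, percentile-baseline drift correction,
duration-classified gap handling (interpolate / LOCF / exclude),
physiological plausibility screens, session completeness gating, and
affine cross-device calibration transfer.

Series are ``pandas.Series`` indexed by time in seconds; missing samples
are NaN on the recorded grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QcPolicy",
    "DriftReport",
    "GapReport",
    "detect_drift_ewma",
    "correct_drift",
    "handle_gaps",
    "plausibility_screen",
    "session_quality",
    "apply_calibration",
]


def _default_bounds() -> dict:
    # Inclusive physiological bounds per channel.
    return {"EMG": (0.0, 150.0), "HR": (40.0, 220.0)}


@dataclass(frozen=True)
class QcPolicy:
    """Thresholds for every QC rule.

    ``ewma_lambda`` is the chart smoothing constant; control limits are
    ``sigma_limit`` sigmas wide around the calibration mean.  The drift
    rule also fires when the rolling percentile baseline shifts by more
    than ``drift_threshold_frac`` of its initial value.  Gap classes are
    [0, interp_max) s -> interpolate, [interp_max, locf_max] s -> LOCF,
    (locf_max, inf) -> exclude and mark the session incomplete.  Sessions
    missing >= ``session_missing_max_frac`` of samples are excluded.  The
    ICC threshold is carried for report annotation only.
    """

    ewma_lambda: float = 0.2
    sigma_limit: float = 3.0
    drift_threshold_frac: float = 0.10
    calibration_s: float = 60.0
    baseline_window_s: float = 300.0
    baseline_percentile: float = 10.0
    gap_interp_max_s: float = 5.0
    gap_locf_max_s: float = 30.0
    session_missing_max_frac: float = 0.05
    plausibility_bounds: Mapping[str, tuple] = field(default_factory=_default_bounds)
    snr_min_db: float = 20.0
    cv_max_frac: float = 0.30
    icc_min: float = 0.85

    def __post_init__(self):
        if not 0 < self.ewma_lambda <= 1:
            raise ValueError("ewma_lambda must be in (0, 1]")
        if self.gap_interp_max_s >= self.gap_locf_max_s:
            raise ValueError("gap_interp_max_s must be < gap_locf_max_s")
        for name in ("sigma_limit", "drift_threshold_frac", "baseline_window_s",
                     "session_missing_max_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "QcPolicy":
        return replace(self, **kwargs)


@dataclass
class DriftReport:
    flags: pd.Series          # bool per sample
    ewma: pd.Series
    limits: tuple             # (low, high) control limits
    rule_fired: pd.DataFrame  # per-sample booleans: ewma_rule, shift_rule
    degenerate: bool = False  # zero-variance calibration segment


def _rolling_percentile_baseline(series: pd.Series, policy: QcPolicy) -> pd.Series:
    """Piecewise-linear baseline through window-percentile checkpoints.

    The initial baseline is the ``baseline_percentile``-th percentile of
    the first window; a new checkpoint is added every ``baseline_window_s``
    seconds from the most recent window, with linear interpolation between
    checkpoints.  A session shorter than two windows has a constant
    baseline (no correction).
    """
    t = series.index.to_numpy(dtype=float)
    x = series.to_numpy(dtype=float)
    w = policy.baseline_window_s
    q = policy.baseline_percentile
    t_end = t[-1]
    first = x[(t >= t[0]) & (t < t[0] + w)]
    if first.size == 0:
        first = x[:1]
    b0 = float(np.nanpercentile(first, q))
    ck_t = [t[0] + w]
    ck_v = [b0]
    k = 2
    while t[0] + k * w <= t_end + 1e-9:
        lo, hi = t[0] + (k - 1) * w, t[0] + k * w
        win = x[(t >= lo) & (t < hi)]
        ck_t.append(hi)
        ck_v.append(float(np.nanpercentile(win, q)) if win.size else ck_v[-1])
        k += 1
    baseline = np.interp(t, ck_t, ck_v, left=b0, right=ck_v[-1])
    return pd.Series(baseline, index=series.index)


def detect_drift_ewma(series: pd.Series, policy: QcPolicy | None = None) -> DriftReport:
    """Flag drift with an EWMA control chart and a baseline-shift rule.

    The chart centre and sigma come from a calibration segment (the first
    ``calibration_s`` seconds); steady-state control limits are
    centre +/- sigma_limit * sigma * sqrt(lambda / (2 - lambda)).  A sample
    is flagged when the EWMA statistic exits the limits *or* the rolling
    percentile baseline has shifted from its initial value by more than
    ``drift_threshold_frac``; the report records which rule fired.
    """
    policy = policy or QcPolicy()
    if len(series) < 2:
        raise ValueError("series must have length >= 2")
    x = series.to_numpy(dtype=float)
    t = series.index.to_numpy(dtype=float)

    cal = x[t <= t[0] + policy.calibration_s]
    if cal.size < 2:
        cal = x[:2]
    mu0 = float(np.nanmean(cal))
    sd0 = float(np.nanstd(cal, ddof=1))
    degenerate = sd0 == 0.0

    lam = policy.ewma_lambda
    ewma = np.empty_like(x)
    z = mu0
    for i, xi in enumerate(x):
        if np.isfinite(xi):
            z = lam * xi + (1 - lam) * z
        ewma[i] = z
    half_width = policy.sigma_limit * sd0 * math.sqrt(lam / (2.0 - lam))
    limits = (mu0 - half_width, mu0 + half_width)
    ewma_rule = (ewma < limits[0]) | (ewma > limits[1])
    if degenerate:
        # Degenerate limits: every deviation of the statistic trips the chart.
        ewma_rule = ewma != mu0

    baseline = _rolling_percentile_baseline(series, policy)
    b0 = baseline.iloc[0]
    if b0 == 0:
        shift_rule = np.abs(baseline.to_numpy() - b0) > 0
    else:
        shift_rule = (np.abs(baseline.to_numpy() - b0) / abs(b0)
                      > policy.drift_threshold_frac)

    flags = ewma_rule | shift_rule
    return DriftReport(
        flags=pd.Series(flags, index=series.index),
        ewma=pd.Series(ewma, index=series.index),
        limits=limits,
        rule_fired=pd.DataFrame({"ewma_rule": ewma_rule,
                                 "shift_rule": shift_rule}, index=series.index),
        degenerate=degenerate)


def correct_drift(series: pd.Series, policy: QcPolicy | None = None) -> pd.Series:
    """Subtract the accumulated baseline shift from a drifting series.

    corrected(t) = raw(t) - (baseline(t) - baseline(0)), with the baseline
    re-estimated every ``baseline_window_s`` seconds as the
    ``baseline_percentile``-th percentile of the most recent window and
    linearly interpolated between re-estimates.  A session spanning a
    single window is returned unchanged.
    """
    policy = policy or QcPolicy()
    if len(series) == 0:
        raise ValueError("empty series")
    baseline = _rolling_percentile_baseline(series, policy)
    return series - (baseline - baseline.iloc[0])


@dataclass
class GapReport:
    series: pd.Series         # imputed values
    flags: pd.Series          # ok | interpolated | locf | excluded
    session_incomplete: bool
    n_gaps: dict              # counts per class


def handle_gaps(series: pd.Series, policy: QcPolicy | None = None) -> GapReport:
    """Impute missing samples according to gap duration.

    Gap duration is the elapsed time between the valid neighbours.  Brief
    gaps (< ``gap_interp_max_s``) are linearly interpolated; moderate gaps
    (up to ``gap_locf_max_s``, inclusive) carry the last observation
    forward with an uncertainty flag; longer gaps stay missing, are
    flagged excluded and mark the session incomplete.  Leading gaps have
    no left anchor and are excluded; trailing gaps fall back to LOCF when
    short enough.
    """
    policy = policy or QcPolicy()
    t = series.index.to_numpy(dtype=float)
    x = series.to_numpy(dtype=float).copy()
    flags = np.full(len(x), "ok", dtype=object)
    incomplete = False
    counts = {"interpolated": 0, "locf": 0, "excluded": 0}

    isnan = ~np.isfinite(x)
    flags[isnan] = "excluded"
    i = 0
    n = len(x)
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        left = i - 1
        right = j if j < n else None
        if left < 0:
            # no left anchor: cannot interpolate or carry forward
            counts["excluded"] += j - i
            incomplete = incomplete or (right is None)
            i = j
            continue
        if right is None:
            elapsed = t[-1] - t[left]
            if elapsed <= policy.gap_locf_max_s:
                x[i:j] = x[left]
                flags[i:j] = "locf"
                counts["locf"] += j - i
            else:
                counts["excluded"] += j - i
                incomplete = True
            i = j
            continue
        elapsed = t[right] - t[left]
        if elapsed < policy.gap_interp_max_s:
            x[i:j] = np.interp(t[i:j], [t[left], t[right]], [x[left], x[right]])
            flags[i:j] = "interpolated"
            counts["interpolated"] += j - i
        elif elapsed <= policy.gap_locf_max_s:
            x[i:j] = x[left]
            flags[i:j] = "locf"
            counts["locf"] += j - i
        else:
            counts["excluded"] += j - i
            incomplete = True
        i = j

    return GapReport(series=pd.Series(x, index=series.index),
                     flags=pd.Series(flags, index=series.index),
                     session_incomplete=incomplete,
                     n_gaps=counts)


def plausibility_screen(channel: str, value: float,
                        policy: QcPolicy | None = None) -> tuple:
    """Check one sample against its channel's physiological bounds.

    Returns (passed, reason); bounds are inclusive at both endpoints.
    Unknown channels are a configuration error.
    """
    policy = policy or QcPolicy()
    if channel not in policy.plausibility_bounds:
        raise KeyError(f"no plausibility bounds configured for channel {channel!r}")
    lo, hi = policy.plausibility_bounds[channel]
    if not math.isfinite(value):
        return False, f"{channel} value {value} is not finite"
    if value < lo:
        return False, f"{channel} value {value} below bound {lo}"
    if value > hi:
        return False, f"{channel} value {value} above bound {hi}"
    return True, "ok"


def _traffic_light(bad: bool, marginal: bool) -> str:
    return "red" if bad else ("yellow" if marginal else "green")


def session_quality(session: pd.DataFrame, policy: QcPolicy | None = None) -> dict:
    """Completeness report and include/exclude decision for a session.

    ``session`` is wide-format: index = time (s), one column per channel,
    NaN marking missing samples.  The session is excluded when any
    channel's missing fraction reaches ``session_missing_max_frac`` or any
    channel shows an extended gap.  The report carries per-channel missing
    fractions, per-minute completeness, rolling coefficients of variation
    over the baseline window, and a traffic-light status per rule.
    """
    policy = policy or QcPolicy()
    if session.empty:
        raise ValueError("empty session")
    t = session.index.to_numpy(dtype=float)
    report: dict = {"channels": {}, "exclude": False, "reasons": []}
    limit = policy.session_missing_max_frac
    for ch in session.columns:
        s = session[ch]
        missing_frac = float((~np.isfinite(s.to_numpy(dtype=float))).mean())
        gaps = handle_gaps(s, policy)
        minutes = pd.Series(np.isfinite(s.to_numpy(dtype=float)),
                            index=(t // 60).astype(int))
        per_minute = minutes.groupby(level=0).mean()
        # rolling CV over baseline windows on the imputed trace
        win = pd.Series(gaps.series.to_numpy(),
                        index=(t // policy.baseline_window_s).astype(int))
        grouped = win.groupby(level=0)
        means = grouped.mean()
        cv = (grouped.std(ddof=1) / means.replace(0, np.nan)).abs()
        max_cv = float(np.nanmax(cv.to_numpy())) if len(cv) else math.nan
        ch_exclude = missing_frac >= limit or gaps.session_incomplete
        report["channels"][ch] = {
            "missing_frac": missing_frac,
            "per_minute_completeness": per_minute.to_dict(),
            "extended_gap": gaps.session_incomplete,
            "gap_counts": gaps.n_gaps,
            "max_rolling_cv": max_cv,
            "status": {
                "completeness": _traffic_light(missing_frac >= limit,
                                               missing_frac >= 0.8 * limit),
                "gaps": _traffic_light(gaps.session_incomplete,
                                       gaps.n_gaps["locf"] > 0),
                "cv": _traffic_light(bool(max_cv > policy.cv_max_frac)
                                     if math.isfinite(max_cv) else False,
                                     bool(max_cv > 0.8 * policy.cv_max_frac)
                                     if math.isfinite(max_cv) else False),
            },
        }
        if ch_exclude:
            report["exclude"] = True
            if missing_frac >= limit:
                report["reasons"].append(
                    f"{ch}: missing fraction {missing_frac:.3f} >= {limit}")
            if gaps.session_incomplete:
                report["reasons"].append(f"{ch}: extended gap (> "
                                         f"{policy.gap_locf_max_s} s)")
    return report


def apply_calibration(series, slope: float, intercept: float):
    """Affine cross-device calibration transfer: standard = intercept + slope * device."""
    if not (math.isfinite(slope) and math.isfinite(intercept)):
        raise ValueError("slope and intercept must be finite")
    if isinstance(series, pd.Series):
        return intercept + slope * series
    return intercept + slope * np.asarray(series, dtype=float)
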