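"""Time-domain gait features on the 0.5-15 Hz body acceleration.

Twenty-one features are computed per axis. Most are per-step statistics:
the signal is sliced at consecutive accepted step peaks, the statistic is
evaluated on each slice (or its first/last half), and the slice values are
averaged. Five are whole-signal measures: the coefficient of variation of
per-step peak amplitudes, step and stride regularity (normalized unbiased
autocovariance at the mean step and stride lags), their ratio, and the mean
trend (mean absolute value of a moving average whose window is the mean step
duration — a drift/variability measure).

The six cross-axis features are Pearson correlation and sample covariance
between each axis pair, computed on the full-length analysis signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .errors import InvalidInputError, NoStepsDetectedError
from .gait_events import StepSegmentation

#: Registry of the 21 per-axis time-domain feature names, in order.
TIME_FEATURES = (
    "mean",
    "std",
    "skew",
    "kurt",
    "rms",
    "range",
    "median",
    "iqr",
    "mean_FH",
    "mean_LH",
    "std_FH",
    "std_LH",
    "zcr",
    "energy",
    "mav",
    "mad",
    "cv_peak",
    "StpReg",
    "StrReg",
    "regRatio",
    "meanTrend",
)

#: Cross-axis feature names (axis-free), in order.
CROSS_AXIS_FEATURES = (
    "corr_V_ML",
    "corr_AP_ML",
    "corr_V_AP",
    "cov_V_ML",
    "cov_AP_ML",
    "cov_V_AP",
)

#: Regularity lags are searched within +/- this fraction of the nominal lag.
REG_LAG_TOLERANCE = 0.10


@dataclass
class StepSlices:
    """Per-step sub-sequences of one axis, with first/last-half splits.

    Each slice spans one accepted step interval, half-open at the next peak.
    The first half takes the midpoint sample when the slice length is odd.
    """

    slices: list[np.ndarray]
    first_halves: list[np.ndarray]
    last_halves: list[np.ndarray]


def step_slices(axis_signal: np.ndarray, seg: StepSegmentation) -> StepSlices:
    """Cut one axis's signal at consecutive accepted step peak indices."""
    x = np.asarray(axis_signal, dtype=float)
    if seg.peak_indices.size and x.size <= seg.peak_indices[-1]:
        raise InvalidInputError("signal shorter than the last step peak index")
    if seg.accepted_intervals.size == 0:
        raise NoStepsDetectedError("segmentation has no accepted step intervals")
    slices, firsts, lasts = [], [], []
    for i in seg.accepted_intervals:
        a, b = seg.peak_indices[i], seg.peak_indices[i + 1]
        s = x[a:b]
        mid = (len(s) + 1) // 2  # odd length: midpoint joins the first half
        slices.append(s)
        firsts.append(s[:mid])
        lasts.append(s[mid:])
    return StepSlices(slices, firsts, lasts)


def _safe_skew(s: np.ndarray) -> float:
    return float(stats.skew(s)) if np.std(s) > 0 else 0.0


def _safe_kurt(s: np.ndarray) -> float:
    # Pearson (non-excess) convention.
    return float(stats.kurtosis(s, fisher=False)) if np.std(s) > 0 else 0.0


def _zcr(s: np.ndarray) -> float:
    signs = np.sign(s)
    signs[signs == 0] = 1
    return float(np.mean(signs[1:] != signs[:-1]))


def autocorr_regularity(
    axis_signal: np.ndarray,
    fs_hz: float,
    step_lag_s: float,
    stride_lag_s: float,
) -> tuple[float, float]:
    """Step and stride regularity via normalized unbiased autocovariance.

    phi(L) = sum_t x(t) x(t+L) / (n - L), normalized by phi(0), with the
    signal mean removed first. Each regularity is the maximum of phi over
    integer lags within +/-10% of the nominal lag, which absorbs the
    mismatch between the mean step period and the sample grid. Values are
    clipped to [-1, 1].
    """
    x = np.asarray(axis_signal, dtype=float)
    duration = x.size / fs_hz
    for lag in (step_lag_s, stride_lag_s):
        if not (0 < lag < duration / 4):
            raise InvalidInputError(
                f"lag {lag:.3f} s outside (0, {duration / 4:.3f} s)"
            )
    x0 = x - x.mean()
    denom = float(np.dot(x0, x0)) / x.size
    if denom == 0:
        return 0.0, 0.0

    def at_lag(lag_s: float) -> float:
        nominal = lag_s * fs_hz
        lo = max(1, int(np.floor(nominal * (1 - REG_LAG_TOLERANCE))))
        hi = min(x.size - 1, int(np.ceil(nominal * (1 + REG_LAG_TOLERANCE))))
        best = -np.inf
        for L in range(lo, hi + 1):
            val = float(np.dot(x0[:-L], x0[L:])) / (x.size - L) / denom
            best = max(best, val)
        return float(np.clip(best, -1.0, 1.0))

    return at_lag(step_lag_s), at_lag(stride_lag_s)


def autocov_at_lag(axis_signal: np.ndarray, lag_samples: int) -> float:
    """Normalized unbiased autocovariance at one exact integer lag."""
    x = np.asarray(axis_signal, dtype=float)
    x0 = x - x.mean()
    denom = float(np.dot(x0, x0)) / x.size
    if denom == 0:
        return 0.0
    L = int(lag_samples)
    if not (1 <= L < x.size):
        raise InvalidInputError(f"lag {L} outside [1, {x.size - 1}]")
    return float(np.dot(x0[:-L], x0[L:])) / (x.size - L) / denom


def mean_trend(axis_signal: np.ndarray, fs_hz: float, seg: StepSegmentation) -> float:
    """Mean absolute moving average, window = mean step duration."""
    x = np.asarray(axis_signal, dtype=float)
    window = max(1, int(round(seg.mean_step_duration_s * fs_hz)))
    trend = uniform_filter1d(x, size=window, mode="nearest")
    return float(np.mean(np.abs(trend)))


def time_features_axis(
    axis_signal: np.ndarray, seg: StepSegmentation, fs_hz: float
) -> dict[str, float]:
    """The 21 time-domain features for one axis (see :data:`TIME_FEATURES`)."""
    x = np.asarray(axis_signal, dtype=float)
    sl = step_slices(x, seg)

    def per_step(fn) -> float:
        return float(np.mean([fn(s) for s in sl.slices]))

    def per_half(halves, fn) -> float:
        return float(np.mean([fn(h) for h in halves]))

    peak_amps = np.array([np.max(s) for s in sl.slices])
    mean_amp = float(np.mean(peak_amps))
    cv_peak = float(np.std(peak_amps, ddof=1) / abs(mean_amp)) if mean_amp != 0 else 0.0

    stp, strd = autocorr_regularity(
        x, fs_hz, seg.mean_step_duration_s, seg.mean_stride_duration_s
    )
    feats = {
        "mean": per_step(np.mean),
        "std": per_step(np.std),
        "skew": per_step(_safe_skew),
        "kurt": per_step(_safe_kurt),
        "rms": per_step(lambda s: np.sqrt(np.mean(s**2))),
        "range": per_step(np.ptp),
        "median": per_step(np.median),
        "iqr": per_step(lambda s: stats.iqr(s)),
        "mean_FH": per_half(sl.first_halves, np.mean),
        "mean_LH": per_half(sl.last_halves, np.mean),
        "std_FH": per_half(sl.first_halves, np.std),
        "std_LH": per_half(sl.last_halves, np.std),
        "zcr": per_step(_zcr),
        "energy": per_step(lambda s: np.sum(s**2) / len(s)),
        "mav": per_step(lambda s: np.mean(np.abs(s))),
        "mad": per_step(lambda s: np.mean(np.abs(s - np.mean(s)))),
        "cv_peak": cv_peak,
        "StpReg": stp,
        "StrReg": strd,
        "regRatio": stp / strd if strd != 0 else 0.0,
        "meanTrend": mean_trend(x, fs_hz, seg),
    }
    assert list(feats) == list(TIME_FEATURES)
    return feats


def cross_axis_features(
    v: np.ndarray, ml: np.ndarray, ap: np.ndarray
) -> dict[str, float]:
    """Pearson correlation and sample covariance for each axis pair."""
    v, ml, ap = (np.asarray(a, dtype=float) for a in (v, ml, ap))
    if not (v.size == ml.size == ap.size) or v.size < 2:
        raise InvalidInputError("axes must have equal length >= 2")
    for name, a in (("V", v), ("ML", ml), ("AP", ap)):
        if np.std(a) == 0:
            raise InvalidInputError(f"axis {name} is constant: correlation undefined")
    pairs = {"V_ML": (v, ml), "AP_ML": (ap, ml), "V_AP": (v, ap)}
    out: dict[str, float] = {}
    for key, (a, b) in pairs.items():
        out[f"corr_{key}"] = float(np.corrcoef(a, b)[0, 1])
    for key, (a, b) in pairs.items():
        out[f"cov_{key}"] = float(np.cov(a, b, ddof=1)[0, 1])
    return out
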