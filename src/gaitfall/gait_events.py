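"""Step detection on the vertical axis and the basic gait-cycle features.

Steps are located as local maxima of the max-normalized 0.5-3 Hz vertical
signal. A step is the interval between successive peaks; a stride is two
consecutive steps (non-overlapping pairing starting at the first accepted
interval). Intervals outside a physiological window are dropped from the
duration statistics without failing the subject, which tolerates an
occasional missed peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidInputError, NoStepsDetectedError

#: Minimum separation between step peaks (supports cadence up to 240 spm), s.
MIN_PEAK_DISTANCE_S = 0.25
#: Minimum peak height on the max-normalized signal.
MIN_PEAK_HEIGHT = 0.2
#: Plausible step-duration window (open interval), s.
STEP_DURATION_RANGE_S = (0.25, 2.5)
#: Fewer accepted peaks than this is treated as "no steps".
MIN_PEAKS = 8


@dataclass
class StepSegmentation:
    """Detected step peaks and the derived durations for one subject.

    ``step_durations_s`` holds the accepted peak-to-peak intervals (those
    inside :data:`STEP_DURATION_RANGE_S`); implausible intervals are dropped
    from the duration lists while their peak indices are retained.
    """

    fs_hz: float
    peak_indices: np.ndarray
    step_durations_s: np.ndarray
    stride_durations_s: np.ndarray
    cadence_spm: float
    #: indices i such that the interval peak[i]..peak[i+1] was accepted
    accepted_intervals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_json(self) -> str:
        return json.dumps(
            {
                "fs_hz": self.fs_hz,
                "peak_indices": self.peak_indices.tolist(),
                "step_durations_s": self.step_durations_s.tolist(),
                "stride_durations_s": self.stride_durations_s.tolist(),
                "cadence_spm": self.cadence_spm,
                "accepted_intervals": self.accepted_intervals.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StepSegmentation":
        d = json.loads(text)
        return cls(
            fs_hz=d["fs_hz"],
            peak_indices=np.asarray(d["peak_indices"], dtype=int),
            step_durations_s=np.asarray(d["step_durations_s"], dtype=float),
            stride_durations_s=np.asarray(d["stride_durations_s"], dtype=float),
            cadence_spm=d["cadence_spm"],
            accepted_intervals=np.asarray(d["accepted_intervals"], dtype=int),
        )

    @property
    def mean_step_duration_s(self) -> float:
        return float(np.mean(self.step_durations_s))

    @property
    def mean_stride_duration_s(self) -> float:
        return float(np.mean(self.stride_durations_s))


def detect_steps(v_band_step: np.ndarray, fs_hz: float) -> StepSegmentation:
    """Segment steps from the max-normalized 0.5-3 Hz vertical signal."""
    v = np.asarray(v_band_step, dtype=float)
    if v.size < 10 * fs_hz:
        raise InvalidInputError("detect_steps needs at least 10 s of signal")
    peaks, _ = find_peaks(
        v,
        height=MIN_PEAK_HEIGHT,
        distance=max(1, int(round(MIN_PEAK_DISTANCE_S * fs_hz))),
    )
    if peaks.size < MIN_PEAKS:
        raise NoStepsDetectedError(
            f"only {peaks.size} plausible step peaks found (need >= {MIN_PEAKS})"
        )
    raw_durations = np.diff(peaks) / fs_hz
    lo, hi = STEP_DURATION_RANGE_S
    accepted = np.flatnonzero((raw_durations > lo) & (raw_durations < hi))
    step_durations = raw_durations[accepted]
    if step_durations.size < MIN_PEAKS - 1:
        raise NoStepsDetectedError(
            f"only {step_durations.size} plausible step intervals after screening"
        )
    n_pairs = step_durations.size // 2
    stride_durations = (
        step_durations[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
    )
    cadence = 60.0 / float(np.mean(step_durations))
    return StepSegmentation(
        fs_hz=fs_hz,
        peak_indices=peaks,
        step_durations_s=step_durations,
        stride_durations_s=stride_durations,
        cadence_spm=cadence,
        accepted_intervals=accepted,
    )


def gait_cycle_features(seg: StepSegmentation) -> dict[str, float]:
    """Average step duration, average stride duration, cadence (spm)."""
    return {
        "avg_step_dur_s": seg.mean_step_duration_s,
        "avg_stride_dur_s": seg.mean_stride_duration_s,
        "cadence_spm": seg.cadence_spm,
    }
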