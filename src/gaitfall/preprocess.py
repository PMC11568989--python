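"""Signal conditioning for waist-worn tri-axial walking accelerometry.

A raw recording carries vertical (V), mediolateral (ML) and
anterior-posterior (AP) acceleration in g units. Each axis is cleaned with a
3-sample median filter, stripped of its slowly varying gravity component to
leave body acceleration, and band-limited into two versions:

* ``band_step`` (0.5-3 Hz) — used only to locate step peaks on V; the band
  brackets plausible step frequencies.
* ``band_analysis`` (0.5-15 Hz) — feeds every time- and frequency-domain
  feature; nearly all walking signal energy lies below 15 Hz.

Both versions are scaled to unit maximum absolute value per axis, so
downstream amplitude-sensitive features are comparable across subjects and
devices. All filtering is zero-phase, keeping step-peak timing unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateSignalError, InvalidInputError

AXES = ("V", "ML", "AP")

#: Band used only for step-period detection, Hz.
STEP_BAND = (0.5, 3.0)
#: Band used for all feature computation, Hz.
ANALYSIS_BAND = (0.5, 15.0)
#: Cut-off of the zero-phase low-pass whose output is taken as gravity, Hz.
GRAVITY_CUTOFF_HZ = 0.25
#: Order of the Butterworth prototypes (applied forward-backward).
FILTER_ORDER = 4

VALID_LABELS = ("faller", "non_faller", "unknown")


@dataclass
class TriaxialRecording:
    """One subject's raw tri-axial acceleration.

    ``samples`` is an (n, 3) array in g, columns ordered (V, ML, AP).
    """

    subject_id: str
    fs_hz: float
    samples: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def validate(self) -> None:
        """Raise if the recording cannot be processed downstream."""
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidInputError(
                f"{self.subject_id}: samples must be (n, 3), got {self.samples.shape}"
            )
        if self.fs_hz <= 30:
            raise InvalidInputError(
                f"{self.subject_id}: fs_hz={self.fs_hz} must exceed 30 Hz "
                "to support the 15 Hz analysis band edge"
            )
        if self.n_samples < 10 * self.fs_hz:
            raise InvalidInputError(
                f"{self.subject_id}: need at least 10 s of signal, "
                f"got {self.duration_s:.2f} s"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError(f"{self.subject_id}: samples contain non-finite values")
        if self.label not in VALID_LABELS:
            raise InvalidInputError(f"{self.subject_id}: unknown label {self.label!r}")


@dataclass
class PreprocessedRecording:
    """The two filtered, max-normalized versions of a recording."""

    fs_hz: float
    band_step: np.ndarray
    band_analysis: np.ndarray
    subject_id: str = ""

    def axis_step(self, axis: str) -> np.ndarray:
        return self.band_step[:, AXES.index(axis)]

    def axis_analysis(self, axis: str) -> np.ndarray:
        return self.band_analysis[:, AXES.index(axis)]


def median_filter3(x: np.ndarray) -> np.ndarray:
    """3-sample sliding median; edge samples pass through unchanged."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidInputError(f"median_filter3 needs at least 3 samples, got {x.size}")
    # mode='nearest' duplicates the edge sample, so the edge median is the
    # edge sample itself — the shrunken-window convention.
    return ndimage.median_filter(x, size=3, mode="nearest")


def remove_gravity(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """Subtract a zero-phase low-pass (0.25 Hz) gravity estimate."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs_hz:
        raise InvalidInputError("remove_gravity needs at least 2 s of signal")
    sos = signal.butter(FILTER_ORDER, GRAVITY_CUTOFF_HZ, btype="low", fs=fs_hz, output="sos")
    gravity = signal.sosfiltfilt(sos, x)
    body = x - gravity
    # filter edge transients leave a tiny residual offset; remove it so the
    # body acceleration is exactly zero-mean over the record
    return body - body.mean()


def bandpass(x: np.ndarray, fs_hz: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 4, applied forward-backward)."""
    x = np.asarray(x, dtype=float)
    if not (0 < lo_hz < hi_hz < fs_hz / 2):
        raise InvalidInputError(
            f"invalid band ({lo_hz}, {hi_hz}) Hz for fs={fs_hz} Hz"
        )
    sos = signal.butter(FILTER_ORDER, (lo_hz, hi_hz), btype="band", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def normalize_max(x: np.ndarray) -> np.ndarray:
    """Scale so the maximum absolute value is 1; idempotent."""
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        raise DegenerateSignalError("cannot max-normalize an all-zero signal")
    return x / peak


def preprocess_recording(rec: TriaxialRecording) -> PreprocessedRecording:
    """median filter -> gravity removal -> two band-passes -> max-normalize.

    Applied independently per axis; raises :class:`DegenerateSignalError`
    naming the axis if a filtered axis is identically zero.
    """
    rec.validate()
    band_step = np.empty_like(rec.samples)
    band_analysis = np.empty_like(rec.samples)
    for j, axis in enumerate(AXES):
        body = remove_gravity(median_filter3(rec.samples[:, j]), rec.fs_hz)
        for out, (lo, hi) in ((band_step, STEP_BAND), (band_analysis, ANALYSIS_BAND)):
            filtered = bandpass(body, rec.fs_hz, lo, hi)
            try:
                out[:, j] = normalize_max(filtered)
            except DegenerateSignalError as exc:
                raise DegenerateSignalError(
                    f"{rec.subject_id}: axis {axis} is degenerate after filtering"
                ) from exc
    return PreprocessedRecording(
        fs_hz=rec.fs_hz,
        band_step=band_step,
        band_analysis=band_analysis,
        subject_id=rec.subject_id,
    )
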