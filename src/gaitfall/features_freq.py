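"""Frequency-domain gait features from a single Tukey-windowed periodogram.

The PSD of each axis's 0.5-15 Hz body acceleration is estimated with one
periodogram over the whole record, tapered by a Tukey window with cosine
fraction 0.5 (density scaling, no detrending). All 32 features are computed
on the 0.5-15 Hz band: the two most prominent spectral peaks (frequency,
amplitude, width at half prominence, prominence), audio-style shape
descriptors (centroid, spread, skewness, kurtosis, flatness, crest,
decrease, slope, rolloff, entropy), band statistics including the first and
last halves of the band (split at 7.75 Hz), and relative powers of the
0.5-3, 3-8 and 8-15 Hz sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateSpectrumError, InvalidInputError

#: Analysis band (Hz); every feature reads power only inside it.
BAND = (0.5, 15.0)
#: Split frequency between the "first half" and "last half" of the band.
BAND_SPLIT_HZ = (BAND[0] + BAND[1]) / 2  # 7.75 Hz
#: Sub-bands for relative power.
SUB_BANDS = ((0.5, 3.0), (3.0, 8.0), (8.0, 15.0))
TUKEY_ALPHA = 0.5
MIN_SAMPLES = 256
ROLLOFF_FRACTION = 0.95

#: Registry of the 32 per-axis frequency-domain feature names, in order.
FREQ_FEATURES = (
    "F1",
    "AmpF1",
    "wF1",
    "pF1",
    "F2",
    "AmpF2",
    "wF2",
    "pF2",
    "centroid_PSD",
    "spread_PSD",
    "skew_PSD",
    "kurt_PSD",
    "flatness_PSD",
    "crest_PSD",
    "decrease_PSD",
    "slope_PSD",
    "rolloff_PSD",
    "entropy_PSD",
    "mean_PSD",
    "med_PSD",
    "std_PSD",
    "max_PSD",
    "mean_FH_PSD",
    "mean_LH_PSD",
    "med_FH_PSD",
    "med_LH_PSD",
    "relpow_low",
    "relpow_mid",
    "relpow_high",
    "totpow_PSD",
    "ratio_F2F1",
    "medfreq_PSD",
)


@dataclass
class PSDEstimate:
    """One-sided periodogram with the 0.5-15 Hz band mask.

    With density scaling, sum(power) * df equals the window-power-normalized
    mean square of the tapered signal (the Parseval contract for this
    scaling).
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    band_mask: np.ndarray

    @property
    def band_freqs(self) -> np.ndarray:
        return self.freqs_hz[self.band_mask]

    @property
    def band_power(self) -> np.ndarray:
        return self.power[self.band_mask]

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def validate(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise InvalidInputError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise InvalidInputError("PSD power must be nonnegative")


def periodogram_tukey(axis_signal: np.ndarray, fs_hz: float) -> PSDEstimate:
    """Single whole-record periodogram with a Tukey(0.5) taper."""
    x = np.asarray(axis_signal, dtype=float)
    if x.size < MIN_SAMPLES:
        raise InvalidInputError(
            f"periodogram needs >= {MIN_SAMPLES} samples, got {x.size}"
        )
    freqs, power = signal.periodogram(
        x, fs=fs_hz, window=("tukey", TUKEY_ALPHA), scaling="density", detrend=False
    )
    mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    est = PSDEstimate(freqs_hz=freqs, power=power, band_mask=mask)
    est.validate()
    return est


def _peak_descriptor(freq: float, amp: float, width: float, prom: float) -> dict[str, float]:
    return {"freq_hz": freq, "amplitude": amp, "width_hz": width, "prominence": prom}


_ZERO_PEAK = _peak_descriptor(0.0, 0.0, 0.0, 0.0)


def dominant_peaks(psd: PSDEstimate) -> tuple[dict[str, float], dict[str, float]]:
    """The two most prominent in-band spectral peaks, most prominent first.

    Width is measured at half prominence, in Hz. When the band spectrum has
    fewer than two interior local maxima, the missing descriptors fall back
    to zeros (frequency 0, amplitude 0, width 0, prominence 0); a spectrum
    with no interior maximum at all contributes its global maximum as the
    first peak with zero width and prominence.
    """
    p = psd.band_power
    f = psd.band_freqs
    df = psd.df
    peaks, _ = signal.find_peaks(p)
    if peaks.size == 0:
        if p.size == 0 or np.max(p) == 0:
            return dict(_ZERO_PEAK), dict(_ZERO_PEAK)
        i = int(np.argmax(p))
        return _peak_descriptor(float(f[i]), float(p[i]), 0.0, 0.0), dict(_ZERO_PEAK)
    proms = signal.peak_prominences(p, peaks)[0]
    widths = signal.peak_widths(p, peaks, rel_height=0.5)[0] * df
    # rank by prominence descending; break ties toward lower frequency
    order = np.lexsort((f[peaks], -proms))
    descs = [
        _peak_descriptor(float(f[peaks[i]]), float(p[peaks[i]]), float(widths[i]), float(proms[i]))
        for i in order[:2]
    ]
    if len(descs) < 2:
        descs.append(dict(_ZERO_PEAK))
    return descs[0], descs[1]


def freq_features_axis(psd: PSDEstimate) -> dict[str, float]:
    """The 32 frequency-domain features for one axis (see :data:`FREQ_FEATURES`)."""
    p = psd.band_power
    f = psd.band_freqs
    total = float(np.sum(p))
    if p.size == 0 or total == 0:
        raise DegenerateSpectrumError("no power in the 0.5-15 Hz band")

    w = p / total  # spectral distribution over frequency
    centroid = float(np.sum(f * w))
    spread = float(np.sqrt(np.sum((f - centroid) ** 2 * w)))
    if spread > 0:
        z = (f - centroid) / spread
        skew_psd = float(np.sum(z**3 * w))
        kurt_psd = float(np.sum(z**4 * w))
    else:
        skew_psd = 0.0
        kurt_psd = 0.0

    mean_p = total / p.size
    flatness = float(np.exp(np.mean(np.log(p))) / mean_p) if np.all(p > 0) else 0.0
    crest = float(np.max(p) / mean_p)

    # spectral decrease: average slope relative to the first band bin
    k = np.arange(2, p.size + 1)
    tail = p[1:]
    decrease = float(np.sum((tail - p[0]) / (k - 1)) / np.sum(tail)) if np.sum(tail) > 0 else 0.0
    slope = float(np.polyfit(f, p, 1)[0])

    cum = np.cumsum(p)
    rolloff = float(f[int(np.searchsorted(cum, ROLLOFF_FRACTION * total))])
    medfreq = float(f[int(np.searchsorted(cum, 0.5 * total))])

    nz = w[w > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(p.size)) if p.size > 1 else 0.0

    first = p[f <= BAND_SPLIT_HZ]
    last = p[f > BAND_SPLIT_HZ]
    rel = []
    for lo, hi in SUB_BANDS:
        sel = (f >= lo) & (f < hi) if hi < BAND[1] else (f >= lo) & (f <= hi)
        rel.append(float(np.sum(p[sel]) / total))

    pk1, pk2 = dominant_peaks(psd)

    feats = {
        "F1": pk1["freq_hz"],
        "AmpF1": pk1["amplitude"],
        "wF1": pk1["width_hz"],
        "pF1": pk1["prominence"],
        "F2": pk2["freq_hz"],
        "AmpF2": pk2["amplitude"],
        "wF2": pk2["width_hz"],
        "pF2": pk2["prominence"],
        "centroid_PSD": centroid,
        "spread_PSD": spread,
        "skew_PSD": skew_psd,
        "kurt_PSD": kurt_psd,
        "flatness_PSD": flatness,
        "crest_PSD": crest,
        "decrease_PSD": decrease,
        "slope_PSD": slope,
        "rolloff_PSD": rolloff,
        "entropy_PSD": entropy,
        "mean_PSD": mean_p,
        "med_PSD": float(np.median(p)),
        "std_PSD": float(np.std(p)),
        "max_PSD": float(np.max(p)),
        "mean_FH_PSD": float(np.mean(first)) if first.size else 0.0,
        "mean_LH_PSD": float(np.mean(last)) if last.size else 0.0,
        "med_FH_PSD": float(np.median(first)) if first.size else 0.0,
        "med_LH_PSD": float(np.median(last)) if last.size else 0.0,
        "relpow_low": rel[0],
        "relpow_mid": rel[1],
        "relpow_high": rel[2],
        "totpow_PSD": total * psd.df,
        "ratio_F2F1": pk2["amplitude"] / pk1["amplitude"] if pk1["amplitude"] > 0 else 0.0,
        "medfreq_PSD": medfreq,
    }
    assert list(feats) == list(FREQ_FEATURES)
    return feats
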