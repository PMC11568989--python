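"""Assembly of the canonical 168-feature vector and the cohort matrix.

The registry order is fixed: 3 gait-cycle features (V only), 6 cross-axis
correlation/covariance features, then for each axis in (V, ML, AP) the 21
time-domain and 32 frequency-domain features, suffixed ``_V``/``_ML``/``_AP``.
That yields 3 + 6 + 3*(21 + 32) = 168 columns, identical for every subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortInvalidError, GaitFallError, InvalidInputError
from .features_freq import FREQ_FEATURES, freq_features_axis, periodogram_tukey
from .features_time import (
    CROSS_AXIS_FEATURES,
    TIME_FEATURES,
    cross_axis_features,
    time_features_axis,
)
from .gait_events import detect_steps, gait_cycle_features
from .preprocess import AXES, TriaxialRecording, preprocess_recording

log = logging.getLogger(__name__)

GAIT_CYCLE_FEATURES = ("avg_step_dur_s", "avg_stride_dur_s", "cadence_spm")

N_FEATURES = 168


def feature_names() -> list[str]:
    """The fixed registry order of all 168 feature names."""
    names = list(GAIT_CYCLE_FEATURES) + list(CROSS_AXIS_FEATURES)
    for axis in AXES:
        names += [f"{n}_{axis}" for n in TIME_FEATURES]
        names += [f"{n}_{axis}" for n in FREQ_FEATURES]
    assert len(names) == N_FEATURES == 3 + 6 + 3 * (21 + 32)
    return names


FEATURE_NAMES = tuple(feature_names())


def extract_features(rec: TriaxialRecording) -> pd.Series:
    """Run the full per-subject pipeline and return the ordered 168-vector.

    preprocess -> step detection on the vertical 0.5-3 Hz signal ->
    gait-cycle + cross-axis + per-axis time and frequency features, all on
    the 0.5-15 Hz signals. Errors are re-raised with the subject id attached.
    """
    try:
        pre = preprocess_recording(rec)
        seg = detect_steps(pre.axis_step("V"), pre.fs_hz)
        values: dict[str, float] = {}
        values.update(gait_cycle_features(seg))
        values.update(
            cross_axis_features(
                pre.axis_analysis("V"), pre.axis_analysis("ML"), pre.axis_analysis("AP")
            )
        )
        for axis in AXES:
            x = pre.axis_analysis(axis)
            tf = time_features_axis(x, seg, pre.fs_hz)
            ff = freq_features_axis(periodogram_tukey(x, pre.fs_hz))
            values.update({f"{k}_{axis}": v for k, v in tf.items()})
            values.update({f"{k}_{axis}": v for k, v in ff.items()})
    except GaitFallError as exc:
        raise type(exc)(f"subject {rec.subject_id}: {exc}") from exc
    vec = pd.Series(values, dtype=float).reindex(list(FEATURE_NAMES))
    if vec.isna().any() or not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise InvalidInputError(f"subject {rec.subject_id}: non-finite features {bad}")
    return vec


@dataclass
class FeatureMatrix:
    """Cohort feature table: subjects x 168, with labels (faller = positive)."""

    X: pd.DataFrame
    labels: pd.Series
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    def y(self) -> np.ndarray:
        """Binary label vector, 1 = faller."""
        return (self.labels == "faller").to_numpy(dtype=int)

    def validate(self) -> None:
        if list(self.X.columns) != list(FEATURE_NAMES):
            raise CohortInvalidError("feature columns do not match the registry order")
        counts = self.labels.value_counts()
        if counts.get("faller", 0) < 2 or counts.get("non_faller", 0) < 2:
            raise CohortInvalidError(
                f"need >= 2 subjects per class, got {counts.to_dict()}"
            )
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise CohortInvalidError("feature matrix contains non-finite values")


def build_matrix(cohort: list[TriaxialRecording]) -> FeatureMatrix:
    """Extract features for every subject; failures are excluded and logged."""
    if len(cohort) < 4:
        raise CohortInvalidError(f"need >= 4 subjects, got {len(cohort)}")
    rows, labels, excluded = {}, {}, []
    for rec in cohort:
        try:
            rows[rec.subject_id] = extract_features(rec)
            labels[rec.subject_id] = rec.label
        except GaitFallError as exc:
            log.warning("excluding %s: %s", rec.subject_id, exc)
            excluded.append((rec.subject_id, str(exc)))
    if not rows:
        raise CohortInvalidError("no subject survived feature extraction")
    X = pd.DataFrame(rows).T.reindex(columns=list(FEATURE_NAMES))
    matrix = FeatureMatrix(X=X, labels=pd.Series(labels), exclusions=excluded)
    matrix.validate()
    return matrix


@dataclass
class MinMaxParams:
    """Column-wise min-max parameters, fit on training data only."""

    mins: pd.Series
    ranges: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        ranges = self.ranges.replace(0.0, np.inf)  # constant columns -> 0
        return (X - self.mins) / ranges


def fit_minmax(X: pd.DataFrame) -> MinMaxParams:
    mins = X.min(axis=0)
    return MinMaxParams(mins=mins, ranges=X.max(axis=0) - mins)


def minmax_scale(matrix: FeatureMatrix) -> tuple[FeatureMatrix, MinMaxParams]:
    """Map every column to [0, 1]; constant columns map to 0."""
    if matrix.n_subjects < 2:
        raise CohortInvalidError("min-max scaling needs >= 2 subjects")
    params = fit_minmax(matrix.X)
    scaled = FeatureMatrix(
        X=params.transform(matrix.X),
        labels=matrix.labels,
        exclusions=list(matrix.exclusions),
    )
    return scaled, params


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """CSV with header subject_id,label,<168 feature names>."""
    df = matrix.X.copy()
    df.insert(0, "label", matrix.labels)
    df.index.name = "subject_id"
    df.to_csv(path)


def read_feature_table(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    labels = df.pop("label")
    matrix = FeatureMatrix(X=df, labels=labels)
    matrix.validate()
    return matrix
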