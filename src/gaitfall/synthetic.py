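"""Synthetic quasi-periodic walking acceleration cohorts.

Each subject is a harmonic oscillation at an individual step frequency with
step-to-step timing and amplitude jitter, axis-specific harmonic content,
additive white noise, and a 1 g gravity offset on the vertical axis. The
vertical and anterior-posterior axes oscillate at the step frequency; the
mediolateral axis is dominated by the stride frequency (half the step
frequency), reflecting the left/right alternation of gait. Fallers are
drawn from a higher-jitter (less regular) parameter regime than
non-fallers, which reproduces the regularity gap the classifier is meant to
detect.

Generation is fully deterministic given a seed; cohort subjects get
independent child seeds spawned from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError
from .preprocess import TriaxialRecording

#: Per-axis amplitudes of harmonics 1..4 of the axis base frequency, in g.
#: V and AP use the step frequency as base; ML uses the stride frequency.
DEFAULT_HARMONIC_AMPS = {
    "V": (0.40, 0.15, 0.06, 0.02),
    "ML": (0.20, 0.12, 0.05, 0.02),
    "AP": (0.25, 0.10, 0.04, 0.015),
}
#: Fixed per-axis harmonic phase offsets (radians).
HARMONIC_PHASES = {
    "V": (0.0, 0.4, 0.8, 1.2),
    "ML": (0.0, 0.6, 1.1, 1.7),
    "AP": (0.5, 0.9, 1.4, 1.9),
}

#: Default step-frequency draw for cohort subjects, Hz.
F_STEP_RANGE = (1.6, 2.1)


@dataclass
class GaitProfile:
    """Generator parameters for one subject."""

    f_step_hz: float = 1.9
    timing_jitter: float = 0.02  # std of per-step period perturbation, fraction
    amp_jitter: float = 0.05  # std of per-step amplitude scaling, fraction
    noise_sd: float = 0.02  # additive white noise std, g
    gravity_v: float = 1.0  # constant vertical offset, g
    harmonic_amps: dict = field(default_factory=lambda: dict(DEFAULT_HARMONIC_AMPS))

    def validate(self) -> None:
        if not (1.0 <= self.f_step_hz <= 3.0):
            raise InvalidInputError(f"f_step_hz={self.f_step_hz} outside [1, 3]")
        if min(self.timing_jitter, self.amp_jitter, self.noise_sd) < 0:
            raise InvalidInputError("jitters and noise_sd must be >= 0")


#: Class parameter regimes: fallers walk with markedly less regular timing
#: and amplitude. ``hard`` variants overlap and are meant for robustness
#: studies, not for acceptance checks.
NON_FALLER_PROFILE = GaitProfile(timing_jitter=0.02, amp_jitter=0.05)
FALLER_PROFILE = GaitProfile(timing_jitter=0.08, amp_jitter=0.15)
NON_FALLER_PROFILE_HARD = GaitProfile(timing_jitter=0.03, amp_jitter=0.06)
FALLER_PROFILE_HARD = GaitProfile(timing_jitter=0.05, amp_jitter=0.09)


@dataclass
class CohortSpec:
    """Cohort composition; defaults mirror the study cohort shape."""

    n_fallers: int = 35
    n_nonfallers: int = 38
    duration_s: float = 60.0
    fs_hz: float = 100.0
    seed: int = 0
    hard: bool = False

    def validate(self) -> None:
        if self.n_fallers < 2 or self.n_nonfallers < 2:
            raise InvalidInputError("need >= 2 subjects per class")
        if self.duration_s < 10:
            raise InvalidInputError("duration must be >= 10 s")


def generate_subject(
    profile: GaitProfile,
    duration_s: float,
    fs_hz: float,
    seed: int,
    subject_id: str = "synthetic",
    label: str = "unknown",
) -> TriaxialRecording:
    """One tri-axial recording from the harmonic jitter model.

    Step periods are T0 * (1 + timing_jitter * eps) with standard-normal
    eps, clipped to [0.5, 1.5] * T0; the instantaneous phase advances
    linearly through each step. Each step carries an amplitude scale
    1 + amp_jitter * eps (clipped at 0.1) shared by all axes.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    T0 = 1.0 / profile.f_step_hz

    # enough steps to cover the record even if every period is short
    max_steps = int(np.ceil(duration_s / (0.5 * T0))) + 4
    eps = rng.standard_normal(max_steps)
    periods = np.clip(T0 * (1.0 + profile.timing_jitter * eps), 0.5 * T0, 1.5 * T0)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    amp_scales = np.clip(
        1.0 + profile.amp_jitter * rng.standard_normal(max_steps), 0.1, None
    )

    step_idx = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, max_steps - 1)
    frac = (t - boundaries[step_idx]) / periods[step_idx]
    phase_steps = step_idx + frac  # cumulative phase in step units
    scale = amp_scales[step_idx]

    samples = np.empty((n, 3))
    for j, axis in enumerate(("V", "ML", "AP")):
        base = 0.5 if axis == "ML" else 1.0  # ML oscillates at stride frequency
        amps = profile.harmonic_amps[axis]
        phases = HARMONIC_PHASES[axis]
        wave = np.zeros(n)
        for h, (A, ph) in enumerate(zip(amps, phases), start=1):
            wave += A * np.cos(2 * np.pi * h * base * phase_steps + ph)
        samples[:, j] = scale * wave + profile.noise_sd * rng.standard_normal(n)
    samples[:, 0] += profile.gravity_v
    return TriaxialRecording(
        subject_id=subject_id, fs_hz=fs_hz, samples=samples, label=label
    )


def generate_cohort(spec: CohortSpec) -> list[TriaxialRecording]:
    """Labeled cohort with per-subject seeds spawned from the cohort seed.

    Subject step frequencies are drawn uniformly from 1.6-2.1 Hz; per-subject
    jitters vary around the class regime by +/-20% so the classes are
    distributions, not two points.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_fallers + spec.n_nonfallers
    children = ss.spawn(n_total + 1)
    rng = np.random.default_rng(children[0])
    if spec.hard:
        profiles = (FALLER_PROFILE_HARD, NON_FALLER_PROFILE_HARD)
    else:
        profiles = (FALLER_PROFILE, NON_FALLER_PROFILE)
    cohort: list[TriaxialRecording] = []
    plan = [("faller", "F", profiles[0], spec.n_fallers), (
        "non_faller", "N", profiles[1], spec.n_nonfallers)]
    k = 1
    for label, prefix, base_profile, count in plan:
        for i in range(count):
            f_step = rng.uniform(*F_STEP_RANGE)
            wobble = rng.uniform(0.8, 1.2, size=2)
            profile = replace(
                base_profile,
                f_step_hz=f_step,
                timing_jitter=base_profile.timing_jitter * wobble[0],
                amp_jitter=base_profile.amp_jitter * wobble[1],
            )
            subject_seed = int(children[k].generate_state(1)[0] % (2**31))
            cohort.append(
                generate_subject(
                    profile,
                    spec.duration_s,
                    spec.fs_hz,
                    seed=subject_seed,
                    subject_id=f"{prefix}{i + 1:03d}",
                    label=label,
                )
            )
            k += 1
    return cohort
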