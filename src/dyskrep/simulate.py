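"""Synthetic wrist-accelerometer cohorts for the pronation-supination task.

Stands in for restricted clinical cohorts when developing and testing the
pipeline.  The task (UPDRS item 3.6) is a rapid alternating rotation of the
forearm; what a wrist accelerometer mainly records is gravity re-orienting
in the sensor frame as the wrist angle oscillates.  The generator therefore
models the wrist angle directly,

    theta(t) = A * sin(2*pi*f*t + phi),

rotates the (per-subject) gravity direction about the forearm axis by
theta(t), and adds a tangential acceleration term proportional to
theta''(t) plus white sensor noise.  ``A`` is the angular amplitude in
radians; the resulting g-scale signal follows from the geometry.

Dyskinetic sessions (label 1) superimpose on theta an irregular band-limited
(default 1-4 Hz) stochastic oscillation with slow amplitude modulation plus
Poisson jerk transients — a caricature of choreiform levodopa-induced
dyskinesia.  ``dysk_severity`` scales the whole overlay: at 0 the two
classes coincide exactly; at 1 the overlay's RMS matches the voluntary
movement's.  Sessions are variable length; subjects carry random effects
(own amplitude, frequency, gravity perturbation) shared across their
sessions; labels are Bernoulli(prevalence).  Everything is determined by
the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MANIFEST_COLUMNS, AccelSession, CohortManifest, STANDARD_GRAVITY


@dataclass
class SyntheticParams:
    """Cohort-level generator settings (defaults emulate an in-clinic source site)."""

    n_subjects: int = 25
    sessions_per_subject: tuple[int, int] = (2, 6)       # inclusive range
    prevalence: float = 0.3                              # fraction of dyskinetic sessions
    sample_rate: float = 50.0                            # Hz
    duration: tuple[float, float] = (10.0, 30.0)         # s, uniform per session
    task_freq: tuple[float, float] = (0.8, 2.0)          # Hz, per subject
    task_amplitude: tuple[float, float] = (0.4, 0.9)     # rad, angular amplitude
    dysk_severity: float = 1.0                           # 0 = classes identical
    dysk_band: tuple[float, float] = (1.0, 4.0)          # Hz
    dysk_am_depth: float = 0.5                           # amplitude-modulation depth
    jerk_rate: float = 0.2                               # transients per second
    noise_sd: float = 0.03                               # g, per-axis white noise
    gravity_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    subject_gravity_jitter: float = 0.25                 # rad, per-subject tilt sd
    sensor_radius: float = 0.03                          # m, lever arm for tangential term
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("sample_rate", "noise_sd", "jerk_rate"):
            if getattr(self, name) < 0 or (name == "sample_rate" and self.sample_rate <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("sessions_per_subject", "duration", "task_freq", "task_amplitude",
                     "dysk_band"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not (0.0 <= self.dysk_severity <= 1.5):
            raise ValueError("dysk_severity must be in [0, 1.5]")
        g = np.asarray(self.gravity_dir, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise ValueError("gravity_dir must be a unit vector")


def shifted_site(params: SyntheticParams) -> SyntheticParams:
    """Covariate-shifted target-site preset: double noise, 30 Hz, tilted gravity.

    Emulates a second clinic with a different device: coarser sampling,
    noisier sensor, and a systematically different wearing orientation.
    """
    g = np.asarray(params.gravity_dir, dtype=float)
    # rotate gravity 60 degrees about the y axis
    c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
    R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return replace(
        params,
        noise_sd=params.noise_sd * 2.0,
        sample_rate=30.0,
        gravity_dir=tuple(R @ g),
    )


def _band_limited_noise(n: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS stochastic oscillation confined to a frequency band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():                       # band above Nyquist: keep top bin
        mask[-1] = True
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _rotate_about_x(g: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Sensor-frame gravity when the sensor rotates by theta about its x axis."""
    c, s = np.cos(theta), np.sin(theta)
    return np.stack([
        np.full_like(theta, g[0]),
        g[1] * c + g[2] * s,
        -g[1] * s + g[2] * c,
    ], axis=1)


@dataclass
class _SubjectEffects:
    amplitude: float
    freq: float
    gravity_dir: np.ndarray


def generate_session(
    params: SyntheticParams,
    label: int,
    seed: int,
    session_id: str = "s0",
    subject_id: str = "subj0",
    dataset_tag: str = "synthetic",
    effects: _SubjectEffects | None = None,
) -> AccelSession:
    """Generate one labeled session; fully determined by ``seed``."""
    params.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    fs = params.sample_rate
    duration = rng.uniform(*params.duration)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    if effects is None:
        effects = _SubjectEffects(
            amplitude=rng.uniform(*params.task_amplitude),
            freq=rng.uniform(*params.task_freq),
            gravity_dir=np.asarray(params.gravity_dir, dtype=float),
        )
    A = effects.amplitude
    f = effects.freq * rng.uniform(0.9, 1.1)         # session-to-session pacing drift
    phi = rng.uniform(0.0, 2.0 * np.pi)

    theta = A * np.sin(2.0 * np.pi * f * t + phi)
    if label == 1 and params.dysk_severity > 0:
        b = _band_limited_noise(n, fs, params.dysk_band, rng)
        am = 1.0 + params.dysk_am_depth * np.sin(
            2.0 * np.pi * rng.uniform(0.1, 0.3) * t + rng.uniform(0.0, 2.0 * np.pi)
        )
        theta = theta + params.dysk_severity * (A / np.sqrt(2.0)) * b * am
    elif label == 1:
        # severity 0: consume the same random draws so only the (zero) overlay differs
        _ = _band_limited_noise(n, fs, params.dysk_band, rng)
        _ = rng.uniform(0.1, 0.3), rng.uniform(0.0, 2.0 * np.pi)

    acc = _rotate_about_x(effects.gravity_dir, theta)
    # tangential acceleration of the sensor on its lever arm, in g-units
    dt = 1.0 / fs
    theta_dd = np.gradient(np.gradient(theta, dt), dt)
    acc[:, 1] += params.sensor_radius * theta_dd / STANDARD_GRAVITY

    if label == 1 and params.dysk_severity > 0 and params.jerk_rate > 0:
        n_jerks = rng.poisson(params.jerk_rate * duration)
        for _ in range(n_jerks):
            t0 = rng.uniform(0.0, duration)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            amp = params.dysk_severity * rng.uniform(0.2, 0.6)
            pulse = amp * np.exp(-np.clip(t - t0, 0.0, None) / 0.05) * (t >= t0)
            acc += pulse[:, None] * direction

    if params.noise_sd > 0:
        acc = acc + rng.normal(0.0, params.noise_sd, size=acc.shape)

    return AccelSession(
        session_id=session_id,
        subject_id=subject_id,
        dataset_tag=dataset_tag,
        task_tag="UPDRS_3_6",
        sample_rate=(n - 1) / (t[-1] - t[0]),
        timestamps=t,
        acc=acc,
        label=int(label),
    )


def _perturbed_gravity(g: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    tilt = rng.normal(0.0, jitter, size=3)
    v = g + tilt
    return v / np.linalg.norm(v)


def generate_cohort(
    params: SyntheticParams, dataset_tag: str = "synthetic"
) -> tuple[CohortManifest, list[AccelSession]]:
    """Generate a labeled cohort with per-subject random effects.

    Subjects share their own amplitude, pace and wearing orientation across
    sessions; labels are Bernoulli(prevalence) per session.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    g = np.asarray(params.gravity_dir, dtype=float)
    sessions, rows = [], []
    for si in range(params.n_subjects):
        effects = _SubjectEffects(
            amplitude=rng.uniform(*params.task_amplitude),
            freq=rng.uniform(*params.task_freq),
            gravity_dir=_perturbed_gravity(g, params.subject_gravity_jitter, rng),
        )
        n_sessions = int(rng.integers(params.sessions_per_subject[0],
                                      params.sessions_per_subject[1] + 1))
        for vi in range(n_sessions):
            label = int(rng.uniform() < params.prevalence)
            sid = f"{dataset_tag}_subj{si:03d}_v{vi:02d}"
            session_seed = int(rng.integers(0, 2**31 - 1))
            sess = generate_session(
                params, label, session_seed,
                session_id=sid, subject_id=f"subj{si:03d}",
                dataset_tag=dataset_tag, effects=effects,
            )
            sessions.append(sess)
            rows.append({
                "file": f"{sid}.csv",
                "session_id": sid,
                "subject_id": sess.subject_id,
                "dataset_tag": dataset_tag,
                "label": label,
                "task_tag": "UPDRS_3_6",
            })
    manifest = CohortManifest(rows=pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    return manifest, sessions


def write_cohort(
    manifest: CohortManifest,
    sessions: list[AccelSession],
    out_dir: str | os.PathLike,
    force: bool = False,
) -> str:
    """Write one CSV per session plus ``manifest.tsv``; round-trippable by the reader."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    if os.path.exists(manifest_path) and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    by_id = {s.session_id: s for s in sessions}
    for row in manifest:
        sess = by_id[row["session_id"]]
        df = pd.DataFrame({
            "t": sess.timestamps,
            "x": sess.acc[:, 0],
            "y": sess.acc[:, 1],
            "z": sess.acc[:, 2],
        })
        df.to_csv(os.path.join(out_dir, row["file"]), index=False, float_format="%.8f")
    manifest.rows.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
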