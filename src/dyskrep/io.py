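"""Reading, validating and harmonizing wrist-accelerometer task sessions.

A *session* is one variable-length tri-axial recording of the rapid
alternating pronation–supination task (UPDRS item 3.6), labeled in its
entirety by a clinician as dyskinetic (1) or not (0).  Sessions arrive as
plain CSV files (``t,x,y,z``; seconds and g-units) referenced from a
tab-separated cohort manifest.  Full task windows are retained: nothing in
this module truncates, pads or resamples.

Device coordinate frames differ between wearables and wearings; a global
rotation maps each session's mean acceleration (the gravity estimate for
this quasi-stationary task) onto the +z axis, so that downstream analysis
sees a common frame up to the residual yaw about gravity.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard gravity, used to convert m/s² inputs to g-units.
STANDARD_GRAVITY = 9.80665

#: Default minimum session duration in seconds.
MIN_DURATION_S = 5.0

MANIFEST_COLUMNS = ["file", "session_id", "subject_id", "dataset_tag", "label", "task_tag"]


@dataclass
class AccelSession:
    """One labeled variable-length tri-axial accelerometer recording."""

    session_id: str
    subject_id: str
    dataset_tag: str
    task_tag: str
    sample_rate: float          # Hz, average rate (n-1)/(t_last - t_first)
    timestamps: np.ndarray      # seconds, strictly increasing
    acc: np.ndarray             # (n, 3) in g-units
    label: int                  # 1 = dyskinesia present
    rotated: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"session {self.session_id}: acc must be (n, 3)")
        if len(self.timestamps) != len(self.acc):
            raise ValueError(f"session {self.session_id}: timestamps/acc length mismatch")
        if self.label not in (0, 1):
            raise ValueError(f"session {self.session_id}: label must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Task duration in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def validate(self, min_duration: float = MIN_DURATION_S) -> list[str]:
        """Return a list of human-readable problems (empty if valid)."""
        problems = []
        if self.n_samples < 2:
            problems.append("fewer than 2 samples")
            return problems
        if not np.all(np.diff(self.timestamps) > 0):
            problems.append("timestamps not strictly increasing")
        if not np.all(np.isfinite(self.acc)):
            problems.append("non-finite acceleration values")
        if not np.all(np.isfinite(self.timestamps)):
            problems.append("non-finite timestamps")
        if self.duration < min_duration:
            problems.append(f"too short: {self.duration:.2f} s < {min_duration:g} s minimum")
        return problems


@dataclass
class CohortManifest:
    """Table of sessions in a cohort: file paths, ids, dataset tags, labels."""

    rows: pd.DataFrame
    path: str | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return (row for _, row in self.rows.iterrows())


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a tab-separated cohort manifest and validate its invariants.

    The manifest must have a header row with the six columns
    ``file, session_id, subject_id, dataset_tag, label, task_tag``;
    ``file`` paths are resolved relative to the manifest's directory.
    """
    rows = pd.read_csv(path, sep="\t", dtype={"session_id": str, "subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    dupes = rows["session_id"][rows["session_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"manifest {path}: duplicate session_id(s) {sorted(set(dupes))}")
    bad_labels = rows.loc[~rows["label"].isin([0, 1]), "session_id"].tolist()
    if bad_labels:
        raise ValueError(f"manifest {path}: non-binary label for session(s) {bad_labels}")
    base = os.path.dirname(os.fspath(path))
    for _, row in rows.iterrows():
        fp = os.path.join(base, row["file"])
        if not os.path.exists(fp):
            raise FileNotFoundError(
                f"manifest {path}: session {row['session_id']} references missing file {fp}"
            )
    return CohortManifest(rows=rows[MANIFEST_COLUMNS].copy(), path=os.fspath(path))


def read_session(path: str | os.PathLike, meta: pd.Series | dict, unit: str = "g") -> AccelSession:
    """Read one session CSV (columns ``t,x,y,z``) into an :class:`AccelSession`.

    Rows containing NaN are dropped (count logged).  The sample rate is the
    average rate ``(n - 1) / (t_last - t_first)``; no resampling happens.
    ``unit`` may be ``"g"`` (default) or ``"ms2"`` (divided by 9.80665).
    """
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
        if df[col].isna().all():
            raise ValueError(f"{path}: column '{col}' is entirely NaN")
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("%s: dropped %d NaN row(s)", path, n_dropped)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 usable samples")
    t = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: timestamps not strictly increasing")
    acc = df[["x", "y", "z"]].to_numpy(dtype=float)
    if unit == "ms2":
        acc = acc / STANDARD_GRAVITY
    elif unit != "g":
        raise ValueError(f"unknown unit {unit!r}; expected 'g' or 'ms2'")
    meta = dict(meta)
    return AccelSession(
        session_id=str(meta["session_id"]),
        subject_id=str(meta["subject_id"]),
        dataset_tag=str(meta["dataset_tag"]),
        task_tag=str(meta.get("task_tag", "UPDRS_3_6")),
        sample_rate=(len(t) - 1) / (t[-1] - t[0]),
        timestamps=t,
        acc=acc,
        label=int(meta["label"]),
    )


def load_cohort(manifest: CohortManifest, unit: str = "g") -> list[AccelSession]:
    """Load every session referenced by a manifest, in manifest order."""
    base = os.path.dirname(manifest.path) if manifest.path else ""
    return [
        read_session(os.path.join(base, row["file"]), row, unit=unit) for row in manifest
    ]


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Minimal (geodesic) rotation matrix mapping unit vector ``v`` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(v, z), -1.0, 1.0))
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:                       # already aligned
            return np.eye(3)
        # antipodal: rotate 180 degrees about x (any axis perpendicular to z)
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def global_rotation_align(session: AccelSession) -> AccelSession:
    """Rotate a session so its mean acceleration (gravity estimate) lies on +z.

    The rotation is the minimal one in the plane spanned by the mean vector
    and +z; per-sample norms are preserved exactly (rotations are isometries).
    The residual yaw about gravity is left undetermined — downstream
    per-session PCA is invariant to it.
    """
    if session.rotated:
        raise ValueError(f"session {session.session_id}: already rotated")
    mean = session.acc.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 0.1:
        raise ValueError(
            f"session {session.session_id}: no stable gravity estimate "
            f"(|mean acc| = {norm:.3f} g < 0.1 g)"
        )
    R = _rotation_to_z(mean / norm)
    return replace(session, acc=session.acc @ R.T, rotated=True)


@dataclass
class CohortReport:
    """Per-session validation outcome plus retention counts."""

    per_session: pd.DataFrame               # session_id, passed, reasons
    counts: pd.DataFrame                    # retained counts per dataset_tag x label
    n_total: int = 0
    n_retained: int = 0
    failures: dict[str, str] = field(default_factory=dict)


def validate_cohort(
    manifest: CohortManifest,
    sessions: list[AccelSession],
    min_duration: float = MIN_DURATION_S,
) -> CohortReport:
    """Report-only validation: per-session pass/fail and retention counts."""
    records, failures, retained = [], {}, []
    for sess in sessions:
        problems = sess.validate(min_duration=min_duration)
        passed = not problems
        records.append(
            {"session_id": sess.session_id, "passed": passed, "reasons": "; ".join(problems)}
        )
        if passed:
            retained.append(sess)
        else:
            failures[sess.session_id] = "; ".join(problems)
            logger.warning("session %s excluded: %s", sess.session_id, "; ".join(problems))
    if retained:
        counts = (
            pd.DataFrame(
                {"dataset_tag": [s.dataset_tag for s in retained],
                 "label": [s.label for s in retained]}
            )
            .value_counts()
            .rename("n_sessions")
            .reset_index()
            .sort_values(["dataset_tag", "label"])
            .reset_index(drop=True)
        )
    else:
        counts = pd.DataFrame(columns=["dataset_tag", "label", "n_sessions"])
    return CohortReport(
        per_session=pd.DataFrame(records),
        counts=counts,
        n_total=len(sessions),
        n_retained=len(retained),
        failures=failures,
    )
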