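"""Semantic movement representation: PC1 projection, segmentation, features.

The pronation–supination task is a near-periodic alternating rotation, so a
single principal component of the tri-axial acceleration captures the
movement as a one-dimensional oscillating trace.  That trace is split into
beginning/middle/end parts; each part is cut at zero crossings into
constant-sign *segments*, characterized by their extremum (the pronation or
supination peak).  Nine interpretable feature kinds — one whole-measurement
statistic plus eight per-part statistics over segment durations and extrema
— yield a 25-value vector per session.

PCA is fit per session (not per cohort): this makes the representation
invariant to device orientation and avoids any cross-session information
flow.  The sign of the component is fixed from the projected trace itself —
flipped so the first sample whose |score| reaches half the peak is positive
— which is stable under rigid rotations of the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AccelSession

#: Feature-kind names; the first applies to the whole measurement, the rest per part.
WHOLE_FEATURE = "abs_mean_extremum"
PART_FEATURE_KINDS = [
    "n_segments",
    "duration_ratio",
    "mean_duration",
    "iqr_duration",
    "relmax_mean",
    "relmax_iqr",
    "relmin_mean",
    "relmin_iqr",
]

#: Stable ordering of the 25 semantic feature names.
SEMANTIC_FEATURE_NAMES = [WHOLE_FEATURE] + [
    f"{kind}__part{p}" for kind in PART_FEATURE_KINDS for p in range(3)
]

#: Sentinel values for degenerate statistics (kept finite for classifiers).
SENTINELS = {"duration_ratio": 1.0, "iqr": 0.0, "mean": 0.0}


@dataclass
class ProjectedSignal:
    """Centered PC1 scores of one session."""

    values: np.ndarray                  # centered scores, mean 0
    loading: np.ndarray                 # unit 3-vector
    explained_variance_ratio: float     # in [1/3, 1]
    sample_rate: float


@dataclass
class Segment:
    """Maximal constant-sign run of the centered trace, half-open [start, end)."""

    start_idx: int
    end_idx: int
    duration: float                     # seconds
    extremum_value: float               # signed, the max-|value| sample
    sign: int                           # +1 or -1

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("segment must be non-empty")


@dataclass
class PartSegmentation:
    part_index: int                     # 0 beginning, 1 middle, 2 end
    segments: list[Segment]


@dataclass
class SemanticFeatureVector:
    """The 25 named semantic features of one session."""

    values: pd.Series                                     # indexed by SEMANTIC_FEATURE_NAMES
    degenerate: dict[str, bool] = field(default_factory=dict)


def project_pc1(session: AccelSession) -> ProjectedSignal:
    """Project a session's tri-axial data onto its first principal component.

    The 3x3 covariance of the centered data is eigendecomposed; scores along
    the top eigenvector form the trace.  Sign convention: the trace is
    flipped so that the first sample whose |score| reaches half the peak is
    positive (rotation of the raw vectors leaves |scores| unchanged, so this is
    orientation-stable; the loading's sign follows the trace).
    """
    X = session.acc
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(len(Xc) - 1, 1)
    total_var = float(np.trace(cov))
    if total_var <= 1e-18:
        raise ValueError(f"session {session.session_id}: constant signal")
    eigvals, eigvecs = np.linalg.eigh(cov)
    loading = eigvecs[:, -1]
    values = Xc @ loading
    # sign convention: the first sample whose |score| reaches half the peak
    # is made positive.  |scores| are rotation-invariant, so this is stable
    # under rigid rotations of the raw data, and it avoids the exact +/- tie
    # an argmax rule hits on symmetric oscillations.
    absv = np.abs(values)
    anchor = int(np.argmax(absv >= 0.5 * absv.max()))
    if values[anchor] < 0:
        values = -values
        loading = -loading
    return ProjectedSignal(
        values=values,
        loading=loading,
        explained_variance_ratio=float(eigvals[-1] / total_var),
        sample_rate=session.sample_rate,
    )


def split_parts(n: int) -> list[tuple[int, int]]:
    """Split ``n`` samples into contiguous beginning/middle/end index ranges.

    Sizes are ``n - 2*(n//3), n//3, n//3`` — remainder samples go to the
    beginning part, deterministically.
    """
    if n < 3:
        raise ValueError(f"signal too short to split into parts (n={n})")
    third = n // 3
    b = n - 2 * third
    return [(0, b), (b, b + third), (b + third, n)]


def segment_by_extrema(
    signal: ProjectedSignal,
    part: tuple[int, int],
    part_index: int = 0,
    min_run: int = 2,
) -> PartSegmentation:
    """Cut one part of the centered trace into extremum-signed segments.

    A zero crossing sits between consecutive samples of strictly opposite
    sign; the boundary index is the first sample of the new sign.  Samples
    equal to zero attach to the preceding run (leading zeros to the first
    signed run).  Maximal constant-sign runs shorter than ``min_run``
    samples are merged into the preceding segment (a leading short run
    merges into the following one), so every sample stays in some segment.
    A part with no sign change yields a single segment.
    """
    start, end = part
    v = signal.values[start:end]
    sign = np.sign(v)
    # zeros attach to the preceding run (leading zeros to the first signed run)
    nz = np.nonzero(sign)[0]
    if len(nz) == 0:
        sign[:] = 1.0                          # all-zero part: one nominal segment
    else:
        sign[: nz[0]] = sign[nz[0]]
        idx = np.where(sign != 0, np.arange(len(sign)), 0)
        np.maximum.accumulate(idx, out=idx)
        sign = sign[idx]
    # maximal constant-sign runs
    change = np.nonzero(np.diff(sign))[0] + 1
    bounds = np.concatenate(([0], change, [len(v)]))
    runs = [
        [int(bounds[i]), int(bounds[i + 1]), int(sign[bounds[i]])]
        for i in range(len(bounds) - 1)
    ]
    # merge runs shorter than min_run into the preceding segment; the
    # same-sign run that follows an absorbed short run coalesces with it, so
    # a brief sign glitch never splits an oscillation half-cycle.  A leading
    # short run absorbs into the run that follows it.
    merged: list[list[int]] = []
    for s, e, sg in runs:
        if not merged:
            merged.append([s, e, sg])
        elif e - s < min_run:
            merged[-1][1] = e                               # absorb short run
        elif sg == merged[-1][2]:
            merged[-1][1] = e                               # coalesce same sign
        elif merged[-1][1] - merged[-1][0] < min_run:
            merged[-1] = [merged[-1][0], e, sg]             # leading short run
        else:
            merged.append([s, e, sg])
    segments = []
    fs = signal.sample_rate
    for s, e, _sg in merged:
        seg_vals = v[s:e]
        ext_i = int(np.argmax(np.abs(seg_vals)))
        ext = float(seg_vals[ext_i])
        segments.append(
            Segment(
                start_idx=start + s,
                end_idx=start + e,
                duration=(e - s) / fs,
                extremum_value=ext,
                sign=1 if ext >= 0 else -1,
            )
        )
    return PartSegmentation(part_index=part_index, segments=segments)


def _iqr(values: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quartiles."""
    q25, q75 = np.percentile(values, [25, 75])
    return float(q75 - q25)


def extract_semantic_features(
    session: AccelSession, min_run: int = 2
) -> SemanticFeatureVector:
    """Compute the 25 semantic features of one session.

    Whole-measurement: mean |segment extremum| over all segments of all
    parts.  Per part: segment count; positive-to-negative total-duration
    ratio (pronation/supination asymmetry); mean and IQR of segment
    durations; mean and IQR of positive-segment extrema (relative maxima)
    and of negative-segment extrema (relative minima).  Degenerate
    statistics (no segment of the needed sign, or fewer than two values for
    an IQR) take documented sentinels — 1 for the duration ratio, 0
    otherwise — and are flagged, never silently dropped.
    """
    signal = project_pc1(session)
    parts = split_parts(len(signal.values))
    segmentations = [
        segment_by_extrema(signal, part, part_index=i, min_run=min_run)
        for i, part in enumerate(parts)
    ]

    out: dict[str, float] = {}
    degenerate: dict[str, bool] = {}

    all_extrema = np.array(
        [seg.extremum_value for ps in segmentations for seg in ps.segments]
    )
    out[WHOLE_FEATURE] = float(np.mean(np.abs(all_extrema)))

    def put(name: str, value: float, is_degenerate: bool = False) -> None:
        out[name] = float(value)
        degenerate[name] = is_degenerate

    for p, ps in enumerate(segmentations):
        segs = ps.segments
        durations = np.array([s.duration for s in segs])
        maxima = np.array([s.extremum_value for s in segs if s.sign > 0])
        minima = np.array([s.extremum_value for s in segs if s.sign < 0])

        put(f"n_segments__part{p}", len(segs))
        pos_total = durations[[s.sign > 0 for s in segs]].sum()
        neg_total = durations[[s.sign < 0 for s in segs]].sum()
        if pos_total > 0 and neg_total > 0:
            put(f"duration_ratio__part{p}", pos_total / neg_total)
        else:
            put(f"duration_ratio__part{p}", SENTINELS["duration_ratio"], True)
        put(f"mean_duration__part{p}", durations.mean())
        if len(durations) >= 2:
            put(f"iqr_duration__part{p}", _iqr(durations))
        else:
            put(f"iqr_duration__part{p}", SENTINELS["iqr"], True)
        for tag, vals in (("relmax", maxima), ("relmin", minima)):
            if len(vals) >= 1:
                put(f"{tag}_mean__part{p}", vals.mean())
            else:
                put(f"{tag}_mean__part{p}", SENTINELS["mean"], True)
            if len(vals) >= 2:
                put(f"{tag}_iqr__part{p}", _iqr(vals))
            else:
                put(f"{tag}_iqr__part{p}", SENTINELS["iqr"], True)

    values = pd.Series([out[name] for name in SEMANTIC_FEATURE_NAMES],
                       index=SEMANTIC_FEATURE_NAMES, dtype=float)
    return SemanticFeatureVector(values=values, degenerate=degenerate)


def semantic_feature_matrix(sessions: list[AccelSession]) -> pd.DataFrame:
    """Stack semantic feature vectors into a (sessions x 25) DataFrame."""
    rows = {s.session_id: extract_semantic_features(s).values for s in sessions}
    return pd.DataFrame(rows).T.loc[[s.session_id for s in sessions]]
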