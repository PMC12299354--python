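"""Automatic time-series feature extraction and statistical relevance filtering.

Complement to the semantic representation: instead of nine task-specific
biomechanical statistics, a broad catalogue of generic time-series features
is computed per series and then pruned by per-feature hypothesis tests of
association with the dyskinesia label under Benjamini–Hochberg FDR control
(the FRESH scheme).  Two representation modes exist:

* ``PCA_AUTO`` — the catalogue on the one-dimensional PC1 trace;
* ``AUTO3D``   — the catalogue on each raw axis, columns axis-prefixed.

The catalogue covers distributional statistics, counts and run lengths,
successive-change statistics, autocorrelation at lags 1–10, linear trend,
energy and spectral descriptors (band powers over 0.5–3 / 3–7 / 7–12 Hz,
spectral entropy, dominant frequency), and a sample-entropy approximation.
It is deterministic for fixed input and its column names are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .io import AccelSession
from .semantic import project_pc1

#: Spectral bands (Hz) relevant to voluntary task motion (~0.8-2 Hz and its
#: harmonics) and dyskinetic/jerk content (higher bands).
SPECTRAL_BANDS = [(0.5, 3.0), (3.0, 7.0), (7.0, 12.0)]

AUTOCORR_LAGS = range(1, 11)

#: Cap for the O(n^2) sample-entropy computation; longer series are strided.
_SAMPEN_MAX_N = 256


def _sample_entropy(v: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r=r_frac*std); strided to <=256 points."""
    if len(v) > _SAMPEN_MAX_N:
        step = int(np.ceil(len(v) / _SAMPEN_MAX_N))
        v = v[::step]
    n = len(v)
    sd = np.std(v)
    if n <= m + 1 or sd == 0:
        return 0.0
    r = r_frac * sd

    def count_matches(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(v, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        return int((np.triu(d <= r, k=1)).sum())

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        return float(np.log(n - m) + np.log(n - m - 1) - np.log(2))  # defined ceiling
    return float(-np.log(a / b))


def series_features(v: np.ndarray, sample_rate: float) -> dict[str, float]:
    """Compute the full named feature catalogue for one 1-D series."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    f: dict[str, float] = {}
    mean = v.mean()
    sd = v.std()
    vc = v - mean

    # distributional
    f["mean"] = mean
    f["median"] = float(np.median(v))
    f["variance"] = float(v.var())
    f["std"] = float(sd)
    f["skewness"] = float(sp_stats.skew(v)) if sd > 0 else 0.0
    f["kurtosis"] = float(sp_stats.kurtosis(v)) if sd > 0 else 0.0
    q = np.percentile(v, [5, 10, 25, 75, 90, 95])
    f["q05"], f["q10"], f["q25"], f["q75"], f["q90"], f["q95"] = map(float, q)
    f["iqr"] = f["q75"] - f["q25"]
    f["min"] = float(v.min())
    f["max"] = float(v.max())
    f["range"] = f["max"] - f["min"]
    f["abs_max"] = float(np.abs(v).max())
    f["mean_abs"] = float(np.abs(v).mean())
    f["rms"] = float(np.sqrt(np.mean(v**2)))
    f["mean_abs_deviation"] = float(np.abs(vc).mean())
    # guarded against a numerically-zero mean, where the ratio is meaningless
    f["variation_coefficient"] = float(sd / mean) if abs(mean) > 1e-10 * (sd + 1e-30) else 0.0

    # counts, locations, runs
    sgn = np.sign(vc)
    sgn = sgn[sgn != 0]
    f["zero_crossings"] = float(np.count_nonzero(np.diff(sgn))) if len(sgn) > 1 else 0.0
    for frac, name in ((0.5, "n_peaks_half_max"), (0.75, "n_peaks_075_max")):
        height = frac * np.abs(vc).max() if np.abs(vc).max() > 0 else None
        if height is None:
            f[name] = 0.0
        else:
            peaks, _ = sp_signal.find_peaks(vc, height=height)
            f[name] = float(len(peaks))
    above = v > mean
    f["count_above_mean"] = float(above.sum())
    f["count_below_mean"] = float((~above).sum())

    def longest_run(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        padded = np.concatenate(([0], mask.astype(int), [0]))
        d = np.diff(padded)
        return float(np.max(np.nonzero(d == -1)[0] - np.nonzero(d == 1)[0]))

    f["longest_strike_above_mean"] = longest_run(above)
    f["longest_strike_below_mean"] = longest_run(~above)
    f["first_loc_max"] = float(np.argmax(v) / n)
    f["last_loc_max"] = float((n - 1 - np.argmax(v[::-1])) / n)
    f["first_loc_min"] = float(np.argmin(v) / n)
    f["last_loc_min"] = float((n - 1 - np.argmin(v[::-1])) / n)
    f["ratio_beyond_1sigma"] = float(np.mean(np.abs(vc) > sd)) if sd > 0 else 0.0
    f["ratio_beyond_2sigma"] = float(np.mean(np.abs(vc) > 2 * sd)) if sd > 0 else 0.0

    # successive changes
    dv = np.diff(v)
    f["mean_abs_change"] = float(np.abs(dv).mean()) if n > 1 else 0.0
    f["mean_change"] = float(dv.mean()) if n > 1 else 0.0
    f["mean_second_derivative"] = (
        float(np.mean(v[2:] - 2 * v[1:-1] + v[:-2]) / 2) if n > 2 else 0.0
    )
    f["cid_ce"] = float(np.sqrt(np.sum(dv**2))) if n > 1 else 0.0
    num = np.mean(v[2:] ** 2 * v[1:-1] - v[1:-1] * v[:-2] ** 2) if n > 2 else 0.0
    f["time_reversal_asymmetry"] = float(num)

    # autocorrelation at lags 1..10 (FFT-based, biased normalization)
    denom = np.sum(vc**2)
    if denom > 0 and n > max(AUTOCORR_LAGS):
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        fv = np.fft.rfft(vc, nfft)
        acf = np.fft.irfft(fv * np.conj(fv), nfft)[: max(AUTOCORR_LAGS) + 1] / denom
        for lag in AUTOCORR_LAGS:
            f[f"autocorr_lag{lag}"] = float(acf[lag])
    else:
        for lag in AUTOCORR_LAGS:
            f[f"autocorr_lag{lag}"] = 0.0

    # linear trend over time
    if n > 2 and sd > 0:
        t = np.arange(n) / sample_rate
        slope, intercept, rvalue, _, _ = sp_stats.linregress(t, v)
        f["trend_slope"] = float(slope)
        f["trend_r2"] = float(rvalue**2)
    else:
        f["trend_slope"] = 0.0
        f["trend_r2"] = 0.0

    # energy and spectrum (linearly detrended, average sample rate)
    f["abs_energy"] = float(np.sum(v**2))
    if n > 3 and sd > 0:
        vd = sp_signal.detrend(v)
        spec = np.abs(np.fft.rfft(vd)) ** 2
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        total = spec[1:].sum()
        for lo, hi in SPECTRAL_BANDS:
            band = spec[(freqs >= lo) & (freqs < hi)].sum()
            f[f"band_power_{lo:g}_{hi:g}"] = float(band)
            f[f"band_power_rel_{lo:g}_{hi:g}"] = float(band / total) if total > 0 else 0.0
        if total > 0:
            p = spec[1:] / total
            p = p[p > 0]
            f["spectral_entropy"] = float(-(p * np.log(p)).sum() / np.log(len(spec) - 1))
            f["dominant_freq"] = float(freqs[1:][np.argmax(spec[1:])])
            f["spectral_centroid"] = float((freqs[1:] * spec[1:]).sum() / total)
        else:
            f["spectral_entropy"] = 0.0
            f["dominant_freq"] = 0.0
            f["spectral_centroid"] = 0.0
    else:
        for lo, hi in SPECTRAL_BANDS:
            f[f"band_power_{lo:g}_{hi:g}"] = 0.0
            f[f"band_power_rel_{lo:g}_{hi:g}"] = 0.0
        f["spectral_entropy"] = 0.0
        f["dominant_freq"] = 0.0
        f["spectral_centroid"] = 0.0

    f["sample_entropy"] = _sample_entropy(v)
    return f


#: Stable list of per-series feature names (order of definition above).
SERIES_FEATURE_NAMES = list(series_features(np.sin(np.arange(64) / 3.0), 50.0).keys())


@dataclass
class FeatureMatrix:
    """Per-session feature matrix under one representation mode."""

    tag: str                                # SEMANTIC | PCA_AUTO | AUTO3D
    df: pd.DataFrame                        # rows: session_ids, cols: features

    @property
    def session_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)


def extract_auto_features(sessions: list[AccelSession], mode: str = "PCA_AUTO") -> FeatureMatrix:
    """Extract the automatic feature catalogue for every session.

    ``PCA_AUTO`` featurizes the PC1 trace (columns ``pc1__<name>``);
    ``AUTO3D`` featurizes each raw axis (columns ``x__/y__/z__<name>``),
    giving exactly three times as many columns.
    """
    if mode not in ("PCA_AUTO", "AUTO3D"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = {}
    for sess in sessions:
        if mode == "PCA_AUTO":
            feats = {
                f"pc1__{k}": val
                for k, val in series_features(project_pc1(sess).values, sess.sample_rate).items()
            }
        else:
            feats = {}
            for ax, name in enumerate("xyz"):
                for k, val in series_features(sess.acc[:, ax], sess.sample_rate).items():
                    feats[f"{name}__{k}"] = val
        rows[sess.session_id] = feats
    df = pd.DataFrame(rows).T.loc[[s.session_id for s in sessions]]
    return FeatureMatrix(tag=mode, df=df.astype(float))


def fresh_relevance_filter(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: np.ndarray,
    fdr_level: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prune features by per-feature association tests under BH FDR control.

    Constant columns are removed first.  Real-valued features use a
    two-sided Mann–Whitney U test against the binary label; binary features
    use Fisher's exact test.  Benjamini–Hochberg adjustment at ``fdr_level``
    decides retention.  Returns ``(filtered_df, info)`` where *info* has one
    row per tested column (p-value, adjusted p, retained flag).
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    if len(df) != len(y):
        raise ValueError("labels length does not match matrix rows")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("single-class labels: relevance testing is undefined")

    keep = df.columns[df.nunique() > 1]
    mask1 = y == classes[1]
    records = []
    for col in keep:
        x = df[col].to_numpy()
        uniq = np.unique(x)
        if len(uniq) == 2:
            table = [
                [int(np.sum((x == uniq[0]) & ~mask1)), int(np.sum((x == uniq[0]) & mask1))],
                [int(np.sum((x == uniq[1]) & ~mask1)), int(np.sum((x == uniq[1]) & mask1))],
            ]
            _, p = sp_stats.fisher_exact(table)
            test = "fisher"
        else:
            _, p = sp_stats.mannwhitneyu(x[~mask1], x[mask1], alternative="two-sided")
            test = "mannwhitney"
        records.append({"feature": col, "test": test, "p_value": float(p)})
    info = pd.DataFrame(records)
    if len(info) == 0:
        return df[[]], info
    rejected, p_adj, _, _ = multipletests(info["p_value"], alpha=fdr_level, method="fdr_bh")
    info["p_adjusted"] = p_adj
    info["retained"] = rejected
    retained_cols = info.loc[info["retained"], "feature"].tolist()
    return df[retained_cols], info
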