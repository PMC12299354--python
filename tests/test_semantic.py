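import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyskrep import (
    AccelSession,
    SEMANTIC_FEATURE_NAMES,
    SyntheticParams,
    extract_semantic_features,
    generate_session,
    project_pc1,
    segment_by_extrema,
    split_parts,
)
from dyskrep.semantic import ProjectedSignal

from conftest import make_sine_session, random_rotation


class TestProjectPC1:
    def test_single_axis_motion(self, sine_session):
        sig = project_pc1(sine_session)
        np.testing.assert_allclose(sig.loading, [1.0, 0.0, 0.0], atol=1e-12)
        assert sig.explained_variance_ratio == pytest.approx(1.0)
        assert abs(sig.values.mean()) < 1e-9

    def test_diagonal_motion_loading(self):
        t = np.arange(601) / 50.0
        x = np.sin(2 * np.pi * 2 * t)
        acc = np.stack([x, x, np.zeros_like(t)], axis=1)
        sess = AccelSession("diag", "s", "d", "T", 50.0, t, acc, 0)
        sig = project_pc1(sess)
        np.testing.assert_allclose(sig.loading, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0],
                                   atol=1e-12)

    def test_explained_variance_matches_eigen_oracle(self):
        # diagonal covariance (4, 1, 1): top eigenvalue / trace = 4/6
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100_000, 3)) * np.sqrt([4.0, 1.0, 1.0])
        sess = AccelSession("g", "s", "d", "T", 50.0, np.arange(len(X)) / 50.0, X, 0)
        assert project_pc1(sess).explained_variance_ratio == pytest.approx(4 / 6, abs=0.01)

    def test_evr_at_least_one_third(self):
        for seed in range(5):
            sess = generate_session(SyntheticParams(), seed % 2, seed=seed)
            sig = project_pc1(sess)
            assert sig.explained_variance_ratio >= 1 / 3
            assert np.linalg.norm(sig.loading) == pytest.approx(1.0)
            # PC1 variance beats any single axis
            axis_var = (sess.acc - sess.acc.mean(0)).var(axis=0, ddof=1).max()
            assert sig.values.var(ddof=1) >= axis_var * (1 - 1e-12)

    def test_constant_signal_rejected(self):
        t = np.arange(300) / 50.0
        acc = np.ones((300, 3))
        with pytest.raises(ValueError, match="constant"):
            project_pc1(AccelSession("c", "s", "d", "T", 50.0, t, acc, 0))


class TestSplitParts:
    def test_exact_thirds(self):
        assert split_parts(9) == [(0, 3), (3, 6), (6, 9)]

    def test_remainder_to_beginning(self):
        parts = split_parts(10)
        sizes = [e - s for s, e in parts]
        assert sizes == [4, 3, 3]

    @given(st.integers(min_value=3, max_value=10_000))
    @settings(max_examples=100, derandomize=True)
    def test_partition_property(self, n):
        parts = split_parts(n)
        sizes = [e - s for s, e in parts]
        assert sum(sizes) == n
        assert parts[0][0] == 0 and parts[2][1] == n
        assert parts[0][1] == parts[1][0] and parts[1][1] == parts[2][0]
        assert sizes[1] == sizes[2] == n // 3

    def test_too_short(self):
        with pytest.raises(ValueError):
            split_parts(2)


def _signal(values, fs=50.0):
    return ProjectedSignal(values=np.asarray(values, dtype=float),
                           loading=np.array([1.0, 0.0, 0.0]),
                           explained_variance_ratio=1.0, sample_rate=fs)


class TestSegmentByExtrema:
    def test_pure_sine_alternating_segments(self):
        # 4 full periods at 1 Hz, 50 Hz sampling: 8 alternating half-period segments
        t = np.arange(200) / 50.0
        sig = _signal(np.sin(2 * np.pi * t))
        ps = segment_by_extrema(sig, (0, 200))
        assert len(ps.segments) == 8
        signs = [s.sign for s in ps.segments]
        assert all(a != b for a, b in zip(signs, signs[1:]))
        durations = [s.duration for s in ps.segments]
        assert np.allclose(durations, 0.5, atol=2 / 50.0)

    def test_all_positive_part_single_segment(self):
        sig = _signal(np.ones(50) + 0.1 * np.sin(np.arange(50)))
        ps = segment_by_extrema(sig, (0, 50))
        assert len(ps.segments) == 1
        assert ps.segments[0].sign == 1
        assert ps.segments[0].duration == pytest.approx(1.0)

    def test_short_run_merged_into_preceding(self):
        t = np.arange(200) / 50.0
        v = np.sin(2 * np.pi * t)
        ps_clean = segment_by_extrema(_signal(v.copy()), (0, 200))
        v2 = v.copy()
        # flip one mid-run sample: creates a 1-sample opposite-sign run,
        # which must be absorbed without splitting the half-cycle
        mid = int(np.argmax(v2))
        v2[mid] = -v2[mid] * 0.01
        ps_flipped = segment_by_extrema(_signal(v2), (0, 200))
        assert len(ps_flipped.segments) == len(ps_clean.segments)
        assert [s.sign for s in ps_flipped.segments] == [s.sign for s in ps_clean.segments]

    def test_segments_tile_the_part(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(333)
        ps = segment_by_extrema(_signal(v), (10, 250))
        assert ps.segments[0].start_idx == 10
        assert ps.segments[-1].end_idx == 250
        for a, b in zip(ps.segments, ps.segments[1:]):
            assert a.end_idx == b.start_idx

    def test_extremum_is_max_abs_sample(self):
        v = np.concatenate([np.linspace(0.1, 1.0, 10), np.linspace(-0.2, -2.0, 10)])
        ps = segment_by_extrema(_signal(v), (0, 20))
        assert [s.extremum_value for s in ps.segments] == [1.0, -2.0]


class TestSemanticFeatures:
    def test_unit_sine_analytic_values(self, sine_session):
        fv = extract_semantic_features(sine_session)
        f = fv.values
        dt = 1.0 / sine_session.sample_rate
        assert f["abs_mean_extremum"] == pytest.approx(1.0, rel=0.02)
        for p in range(3):
            assert f[f"n_segments__part{p}"] == 16
            assert f[f"mean_duration__part{p}"] == pytest.approx(0.25, abs=2 * dt)
            assert f[f"duration_ratio__part{p}"] == pytest.approx(1.0, abs=0.1)
            assert f[f"relmax_mean__part{p}"] == pytest.approx(1.0, rel=0.02)
            assert f[f"relmin_mean__part{p}"] == pytest.approx(-1.0, rel=0.02)
            assert abs(f[f"relmax_iqr__part{p}"]) <= 0.02
            assert abs(f[f"relmin_iqr__part{p}"]) <= 0.02
            assert abs(f[f"iqr_duration__part{p}"]) <= 2 * dt

    def test_names_count_and_order(self, sine_session):
        f = extract_semantic_features(sine_session).values
        assert list(f.index) == SEMANTIC_FEATURE_NAMES
        assert len(SEMANTIC_FEATURE_NAMES) == 25
        assert len(set(SEMANTIC_FEATURE_NAMES)) == 25

    def test_amplitude_ramp_orders_extremum_means(self):
        # amplitude doubles linearly: whole-measurement |extremum| mean lies
        # strictly between the first and last part's extremum magnitudes
        fs = 50.0
        t = np.arange(int(12 * fs) + 1) / fs
        ramp = 1.0 + t / t[-1]
        acc = np.zeros((len(t), 3))
        acc[:, 0] = ramp * np.sin(2 * np.pi * 2 * t)
        acc[:, 2] = 1.0
        sess = AccelSession("ramp", "s", "d", "T", fs, t, acc, 0)
        f = extract_semantic_features(sess).values
        lo = f["relmax_mean__part0"]
        hi = f["relmax_mean__part2"]
        assert lo < f["abs_mean_extremum"] < hi

    def test_constant_sign_parts_degenerate_policy(self):
        # piecewise-constant trace: each part holds a single constant-sign
        # segment, so per-part ratios and sign-specific statistics fall back
        # to their sentinels instead of NaN
        fs = 50.0
        t = np.arange(600) / fs
        acc = np.zeros((len(t), 3))
        acc[:200, 0] = 1.0
        acc[200:400, 0] = -1.0
        acc[400:, 0] = 2.0
        acc[:, 2] = 1.0
        sess = AccelSession("steps", "s", "d", "T", fs, t, acc, 0)
        fv = extract_semantic_features(sess)
        f = fv.values
        for p in range(3):
            assert f[f"n_segments__part{p}"] == 1
            assert f[f"duration_ratio__part{p}"] == 1.0
            assert fv.degenerate[f"duration_ratio__part{p}"]
            assert f[f"iqr_duration__part{p}"] == 0.0
        # exactly one of relmax/relmin is the sentinel in every part
        for p in range(3):
            flags = [fv.degenerate[f"relmax_mean__part{p}"],
                     fv.degenerate[f"relmin_mean__part{p}"]]
            assert sorted(flags) == [False, True]
        assert f["abs_mean_extremum"] == pytest.approx(10 / 9)
        assert np.isfinite(f.to_numpy()).all()

    def test_orientation_invariance(self):
        rng = np.random.default_rng(7)
        for seed in (3, 8):
            sess = generate_session(SyntheticParams(), 1, seed=seed)
            base = extract_semantic_features(sess).values
            for _ in range(3):
                M = random_rotation(rng)
                rot = AccelSession("r", "s", "d", "T", sess.sample_rate,
                                   sess.timestamps, sess.acc @ M.T, 1)
                f = extract_semantic_features(rot).values
                rel = np.abs(f - base) / (np.abs(base) + 1e-12)
                assert rel.max() < 1e-6

    def test_amplitude_equivariance(self):
        sess = generate_session(SyntheticParams(noise_sd=0.0), 1, seed=5)
        f1 = extract_semantic_features(sess).values
        c = 3.0
        scaled = AccelSession("c", "s", "d", "T", sess.sample_rate,
                              sess.timestamps, sess.acc * c, 1)
        f2 = extract_semantic_features(scaled).values
        amp_kinds = {"abs_mean_extremum", "relmax_mean", "relmin_mean",
                     "relmax_iqr", "relmin_iqr"}
        for name in f1.index:
            kind = name.split("__")[0]
            if kind in amp_kinds:
                assert f2[name] == pytest.approx(c * f1[name], rel=1e-9, abs=1e-12)
            else:
                assert f2[name] == pytest.approx(f1[name], abs=1e-12)

    def test_severity_monotone_relmax_iqr(self):
        # irregular dyskinetic motion widens the spread of pronation peaks
        means = []
        for sev in (0.1, 0.5, 1.0):
            params = SyntheticParams(task_amplitude=(0.6, 0.6), dysk_severity=sev)
            vals = [
                extract_semantic_features(
                    generate_session(params, 1, seed=100 + i)
                ).values[["relmax_iqr__part0", "relmax_iqr__part1", "relmax_iqr__part2"]].mean()
                for i in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
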