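import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrfboost.design import (
    EventTimeline,
    boxcar,
    build_design,
    convolve_to_scans,
    drift_basis,
    orthogonalize,
    read_events_tsv,
)
from hrfboost.hrf import SampledKernel


def single_event(onset=0.0, duration=10.0, amplitude=1.0):
    return EventTimeline(onsets=[onset], durations=[duration], amplitudes=[amplitude])


class TestEventTimeline:
    def test_validation(self):
        with pytest.raises(ValueError):
            EventTimeline(onsets=[-1.0], durations=[1.0], amplitudes=[1.0])
        with pytest.raises(ValueError):
            EventTimeline(onsets=[5.0, 1.0], durations=[1.0, 1.0], amplitudes=[1.0, 1.0])
        with pytest.raises(ValueError):
            EventTimeline(onsets=[0.0], durations=[-1.0], amplitudes=[1.0])

    def test_read_events_tsv(self, tmp_path):
        path = tmp_path / "events.tsv"
        path.write_text(
            "onset\tduration\ttrial_type\tamplitude\n"
            "0.0\t10.0\tvib100\t1.0\n"
            "20.0\t10.0\tvib30\t0.5\n"
            "40.0\t10.0\tvib100\t1.0\n"
        )
        timelines = {t.condition: t for t in read_events_tsv(path)}
        assert set(timelines) == {"vib100", "vib30"}
        np.testing.assert_array_equal(timelines["vib100"].onsets, [0.0, 40.0])
        assert timelines["vib30"].amplitudes[0] == 0.5

    def test_read_events_tsv_defaults(self, tmp_path):
        path = tmp_path / "events.tsv"
        path.write_text("onset\tduration\n0.0\t10.0\n20.0\t10.0\n")
        (tl,) = read_events_tsv(path)
        assert tl.condition == "task"
        np.testing.assert_array_equal(tl.amplitudes, [1.0, 1.0])


class TestBoxcar:
    def test_ten_second_event_at_half_second_resolution(self):
        u = boxcar(single_event(), dt=0.5, total_duration=20.0)
        assert np.sum(u == 1.0) == 20
        assert np.all(u[:20] == 1.0)
        assert np.all(u[20:] == 0.0)

    def test_empty_timeline(self):
        empty = EventTimeline(onsets=[], durations=[], amplitudes=[])
        assert np.all(boxcar(empty, 0.5, 10.0) == 0.0)

    def test_amplitude_linearity(self):
        ev = EventTimeline(onsets=[0.0, 20.0], durations=[10.0, 5.0], amplitudes=[1.0, 2.0])
        u1 = boxcar(ev, 0.5, 30.0)
        u2 = boxcar(ev.scaled(2.0), 0.5, 30.0)
        np.testing.assert_allclose(u2, 2.0 * u1)

    def test_overlap_rejected(self):
        ev = EventTimeline(onsets=[0.0, 5.0], durations=[10.0, 10.0], amplitudes=[1.0, 1.0])
        with pytest.raises(ValueError, match="overlap"):
            boxcar(ev, 0.5, 30.0)

    @settings(max_examples=25, deadline=None)
    @given(amp=st.floats(0.1, 10.0), onset=st.floats(0.0, 5.0))
    def test_event_samples_carry_amplitude(self, amp, onset):
        ev = EventTimeline(onsets=[onset], durations=[4.0], amplitudes=[amp])
        u = boxcar(ev, 0.5, 20.0)
        assert set(np.unique(u)) <= {0.0, amp}
        assert np.isclose(u.sum(), amp * 8)


class TestConvolveToScans:
    def test_impulse_identity(self, rng):
        u = rng.standard_normal(200)
        dt = 0.5
        impulse = np.zeros(8)
        impulse[0] = 1.0 / dt  # unit mass at t=0 under the dt-scaled convolution
        kernel = SampledKernel(times=np.arange(8) * dt, values=impulse, kind="canonical")
        out = convolve_to_scans(u, kernel, tr=1.0, n_scans=50)
        np.testing.assert_allclose(out, u[::2][:50], atol=1e-12)

    def test_linearity(self, canonical, rng):
        u1 = rng.standard_normal(800)
        u2 = rng.standard_normal(800)
        a = convolve_to_scans(u1, canonical, 2.0, 30)
        b = convolve_to_scans(u2, canonical, 2.0, 30)
        ab = convolve_to_scans(u1 + u2, canonical, 2.0, 30)
        np.testing.assert_allclose(ab, a + b, atol=1e-10)

    def test_matches_double_loop_convolution(self, canonical, rng):
        u = rng.standard_normal(50)
        h = canonical.values
        dt = canonical.dt
        expected_full = np.zeros(50)
        for n in range(50):
            for k in range(len(h)):
                if 0 <= n - k < 50:
                    expected_full[n] += h[k] * u[n - k]
        expected_full *= dt
        tr = 0.2
        out = convolve_to_scans(u, canonical, tr, 20)
        idx = np.round(np.arange(20) * tr / dt).astype(int)
        np.testing.assert_allclose(out, expected_full[idx], atol=1e-10)


class TestOrthogonalize:
    def test_already_orthogonal_unchanged(self):
        x1 = np.array([1.0, 0.0, 0.0, 0.0])
        x2 = np.array([0.0, 1.0, -1.0, 0.0])
        np.testing.assert_allclose(orthogonalize(x2, x1), x2, atol=1e-12)

    def test_self_projection_gives_zero(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_allclose(orthogonalize(x, x), 0.0, atol=1e-10)

    def test_matches_least_squares_residual(self, rng):
        x1 = rng.standard_normal(20)
        x2 = rng.standard_normal(20)
        slope = float(np.linalg.lstsq(x1[:, None], x2, rcond=None)[0][0])
        np.testing.assert_allclose(orthogonalize(x2, x1), x2 - slope * x1, atol=1e-10)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            orthogonalize(np.ones(5), np.zeros(5))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_output_orthogonal_and_span_preserved(self, seed):
        r = np.random.default_rng(seed)
        x1 = r.standard_normal(25)
        x2 = r.standard_normal(25)
        y = r.standard_normal(25)
        x2o = orthogonalize(x2, x1)
        assert abs(x2o @ x1) < 1e-8 * np.linalg.norm(x2o) * np.linalg.norm(x1) + 1e-12
        # fitted values identical before/after orthogonalization
        yhats = []
        for pair in (np.column_stack([x1, x2]), np.column_stack([x1, x2o])):
            coef, *_ = np.linalg.lstsq(pair, y, rcond=None)
            yhats.append(pair @ coef)
        np.testing.assert_allclose(yhats[0], yhats[1], atol=1e-8)


class TestDriftBasis:
    def test_cutoff_too_short_rejected(self):
        with pytest.raises(ValueError):
            drift_basis(100, 2.0, 3.0)

    def test_long_cutoff_constant_only(self):
        cols = drift_basis(50, 2.0, cutoff=2 * 50 * 2.0 + 1)
        assert cols.shape == (50, 1)
        np.testing.assert_array_equal(cols[:, 0], 1.0)

    def test_captures_slow_cosine(self):
        n, tr = 256, 2.0
        cols = drift_basis(n, tr, cutoff=128.0)
        t = np.arange(n) * tr
        target = np.cos(2 * np.pi * t / 256.0)
        resid = target - cols @ np.linalg.lstsq(cols, target, rcond=None)[0]
        assert np.var(resid) < 0.01 * np.var(target)

    def test_columns_mutually_orthogonal(self):
        cols = drift_basis(128, 2.0, cutoff=100.0)
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8


class TestBuildDesign:
    def test_column_order_and_labels(self, events, params):
        X = build_design(events, 2.0, 100, params, basis="informed")
        assert X.labels == ["task_canonical", "task_derivative", "constant"]

    def test_derivative_orthogonal_to_canonical(self, design_informed):
        x1 = design_informed.column("task_canonical")
        x2 = design_informed.column("task_derivative")
        assert abs(x1 @ x2) < 1e-8 * np.linalg.norm(x1) * np.linalg.norm(x2)

    def test_column_ssq_matches_definition(self, design_informed):
        np.testing.assert_allclose(
            design_informed.column_ssq, np.sum(design_informed.matrix**2, axis=0)
        )

    def test_motion_covariates_appended(self, events, params, rng):
        motion = rng.standard_normal((100, 6))
        X = build_design(events, 2.0, 100, params, basis="canonical", motion=motion)
        assert X.labels[-6:] == [f"motion_{k}" for k in range(1, 7)]

    def test_tsv_round_trip(self, design_informed, tmp_path):
        path = tmp_path / "design.tsv"
        design_informed.to_tsv(path)
        from hrfboost.design import DesignMatrix

        back = DesignMatrix.from_tsv(path, design_informed.tr, design_informed.microtime_dt)
        assert back.labels == design_informed.labels
        np.testing.assert_allclose(back.matrix, design_informed.matrix, atol=1e-6)

    def test_drift_and_constant(self, events, params):
        X = build_design(events, 2.0, 100, params, basis="canonical", drift_cutoff=128.0)
        assert "constant" in X.labels
        assert any(lbl.startswith("drift_") for lbl in X.labels)
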