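"""Core stride engine: segmentation, integration, the guard velocity, the
offset search, the zero-velocity update and full-sprint processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import stridesense as ss
from stridesense.stride import linear_dedrift, _zero_phase_lowpass


def make_sprint(acc_x, acc_z, fs=500.0, events=None):
    n = len(acc_x)
    return ss.GlobalSprint(
        t=np.arange(n) / fs, acc_x=acc_x, acc_z=acc_z, fs=fs, events=events
    )


class TestSegmentStrides:
    def test_first_stride_starts_280ms_before_first_toeoff(self):
        ev = ss.GaitEvents(td=[600], to=[400], foot="left")
        segs = ss.segment_strides(ev, fs=500.0, n_samples=2000)
        assert segs[0].stride_index == 1
        assert (segs[0].start_idx, segs[0].end_idx) == (260, 600)
        assert segs[0].td_idx is None

    def test_consecutive_touchdowns_define_later_strides(self):
        ev = ss.GaitEvents(td=[600, 1100, 1650], to=[400, 700, 1250], foot="left")
        segs = ss.segment_strides(ev, fs=500.0, n_samples=2000)
        assert [(s.start_idx, s.end_idx) for s in segs[1:]] == [
            (600, 1100),
            (1100, 1650),
        ]
        assert [s.stride_index for s in segs] == [1, 2, 3]
        # stance terminating toe-off of stride 2 is the TO after its TD
        assert segs[1].contact_end_idx == 700

    def test_insufficient_prestart_samples_is_an_error(self):
        ev = ss.GaitEvents(td=[300], to=[100], foot="left")
        with pytest.raises(ValueError, match="pre-start"):
            ss.segment_strides(ev, fs=500.0, n_samples=1000)

    def test_stride_truncated_by_signal_end_dropped_with_warning(self):
        ev = ss.GaitEvents(td=[600, 1100, 1650], to=[400, 700, 1250], foot="left")
        with pytest.warns(UserWarning, match="dropped"):
            segs = ss.segment_strides(ev, fs=500.0, n_samples=1200)
        assert [s.stride_index for s in segs] == [1, 2]

    def test_alternation_violation_rejected(self):
        ev = ss.GaitEvents(td=[100, 200], to=[400], foot="left")
        with pytest.raises(ValueError, match="alternate"):
            ss.segment_strides(ev, fs=500.0, n_samples=1000)


class TestIntegrateAndMirror:
    def test_constant_acceleration_analytic_integral(self):
        n = 251  # 0.5 s at 500 Hz
        sp = make_sprint(np.full(n, 2.0), np.zeros(n))
        seg = ss.StrideSegment(foot="x", stride_index=1, start_idx=0, end_idx=n)
        vx, vz, mx, mz = ss.integrate_and_mirror(seg, sp)
        assert vx[-1] == pytest.approx(1.0, abs=1e-12)
        assert not mx
        assert np.all(vz == 0.0)

    def test_negative_axis_is_mirrored(self):
        n = 251
        sp_pos = make_sprint(np.full(n, 2.0), np.zeros(n))
        sp_neg = make_sprint(np.full(n, -2.0), np.zeros(n))
        seg = ss.StrideSegment(foot="x", stride_index=1, start_idx=0, end_idx=n)
        vxp, _, mxp, _ = ss.integrate_and_mirror(seg, sp_pos)
        vxn, _, mxn, _ = ss.integrate_and_mirror(seg, sp_neg)
        np.testing.assert_allclose(vxn, vxp, atol=1e-12)
        assert (mxp, mxn) == (False, True)

    @given(
        acc=hnp.arrays(
            float,
            st.integers(30, 200),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_sign_flip_invariance(self, acc):
        sp_a = make_sprint(acc, -acc)
        sp_b = make_sprint(-acc, acc)
        seg = ss.StrideSegment(foot="x", stride_index=1, start_idx=0, end_idx=len(acc))
        va = ss.integrate_and_mirror(seg, sp_a)
        vb = ss.integrate_and_mirror(seg, sp_b)
        np.testing.assert_allclose(va[0], vb[0], atol=1e-12)
        np.testing.assert_allclose(va[1], vb[1], atol=1e-12)


class TestTemporaryVelocity:
    def test_zero_input_guard_forces_unit_start(self):
        v = np.zeros(200)
        out = ss.temporary_velocity(v, fs=500.0)
        # pre-filter guard is +1 over the first 10 samples; the filtered trace
        # starts near 1 and decays toward the zero plateau
        assert out[0] == pytest.approx(1.0, abs=0.05)
        assert out[60:].max() < 0.05
        assert np.all(v == 0.0)  # input untouched

    def test_guard_value_is_20ms_sample_plus_one(self):
        v = np.zeros(200)
        v[10] = 0.3
        clamped = v.copy()
        clamped[:10] = v[10] + 1.0
        out = ss.temporary_velocity(v, fs=500.0)
        expected = _zero_phase_lowpass(clamped, 500.0, 40.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert clamped[0] == pytest.approx(1.3)

    def test_white_noise_power_above_cutoff_attenuated_20db(self, rng):
        x = rng.normal(size=100000)
        y = _zero_phase_lowpass(x, 500.0, 40.0)
        f = np.fft.rfftfreq(len(x), 1 / 500.0)
        band = f > 40.0
        pin = np.sum(np.abs(np.fft.rfft(x))[band] ** 2)
        pout = np.sum(np.abs(np.fft.rfft(y))[band] ** 2)
        assert 10 * np.log10(pout / pin) <= -20.0

    def test_guard_step_does_not_undershoot_the_plateau(self):
        # a monotone step response is what keeps the offset search unbiased
        # when the true stance velocity is a flat plateau
        v = np.zeros(300)
        out = ss.temporary_velocity(v, fs=500.0)
        assert out[10:51].min() >= -1e-6

    def test_too_short_stride_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            ss.temporary_velocity(np.zeros(8), fs=500.0)


class TestFindOffset:
    def test_monotone_trace_puts_offset_at_window_start(self):
        v = np.linspace(0.0, 3.0, 200)
        val, idx = ss.find_offset(v, 0, (0.020, 0.100), fs=500.0)
        assert idx == 10
        assert val == pytest.approx(v[10])

    def test_matches_brute_force_scan(self, rng):
        fs = 500.0
        for _ in range(200):
            v = rng.normal(size=120)
            val, idx = ss.find_offset(v, 0, (0.020, 0.100), fs)
            lo, hi = round(0.020 * fs), round(0.100 * fs)
            best = min(range(lo, hi + 1), key=lambda i: (v[i], i))
            assert (val, idx) == (v[best], best)

    def test_stride2_window_reaches_160ms(self):
        fs = 500.0
        v = np.ones(200)
        v[70] = 0.1  # minimum at 140 ms: outside 20–100 ms, inside 20–160 ms
        val_std, idx_std = ss.find_offset(v, 0, (0.020, 0.100), fs)
        val_s2, idx_s2 = ss.find_offset(v, 0, (0.020, 0.160), fs)
        assert idx_std != 70 and val_std == pytest.approx(1.0)
        assert (val_s2, idx_s2) == (pytest.approx(0.1), 70)

    def test_window_exceeding_stride_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ss.find_offset(np.zeros(30), 0, (0.020, 0.100), fs=500.0)


class TestZeroVelocityUpdate:
    def test_zero_offset_identity(self):
        v = np.array([0.1, 0.2, 0.3])
        np.testing.assert_array_equal(ss.zero_velocity_update(v, 0.0, 0), v)

    def test_spec_arithmetic(self):
        out = ss.zero_velocity_update(np.array([0.5, 0.6, 0.7, 0.9]), 0.7, 2)
        np.testing.assert_allclose(out, [0.0, 0.0, 0.0, 0.2], atol=1e-15)

    @given(
        v=hnp.arrays(float, st.integers(5, 60), elements=st.floats(-10, 10)),
        frac=st.floats(0, 0.99),
        off=st.floats(-5, 5),
    )
    def test_postcondition_exact(self, v, frac, off):
        idx = int(frac * len(v))
        out = ss.zero_velocity_update(v, off, idx)
        assert np.all(out[:idx] == 0.0)
        np.testing.assert_array_equal(out[idx:], v[idx:] - off)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            ss.zero_velocity_update(np.zeros(5), 0.0, 5)


class TestStrideLength:
    def test_constant_velocity_analytic(self):
        n = 401  # 0.8 s
        vx = np.full(n, 5.0)
        length, dx, dz = ss.stride_length(vx, np.zeros(n), fs=500.0)
        assert length == pytest.approx(4.0, abs=1e-12)

    def test_norm_of_two_axes(self):
        n = 501  # 1 s
        v = np.full(n, 3.0 / np.sqrt(2))
        length, dx, dz = ss.stride_length(v, v, fs=500.0)
        assert length == pytest.approx(3.0, abs=1e-12)

    def test_matches_fine_grid_quadrature(self, rng):
        # trapezoid on the sample grid == trapezoid on the same grid computed
        # by an independent fine-grid reference (refined with linear interp)
        fs = 500.0
        v = rng.normal(size=300)
        t = np.arange(300) / fs
        tf = np.linspace(t[0], t[-1], 30 * 299 + 1)
        vf = np.interp(tf, t, v)
        ref = np.trapezoid(vf, tf)
        length, dx, _ = ss.stride_length(v, np.zeros_like(v), fs)
        assert dx == pytest.approx(ref, abs=1e-9)


class TestLinearDedrift:
    def test_forces_zero_terminal_velocity(self, rng):
        v = rng.normal(size=100).cumsum()
        out = linear_dedrift(v)
        assert out[0] == pytest.approx(v[0])
        assert out[-1] == pytest.approx(0.0, abs=1e-12)


class TestProcessSprint:
    def test_noiseless_recovery_within_half_percent(self, clean_sprints):
        for eff, sp in clean_sprints.items():
            for foot, gs in sp.sprints.items():
                table = ss.process_sprint(gs, cfg=ss.RunConfig())
                truth = sp.true_stride_lengths[foot]
                assert len(table) == len(truth)
                rel = np.abs(table["length_m"].to_numpy() - truth) / truth
                assert rel.max() < 0.005, (eff, foot)

    def test_stride_numbering_consecutive_from_one(self, default_sprint):
        table = ss.process_sprint(default_sprint.sprints["left"], cfg=ss.RunConfig())
        assert table["stride_index"].tolist() == list(range(1, len(table) + 1))

    def test_lengths_increase_during_acceleration(self, clean_sprints):
        table = ss.process_sprint(
            clean_sprints["100"].sprints["left"], cfg=ss.RunConfig()
        )
        lengths = table["length_m"].to_numpy()
        assert np.all(np.diff(lengths) > -0.01)  # monotone up to plateau jitter

    def test_heading_invariance(self, clean_sprints):
        sp = clean_sprints["80"].sprints["right"]
        table = ss.process_sprint(sp, cfg=ss.RunConfig())
        ang = 0.83
        rot = ss.GlobalSprint(
            t=sp.t,
            acc_x=np.cos(ang) * sp.acc_x - np.sin(ang) * sp.acc_z,
            acc_z=np.sin(ang) * sp.acc_x + np.cos(ang) * sp.acc_z,
            fs=sp.fs,
            foot=sp.foot,
            events=sp.events,
        )
        table_rot = ss.process_sprint(rot, cfg=ss.RunConfig())
        np.testing.assert_allclose(
            table_rot["length_m"], table["length_m"], rtol=1e-6
        )

    def test_mirror_invariance(self, clean_sprints):
        sp = clean_sprints["60"].sprints["left"]
        table = ss.process_sprint(sp, cfg=ss.RunConfig())
        flipped = ss.GlobalSprint(
            t=sp.t, acc_x=-sp.acc_x, acc_z=sp.acc_z, fs=sp.fs,
            foot=sp.foot, events=sp.events,
        )
        table_f = ss.process_sprint(flipped, cfg=ss.RunConfig())
        np.testing.assert_allclose(table_f["length_m"], table["length_m"], atol=1e-9)
        assert table_f["mirrored_x"].iloc[1:].all()

    def test_artefact_correction_mechanism(self, clean_sprints):
        # a ±30 g, 15 ms touch-down transient carrying a spurious net
        # velocity integral (the true foot velocity change is zero) must be
        # neutralized by the correction and must corrupt naive integration
        base = clean_sprints["100"]
        rng = np.random.default_rng(7)
        for foot in ("left", "right"):
            gs = base.sprints[foot]
            acc_x = gs.acc_x.copy()
            td = base.true_events[foot].td
            d = 0.015
            for k in td:
                tr = gs.t[k : k + int(d * gs.fs)] - gs.t[k]
                osc = 30 * 9.81 * np.exp(-tr / 0.004) * np.sin(2 * np.pi * 120 * tr)
                osc -= osc.mean()  # the burst itself changes true velocity by ~0
                pulse = 0.4 * rng.choice([-1, 1]) * (np.pi / (2 * d)) * np.sin(np.pi * tr / d)
                acc_x[k : k + len(tr)] += osc + pulse
            noisy = ss.GlobalSprint(
                t=gs.t, acc_x=acc_x, acc_z=gs.acc_z, fs=gs.fs,
                foot=foot, events=gs.events,
            )
            clean_tab = ss.process_sprint(gs, cfg=ss.RunConfig())
            corr_tab = ss.process_sprint(noisy, cfg=ss.RunConfig())
            naive_tab = ss.process_sprint(
                noisy, cfg=ss.RunConfig({"zvu.enabled": False})
            )
            ref = clean_tab["length_m"].to_numpy()[1:]
            with_corr = np.abs(corr_tab["length_m"].to_numpy()[1:] - ref) / ref
            without = np.abs(naive_tab["length_m"].to_numpy()[1:] - ref) / ref
            assert np.median(with_corr) < 0.02
            assert np.median(without) > 0.05

    def test_injected_offset_biases_naive_length_by_dv_times_duration(
        self, clean_sprints
    ):
        sp = clean_sprints["80"]
        gs = sp.sprints["left"]
        dv, d = 0.4, 0.015
        acc_x = gs.acc_x.copy()
        for k in sp.true_events["left"].td:
            tr = gs.t[k : k + int(d * gs.fs)] - gs.t[k]
            acc_x[k : k + len(tr)] += dv * (np.pi / (2 * d)) * np.sin(np.pi * tr / d)
        biased = ss.GlobalSprint(
            t=gs.t, acc_x=acc_x, acc_z=gs.acc_z, fs=gs.fs,
            foot="left", events=gs.events,
        )
        naive = ss.process_sprint(biased, cfg=ss.RunConfig({"zvu.enabled": False}))
        clean = ss.process_sprint(gs, cfg=ss.RunConfig({"zvu.enabled": False}))
        for i in range(1, len(clean)):
            extra = naive["length_m"][i] - clean["length_m"][i]
            expected = dv * clean["duration_s"][i]
            assert extra == pytest.approx(expected, rel=0.10)

    def test_max_stride_speed(self, clean_sprints):
        tabs = [
            ss.process_sprint(clean_sprints["100"].sprints[f], cfg=ss.RunConfig())
            for f in ("left", "right")
        ]
        import pandas as pd

        v = ss.max_stride_speed(pd.concat(tabs))
        assert 7.0 < v < 9.0  # approaches but does not exceed realistic v_max

    def test_missing_events_is_an_error(self, clean_sprints):
        gs = clean_sprints["60"].sprints["left"]
        bare = ss.GlobalSprint(t=gs.t, acc_x=gs.acc_x, acc_z=gs.acc_z, fs=gs.fs)
        with pytest.raises(ValueError, match="events"):
            ss.process_sprint(bare, cfg=ss.RunConfig())
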