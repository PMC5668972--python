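"""Waveform plumbing: volume integration, breath/PEEP-step segmentation,
PIP extraction and CSV round trips."""

import numpy as np
import pytest

import pulmonarx as px
from pulmonarx.errors import InvalidInputError
from pulmonarx.waveforms import (
    BreathSegment,
    detect_peep_steps,
    extract_pip,
    integrate_volume,
    read_waveform_csv,
    segment_breaths,
    write_waveform_csv,
)

FS = 50.0


def make_record(flow, pressure=None, fs=FS):
    flow = np.asarray(flow, dtype=float)
    if pressure is None:
        pressure = np.zeros_like(flow)
    t = np.arange(flow.size) / fs
    return px.WaveformRecord(time=t, pressure=pressure, flow=flow, sample_rate=fs)


class TestRecordInvariants:
    def test_rejects_nonuniform_grid(self):
        t = np.array([0.0, 0.02, 0.05, 0.06])
        with pytest.raises(InvalidInputError):
            px.WaveformRecord(t, np.zeros(4), np.zeros(4), sample_rate=FS)

    def test_rejects_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            px.WaveformRecord(
                np.arange(3) / FS, np.zeros(3), np.zeros(2), sample_rate=FS
            )

    def test_rejects_single_sample(self):
        with pytest.raises(InvalidInputError):
            px.WaveformRecord(np.zeros(1), np.zeros(1), np.zeros(1))


class TestIntegrateVolume:
    def test_square_breath_symmetric_integral(self):
        # +0.5 L/s inspiration (samples 0..50), then an expiratory limb
        # arranged so the trapezoidal integral closes exactly at 0
        flow = np.empty(102)
        flow[:51] = 0.5
        flow[51:] = -0.5
        rec = make_record(flow)
        breath = BreathSegment(0, 51, 102, 0.0, 0.0)
        out = integrate_volume(rec, [breath])
        assert out.volume[50] == pytest.approx(0.5, abs=1e-12)
        assert out.volume[101] == 0.0
        assert out.volume[0] == 0.0

    def test_zero_flow_gives_zero_volume(self):
        rec = make_record(np.zeros(100))
        out = integrate_volume(rec, [BreathSegment(0, 50, 100, 0.0, 0.0)])
        np.testing.assert_array_equal(out.volume, 0.0)

    def test_drift_compensation_matches_linear_detrend_oracle(self):
        # sinusoidal breaths with the expiratory limb scaled down so each
        # breath leaks +0.01 L; compensation must re-zero every breath end
        fs, n_b, n_breaths = FS, 100, 6
        one = np.sin(2 * np.pi * np.arange(n_b) / n_b)
        one[one < 0] *= 0.9  # expiratory limb shrunk -> volume drift
        flow = np.tile(one, n_breaths)
        rec = make_record(flow)
        breaths = [
            BreathSegment(k * n_b, k * n_b + n_b // 2, (k + 1) * n_b, 0.0, 0.0)
            for k in range(n_breaths)
        ]
        out = integrate_volume(rec, breaths)
        # oracle: raw integral minus per-breath linearly interpolated ramp
        from scipy.integrate import cumulative_trapezoid

        raw = cumulative_trapezoid(flow, dx=1 / fs, initial=0.0)
        for b in breaths:
            s, e = b.start_index, b.end_index
            seg = raw[s:e] - raw[s]
            oracle = seg - np.linspace(0.0, seg[-1], e - s)
            np.testing.assert_allclose(out.volume[s:e], oracle, atol=1e-14)
            assert out.volume[e - 1] == 0.0

    def test_overlapping_breaths_rejected(self):
        rec = make_record(np.ones(100))
        with pytest.raises(InvalidInputError):
            integrate_volume(
                rec,
                [BreathSegment(0, 30, 60, 0, 0), BreathSegment(50, 70, 100, 0, 0)],
            )


class TestSegmentBreaths:
    def test_sinusoid_18_breaths_per_minute(self):
        t = np.arange(int(60 * FS)) / FS
        flow = 0.5 * np.sin(2 * np.pi * t / 3.333)
        rec = make_record(flow)
        assert len(segment_breaths(rec)) == 18

    def test_zero_flow_gives_empty_list(self):
        assert segment_breaths(make_record(np.zeros(500))) == []

    def test_simulator_breath_count_recovered(self, inclass_sim):
        proto = inclass_sim.protocol
        breaths = segment_breaths(inclass_sim.record)
        assert len(breaths) == proto.n_steps * proto.breaths_per_step

    def test_hysteresis_rejects_subthreshold_wiggle(self):
        # a 0.01 L/s wiggle during expiration must not start a new breath
        flow = np.concatenate(
            [
                np.full(30, 0.4),
                np.full(20, -0.4),
                np.full(20, 0.01),
                np.full(30, 0.4),
                np.full(30, -0.4),
            ]
        )
        rec = make_record(flow)
        breaths = segment_breaths(rec)
        assert len(breaths) == 2
        assert breaths[0].start_index == 0
        assert breaths[1].start_index == 70

    def test_concatenation_consistency(self):
        """Segmenting two records glued at a breath boundary equals the
        concatenation of per-record segmentations."""
        t = np.arange(300) / FS
        one = 0.5 * np.sin(2 * np.pi * np.arange(100) / 100)
        a, b = np.tile(one, 2), np.tile(one, 1)
        both = np.concatenate([a, b])
        seg_a = segment_breaths(make_record(a))
        seg_b = segment_breaths(make_record(b))
        seg_all = segment_breaths(make_record(both))
        starts = [s.start_index for s in seg_a] + [
            s.start_index + a.size for s in seg_b
        ]
        assert [s.start_index for s in seg_all] == starts


class TestPeepSteps:
    @staticmethod
    def _staircase(levels, breaths_each=10):
        n_b = 100
        one = 0.5 * np.sin(2 * np.pi * np.arange(n_b) / n_b)
        flow = np.tile(one, breaths_each * len(levels))
        pressure = np.repeat(levels, breaths_each * n_b).astype(float)
        # add a tidal swing so peak != baseline
        pressure = pressure + 8.0 * np.clip(np.tile(one, breaths_each * len(levels)), 0, None)
        return make_record(flow, pressure)

    def test_staircase_grouping(self):
        rec = self._staircase([8, 10, 12])
        steps = detect_peep_steps(rec, segment_breaths(rec))
        assert [round(s.peep) for s in steps] == [8, 10, 12]
        assert all(len(s.breaths) == 10 for s in steps[:-1])

    def test_single_level_single_step(self):
        rec = self._staircase([10])
        steps = detect_peep_steps(rec, segment_breaths(rec))
        assert len(steps) == 1

    def test_simulator_levels_recovered(self, inclass_sim):
        ds = px.StepDataset.from_record(inclass_sim.record)
        programmed = inclass_sim.protocol.peeps
        assert len(ds.steps) == len(programmed)
        for step, peep in zip(ds.steps, programmed):
            assert step.peep == pytest.approx(peep, abs=0.5)

    def test_noisy_simulator_levels_recovered(self, noisy_sim):
        ds = px.StepDataset.from_record(noisy_sim.record)
        assert len(ds.steps) == noisy_sim.protocol.n_steps

    def test_baselines_within_tolerance_of_peep(self, noisy_sim):
        ds = px.StepDataset.from_record(noisy_sim.record)
        for step in ds.steps:
            for b in step.breaths:
                assert abs(b.baseline_pressure - step.peep) <= 1.0


class TestExtractPip:
    def test_median_of_peaks(self):
        n_b = 100
        peaks = [41.0, 42.0, 41.0]
        tri = 1.0 - np.abs(np.arange(n_b) - 50) / 50.0  # exact 1.0 at sample 50
        pressure = np.concatenate(
            [np.full(n_b, 10.0) + (p - 10.0) * tri for p in peaks]
        )
        flow = np.tile(0.5 * np.sin(2 * np.pi * np.arange(n_b) / n_b), 3)
        rec = make_record(flow, pressure)
        breaths = segment_breaths(rec)
        steps = detect_peep_steps(rec, breaths)
        assert extract_pip(steps[0], rec) == pytest.approx(41.0, abs=1e-9)

    def test_single_breath(self):
        n_b = 100
        flow = 0.5 * np.sin(2 * np.pi * np.arange(n_b) / n_b)
        rec = make_record(flow, 10.0 + 29.5 * np.hanning(n_b))
        steps = detect_peep_steps(rec, segment_breaths(rec))
        assert extract_pip(steps[0], rec) == pytest.approx(
            float((10.0 + 29.5 * np.hanning(n_b)).max())
        )

    def test_noiseless_vc_step_matches_first_order_closed_form(self):
        """PIP of a linear single-compartment VC breath equals
        PEEP + E*VT + R*flow."""
        from pulmonarx.simulate import RmProtocol, VirtualPatient, simulate_rm

        patient = VirtualPatient(elastance=px.ElastanceCurve([25.0]), resistance=10.0)
        proto = RmProtocol(
            peep_start=10.0, n_steps=2, breaths_per_step=5, respiratory_rate=20.0,
            tidal_volume=0.5, noise_sd=0.0, flow_noise_sd=0.0,
            amplitude_jitter=0.0, timing_jitter_s=0.0, seed=0,
        )
        sim = simulate_rm(patient, proto)
        ds = px.StepDataset.from_record(sim.record)
        # inspiration lasts 1 s at 20 breaths/min -> flow = VT / 1 s
        expected = 10.0 + 25.0 * 0.5 + 10.0 * 0.5
        assert extract_pip(ds.steps[0], ds.record) == pytest.approx(expected, abs=1e-9)


class TestCsvRoundTrip:
    def test_round_trip_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = make_record(rng.normal(0, 0.5, 100), rng.uniform(5, 40, 100))
        path = tmp_path / "rec.csv"
        write_waveform_csv(rec, path)
        back = read_waveform_csv(path)
        np.testing.assert_allclose(back.time, rec.time, atol=1e-9)
        np.testing.assert_allclose(back.pressure, rec.pressure, atol=1e-9)
        np.testing.assert_allclose(back.flow, rec.flow, atol=1e-9)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,pressure_cmH2O\n0.0,10.0\n0.02,11.0\n")
        with pytest.raises(InvalidInputError, match="flow_Lps"):
            read_waveform_csv(path)

    def test_nan_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_s,pressure_cmH2O,flow_Lps\n0.0,10.0,0.1\n0.02,,0.2\n"
        )
        with pytest.raises(InvalidInputError):
            read_waveform_csv(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_s,pressure_cmH2O,flow_Lps\n0.0,10.0,0.1\n0.0,10.0,0.2\n"
        )
        with pytest.raises(InvalidInputError):
            read_waveform_csv(path)

    def test_crlf_and_lf_parse_identically(self, tmp_path):
        body = "time_s,pressure_cmH2O,flow_Lps\n0.0,10.0,0.1\n0.02,11.0,0.2\n0.04,12.0,0.3\n"
        lf, crlf = tmp_path / "lf.csv", tmp_path / "crlf.csv"
        lf.write_bytes(body.encode())
        crlf.write_bytes(body.replace("\n", "\r\n").encode())
        a, b = read_waveform_csv(lf), read_waveform_csv(crlf)
        np.testing.assert_array_equal(a.pressure, b.pressure)
        np.testing.assert_array_equal(a.flow, b.flow)


def test_step_summary_json(noisy_sim):
    import json

    ds = px.StepDataset.from_record(noisy_sim.record)
    loaded = json.loads(ds.steps[0].summary_json())
    assert set(loaded) == {"peep", "n_breaths", "step_pip"}
    assert loaded["n_breaths"] == len(ds.steps[0].breaths)
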