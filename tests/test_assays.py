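"""Hill fits, single-channel idealization, baseline, temperature relations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ardscan as a
from ardscan.assays import (
    ASSAY_CONCENTRATIONS_UM,
    read_dose_response_csv,
    read_trace_csv,
)
from ardscan.errors import (
    FitError,
    MissingReferenceError,
    NoReferenceWindowError,
    SegmentError,
    WindowError,
    ZeroReferenceError,
)
from ardscan import synth


def points(pairs):
    return [a.DoseResponsePoint(c, i) for c, i in pairs]


class TestNormalizeDoseResponse:
    def test_reference_maps_to_one(self):
        out = a.normalize_dose_response(points([(5.0, 4.0), (0.3, 2.0)]))
        by_conc = {p.concentration_um: p.normalized for p in out}
        assert by_conc[5.0] == 1.0
        assert by_conc[0.3] == 0.5

    def test_missing_reference(self):
        with pytest.raises(MissingReferenceError):
            a.normalize_dose_response(points([(0.3, 2.0)]))

    def test_zero_reference(self):
        with pytest.raises(ZeroReferenceError):
            a.normalize_dose_response(points([(5.0, 0.0), (0.3, 2.0)]))


class TestHillFit:
    def test_noiseless_inversion_exact(self):
        (pts,) = synth.simulate_dose_response(
            imax=1.0, ec50_um=0.3, n=2.0, noise_sigma=0.0, seed=0
        )
        fit = a.hill_fit(pts)
        assert fit.converged
        assert fit.imax == pytest.approx(1.0, rel=1e-6)
        assert fit.ec50_um == pytest.approx(0.3, rel=1e-6)
        assert fit.n == pytest.approx(2.0, rel=1e-6)

    def test_half_maximum_at_ec50(self):
        fit = a.HillFit(imax=0.98, ec50_um=0.27, n=2.3, rss=0.0, converged=True)
        assert fit.predict(0.27) == pytest.approx(0.98 / 2)

    def test_recovery_under_noise(self):
        # 200 seeded replicates at sigma=0.05: median EC50 error < 10 %
        errors = []
        for seed in range(200):
            (pts,) = synth.simulate_dose_response(
                imax=1.0, ec50_um=0.3, n=2.0, noise_sigma=0.05, seed=seed
            )
            fit = a.hill_fit(pts)
            errors.append(abs(fit.ec50_um - 0.3) / 0.3)
        assert np.median(errors) < 0.10

    def test_too_few_concentrations(self):
        with pytest.raises(FitError):
            a.hill_fit(points([(0.3, 0.5), (5.0, 1.0)]))

    def test_multistart_handles_steep_low_ec50(self):
        conc = np.array(ASSAY_CONCENTRATIONS_UM)
        resp = a.hill_curve(conc, 1.0, 0.05, 4.0)
        fit = a.hill_fit(
            [a.DoseResponsePoint(c, r, r) for c, r in zip(conc, resp)]
        )
        assert fit.ec50_um == pytest.approx(0.05, rel=1e-4)


class TestConcatenateSegments:
    def _sweep(self, fill, n=100, fs=1000.0):
        x = np.full(n, fill)
        return a.ChannelTrace(x, fs, {"+80mV": (50, 100), "-80mV": (0, 50)})

    def test_lengths_add(self):
        out = a.concatenate_segments([self._sweep(1.0), self._sweep(2.0)])
        assert len(out.current_pa) == 100
        assert out.labels["segment"] == "+80mV"

    def test_order_preserved(self):
        s1, s2 = self._sweep(1.0), self._sweep(2.0)
        fwd = a.concatenate_segments([s1, s2]).current_pa
        rev = a.concatenate_segments([s2, s1]).current_pa
        assert fwd[0] == 1.0 and rev[0] == 2.0
        assert not np.array_equal(fwd, rev)

    def test_missing_tag_and_empty(self):
        sweep = a.ChannelTrace(np.zeros(10), 1000.0, {"-80mV": (0, 5)})
        with pytest.raises(SegmentError):
            a.concatenate_segments([sweep])
        with pytest.raises(SegmentError):
            a.concatenate_segments([])


class TestSubtractBaseline:
    def test_constant_offset_removed(self):
        trace, _ = synth.simulate_two_state_channel(
            30, 70, 8.0, 5000, 10, noise_sigma_pa=0.4, seed=1
        )
        shifted = a.ChannelTrace(trace.current_pa + 12.5, 5000)
        recovered = a.subtract_baseline(shifted, 1.0)
        rms = np.sqrt(np.mean((recovered.current_pa - trace.current_pa) ** 2))
        # closed level moves to ~0; compare against the self-subtracted original
        own = a.subtract_baseline(trace, 1.0)
        assert np.allclose(recovered.current_pa, own.current_pa, atol=1e-9)
        assert rms < np.sqrt(np.mean(trace.current_pa**2)) + 12.5

    def test_zero_trace_stays_zero(self):
        trace = a.ChannelTrace(np.zeros(5000), 5000.0)
        out = a.subtract_baseline(trace, 0.5)
        assert np.allclose(out.current_pa, 0.0)

    def test_linear_drift_removed(self):
        i = 8.0
        trace, _ = synth.simulate_two_state_channel(
            30, 70, i, 20000, 30, noise_sigma_pa=0.1 * i,
            drift_pa_per_s=0.2, seed=7,
        )
        out = a.subtract_baseline(trace, 1.0)
        ideal = a.idealize_half_amplitude(out, i)
        closed = out.current_pa[ideal.levels == 0]
        assert abs(closed.mean()) < 0.05 * i

    def test_window_must_fit(self):
        trace = a.ChannelTrace(np.zeros(100), 100.0)
        with pytest.raises(WindowError):
            a.subtract_baseline(trace, 2.0)


class TestIdealizeHalfAmplitude:
    def test_square_wave_po_exact(self):
        x = np.tile([0.0, 8.0], 500)
        trace = a.ChannelTrace(x, 1000.0)
        ideal = a.idealize_half_amplitude(trace, 8.0)
        assert ideal.open_probability == 0.5

    def test_all_zero_trace(self):
        trace = a.ChannelTrace(np.zeros(100), 1000.0)
        assert a.idealize_half_amplitude(trace, 8.0).open_probability == 0.0

    def test_markov_simulation_recovery(self):
        trace, truth = synth.simulate_two_state_channel(
            open_rate_per_s=30, close_rate_per_s=70, unitary_current_pa=8.0,
            sampling_rate_hz=20_000, duration_s=60,
            noise_sigma_pa=0.8, seed=12,
        )
        ideal = a.idealize_half_amplitude(trace, 8.0)
        # standard error of the time-averaged Po of a two-state chain
        po, alpha, beta, t = 0.3, 30.0, 70.0, 60.0
        se = np.sqrt(2 * po**2 * (1 - po) ** 2 * (1 / alpha + 1 / beta) / t)
        assert abs(ideal.open_probability - po) < 3 * se
        # and the idealization agrees with the noise-free occupancy
        assert abs(ideal.open_probability - truth.occupancy.mean()) < 0.01

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 10_000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.5, 400) + 8.0 * rng.integers(0, 2, 400)
        t1 = a.ChannelTrace(x, 1000.0)
        t2 = a.ChannelTrace(x * scale, 1000.0)
        po1 = a.idealize_half_amplitude(t1, 8.0).open_probability
        po2 = a.idealize_half_amplitude(t2, 8.0 * scale).open_probability
        assert po1 == po2

    def test_multichannel_levels_clip(self):
        x = np.array([0.0, 8.0, 16.0, 24.0, 80.0])
        trace = a.ChannelTrace(x, 1000.0)
        ideal = a.idealize_half_amplitude(trace, 8.0, n_channels=2)
        assert list(ideal.levels) == [0, 1, 2, 2, 2]

    def test_estimator_unbiased_across_seeds(self):
        diffs = []
        for seed in range(100):
            trace, truth = synth.simulate_two_state_channel(
                30, 70, 8.0, 20_000, 10, noise_sigma_pa=0.8, seed=seed
            )
            est = a.idealize_half_amplitude(trace, 8.0).open_probability
            diffs.append(est - truth.occupancy.mean())
        # noise is symmetric around each level: bias within Monte-Carlo error
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / 10 + 1e-4

    def test_nonpositive_unitary_rejected(self):
        trace = a.ChannelTrace(np.zeros(10), 1000.0)
        with pytest.raises(ZeroReferenceError):
            a.idealize_half_amplitude(trace, 0.0)


class TestMacroOpenProbability:
    @pytest.mark.parametrize(
        "i,ref,po,flag",
        [(2.0, 4.0, 0.5, False), (4.0, 4.0, 1.0, False), (5.0, 4.0, 1.25, True)],
    )
    def test_ratio_and_over_unity_flag(self, i, ref, po, flag):
        assert a.macro_open_probability(i, ref) == (pytest.approx(po), flag)

    def test_nonpositive_reference(self):
        with pytest.raises(ZeroReferenceError):
            a.macro_open_probability(1.0, 0.0)


class TestTemperatureRelation:
    def test_constant_current_normalizes_to_one(self):
        sweeps = [("c1", float(t), 100.0) for t in range(10, 61)]
        rel = a.temperature_relation(sweeps)
        assert np.allclose(rel.medians, 1.0)

    def test_room_window_required(self):
        with pytest.raises(NoReferenceWindowError):
            a.temperature_relation([("c1", 40.0, 5.0)])

    def test_single_bin(self):
        rel = a.temperature_relation([("c1", 21.0, 3.0), ("c1", 21.4, 3.0)])
        assert len(rel.bin_centers_c) == 1
        assert rel.medians[0] == pytest.approx(1.0)

    def test_synthetic_heat_activation_monotone_above_35(self):
        rows = synth.simulate_temperature_currents(
            delta_h_kcal=60.0, t_half_c=44.0, n_cells=8, noise_sigma=0.03, seed=5
        )
        rel = a.temperature_relation(rows)
        hot = rel.medians[rel.bin_centers_c >= 35.0]
        assert np.all(np.diff(hot) > -0.02 * np.max(hot))  # non-decreasing

    def test_room_bin_median_near_one(self):
        rows = synth.simulate_temperature_currents(seed=2)
        rel = a.temperature_relation(rows)
        room = rel.medians[(rel.bin_centers_c >= 20) & (rel.bin_centers_c <= 25)]
        assert np.allclose(room, 1.0, atol=0.05)


class TestDelimitedIO:
    def test_dose_response_csv_round_trip(self, tmp_path):
        path = tmp_path / "dr.csv"
        path.write_text("conc_uM,current_pA\n0.3,2.0\n5.0,4.0\n10.0,4.1\n")
        pts = read_dose_response_csv(path)
        assert [p.concentration_um for p in pts] == [0.3, 5.0, 10.0]

    def test_trace_csv_with_segments(self, tmp_path):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.where((t % 1.0) >= 0.5, 8.0, -8.0)  # +80 mV half of each sweep
        trace_csv = tmp_path / "trace.csv"
        trace_csv.write_text(
            "time_s,current_pA\n"
            + "\n".join(f"{ti:.6f},{xi:.3f}" for ti, xi in zip(t, x))
        )
        seg_csv = tmp_path / "segments.csv"
        seg_csv.write_text(
            "sweep_id,segment,start_s,end_s,voltage_mV,ligand_uM,pH\n"
            "0,-80mV,0.0,0.5,-80,0.1,7.2\n"
            "0,+80mV,0.5,1.0,80,0.1,7.2\n"
            "1,-80mV,1.0,1.5,-80,0.1,7.2\n"
            "1,+80mV,1.5,2.0,80,0.1,7.2\n"
        )
        sweeps = read_trace_csv(trace_csv, seg_csv)
        assert len(sweeps) == 2
        cat = a.concatenate_segments(sweeps, "+80mV")
        assert len(cat.current_pa) == 1000
        assert np.all(cat.current_pa == 8.0)
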