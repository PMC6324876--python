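import numpy as np
import pytest

from ffnquant import (
    RegionKinetics,
    auc,
    compute_dff,
    fit_baseline,
    frame_mean_trace,
    hill_saturation,
    make_stimulus_protocol,
    pulse_amplitudes,
    recovery_fraction,
    region_kinetics,
    simulate_movie,
    simulate_slice_session,
    simulate_trace,
    transient_kernel,
)


def _dff_of(raw, protocol):
    return compute_dff(raw, fit_baseline(raw, protocol), protocol)


class TestSimulateTrace:
    def test_zero_amplitude_gives_pure_bleaching_baseline(self, single_pulse):
        kin = RegionKinetics(amplitude_per_pulse=0.0, bleach_slope=0.01)
        raw, truth = simulate_trace(kin, single_pulse, duration_s=5.0, noise_sd=0.0)
        expected = kin.baseline_f0 * (1.0 - 0.01 * raw.times_s)
        assert np.allclose(raw.values, expected)
        assert truth.total_amplitude_pct == 0.0

    def test_single_pulse_peak_equals_true_amplitude(
        self, probe_kinetics, single_pulse
    ):
        raw, truth = simulate_trace(
            probe_kinetics, single_pulse, duration_s=8.0, noise_sd=0.0
        )
        dff = _dff_of(raw, single_pulse)
        assert dff.values.max() == pytest.approx(truth.amplitudes_pct[0], rel=1e-9)

    def test_calcium_scaling_matches_hill_ratio(self, probe_kinetics, single_pulse):
        # closed-form Hill ratio: A(0.5) / A(2) = hill(0.5) / hill(2)
        lo, _ = simulate_trace(
            probe_kinetics, single_pulse, calcium_mM=0.5, duration_s=5.0
        )
        hi, _ = simulate_trace(
            probe_kinetics, single_pulse, calcium_mM=2.0, duration_s=5.0
        )
        ec50, h = probe_kinetics.ca_ec50_mM, probe_kinetics.ca_hill
        expected = (0.5**h / (0.5**h + ec50**h)) / (2.0**h / (2.0**h + ec50**h))
        peak_lo = _dff_of(lo, single_pulse).values.max()
        peak_hi = _dff_of(hi, single_pulse).values.max()
        assert peak_lo / peak_hi == pytest.approx(expected, rel=1e-9)

    def test_protocol_beyond_duration_rejected(self, train_10hz):
        with pytest.raises(ValueError):
            simulate_trace(region_kinetics("GPe"), train_10hz, duration_s=1.5)

    def test_amplitude_monotone_in_calcium(self, single_pulse):
        kin = region_kinetics("GPe")
        amps = [
            pulse_amplitudes(kin, single_pulse, calcium_mM=c)[0]
            for c in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(amps) > 0) and amps[0] == 0.0

    def test_calcium_saturation_above_2mM(self):
        # increments shrink: hill(4) - hill(2) < hill(2) - hill(0.5)
        h = [hill_saturation(c) for c in (0.5, 2.0, 4.0)]
        assert h[2] - h[1] < h[1] - h[0]

    def test_recovery_fraction_saturates(self):
        assert recovery_fraction(0.0, 60.0) == 0.0
        assert recovery_fraction(600.0, 60.0) == pytest.approx(1.0, abs=1e-4)
        # GPe recovers much faster than striatum at a 10 s interval
        assert recovery_fraction(10.0, 10.0) > recovery_fraction(10.0, 60.0)

    def test_determinism(self, probe_kinetics, single_pulse):
        a, _ = simulate_trace(
            probe_kinetics, single_pulse, duration_s=5.0, noise_sd=5.0, seed=42
        )
        b, _ = simulate_trace(
            probe_kinetics, single_pulse, duration_s=5.0, noise_sd=5.0, seed=42
        )
        assert np.array_equal(a.values, b.values)


class TestKernelAndPresets:
    def test_kernel_unit_peak_and_causality(self):
        t = np.linspace(-1, 5, 2000)
        h = transient_kernel(t, 0.05, 1.0)
        assert np.all(h[t < 0] == 0)
        assert h.max() == pytest.approx(1.0, abs=1e-4)

    def test_presets_differ_in_the_documented_directions(self):
        stri, gpe = region_kinetics("striatum"), region_kinetics("GPe")
        assert gpe.decay_tau_s < stri.decay_tau_s
        assert gpe.recovery_tau_s == pytest.approx(10.0)
        assert stri.recovery_tau_s == pytest.approx(60.0)
        assert stri.facilitation_per_pulse == 0.0
        assert gpe.facilitation_per_pulse > 0.0

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            region_kinetics("cerebellum")

    def test_gpe_train_amplitude_strictly_increasing_in_frequency(self):
        kin = region_kinetics("GPe")
        totals = []
        for freq in (5.0, 10.0, 20.0, 50.0):
            protocol = make_stimulus_protocol(freq, 5, onset_s=1.0)
            totals.append(pulse_amplitudes(kin, protocol).sum())
        assert np.all(np.diff(totals) > 0)

    def test_striatum_train_amplitude_frequency_independent(self):
        kin = region_kinetics("striatum")
        t10 = pulse_amplitudes(kin, make_stimulus_protocol(10.0, 5, 1.0)).sum()
        t50 = pulse_amplitudes(kin, make_stimulus_protocol(50.0, 5, 1.0)).sum()
        assert t10 == pytest.approx(t50, rel=1e-12)


class TestSimulateMovie:
    def test_static_when_nothing_happens(self, single_pulse):
        kin = RegionKinetics(amplitude_per_pulse=0.0, bleach_slope=0.0)
        movie, truth = simulate_movie(
            kin, single_pulse, puncta_count=0, duration_s=3.0, noise_model="none"
        )
        assert truth.puncta_count == 0
        assert np.all(movie.frames == movie.frames[0])

    def test_frame_mean_conserves_simulated_trace(self, single_pulse):
        kin = region_kinetics("striatum")
        movie, _ = simulate_movie(
            kin, single_pulse, duration_s=5.0, noise_model="none", seed=3
        )
        raw_trace, _ = simulate_trace(kin, single_pulse, duration_s=5.0, seed=3)
        assert np.allclose(
            frame_mean_trace(movie).values, raw_trace.values, rtol=1e-12
        )

    def test_same_seed_bit_identical(self, single_pulse):
        kin = region_kinetics("GPe")
        a, _ = simulate_movie(kin, single_pulse, duration_s=3.0, noise_sd=3.0, seed=9)
        b, _ = simulate_movie(kin, single_pulse, duration_s=3.0, noise_sd=3.0, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_punctum_outside_frame_rejected(self, single_pulse):
        with pytest.raises(ValueError):
            simulate_movie(
                region_kinetics("GPe"),
                single_pulse,
                puncta_count=1,
                duration_s=3.0,
                puncta_positions=np.array([[80.0, 10.0]]),
            )

    def test_end_to_end_peak_recovery_noiseless(self, probe_kinetics, single_pulse):
        # extraction applied to the movie recovers the true peak within 5 %
        movie, truth = simulate_movie(
            probe_kinetics,
            single_pulse,
            duration_s=6.0,
            noise_model="none",
            seed=11,
        )
        raw = frame_mean_trace(movie)
        dff = _dff_of(raw, single_pulse)
        assert dff.values.max() == pytest.approx(
            truth.amplitudes_pct[0], rel=0.05
        )


class TestSliceSession:
    def test_no_hotspots_draws_only_low_distribution(self):
        session = simulate_slice_session(
            50, hotspot_fraction=0.0, auc_distributions={"low": (2.0, 0.1), "high": (50.0, 0.1)}, seed=0
        )
        assert not any(f.is_hotspot for f in session.fovs)
        assert session.aucs().max() < 10.0

    def test_hotspots_draw_high_distribution(self):
        session = simulate_slice_session(40, hotspot_fraction=0.25, seed=1)
        hot = np.array([f.is_hotspot for f in session.fovs])
        assert hot.sum() == 10
        assert session.aucs()[hot].mean() > session.aucs()[~hot].mean()

    def test_same_seed_identical_session(self):
        a = simulate_slice_session(12, seed=5)
        b = simulate_slice_session(12, seed=5)
        assert np.array_equal(a.positions(), b.positions())
        assert np.array_equal(a.aucs(), b.aucs())

    def test_positions_within_extent(self):
        session = simulate_slice_session(
            30, hotspot_fraction=0.2, placement="clustered", extent_um=(500, 300), seed=2
        )
        pos = session.positions()
        assert pos[:, 0].min() >= 0 and pos[:, 0].max() <= 500
        assert pos[:, 1].min() >= 0 and pos[:, 1].max() <= 300

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_fovs": 0},
            {"n_fovs": 5, "hotspot_fraction": 1.5},
            {"n_fovs": 5, "extent_um": (0.0, 100.0)},
            {"n_fovs": 5, "placement": "spiral"},
        ],
    )
    def test_invalid_session_parameters(self, kwargs):
        with pytest.raises(ValueError):
            simulate_slice_session(**kwargs)
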