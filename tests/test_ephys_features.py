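"""Spike detection/characterisation, passive properties, ISI statistics,
average shapes and the AHP ICA."""

import numpy as np
import pytest

from glomcluster.ephys_features import (
    NoSpikesError,
    average_spike_shape,
    characterize_spike,
    compute_ephys_features,
    cv_isi,
    detect_spikes,
    fit_ahp_ica,
    input_resistance,
    membrane_time_constant,
    score_ahp,
)
from glomcluster.io_formats import Sweep, SweepSet
from glomcluster.synthetic_data import (
    CohortSpec,
    _ahp_sources,
    generate_sweeps,
    spike_template,
)

from conftest import make_step_sweep, passive_sweep, sweepset

RATE = 33000.0


def spiking_sweep(times_s, amplitude=60.0, half_width=0.6, speed_ratio=2.0,
                  rate=RATE, amp_step=40.0):
    template = spike_template(rate, amplitude, half_width, speed_ratio)
    n_pre = int(np.argmax(template))

    def v_of_t(t):
        v = np.full(len(t), -60.0)
        for st in times_s:
            k0 = int(round(st * rate)) - n_pre
            k1 = min(k0 + len(template), len(v))
            v[k0:k1] += template[:k1 - k0]
        return v

    return make_step_sweep(rate=rate, amplitude=amp_step, v_of_t=v_of_t)


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        s = make_step_sweep(amplitude=-20.0)
        assert len(detect_spikes(s, RATE)) == 0

    def test_three_planted_spikes_found_within_100us(self):
        times = [0.15, 0.3, 0.45]
        s = spiking_sweep(times)
        peaks = detect_spikes(s, RATE) / RATE
        assert len(peaks) == 3
        assert np.allclose(peaks, times, atol=1e-4)

    def test_doublet_3ms_apart_gives_two_peaks(self):
        s = spiking_sweep([0.2, 0.203])
        assert len(detect_spikes(s, RATE)) == 2


class TestCharacterisation:
    def test_symmetric_spike_speed_ratio_one(self):
        s = spiking_sweep([0.2], half_width=1.0, speed_ratio=1.0)
        peak = detect_spikes(s, RATE)[0]
        ev = characterize_spike(s, peak, RATE)
        assert ev.speed_ratio == pytest.approx(1.0, rel=0.05)
        assert ev.half_width == pytest.approx(1.0, rel=0.1)

    def test_asymmetric_spike_speed_ratio_two(self):
        s = spiking_sweep([0.2], half_width=1.0, speed_ratio=2.0)
        ev = characterize_spike(s, detect_spikes(s, RATE)[0], RATE)
        assert ev.speed_ratio == pytest.approx(2.0, rel=0.08)

    def test_amplitude_close_to_template(self):
        s = spiking_sweep([0.2], amplitude=50.0)
        ev = characterize_spike(s, detect_spikes(s, RATE)[0], RATE)
        assert ev.amplitude == pytest.approx(50.0, rel=0.05)
        assert ev.t_halfmax_pre < ev.peak_time < ev.t_halfmax_post

    def test_offset_invariance(self):
        """Adding a DC offset changes no spike feature (all are differences)."""
        s1 = spiking_sweep([0.2])
        s2 = Sweep(voltage=s1.voltage + 17.0, current_command=s1.current_command,
                   step_amplitude=s1.step_amplitude, step_onset=s1.step_onset,
                   step_offset=s1.step_offset)
        p1, p2 = detect_spikes(s1, RATE)[0], detect_spikes(s2, RATE)[0]
        e1, e2 = characterize_spike(s1, p1, RATE), characterize_spike(s2, p2, RATE)
        assert e1.amplitude == pytest.approx(e2.amplitude, abs=1e-12)
        assert e1.half_width == pytest.approx(e2.half_width, abs=1e-12)
        assert e1.rise_velocity == pytest.approx(e2.rise_velocity, abs=1e-9)

    def test_resampling_changes_widths_below_one_percent(self):
        e = {}
        for rate in (33000.0, 66000.0):
            s = spiking_sweep([0.2], rate=rate)
            e[rate] = characterize_spike(s, detect_spikes(s, rate)[0], rate)
        assert e[66000.0].half_width == pytest.approx(e[33000.0].half_width, rel=0.01)


class TestPassive:
    def test_single_sweep_input_resistance(self):
        ss = sweepset([passive_sweep(0.1, 20.0, -20.0)])
        assert input_resistance(ss) == pytest.approx(0.1, rel=1e-3)

    def test_linear_cell_slope_exact(self):
        ss = sweepset([passive_sweep(0.25, 15.0, a) for a in (-40, -20, -10, 10, 20)])
        assert input_resistance(ss) == pytest.approx(0.25, rel=1e-6)

    def test_no_subthreshold_sweep_raises(self):
        ss = sweepset([spiking_sweep([0.2, 0.25, 0.3])])
        with pytest.raises(ValueError):
            input_resistance(ss)

    def test_exact_exponential_tau(self):
        ss = sweepset([passive_sweep(0.3, 20.0, -20.0)])
        assert membrane_time_constant(ss) == pytest.approx(20.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_tau_within_5pct(self, seed):
        ss = sweepset([passive_sweep(0.3, 20.0, -20.0, noise_sd=0.2, seed=seed)])
        assert membrane_time_constant(ss) == pytest.approx(20.0, rel=0.05)


class TestCvIsi:
    def test_regular_train_zero(self):
        assert cv_isi([np.array([0.1, 0.2, 0.3, 0.4])]) == pytest.approx(0.0, abs=1e-12)

    def test_single_spike_per_sweep_zero(self):
        assert cv_isi([np.array([0.1]), np.array([0.2]), np.array([0.15])]) == 0.0

    def test_known_isis(self):
        # ISIs 10, 20, 30 ms: sample SD 10, mean 20 -> CV 0.5
        assert cv_isi([np.array([0.0, 0.010, 0.030, 0.060])]) == pytest.approx(0.5)


class TestAverageShape:
    def test_two_identical_spikes_average_equals_one(self):
        s = spiking_sweep([0.2, 0.4])
        shape = average_spike_shape(sweepset([s]))
        one = average_spike_shape(sweepset([spiking_sweep([0.2])]))
        assert np.allclose(shape.waveform, one.waveform, atol=1e-9)
        assert shape.waveform[shape.alignment_index] == shape.waveform.max()

    def test_normalised_at_1ms_prepeak(self):
        shape = average_spike_shape(sweepset([spiking_sweep([0.2])]))
        ref = shape.alignment_index - int(round(1e-3 * RATE))
        assert shape.waveform[ref] == pytest.approx(0.0, abs=1e-12)

    def test_no_spikes_raises(self):
        with pytest.raises(NoSpikesError):
            average_spike_shape(sweepset([make_step_sweep(amplitude=-20.0)]))


class TestIca:
    def _planted(self, seed, n=95, noise=0.05):
        t_ms = np.arange(0, 20.0, 1000.0 / RATE)
        S = _ahp_sources(t_ms)
        rng = np.random.default_rng(seed)
        C = rng.normal(-2.0, 1.5, size=(n, 3))
        return C @ S + noise * rng.normal(size=(n, S.shape[1])), S, C

    def test_planted_sources_recovered(self):
        X, S, _ = self._planted(0)
        model = fit_ahp_ica(X, RATE, seed=0)
        crop = S.shape[1] - model.factors.shape[1]
        cors = np.abs(np.corrcoef(np.vstack([model.factors, S[:, crop:]]))[:3, 3:])
        assert (cors.max(axis=1) > 0.95).all()
        assert sorted(cors.argmax(axis=1)) == [0, 1, 2]

    def test_factor_order_is_early_to_late(self):
        X, _, _ = self._planted(1)
        model = fit_ahp_ica(X, RATE, seed=0)
        extrema = [int(np.argmin(f)) for f in model.factors]
        assert extrema == sorted(extrema)
        for f in model.factors:  # dominant deflection negative
            assert -f.min() >= f.max()

    def test_scores_recover_mixing_up_to_affine(self):
        X, _, C = self._planted(2)
        model = fit_ahp_ica(X, RATE, seed=0)
        for i in range(3):
            r = abs(np.corrcoef(model.scores[:, i], C[:, i])[0, 1])
            assert r > 0.95

    def test_score_ahp_matches_fitted_scores(self):
        X, _, _ = self._planted(3)
        model = fit_ahp_ica(X, RATE, seed=0)
        s = score_ahp(model, X[7])
        assert np.corrcoef(s, model.scores[7])[0, 1] > 0.99

    def test_rank_deficient_input_rejected(self):
        x = np.ones((10, 100)) * np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="dimensions|components"):
            fit_ahp_ica(x, RATE)


class TestAggregate:
    def test_synthetic_cell_parameters_recovered(self):
        spec = CohortSpec()
        rng = np.random.default_rng(4)
        targets = {"early_ahp": -2.0, "late_ahp": 0.0, "intermediate_ahp": 0.5,
                   "half_width": 0.8, "time_constant": 25.0, "input_resistance": 0.8,
                   "speed_ratio": 2.0, "cv_isi": 0.2, "amplitude": 55.0}
        ss, _ = generate_sweeps("C", spec, rng, noise_scale=0.3, targets=targets)
        # a tiny ICA model from planted shapes
        t_ms = np.arange(0, 20.0, 1000.0 / RATE)
        S = _ahp_sources(t_ms)
        rng2 = np.random.default_rng(0)
        shapes = rng2.normal(-2, 1.5, size=(20, 3)) @ S + 0.05 * rng2.normal(size=(20, S.shape[1]))
        model = fit_ahp_ica(shapes, RATE, seed=0)
        f = compute_ephys_features(ss, model)
        assert f.input_resistance == pytest.approx(0.8, rel=0.1)
        assert f.time_constant == pytest.approx(25.0, rel=0.1)
        assert f.half_width == pytest.approx(0.8, rel=0.1)
        assert f.amplitude == pytest.approx(55.0, rel=0.1)

    def test_spike_free_cell_raises_naming_spikes(self):
        ss = sweepset([passive_sweep(0.2, 20.0, -20.0),
                       passive_sweep(0.2, 20.0, 20.0)])
        t_ms = np.arange(0, 20.0, 1000.0 / RATE)
        S = _ahp_sources(t_ms)
        rng = np.random.default_rng(0)
        shapes = rng.normal(size=(10, 3)) @ S + 0.05 * rng.normal(size=(10, S.shape[1]))
        model = fit_ahp_ica(shapes, RATE, seed=0)
        with pytest.raises(NoSpikesError, match="spikes"):
            compute_ephys_features(ss, model)
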