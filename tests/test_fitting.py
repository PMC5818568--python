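"""Stage-1 fits: spike detection and parameter recovery on ground-truth cells."""

import dataclasses

import numpy as np
import pytest

from glifkit.core import GLIFParameters, simulate
from glifkit.fitting import (
    DegenerateInputError,
    InsufficientDataError,
    detect_spikes,
    fit_after_spike_currents,
    fit_cell,
    fit_instantaneous_threshold_init,
    fit_membrane_rc,
    fit_resting_potential,
    fit_spike_cut_and_reset,
    fit_spike_threshold_dynamics,
    fit_voltage_threshold_dynamics,
)
from glifkit.sweeps import Sweep

from conftest import make_cell


class TestDetectSpikes:
    def test_pasted_spikes_found_at_true_onsets(self, cells_noisy):
        sweep = cells_noisy[3].sweeps["noise1"][4]  # supra-threshold epoch
        anns = detect_spikes(sweep)
        true = np.asarray(sweep.meta["true_spike_idx"])
        det = np.array([a.spike_index for a in anns])
        assert det.size == true.size > 10
        assert np.max(np.abs(det - true)) <= 1

    def test_flat_trace_yields_empty_list(self):
        sweep = Sweep(fs=10_000.0, current=np.zeros(1000), voltage=np.full(1000, -70e-3))
        assert detect_spikes(sweep) == []

    def test_annotation_windows_do_not_overlap(self, cells_noisy):
        sweep = cells_noisy[1].sweeps["noise1"][4]
        anns = detect_spikes(sweep)
        assert len(anns) > 5
        for a, b in zip(anns[:-1], anns[1:]):
            assert a.cut_window[1] <= b.spike_index
            assert a.spike_index < a.peak_index <= a.cut_window[1]

    def test_two_sample_minimum(self):
        with pytest.raises(InsufficientDataError):
            detect_spikes(Sweep(fs=1000.0, current=np.zeros(1), voltage=np.zeros(1)))


class TestRestingPotential:
    def test_mean_of_constant(self):
        assert fit_resting_potential([np.full(100, -70e-3)]) == pytest.approx(-70e-3)

    def test_pooled_mean_of_two_segments(self):
        segs = [np.full(50, -70e-3), np.full(50, -72e-3)]
        assert fit_resting_potential(segs) == pytest.approx(-71e-3)

    def test_noisy_mean_within_standard_error(self):
        rng = np.random.default_rng(0)
        seg = -70e-3 + rng.normal(0, 1e-3, 10_000)
        est = fit_resting_potential([seg])
        assert abs(est - (-70e-3)) < 3 * 1e-3 / np.sqrt(10_000)

    def test_empty_segments_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_resting_potential([])


class TestMembraneRC:
    def test_exact_recovery_on_noiseless_response(self):
        p = GLIFParameters(
            level=1, C=150e-12, R=100e6, E_L=-70e-3, theta_inf=-45e-3, spike_cut=3e-3
        )
        from glifkit.stimulus import make_pink_noise

        ep = make_pink_noise(100e-12, 3.0, 10_000.0, 5)
        res = simulate(p, ep)
        assert res.n_spikes == 0
        sweep = Sweep(fs=ep.fs, current=ep.current, voltage=res.voltage)
        R, C, tau = fit_membrane_rc(sweep, p.E_L)
        assert R == pytest.approx(100e6, rel=1e-6)
        assert C == pytest.approx(150e-12, rel=1e-6)
        assert tau == pytest.approx(R * C)

    def test_flat_zero_current_trace_is_degenerate(self):
        sweep = Sweep(fs=10_000.0, current=np.zeros(1000), voltage=np.full(1000, -70e-3))
        with pytest.raises(DegenerateInputError):
            fit_membrane_rc(sweep, -70e-3)


class TestSpikeCutAndReset:
    def test_noiseless_reset_rule_recovery(self, cells_noiseless):
        cell = cells_noiseless[2]
        sweeps = cell.sweeps["noise1"]
        anns = [detect_spikes(s) for s in sweeps]
        fit = fit_spike_cut_and_reset(sweeps, anns, cell.params.E_L)
        fs = sweeps[0].fs
        n_ref = round(cell.params.spike_cut * fs)
        assert fit.spike_cut == pytest.approx(n_ref / fs, abs=1e-9)  # grid exact
        assert fit.f_v == pytest.approx(0.4, abs=0.01)
        assert fit.delta_V == pytest.approx(5e-3, abs=0.1e-3)

    def test_identity_reset_recovered(self):
        cell = make_cell(2, 0.0, seed=3, f_v=1.0, delta_V=0.0)
        sweeps = cell.sweeps["noise1"]
        anns = [detect_spikes(s) for s in sweeps]
        fit = fit_spike_cut_and_reset(sweeps, anns, cell.params.E_L)
        assert fit.f_v == pytest.approx(1.0, abs=0.02)
        assert abs(fit.delta_V) < 0.3e-3

    def test_standard_error_tracks_noise_scale(self, cells_noisy):
        cell = cells_noisy[2]
        sweeps = cell.sweeps["noise1"]
        anns = [detect_spikes(s) for s in sweeps]
        fit = fit_spike_cut_and_reset(sweeps, anns, cell.params.E_L)
        # residuals reflect the recording noise on both regression variables
        meas = cell.recording_noise_sd
        assert 0.5 * meas < fit.standard_error < 4 * meas

    def test_too_few_spikes_rejected(self):
        sweep = Sweep(fs=10_000.0, current=np.zeros(1000), voltage=np.full(1000, -70e-3))
        with pytest.raises(InsufficientDataError, match="5"):
            fit_spike_cut_and_reset([sweep], [[]], -70e-3)


class TestAfterSpikeCurrents:
    def _supra(self, cell):
        sweeps = [
            s
            for s in cell.sweeps["noise1"]
            if s.meta.get("fraction_of_threshold", 1.0) >= 1.0
        ]
        return sweeps, [detect_spikes(s) for s in sweeps]

    def test_noiseless_recovery_selects_true_pair(self, cells_noiseless):
        cell = cells_noiseless[3]
        gt = cell.params
        sweeps, anns = self._supra(cell)
        n_cut = round(gt.spike_cut * cell.fs)
        asc = fit_after_spike_currents(sweeps, anns, gt.E_L, n_cut / cell.fs)
        assert asc.k == gt.k
        assert asc.delta_I[0] == pytest.approx(gt.delta_I[0], rel=0.01)
        assert asc.delta_I[1] == pytest.approx(gt.delta_I[1], rel=0.01)
        assert asc.R_asc == pytest.approx(gt.R, rel=0.01)
        assert asc.C_asc == pytest.approx(gt.C, rel=0.01)

    def test_null_currents_fit_below_noise_floor(self):
        cell = make_cell(3, 0.2e-3, seed=11, delta_I=(0.0, 0.0))
        sweeps, anns = self._supra(cell)
        asc = fit_after_spike_currents(sweeps, anns, cell.params.E_L, cell.params.spike_cut)
        # regression noise floor under recording noise is a few pA
        assert abs(asc.delta_I[0]) < 10e-12
        assert abs(asc.delta_I[1]) < 10e-12

    def test_rc_and_asc_resistance_agree_when_currents_null(self):
        cell = make_cell(3, 0.2e-3, seed=11, delta_I=(0.0, 0.0))
        sweeps, anns = self._supra(cell)
        asc = fit_after_spike_currents(sweeps, anns, cell.params.E_L, cell.params.spike_cut)
        sub = cell.sweeps["noise1"][0]
        R, _, _ = fit_membrane_rc(sub, cell.params.E_L)
        assert asc.R_asc == pytest.approx(R, rel=0.05)

    def test_total_charge_arithmetic(self, cells_noiseless):
        cell = cells_noiseless[3]
        sweeps, anns = self._supra(cell)
        asc = fit_after_spike_currents(sweeps, anns, cell.params.E_L, cell.params.spike_cut)
        q1, q2 = asc.total_charges
        assert q1 == pytest.approx(asc.delta_I[0] / asc.k[0])
        assert q2 == pytest.approx(asc.delta_I[1] / asc.k[1])

    def test_small_rate_library_rejected(self, cells_noiseless):
        cell = cells_noiseless[3]
        sweeps, anns = self._supra(cell)
        with pytest.raises(InsufficientDataError):
            fit_after_spike_currents(
                sweeps, anns, cell.params.E_L, cell.params.spike_cut, k_library=(100.0,)
            )


class TestSpikeThresholdDynamics:
    def test_recovery_from_triple_sweeps(self, cells_noiseless):
        cell = cells_noiseless[2]
        sweeps = cell.sweeps["triple"]
        anns = [detect_spikes(s) for s in sweeps]
        fs = sweeps[0].fs
        n_ref = round(cell.params.spike_cut * fs)
        fit = fit_spike_threshold_dynamics(sweeps, anns, n_ref / fs)
        assert fit.b_s == pytest.approx(50.0, rel=0.05)
        assert fit.delta_theta_s == pytest.approx(5e-3, rel=0.05)
        assert fit.identifiable

    def test_null_amplitude_flagged_unidentifiable(self):
        cell = make_cell(2, 0.0, seed=5, delta_theta_s=0.0)
        sweeps = cell.sweeps["triple"]
        anns = [detect_spikes(s) for s in sweeps]
        fit = fit_spike_threshold_dynamics(sweeps, anns, cell.params.spike_cut)
        assert abs(fit.delta_theta_s) < 0.5e-3
        assert not fit.identifiable

    def test_two_point_closed_form_oracle(self, cells_noiseless):
        # restricting to single-elevation observations at two intervals, the
        # least-squares fit must match the exact 2-point exponential solve
        cell = cells_noiseless[2]
        sweeps = cell.sweeps["triple"][:2]
        fs = sweeps[0].fs
        n_ref = round(cell.params.spike_cut * fs)
        dt = n_ref / fs
        anns = [detect_spikes(s)[:2] for s in sweeps]  # first two spikes only
        obs = []
        for s, a in zip(sweeps, anns):
            t = np.array([x.spike_index for x in a]) / s.fs
            e = a[1].threshold_voltage - a[0].threshold_voltage
            obs.append((t[1] - t[0] - dt, e))
        (d1, e1), (d2, e2) = obs
        b_closed = np.log(e1 / e2) / (d2 - d1)
        amp_closed = e1 * np.exp(b_closed * d1)
        fit = fit_spike_threshold_dynamics(sweeps, anns, dt)
        assert fit.b_s == pytest.approx(b_closed, rel=1e-3)
        assert fit.delta_theta_s == pytest.approx(amp_closed, rel=1e-3)

    def test_no_subsequent_spikes_rejected(self):
        sweep = Sweep(fs=10_000.0, current=np.zeros(100), voltage=np.full(100, -70e-3))
        with pytest.raises(InsufficientDataError):
            fit_spike_threshold_dynamics([sweep], [[]], 3e-3)


class TestVoltageThresholdDynamics:
    def _supra(self, cell):
        sweeps = [
            s
            for s in cell.sweeps["noise1"]
            if s.meta.get("fraction_of_threshold", 1.0) >= 1.0
        ]
        return sweeps, [detect_spikes(s) for s in sweeps]

    def test_recovery_on_level5_cell(self, cells_noiseless):
        cell = cells_noiseless[5]
        sweeps, anns = self._supra(cell)
        fit = fit_voltage_threshold_dynamics(sweeps, anns, cell.params)
        assert fit.a_v == pytest.approx(10.0, rel=0.10)
        assert fit.b_v == pytest.approx(20.0, rel=0.10)

    def test_null_coupling_recovered_as_zero(self):
        cell = make_cell(5, 0.0, seed=5, a_v=1e-9)
        params = dataclasses.replace(cell.params, a_v=1e-9)
        sweeps, anns = self._supra(cell)
        fit = fit_voltage_threshold_dynamics(sweeps, anns, params)
        assert abs(fit.a_v) < 0.5
        assert not fit.identifiable

    def test_too_few_spikes_rejected(self, cells_noiseless):
        cell = cells_noiseless[5]
        sweeps, anns = self._supra(cell)
        with pytest.raises(InsufficientDataError, match="10"):
            fit_voltage_threshold_dynamics(
                [sweeps[0]], [anns[0][:3]], cell.params
            )


class TestInstantaneousThreshold:
    def test_ladder_recovery(self, cells_noiseless):
        cell = cells_noiseless[1]
        est = fit_instantaneous_threshold_init(cell.sweeps["short_square"])
        assert est == pytest.approx(cell.params.theta_inf, abs=0.3e-3)

    def test_tie_between_equal_amplitudes_averaged(self, cells_noiseless):
        sweeps = cells_noiseless[1].sweeps["short_square"]
        spiking = [s for s in sweeps if s.meta["true_spike_idx"]]
        dup = [spiking[0], spiking[0]]
        est = fit_instantaneous_threshold_init(dup)
        single = fit_instantaneous_threshold_init([spiking[0]])
        assert est == pytest.approx(single)

    def test_all_subthreshold_rejected(self, cells_noiseless):
        sweeps = cells_noiseless[1].sweeps["short_square"]
        quiet = [s for s in sweeps if not s.meta["true_spike_idx"]]
        with pytest.raises(InsufficientDataError):
            fit_instantaneous_threshold_init(quiet)


class TestFitCell:
    def test_missing_triple_named_in_error(self, cells_noiseless):
        sweeps = {k: v for k, v in cells_noiseless[4].sweeps.items() if k != "triple"}
        with pytest.raises(InsufficientDataError, match="triple short square"):
            fit_cell(sweeps, level=4)

    def test_spike_cut_invariant_to_sweep_order(self, cells_noisy):
        cell = cells_noisy[2]
        a = fit_cell(cell.sweeps, 2).params.spike_cut
        flipped = dict(cell.sweeps)
        flipped["noise1"] = list(reversed(cell.sweeps["noise1"]))
        b = fit_cell(flipped, 2).params.spike_cut
        assert a == b
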