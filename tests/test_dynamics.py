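import numpy as np
import pytest

from barrelsim import (
    ModelParams,
    StimulusSpec,
    TCSpikeSet,
    apply_adaptation,
    build_wiring,
    run_condition,
    simulate_trial,
    synaptic_kernel,
)
from barrelsim.dynamics import IntegrationError
from barrelsim.params import ParameterError


class TestSynapticKernel:
    def test_zero_before_onset(self):
        assert synaptic_kernel(4.999, 5.0, amplitude=0.3, decay=0.73) == 0.0
        assert synaptic_kernel(6.999, 5.0, amplitude=0.3, decay=0.73, delay=2.0) == 0.0

    def test_amplitude_at_onset(self):
        assert synaptic_kernel(7.0, 5.0, 0.3, 0.73, delay=2.0) == pytest.approx(0.3)

    def test_e_folding(self):
        alpha = 0.73
        v = synaptic_kernel(5.0 + 1 / alpha, 5.0, 0.3, alpha)
        assert v == pytest.approx(0.3 / np.e)

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            synaptic_kernel(1.0, 0.0, -0.1, 0.5)


class TestAdaptation:
    def test_scales_only_rs_targeting_amplitudes(self, params):
        adapted = apply_adaptation(params)
        assert adapted.amplitude["tc->rs"] == pytest.approx(0.03)
        assert adapted.amplitude["fs->rs"] == pytest.approx(0.004)
        assert adapted.amplitude["tc->fs"] == params.amplitude["tc->fs"]
        assert adapted.amplitude["fs->fs"] == params.amplitude["fs->fs"]
        assert adapted.amplitude["rs->rs"] == params.amplitude["rs->rs"]
        assert adapted.adapted and not params.adapted

    def test_double_application_guarded(self, params):
        with pytest.raises(ParameterError):
            apply_adaptation(apply_adaptation(params))


def _empty_spikes(params, spec=None):
    spec = spec or StimulusSpec(0, 1.0)
    return TCSpikeSet(np.full(params.n_tc, np.nan), spec, seed=0)


class TestSimulateTrial:
    def test_no_input_means_silence(self, wiring, params):
        res = simulate_trial(wiring, params, _empty_spikes(params), record_cells=[0])
        assert not res.fs_spikes and not res.rs_spikes
        rec = res.recorded_currents[0]
        assert (rec["v"] == 0).all()
        assert (rec["tc"] == 0).all() and (rec["fs"] == 0).all()

    def test_single_epsp_matches_closed_form(self, params):
        """One TC spike onto an RS cell: Euler at dt=0.01 ms tracks the exact
        double-exponential V(t) = A/(a-g) (e^{-g t} - e^{-a t}) within 1e-3."""
        quiet = params.replace(amplitude={**params.amplitude, "tc->fs": 0.0})
        wiring = build_wiring(quiet, seed=2)
        cell = 0
        pre = np.flatnonzero(wiring.conn["tc->rs"][:, cell])[0]
        times = np.full(quiet.n_tc, np.nan)
        t0 = 5.0
        times[pre] = t0
        res = simulate_trial(
            wiring, quiet, TCSpikeSet(times, StimulusSpec(0, 1.0), 0), record_cells=[cell]
        )
        v = res.recorded_currents[cell]["v"]
        a, g = quiet.decay["tc->rs"], quiet.g
        A = quiet.amplitude["tc->rs"]
        t = np.arange(len(v)) * quiet.dt_ms
        exact = np.where(t >= t0, A / (a - g) * (np.exp(-g * (t - t0)) - np.exp(-a * (t - t0))), 0.0)
        assert np.max(np.abs(v - exact)) < 1e-3
        t_star = np.log(a / g) / (a - g)
        assert v.max() == pytest.approx(A / (a - g) * (np.exp(-g * t_star) - np.exp(-a * t_star)), abs=1e-3)
        assert v.max() == pytest.approx(0.0659, abs=1e-3)

    def test_constant_current_reaches_steady_state(self, params):
        """With constant drive I and no synapses, V settles at I / g."""
        long = params.replace(trial_duration_ms=200.0)
        wiring = build_wiring(long, seed=2)
        res = simulate_trial(
            wiring, long, _empty_spikes(long), record_cells=[0],
            external_current={"rs": 0.03},
        )
        v = res.recorded_currents[0]["v"]
        assert v[-1] == pytest.approx(0.03 / long.g, rel=1e-3)

    def test_dimension_mismatch_raises(self, wiring, params):
        small = ModelParams(
            n_tc=80, n_tc_groups=8, tc_group_size=10,
            n_rs=80, n_rs_domains=8, rs_domain_size=10,
        )
        with pytest.raises(IntegrationError):
            simulate_trial(wiring, small, _empty_spikes(small))


class TestTrialInvariants:
    def test_refractory_interval(self, fast_trials, params):
        for res in fast_trials:
            for spikes in (res.fs_spikes, res.rs_spikes):
                for times in spikes.values():
                    if len(times) > 1:
                        assert np.diff(times).min() >= params.refractory_ms

    def test_spike_times_within_trial_window(self, fast_trials, params):
        for res in fast_trials:
            for spikes in (res.fs_spikes, res.rs_spikes):
                for times in spikes.values():
                    assert (times >= 0).all()
                    assert (times <= params.trial_duration_ms).all()

    def test_current_sign_conventions(self, wiring, params):
        spec = StimulusSpec(0, 1.0)
        trials = run_condition(
            wiring, params, spec, n_trials=5, base_seed=77, record_cells=[0, 40]
        )
        for res in trials:
            for cell, rec in res.recorded_currents.items():
                assert (rec["tc"] >= 0).all()
                assert (rec["fs"] <= 0).all()
                assert (rec["rs"] >= 0).all()

    def test_inhibition_dominates_excitation_before_adaptation(self, fast_trials, wiring):
        """Aligned domain, sigma=1, unadapted: peak |FS current| exceeds peak
        TC current in RS cells (feedforward inhibition dwarfs excitation)."""
        cells = wiring.rs_cells_in_domain(0)
        peak_e = np.mean([t.peak_tc_current[cells] for t in fast_trials])
        peak_i = np.mean([t.peak_fs_current[cells] for t in fast_trials])
        assert peak_i > peak_e


class TestRunCondition:
    def test_rerun_reproduces_every_spike(self, wiring, params):
        spec = StimulusSpec(45, 1.5)
        a = run_condition(wiring, params, spec, 10, base_seed=5)
        b = run_condition(wiring, params, spec, 10, base_seed=5)
        for ra, rb in zip(a, b):
            assert set(ra.rs_spikes) == set(rb.rs_spikes)
            for c in ra.rs_spikes:
                np.testing.assert_array_equal(ra.rs_spikes[c], rb.rs_spikes[c])
            assert set(ra.fs_spikes) == set(rb.fs_spikes)

    def test_extending_a_run_preserves_earlier_trials(self, wiring, params):
        spec = StimulusSpec(0, 1.0)
        short = run_condition(wiring, params, spec, 5, base_seed=5)
        longer = run_condition(wiring, params, spec, 8, base_seed=5)
        for ra, rb in zip(short, longer):
            assert set(ra.rs_spikes) == set(rb.rs_spikes)

    def test_different_base_seeds_differ(self, wiring, params):
        spec = StimulusSpec(0, 1.0)
        a = run_condition(wiring, params, spec, 3, base_seed=1)
        b = run_condition(wiring, params, spec, 3, base_seed=2)
        assert any(set(ra.rs_spikes) != set(rb.rs_spikes) for ra, rb in zip(a, b))

    def test_singleton_run(self, wiring, params):
        assert len(run_condition(wiring, params, StimulusSpec(0, 1.0), 1, 0)) == 1
        with pytest.raises(ValueError):
            run_condition(wiring, params, StimulusSpec(0, 1.0), 0, 0)

    def test_adaptation_lowers_spike_probability(self, wiring, params):
        """Halving TC->RS drive cuts RS responses despite weaker inhibition."""
        from barrelsim.metrics import domain_spike_probability

        spec = StimulusSpec(0, 1.0)
        pre = run_condition(wiring, params, spec, 60, base_seed=3)
        post = run_condition(wiring, params, spec, 60, base_seed=3, adapted=True)
        assert domain_spike_probability(post, wiring, 0) < domain_spike_probability(
            pre, wiring, 0
        )

    def test_rs_rs_synapses_are_nearly_inert(self, wiring, params):
        """Zeroing the RS->RS amplitude leaves per-cell spike probabilities
        essentially unchanged (paired trials, same TC inputs)."""
        from barrelsim.metrics import spike_probability

        spec = StimulusSpec(0, 1.25)
        base = run_condition(wiring, params, spec, 150, base_seed=9)
        no_rsrs = params.replace(amplitude={**params.amplitude, "rs->rs": 0.0})
        silent = run_condition(wiring, no_rsrs, spec, 150, base_seed=9)
        diffs = [
            abs(spike_probability(base, c) - spike_probability(silent, c))
            for c in range(params.n_rs)
        ]
        assert max(diffs) < 0.02
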