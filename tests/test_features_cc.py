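import numpy as np
import pytest

from sgnpos.features_cc import (
    ahp_tau,
    classify_firing_pattern,
    current_threshold,
    detect_spikes,
    extract_cc_features,
    first_spike_latency,
    resting_potential,
    response_latency_graded,
    SpikeEvent,
)
from sgnpos.simulate import Sweep, simulate_current_clamp

from conftest import cc_protocol, flat_sweep, make_neuron


def spike_template(dt, width_ms=2.0, height=80.0):
    """Stereotyped action-potential waveform (fast rise, slower fall)."""
    n = int(width_ms / dt)
    t = np.arange(n) * dt
    rise = np.exp(-((t - 0.4) / 0.15) ** 2)
    fall = np.exp(-((t - 0.4) / 0.6) ** 2)
    w = np.where(t < 0.4, rise, fall)
    return height * w


def sweep_from_signal(signal, dt=0.1, pre_ms=0.0, step_ms=None):
    n = len(signal)
    step_ms = step_ms if step_ms is not None else n * dt
    proto = cc_protocol([100.0], step_ms=step_ms, pre_ms=pre_ms, post_ms=0.0,
                        sample_rate=1.0 / dt)
    t = np.arange(n) * dt
    return Sweep(time=t, signal=np.asarray(signal, float),
                 stimulus_level=100.0, protocol=proto)


class TestDetectSpikes:
    def test_flat_trace_no_events(self):
        proto = cc_protocol([10.0], step_ms=100.0, pre_ms=0.0, post_ms=0.0)
        assert detect_spikes(flat_sweep(-60.0, proto)) == []

    def test_spliced_templates_found_at_known_times(self):
        dt = 0.1
        sig = np.full(1000, -60.0)
        tpl = spike_template(dt)
        for t_ms in (12.0, 40.0):
            i = int(t_ms / dt)
            sig[i:i + len(tpl)] += tpl
        events = detect_spikes(sweep_from_signal(sig, dt=dt))
        assert len(events) == 2
        peaks = np.array([e.peak_time for e in events])
        # template peak sits 0.4 ms after splice onset
        np.testing.assert_allclose(peaks, [12.4, 40.4], atol=dt + 1e-9)
        for e in events:
            assert e.peak_v > e.threshold_v
            assert e.threshold_time <= e.peak_time

    def test_threshold_matches_finite_difference_oracle(self, base_cfg):
        p = make_neuron(base_cfg, g_ss=30.0)
        fam = simulate_current_clamp(p, cc_protocol([200.0], step_ms=300.0),
                                     cfg=base_cfg)
        sw = fam[0]
        events = detect_spikes(sw)
        assert events
        # independent brute-force pass over the same trace
        dt = sw.dt
        dvdt = np.diff(sw.signal) / dt
        crossing = next(i for i in range(1, len(dvdt))
                        if dvdt[i] >= 10.0 and dvdt[i - 1] < 10.0)
        assert events[0].threshold_v == pytest.approx(sw.signal[crossing])

    def test_small_bumps_rejected_by_min_height(self):
        dt = 0.1
        sig = np.full(500, -60.0)
        sig[100:120] += 10.0 * np.sin(np.linspace(0, np.pi, 20))  # 10 mV bump
        assert detect_spikes(sweep_from_signal(sig, dt=dt)) == []

    def test_nonuniform_sampling_rejected(self):
        proto = cc_protocol([10.0], step_ms=10.0, pre_ms=0.0, post_ms=0.0)
        sw = flat_sweep(-60.0, proto)
        sw.time = sw.time.copy()
        sw.time[5] += 0.03
        with pytest.raises(ValueError):
            detect_spikes(sw)


class TestRestingPotential:
    def test_exact_baseline(self):
        proto = cc_protocol([10.0], step_ms=100.0, pre_ms=50.0, post_ms=0.0)
        fam = [flat_sweep(-57.0, proto)]
        assert resting_potential(fam) == pytest.approx(-57.0)

    def test_mean_across_sweeps(self):
        proto = cc_protocol([10.0], step_ms=100.0, pre_ms=50.0, post_ms=0.0)
        fam = [flat_sweep(-56.0, proto), flat_sweep(-58.0, proto)]
        assert resting_potential(fam) == pytest.approx(-57.0)

    def test_recovers_target_with_noise(self, base_cfg):
        p = make_neuron(base_cfg, v_rest=-56.9, g_ss=25.0)
        fam = simulate_current_clamp(p, cc_protocol([50.0, 100.0], step_ms=200.0),
                                     seed=4, noise_sd_mv=0.2, cfg=base_cfg)
        assert resting_potential(fam) == pytest.approx(-56.9, abs=0.5)

    def test_no_baseline_errors(self):
        proto = cc_protocol([10.0], step_ms=100.0, pre_ms=0.0, post_ms=0.0)
        with pytest.raises(ValueError):
            resting_potential([flat_sweep(-60.0, proto)])


def family_with_spikes(spike_map, step_ms=1000.0, dt=0.1):
    """Families built by splicing templates; spike_map: {amplitude: [times]}."""
    fam = []
    proto = cc_protocol(sorted(spike_map), step_ms=step_ms, pre_ms=20.0,
                        post_ms=20.0, sample_rate=1.0 / dt)
    t = proto.time_axis()
    tpl = spike_template(dt)
    for amp in sorted(spike_map):
        sig = np.full(len(t), -60.0)
        for t_ms in spike_map[amp]:
            i = int((t_ms + 20.0) / dt)
            sig[i:i + len(tpl)] += tpl
        fam.append(Sweep(time=t, signal=sig, stimulus_level=float(amp),
                         protocol=proto))
    return fam


class TestCurrentThreshold:
    def test_first_spiking_amplitude(self):
        fam = family_with_spikes({50.0: [], 100.0: [], 150.0: [30.0], 200.0: [20.0]})
        assert current_threshold(fam) == 150.0

    def test_no_spikes_undefined(self):
        fam = family_with_spikes({50.0: [], 100.0: []})
        assert current_threshold(fam) is None
        feats = extract_cc_features(fam + family_with_spikes({150.0: []}))
        assert feats.spiking is False

    def test_empty_family_errors(self):
        with pytest.raises(ValueError):
            current_threshold([])

    def test_agrees_with_rc_threshold_oracle(self, base_cfg):
        """Passive + sodium toy neuron: measured threshold within one ladder
        increment of I_th = g (V_th - V_r) / (1 - exp(-g T / C))."""
        import dataclasses
        cfg = dataclasses.replace(base_cfg, na_m_k=0.05, na_m_half=-35.0)
        p = make_neuron(cfg, v_rest=-60.0, g_ss=30.0, g_na=200.0, g_leak=2.0)
        p = dataclasses.replace(p, g_max_true=1e-9)  # potassium off
        p = dataclasses.replace(
            p, e_leak=-60.0 - (p.g_na * 0.0) / p.g_leak)  # rest = E_leak
        increment = 2.0
        ladder = cc_protocol(np.arange(4.0, 120.0, increment))
        fam = simulate_current_clamp(p, ladder, cfg=cfg)
        measured = current_threshold(fam)
        assert measured is not None
        # the near-step activation places the spike barrier at -35 mV by
        # construction, so the RC threshold formula is fully analytic
        dv = 25.0
        tau = p.c_m / p.g_leak
        oracle = p.g_leak * dv / (1.0 - np.exp(-ladder.step_ms / tau))
        assert abs(measured - oracle) <= increment + 0.05 * oracle


class TestFirstSpikeLatency:
    def test_reads_peak_time_at_threshold_sweep(self):
        fam = family_with_spikes({100.0: [], 150.0: [22.0], 200.0: [5.0]})
        # template peak offset 0.4 ms after splice
        assert first_spike_latency(fam) == pytest.approx(22.4, abs=0.2)

    def test_graded_neuron_errors(self):
        fam = family_with_spikes({100.0: [], 150.0: []})
        with pytest.raises(ValueError):
            first_spike_latency(fam)

    def test_rc_oracle_latency_at_fixed_overdrive(self, base_cfg):
        """Latency within 5% of t = -tau ln(1 - g dV_th / I) for the
        passive + sodium toy neuron."""
        import dataclasses
        cfg = dataclasses.replace(base_cfg, na_m_k=0.05, na_m_half=-35.0)
        p = make_neuron(cfg, v_rest=-60.0, g_ss=30.0, g_na=200.0, g_leak=2.0)
        p = dataclasses.replace(p, g_max_true=1e-9, e_leak=-60.0)
        dv = 25.0  # barrier at -35 mV by construction (near-step activation)
        current = 1.25 * p.g_leak * dv
        fam = simulate_current_clamp(p, cc_protocol([current]), cfg=cfg)
        lat = first_spike_latency(fam)
        tau = p.c_m / p.g_leak
        oracle = -tau * np.log(1.0 - p.g_leak * dv / current)
        assert lat == pytest.approx(oracle, rel=0.05)

    def test_latency_monotone_in_conductance(self, base_cfg):
        ladder = cc_protocol(40.0 * 1.05 ** np.arange(0, 45))
        lats = []
        for g_ss in (18.0, 30.0, 50.0, 80.0):
            p = make_neuron(base_cfg, g_ss=g_ss)
            fam = simulate_current_clamp(p, ladder, cfg=base_cfg)
            lats.append(first_spike_latency(fam))
        assert all(a > b for a, b in zip(lats, lats[1:]))


class TestAhpTau:
    def make_ahp_sweep(self, tau, v_min=-70.0, amp=10.0, noise=0.0, seed=0,
                      dt=0.1):
        """Spike template followed by an AHP recovering as
        V = v_min + amp (1 - exp(-t/tau))."""
        rng = np.random.default_rng(seed)
        tpl = spike_template(dt)
        t_rec = np.arange(0.0, 400.0, dt)
        recovery = v_min + amp * (1.0 - np.exp(-t_rec / tau))
        pre = np.full(200, -60.0)
        sig = np.concatenate([pre, tpl - 60.0, recovery])
        if noise:
            sig = sig + rng.normal(0, noise, size=len(sig))
        sw = sweep_from_signal(sig, dt=dt, step_ms=len(sig) * dt)
        spike = detect_spikes(sw)[0]
        return sw, spike

    def test_generated_exponential_recovered(self):
        sw, spike = self.make_ahp_sweep(tau=15.0)
        assert ahp_tau(sw, spike) == pytest.approx(15.0, rel=0.01)

    def test_ordering_preserved(self):
        sw5, sp5 = self.make_ahp_sweep(tau=5.0)
        sw25, sp25 = self.make_ahp_sweep(tau=25.0)
        assert ahp_tau(sw5, sp5, max_window_ms=300.0) < ahp_tau(
            sw25, sp25, max_window_ms=300.0)

    def test_noisy_monte_carlo_mean_within_5pct(self):
        taus = [ahp_tau(*self.make_ahp_sweep(tau=20.0, noise=0.5, seed=s),
                        max_window_ms=300.0)
                for s in range(100)]
        assert np.mean(taus) == pytest.approx(20.0, rel=0.05)

    def test_no_minimum_errors(self):
        dt = 0.1
        tpl = spike_template(dt)
        sig = np.concatenate([np.full(100, -60.0), tpl - 60.0,
                              np.linspace(-60.0, -75.0, 2000)])  # keeps falling
        sw = sweep_from_signal(sig, dt=dt, step_ms=len(sig) * dt)
        spike = detect_spikes(sw)[0]
        with pytest.raises(ValueError):
            ahp_tau(sw, spike)


class TestGradedLatency:
    def ramp_family(self, peaks, step_ms=200.0, dt=0.1):
        proto = cc_protocol(np.arange(1, len(peaks) + 1) * 50.0,
                            step_ms=step_ms, pre_ms=20.0, post_ms=10.0,
                            sample_rate=1.0 / dt)
        t = proto.time_axis()
        fam = []
        for amp, peak_ms in zip(proto.amplitudes, peaks):
            ts = t - 20.0
            sig = -60.0 + 10.0 * np.exp(-0.5 * ((ts - peak_ms) / 15.0) ** 2)
            sig[ts < 0] = -60.0
            fam.append(Sweep(time=t, signal=sig, stimulus_level=amp,
                             protocol=proto))
        return fam

    def test_mean_time_to_peak(self):
        res = response_latency_graded(self.ramp_family([30.0, 40.0, 50.0]))
        assert res.latency_ms == pytest.approx(40.0, abs=0.2)
        assert not res.boundary

    def test_monotone_rc_rise_flags_boundary(self, base_cfg):
        # pure-RC neuron: no interior peak, the maximum sits at the step end
        p = make_neuron(base_cfg, g_ss=25.0)
        fam = simulate_current_clamp(p, cc_protocol([40.0, 80.0], step_ms=300.0),
                                     passive=True, cfg=base_cfg)
        assert response_latency_graded(fam).boundary

    def test_larger_conductance_shorter_graded_latency(self, base_cfg):
        proto = cc_protocol([50.0, 100.0, 150.0], step_ms=500.0)
        lats = []
        for g_ss in (15.0, 35.0, 70.0):
            p = make_neuron(base_cfg, v_rest=-51.8, g_ss=g_ss)
            fam = simulate_current_clamp(p, proto, cfg=base_cfg)
            lats.append(response_latency_graded(fam).latency_ms)
        assert all(a > b for a, b in zip(lats, lats[1:]))

    def test_needs_two_depolarizing_sweeps(self):
        with pytest.raises(ValueError):
            response_latency_graded(self.ramp_family([30.0]))


class TestClassifyFiringPattern:
    def test_single_spike_everywhere_is_rapid(self):
        fam = family_with_spikes({100.0: [], 150.0: [15.0], 200.0: [10.0],
                                  250.0: [8.0]})
        assert classify_firing_pattern(fam) == "rapid"

    def test_few_early_spikes_is_intermediate(self):
        fam = family_with_spikes({100.0: [], 150.0: [15.0],
                                  200.0: [10.0, 60.0, 120.0, 180.0]})
        assert classify_firing_pattern(fam) == "intermediate"

    def test_spikes_into_final_fifth_is_slow(self):
        fam = family_with_spikes({100.0: [],
                                  150.0: [100.0, 400.0, 850.0, 950.0]})
        assert classify_firing_pattern(fam) == "slow"

    def test_no_spikes_is_graded(self):
        fam = family_with_spikes({100.0: [], 150.0: []})
        assert classify_firing_pattern(fam) == "graded"


class TestExtractedFeatureInvariants:
    def test_spiking_feature_consistency(self, base_cfg):
        ladder = cc_protocol(np.arange(20.0, 401.0, 20.0))
        for g_ss in (20.0, 45.0, 80.0):
            p = make_neuron(base_cfg, g_ss=g_ss)
            fam = simulate_current_clamp(p, ladder, seed=1, noise_sd_mv=0.2,
                                         cfg=base_cfg)
            f = extract_cc_features(fam)
            assert f.spiking
            assert f.v_threshold > f.resting_potential
            assert f.first_spike_latency < ladder.step_ms
            assert f.i_threshold in ladder.amplitudes
            assert f.response_latency == f.first_spike_latency
            assert f.relative_threshold == pytest.approx(
                f.v_threshold - f.resting_potential)

    def test_response_latency_defined_for_graded(self, base_cfg):
        p = make_neuron(base_cfg, v_rest=-51.0, g_ss=30.0)
        fam = simulate_current_clamp(p, cc_protocol(np.arange(20.0, 301.0, 40.0)),
                                     cfg=base_cfg)
        f = extract_cc_features(fam)
        assert not f.spiking
        assert f.i_threshold is None and f.first_spike_latency is None
        assert f.response_latency is not None and f.response_latency > 0


class TestThresholdLatencyCoupling:
    def test_reciprocal_relation_on_noiseless_population(self, base_cfg):
        """Extracted current thresholds and first-spike latencies are coupled
        reciprocally across a noiseless spiking population (both are readouts
        of the same input conductance); the I = K/latency fit captures most
        of the threshold variance and the coupling is strictly monotone."""
        import dataclasses
        from sgnpos.simulate import SimulationConfig, generate_dataset
        from sgnpos.models import fit_inverse_law
        from scipy.stats import spearmanr

        amps = tuple(20.0 * 1.03 ** np.arange(0, 110))
        proto = cc_protocol(amps)
        cfg = SimulationConfig(
            n_neurons=25, seed=4, graded_fraction=0.0,
            trace_noise_cc_mv=0.0, trace_noise_vc_pa=0.0,
            gmax_cv_total=0.0, gmax_cv_floor=0.0, tau_cv=0.0,
            gleak_cv=0.0, v_rest_sd=0.0, v_half_sd=0.0, slope_k_sd=0.0)
        recs = generate_dataset(cfg, cc_protocol=proto)
        iths, lats = [], []
        for r in recs:
            f = extract_cc_features(r.cc_family)
            if f.spiking:
                iths.append(f.i_threshold)
                lats.append(f.first_spike_latency)
        iths, lats = np.array(iths), np.array(lats)
        assert len(iths) >= 20
        fit = fit_inverse_law(lats, iths)
        assert fit.constant > 0
        assert fit.fit_r2 > 0.8
        rho, _ = spearmanr(iths, lats)
        assert rho < -0.95
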