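"""Simulate one neuron's current- and voltage-clamp families and extract the
standard patch-clamp feature set.

The current-clamp family (1000 ms current steps) yields the firing pattern,
current threshold, first-spike latency and resting potential; the
voltage-clamp family (400 ms steps, -120 to +70 mV) yields the Boltzmann
conductance features g_max, g_-30, V_1/2 and the inactivation constant
tau_inact.
"""

from sgnpos import (
    SimulationConfig,
    default_cc_protocol,
    default_vc_protocol,
    extract_cc_features,
    extract_vc_features,
    sample_population,
    simulate_current_clamp,
    simulate_voltage_clamp,
)

cfg = SimulationConfig(n_neurons=1, seed=3)
neuron = sample_population(cfg)[0]
print(f"ground truth: g_ss = {neuron.g_ss_true:.1f} nS, "
      f"tau_inact = {neuron.tau_inact_true:.0f} ms, "
      f"rest target = {neuron.v_rest_target:.1f} mV")

cc = simulate_current_clamp(neuron, default_cc_protocol(), seed=1,
                            noise_sd_mv=cfg.trace_noise_cc_mv, cfg=cfg)
vc = simulate_voltage_clamp(neuron, default_vc_protocol(), seed=2,
                            noise_sd_pa=cfg.trace_noise_vc_pa, cfg=cfg)

f = extract_cc_features(cc)
print(f"\ncurrent clamp: pattern = {f.firing_pattern}, "
      f"rest = {f.resting_potential:.1f} mV")
if f.spiking:
    print(f"  I_threshold = {f.i_threshold:.0f} pA, "
          f"first-spike latency = {f.first_spike_latency:.1f} ms, "
          f"V_threshold = {f.v_threshold:.1f} mV")
else:
    print(f"  graded response latency = {f.response_latency:.1f} ms")

row = extract_vc_features(vc, e_k=neuron.e_k)
print(f"\nvoltage clamp: g_max = {row['g_max']:.1f} nS "
      f"(truth {neuron.g_ss_true:.1f}), g_-30 = {row['g_minus30']:.1f} nS, "
      f"V_1/2 = {row['v_half']:.1f} mV, tau_inact = {row['tau_inact']:.0f} ms")
print("The fitted steady-state ceiling recovers the generating conductance; "
      "larger values mean a less excitable, higher-threshold neuron.")
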