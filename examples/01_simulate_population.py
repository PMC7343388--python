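"""Generate a small synthetic SGN population and look at its ground truth.

Each neuron gets a synaptic contact position (NBP), an age, and a set of
biophysical parameters in which the steady-state K conductance grows with
both position (pillar -> modiolar) and age along the configured face lines.
"""

import numpy as np

from sgnpos import SimulationConfig, sample_population

cfg = SimulationConfig(n_neurons=12, seed=42)
population = sample_population(cfg)

print(f"{'nbp':>6} {'age':>4} {'g_ss (nS)':>10} {'tau_inact (ms)':>15} "
      f"{'v_rest (mV)':>12} {'phenotype':>10}")
for p in population:
    phenotype = "spiking" if p.v_rest_target < -54.5 else "graded"
    print(f"{p.nbp_true:+6.2f} {p.age:4d} {p.g_ss_true:10.1f} "
          f"{p.tau_inact_true:15.0f} {p.v_rest_target:12.1f} {phenotype:>10}")

# the gradient is easier to see at population scale
big = sample_population(SimulationConfig(n_neurons=300, seed=42))
g = np.array([p.g_ss_true for p in big])
nbp = np.array([p.nbp_true for p in big])
print(f"\ncorr(g_ss, NBP) at n = 300: {np.corrcoef(g, nbp)[0, 1]:+.2f}  "
      "(modiolar-contacting neurons carry more K conductance)")
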