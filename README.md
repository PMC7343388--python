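# sgnpos

Biophysics-based prediction of synaptic contact position for neonatal
spiral ganglion neurons (SGN).

Type I SGN — the afferents that carry sound information from inner hair
cells to the brainstem — differ systematically depending on *where* on the
hair cell their fiber terminates: fibers on the modiolar face correspond to
the high-threshold, low-spontaneous-rate group in vivo, fibers on the
pillar face to the low-threshold, high-spontaneous-rate group. In
early post-natal development the neurons' intrinsic electrophysiology
(current threshold, first-spike latency, whole-cell K conductance,
inactivation kinetics) forms a spatial gradient along the same axis, strong
enough that contact position can be predicted from patch-clamp measurements
alone. `sgnpos` implements that entire analysis as a reusable, tested
library:

* **`sgnpos.simulate`** — a single-compartment conductance-based SGN
  simulator and population generator with position- and age-dependent K
  conductance, producing raw current-clamp (1000 ms current steps) and
  voltage-clamp (400 ms steps, −120…+70 mV) sweep families with ground
  truth attached;
* **`sgnpos.features_cc` / `sgnpos.features_vc`** — extraction of the
  standard features: firing pattern, current/voltage threshold, first-spike
  and graded response latency, AHP time constant, resting potential;
  steady-state conductance curves with Boltzmann fits (g_max, g_−30,
  V_1/2), and the +70 mV inactivation constant τ_inact;
* **`sgnpos.morphometry`** — the normalized basal position metric,
  NBP = ±c/L (positive modiolar, negative pillar, most extreme contact);
* **`sgnpos.models`** — the position-prediction models
  (ŷ = β₀ + Σ βᵢxᵢ, variables screened by Pearson correlation with NBP,
  pruned by variance inflation factor VIF = 1/(1−R²ₙ) > 4, then backward-
  stepped on adjusted R²), the reciprocal law y = K/x, and the face-binned
  conductance-vs-age lines with the constrained intersection and their
  inversion into developmental latency curves L = K/g(age);
* **`sgnpos.stats`** — Pearson r with df reporting, Welch's ANOVA,
  two-way ANCOVA (Type III), Welch's t, coefficient of variation;
* **`sgnpos.io_tables` / `sgnpos.pipeline` / `sgnpos.cli`** — feature-table
  CSV I/O (including a dialect for deposited per-figure spreadsheets), the
  end-to-end pipeline, and a thin `sgnpos` command-line driver
  (`simulate`, `extract`, `model`, `report`, `run`, `reproduce-paper`).

The science, model assumptions and numerical choices are documented in
[`docs/methods.md`](docs/methods.md); short narrative scripts live in
[`examples/`](examples/). The whole pipeline also runs from the shell:

```bash
sgnpos run examples/pipeline_config.yaml --output-dir demo_run
```

which writes `features.csv`, the fitted model JSONs, `models.csv`,
`correlations.csv`, `ancova.csv` and a `run.json` embedding the seed and
configuration hash (re-running reproduces every artifact byte for byte).

## Worked example

```python
from sgnpos import SimulationConfig, generate_dataset, extract_features, build_position_model

cfg = SimulationConfig(n_neurons=100, seed=0)      # defaults = study conditions
features = extract_features(generate_dataset(cfg))
model = build_position_model(features, subset="spiking_only", age_range=(3, 10))
print(model.variables, round(model.adj_r2, 2), round(model.rmse, 3))
```

Running `python examples/04_age_gradients.py` fits the face-binned
conductance lines on such a population and prints

```
modiolar face: g_max = 4.73 * age + 10.7   (generating line: 4.93 * age + 10)
pillar face:   g_max = 2.08 * age + 10.7   (generating line: 2.29 * age + 10)
lines intersect at P0.0 (constrained to [P0, P3])

predicted latency L = 420 / g_max(age), ms:
 age  modiolar   pillar
   2      20.8     28.3
   6      10.7     18.1
  10       7.2     13.3
  14       5.5     10.5
```

meaning: the fitted slopes recover the generating spatial gradient to within
sampling error, and inverting the lines through L = K/g gives the
developmental latency curves — pillar-contacting neurons keep longer
first-spike latencies at every age (≈13 ms at P10 versus ≈7 ms on the
modiolar face), the same maturation trajectory delayed by roughly six days.
`python examples/03_position_model.py` builds the prediction models on the
same population; its spiking-subset model (g_−30, V_1/2, τ_inact) prints
adjusted R² = 0.80 with RMSE = 0.092 — position recovered to about a tenth
of the hair-cell length.

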