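# Methods

`sgnpos` links the biophysics of neonatal type I spiral ganglion neurons
(SGN) to where their peripheral fibers contact inner hair cells. It has four
parts: a synthetic-recording generator that serves as a test bed with known
ground truth; feature extraction from current- and voltage-clamp sweep
families; the normalized-basal-position (NBP) contact metric; and the
statistical machinery (screening, VIF pruning, backward-stepped regression,
reciprocal-law and constrained age-gradient fits) that predicts NBP from the
extracted features. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## The position metric

A hair cell of length `L` is bisected from basal pole to cuticular plate;
a contact at distance `c` from the pole gets `NBP = ±c/L`, positive on the
modiolar face, negative on the pillar face. With several contacts the most
extreme `|c/L|` counts, ties broken toward modiolar. The binary face class
is `modiolar iff NBP >= 0` (the inclusive rule, consistent with the
tie-break). NBP is dimensionless, in [-1, 1], and invariant under joint
rescaling of `c` and `L`.

## The neuron model

Each synthetic neuron is a single isopotential compartment:

    C dV/dt = -g_L (V - E_L) - g_K n w (V - E_K) - g_Na m h (V - E_Na) + I_inj

* **Potassium.** Activation is a Boltzmann `B(V) = 1/(1+exp(-(V-V1/2)/k))`
  tracked by the gate `n` with a short lag (`k_act_tau`, 1.5 ms by default;
  the lag is what produces the early depolarization peak of graded cells).
  Slow inactivation `w` relaxes toward `1 - (1-floor) B(V)` with time
  constant `tau_inact`, so no inactivation develops at rest while a strong
  depolarization decays from 1 toward `floor`. Under voltage clamp this
  reduces to the closed form `g_K(V,t) = g_max B(V) h(t)` with
  `h(t) = floor + (1-floor) exp(-t/tau_inact)`, which is how the
  voltage-clamp families are generated (no ODE needed when V is clamped).
* **Sodium.** Transient, two gates: fast activation `m` (midpoint -28 mV,
  slope 4 mV, tau 0.1 ms) and slower inactivation `h` (midpoint -57 mV,
  slope 1.2 mV, tau 150 ms). The steep, hyperpolarized `h` curve is placed
  between the two resting-potential modes so that a cell resting near
  -57 mV spikes while one resting near -52 mV has essentially no available
  sodium and responds with graded depolarizations; holding such a cell at
  -80 mV before the step (`prehold_mv=-80`) restores its spike.
* **Leak.** `E_L` is solved per neuron so the full model rests exactly at
  the drawn resting potential (residual K and Na window currents are
  cancelled through the leak battery). With `passive=True` every
  voltage-gated conductance is zeroed and the cell starts at `E_L`; the
  response is then the RC closed form `V_r + (I/g_L)(1 - e^{-g_L t / C})`,
  which the integrator matches to < 0.1 mV (an accuracy oracle, not a
  tautology: fixed-step Heun at `dt_ms = 0.02`, recorded at the protocol
  sample rate).

### Units and scales

Internally everything is mV / ms / nS / pA / pF, a consistent system
(pA = nS·mV, pF·mV/ms = pA). Conductance magnitudes are kept on the scale
the feature tables print (tens of nS); the effective capacitance default is
55 pF — larger than an isolated soma, standing in for soma plus attached
neurite in the semi-intact configuration — chosen so first-spike latencies
land on the observed 5–40 ms scale with the latency–conductance product
near the reference constant K = 420.

### Channel-density coupling

The leak and sodium conductances scale with the K ceiling
(`g_L = 0.06 g_ss`, `g_Na = 60 g_L`). This overall channel-density scaling
is what makes current threshold roughly proportional, and first-spike
latency roughly reciprocal, in conductance — the empirical coupling
`I_thresh ∝ 1/latency` that drives the collinearity handling in the models.
Two limits of this design are worth knowing:

* The reciprocal law is not exact over arbitrarily wide conductance ranges:
  gate time constants do not scale with channel density, so the law holds to
  better than 10% only over roughly a three-fold range (about the span of a
  young-age population); over the full 12–90 nS range the latency-
  conductance product drifts by ~25%.
* A deep inactivation floor would make the Boltzmann ceiling strongly
  tau-dependent (`g_max = g_ss/h(400)`), which injects an inverted
  tau-mediated position signal into thresholds. The default floor of 0.7
  (mild inactivation, "nearly steady" outward current) keeps `h(400)` in a
  narrow band and the threshold gradient clean.

## The synthetic population

`SimulationConfig` defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `nbp_mean`, `nbp_sd`, `nbp_bounds` | 0.11, 0.23, (-0.6, 0.6) | truncated-normal contact-position distribution |
| `gmax_slope/intercept_modiolar` | 4.93, 10 | modiolar-face steady-state conductance line (nS/day, nS) |
| `gmax_slope/intercept_pillar` | 2.29, 10 | pillar-face line; both lines meet at age 0 |
| `latency_constant` | 420 | reference K in L = K/g |
| `graded_fraction` | 0.4 | share of neurons drawn from the depolarized resting mode |
| `v_rest_spiking/graded` | -56.9 / -51.8 mV | resting-potential mixture means (SD 1.0) |
| `tau_inact_base`, `tau_inact_nbp_slope` | 220, 180 ms | K inactivation constant, increasing toward the modiolar face |
| `gmax_cv_total` | 0.42 | target total conductance CV per age bin |
| `trace_noise_cc_mv`, `trace_noise_vc_pa` | 0.2, 5 | additive recording noise |

Position enters the conductance through a bounded logistic response
(width 0.10 NBP units) interpolating between the pillar and modiolar age
lines. The response is affinely renormalized so that its conditional mean is
exactly 0 on the pillar face and 1 on the modiolar face: the two printed
lines are *face-binned group fits*, and this construction makes a generated
population's face-binned regression centered on them by design, while the
response still rises monotonically across the NBP axis and flattens toward
the observed position extremes.

Dispersion is multiplicative (unit-mean lognormal). Because the face lines
diverge with age, the position-driven share of the conductance variance
grows; the noise CV is therefore budgeted per canonical age bin
(P1–5, P6–9, P10–16, including the within-bin age mix) so that the total
bin-level CV stays flat at `gmax_cv_total` — the age-invariant relative
dispersion that motivates comparing age bins at all. A consequence worth
stating: the correlation between conductance and age in these populations
(~0.7) is tighter than in real recordings; the generator prioritizes the
position-correlation structure and the recoverability of the gradient lines
over matching every marginal statistic simultaneously.

What the generator does *not* emulate: synaptic (EPSC) input, multi-
compartment/dendritic effects, series-resistance and junction-potential
artifacts, channel diversity beyond one K and one Na conductance, and any
type II biophysical phenotype (type II is a label only, excluded from
models). Passing recovery tests on these populations therefore shows that
the estimators are correct and well-calibrated for data with this
covariance structure — not that real recordings satisfy the model.

## Feature extraction

* **Spikes**: an upward dV/dt crossing of 10 mV/ms whose following peak
  rises at least 20 mV above the crossing voltage; the crossing voltage is
  the operational voltage threshold. Both constants are keyword arguments.
* **Current threshold**: smallest ladder amplitude whose sweep spikes;
  undefined (None) for graded cells.
* **First-spike latency**: peak time of the first spike in the threshold
  sweep itself (not threshold plus an increment), from step onset.
* **AHP tau**: single exponential from the after-hyperpolarization minimum
  to the post-AHP plateau, truncated at the next spike threshold and capped
  at 100 ms so slow K inactivation does not contaminate the recovery fit.
  The fit can legitimately fail (no AHP minimum) and is then reported
  missing, like any other per-cell fit failure.
* **Graded response latency**: mean time-to-peak of the depolarization over
  depolarizing sweeps. A peak on the final 2% of the step window raises the
  `boundary` flag (a monotone, RC-like rise has no meaningful peak); the
  value is still reported so every neuron carries a response latency, and
  the flag marks it as degenerate.
* **Firing pattern**: graded (no spikes) / rapid (exactly one spike on every
  suprathreshold sweep) / slow (spikes within the final 20% of the step on
  the maximal sweep) / intermediate (everything else). The 20% tail is a
  declared constant.
* **Steady-state current**: mean over 380–400 ms after step onset.
* **Conductance curve**: `g(V) = I_ss/(V - E_K)` after subtracting a leak
  line estimated on the hyperpolarized limb (-120 to -90 mV, where
  voltage-gated K is closed; toggleable). Voltages within ±5 mV of E_K are
  excluded (driving-force singularity); negative quotients are floored at
  zero with a flag. E_K defaults to -85 mV, the Nernst potential for 165 mM
  internal / 5.8 mM bath potassium at room temperature, and is a parameter.
* **Boltzmann fit**: least squares for (g_max, V_1/2, k); the curve counts
  as saturated only if `V_1/2 + 2k` lies inside the command range *and* the
  fitted ceiling is at most 1.25 x the largest measured conductance.
  Unsaturated cells keep their row with `vc_excluded` set and missing
  conductance features — exclusions are bookkept, never silently dropped.
  `g_-30` is evaluated from the fitted curve (not read off the raw point).
* **tau_inact**: single exponential (with offset) from the outward-current
  peak to the end of the +70 mV step, skipping the first 5 ms (fast inward
  transient). Excluded when R^2 < 0.8 or tau exceeds the step duration.

## Model building

Candidates are screened by two-sided Pearson correlation with NBP at
p < 0.05 (pairwise-complete); for pooled (spiking + non-spiking) subsets the
candidate set is restricted to features measurable without a spike, with
response latency standing in for current threshold. Screening is followed by
iterative VIF pruning at the 4.0 cutoff (`VIF = 1/(1-R_n^2)` from regressing
each predictor on the rest), then backward stepping on adjusted R^2 with
RMSE as tie-break, stopping when no single removal improves the objective;
rows with any missing retained feature are deleted list-wise. Because
current threshold and response latency are reciprocal readouts of the same
input conductance, no final model may carry both: if pruning leaves the
pair, the one less correlated with NBP is eliminated. RMSE uses residual
degrees of freedom, `sqrt(SSE/(n-p-1))`; `rmse_population=True` switches to
`sqrt(SSE/n)` (the two conventions differ by ~2% at these sample sizes).

The face-binned conductance-vs-age lines are fit jointly by weighted least
squares (weights `1/fitted^2`, appropriate for constant-CV multiplicative
dispersion) under the constraint that the two lines intersect at an age in
[0, 3], scanned on a 0.1-day grid; the candidate with minimal weighted SSE
wins. Constraining the pillar fit through the jointly estimated intersection
stabilizes its slope, which is otherwise poorly determined from the smaller
pillar sample. Inverting the fitted lines through `L = K/g(age)` gives the
developmental latency curves; with the reference parameters
(2.29·10 + 10 = 32.9 nS at P10, K = 420) the pillar latency at P10 is
420/32.9 = 12.77 ≈ 13 ms.

The reciprocal fit `y = K/x` is closed-form least squares,
`K = Σ(y/x) / Σ(1/x^2)`.

## Statistics

Pearson r is reported with `df = n - 2`. Welch's heteroscedastic ANOVA is
implemented in closed form (and cross-checked against an independent
implementation in the tests). The two-way ANCOVA (class, continuous
covariate, interaction) uses Type III sums of squares with sum-to-zero
contrasts — each term assessed against the full interaction model. The
coefficient of variation is the sample SD (ddof = 1) over the mean. All
tests are two-sided at alpha = 0.05.

## Reproducibility and problem sizes

Every random draw flows from a single integer seed through
`numpy.random.default_rng`; identical configurations give bit-identical
recordings, and pipeline artifacts embed the seed and a configuration hash.
The recovery analyses in the test suite and the acceptance script use a
population of 100 neurons (the scale at which the face-line slopes, the
held-out position model and the dispersion flatness are all measurable),
200-replicate Monte Carlo loops for fitter calibration, and 100 random
instances for the algebraic oracles. Current-clamp integration is batched
across the population; a 100-neuron dataset simulates in well under a
minute on one core.

## Known limitations

* The latency law and threshold proportionality degrade outside a ~3x
  conductance range (gate kinetics do not scale with channel density).
* AHP time constants are frequently unavailable in simulated spiking cells
  (the model's fast activation gate produces little undershoot), so the AHP
  feature rarely survives screening on synthetic populations even though the
  extractor itself is calibrated on constructed traces.
* Graded cells with very small conductance rise monotonically (boundary-
  flagged response latency) instead of showing an interior peak.
* Face-line slope recovery at n = 100 carries appreciable sampling
  variance (the pillar group is ~30 cells); recovered slopes should be read
  with that in mind.
* The deposited-spreadsheet dialect needs a user-supplied column map; the
  deposited files' internal naming is not standardized.
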