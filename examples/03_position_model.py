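"""Predict synaptic contact position from biophysics.

Generates a full population, extracts per-neuron features, and runs the
model-building procedure: screen features by their correlation with
normalized basal position (NBP), prune collinear ones by variance inflation
factor, then backward-step to the smallest model with the best adjusted R^2.
"""

from sgnpos import SimulationConfig, build_position_model, extract_features, generate_dataset
from sgnpos.pipeline import correlation_report

cfg = SimulationConfig(n_neurons=100, seed=0)
features = extract_features(generate_dataset(cfg))

print("per-feature correlations with NBP:")
print(correlation_report(features).round(3).to_string(index=False))

for subset in ("spiking_only", "pooled"):
    model = build_position_model(features, subset=subset, age_range=(3, 10))
    terms = ", ".join(f"{b:+.4f}*{v}" for v, b in zip(model.variables, model.beta))
    print(f"\n{subset} model (P3-P10, n = {model.n}):")
    print(f"  NBP ~ {model.beta0:+.3f} {terms}")
    print(f"  adjusted R^2 = {model.adj_r2:.2f}, RMSE = {model.rmse:.3f} "
          "(RMSE is in NBP units: ~fraction of the hair-cell length)")
    print(f"  screened in: {model.selection['screened_in']}")
    print(f"  removed as collinear: {model.selection['vif_removed']}")
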