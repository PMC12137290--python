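"""Explain the hybrid model globally and locally.

Permutation importance ranks features by how much shuffling them inflates
prediction error; the direction column gives the sign of each feature's
association with the prediction.  A local sparse-linear surrogate explains
one record.  On the default synthetic data the generator's planted signs
must come back: total biomass strongly positive, iron negative.
"""

import warnings

from fohem.core import FOHEMConfig, fohem_fit, numeric_model_fn
from fohem.ga import GAConfig
from fohem.interpret import local_surrogate, permutation_importance
from fohem.synthetic import default_config, generate

data = generate(default_config(seed=42))
model = fohem_fit(
    data,
    FOHEMConfig(
        seed=7, evaluator="ridge", n_trees=80,
        feature_ga=GAConfig(population_size=20, max_generations=12, patience=5, seed=8),
    ),
)
fn = numeric_model_fn(model, data)

report = permutation_importance(fn, data.X, data.y, repeats=5, seed=0)
print("top global features (importance = MSE increase when permuted):")
print(report.to_frame().head(6).round(4).to_string(index=False))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    local = local_surrogate(fn, data.X.iloc[0].to_numpy(), data.X.to_numpy(),
                            n_perturb=400, sparsity_k=5, seed=1)
top = sorted(zip(local.features, local.contributions), key=lambda t: -abs(t[1]))[:5]
print("\nlocal surrogate for record 0 (slope per feature unit):")
for name, coef in top:
    print(f"  {data.feature_names[int(name[1:])] if name.startswith('x') else name}: {coef:+.4f}")
print(f"surrogate fidelity R^2: {local.fidelity_r2:.3f}")
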