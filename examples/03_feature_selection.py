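"""GA feature selection on data with a planted answer.

Five informative features carry a linear yield signal; fifteen are pure
noise.  The binary-mask GA, scored by cross-validated ridge R^2 minus a
parsimony penalty, should return (most of) the informative set.
"""

from fohem.features import ga_select_features, make_ridge_cv_evaluator
from fohem.ga import GAConfig
from fohem.synthetic import FeatureSpec, default_config, generate

schema = [
    FeatureSpec(f"info_{i}", "soil", 0.0, 10.0, e)
    for i, e in enumerate([0.9, 0.7, 0.6, 0.5, 0.4])
] + [
    FeatureSpec(f"noise_{i}", "soil", 0.0, 10.0, 0.0, noise_only=True)
    for i in range(15)
]
data = generate(default_config(seed=10, features=tuple(schema), noise_sd=0.1, n_records=200))

result = ga_select_features(
    data,
    GAConfig(population_size=30, max_generations=20, patience=8, seed=0),
    evaluator=make_ridge_cv_evaluator(data, seed=0),
)

selected = set(result.mask.selected)
print(f"selected {len(selected)} of {len(schema)} features: {sorted(selected)}")
print(f"informative recovered: {len(selected & {f'info_{i}' for i in range(5)})}/5")
print(f"cross-validated R^2 of the final mask: {result.cv_score:.3f}")
# The fitness history is monotone (elitism); the parsimony penalty prunes
# noise features that add nothing to the CV score.
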