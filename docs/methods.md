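# Methods

## The model

`fohem` predicts plot-season yield Ŷ (t/ha) as a convex combination of two
components, Ŷ = w_fis·Y_FIS + w_ens·Y_ens with w_fis + w_ens = 1. The
general N-component form Ŷ = Σ w_i f_i(X) is implemented once
(`core.weighted_combine`); the two-component blend is its N = 2 case.

**Fuzzy component.** A Mamdani system over 2–4 input variables. Triangular
membership functions are parameterized by feet a, c and peak b; boundary
sets are *shouldered* (membership saturates at 1 beyond the peak) so
extreme inputs keep full membership. Rule antecedents are AND-combined —
min by default, product selectable, since both t-norms are standard and the
source material is ambiguous between them. Implication clips each
consequent set at the rule's strength; aggregation is pointwise max over
the output universe discretized at `resolution` points (default 1000);
defuzzification is the centroid Σxᵢμᵢ/Σμᵢ. The expert yield variable uses
three bands on a 0–10 t/ha universe: low (left-shouldered, foot 7.5),
medium (7.5–9, peak 8.25), high (9–10, right-shouldered). Expert
breakpoints are built in for total biomass (low 0–10, medium 5–20, high
15–20 t, with the overlapping printed ranges realized as peak-at-midpoint
triangles) and maize residue biomass (low 0–4000, high 6000–10000 kg/ha);
any other selected feature gets tertile-style sets over its range. The rule
grid maps each combination of input levels to the output band nearest the
mean input level (all-high → high, all-low → low, mixed → medium). Records
that fire no rule receive the universe midpoint with a warning rather than
an exception, so batch prediction is total.

**Ensemble component.** Random forest and gradient boosting with native
categorical handling are delegated to scikit-learn
(`RandomForestRegressor`, `HistGradientBoostingRegressor`); the extreme
learning machine is implemented here: inputs standardized, hidden weights
and biases drawn once from Uniform(−1,1) with a fixed seed, and the linear
read-out solved in closed form from the ridge normal equations with an
unpenalized intercept (handled by centering). ELM defaults: 100 hidden
units, sigmoid activation, λ = 1e−3. The stacker regresses y on the
learners' out-of-fold predictions (5 folds) by non-negative least squares
with a free intercept — the simplest leak-free combiner that can only
up-weight learners; it can never do worse in-sample than its best base
column.

**Genetic algorithm.** One engine serves all three loops: binary or
bounded-real chromosomes, tournament selection (size 3, drawn with
replacement, ties to the lowest index), one-point crossover for binary and
arithmetic blending for real genes, per-gene mutation (bit flip / Gaussian
perturbation with sd = 0.1·range, clipped to bounds), elitism (1 elite
default, making best fitness monotone), and dual stopping: a hard cap of
50 generations plus early stop after 10 stagnant generations. Default
rates: population 100, crossover 0.8, mutation 0.02. Fitness is always
maximized; error-minimizing callers pass the negation.

**Feature selection and engineering** run sequentially. Selection evolves
a binary inclusion mask; fitness is a 3-fold cross-validated R² minus a
parsimony penalty λ·(included/total), λ = 0.05. All-zero masks are
repaired by activating one random gene. Two evaluator backbones are
provided: a fast tree ensemble (ExtraTrees, the default) and a
standardized ridge regression — orders of magnitude faster and blind to
nonlinearity it is not handed explicitly, which makes it the sharper
instrument for judging engineered transformations. Engineering evolves a
second mask over a finite candidate pool: squares and log1p (non-negative
features only) of the top-k = 8 features by |correlation with yield|, plus
their pairwise products (pool ≤ 2k + C(k,2) = 44). A strict retention rule
discards the engineered set unless it scores at least as well as the base
mask alone.

**Weight optimization.** A real-coded GA with one gene per
treatment×location group plus a global gene (bounds [0,1]; w_fis = gene)
maximizes negative validation MSE of the blend. The 1-D problem has the
closed form w* = clamp(⟨y−y_ens, y_fis−y_ens⟩/‖y_fis−y_ens‖², 0, 1), which
serves as the independent oracle in tests; the GA must land within 0.02 of
it. Groups with fewer than 2 validation records are merged into the global
key; if nothing constrains the global gene it is pinned to the closed-form
global optimum. Per-group mode engages automatically only when every group
has ≥ 10 validation records (with a 225-record dataset and a 20%
validation split it does not, avoiding 8 weights fitted to ~45 rows).

**Pipeline** (`fohem_fit`): stratified 80/20 fit/validation split → GA
selection → GA engineering → FIS over the 2–4 selected features most
correlated with yield → stacked ensemble on the engineered design → GA
weights on the validation part → ensemble refit on all records. Stage
failures propagate with the stage name prefixed; all seeds derive from one
config seed by fixed offsets.

## Synthetic data

The generator emulates a two-site maize–soybean strip-intercropping trial:
225 records, 26 numeric features (soil, crop, management groups) plus
treatment ∈ {SS, SM, 2M2S, 2M3S} and location ∈ {Khairpur, Bahawalpur}.
Features are uniform on expert ranges; yield is

    base (6.0) + treatment effect + location effect + Σ effect_j·z_j + N(0, 0.25),

clipped at 0, with z_j the feature standardized to [−1,1]. Treatment
effects (SM +1.2, 2M3S +0.5, 2M2S +0.45, SS −1.2 t/ha) and location
effects (Khairpur +0.4, Bahawalpur −0.4) reproduce the qualitative
orderings of the emulated study: maize-dominant treatments out-yield sole
soybean and Khairpur out-yields Bahawalpur. Effect signs plant the ground
truth the interpretability tests recover (total_biomass +0.8,
M_residue_biomass +0.35, PMC +0.25, soil_pH +0.15 positive; iron −0.3,
clay −0.2 negative); several features are flagged `noise_only` so
selection tests have an exact answer.

What the generator does **not** emulate: multi-year panel structure
(seasons are independent records), weather time series, feature
correlations (features are drawn independently), and any nonlinearity in
the yield signal beyond what tests plant explicitly. Passing tests
therefore demonstrate that the machinery recovers known structure under
clean conditions, not that the model is accurate on real field data.

## Interpretability

Permutation importance reports the mean MSE increase over seeded column
permutations, with a `direction` column (correlation between feature and
prediction) carrying the sign. Sampling Shapley values average marginal
contributions over random feature orderings with background-row
imputation; per construction each sample telescopes, so contributions sum
to f(x) − mean f(background) up to the Monte-Carlo error on the background
mean. The local surrogate perturbs one instance with Gaussian noise
(per-feature sd from the data), weights samples by exp(−d²/w²) with
kernel width w = 0.75·√d on sd-scaled coordinates, screens to the
`sparsity_k` = 8 features with the largest weighted correlation, and fits
a weighted ridge with a tiny (1e−8) penalty used purely for numerical
stability. Zero-variance features are held fixed and get zero
contribution. Reports export to CSV.

## Numerical and design choices

- Centroid defuzzification at resolution 1000; doubling the resolution
  moves the crisp output by well under 0.5% of the universe span, and the
  engine agrees with an independent 10⁴-point brute-force Mamdani
  implementation to 1e−3·span.
- Tournament draws are with replacement, so for k = 2 over fitnesses
  (1,2,3) the selection probabilities are exactly (5/9, 3/9, 1/9) — used
  as a distributional test.
- Metrics follow the standard conventions: R² = 1 − SS_res/SS_tot about
  the mean of y_true, per CV fold using the test-fold mean; R² is
  reported missing (with a warning) for zero-variance or singleton
  targets. RMSE² = MSE and MAE ≤ RMSE hold identically.
- CSV is the interchange format throughout (RFC-4180, header row, 17
  significant digits, so numeric round trips are exact to ≥ 12 digits);
  the FIS serializes to YAML so rule bases are diffable; fitted sklearn
  learners inside a model bundle use joblib.
- Default problem sizes are desk-scale choices: `fohem_fit` uses a reduced
  GA (population 24, ≤ 14 generations) for the two feature loops —
  the engine's own defaults remain population 100 / 50 generations —
  and the acceptance script runs its 5-fold pipeline CV with the ridge
  evaluator and 60-tree forests. All are configurable.

## Known limitations

- The expert FIS is deliberately coarse (three bands per variable). On
  clean synthetic data the GA typically assigns it little or no blend
  weight; its value lies in interpretable categories and in regimes where
  the data-driven component is unreliable, neither of which the clean
  generator exercises. The blend's non-degradation property (never worse
  than the better component on validation) is what the tests guarantee.
- Feature engineering searches a finite candidate pool, not open-ended
  expression space.
- Membership function breakpoints are fixed by the expert design; they are
  not themselves optimized.
- Per-group weights need ≥ 10 validation records per group to engage; with
  small datasets the model silently falls back to one global weight pair.
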