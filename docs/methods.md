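# Methods

This note defines the models, fitting conventions and evaluation
protocol implemented in `enantioselect`, the design rationale of the
synthetic data generator, and the package's known limitations.

## Data model

A reaction table (`core_data.ReactionFeatureTable`) is an
`n_reactions × n_features` float matrix with a string `reaction_id` per
row, a unique name and a molecule role (solvent, catalyst, nucleophile,
imine) per column, and an optional ΔΔG‡ target in kcal/mol. All values
must be finite. Tables round-trip bit-exactly through a CSV pair (data
+ `feature,role` metadata).

Conversions use ΔΔG‡ = −R·T·ln(e.r.) with
R = 1.98720425 × 10⁻³ kcal mol⁻¹ K⁻¹.

Target screening: Shapiro–Wilk normality p-value plus an outlier flag
for any reaction with |z| > 3, where z-scores use the sample standard
deviation (ddof = 1).

Feature views: `all` (282 columns in the canonical layout),
`exclude_imine` (260; nucleophile-focused models) and
`exclude_nucleophile` (267).

## Base learners

Five regressors, each with exactly one tuned hyperparameter
(scikit-learn estimators behind a uniform surface):

| Model | Tuned hyperparameter | Fixed settings |
|---|---|---|
| LASSO | `alpha` | — |
| Decision tree | `min_split` | — |
| Random forest | `num_trees` | — |
| Gradient boosting | `num_iter` | learning rate 0.1 |
| SVR | `C` | RBF kernel, `gamma="scale"`, ε = 0.1 |

Features are z-score standardized (training statistics; constant
features get std treated as 1) for LASSO and SVR only; tree ensembles
see raw features. A greedy forward stepwise linear-regression baseline
is included, excluding candidates with |r| > 0.3 to any selected
feature.

## Evaluation protocol

Monte-Carlo cross-validation: 100 replications; each draws a random
⌊0.8 n⌋ training split and validates on the rest. Per-replication MSE
and R² are aggregated as mean and ddof = 1 standard deviation.
Replication seeds are spawned from one `SeedSequence`, so results are
reproducible and replication r is independent of how many replications
run.

Model comparison uses the two-sample z statistic

```
z = (m₁ − m₂) / sqrt((s₁² + s₂²) / n)
```

with n = 100 replications and one-sided critical value 1.64
(α = 0.05): model 1's MSE is significantly lower when z ≤ −1.64, its
R² significantly higher when z ≥ 1.64.

## Hyperparameter optimization

Bayesian optimization of the single hyperparameter per learner,
minimizing validation MSE on one fixed 20% split drawn from the seed.
Surrogate: Gaussian process (constant × Matérn ν = 2.5 + white noise,
normalized targets). The first ⌈budget/4⌉ evaluations are a
space-filling design with the search-space midpoint first; remaining
evaluations maximize expected improvement over a 512-point grid.
Default budget 25. Log-scaled spaces for `alpha` ∈ [10⁻⁴, 1] and
`C` ∈ [0.1, 10]; linear integer spaces for `min_split` ∈ [2, 20] and
`num_iter`, `num_trees` ∈ [10, 200] (continuous relaxation, rounded at
evaluation).

## Sensitivity analysis

Permutation feature importance: the increase in the model's MSE when
one feature column is shuffled across the evaluation rows, averaged
over seeded replications (mean and ddof = 1 std). Ranking breaks ties
alphabetically. Partial dependence sweeps one feature over a 20-point
grid between its observed bounds, averaging predictions over the table.

## Composite model (GMM density routing)

The package's core contribution. Two Gaussian mixture models are
fitted to the training distribution of key descriptors:

* nucleophile GMM over `H-X-Nu`, `H-X-CNu`, `Nu`, `Polarizability`;
* imine GMM over `C`, `N`, `SL`, `LUMO`.

These default key features are the top permutation-importance
descriptors of the nucleophile-focused RF and the overall SVR
respectively; both lists are configurable.

EM fitting conventions (implemented in the package, not delegated):

* features standardized with the fit data's own mean/std; reported
  log-likelihoods include the change-of-variable Jacobian
  −Σⱼ log(stdⱼ), i.e. they are densities in original units;
* k-means initialization (`n_init=1`), full covariances with a 10⁻⁶
  diagonal ridge each M-step;
* convergence when the average log-likelihood improves by less than
  10⁻⁴, cap 200 iterations, best of 5 seeded restarts.

Component counts are selected by scanning K = 1..k_max and minimizing

```
BIC = −2·logL + p·ln(n),   p = (K−1) + K·d + K·d·(d+1)/2
```

with ties going to the smaller K.

Routing compares the average log-likelihood of a test group's key
descriptors to the threshold 1.0 (strict `>`): nucleophile low →
LASSO (all features); nucleophile high and imine low →
nucleophile-focused RF (`exclude_imine` view); both high → overall
SVR. The decision is set-level by default — a reaction group shares
one predictor — with per-reaction routing behind a flag. Default
predictor hyperparameters are the tuned standalone settings
(C = 9.99, num_trees = 28, alpha = 0.016). A fitted composite persists
as a directory (three joblib archives, two GMM JSON files, a
manifest).

Convention note: the routing rule is stated and implemented in terms
of the *nucleophile* likelihood first; the likelihood values reported
alongside routed predictions always carry the Jacobian term, so both
sides of every comparison use the same units.

## Synthetic data generator

The generator (`synthetic_data`) produces CPA-like tables for
validation: 307 training reactions × 282 descriptors
(160/85/15/22 role blocks), 27-reaction test groups, named informative
descriptors matching the key-feature lists above. Its defaults are the
package's study conditions. Design rationale:

* **Molecule reuse.** Each reaction draws one latent molecule identity
  (mixture cluster) per role — 12 clusters per role, centers uniform
  on ±1.5, within-cluster std 0.05. Tight repeated clusters are what
  make the key-feature densities concentrated enough that an
  in-distribution group scores average log-likelihood above the
  routing threshold of 1, as real descriptor tables do. The imine
  cluster copies the nucleophile's with probability 0.6 (imine
  identity partially explained by the partner molecule).
* **Target.** Linear in the 8 informative descriptors (coefficients
  uniform on ±[0.12, 0.28]) plus a small imine-only nonlinearity
  (amplitude 0.1: one pairwise interaction, one quadratic) and
  Gaussian noise (σ = 0.5, clipped at 2.5σ). The assembled target is
  winsorized at ±2.8 sample standard deviations: measured e.r. values
  saturate at detection limits, so real ΔΔG‡ tables are light-tailed
  and pass the |z| > 3 screen. Noise-free tables skip winsorization
  (they are diagnostic constructions).
* **Shifts.** `nucleophile_shift` / `imine_shift` translate the
  informative test descriptors of that role by 10 training standard
  deviations *before* the target is computed, so shifted reactions
  still obey the true structure–selectivity relationship: a linear
  model can extrapolate to them, a saturating learner cannot. Keeping
  the nonlinearity imine-only makes the nucleophile-shifted target
  exactly linear in the shifted block.

Verified generator invariants (see the test suite): over 50 seeds the
training target passes Shapiro–Wilk (p > 0.01) in ≥ 90% of draws and
is outlier-free in ≥ 80%; in-distribution key-feature likelihood
exceeds the routing threshold; density routing recovers the injected
regime in ≥ 95% of trials; BIC recovers planted component counts.

Two identifiability consequences of the molecule-reuse design are
worth noting. First, features within a role are near-duplicates
(they share the cluster identity), so permutation importance reliably
separates the signal-carrying *roles* (nucleophile/imine) from the
nuisance blocks (solvent/catalyst) but cannot reliably single out the
named informative columns among their role-mates; the validation
checks are therefore stated at role level. Second, linear
extrapolation under shift requires the linear map to be identified,
i.e. more training rows than descriptors (307 > 282 holds at the
defaults).

## Limitations

* The routing threshold (1.0) and the GMM likelihood convention are
  calibrated to concentrated, repeated-molecule descriptor tables;
  tables whose key features are continuous-valued without reuse will
  score low likelihoods even in distribution.
* Set-level routing assumes a test group is homogeneous; heterogeneous
  groups should use per-reaction routing, which is noisier.
* The Bayesian optimizer is 1-dimensional by design (one key
  hyperparameter per learner); joint tuning is out of scope.
* Permutation importance shares credit across correlated features;
  with strongly collinear descriptor blocks, interpret rankings at the
  group/role level.
* The two-sample z-test treats Monte-Carlo CV replications as
  independent; overlapping training splits make them positively
  correlated, so significance levels are approximate (shared practice
  for this protocol).
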