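# Methods

This note documents the models, numerical choices and open design
decisions behind `thermosolv`, and what the synthetic test bed does and
does not establish about real solubility data.

## Model

### Solution representation

A measurement is mapped to
`x = [d(solute) ⊕ d(solvent) ⊕ t(T)]`, where `d(·)` is a fixed vector of
2-D RDKit descriptors and `t(T)` the temperature feature. The default
schema (`rdkit_core`, 38 descriptors) is a curated subset covering size,
polarity, H-bonding, flexibility and electronics; it always contains
molecular weight and Wildman–Crippen logP, which double as the ordering
features of the cumulative-residual diagnostics. The full 210-descriptor
RDKit set is available as `rdkit_full`. Descriptor values that RDKit
cannot define for a molecule are imputed to 0.0 *before* scaling;
descriptors undefined for more than half the training molecules can be
pruned from the schema (`prune_schema`). Features are standardized to zero
mean and unit sample variance with statistics fitted on training rows
only; zero-variance features get scale 1. The temperature feature is
scaled by its own training statistics.

Two temperature parameterizations are supported: raw kelvin (default) and
`inverse` (1000/T). The inverse axis is the natural one for van't Hoff
behavior, where log₁₀ S is nearly linear in 1/T.

### Network and Sobolev training

The regressor is a tanh feed-forward network. Optionally, separate linear
"branch" layers transform solute and solvent descriptors before they are
combined (concatenation by default; elementwise add / subtract / multiply
are available and require equal branch widths). The combined
representation plus the temperature feature feeds the trunk; default trunk
widths are (256, 256).

The loss is `MSE(value) + λ·MSE(∂f/∂T)` with gradient targets from finite
differences of each experimental curve (central differences at interior
temperatures, one-sided at the ends — adequate for the monotone,
locally-linear curves the targets come from; single-temperature
experiments contribute a masked target, and an all-masked batch simply
drops the gradient term). The predicted derivative is computed by
forward-mode tangent propagation through the network, seeded on the
temperature input with the chain-rule factor `d t(T)/dT / scale`, so both
the targets and the penalty live in log₁₀ units per kelvin regardless of
feature scaling. Optimizing this term requires differentiating the tangent
computation itself; the reverse pass implements this double
backpropagation analytically for tanh layers (it is exact — verified
against numerical differentiation in the test suite).

λ defaults to 400. The scale is set by the units: experimental gradients
are of order 10⁻² log/K, so squared-gradient errors are ~10⁻⁴–10⁻⁵ and a
λ of order 10²–10³ makes the two loss terms commensurate. λ = 0 recovers
plain value regression.

Optimization is minibatch Adam (learning rate 10⁻³, batch 512, optional
decoupled weight decay), with early stopping on validation RMSE
(patience 20, max 300 epochs) and restoration of the best weights. All
randomness flows from a single integer seed; identical inputs and seed
reproduce the network bit-for-bit.

### Van't Hoff linear baseline (optional)

With `vant_hoff_baseline=True` the model first fits, in closed form, a
ridge regression of log₁₀ S on `[1, rep, t, rep·t]` (ridge 10⁻⁶ per
sample), i.e. a + b/T behavior with a and b linear in the scaled
representation when the inverse temperature feature is used; the network
then trains on the residuals and the two are summed at inference (values
and temperature derivatives both). Rationale: a saturating network cannot
extrapolate even an exactly linear structure–property trend to solutes
outside the training descriptor range, while a linear model extrapolates
it exactly — and the near-minimum-norm ridge solution generalizes the
underdetermined directions gracefully. On the synthetic benchmark this is
the difference between held-out-solute failure on descriptor-space
outliers and uniform recovery; on real data it is a physically sensible
prior, not a guarantee. The baseline is off by default so that the default
model is the plain concatenation network.

### Clamp, ensembles, uncertainty

At inference the temperature input saturates at `clamp_T` (default 350 K,
near the boiling points of common solvents): predictions above the clamp
are exactly constant in T, and the reported gradient is exactly zero
there. The clamp is off during training.

A model is an ensemble of exactly four networks. Member k re-splits the
training experiments by solute with seed `base_seed + k`, fits its own
scaler on its own training rows, and trains independently; predictions
are the member mean, uncertainty the member sample standard deviation
(which is zero only if members agree exactly).

## Data handling

* CSV dialects for the native format and the three public deposit layouts
  are shipped as an editable YAML map (deposit headers drift between
  releases). Temperatures are normalized to kelvin and solubilities to
  log₁₀ mol/L at ingestion; rows with unparseable structures, missing
  temperatures, non-positive solubilities or multi-component solvents are
  skipped and counted in the log.
* Structures are canonicalized with RDKit; all matching (overlap dropping,
  grouping, duplicate detection) is on canonical SMILES.
* Records sharing (solute, solvent, source) form an experiment; replicate
  measurements at the same temperature within an experiment are merged to
  their mean so finite differences see one value per temperature.
* `split_by_solute` shuffles solutes with the given seed and moves whole
  solutes into validation until it holds the requested record share —
  train/validation solute sets are disjoint by construction.
* Inter-laboratory duplicates are (solute, solvent) measurements from ≥2
  distinct sources whose temperatures agree within a tolerance (default
  0.1 K, effectively exact after unit normalization), clustered by single
  linkage along temperature. Their variability is summarized two ways:
  the mean over groups of the within-group sample standard deviation
  (ddof 1), and an RMSE-like statistic — the root of the mean squared
  log₁₀ S difference pooled over all ordered cross-source pairs. The
  pairwise definition is a documented choice; deviation-from-group-mean
  is the natural alternative and is easy to substitute.

## Synthetic test bed

`generate` draws real molecules from a shipped library (common organic
solutes, substituted benzenes and naphthalenes; 30 common solvents) and
assigns each pair the law `log₁₀ S = a + b·(1000/T) + ε`,
ε ~ N(0, noise_sd), with a and b linear in five designated descriptors
(MolWt, MolLogP, TPSA, rotatable bonds, H-donors) standardized over the
drawn set. Shipped weights center a near 3 and b near −1.2, giving
log₁₀ S centered near −1 with a multi-decade spread and gradients of
+0.004 to +0.024 log/K near room temperature — the magnitudes typical of
published organic solubility curves. Defaults: 200 solutes × 5 solvents ×
5 temperatures evenly spaced on 280–340 K, noise 0.3 log units
(a mid-range value for reported inter-laboratory spread). The analytic
gradient −1000·b/T² is exported for oracle comparisons, and
`make_interlab_twin` fabricates a second "laboratory" re-measuring chosen
records with a Normal offset, exercising the duplicate-curation path.

What passing on this bed shows: the pipeline is leak-free and
deterministic; the network plus baseline recovers a descriptor-linear
van't Hoff law to below the noise floor on held-out solutes; gradient
supervision measurably improves gradient accuracy when its targets are
informative. What it does not show: performance on real data, where the
structure–property map is not linear in any fixed descriptor set, errors
are systematic rather than i.i.d. Gaussian, solvents are far more diverse,
and label noise is correlated within literature sources.

## Study designs in the acceptance script

* **Parameter recovery** uses the generator defaults (200×5×5), holding
  out 20% of solutes, with the recommended configuration (inverse
  temperature, baseline, weight decay 10⁻⁴, widths 256×256). At noise 0.3
  the held-out RMSE lands at the noise level; at noise 0 it falls well
  below 0.05.
* **Gradient supervision** is evaluated at noise 0.1 with 7 temperatures
  per curve, λ = 2000 vs λ = 0, three training seeds, gradient RMSE
  measured against the analytic slope on the curves the supervision acted
  on. Noise 0.1 is the informative regime: at noise 0.3 with a 15 K
  temperature grid the finite-difference targets carry error
  (~1.4·10⁻² log/K) larger than the gradient signal itself
  (~1.3·10⁻² log/K), and supervision cannot help on this bed — worth
  remembering when choosing λ for sparse, noisy real curves.
* **The learning curve** uses the generator defaults (200 solutes ×
  5 solvents, noise 0.3), a size ladder of 50/150/800 experiments, three
  replicates per size, and a compact 64×64 configuration; each (size,
  replicate) cell derives an
  independent seed (splittable SeedSequence), so any cell can be re-run
  in isolation. The curve's plateau is reported against the band
  (0.24, 0.40) around the injected noise. These problem sizes keep the
  whole study at a few minutes on one CPU while leaving the qualitative
  behavior (monotone decrease, plateau at the noise floor) intact.
* **Duplicate curation** constructs 34 twin groups (offset sd 0.48) and
  re-identifies them exactly; the variability statistics are checked
  against their definitions.

## Limitations

* Descriptors are 2-D only; stereochemistry, conformers and crystal-form
  effects (a dominant source of real measurement bias) are invisible.
* The clamp is a hard saturation, not a learned plateau; predictions at
  the clamp boundary have a gradient discontinuity by design.
* The baseline's extrapolation advantage is proven on the synthetic bed
  only; on real data its ridge fit may absorb noise along weakly
  determined descriptor directions.
* Solvent mixtures and aqueous-specific curation are out of scope; records
  with mixture solvents are dropped at ingestion.
* The full-deposit workflow (training on BigSolDB and testing on the
  Leeds and SolProp sets) is wired through the dialect maps but not run
  anywhere in the test suite; no claims are made here about accuracy on
  those datasets.
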