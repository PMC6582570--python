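# Methods

This document describes the statistical model, the numerical choices behind
the implementation, and the known limitations.

## Problem

Hair whorls on a horse's forehead are easy to score in the field and have
been proposed as markers of temperament and laterality. Two ordinal traits
are analyzed:

- **whorl number** — how many facial whorls a horse has (1, 2, 3, ...),
  analyzed in practice as a binary trait (one vs. two or more) because
  higher counts are rare;
- **whorl position** — the height of a single whorl on the forehead,
  an ordered three-category trait (low < medium < high).

Both traits are categorical, so a linear animal model is inappropriate; the
package implements the standard Bayesian **threshold (liability) animal
model** fitted by Gibbs sampling.

## Model

For horse *i* with sex *s(i)* and (unobserved) liability `L_i`:

```
L_i = beta_{s(i)} + u_{k(i)} + e_i
u ~ N(0, A sigma2_u),   e ~ N(0, I sigma2_e)
Y_i = c  iff  t_{c-1} < L_i <= t_c,    t_0 = -inf < t_1 < ... < t_{C-1} < t_C = +inf
```

- `beta` is a per-sex fixed effect (cell-means coding, flat prior).
- `u` is the vector of additive genetic effects for **all** pedigree
  members, phenotyped or not, with covariance proportional to the numerator
  relationship matrix `A`.
- Heritability on the liability scale is `h2 = sigma2_u / (sigma2_u + sigma2_e)`.

### Identifiability

The categorical likelihood is invariant to location and scale shifts of the
liability, so two constraints are required. The package supports both
standard conventions (`parameterization` in `MCMCConfig`):

- `fix_var_e`: `t_1 = 0` and `sigma2_e = 1`; remaining thresholds are
  sampled from their uniform full conditionals (single-site update).
- `fix_two_thresholds`: `t_1 = 0`, `t_2 = 1`; `sigma2_e` is sampled from
  its scaled inverse chi-square full conditional.

`"auto"` (the default) resolves to `fix_var_e` for binary traits (there is
only one threshold) and `fix_two_thresholds` for three or more categories.
The reason is mixing: the single-site threshold update is notoriously slow
because a threshold can only move within the gap between adjacent
categories' extreme liabilities, which shrinks as `n` grows. Fixing two
thresholds and letting the scale parameter `sigma2_e` move instead gave
roughly six times the effective sample size per iteration for the
three-category trait in our recovery experiments, at identical posterior
inferences for `h2`.

### Priors

`sigma2_u` and (when sampled) `sigma2_e` carry scaled inverse chi-square
priors. Defaults are `nu = 4, S = 0.25` (prior mean 0.5) for both.

A flat prior on the variance (`nu = -2, S = 0`) is expressible but **not**
the default, deliberately: for this model the marginal likelihood tends to
a positive constant as `sigma2_u -> inf` (each observation's latent
liability can absorb any genetic value), so the flat-prior posterior is
improper. Empirically a chain under the flat prior drifts monotonically
toward `h2 = 1` and never stabilizes. This was diagnosed with an exact
marginal-likelihood oracle (Gauss–Hermite quadrature over the sire effect
of each half-sib family) and is why a weakly informative proper prior is
the default. With the proper prior, the full Gibbs sampler reproduces an
exact 2-D quadrature posterior on small datasets
(`tests/test_gibbs.py::test_gibbs_matches_exact_quadrature_posterior`).

### Full conditionals

One Gibbs iteration cycles:

1. **Liabilities**: independent truncated normals on the interval of the
   observed category.
2. **Fixed effects**: Gaussian cell means (flat prior).
3. **Breeding values**: single-site Gaussian updates from the
   mixed-model-equations conditional, with precision
   `n_k / sigma2_e + a^{kk} / sigma2_u`, executed in *chromatic* batches:
   a greedy coloring of the sparse `A^-1` adjacency graph partitions the
   pedigree into classes with no mutual conditional dependence, so each
   class updates simultaneously as a vectorized numpy operation. For a
   paternal half-sib design this yields three colors, making the sweep a
   handful of sparse matrix-vector products per iteration while retaining
   exactly the single-site stationary distribution (validated against the
   exact joint Gaussian conditional in the test suite).
4. **Variances**: scaled inverse chi-square draws;
   `sigma2_u` from `(u' A^-1 u + nu S) / chi2(q + nu)`.
5. **Free thresholds** (only when `C - 1` exceeds the number of fixed
   thresholds): uniform between the adjacent categories' extreme
   liabilities.

### Numerical choices

- **Truncated normal sampling** uses the inverse-CDF method with interval
  reflection into the lower tail, where `scipy.special.ndtr` retains full
  precision; the uniform deviate is clipped away from 0 and 1 and the
  resulting draw pinned to the interval. This keeps draws finite and inside
  the support even ~40 standard deviations into a tail.
- **`A^-1`** is assembled sparsely by the standard rules from pedigree
  structure with inbreeding accounted for (Mendelian sampling variance
  `0.5 - 0.25 (F_s + F_d)` with both parents known, `0.75 - 0.25 F_p` with
  one). Inbreeding coefficients come from a memoized recursive kinship
  computation; the dense `A` (used for reporting and oracles) comes from
  the tabular method.
- **A small floor on `sigma2_u`** (`1e-8`) prevents an absorbing state at
  zero in early iterations.
- **Posterior mode** is the maximizer of a Gaussian KDE (Silverman
  bandwidth) on a 512-point grid over [0, 1], the conventional point
  estimate for threshold-model heritability; a warning is emitted if the
  density has more than one substantial peak.
- **Convergence**: split-Rhat (PSRF) and effective sample size via `arviz`
  across chains started from different seeds; PSRF > 1.1 is flagged.

## Data preparation

- Pedigrees are topologically sorted and validated (unique ids, no
  ancestry cycles); parents referenced but never defined are auto-inserted
  as founders with a logged warning.
- The pedigree is truncated to the phenotyped horses plus a configurable
  number of ancestral generations (3 by default, as in the source study).
- Horses with multiple whorls are excluded from the position trait.
- **Half-sib informativeness filters**, applied in this order:
  1. restriction to retained categories (e.g. dropping the rare 3- and
     4-whorl horses),
  2. removal of paternal half-sib families below a minimum size
     (family sizes recomputed after step 1; horses with unknown sires count
     as singleton families),
  3. removal of monomorphic families (no phenotypic variation carries no
     information about within-family resemblance under a threshold model).
  The exclusion report partitions the input exactly and the filters are
  idempotent; both properties are asserted in the test suite.

## Synthetic data generator

`synthetic_data` simulates a paternal half-sib design: founder sires, one
founder dam per offspring by default (configurable to create full-sib
nests), and one phenotyped offspring generation. Breeding values are
generated by gene flow (founders `N(0, sigma2_u)`, non-founders midparent
average plus Mendelian deviation with the inbreeding-corrected variance),
which reproduces `cov(u) = A sigma2_u` exactly. Thresholds can be placed to
match target category frequencies via `thresholds_for_frequencies`;
`study_like_config` presets the two traits' approximate observed frequency
profiles (~81/19 for whorl number; ~67.6/29.4/3.0 for one-whorl position).

Realism limits:

- one offspring generation; real studbooks are deep, so the synthetic `A`
  is far sparser and founders are not inbred;
- dams are sampled at random (no assortative mating, no repeated matings
  across sires, no maternal or permanent-environment effects);
- sexes alternate deterministically and the sex effect defaults to zero;
- family sizes are balanced by default, unlike real sire usage.

These choices make the generator a calibration instrument for the
estimator (its defaults mirror the study's design scale), not a demographic
model of a horse population.

## Parameter recovery

The end-to-end check simulates data at a known `h2`, fits the model, and
summarizes bias, RMSE, and 95%-credible-interval coverage over replicates
(`recovery_experiment`). The acceptance test runs 20 replicates per trait
at both published heritability values (0.16 for whorl number, 0.64 for
whorl position) using 50 sires x 20 offspring — a reduced version of the
study's ~150 x 25 design chosen so the experiment completes in minutes on
one core — with 20,000 iterations and 2,000 burn-in per replicate, and
requires |mean bias| < 0.05 and coverage >= 90%.

## Limitations

- The sampler is single-threaded pure numpy/scipy; the published protocol
  (1,050,000 iterations) on the full study scale takes hours, so tests and
  examples use shorter chains.
- Only one fixed effect (sex) is supported, matching the source analysis;
  arbitrary design matrices would require generalizing the cell-means
  update.
- The threshold model assumes a single underlying normal liability;
  genuine multimodality or non-additive genetic architecture is outside
  the model class (the reporting layer warns when the `h2` posterior looks
  multimodal).
- Binary traits with extreme category imbalance in small families carry
  little information; posteriors then lean on the prior, and the prior
  sensitivity should be checked by rerunning with different `(nu, S)`.
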