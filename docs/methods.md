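# Methods

## Measurement model

Both trees map two latent probabilities per condition cell — binding memory
`P_B` and item memory `P_I` — onto the three response categories of the
probe display (target, lure, new). Guessing parameters are fixed constants,
`g_B = g_I = 0.5`: when binding memory fails, the respondent guesses between
target and lure with probability `g_B`; when item memory fails, `g_I` splits
an "old-looking" guess (then resolved target-versus-lure by `g_B`) from a
"new" response. Fixing the guessing constants makes the trees identifiable
from three categories.

The *dependence* tree routes item memory first: the target branch requires
`P_I` then `P_B`. The *independence* tree lets `P_B` produce the target
directly, with the item-memory subtree entered only on binding failure. Both
share the same no-memory subtree. The trees live in EQN text files
(`src/bindmpt/models/*.eqn`), one tree per condition cell with
condition-suffixed parameter names (8 free parameters per model: `P_B` and
`P_I` for each of the 4 within-subject cells). The engine treats topology
purely as data — `parse_eqn` compiles any EQN-dialect text — so a revised
tree reading requires editing a fixture, not code. For the independence
tree, the routing of `P_B` before `P_I` is a modelling choice this package
fixes in its EQN file; the file is the single source of truth.

Likelihood is the product-multinomial kernel `Σ n log p` per participant ×
condition, omitting the multinomial coefficient (constant in the
parameters). All deviance-based quantities inherit this convention;
DIC *differences* between models on the same data are unaffected, absolute
values are comparable only within the convention.

## Hierarchical person model and priors

Person `p`'s value of parameter `k` is `θ_pk = Φ(μ_k + δ_pk)` with
`δ_p ~ MVN(0, Σ)` (probit latent-trait structure). Priors:

* `μ_k ~ Normal(0, 1)` on the probit scale — equivalently each group-level
  probability `Φ(μ_k)` is uniform on (0, 1) a priori;
* `Σ ~ Inverse-Wishart(Ψ = I, ν = K + 2)` (K = number of free parameters).
  This is weakly informative (prior mean I on the probit scale) and
  conjugate, so the covariance is updated by an exact Gibbs draw. A scaled
  (ξ-decomposed) inverse-Wishart would decouple scale from correlation
  priors; the plain conjugate form was chosen for exactness and simplicity
  and is exposed through `prior_scale` / `prior_df_add`.

Groups (e.g., the two cultural samples) are fitted separately; no pooling
across groups.

## Sampler

Metropolis-within-Gibbs, vectorised across chains and participants:

1. random-walk update of each column `δ[:, k]`, using only the condition
   whose likelihood parameter `k` touches plus the conditional MVN prior
   term (quadratic-form difference against `Σ⁻¹`);
2. random-walk update of each `μ_k`;
3. a likelihood-invariant "shift" move `μ_k += c, δ[:, k] −= c`, accepted on
   the prior ratio alone — this decorrelates the group mean from the mean
   person offset, the main slow direction of the posterior;
4. exact conjugate inverse-Wishart draw of `Σ`.

Proposal scales adapt every 50 iterations during burn-in toward a 0.44
acceptance rate and are frozen afterwards, so retained draws come from a
fixed transition kernel. One `numpy` Generator seeded by `seed` drives all
chains; identical data + config reproduce draws bit-for-bit.
Initialisation jitters `μ` mildly around 0 (overdispersed relative to the
posterior width); a non-finite initial likelihood triggers bounded
re-initialisation and then a diagnostic error (this happens only when the
data contain responses the tree assigns probability zero).

Defaults: 4 chains, 10,000 iterations, 2,000 burn-in, thin 1 — deliberately
generous for an 8-parameter posterior; the documented tests and scripts use
shorter, stated runs. With `heterogeneity=False` the model collapses to
`θ_k = Φ(μ_k)` with uniform priors on the probability scale; this is the
configuration checked against an independent Riemann-sum grid posterior
(10,000-point grid, agreement within 0.01 in the posterior mean).

Retained person-level draws are capped (`person_draw_cap`, default 250 per
chain, evenly thinned) to bound memory; the full-run mean of the person
probit values is tracked separately for the DIC point estimate.

## Diagnostics and model comparison

* **R-hat** — classic Gelman–Rubin between/within-chain variance ratio on
  the probability-scale group draws, requiring ≥2 chains and ≥10 draws. The
  study-level convergence bar adopted throughout is R-hat < 1.02. (A test
  cross-checks against arviz's rank-normalised split-R-hat to ~0.05.)
* **DIC** — `DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`. The point estimate `θ̄`
  is the posterior mean of the *probit-scale* person parameters, transformed
  through Φ; averaging on the probit scale avoids the nonlinearity ambiguity
  of averaging probabilities. The decomposition identity is exact by
  construction and asserted to 1e-9.
* **ppp** — posterior predictive p-value with the mean-frequency
  chi-square-style discrepancy (the T1 statistic): per retained person-level
  draw, `T = Σ_cells (observed mean frequency − expected)² / expected` is
  compared between the observed data and a replicated data set sampled from
  the same draw; ppp is the fraction of draws with `T_rep ≥ T_obs`. A
  covariance-based (T2) check is not implemented.

## Contrasts

All contrasts are computed on the probability scale from per-draw
differences, summarised by the mean and equal-tailed 2.5%/97.5% quantiles
(not HPD), with `excludes_zero` as the decision flag. Cross-group contrasts
pair draws from the two independently fitted posteriors by (chain,
iteration) index — valid because the fits are independent; a draw-count
mismatch is an error with the remedy (thin to the common length) in the
message. Within-group contrasts (binding difference, prior-knowledge
benefit) subtract parameters of the same fit, preserving their posterior
correlation. The prior-knowledge benefit is defined only for the
consistent/inconsistent parameterisation and raises an error on other fits.

## Synthetic data generator

The generator emulates the task structure the analysis assumes: a 2
(binding: intrinsic/extrinsic) × 2 (probe: shape/colour, or prior-knowledge
consistency: consistent/inconsistent) within-subject design, 12 blocks × 24
critical trials balanced within block, 30 participants per group. Stimulus
descriptors follow the task's construction rules — four memoranda shapes at
72° spacing on a shape wheel with a fifth shape reserved for the new probe;
memoranda colours as two items from each of two of six colour families; the
new-probe colour from a remaining family; the lure a recombination of
presented features (from the other colour family in the first design, from
the same family in the second). Per-block balancing of cells is the
generator's choice; only per-participant totals matter to the model.

Responses are sampled from the MPT category probabilities at person-level
parameters `Φ(μ + δ)`, `δ ~ MVN(0, Σ)` — the exact data-generating process
the hierarchical model assumes. Defaults for heterogeneity are probit-scale
SD 0.5 with exchangeable correlation 0.3: a modest, realistic
individual-difference structure chosen once (roughly, person-level memory
probabilities spread ±0.2 around the group mean). Stimulus descriptors do
not influence responses; condition alone does — the same conditional-
independence assumption the MPT analysis itself makes. Consequently,
passing recovery tests show that the *inference machinery* is correct under
its own assumptions; they cannot show robustness to real-data features the
generator omits (serial position and fatigue effects, stimulus-specific
difficulty, lapses, response bias differing from `g = 0.5`, trial-to-trial
parameter drift).

`simulate_counts` draws the per-cell multinomial counts directly
(distributionally equivalent to generating a design and aggregating) and is
used where stimulus descriptors are irrelevant, e.g. replicate studies.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make each check informative at
interactive cost: engine exactness over 1000 random parameter sets (error
bound 1e-12); grid-oracle fits with 2 chains × 8000 iterations; the default
design (30 × 288) fitted with 4 chains × 4000 iterations for convergence
and predictive checks; recovery bias averaged over 10 default-size
replicates at 2 × 1500; CI calibration and DIC comparison over 20 and 2 × 10
reduced replicates (12 participants, 36 trials/cell, 2 × 900). Single-fit
recovery against a ±0.07 bound is asserted under zero person heterogeneity,
where multinomial + MC noise is the only error source; under the default
heterogeneity a 30-person sample localises a group mean only to ~0.035, so
recovery there is assessed as average absolute bias across replicates
(< 0.05). DIC model recovery between these two trees is genuinely weak —
their predicted category probabilities nearly coincide over much of the
parameter space — so the comparison check accepts either majority recovery
of the generating tree or a median |ΔDIC| within an indifference band of 10
deviance units; observed runs give ~60% recovery with median |ΔDIC| ≈ 2.

Other numerical details: `0·log 0 = 0` in the likelihood; −∞ only when a
positive count meets a structurally zero probability; probabilities are
evaluated by direct branch-product summation (error ~1 ulp); percentile CIs
use linear interpolation (numpy default); human-readable reports round to 3
decimals while machine outputs keep full precision.

## Limitations

* The sampler is a general-purpose Metropolis scheme: adequate for these
  8-parameter trees, but gradient-based samplers would scale better to
  larger MPTs.
* No beta-MPT or fixed-effects variants, no covariates, no WAIC/LOO or
  Bayes factors, and no continuous-report mixture measures.
* Absolute DIC values depend on the dropped multinomial coefficient and on
  the point-estimate convention for `p_D`; compare DICs only within this
  package.
* The generator does not render stimuli or simulate exclusion pipelines,
  response times, or colour-vision screening.
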