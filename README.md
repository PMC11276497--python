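# bindmpt

Hierarchical Bayesian multinomial-processing-tree (MPT) modelling of feature
binding in visual working memory.

## The problem

In a three-alternative working-memory probe task, participants study four
coloured shapes — colour either integrated in the shape (*intrinsic* binding)
or as its background (*extrinsic* binding) — and then choose among a
**target** (the studied conjunction), a **lure** (a recombination of studied
features), and a **new** probe (a feature not studied in the trial). Raw
accuracy confounds memory for the individual features with memory for their
conjunction. MPT measurement models separate the two: they express the
probability of each response category as sums of branch products of latent
process probabilities, here **binding memory** `P_B` and **item memory**
`P_I`, with guessing parameters fixed at `g_B = g_I = 0.5` for
identifiability.

Two tree structures are shipped as EQN model files and compared:

* **dependence model** — the target can only be chosen via binding memory
  when item memory has already succeeded:
  `P(target) = P_I·P_B + P_I·(1−P_B)·g_B + (1−P_I)·g_I·g_B`
* **independence model** — binding memory can produce the target on its own:
  `P(target) = P_B + (1−P_B)·P_I·g_B + (1−P_B)·(1−P_I)·g_I·g_B`

Person heterogeneity follows a probit latent-trait structure:
`θ_pk = Φ(μ_k + δ_pk)`, `δ_p ~ MVN(0, Σ)`, with standard-normal priors on the
group probit means `μ` (uniform on the probability scale) and a conjugate
inverse-Wishart prior on `Σ`. Fits are compared by DIC (penalised deviance),
checked by Gelman–Rubin R-hat and posterior predictive p-values, and
interpreted through 95% credibility intervals of posterior contrasts
(group difference, extrinsic−intrinsic binding difference, and the
consistent−inconsistent prior-knowledge benefit in the second experiment's
design). The package is aimed at cognitive psychometricians who want these
measurement models with a reproducible, fully synthetic test bed.

## Worked example

```python
import bindmpt as bm

model = bm.load_model("dependence", "E1")
truth = bm.SimulationTruth.from_probabilities(model, p_b=0.5, p_i=0.7)

spec = bm.DesignSpec("E1")                      # 30 participants, 12 x 24 trials
design = bm.generate_design(spec, seed=7)
trials = bm.simulate_responses(design, model, truth, seed=8)
table = bm.aggregate(trials)

est = bm.HierarchicalMPT(model="dependence", experiment="E1",
                         n_chains=4, n_iter=4000, n_burnin=1500, seed=9)
est.fit(table)
print(est.summary_.round(3).to_string(index=False))

rhat = bm.compute_rhat(est.draws_)
dic, p_d = bm.compute_dic(est.draws_, est.model_, table)
ppp = bm.posterior_predictive_p(est.draws_, est.model_, table, seed=10)
print(f"max R-hat = {max(rhat.values()):.3f}   DIC = {dic:.1f} (p_D = {p_d:.1f})   ppp = {ppp:.2f}")

bd = bm.binding_difference(est.draws_, "P_B", "shape")
print(f"binding difference (extrinsic - intrinsic, shape): "
      f"{bd.mean_diff:.3f} [{bd.ci_low:.3f}, {bd.ci_high:.3f}] "
      f"excludes zero: {bd.excludes_zero}")
```

Output:

```
           parameter  mean    sd  q2.5  median  q97.5
 P_I_intrinsic_shape 0.628 0.041 0.546   0.629  0.708
 P_B_intrinsic_shape 0.517 0.056 0.404   0.517  0.627
P_I_intrinsic_colour 0.693 0.038 0.615   0.695  0.765
P_B_intrinsic_colour 0.584 0.047 0.493   0.585  0.674
 P_I_extrinsic_shape 0.694 0.045 0.600   0.695  0.781
 P_B_extrinsic_shape 0.391 0.075 0.231   0.396  0.526
P_I_extrinsic_colour 0.648 0.042 0.563   0.649  0.728
P_B_extrinsic_colour 0.453 0.047 0.364   0.452  0.545
max R-hat = 1.004   DIC = 16093.5 (p_D = 167.6)   ppp = 0.47
binding difference (extrinsic - intrinsic, shape): -0.126 [-0.318, 0.043] excludes zero: False
```

The summary rows are the group-level posterior means of binding and item
memory per condition cell (true values here: every `P_B` 0.5, every `P_I`
0.7; single-sample deviations of a few hundredths reflect the 30-person
sample). All chains converge (R-hat below 1.02), the posterior predictive
check shows no misfit (ppp far from 0), and the binding-difference CI
straddles zero, as it must when the generating truth has no
extrinsic/intrinsic difference. Deviance uses the multinomial kernel without
the data-dependent multinomial coefficient, so absolute DIC values are
comparable only between models fit to the same data.

A command-line interface wraps the same pipeline:

```bash
bindmpt simulate --experiment E1 --seed 1 --out trials.csv
bindmpt fit --data trials.csv --model dependence --seed 2 --iters 4000 --out draws.npz
bindmpt assess --draws draws.npz --data trials.csv --out assessment.json
bindmpt reproduce --experiment E1 --seed 3 --out run_dir   # two groups, both models
```

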