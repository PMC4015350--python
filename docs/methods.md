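# Methods

## The estimation problem

Given a binary outcome $Y$ and binary features $X_1,\dots,X_p$, two
questions recur in epidemiological analysis: what is the conditional
success probability $P(Y{=}1\mid X)$ for a subject, and what is the
effect of changing one feature — the risk difference, risk ratio or
conditional odds ratio — holding everything else about the subject
fixed? Logistic regression answers both, but only under a correctly
specified logit-linear model; under misspecification (unmodeled
interactions, a saturated generating law) its probabilities and
exponentiated coefficients are biased.

A *probability machine* (PM) is any consistent nonparametric regression
applied to the $\{0,1\}$ outcome: its fitted regression function is
$E[Y\mid X]=P(Y{=}1\mid X)$ with no structural assumptions. This
package implements the random-forest probability machine (RFPM): a
forest of **regression** trees whose per-tree estimates are averaged.
The classifier-vote fraction is deliberately not used; it is a
different, less efficient estimator whose consistency for the
probability is not established.

## Counterfactual (risk) machines

Effect estimation leverages the counterfactual reading of regression
coefficients directly. For a target feature $X_t$:

1. split the data into $D_0 = \{X_t{=}0\}$ and $D_1 = \{X_t{=}1\}$;
2. train identically specified machines $PM_0$ on $D_0$ and $PM_1$ on
   $D_1$, excluding $X_t$ from the design (it is constant within each
   subgroup);
3. score **every** subject with both machines, giving per-subject
   probabilities $(p_0, p_1)$ — one observed, one counterfactual.

Any effect function follows per subject:
$RD = p_1 - p_0$, $RR = p_1/p_0$,
$OR = p_1(1-p_0) / \big(p_0(1-p_1)\big)$,
and group or study-level effects are the mean or median over subjects
(this package defaults to the median, aggregated on the ratio scale for
RR/OR). The construction generalizes to $2^k$ machines over the cells
of $k$ target features.

The **4-machine method** estimates a multiplicative interaction for a
pair $(X_a, X_b)$: one machine per observed $(X_a,X_b)$ cell yields
per-subject $(p_{00}, p_{01}, p_{10}, p_{11})$ and the interaction
ratio

$$\mathrm{ior} = \frac{p_{11}(1-p_{10})/\big((1-p_{11})p_{10}\big)}
                      {p_{01}(1-p_{00})/\big((1-p_{01})p_{00}\big)},$$

the nonparametric analogue of the exponentiated interaction coefficient
of a logistic model. The additive contrast
$p_{11}-p_{10}-p_{01}+p_{00}$ is exposed alongside; nothing ties the
framework to the multiplicative scale.

## Single-run interaction detection

From one machine fitted to all features, predictions are averaged
within the four *observed* $(X_a, X_b)$ subgroups on the logit scale
(probability scale for the additive variant) and the classical contrast
$T = m_{11}-m_{10}-m_{01}+m_{00}$ is formed; $T \approx 0$ when the two
interaction-plot lines are parallel. These are observed-subgroup
averages, not counterfactual computations, so $T$ is a cheap screen —
`scan` evaluates it for every pair from a single fit — not an
estimator. No significance test for $T$ is defined by the method; an
optional permutation reference exists but is off by default.

## Tuning contract

The forest tuning is fixed rather than cross-validated:

- `n_trees = 100`. Between 20 and 1000 trees results barely move.
- `mtry` = all usable features at every split.
- `nodesize` = 5% of the **total study size** $n$. Two points deserve
  emphasis. First, the parameter follows the convention of the classic
  Fortran-lineage random-forest implementations: a node of size at or
  below `nodesize` is not split (children may be smaller). Mapping it
  instead onto a hard minimum leaf size (`nodesize_is_min_leaf=True`)
  over-smooths markedly: at $n=1000$ the detection contrast under an
  interaction odds ratio of 2 centers near 0.50 instead of
  $\log 2 \approx 0.693$. Second, the counterfactual subgroup machines
  keep the node size anchored to the *overall* $n$, not to each
  training cell's size. Anchoring to the cell size lets small-cell
  machines grow deep trees that overfit noise features, with
  predictions pushed away from 0.5 toward each cell's majority class;
  the four cell errors compound in the interaction ratio (the 4-machine
  median for a true ratio of 5 moves from ≈6.2 to ≈7.4 at $n=1000$).
- Training subjects are scored in-sample; an out-of-bag option was
  evaluated and changes none of the reported quantities materially.

Probabilities are clipped to $[\varepsilon, 1-\varepsilon]$ before
odds or logits are formed, with
$\varepsilon = \max\!\big(10^{-6}, 1/(2\,n_{\min})\big)$ where
$n_{\min}$ is the smallest training subgroup — the clip scales with the
resolution of the smallest machine. Results are insensitive to
$\varepsilon$ over several orders of magnitude.

A minimum training-subgroup size of 25 subjects is enforced for every
counterfactual machine (configurable); smaller cells are rejected with
the offending cell named rather than silently fitted.

## Logistic comparators

`LR1` (intercept + main effects) and `LR2` (+ all pairwise products)
are maximum-likelihood GLM fits. Perfect separation and
non-convergence are recorded on a flag, never raised: replicate studies
report and exclude degenerate comparator fits with counts, since LR2
spends $p(p-1)/2$ extra parameters and separates occasionally at
$n=1000$, $p=10$. A post-fit coefficient-magnitude check (|log OR| >
15) also flags quasi-separated fits that IRLS nominally converged.

## Synthetic generating laws

All study inputs come from the built-in generators; no external data.

| model | structure |
|---|---|
| `model1` | baseline 0.3; main ORs 1.2, 1.5, 2 on X1–X3; 7 noise features |
| `model1_table1` | variant with main ORs 1.3, 1.7, 2.5 |
| `model2` | model1 + interaction ORs 2 on (X1,X2) and 5 on (X2,X3) |
| `model3` | saturated stratum table over (X1,X2,X3): 0.300, 0.176, 0.563, 0.391, 0.563, 0.096, 0.794, 0.836; 7 noise features |
| `model4` | baseline 0.3; main ORs 1.3, 2 on X1, X2; 8 noise features |
| `model5` | model4 + interaction OR 2 on (X1,X2) |
| sparse-100 | 100 features, 20 non-zero log-ORs ~ ±N(0.7, 0.2²), intercept 0 |

Features are independent Bernoulli(0.3) throughout (the 4/5 family
states this marginal; it is adopted for all models for internal
consistency — the 1–3 family's marginals are not pinned down
elsewhere). Two numbers are deliberate resolutions of gaps: `model4`'s
baseline probability (0.3, matching the rest of the family) and the
sparse model's intercept (0, i.e. baseline 0.5) and marginals (0.3);
all are configurable. Both `model1` variants are shipped because the
two main-effect OR triples appear in different places of the source
material; the equation-derived (1.2, 1.5, 2) triple is the default
since it is the only fully explicit generating law.

The generators emulate the simulation conditions of the evaluation
studies: independent binary features, exact logit-linear or saturated
laws, sparse signals among noise features. They do not emulate feature
correlation (linkage), measurement error, missingness, continuous
covariates or case-control sampling — passing tests therefore show
correctness of the machinery under the stated laws, not robustness to
those real-data complications.

Seeding: every study takes one master seed; `numpy` `SeedSequence`
spawning derives independent child seeds per replicate and per machine,
so any replicate is reproducible in isolation and identical
configurations give byte-identical results.

## Study designs and problem sizes

- **Probability studies** (bias/efficiency): a fixed evaluation set of
  500 subjects is drawn once and scored by every replicate's fitted
  models. Bias is mean prediction minus true probability per evaluation
  subject; efficiency is the width of the 5th–95th percentile interval
  of the per-subject prediction distribution; summaries are additionally
  collapsed onto the 8 (X1,X2,X3) strata, on which the true probability
  exclusively depends in models 1–3. The fixed-evaluation-set design is
  this package's resolution of "for each individual"; per-replicate
  evaluation sets would conflate composition noise with method
  variability.
- **Effect / interaction studies**: per replicate, exponentiated
  logistic coefficients versus two-machine (or 4-machine) aggregates;
  distributions summarized by median and 5th/95th percentiles against
  the known parameter.
- **Attenuation study** (sparse 100-feature regime): the coefficient
  vector is realized once; replicates redraw data. The attenuation
  index per method is the median over non-null features of
  |median estimated log-OR| / |true log-OR| — below 1 means shrinkage
  toward the null, above 1 inflation away from it. The two-machine arm
  defaults to the non-null features, which is exactly the set the index
  is defined over.

Default sizes are desk-scale choices: 200 replicates (100 for the
slower model-2 interaction study, 50 for detection distributions) of
n = 1000, and reps = 10 at n = 2000 with 20 target features for the
attenuation study. Full-scale settings (1000 replicates, n = 10,000)
are one configuration flag away and change no code paths.

## Numerical and degenerate-input behavior

- Constant outcome: a PM fit succeeds and predicts the constant.
- Constant target feature: the two-machine split is rejected with "no
  counterfactual contrast".
- Empty or undersized observed cells: rejected with the cells and
  sizes listed; in `scan`, such pairs become NaN entries instead of
  failing the whole matrix.
- Ties in medians follow `numpy` midpoint conventions; forests resolve
  split ties by feature order, so fits are bit-reproducible for a seed.
- `logit`/`expit` round-trip at 1e-12 over (0.001, 0.999); clipping
  keeps all logits finite.

## Known limitations

- At n = 1000 the single-run contrast $T$ carries a small negative
  structural bias under a weak main effect paired with a strong one
  (the weak feature's effect is resolved less in the smaller companion
  subgroup): under the no-interaction `model4`, replicate medians sit
  near −0.13 rather than 0, with a 5th–95th spread of roughly ±0.4.
  The screen remains directionally reliable (the true interacting pair
  tops the scan in a large majority of replicates) but $T$ is not an
  estimator, which is precisely why the 4-machine method exists.
- Ratio-of-odds-ratio estimands are inherently noisy and finite-sample
  inflated at moderate n: with a ~90-subject smallest cell even the
  saturated empirical ratio of odds ratios has a replicate median near
  5.8 for a true value of 5. The 4-machine median (≈6.2 under
  `model2`) should be read against that baseline.
- Under the saturated `model3` the RFPM's 5th–95th widths are below
  LR2's but remain ~1.4× LR1's at n = 1000–5000 in this
  implementation; the width-parity observation reported for that design
  elsewhere is not reproduced at these sizes and is not asserted.
- Continuous features and outcomes, multi-level categorical targets,
  binned exposures and formal inference for $T$ are out of scope.
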