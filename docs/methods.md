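# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data it is validated on, and the
design choices made where the published descriptions of these algorithms
leave details open.

## The Hunger Games Search model

HGS is a swarm minimizer over a box `[LB, UB]^D`. Each of `N` agents keeps
a position `X_i` and a hunger level `hungry_i ≥ 0`. After each evaluation
round:

- the running best/worst fitness `BF`/`WF` and best position `Xb` are
  updated (they are extremes over the whole history, so the best-so-far
  curve is non-increasing by construction);
- agents at `BF` reset their hunger to 0; every other agent gains
  `H = max-like(TH, LH)` where `TH = (F_i − BF)/(WF − BF) · r6 · 2·(UB−LB)`
  and `H = LH·(1+r)` whenever `TH < LH`. The hunger floor `LH` (default
  100) keeps stagnating agents restless;
- hunger is converted to the weights
  `W1_i = hungry_i·N/SHungry · r4` (with probability `l`, else 1) and
  `W2_i = (1 − e^{−|hungry_i − SHungry|})·r5·2 ∈ [0, 2)`;
- positions update by the three-branch rule in the README, with
  `E = sech(|F_i − BF|)` steering exploitation toward the best agent and
  the envelope `a = 2(1 − t/T)` shrinking perturbations linearly.

Defaults `l = 0.08`, `LH = 100` are the standard HGS setting and are
exposed on `HGSParams`.

Degenerate inputs are defined explicitly: `WF == BF` forces the hunger
floor branch (`TH := 0`); `SHungry == 0` makes `W1 = 1` (neutral); branch
equalities (`r1 == l`, `r2 == E`) route to the strict-inequality
complement. With vector bounds, the scalar `(UB − LB)` in `TH` is the mean
per-dimension range. One standard-normal draw per agent (not per
dimension) drives the self-perturbation branch, and `r4`, `r5` are
per-agent scalars; these match the published scalar notation of the
update rules.

## Hybrid strategies

**Gaussian bare-bone refinement** (per agent, per dimension): with
probability `CR` the candidate component is `N((pbest_ij + Xb_j)/2,
|pbest_ij − Xb_j|)`; otherwise `pbest_ij + k·(X_k1,j − X_k2,j)` with one
uniform scale `k` per agent and distinct partners `k1, k2 ≠ i`. Candidates
are clamped and accepted only on strict improvement (for both the position
and the personal best). The second Gaussian argument is treated as the
standard deviation, the canonical bare-bones convention. `CR` has no
published value for this hybrid; the default 0.5 is the canonical choice
in bare-bone/differential variants and is configurable.

**Artificial-bee block** over `M = ⌊N/2⌋` food sources, initialized
uniformly and kept across iterations:

1. *employed bees*: `food_i' = food_i + r ⊙ (food_i − food_k)` with `r`
   uniform in `[−1, 1]` per dimension and `k ≠ i`, greedy;
2. *onlookers*: sources are cycled and probed with probability
   `prob(i) = 0.9·min(F)/F(i) + 0.1` (fitness shifted by `1 − min(F)` when
   non-positive, so `prob ∈ (0.1, 1]` and the phase terminates); the phase
   ends after exactly `M` accepted probes;
3. *random replacement*: each food source challenges one uniformly random
   swarm member and replaces it if better (no new evaluations).

Phase order per iteration is HGS move → bare-bone → bee block:
exploitation refinement first, exploration injection second. The bare-bone
phase refines the population only; a flag (`BareboneParams.on_food`)
optionally extends it to the food sources. No scout-bee abandonment
counter is kept — the random-replacement phase plays that role.

**Budget accounting.** The termination budget counts objective
evaluations, not iterations, because the hybrid spends ~3N evaluations per
iteration (N HGS + N bare-bone + 2M bee probes) while plain HGS spends N;
an iteration budget would hand the hybrid triple the compute. A phase only
runs if it fits completely in the remaining budget, so `evals_used ≤
max_evals` always and traces are deterministic. The annealing horizon `T`
is `ceil(max_evals / evals-per-iteration)`, so `a` still reaches 0 under
budget-based termination. With both strategies disabled the hybrid loop
reduces bit-exactly to plain HGS under the same seed (this is tested).

**Determinism.** Each run consumes a single `numpy` Generator seeded from
`RunConfig.seed`; run `r` of a multi-run experiment uses `base_seed + r`,
which also pairs the runs across algorithms. The draw order within an
iteration is fixed and documented in the module docstrings of `abhgs.hgs`
and `abhgs.hybrid`; the test suite pins it with a scripted-stream trace of
one full iteration against a straight-line reference computation.

## Diversity and balance diagnostics

`DIV_j = (1/N) Σ_i |median(X_j) − X_ij|`, `DIV = mean_j DIV_j`, computed
once per outer iteration on the post-update population (even-N medians
average the two central order statistics). Exploration% is
`DIV/DIVmax·100` against the *running* maximum `DIVmax`; exploitation% is
its complement, so the two sum to 100 identically. A retrospective
renormalization against the final-run maximum is available
(`DiversityTrace.renormalize`). A zero `DIVmax` (population identical in
every recorded iteration) is defined as fully exploitative `(0, 100)`.

One property of the *mean* exploration% deserves care when comparing
variants: it is sensitive to the averaging window. Because a hybrid
iteration costs more evaluations, an evaluation-matched comparison gives
the hybrid fewer iterations, and the high-diversity early phase then
carries more weight in its mean. The expected ordering (bee strategy
raises exploration, bare-bone refinement lowers it) expresses itself once
runs are long enough that the collapsed-diversity tail dominates the
average; the balance comparisons in this package therefore use 30,000
evaluations (pop 30, sphere D=10), a tenth of the full 300,000-evaluation
protocol.

## Binary feature selection

Positions live in `[0, 1]^D` (so `UB − LB = 1` in the hunger update) and
are initialized as random 0/1 vectors (`P(bit=1) = 1/2`). After each
continuous move and clamp, every component is negated with probability
`T(x) = |(2/π)·arctan((π/2)x)|`; a mask is decoded as `bit_j = (x_j > 0)`
— negation therefore toggles selection state — and an empty mask is
repaired by setting one random bit. An alternative rounding decode
(`x ≥ 0.5`) is available behind `FSConfig.decode`. The decode rule is an
interpretive choice: the published update rules connect the transfer
function to sign flips but never state the sign-to-bit map explicitly.

Fitness is `α·(1 − Acc) + (1 − α)·DR/D` with `α = 0.05` as printed in the
protocol this follows. Note the consequence, which the tests confirm: the
subset-ratio term dominates, so the search drives `DR` down aggressively
and accepts a small accuracy cost when it buys a much smaller subset; on
well-separated data it typically returns 1–3 features at near-zero error.
`α` is a config knob for users who want accuracy-dominated weighting.

`Acc` is stratified 10-fold 1-NN accuracy (Euclidean distance), pooled
over held-out folds; leave-one-out CV is available. Fold assignment is
fixed once per run from the seed, so a mask's fitness is deterministic
within a run. Fold counts are reduced when the smallest class has fewer
members than folds. 1-NN distance ties break toward the lowest
training-row index; vote ties (k > 1) toward the nearer neighbour.

The driver runs 50 outer iterations of the hybrid machinery with 20
agents. A budget of "50 evaluations" would not cover even a single
population evaluation, so the published evaluation count is interpreted as
outer iterations (~3,030 mask evaluations per run at pop 20 with both
strategies on).

## Synthetic expression data

The generator emulates the shape of microarray gene-selection benchmarks
(tens of samples × thousands of features, balanced classes):
`g` informative features are `N(mu_c, 1)` with class means spaced
`effect_size` apart (default 3 within-class SDs — a strong but realistic
marker-gene separation); `r` redundant features are random linear
combinations of the informative block plus `N(0, noise_sd)` noise
(mirroring co-regulated genes that are selected or dropped together);
the rest are independent `N(0, 1)` noise. Columns are shuffled, the
ground-truth indices recorded, and the matrix min-max normalized to
`[−1, 1]` per feature (constant features map to 0).

What it does *not* emulate: heavy-tailed and heteroscedastic expression
noise, batch effects, correlated noise blocks, class imbalance, and
missing values. Passing the recovery tests therefore shows the wrapper can
find planted low-dimensional signal under Gaussian noise at the stated
effect size — not that it matches any published error rate on real
microarray data.

## Comparison harness

All algorithms in a grid share the budget, population size and the seed
schedule `base_seed + run`, making final-fitness samples paired. Wilcoxon
signed-rank (two-sided) drops zero differences; for n ≤ 12 retained pairs
the p-value is an exact enumeration over all 2^n sign assignments of the
observed tie-averaged ranks (correct under ties), otherwise the tie- and
continuity-corrected normal approximation — at n = 12 the two agree within
0.02. `+/=/−` tallies use the 0.05 level with `+` meaning the reference
algorithm is better by mean with p < 0.05. Friedman average ranks (ARV)
use average ranks for ties, so per problem the k ranks sum to k(k+1)/2.

The classical objectives bundled for benchmarking (sphere, Rosenbrock,
Rastrigin, Ackley, Griewank, all with minimum 0) are stand-ins: shifted/
rotated competition suites need external data files and are deliberately
pluggable rather than bundled — `ObjectiveProblem` accepts any callable.

## Problem sizes used in the shipped checks

The acceptance script and the heavier tests run a scaled-down version of
the full study, chosen to exercise every mechanism in minutes on one CPU:
optimizer comparisons at D=10, pop 30, 20,000 evaluations, 10 paired
seeds; balance analysis at 30,000 evaluations; feature selection at
n=60 × D=500 with 10 planted features over 10 seeds. The full-scale
protocol (300,000 evaluations, 30 runs, 17 comparator algorithms, 14 real
microarray datasets) is out of scope; directions and magnitudes at the
scaled-down sizes are what the tests assert.

## Known limitations

- Evaluation is sequential; no parallel objective evaluation.
- The onlooker phase's accepted-update loop can draw many acceptance
  uniforms when probabilities are small (bounded in expectation since
  `prob ≥ 0.1`), so scripted-stream replay must account for visit order.
- The FS objective is cached only through the best-so-far record; repeated
  masks are re-scored (mask evaluation is cheap relative to bookkeeping at
  the shipped sizes).
- `OptimizationResult.convergence` records per-iteration best-so-far, not
  per-evaluation, so curves from variants with different per-iteration
  costs should be compared on the evaluation axis (`evals_used`).
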