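# Methods

## Model

A constant-size population of `N` individuals contains an ancestor type
(growth rate 1 by definition) and mutant lineages. Each mutant lineage `j`
carries an intrinsic fitness `fi_j` (its monoculture growth rate; the cost
of resistance is `1 − fi_j`) and an ecological fitness `fe_j` (its growth
rate when the population is almost entirely ancestor). At ancestor
fraction `x` the lineage grows at

    f_j(x) = fi_j + (fe_j − fi_j) · x ,

i.e. fitness interpolates linearly between the two endpoints. `fe > fi`
is a positive ecological interaction (negative frequency-dependent
selection); `fe > 1` means the mutant outcompetes the ancestor while rare.

Mutant–mutant interactions are ignored: lineages affect one another only by
diluting the ancestor fraction and through the selection normalization.
This dilute-mutant assumption is what makes the closed forms tractable; its
failure mode at small `N` is quantified under *Limitations*.

### Generalized Moran process (single clone, no mutation)

For one mutant clone vs the ancestor we use a one-step birth–death chain on
`s ∈ {0, …, N}` with absorbing boundaries. Payoffs come from the 2×2 game
(mutant–mutant payoff `1 − fc`, mutant–ancestor `fe`, ancestor–anything 1),
with self-interaction excluded:

    P_R(s) = (s−1)/(N−1)·(1−fc) + (N−s)/(N−1)·fe ,   P_A = 1 .

One event chooses the reproducing individual with probability proportional
to payoff and the dying individual uniformly:

    b_s = [s·P_R / (s·P_R + (N−s)·P_A)] · (N−s)/N ,
    d_s = [(N−s)·P_A / (s·P_R + (N−s)·P_A)] · s/N .

This is the standard generalized Moran process of the frequency-dependent
selection literature; the chain is treated in discrete time (one event per
step), and times are reported both in events and in generations
(events / N). Absorption probabilities use the classical ratio formula with
products `d_j/b_j = 1/P_R(j)` accumulated in log space (the dense linear
solve loses all precision when `p_fix ~ 1e−13`; the log-space form matches
exact rational arithmetic to 1e−12 relative). Extinction-time distributions
are computed by iterating the transient tridiagonal kernel (a discrete
phase-type distribution), and conditional mean absorption times by a banded
solve of `(I − Q)w = a`, `t = w/a`. Extinction-time distributions are
conditioned on extinction by default — for costly mutants fixation is
astronomically rare — with the unconditioned mass exposed. A horizon that
captures <99.9% of the conditional mass sets a `truncated` flag and warns
rather than silently truncating.

### Wright–Fisher simulator

Each generation: (1) *mutation* — every ancestor mutates with probability
`μ` (binomial draw; simultaneous mutations allowed, each founding its own
size-1 lineage with fresh `(fi, fe)` draws); (2) *selection* — one
multinomial draw of `N` offspring with weights `count × fitness`, the
ancestor fraction being evaluated once, after mutation. Only ancestors
mutate. A lineage whose count reaches 0 is extinct; its extinction time τ
is the number of generations survived after emergence (τ = 0 when it
leaves no offspring in its first selection step). Lineages alive at the end
are censored, excluded from mean-τ summaries and counted separately
(including them would bias means downward).

All-ancestor stretches are advanced in one step by sampling the waiting
time to the next mutation event from its exact geometric law and the
mutant count at that event from the exact zero-truncated binomial, so the
fast path leaves the process distribution unchanged. Seed handling uses
`numpy.random.SeedSequence`; replicate runs spawn child seeds so adding
replicates never perturbs existing streams.

Per-generation totals are always recorded. Full per-lineage trajectories
are recorded only on request (`record_trajectories=True`): at production
scales (~4×10⁶ lineages) they are memory-prohibitive, and every downstream
summary is served by the per-lineage record (fi, fe, birth generation, τ,
censoring, post-burn-in person-generations).

### Closed forms

* **Mean extinction time.** `τ(fe) = 3 ln(1−fe) / (fe² − 3)` generations —
  a function of ecological fitness only. Intuition: while rare, a mutant's
  fitness is ≈ `fe` regardless of `fi`, `fc`, `N` or `μ`, and its offspring
  number is ≈ Poisson(`fe`), a subcritical branching process whose
  extinction-time expectation this expression approximates within a few
  percent across the whole range (the test suite checks it against the
  exact Poisson branching recursion).
* **Expected mutant numbers.** At mutation–selection balance each fitness
  class holds `Nμρ·g/(1−g)` individuals (expected person-generations per
  arriving lineage of a subcritical branching process). Averaging over the
  uniform DFE/DEE gives

      N_mut^no-eco = Nμ·(−ln(fc)/(1−fc) − 1)
      N_mut^eco    = Nμ·(−ln(1−fmax)/fmax − 1)        (μ → 0)

  (the `−1` removes the fresh, not-yet-selected cohort). `fmax` must be
  strictly below 1 for the normalization to exist.
* **Lambert-W form.** At larger `μ` the mutant load `M` feeds back on
  itself: the stationary mean fitness is `w̄ = 1 − μ` (the ancestor's
  stationarity condition) and each class grows at
  `g = fe(1−M) + fi·M`. The self-consistent balance
  `M = μ(1−M)·E[g/(w̄−g)]`, with the fi-average of the logarithmic
  divergence taken through the geometric mean
  `G = fc^{fc/(fc−1)}/e` of `1 − fi`, reduces to

      M = −(μ/fmax)·ln((1 − fmax − μ) + G·M) − μ/(1−μ) ,

  solved in closed form by the principal Lambert-W branch; numerically it
  is evaluated through the Wright omega function (`W(e^t) = ω(t)`) so the
  small-μ regime does not overflow. `n_mut_eco` switches to the simple
  small-μ form below `μ = 10⁻⁶` (the branches agree to <0.1% there); the
  un-approximated balance is exposed as `n_mut_eco_selfconsistent` and the
  two agree to ≤0.3% over `μ ∈ [10⁻⁸, 10⁻²]`.
* **Stationary density.** `P(fe) = fe·μ/(1−fe)·ρ₀(fe)` for any DEE density
  ρ₀ — inflow of surviving new mutants (∝ `fe·μ·ρ₀`) balancing outflow of
  existing ones (∝ `1−fe`). Its integral recovers `N_mut^eco/N` exactly for
  the uniform DEE. The density is per mutant *individual*; the simulator's
  histogram therefore weights lineages by person-generations (a by-lineage
  variant is also reported).
* **Regimes.** `small-Nμ` (both expected numbers < 1), `rare-mutant`
  (ecology pushes the count above 1 while the no-ecology count stays
  below — ecological rescue is the primary mode of preexistence), and
  `many-mutant` (both > 1). The fourth combination is impossible for
  `fmax ≥ 1 − fc` since both formulas are the same increasing function.
* **Coexistence.** For `fe > 1` (with nonzero cost) the linear fitness
  crosses 1 at the ancestor fraction `x* = (1−fi)/(fe−fi)`, a stable mixed
  equilibrium; `fc` and `fe` jointly set it. The closed-form layer above
  does not apply for `fe` support above 1; the simulator is the instrument
  there.

### Game assay

Coculture wells seeded at initial ancestor fractions `p` grow ~96 h with
imaging every 4 h (25 timepoints); both channels are fit log-linearly for
per-well growth rates. The mutant rate, normalized by the mean ancestor
rate across wells, is regressed on the *initial* ancestor fraction; the fit
at `p = 0` estimates `fi`, at `p = 1` estimates `fe`, and a one-sided
t-test of positive slope (α = 0.05) declares a positive ecological
interaction. Uncertainty comes from a bootstrap over wells with the two variance
sources accounted separately: the regression itself (well bootstrap with
the reference rate held fixed, variance inflated by `n/(n-2)` to undo the
case bootstrap's small-sample bias) and the shared reference rate (delta
method on the mean ancestor rate, which multiplies every relative rate).
Intervals are t-quantile on the combined standard error; the test suite's
closed-loop calibration verifies near-nominal coverage (simple percentile
intervals undercover at ~27 wells, which is why they are not used).
This is a standard log-linear variant of the published evolutionary game
assay, not a restatement of its exact pipeline. Frequencies drift within a
well during growth; regressing on the initial fraction follows the assay's
design and leaves that drift as part of the noise budget.

The synthetic generator emulates the same design: exponential growth of
both channels, mutant rate `r_A · (fi + (fe−fi)p)`, i.i.d. multiplicative
lognormal count noise (default log-sd 0.05, roughly the well-to-well
scatter of imaging-derived counts), ancestor rate 0.035/h (~20 h doubling,
typical of NSCLC lines), 1500 seeded cells per well, 9 fractions × 3
replicate wells. It does not emulate within-well frequency drift, lag
phases, confluence saturation or segmentation artifacts — so passing
closed-loop tests demonstrates correctness of the estimator under the
stated noise model, not robustness to every failure mode of real imaging
data. Wells with nonpositive counts in the fitting window are flagged and
excluded, never imputed.

## Parameters that matter

| Parameter | Meaning | Default | Why |
| --- | --- | --- | --- |
| `N` | population size | — | set by the study question; formulas are N-free except via `Nμ` |
| `μ` | mutation probability / individual / generation | — | `Nμ` sets the supply of lineages |
| `fc` | minimum fitness cost; DFE is uniform on `[0, 1−fc]` | 0 | each mutant's own cost is `1 − fi` |
| `fmax` | DEE upper bound | 0.999 | must be < 1 for the closed forms; simulators accept up to 1.5 for the coexistence regime |
| Gaussian DEE | truncated to `[0, fmax]`, renormalized | center 0.5, sd 0.15 | a null model in which extreme interactions are rare; sd is a free choice, configurable |
| `burn_in` | generations excluded from stationary summaries | 0 | relaxation is ~`1/(1−fmax)` generations; stationarity is additionally checked by a first-half/second-half batch-means comparison (3 SE), which warns rather than errors |
| horizon (Moran) | pmf truncation, events | 1e5 | flagged if <99.9% of conditional mass captured |

## Numerical choices

* Absorption probabilities in log space (`logaddexp.accumulate`), exact to
  ~1e−12 even when `p_fix ~ 1e−13`; a payoff of exactly zero (e.g. `fe = 0`
  at `s = 1`) is handled as a blocked upward passage, not a division error.
* Conditional means via banded (tridiagonal) solves, O(N).
* `tau_approx` uses `log1p`; the Lambert-W form uses `wrightomega` to avoid
  `exp` overflow at small μ; degenerate inputs raise `ValueError` with the
  offending constraint named.
* The simulator's per-generation work is O(live lineages); quiescent
  generations cost O(1) via the exact skip. Identical params + seed give
  bit-identical results.
* Tie-breaks: regime boundaries classify `≤ 1` as the lower regime.

## Simulation scales used in the checks

The test suite and `scripts/acceptance.py` size their simulations to keep a
single-CPU run in minutes while leaving each measured quantity
statistically decisive: the extinction-time survey uses N=10⁴, μ=10⁻⁴ and
~4.2×10⁶ lineages (so the `fe ≤ 0.002` stratum, whose mean τ is ~10⁻³
generations, still contains thousands of lineages); the mutant-number
comparison uses N=10³ with 20 replicates × 2×10⁵ post-burn-in generations
per mutation rate; distribution-shape checks use 16 replicates of
3.6×10⁴ generations. Mean extinction times are μ-independent (checked by
curve collapse across `fc`, `μ`, `N`), which is why a mutation rate above
the biologically motivated 10⁻⁶ can be used to accumulate lineages.

## Known limitations

* **Finite-N bias of the mutant-number closed forms.** The expectation of
  a near-critical class (`fe → fmax`) is dominated by rare excursions to
  sizes `m ~ (1−fe)·N/(fe−fi)`; during such an excursion the lineage
  dilutes the ancestor enough to depress its own fitness, which truncates
  exactly the excursions that carry the expectation. At `N = 10³`
  (fc = 0.25, fmax = 0.99) the simulated stationary mean sits ~10–14%
  below the closed form for `μ ≥ 10⁻⁴` (measured by the acceptance
  script), roughly independently of μ; the gap shrinks with `N` — the
  test suite verifies agreement within 10% at `N = 10⁴`.
  No deterministic formula of `(N, μ, fc, fmax)` that reduces
  to the small-μ balance at the same `N` can absorb this correction. The
  package reports what the simulator produces.
* The Moran layer covers two types and no mutation; the Wright–Fisher layer
  covers one ancestor genotype, no back-mutation, no epistasis, no spatial
  structure, no treatment phases, constant `N`.
* The closed-form layer requires `fmax < 1`; for DEE support above 1 only
  the simulator applies.
* The DEE has never been measured experimentally; the uniform and Gaussian
  choices are null models, and any tabulated density can be substituted.
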