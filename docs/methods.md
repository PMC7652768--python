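# Methods

## Model

`prmix` fits a hierarchical mixture linking three sub-models through a
shared cluster label per subject.

**Disease sub-model.** The hazard of the event (death by lung cancer)
at attained age *t* for subject *i* is `h_i(t) = h0(t) (1 + β_{C_i})`
with `β_c > −1` so the hazard stays positive. The baseline `h0` is
piecewise constant on four age intervals with cutpoints at 40, 55 and
70 years; internally all ages are in days and years convert at 365.25
days/year. Intervals are half-open `[lower, upper)`: an age exactly at
a cutpoint belongs to the interval whose left edge it is. The
likelihood of a subject observed from entry age `a_i` to exit `y_i`
with event indicator `δ_i` is

```
δ_i log( λ_{j(y_i)} (1+β) )  −  (1+β) ∫_{a_i}^{y_i} h0(u) du
```

Delayed entry (left truncation at hire age) is on by default — the
cohort enters follow-up at adult ages, so conditioning on survival to
entry is the only safe treatment; a switch (`delayed_entry=False`)
accrues person-time from birth instead.

**Exposure sub-model.** Given cluster `c`, the cumulative radon, γ-ray
and uranium-dust exposures and the age at first exposure are
independent lognormals `LogN(μ_c, σ_c)`, and the job type (5 levels),
mine district (2 levels: Hérault vs. other) and exposure-duration class
(4 levels) are multinomial. Subjects with all three exposures equal to
zero form the *reference* cluster: label 0, `β ≡ 0`, survival likelihood
only; their categorical covariates are outside the mixture. Subjects
with some-but-not-all zero exposures cannot enter a lognormal model
directly; by default each zero component is replaced by half the
smallest positive observed value of that exposure
(`zero_policy="impute_half_min"`), with `"to_reference"` routing such
subjects to the reference cluster instead.

**Attribution sub-model.** Cluster weights follow a truncated
stick-breaking construction, `V_c ~ Beta(1, α)` and
`φ_c = V_c Π_{k<c}(1−V_k)`, with the final component taking the
unbroken remainder. With `α ≤ 10` and truncation `C_max = 50`, the
prior mean of the remainder is `(α/(1+α))^{49} ≈ 0.94%` at the top of
the α support — the truncation error is negligible for inference while
keeping the state size bounded. The restricted variant (RPRM) fixes
the number K of clusters *including* the reference, i.e. `K−1` exposed
components; α is still sampled (its conditional reduces toward the
prior as K shrinks), and component emptiness is reported per iteration
rather than forbidden.

## Priors

Defaults (overridable via `PriorSpec`):

| parameter | prior |
|---|---|
| β_c | N(0, 10⁶) |
| λ₁…λ₄ | Gamma(23.7, 4.9·10⁸), (35.5, 2.6·10⁷), (88.1, 1.6·10⁷), (29.7, 3.2·10⁶) |
| μ_c (γ, radon, dust) | N(0.10, 2.25), N(−2.3, 8.08), N(1.01, 11.79) |
| μ_c (age at first exposure) | N(0, 10⁶) |
| all σ_c | U[0, 100] |
| p_c (job/mine/duration) | Dirichlet(0.5, …, 0.5) |
| α | U[0.3, 10] |

Two parametrisation conventions matter and are configurable. Normal
priors are read as (mean, **variance**) — 2.25 = 1.5² is clearly a
variance; a `normal_dialect="sd"` switch reads (mean, sd). Gamma priors
are (shape, **rate**) with time in days: Gamma(23.7, 4.9·10⁸) then has
mean 4.8·10⁻⁸/day ≈ 1.8·10⁻⁵/yr, a plausible pre-40 lung-cancer
mortality; a (shape, scale) reading would be absurd by twenty orders of
magnitude. The baseline priors are informative (external national
mortality data); the exposure-mean priors encode levels observed in a
comparable miner cohort.

## Sampler

One sweep of the Metropolis-within-Gibbs cycle updates:

1. **Allocations** — exact categorical full conditional
   `P(C_i = c) ∝ φ_c f_expo(x_i|c) f_surv(i|β_c)`, sampled by
   Gumbel-max over the log-probability matrix.
2. **Stick fractions** — conjugate
   `V_c ~ Beta(1+n_c, α + Σ_{l>c} n_l)`; weights recomputed.
3. **μ** — conjugate normal given σ; **σ** — random-walk MH inside the
   uniform bounds; **β** — random-walk MH on `β > −1` using the
   sufficient statistics (events d_c, cumulative baseline hazard E_c of
   the members); **α** — random-walk MH inside its uniform support.
4. **λ** — conjugate `Gamma(a_j + d_j, b_j + Σ_i (1+β_{C_i}) e_{ij})`
   with `e_{ij}` the person-time of subject i in age interval j;
   **p vectors** — conjugate Dirichlet(0.5 + counts).
5. **Label-switching moves** (one attempt of each per sweep, on
   uniformly chosen component pairs).

Conjugate draws are used wherever the full conditional is exact
(λ, V, μ, p); Metropolis steps handle the rest. Every Metropolis
acceptance uses the conditional log-ratio, which equals the difference
of the full joint density (tested exactly).

**Adaptation.** Random-walk scales adapt over 100 batches of 100
iterations: after each batch the log scale moves by
`±min(0.05, batch^{−1/2})` toward the target rate — 40% for scalar
blocks, 20% for vector blocks (the three-coefficient EHR regression
block is the vector case). Scales are frozen afterwards, so the
post-adaptation kernel is fixed and draws are from an honest Markov
chain. Initial scales are set from the local curvature at the starting
point (`2.4·√d_c/E_c` for β, `σ/√(2m_c)` for σ), so short adaptive
phases only fine-tune.

**Label-switching moves.** The mixture posterior is invariant under
permuting component labels, with the stick-breaking prior weakly
ordering the weights; chains can stall in one permutation mode. Move 1
swaps the parameters and allocations of an arbitrary pair (j, k),
leaving V and φ untouched, with probability
`min(1, (φ_j/φ_k)^{n_k−n_j})`. Move 2 swaps an adjacent pair (j, j+1)
*including* their stick fractions, with probability
`min(1, (1−V_{j+1})^{n_j} / (1−V_j)^{n_{j+1}})` — both ratios are exact
posterior ratios (verified against the joint density). Move 3 swaps an
adjacent pair and proposes *fresh* stick fractions for it from their
full conditionals under the swapped counts
(`V'_j ~ Beta(1+n_{j+1}, α+n_j+S)`, `V'_{j+1} ~ Beta(1+n_j, α+S)`, with
S the allocation mass beyond the pair), so the implied weights land
near their conditional expectations given the new labels. Because the
proposal is the exact conditional of the V pair, the
Metropolis–Hastings ratio telescopes to a ratio of Beta normalising
constants:

```
r = B(1+n_{j+1}, α+n_j+S) B(1+n_j, α+S)
    ───────────────────────────────────────
    B(1+n_j, α+n_{j+1}+S) B(1+n_{j+1}, α+S)
```

independent of the drawn fractions. (When j+1 is the final remainder
component only the first factor of each product appears.) The move is
validated by an invariance test: chains run with and without the moves
produce indistinguishable sorted-weight marginals.

**Schedule.** The production schedule is 10,000 adaptive iterations,
10,000 burn-in, 150,000 retained thinned by 20 (7,500 stored draws per
unknown, plus the full allocation vector per stored draw). A reduced
"smoke" schedule (10×50 adaptive, 500 burn-in, 5,000 retained thinned
by 10) is used throughout the validation suite; the problem sizes there
(n = 80–500 subjects, C_max ≤ 10) were chosen so that a full validation
cycle runs in minutes while still leaving tens of events per cluster.

**Initialisation.** Allocations come from k-means on the standardised
log covariates (reproducible given the seed). Occupied components
start at their members' empirical moments; β at 0, λ at the prior
means, α at 1, V at its conditional mean given the initial counts.
Starting σ at its prior mean (50 on the log scale) would place the
chain absurdly far from any posterior mass, which is why empirical
moments are preferred for the exposure parameters.

## Post-treatment

The similarity matrix S holds, for each subject pair, the fraction of
retained draws in which they share a cluster (reference subjects always
co-cluster with each other and never with exposed subjects). The
reported partition `C_best` is the *sampled* partition minimising
`Σ_{i<j} (S_k(i,j) − S(i,j))²` — distances over unordered pairs,
diagonal excluded (a pure convention; the diagonal is constant). Ties
break toward the earliest draw. Restricting to sampled partitions
avoids inventing a clustering the posterior never visited and is less
Monte-Carlo-fragile than a MAP search.

Cluster-conditional posteriors: for a cluster-indexed parameter θ and
best-partition cluster c, the draw-k sample is the average over members
i of θ at i's draw-k component. Applied to β, all μ/σ pairs, all p
vectors, and the weights φ. Per-cluster 95% equal-tailed intervals of
β drive the risk flags (significant high/low risk when the interval
excludes 0); covariate flags compare the interval of the
cluster-conditional posterior (medians `exp(μ)` for lognormal
covariates, category probabilities for categorical ones) with the
corresponding all-subject reference value.

**DIC and WAIC** use the per-subject mixture likelihood
`p_i = Σ_c φ_c f_expo f_surv` (survival-only with β = 0 for reference
subjects). WAIC = −2(lppd − p_waic) with p_waic the per-subject
posterior variance of log p_i. DIC = D̄ + pD with
pD = D̄ − D(plug-in); the plug-in is the deviance at the posterior
means of the continuous parameters with allocations marginalised. One
numerical subtlety: because the label-switching moves deliberately hop
between permutation modes, raw component-wise posterior means blend
different clusters and can make the plug-in deviance *worse* than the
posterior average (negative pD). Draws are therefore aligned to a
common labelling (Hungarian matching of each draw's allocations to the
first draw) before averaging; per-draw likelihoods are
permutation-invariant, so nothing else changes.

## Synthetic cohorts

The generator reproduces the *structure* the model assumes, at
study scale by default (`default_truth()`): n = 3,377 subjects,
lognormal entry ages around 27 years, five exposure profiles ordered
from light to heavy co-exposure on all three sources simultaneously,
~4% fully unexposed reference subjects, baseline rates at the prior
means, constant-rate competing mortality (≈0.8%/yr, giving roughly a
quarter of subjects dying of other causes) and administrative censoring
at age 80 (capped at 85). Cluster-level separation is what induces the
strong pooled exposure correlations (≈0.8–0.97 on the log scale) —
deliberately the same mechanism the mixture model can represent;
within-cluster draws are independent given the cluster. The
duration-class covariate is generated directly as a categorical, not
derived from a career history.

What it does **not** emulate: calendar-period effects, per-year
exposure time series, cause-specific competing-mortality age curves,
measurement error, or dependence between entry age and exposure
accrual. Passing the validation suite therefore demonstrates that the
inference machinery recovers the generating process *of this class*,
not that the model is adequate for any particular real cohort.

`toy_truth()` provides the desk-scale validation conditions: 2–3
well-separated clusters with excess hazards spread between 0 and 4 and
a few hundred subjects, leaving ~5–35 events per cluster — enough to
identify the per-cluster risks while keeping a 20-replicate recovery
experiment within minutes. Event-time simulation inverts the
piecewise-exponential cumulative hazard conditioned on survival to
entry, then competes the event age with an exponential other-cause
death age and the administrative cutoff.

## Numerical choices and edge cases

- Stick fractions from conjugate draws are clipped to
  `[1e−12, 1−1e−12]` to protect the log terms; the final weight is the
  remainder clipped at 0.
- `log_joint` returns −∞ (never raises) for parameter values outside
  their support — β ≤ −1, σ outside its bounds, α outside [0.3, 10] —
  which is exactly the behaviour Metropolis steps rely on; structurally
  invalid states (wrong shapes, labels out of range) raise instead.
- Allocation sampling uses the Gumbel-max trick on log probabilities,
  avoiding any normalisation underflow.
- Empty components draw their parameters from the conditional priors
  (μ from its prior given σ, p from Dirichlet(0.5), σ/β by Metropolis
  against the prior); they stay exchangeable with occupied ones.
- In the EHR regression, a proposed coefficient vector making any
  subject's multiplier `1 + βᵀx̃ ≤ 0` is rejected as inadmissible.
  Radon enters per 100 WLM by default; γ and dust in raw cumulative
  units, overridable per fit.
- Ages are validated on read (`y > entry ≥ 0`, categorical codes in
  range, exposed subjects need a positive age at first exposure), with
  offending CSV line numbers in the error.

## Limitations

- The full mixture posterior is multimodal in the number of occupied
  clusters when the event signal is weak; the restricted fixed-K
  variant plus DIC/WAIC comparison is the supported workaround, and
  the per-iteration occupancy trace is logged for diagnosis.
- DIC's plug-in remains a convention; WAIC needs no plug-in and is the
  more stable criterion here.
- No time-varying exposures or covariates, no measurement-error model,
  no Weibull/spline baselines, no Hamiltonian Monte Carlo.
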