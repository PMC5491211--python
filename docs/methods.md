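# Methods

## Model

`coevnet` models the joint evolution of a binary directed
emotional-support network x (x<sub>ij</sub> = 1: actor *i* provides
support to *j*; no self-ties) and an ordinal smoking score z<sub>i</sub> ∈
{0 = never, 1 = 1–3 days, 2 = 4–21 days, 3 = 22+ days in the past 30
days}, observed on a fixed roster of n actors at M ≥ 2 waves. The
observations are treated as snapshots of a latent continuous-time Markov
chain of elementary decisions ("micro-steps"):

- **Timing.** Within a period (normalized to length 1), change
  opportunities arrive as a Poisson process with intensity
  n·(λ<sup>net</sup><sub>m</sub> + λ<sup>beh</sup><sub>m</sub>); the rate
  parameters are per period and constant across actors, so the acting
  actor is uniform and the process (network vs behavior) is chosen
  proportionally to its rate. Simulation is unconditional (time-driven):
  a period ends when the clock passes 1.
- **Network choice.** The actor weighs n options — keep everything, or
  toggle the tie to one other actor — with multinomial-logit
  probabilities ∝ exp(Δf<sup>net</sup><sub>i</sub>), where
  Δf is the change in the network objective function
  f<sup>net</sup><sub>i</sub> = Σ<sub>k</sub> β<sub>k</sub> s<sub>ik</sub>
  and the "keep" option has Δf = 0.
- **Behavior choice.** Candidates are {z<sub>i</sub>−1, z<sub>i</sub>,
  z<sub>i</sub>+1} truncated to the scale, weighted by
  exp(f<sup>beh</sup><sub>i</sub>(candidate)).

Assumptions inherited from this family: myopic actors (no forward
planning), full information, at most one elementary change at a time, a
closed roster (no joiners or leavers), and rates that do not depend on
actor attributes.

## Effect statistics and centering

The catalog (`coevnet.effects`) covers the full roster used in the
published school analysis: out-degree, reciprocity, transitive triplets
(Σ x<sub>ij</sub>x<sub>ik</sub>x<sub>kj</sub>), 3-cycles
(Σ x<sub>ij</sub>x<sub>jk</sub>x<sub>ki</sub>), betweenness
(Σ<sub>j≠k</sub> x<sub>ji</sub>x<sub>ik</sub>(1−x<sub>jk</sub>)),
in-degree popularity (raw in-degree of the target, including the focal
tie), out–in √-degree assortativity, in-degree activity
(indeg<sub>i</sub>·outdeg<sub>i</sub>) and its squared variant, same-grade
and same-gender matches, covariate alter/ego terms, smoking similarity
(sim<sub>ij</sub> = 1 − |z<sub>i</sub>−z<sub>j</sub>|/3); for the behavior
equation linear/quadratic shape, in-degree, average incoming-alter
similarity (mean over one's support providers, 0 for actors with none —
averaging keeps the peer-influence effect degree-invariant), and
covariate main effects.

Centering: continuous covariates are grand-mean centered over actors; the
behavior score by its grand mean over all actors and waves of the
*observed* panel; dyadic similarity by the mean similarity over all
ordered pairs and waves. Match indicators stay raw. Centering constants
are computed once from the observed panel and held fixed during
simulation and estimation; during forward generation of synthetic data
(where later waves do not exist yet) they come from the initial wave
alone. Square roots of zero degrees are 0; no smoothing constant.

Every statistic has two implementations: a vectorized production path and
a deliberately naive loop transcription (`coevnet.reference`). Tests and
the acceptance checks enumerate all digraphs on up to 4 actors
(4 164 graphs), sample 500 random 5-actor digraphs and 100 random
15-actor states, and require exact agreement for all 31 statistics and
for the incremental change contributions against full recomputation. The
exhaustive enumeration stops at n = 4 because the n = 5 space (2²⁰
graphs) is out of desk-scale reach for loop oracles; sampling covers it
instead.

## Estimation

Unconditional method of moments. Targets: for each network rate, the
period's tie Hamming distance; for each behavior rate, the summed
|Δz<sub>i</sub>|; for each evaluation effect, the statistic summed over
actors at each period's end state, summed over periods. Simulations
restart every period from the *observed* start-of-period state.

The solver (`coevnet.estimate.robbins_monro`):

1. **Phase 1.** Jacobian D = ∂E S/∂θ by forward finite differences
   (ε = 0.1) under common random numbers — every base/perturbed pair
   replays an identical random stream, and each period has its own
   substream so a perturbation in one period's parameters leaves the
   others' draws untouched. Defaults: 60 replicates.
2. **Phase 2.** Robbins–Monro iterations θ ← θ − a·D⁻¹(S<sub>sim</sub> −
   S<sub>obs</sub>) over four subphases of doubling length (from 50) with
   gain a halved from 0.2, averaging iterates within each subphase. Each
   update is clipped to ±1 per component and θ is clamped (rates ≥ 0.01,
   |β| ≤ 20) to prevent excursions into logit overflow.
3. **Phase 2b (polish).** Full Newton steps on batch-averaged deviations
   with growing batches (default 100, 400), the Jacobian re-estimated at
   the current θ before every step. Phase 2 with a fixed early Jacobian
   approaches the root but stalls within ~0.1–0.3 target standard
   deviations of it; the polish removes that residual, with a noise floor
   of about 1/√batch in t-ratio units.
4. **Phase 3.** N₃ simulations at θ̂ (default 500) give convergence
   t-ratios t<sub>k</sub> = mean(S<sub>sim,k</sub> −
   S<sub>obs,k</sub>)/sd(S<sub>sim,k</sub>) — all |t| < 0.1 is the
   adequacy convention — and sandwich standard errors
   √diag(D⁻¹ Σ̂ D⁻ᵀ) with Σ̂ the phase-3 target covariance.

Start values: β = 0 except out-degree at the logit of the observed mean
density; rates at observed per-actor change counts floored at 0.1. A
singular Jacobian fails loudly, naming the most collinear parameters; a
panel with no change between waves floors the rates and warns.

## Simulation engine

The micro-step loop exists twice: a pure-numpy loop using closed-form
change statistics (each effect contributes an O(n) delta vector over all
candidate alters; triadic effects share a handful of matrix–vector
products), and a numba-compiled kernel that mirrors it operation for
operation and consumes the identical pre-drawn randomness blocks
(fixed-size blocks of 256 draws — the size must not depend on θ, or the
common-random-number pairing would desynchronize). The two paths produce
bitwise-identical trajectories on test seeds; the kernel is ~30× faster
and is used whenever no per-step trace is requested. Without numba the
numpy loop runs everywhere.

## Synthetic cohorts

`jefferson_preset` encodes the published marginals of the study school:
48.46% female; grade shares 28.79/28.48/21.72/21.00 (9th–12th);
parental discussion 58.40%; depressive symptoms N(0.00, 0.53); parental
support N(−0.04, 0.29); parental monitoring N(−0.04, 0.10); home smoking
environment N(1.42, 0.73) clamped to [0, 3]; mother's education
9.18/49.62/36.61/4.59; limited nominations 4.82% then 0.41%; initial
smoking categories 42.01/21.31/9.02/27.66; mean out-degree 2.28
(= 2 225 ties / 976 actors); reciprocity index 0.30. Default synthetic
n = 150 (not 976) for desk-scale estimation speed; per-actor targets
scale with n.

Covariates are drawn independently across actors and variables — only
marginals are published, and no correlation structure is invented. The
initial network is drawn dyad-wise: each unordered pair lands in
{null, i→j, j→i, mutual} with the mutual mass set so the expected share
of reciprocated ties equals the 0.30 target and the total tie mass
matching mean out-degree 2.28; same-grade and same-gender dyads have
their tie rates boosted ×2 (a chosen default — the mixing matrix of the
original network is unpublished). Later waves come from the forward
simulator at a supplied θ. Limited-nomination actors are flagged (so the
ego effect has variance) but not degree-capped: the flag models an
instrument artifact, not a mechanism worth reproducing.

What passing tests on these cohorts do *not* show: robustness to
covariate correlation, degree heterogeneity beyond the dyadic scheme,
missing data (the loader enforces complete cases), or composition change.

## Validation experiments (`coevnet.validation`)

- **Oracle agreement** as described above (exact, tolerance 1e-9).
- **Micro-step law:** empirical choice frequencies over 10⁵ draws vs the
  exact logit probabilities; max binomial z-score ~1.7 at the shipped
  seeds.
- **Rate law:** mean opportunities per actor per period vs λ over 500
  replicate periods (Poisson check).
- **Parameter recovery:** 20 synthetic panels at n = 60, M = 3, network
  rates 4, out-degree −2, reciprocity 1.5, re-estimated with desk-scale
  settings (phase-1 40, polish batches 200/500/2000, Jacobian 100
  replicates, phase-3 3000 — sized so the t-ratio noise floor ~0.026 sits
  well under the 0.1 convention). Success = all parameters within 3 SE of
  truth and all |t| < 0.1; observed success rates 19–20 of 20 across
  master seeds.
- **Local hierarchy:** paired one-period simulations with (+1.0
  transitive triplets, −0.8 three-cycles) vs all-zero betas from the same
  start state and seeds; the transitivity index rises by ~0.15 (z ≈ 35
  over 200 pairs).

## Numerical and design choices

- Undefined descriptive indices (empty network, no two-paths) raise a
  typed error rather than returning 0; the descriptive table renders them
  as blanks with a warning.
- Transitivity two-paths require all three actors distinct (i→j→i loops
  excluded).
- The odds transform rounds to one decimal (100·(exp(β)−1)); significance
  markers use the two-sided normal approximation at 0.1/0.05/0.01/0.001
  with no small-sample correction.
- The in-degree activity curve exports only the two activity terms'
  per-tie contribution β₁d + β₂d²; other effects' contributions are
  deliberately excluded.
- The wave-1 smoking item of the original instrument was a 12-month
  frequency scale whose mapping to the 30-day categories is unpublished;
  only the day-count recode (0→0, 1–3→1, 4–21→2, 22–30→3) is implemented,
  and wave-1 recoding is left to the data provider.
- No endowment/creation split of the objective function, no conditional
  (change-count) simulation, no time-heterogeneity tests, no
  goodness-of-fit auxiliary statistics: evaluation effects and
  unconditional moments only.

## Known limitations

- The finite-difference Jacobian is the main fidelity gap versus
  score-function derivatives; it is adequate at desk scale but costs
  (p+1) simulations per replicate.
- Standard errors are plug-in (evaluated at θ̂); for weakly identified
  rate parameters they inherit the estimate's noise.
- Rates are constant across actors by design; covariate-dependent rate
  functions are out of scope.
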