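# Methods

## The problem being simulated

A social-network intervention trains a small set of pupils — *influence
agents* — hoping their behaviour diffuses through the class's friendship
network. The framework compares five ways of choosing those agents (top 15%
by in-degree, betweenness or closeness centrality; a random 15%; or nobody)
by simulating a year of activity diffusion in each class and measuring the
percent change of the class's mean physical activity level (PAL) from day 0
to day 364.

Because the underlying cohort study's data are not publicly deposited, the
package ships a synthetic-cohort generator that reproduces the *statistical
shape* of such a sample rather than any real class.

## Synthetic cohort

Defaults describe one cohort: 26 classes of 10–30 pupils, fully observed.

* **Activity.** Each pupil's true PAL is drawn from a normal distribution
  (mean 1.50, SD 0.55) truncated to [0.45, 4.27]; their true daily steps are
  `PAL/1.53 × 10,000`. Four 7-day waves of daily records are then simulated:
  the first and last day of each wave are partial (device hand-out/return),
  ~10% of interior days are invalid (short wear or < 1000 steps), ~5% of
  waves are lost entirely, and valid days carry day-to-day noise with SD
  0.3 × 5,730 steps. The measurement pipeline — drop boundary days, keep
  1440-minute days with ≥ 1000 steps, average waves with ≥ 3 valid days,
  rescale to PAL — recovers a baseline PAL per pupil; missing waves are
  imputed with the pupil's own mean over observed waves (class mean as a
  last resort). The day-level imputation machinery of the original
  measurement protocol is deliberately simplified to this per-pupil mean:
  the simulator consumes exactly one baseline PAL per pupil, so anything
  more elaborate cannot affect a downstream result.
* **Environment.** Family-affluence item scores sum to 0–13 (normal around
  4.0, SD 1.5, rounded and clamped); the environment score is the reflected
  sum divided by 6.5, clamped to [0, 2]. Higher env = lower affluence. The
  divisor 6.5 is forced by requiring the printed range [0, 2] given a 0–13
  sum; the underlying item count is not otherwise constrained.
* **Nominations.** A latent-popularity model: each pupil draws a gamma
  popularity weight (per-class shape drawn log-uniformly from [0.3, 3.0]),
  and the probability that any classmate nominates them on any one of the
  six questions is proportional to that weight, scaled (by per-class root
  finding) so that the expected edge density hits a per-class target drawn
  from [0.46, 0.90]. Nominations receive random waves, a quarter are
  duplicated into a second wave (deduplication removes them again), and
  every pupil nominates at least one classmate. The gamma-shape dispersion
  makes in-degree centralization controllable: across seeds the generated
  classes span densities ≈ 0.43–0.94 and in-degree centralizations
  ≈ 0.07–0.6, covering the descriptive ranges the design targets
  (density 0.46–0.90, in-degree centralization 0.07–0.40).

What the generator does **not** emulate: partial class participation,
cross-class friendships, longitudinal network change, measurement
reactivity, or any correlation between affluence and network position.
Passing tests therefore demonstrate properties of the *method* under a
plausible data-generating process, not findings about real school classes.

## Networks and statistics

Edges pool all four waves; the weight of u→v is the number of *distinct*
questions on which u ever nominated v, divided by 6, so weights lie on
{1/6, …, 1}. Centralities are computed on the unweighted digraph — observed
in-degree descriptives (integer counts up to 27) identify them as
nomination counts, and weights are reserved for the diffusion model.
Closeness uses incoming distances (how quickly a pupil is *reached*) with
the Wasserman–Faust correction, which is defined for every graph the
generator can emit. Freeman centralization divides the summed differences
from the most central pupil by the same sum in the maximizing star of equal
size: the inward star for in-degree ((n−1)²) and closeness (n−1, since star
leaves are unreachable and score 0), the reciprocal star for betweenness
(n−1). All three land in [0, 1] for every class size.

## Diffusion model

Each simulated day updates all pupils synchronously in three phases:

1. **Social influence** `Sᵢ = Σⱼ wᵢⱼ PALⱼ / Σⱼ wᵢⱼ`, summed over the peers
   pupil i *nominated* (out-edges). Nominations express attention, and
   attention is the channel through which modelling occurs; a pupil with no
   nominations feels no social pull. The weighted sum is accumulated peer by
   peer in a fixed order rather than via a matrix product, so replicate
   batches are bit-identical to single runs.
2. **Socio-environmental influence** `Δᵢ = (1−λ)Sᵢ + λ·a(envᵢ) − PALᵢ` with
   anchor `a(env) = pal_ref (2−env)/2`: affluent environments anchor high
   activity, deprived ones low.
3. **Threshold gate** — only influences exceeding the pupil's change
   threshold act: if `|Δᵢ| > θᵢ` then `PALᵢ ← clamp(PALᵢ + ηΔᵢ)`, else PAL
   is unchanged. Thresholds are per-pupil capable; the default is global.

The model is deterministic (no stochastic transmission), and with λ > 0 the
ungated map is a strict contraction, so trajectories plateau; with the
threshold they freeze exactly.

### Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| η | 0.05 /day | fraction of the influence applied per day (≈ multi-week transients) |
| λ | 0.15 | weight of the environment anchor vs the social signal |
| θ | 0.2 | dead-band half-width of the threshold gate (PAL units) |
| pal_ref | 7.0 | anchor extrapolated to env = 0; over the realized env range (≈ 0.6–2.0) anchors span ≈ 0–4.9 |
| pal_bounds | (0.1, 4.27) | hard clamp, upper bound = maximum observed PAL |
| days | 365 | day 0 (post-boost initial state) through day 364 |

η, λ, θ and pal_ref are calibration knobs, not estimates. They were fixed
once, by a coarse grid on three pilot cohorts, to place the model in the
regime the framework is meant to study: year-long trajectories that plateau,
all-condition success rates of order 10%, and genuine sensitivity to *who*
is boosted. Two features of that regime deserve note:

* the anchor mean (≈ 2.1 at the default env distribution) sits above the
  baseline PAL mean (1.5), producing the upward drift of every condition,
  control included;
* the threshold creates hysteresis, which is what makes seeding matter at
  all. In a strict contraction the year-end state is independent of initial
  conditions, so a boost could only inflate the day-0 denominator and every
  intervention would *trail* control. With a dead band, control classes
  freeze early while a boost pushes the boosted pupils' neighbourhoods over
  the threshold and the gains partially lock in. Central agents reach more
  of the class, hence centrality-based seeding outperforms random seeding.

Under these defaults, across 30 independent cohorts, mean success rates are
roughly: control 8.6, random 7.9, betweenness 8.7, closeness 9.5, in-degree
9.5 — centrality > random in all cohorts and interventions > control in 90%.

## Interventions

k = max(1, round-half-up(0.15 n)) agents per class. Centrality ties at the
selection cutoff are resolved uniformly at random among the tied pupils.
Boost: PAL × 1.17 at day 0, clamped. The random condition repeats
select-boost-run 100 times (run in lockstep as replicate columns) and
averages the success rates with a first-replicate-shifted mean, which is
exact when replicates coincide (e.g. zero boost). Day 0 of the success rate
is the *post*-boost state, so the statistic measures diffusion, not the
boost itself. Seeds: one master seed spawns per-class × per-condition child
streams; each cell's seed is logged in `results.csv` for replay.

## Evaluation

* **Mixed model.** success ~ condition with random class intercepts, REML
  (statsmodels `MixedLM`), cell-means coding. The four Helmert contrasts
  (interventions−control, centrality−random, (betweenness+closeness)/2 −
  in-degree, closeness−betweenness) are estimated as linear combinations of
  condition means; each t-test carries Satterthwaite degrees of freedom
  computed from the fitted variance components (g = c'(X'V⁻¹X)⁻¹c,
  df = 2g²/∇g'A∇g with A the inverse REML information). In the balanced
  design this lands on (k−1)(n−1) df — 100 at 26 classes — and is
  cross-checked against R's `lmerTest` on an unbalanced table in the test
  suite. Singular fits (e.g. zero class variance, or more parameters than
  observations in tiny cohorts) are reported as such, never dropped.
* **RM-ANOVA.** Mauchly's W, Huynh–Feldt ε (clamped at 1.0, standard
  practice so the reported ε stays interpretable) and the ε-corrected F for
  the condition effect, via pingouin.
* **Moderation.** The same model plus a standardized class-structure
  measure and its interactions with the contrast codes.
* **Correlations.** Pearson r of per-class success rates (4 intervention
  conditions) against the 4 structure measures, flagged at α = .05,
  two-sided. No multiplicity correction beyond the planned-contrast
  structure.

The random condition enters all models as its replicate average — one value
per class — matching the averaging built into the experiment stage.

## Numerical and testing choices

* All randomness flows from numpy `SeedSequence` spawning; identical seeds
  give byte-identical tables and bit-stable trajectories.
* Oracle tests recompute betweenness/closeness by explicit shortest-path
  enumeration on all 3-node digraphs and 500 random digraphs of ≤ 6 nodes
  (tolerance 1e-9), and centralization against star maxima evaluated with
  the same brute-force oracle.
* The type-I calibration of the interventions-vs-control contrast uses 300
  null replicates (observed rejection within [3%, 7%]); planted-effect
  recovery uses 200 replicates. The ordering-recovery check uses 30 cohorts
  of 26 classes. These sizes keep the full suite in a few minutes while
  leaving the binomial noise well inside the asserted bands.
* Degenerate inputs fail loudly: classes of < 2 pupils (density/centrality),
  < 3 (centralization), empty rosters, off-roster or self-nominations,
  infeasible density targets, zero-variance moderators, zero day-0 PAL.

## Known limitations

* The three-phase update is one defensible instantiation of the
  social/environment/threshold scheme; every functional choice (anchor map,
  λ, η, θ) is exposed in configuration so alternative forms can be swapped
  in without restructuring.
* The env→anchor map extrapolates beyond the realized env range; only
  anchors for observed env values matter to the dynamics.
* Success rates depend on the calibration regime; the framework supports
  claims about the *ordering* of selection strategies under stated
  assumptions, not about absolute effect sizes in real classes.
* Influence flows along out-edges (who you nominate influences you). The
  opposite convention (being nominated confers influence) is one config
  swap away but is not the default.
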