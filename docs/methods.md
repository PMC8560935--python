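# Methods

## Mussel–hog dynamics

The core state variable is mussel cover `M ∈ [0, 1]`, scaled so the
maximum standing crop is 1 (about 10% absolute marsh surface cover).
Cordgrass cover is treated as proportional to mussel cover (`V = q·M`,
`q = 1` by default), reflecting the facilitation between mussel mounds
and cordgrass; the model does not resolve vegetation dynamics separately.
Hog density `H` is a fixed forcing in relative units — hog population
dynamics, seasonality, and demographic noise are out of scope.

Regrowth is logistic at rate `g` (per year) and predation is
`M · f(M)`, with the per-mussel pressure `f` chosen by foraging mode:

* `none` — `f = aH`: hogs do not track mussels; losses are proportional
  to cover (trampling / haphazard consumption). Holling type I.
* `incomplete` — `f = aH·M/(M² + h²)`: classical prey depletion;
  per-mussel pressure vanishes as mussels thin out. Type III shape.
* `complete` — `f = aH/(M + h)`: depensation; hogs concentrate on the
  remaining mussels so per-mussel pressure *rises* as cover falls, with
  the half-saturation constant `h` bounding it at `aH/h`. Type II shape.

These are the minimal standard functional responses matching the three
verbally defined behaviors (constant, decreasing-with-scarcity,
increasing-with-scarcity per-mussel pressure); the rate function is a
plain callable so alternative response forms can be swapped in.

Parameter defaults: `g = 1 /yr`, `a = 1` cover·hog⁻¹·yr⁻¹, `h = 0.2`
(cover fraction), `q = 1`. These produce the worked closed forms used
throughout the tests: for `none`, the stable equilibrium is
`M* = max(0, 1 − aH/g)`; for `complete`, interior equilibria solve
`g(1 − M)(M + h) = aH` and the fold sits at `H_fold = g(1+h)²/(4a)`,
`M_fold = (1−h)/2` (tangency of the parabola with the predation level).

### Numerics

Equilibria are located by bracketing sign changes of `dM/dt` on a
2,001-point uniform grid over `[0, 1]` and refining by bisection to
1e−10; roots closer than 1e−6 are merged; `M = 0` is always included
(extinction is absorbing). Stability is classified from the sign of the
rate function at `M ± 1e−5`; degenerate points where the one-sided flows
do not both point inward (folds) are labelled unstable — the
conservative choice when the quantity at stake is resilience. A
dense-grid (10⁴ points) sign-scan root finder serves as an independent
oracle in the test suite.

## Recolonization and recovery time

A die-off disturbance leaves only randomly placed remnant discs of
vegetated mussel mound (radius 2 m by default, the order of observed
mound areas); all other cells are bare. Vegetation then regrows by
clonal lateral spread, modelled as Fisher–KPP reaction–diffusion

    ∂V/∂t = r_v·V·(1 − V) + D·∇²V

on a square lattice (5-point Laplacian, zero-flux boundaries, explicit
Euler at half the stability bound `Δx²/4D`, additionally capped at
`0.5/r_v` so cover cannot overshoot 1). Defaults: `r_v = 1 /yr`,
`D = 1 m²/yr`, 256 × 256 cells at 1 m, 5 replicate landscapes.
"Recovered" means 90% of unmasked cells at ≥ 0.5 cover; the threshold is
a configuration knob because "recolonized" has no canonical numeric
definition. With no remnant cover inside the domain the sentinel
`NO_RECOVERY` (∞) is returned — fronts must nucleate from remnants.

Recovery-time curves couple the two layers: for each hog density the
largest stable mussel equilibrium sets the remnant cover after die-off,
scaled by 0.10 (standing crop → absolute cover); past the fold the only
stable state is bare and recovery time is infinite.

Two numerical cautions, both visible in the tests: lattice Fisher fronts
travel a few percent slower than the asymptotic speed `c = 2√(r_v·D)`,
and pulled fronts converge to that speed only logarithmically in time,
so transit-time comparisons against `c` are made on domains long enough
that the transient is ≲15% (the front-speed check uses cells of
0.5·√(D/r_v)). A cellular-automaton backend (distance transform from
the seeds divided by the front speed) provides an independent
cross-check of front transit times.

## Patch metrics

Remnant-patch structure is measured by connected-component labeling of
binary rasters (continuous rasters thresholded at 0.5). Default
adjacency is 8-connected — a human circling visually contiguous patches
joins diagonal touches — with 4-connectivity available. Patch areas are
cell counts × cell area; background (mud) area is the unmasked
remainder, so patch areas and mud area sum to the unmasked extent
exactly. A minimum mapping unit (`min_area_m2`) can drop slivers, with
labels renumbered consecutively. With zero patches the mean patch area
is undefined (NaN), never zero. Labeling is verified against an
independent flood-fill oracle on randomized small rasters.

## Synthetic field designs

Every generator is a pure function of (configuration, seed) and returns
the data alongside a truth record, so estimation is always scoreable as
parameter recovery. Defaults encode the study's printed effect sizes:

* **Exclusion experiment** — 2 sites × (8 exclusion + 8 control) plots,
  9 quarterly visits over 2 years. Cover starts at exactly 50% (the
  experiment's imposed initial condition), then follows
  `clip(50 + rate·t + plot_effect + ε, 0, 100)` with arm rates 17.85
  and 6.85 % cover/yr. Noise defaults `sd_resid = 10`, `sd_plot = 5`
  (% cover) are back-calculated so the arm-rate standard error at this
  design is ≈1.3 %/yr, matching the reported uncertainty. A known
  consequence: ≈2% of exclusion-arm observations saturate at the 100%
  ceiling near the end of the experiment, which biases estimated
  exclusion rates down by ≈0.3 %/yr (≈1.6%). This is a property of the
  bounded response at the calibrated noise level, not of the estimator;
  the unit suite demonstrates both the bias and the estimator's
  unbiasedness on unbounded data.
* **Hog × mussel factorial** — 40 plots (2 sites × 4 arms × 5).
  Biomass arm means are derived from the reported contrasts rather than
  invented: hogs reduce biomass by 48% in mussel-addition plots with an
  absolute difference of −298.7 g/m², giving caged+added = 622.29;
  mussels raise caged biomass 1.5×, giving caged+none = 414.86; the
  −98.9 g/m² secondary contrast gives uncaged+none = 422.49. Mussel
  density is 18.7 /m² in caged-addition plots and exactly 0 wherever
  hogs can reach (total predation) or mussels were never added. Crab
  burrows: 32.6 (caged+added), 13.3 (uncaged arms), 32.6/3 (caged,
  no mussels — the tripling effect). Responses are Normal, truncated
  at 0 (a mild upward bias at small means, accepted and documented).
* **Mussel transect survey** — per hog-access level, marshes contribute
  5 creek-head and 5 platform transects; marsh-level mean totals 2427.4
  (hog-free) vs 141.6 (hog-accessed) are split 60/40 between creek head
  and platform and drawn as independent negative-binomial counts with
  dispersion (size) k = 2. Cordgrass association is
  Binomial(count, 0.99) without hogs vs Binomial(count, 0.60) with —
  both probabilities are approximations of reported "nearly 99%" /
  "around 60%" values. No marsh-level random effect is simulated.
* **Scat survey** — Bernoulli(0.821) over n = 190 samples.
* **Drone-style landscapes** — Poisson patch count (mean 75.7 high /
  16.0 low hog activity) and gamma patch areas (mean 13.9 / 47.9 m²,
  shape 2 — a right-skewed but not extreme size distribution), placed
  as non-overlapping near-circular discs with a one-cell gap on a
  400 × 400 grid at 0.5 m, so component labeling recovers the placed
  count exactly. Rasterization quantizes patch areas (sub-cell discs
  are stamped into their nearest cell), which depresses measured mean
  areas by a few percent at the high-activity patch scale.

Noise-free modes (`sd = 0`, `noise_free=True`) reproduce configured
truths exactly and are the identifiability contract for every
estimation stage. What the generators do **not** emulate: spatial
autocorrelation among plots, tidal/seasonal structure, marsh-level
random effects in counts, or edge-clipped patches — so passing recovery
tests demonstrate estimator correctness under the declared generating
process, not robustness to every feature of real field data.

## Estimation stages

All stages present a statsmodels-like surface: a model object built
from a tidy DataFrame, `fit()` returning a `FitResult` with named
estimates ± SE, contrasts, an interaction statistic, per-arm summaries
and a text `summary()`.

* **Recovery rates** — linear mixed model (ML) of percent cover on
  time × treatment with a random intercept per plot; arm rates are the
  arm-specific time slopes. A mean-of-per-plot-OLS-slopes estimator is
  computed as a cross-check; on balanced designs the two coincide.
  When the variance structure degenerates (noise-free data) the fit
  falls back to OLS, which has identical fixed-effect estimates on
  balanced data.
* **Factorial** — linear model of the response on hog × mussels (mixed
  with site intercepts where estimable, OLS fallback), with arm means,
  the uncaged−caged contrast under mussel addition, and the caged
  mussel-effect ratio.
* **Survey counts** — negative-binomial (NB2, log link; the
  conventional link for count models) regression saturated in
  hog access × marsh area. Saturation means fitted stratum means equal
  stratum sample means for any dispersion — the NB score equations
  enforce it — which makes predicted per-marsh totals robust to
  dispersion estimation; a Poisson fit is the degenerate-dispersion
  cross-check. Pairwise stratum contrasts carry Tukey-corrected
  p-values via the studentized range over the four strata. An all-zero
  stratum (no finite log-mean) triggers a flagged +0.5 continuity
  adjustment.
* **Association** — pooled binomial proportions per hog-access level
  with exact (Clopper–Pearson) intervals; strata with zero mussels are
  excluded with a warning. Bernoulli scat tables are recognized by
  their `contains_shell` column and reported as percent positive with
  the exact interval.

F-like interaction statistics are 1-df Wald tests with residual-based
denominator df; they are reported for completeness, not calibrated
against any external analysis of the original field data, whose F and
p values depend on data this package does not consume.

## Design choices made where the design was open

* Regrowth is modelled on mussel cover itself (vegetation proportional),
  the simplest reading consistent with a single-state-variable model;
  the rate function is pluggable should mussels instead be treated as
  purely predation-set.
* Recovery threshold (90% of cells ≥ 0.5), landscape size, patch radius
  and replicate count are configuration, since no numeric definitions
  exist for them; defaults are stated above.
* The ordering of per-mussel pressures across modes (complete > none >
  incomplete) is a *low-cover* statement: it provably holds for
  `M < h²` (with `h < ½`), and the incomplete response exceeds the
  constant response near its peak at `M = h`, so the property is tested
  in the scarce-mussel regime where it is mathematically true.
* Per-stage random seeds are derived as `blake2s(global_seed, stage)`,
  so adding a stage never shifts another stage's stream.

## Known limitations

* One state variable: no separate vegetation dynamics, no hog numerical
  response, no external mussel recruitment into the die-off area.
* The lattice reaction–diffusion engine under-speeds the asymptotic
  Fisher front by a few percent and carries the usual pulled-front
  logarithmic transient; recovery *times* are therefore slight
  overestimates at small domains.
* Mixed-model machinery is a contract, not a claim of equivalence with
  any particular field analysis: arm means, slopes and contrasts (the
  scored quantities) are robust to the random-effects details, but
  reported F statistics are not comparable across packages.
* The exclusion-experiment generator's bounded cover induces the small
  ceiling-censoring bias quantified above; estimators here are linear,
  not censoring-aware.
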