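# Methods

This note documents the models, assumptions and numerical choices behind
`soilwebflux`, the defaults of the synthetic-experiment generator, and what
the test suite does and does not demonstrate about real data.

## Steady-state energy fluxes

The flux model assumes each population is at steady state over the inference
window: energy lost to metabolism and to consumers is exactly balanced by
assimilated intake. For animal node `j` with total intake `G_j` (J/h),
population metabolic loss `X_j`, diet matrix `W` (column `j` gives the
proportions of `j`'s diet over all nodes) and diet-weighted assimilation
efficiency `ē_j = Σ_i e(type_i) W[i,j]`:

    ē_j · G_j = X_j + Σ_k W[j,k] · G_k

Basal nodes (plant, microbe, detritus) carry no balance equation; per-link
fluxes are `F[i,j] = W[i,j]·G_j`. Efficiencies attach to the *resource* type
("prey-level" convention): defaults 0.906 for animal prey and microbes, 0.545
for plant tissue, 0.158 for detritus, all configurable in `EfficiencyTable`.

**Solver.** Webs have tens of nodes, so the linear system
`(diag(ē) − W_aa) G = X` is solved densely (`numpy.linalg.solve`). A damped
fixed-point iteration `G ← (1−d)G + d(X + W_aa G)/ē` is kept solely as an
independent oracle for tests; it converges whenever every consumer's
predation loop gain `a_j/ē_j < 1` (guaranteed when animal diet fractions are
below `0.158/(1 − 0.906 + 0.158) ≈ 0.63` under the default efficiencies).
A singular system raises "degenerate food web"; any negative consumption rate
(beyond a 1e-12 relative tolerance absorbed as exact zero) raises an
infeasibility error naming the offending nodes — negative solutions indicate
a preference/metabolism combination the user must see, so they are never
clipped. Balance residuals are reported per consumer, relative to
`max(X_j, ε)`; the direct solve leaves them at machine precision, far below
the 1e-8 contract asserted in tests.

**Aggregation.** The four trophic-function fluxes (predation, herbivory,
microbivory, detritivory) are row sums of `F` grouped by the donor node's
type; the *total* flux is defined as their sum, which makes the
decomposition exact by construction rather than up to rounding.

**Metabolism.** Individual metabolic rate is Arrhenius–allometric,
`exp(ln x0 + a·ln M − E/(kT))` J/h with `M` in mg, `k` the Boltzmann
constant in eV/K, and per-taxon coefficients `(ln x0, a, E)` from the trait
table (the defaults in the synthetic pool are in the vicinity of published
invertebrate regressions, e.g. `ln x0 ≈ 23`, `a ≈ 0.7`, `E ≈ 0.69 eV`).
Temperature is a single configured value for all mesocosms — the facility
climate is controlled — defaulting to 288.15 K (15 °C). Population loss is
the individual rate at the population's mean body mass times density; with
`a < 1` this makes equal biomass packaged in smaller bodies metabolically
more expensive, the mechanism linking the CWM body-mass shift to higher
community flux.

## Diet matrices

Consumer columns are assembled from the trait table's general diet fractions
over {animal, plant, microbe, detritus}. The animal fraction is split over
the prey present in that mesocosm with weights

    link(M_pred, M_prey) × agility_mod × defense_mod × stratum_overlap × prey biomass

where `link` is the quadratic-logistic mass-ratio model
`logistic(b0 + b1 r + b2 r²)`, `r = log10(M_pred/M_prey)`, `b2 ≤ 0`. The
default coefficients `(−1.8, 2.0, −0.5)` are illustrative — optimum
predator:prey mass ratio 100, peak link probability ≈ 0.55 — and real
analyses should supply coefficients estimated for their fauna. The agility
modifier is `(1 − agility)·k + (1 − k)` with strength `k = 0.5` by default
(k = 0 disables agility, k = 1 makes maximally agile prey uncatchable);
defended prey are discounted by a single factor (default 0.5); stratum
overlap is a symmetric 3×3 matrix over (epigeic, hemiedaphic, euedaphic)
defaulting to 1 on the diagonal, 0.5 between adjacent strata, 0 otherwise.
These modifier forms are declared package defaults, not field estimates.

Basal fractions are split uniformly over same-type basal nodes (or
biomass-proportionally when pool biomasses are configured); with the default
one-node-per-type web this is inert. A diet component absent from the
mesocosm — no basal node of that type, or all prey weights zero — is
redistributed proportionally over the remaining components, keeping every
consumer column stochastic without inventing resources; a consumer left with
no feasible resource at all is an error. Self-predation is excluded
(cannibalism is not representable at taxon resolution).

## Communities from raw samples

Densities are area-scaled from core counts (`count × mesocosm area / total
core area`); nematode counts, made on animals extracted from 20 g fresh
soil, are converted through the dry-soil fraction and dry bulk density to
the sampled layer (mesocosm surface × 10 cm depth). No extraction-efficiency
corrections are applied. Length(–width)–mass regressions are applied *per
measured individual* and back-transformed masses averaged arithmetically
(the mass of the mean length would be biased for convex allometries). A
taxon unmeasured in some mesocosm falls back to its density-weighted
cross-mesocosm mean mass, then to the trait table's reference mass.

Community metrics: biomass is `Σ density × mean mass`; CWM body mass is the
abundance-weighted mean of `ln(mass)`, back-transformed — a geometric-style
mean chosen because body masses span six orders of magnitude and responses
are analysed on the log scale (whether the original field analysis weighted
by abundance or biomass is not documented; this choice is fixed here);
diversity is the exponent of Shannon entropy of relative biomass shares.

## Sensitivity analyses

*Fixed body mass*: every population's mass is replaced by its taxon's
cross-mesocosm density-weighted average (unweighted optional) and the whole
pipeline re-run, separating within-taxon mass shifts from compositional
change. When a taxon's mass is already identical everywhere the shared value
is passed through exactly (no re-averaging), so the operation is a true
fixed point on mass-homogeneous inputs.

*Perturbation*: independent mean-one lognormal factors with configurable
coefficients of variation multiply each population's biomass and metabolic
loss per draw (the latter relaxing the steady-state assumption); the
preference matrix is rebuilt per draw because prey-biomass weighting responds
to the biomass perturbation. Draws are seeded and reproducible.

## Synthetic experiments

The generator emulates the nested design — 6 blocks × 4 EcoUnits × 4
mesocosms (soil history × plant history crossed within every EcoUnit),
plant richness {1, 2, 3, 6} assigned once per EcoUnit, 96 communities — and
emits raw records in exactly the format the community builder reads.

**Taxon pool.** 30 taxa: 10 nematode genera (reference masses 8e-5–5e-3 mg,
microbivores, root feeders, a predator and an omnivore), 11 mesofauna
families (collembola, oribatid and predatory mites, enchytraeids;
2e-3–1e-1 mg, with defended oribatids and agile collembola) and 9
macrofauna families (earthworms, myriapods, spiders, beetle larvae,
isopods; 4–40 mg, two taxa with length–width–mass regressions). Baseline
expected abundances per mesocosm are class-anchored (2e5 / 5e3 / 1e2
individuals per taxon for nematodes / mesofauna / macrofauna) with a
per-taxon lognormal dispersion (sd 0.6 on the log scale) drawn once per
experiment.

**Imposed effects.** Soil history multiplies expected community biomass by
`exp(0.41)` and CWM body mass by `exp(−0.64)` (defaults; any multipliers can
be configured). The body-mass effect is strictly compositional: within each
fauna class, abundances are exponentially tilted toward smaller-bodied taxa
(class totals preserved), with the tilt exponent solved by root-finding so
the expected abundance-weighted CWM shift matches the target exactly; a
global abundance rescaling then restores the biomass target exactly. The
tilt saturates at the smallest taxon per class, so a target beyond the
achievable range raises a clear error rather than silently under-shooting.
Individual body masses are never shrunk. Plant history and richness effects
default to neutral.

**Noise.** Mean-one lognormal noise (cv 0.3) per taxon per mesocosm on
expected abundances; block (sd 0.1) and EcoUnit (sd 0.15) random intercepts
on the log scale, giving the nested bootstrap true hierarchy to recover;
Poisson sampling of realized core counts; lognormal within-taxon body-size
variation (cv 0.2) among measured individuals (up to 10 per taxon per
mesocosm).

**What the generator does not emulate:** extraction inefficiency,
identification error, within-taxon body-mass responses to treatment,
between-mesocosm temperature differences, plant dynamics, or any real
trait values — the pool's diets, agilities and regression coefficients are
plausible but invented. Passing recovery tests therefore demonstrates that
the estimators are correct under the stated noise model, not that the
field-data conclusions are reproduced.

## Contrasts

Uncertainty respects the nesting through a two-stage nonparametric
bootstrap: blocks resampled with replacement, then EcoUnits within each
sampled block, each resampled EcoUnit contributing all four of its
mesocosms. Treatment means, the six pairwise differences of the four-level
history factor and the pooled soil-/plant-history main effects are
recomputed per draw; percentile intervals (95% and 90%) summarise the
draws. All contrasts derived from one draw set share the same resampling,
so antisymmetry holds exactly per draw. Responses are log-transformed by
default. Percentile intervals stand in for HPD intervals; for the
near-symmetric bootstrap distributions encountered here the difference is
negligible.

Two properties of this scheme are worth knowing. First, resampling both
levels with replacement over-counts within-block variation, making the
intervals mildly conservative: on neutral synthetic data the 95% interval
excludes zero in roughly 2% of replicates rather than 5%. Second, with only
six blocks the block stage is coarse; the intervals should be read as
honest-but-conservative rather than exactly calibrated. Model simplification
mirrors standard practice: richness and interaction terms are omitted from
the default contrast (the bootstrap compares raw treatment means, which are
balanced over richness by design).

Flux–structure slopes (`structure_slopes`) are ordinary least-squares
log–log slopes recomputed per bootstrap draw. The default is the raw
elasticity (so exact proportionality of flux to biomass yields slope 1);
`standardize=True` instead scales the slope per SD of the log predictor.

## Problem sizes and determinism

Default test and acceptance runs use webs of ≤ 33 nodes, 1,000-web random
suites for conservation/oracle checks, 2,000 bootstrap draws for reported
contrasts (1,000 within replicate loops), and 200 replicate experiments for
recovery and calibration checks — sizes at which every check completes in
seconds to a couple of minutes on one core. All random draws flow from
explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

- Trait values, link-model coefficients and modifier weights are user
  configuration; the shipped defaults are documented illustrations.
- One basal node per resource type by default; basal pool dynamics are not
  modelled (the steady-state snapshot is the object of interest).
- The bootstrap replaces hierarchical Bayesian fitting; point estimates are
  comparable to posterior means under weak priors, but no Student-t
  robustification or posterior predictive checking is provided.
- No dynamic (time-stepped) food-web simulation.
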