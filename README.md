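# soilwebflux

Energetics of soil food webs in nested mesocosm experiments.

`soilwebflux` is for ecologists who want to quantify the *multitrophic
functioning* of a soil fauna community — the total energy flowing through its
food web, decomposed into predation, herbivory, microbivory and detritivory —
and to test how experimental treatments change it. It implements the complete
chain from raw faunal sample records to treatment contrasts:

1. **Community assembly** — counts in class-specific soil cores (15 cm Ø for
   macrofauna, 5 cm Ø for mesofauna, three pooled 2 cm Ø cores for nematodes,
   all to 10 cm depth) are scaled to whole-mesocosm densities; body masses come
   from group-specific length(–width)–mass regressions over up to 10 measured
   individuals per taxon, or from reference masses for nematodes.
2. **Diet matrices** — each consumer's diet is a column of proportions over
   the web's nodes. General diet fractions over {animal, plant, microbe,
   detritus} come from a trait table; the animal fraction is refined by the
   predator–prey mass-ratio niche model
   `P(link) = logistic(b0 + b1 r + b2 r²)`, `r = log10(M_pred / M_prey)`,
   together with prey agility, defenses, vertical stratum overlap and relative
   prey biomass.
3. **Steady-state fluxes** — writing `G_j` for consumer `j`'s total intake,
   `X_j` for its population metabolic loss (Arrhenius–allometric:
   `exp(ln x0 + a ln M − E/(kT))` per individual, times density) and `W` for
   the diet matrix, the balance `ē_j G_j = X_j + Σ_k W[j,k] G_k` with
   diet-weighted assimilation efficiency `ē_j = Σ_i e(type_i) W[i,j]`
   (defaults: 0.906 animal/microbe, 0.545 plant, 0.158 detritus) is solved
   directly; per-link fluxes are `F[i,j] = W[i,j] G_j`.
4. **Contrasts** — treatment means, pairwise differences of the four-level
   community-history factor (soil × plant history) and flux–structure slopes,
   with uncertainty from a two-stage hierarchical bootstrap (blocks, then
   EcoUnits within blocks), and a clear/marginal/unclear decision rule from
   exclusion of zero at 95%/90%.

A synthetic-experiment generator reproduces the nested design (6 blocks × 24
EcoUnits × 96 mesocosms, plant richness 1/2/3/6) with *known*, configurable
treatment effects — by default soil history raises community biomass by
`exp(0.41)` and lowers community-weighted mean (CWM) body mass by
`exp(−0.64)` through a compositional shift toward smaller-bodied taxa — so
every estimator can be validated against ground truth without field data.

## Worked example

```python
import soilwebflux as swf

exp = swf.generate_experiment(seed=1)                       # 96 mesocosms
table = swf.run_pipeline(exp.samples, exp.traits, exp.design, exp.cores)
res = swf.pairwise_contrasts(table, "biomass", n_boot=2000, seed=7)
soil = next(r for r in res if r.level_a == "soil_history+")
print(f"{soil.estimate:+.3f}  95% [{soil.ci95[0]:+.3f}, {soil.ci95[1]:+.3f}]"
      f"  -> {soil.decision}")
```

prints

```
+0.437  95% [+0.346, +0.522]  -> clear
```

the estimated log-scale soil-history effect on community biomass for this
realization (truth imposed by the generator: +0.41), with its hierarchical
bootstrap interval excluding zero — a "clear" difference under the interval
decision rule. The same call with `"cwm_body_mass"` recovers the imposed
−0.64 body-mass shift, and `swf.structure_slopes(table, "total_flux",
"biomass")` gives the log–log elasticity of flux to standing biomass.

Or from the shell:

```bash
soilwebflux simulate --seed 3 --out exp/
soilwebflux analyze exp/ --out responses.csv
soilwebflux contrast responses.csv --response total_flux --out contrasts.csv --slopes
```

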