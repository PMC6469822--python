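# Methods

This note records the model conventions, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Study design emulated by the synthetic generator

The generator (`aggexpo.synthetic`) produces the four inputs a real
assessment would draw from national surveys:

1. **Field survey** — a stratified sample of sprayed fields per crop, each
   with an area (ha), a raising factor (the survey weight extrapolating the
   field to the national total), a count of residents living adjacent, and
   the set of CAG compounds applied over the year with their total amounts.
   Applied amounts are constructed as dose rate × area, so dose-rate
   derivation has an exact known inverse. Resident counts are Poisson per
   field; a configurable share of fields has the count missing, standing in
   for fields without a recorded postcode. A postcode/census layer is not
   modelled — counts are generated per field directly.
2. **Dietary survey** — a multi-day consumption diary (default 4 days, the
   typical national-diary length) for 1724 adults with normal bodyweights
   truncated at 30 kg; each food's daily amount is Bernoulli(consumption
   probability) × log-normal grams.
3. **Residue concentrations** — log-normal samples per (food, compound)
   pair around a configured mean grid, with a Bernoulli non-detect flag
   (default 70%, typical of residue monitoring); non-detects carry value 0.
4. **Hazard table** — log-normal NOAELs (median 10 mg/kg bw/day); a
   configurable share of compounds (default 20%) has only a LOAEL, drawn a
   study-spacing factor of 2–5 above the NOAEL. Exactly one reference
   compound, which always keeps its NOAEL.

Defaults are set once to the study conditions: four crops (wheat, sugar
beet, potatoes as arable; dessert apples as orchard), 1–12 compounds per
field, a 52-compound assessment group, a UK-scale population of 63.2 M with
82.4% adults. Per-crop resident means are sized so the raised national
proportions land near the scenario shares (wheat ≈ 8.5% of adults, ≈10% in
total); the residue grid is sized so chronic dietary totals sit near a
quarter µg/kg bw/day for a typical adult. Where the design gave no
distributional form (dose rates, areas, raising factors, consumption), the
package uses log-normals with field-plausible medians; all are
config-exposed.

All randomness flows from one master seed through fixed integer stream keys
(`aggexpo._rng.STREAMS`), so any stage can be regenerated in isolation and
adding a stage never shifts the draws of another.

## Usage-survey processing

Dose rate = applied amount / sprayed area (kg/ha), per field and compound;
zero-amount rows are dropped, and applications can be restricted to a
caller-supplied CAG list first. Missing resident counts are imputed by
resampling, with replacement, the observed counts of fields of the same
crop (raising factors are left untouched by imputation). National resident
counts per crop are Σ_fields raising factor × residents × adult fraction;
proportions are reported relative to the adult subpopulation, where the
adult fraction (default 0.824) cancels. Proportions summing above 1 are an
error: an individual lives beside at most one crop.

## Spray-exposure surrogate

The resident exposure simulator is a deliberately simple parametric
surrogate with the scenario geometry of the two sprayer types; it is not a
drift-physics model, and any externally generated unit-dose table in the
same format can be substituted for it. Seasonal deposition at distance
`d ~ Uniform(2, 20) m` from the field edge is

```
w · Σ_{p=0}^{P-1} c · (d + 24 p)^(-e)        (P = 3 boom passes, arable;
                                              P = 1, orchard)
```

with `w` a log-normal wind multiplier (mean 1, CV 0.4). The deposition is
split across routes by fixed fractions (dermal 1 : inhalation 0.004 :
oral 0.0008, strictly ordered) and divided by the 90-day spraying-season
averaging period to give chronic daily mg/day per 1 kg/ha applied. All
three routes share the same `(d, w)` draw, which is this package's contract
for the positive between-route correlation a shared physical process
produces. Exposure is exactly linear in applied dose, so triples
standardised at any dose rescale multiplicatively (0.2 → 1 kg/ha is ×5),
and halving the averaging period exactly doubles the chronic triple.

The drift coefficients (`c` = 45 arable, 225 orchard, exponent 0.95/0.85)
absorb all unit conversions between areal drift deposition and mg/day on a
person; they are sized so that the simulated population lands on the
reported resident-exposure scale — dermal contributing ≈40% of the
RPF-weighted population total against ≈60% dietary, with a strongly
spray-dominated upper tail. The orchard scenario differs only by settings
(stronger drift from a very fine spray, no pass structure). Vapour-driven
inhalation is folded into the fixed route fraction; no climate scenario is
modelled.

The two-dimensional variant perturbs the drift coefficient and exponent per
uncertainty realisation by log-normal factors with mean 1 (CVs 0.3 and
0.05), held fixed within a realisation, and uses common random numbers for
the variability draws across realisations — so a degenerate uncertainty
distribution reproduces the one-dimensional simulator exactly.

## Non-dietary surveys and linking

Per crop, a fixed number I = 2000 of positive-exposure residents is
simulated; each draws a field uniformly (optionally weighted by raising
factor × residents) and, per compound of that field, an independent
unit-dose triple scaled by that compound's dose rate. One triple per
(individual, compound) reflects that a field's yearly amounts of different
compounds need not come from the same spray events. Each crop forms one
survey; individuals belong to exactly one survey; the combined survey set
carries a zero-proportion parameter `1 − resident proportion` per survey.

Dietary individuals are linked by one uniform draw: unlinked with
probability `1 − Σ crop weights`, otherwise to a survey with probability
equal to its crop weight and a uniformly random simulated resident within
it. Non-dietary mg/day values are converted with the *dietary* bodyweight
(×1000 / bw, × per-route absorption, default 1); RPF weighting is applied
only after linking and aggregation, never stored in input files.

Weighted population summaries use an exact atom at zero for the unexposed
mass and, within the exposed part, linear interpolation over
cumulative-weight midpoints (reducing to numpy's `linear` quantile method
for equal weights). Raw exposure columns are never RPF-scaled; only
contribution shares are.

## Mixture prioritisation

The SNMU decomposition factors the RPF-weighted individuals × compounds
matrix into sequential rank-one nonnegative terms constrained below the
running residual (underapproximation), deflating after each term. The
rank-one subproblem is solved over the compound direction `h` alone — the
optimal feasible `w` is closed-form per row — using Lagrangian-relaxed
alternation for candidate directions and a derivative-free direct search
for the polish; every candidate is polished on small matrices, the top
three (with a bounded evaluation budget) on survey-scale ones. The solver
is deterministic; the seed only breaks exact ties.

Conventions fixed by this package where the method family leaves them open:

* **Variance explained** of a term is its Frobenius-reduction share
  `(||R||² − ||R − w hᵀ||²) / ||X||²` on the raw (uncentred) matrix,
  per component. These shares telescope — they sum to at most 1 and are
  non-increasing in rank when each solve is optimal — and equal the
  `||w hᵀ||²/||X||²` convention whenever the term fits its support exactly.
* **Sparsity** is a post-fit relative threshold: weights below
  `sparsity × max(weight)` (default 5%) are zeroed and the term refit, so
  sparsity 0 is exact and the rule is scale-invariant.
* Zero columns are pruned before decomposition.

MCR filtering (threshold 2 by default, per the prioritisation variant that
focuses on individuals exposed to genuine mixtures) drops rows with
MCR ≤ threshold before the decomposition; component exposure summaries
(mean, median, P5, P95) are computed on the retained subpopulation from the
non-RPF-scaled matrix. Both the full-population and filtered reporting
modes are available, k defaults to 3 mixtures.

## Two-dimensional Monte Carlo

Each of the (default 100) uncertainty cycles bootstrap-resamples the
dietary individuals with replacement — resampling is at the individual
level, so an individual's diary days and bodyweight travel together — draws
one non-dietary uncertainty realisation uniformly, re-links and
re-aggregates, and records the population percentiles. The 2.5th and 97.5th
empirical quantiles over cycles form the interval; the nominal estimate is
a separate full run at the central realisation (the one whose mean
RPF-weighted record total is the median across realisations), so the
interval need not bracket it. Within-cycle spread is variability,
between-cycle spread is uncertainty; the two are never pooled.

## Numerical and I/O conventions

* Empirical percentiles: linear interpolation (numpy default), documented
  and fixed; weighted variants as above.
* CSV dialects: UTF-8, dot decimal, mandatory header in fixed column order;
  the non-dietary dialect is `idIndividual, idSurvey, compound, Dermal,
  Oral, Inhalation, idUncertaintySet` with a survey-properties sidecar
  carrying crop weights and zero-proportions. Write-then-read round-trips
  are lossless; malformed rows are reported with their line number.
* Configuration objects validate eagerly and name the offending field.
* Identical config + seed yields byte-identical report bundles.

## Problem sizes

The analysis scripts run the study at full scale: 500 fields per crop,
17,500 unit-dose draws per scenario, 2000 simulated residents per crop,
1724 dietary individuals, 100 × 1000 draws in the uncertainty
demonstration. The test suite exercises the same code on smaller
populations (tens of fields, hundreds of individuals, 2000-draw pools) and
checks the stochastic calibrations at the replicate counts stated in the
tests; the 2DMC coverage check uses 200 replicated experiments of the
1724-adult survey with 100 cycles each against a 60,000-person
simulation of the generating process.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the real data —
stratified weights, sparse co-occurring applications, diary-based diets,
heavy non-detect shares, a small linked subpopulation with a heavy-tailed
spray exposure — but not its content: crop statistics, the food hierarchy,
true residue co-occurrence patterns and the real CAG's potency spread are
all simplified. Passing tests therefore demonstrate that the pipeline's
arithmetic, linking probabilities, decomposition and uncertainty intervals
are correct under known generating conditions; they say nothing about the
realism of any absolute exposure level. The synthetic diet is more
mixture-rich than a real one (most individuals carry many compounds, so
MCR values run higher than in real assessments), which makes the MCR filter
less selective here than on real data.

## Known limitations

* The spray surrogate has no boom-height/nozzle/droplet physics, no
  volatilisation model and no acute (single-day) tier; its between-route
  correlation is perfect by construction, an upper bound on the real one.
* The optimistic residue model only; the conservative upper-bound residue
  treatment is out of scope.
* RPF uncertainty is not propagated (hazard values enter as fixed).
* Dose additivity is assumed throughout; synergy/antagonism is out of
  scope.
* The SNMU rank-one solve is a nonconvex search; optimality is verified
  against brute force only at small matrix sizes, and on survey-scale
  matrices the bounded polish budget trades exactness for speed.
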