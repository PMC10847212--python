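# Methods

This note documents the models, conventions, and design choices behind the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Label vocabulary

The working vocabulary is the 18 FBP fuel-type codes (O-1a/O-1b held
distinct) plus NF (non-fuel). All reporting uses the **collapsed** view in
which O-1a/b merge into O-1 — 17 fuel codes plus NF — because grass curing
state is a seasonal attribute, not a mapped one. A separate deseasonalized
view (D, M) exists for analyses that must not distinguish leafless/green
variants; reporting uses the leafed representatives D-2/M-2. Seasonal
percent-conifer and curing rate modifiers are out of scope: they modify
predicted fire behavior within a fuel type, not the categorical label this
package compares.

## Survey generator

`synthetic_survey.generate_field_plots` emulates a stratified-random survey
of 1-ha plots. Defaults are the study conditions: six strata — grassland
0–5 % canopy cover (n=9), woodland 6–15 % (n=11), open forest 16–35 %
(n=11), closed forest 36–59 % (n=14), dense forest ≥ 60 % (n=19), and
recently harvested (harvest year ≥ 2000, n=12) — totalling 76 plots, field
season 2022. Stratum counts are exact, never expected values.

Within-stratum distributions are not published anywhere, so they are modeling
choices, fixed once:

- canopy cover uniform over the stratum interval (harvested plots uniform on
  [0, 50] %, reflecting regenerating cutblocks);
- canopy height ~ N(4 + 0.22·cover, 4) m truncated at 0 (harvested plots
  capped at a uniform 0.5–8 m regeneration height); age ~ N(30 + 1.2·cover,
  25) years; live density ~ N(30·cover, 400) stems/ha — magnitudes chosen so
  dense stands fall in the 1 000–3 000 stems/ha range typical of infilled
  interior forests;
- leading/secondary species drawn from per-zone mixtures (Interior
  Douglas-fir, Montane Spruce, and Engelmann Spruce–Subalpine Fir zone
  analogues) dominated by Douglas-fir, ponderosa pine, lodgepole pine,
  western larch, spruce, subalpine fir, and trembling aspen;
- plots placed uniformly in a 20-km planar square; `min_spacing` optionally
  enforces a minimum pairwise distance (used by the closed-loop
  configuration).

What the generator does **not** emulate: spatial placement relative to
roads, variable-radius subplot mechanics, within-plot heterogeneity,
non-harvest disturbance dynamics, and any covariance between attribute
errors. Passing tests therefore demonstrate the correctness of the pipeline
arithmetic and its contracts, not that real surveys would show these
agreement levels.

## Inventory bias model

`apply_inventory_bias` produces the paired inventory view:
`inventory = field + mean_offset + N(0, noise_sd)`, then clipping to the
attribute's legal range (percentages to [0, 100], heights and densities to
≥ 0). Defaults encode the measured photo-interpretation bias — inventory
underpredicts canopy cover by 9.4 % (SD 19.7 %), canopy height by 3.6 m
(SD 9.2 m), and live density by 765 stems/ha (SD 1102 stems/ha). Three
deliberate simplifications:

1. **Noise is Gaussian and attribute-independent.** Only the mean and SD of
   paired differences are known; no cross-attribute covariance is published.
2. **The published SD is of paired differences**, not separable field and
   inventory error components; the generator attributes all of it to the
   inventory side. Any decomposition with the same difference distribution
   is observationally equivalent for the statistics computed here.
3. **Clipping, not resampling**, handles range violations, so the configured
   offset is the *pre-clip* mean. Parameter-recovery checks are run where
   clipping is rare (mid-range cover, large heights/densities); near a bound
   the realized mean offset is attenuated, which the clip-fraction report
   quantifies.

The inventory view also recomputes the landcover density class from the
biased cover, so categorical landcover disagreement emerges mechanically.

## Rule engine

`fuel_rules` is an ordered, declarative rule list: each rule is a
conjunction of predicates (=, ≠, <, ≤, >, ≥, in-set, not-in-set,
absent, present) over record attributes and derived attributes
(density label, stratum, years since harvest, deciduous percent, mixedwood
flag, recent-harvest flag). First match wins — mirroring decision-tree
traversal — and the audit trail records every rule evaluated.

Conventions fixed for reproducibility:

- thresholds quoted as "greater than" are strict (cover > 55 %, height >
  12 m, not logged in the past 6 years); quoted ranges are closed on both
  ends (mixedwood 20–80 % deciduous; density bins dense 61–100, open 26–60,
  sparse 10–25, non-treed < 10);
- covers falling between stated integer bin edges resolve to the upper bin;
- "recently harvested" means years-since-harvest (from a configurable
  reference year, default 2022) inside the slash window [0, 7] years — the
  upper bound is a config value inside the documented 5–10-year range;
- `larch_as_deciduous` (default true) adds western larch to the broadleaf
  fraction, reproducing the provincial convention that routes pure larch to
  D-1/D-2 and mixed conifer–larch stands to M-1/M-2; toggled off, no
  conifer+larch stand can reach a deciduous or mixedwood code (a property
  test enforces this);
- a missing attribute fails every value predicate and matches only `absent`;
- rule sets must carry a fallback (default NF); loading a fallback-free rule
  set is an error, because totality cannot be proven symbolically.

The shipped `default_ruleset.yaml` is a **fixture**: it encodes only
branches of the provincial process that are publicly documented (slash
assignment by harvest recency with species-specific slash types, non-treed
grass, deciduous > 80 %, mixedwood 20–80 %, the dry-zone Douglas-fir C-7
composition branch, immature/mature pine split at 12 m, spruce-fir,
cedar-hemlock as C-5 by operational convention) plus structural
fall-throughs. Process numbers are local to the rule set; the official
identifiers are not public. `validate_ruleset` reports rules provably
shadowed by earlier rules (interval/set containment, conservatively — only
certain containment is flagged), unknown attribute names, and, given a plot
sweep, the fallback fraction.

## Grids and scaling

Grids are north-up, row-major, integer-coded through a fixed code↔integer
registry, serialized as Esri ASCII (text). Cell membership is half-open:
a cell covers [left, left+size) × [bottom, bottom+size), so a point on a
shared vertical edge belongs to the right cell and on a horizontal edge to
the upper cell. Rasterization assigns each cell the code of the **last**
polygon in list order covering its center (boundary contact counts). The
cell-center rule is the simplest well-defined choice; the real provincial
and national rasterization rules are not published, so the 250-m product's
mixed-pixel behavior here is a stand-in. The mechanism of scaling loss —
patches small relative to the coarse cell losing their identity — is
exercised directly by a monotonicity test.

## Agreement statistics

Confusion matrices cross-tabulate predicted vs reference labels over the
collapsed vocabulary; overall agreement is trace/n; NF is an ordinary label.
Per-type mismatch = row total − diagonal, with percent of the row total
rounded to the nearest integer; suitability/confidence percentages are
rounded to one decimal; all rounding is half-away-from-zero, chosen to make
published-style tables digit-exactly recomputable from emitted counts.
Frequent mismatches list off-diagonal cells ≥ a threshold (default 3),
sorted by count with lexicographic tie-breaks. Cohen's kappa is available
on the matrix but sits outside the reported surface.

Mismatch typing compares per-code structural and compositional classes from
a trait table. The shipped table is a synthetic rubric derived from the FBP
descriptive fuel-type names; codes equal after collapse are "none", and
distinct codes whose classes tie on both axes (seasonal pairs) are typed as
composition mismatches.

Paired one-sided *t*-tests use t = d̄/(s/√n), df = n − 1, with the
alternative "field > inventory" by default (underprediction); the direction
stays configurable because only the word "underpredicted" pins it down.
A summary-statistic route reproduces the identical contract without raw
vectors. No multiple-testing correction is applied across the three
attribute tests, matching the reported analysis; with three tests at these
effect sizes the conclusion is unaffected, but users adding attributes
should correct. n < 2 or zero-variance differences raise a degenerate-input
error rather than returning NaN.

## End-to-end pipeline

`run_synthetic` chains: survey → bias → rule-engine classification of the
field view (decision-tree labels) and of the inventory view; the inventory
labels are painted onto square polygons (default half-side 150 m) around
each plot and rasterized at 50 m (provincial analogue) and 250 m (national
analogue), then re-extracted at plot coordinates; the subjective field call
is the decision-tree label retained with probability `field_agreement_rate`
(default 0.25, the decision-tree agreement level) else resampled. All
randomness derives from one seed through spawned substreams; rerunning a
config is byte-identical (verified by manifest digests).

The closed-loop identity: with a zero bias model, `field_agreement_rate` =
1.0, and `min_spacing` = 650 m (so each plot's 300-m polygon covers the
center of its own 50-m and 250-m cells and no neighbour's polygon can
overwrite them — the worst-case center offset in a 250-m cell is 125√2 ≈
177 m < the spacing guarantee), every one of the five axes must report 100 %
agreement. This is the pipeline's strongest self-consistency check and is
asserted in the acceptance suite.

Default problem sizes: 76-plot surveys for pipeline runs, 10 000 plots for
Monte-Carlo bias recovery (3-standard-error bands), 40 replicates for the
paired-*t* power check — sizes at which the Monte-Carlo error is far below
the tolerances being asserted while the whole suite runs in seconds.

## Known limitations

- The default rule set is not the official provincial tree; agreement levels
  produced by the synthetic pipeline are properties of this fixture and the
  generator, and are not expected to match (and do not match) field-study
  agreement levels. The reported-value reproduction in
  `scripts/acceptance.py` therefore works from published summary tables, not
  from the synthetic pipeline.
- Whether the 6-year "recently logged" guard of the C-7 branch interacts
  with the 5–10-year slash window is not publicly resolvable; they are
  independent config values here.
- Species percentages cover only the two leading species; the unallocated
  remainder is treated as neither broadleaf nor larch in the deciduous
  derivation.
- No geodesy: coordinates are planar metric; no reprojection, no NoData
  semantics beyond NF.
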