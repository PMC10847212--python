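# fueltyping

Agreement analysis for Canadian **Fire Behavior Prediction (FBP) System**
fuel-type maps against field surveys.

## The problem

Canada characterizes wildland fuels with the FBP System, which associates
vegetation with 16 categorical fuel types (C-1…C-7 conifer, D-1/D-2
deciduous, M-1…M-4 mixedwood, S-1…S-3 slash, O-1a/b grass) based on stand
structure and composition. In British Columbia, a provincial 50-m fuel-type
layer is produced by running an expert decision tree over photo-interpreted
forest-inventory polygons, and a national 250-m layer is produced by a
simpler national process. Fire analysts, fuel-management planners, and fire
scientists all consume these maps — but how well do the mapped labels match
what a crew finds standing on the ground?

This package provides the machinery to answer that question, end to end and
fully synthetically testable:

- **`plot_model`** — the fuel-type vocabulary, validated 1-ha plot records
  (cover, height, age, stem densities, species composition, harvest and
  disturbance history), and delimited-text I/O.
- **`synthetic_survey`** — a stratified survey generator (76 plots across
  grassland/woodland/open/closed/dense/recently-harvested strata) and a
  configurable inventory **bias model**: inventory value = field value +
  mean offset + Gaussian noise, clipped to the legal range. Defaults encode
  measured photo-interpretation bias: cover −9.4 % (SD 19.7), height −3.6 m
  (SD 9.2), live density −765 stems/ha (SD 1102).
- **`fuel_rules`** — a config-driven, ordered, first-match-wins decision-tree
  engine assigning a fuel type plus process number, with an audit trail,
  static rule validation (shadowed rules, attribute typos, totality), and the
  contested conventions exposed as switches (`larch_as_deciduous`, mixedwood
  bounds 20–80 % deciduous, post-harvest slash window).
- **`map_sampler`** — categorical fuel grids at any resolution (Esri ASCII
  I/O), cell-center rasterization of polygon landscapes, and half-open
  point sampling — the 50-m vs 250-m scaling mechanics.
- **`agreement_stats`** — confusion matrices over the collapsed label set,
  the five named comparison axes, per-type mismatch rates, frequent-mismatch
  pairs, structure/composition mismatch typing, suitability and confidence
  summaries, and paired one-sided *t*-tests
  (*t* = d̄ / (s/√n), df = n − 1).
- **`reporting` / CLI** — frequency and mismatch tables, and a one-command
  seeded synthetic pipeline.

The five comparison axes are: provincial vs field assigned and national vs
field assigned (*field observed agreement*), field decision tree vs field
assigned (*decision-tree agreement*, holding data constant), provincial vs
field decision tree (*forest inventory agreement*, holding process constant),
and national vs provincial (*scaling agreement*).

## Worked example

Classify a dense, unlogged Interior Douglas-fir stand through the default
rule set (a fixture encoding the publicly documented branches, not the
official provincial tree):

```python
>>> import fueltyping as ft
>>> rs = ft.default_ruleset()
>>> res = ft.classify(plot, rs)   # IDF zone, FD leading, 14 m, 60 % cover
>>> res.fuel_type, res.process_number, res.rule_id
('C-7', '5.1', 'c7-dry-dense-composition')
```

The stand lands in C-7 (open ponderosa pine / Douglas-fir) purely on
composition, although its structure is closed — the exact mechanism behind
frequent C-7 mismatches in dry interior forests. Likewise the larch
convention: a 70 % Douglas-fir / 30 % western larch stand is `M-2` with
`larch_as_deciduous=True` (larch counted toward the broadleaf fraction) and
`C-7` with the flag off.

Run the full synthetic pipeline and print per-axis agreement:

```python
>>> result = ft.run_synthetic(ft.RunConfig(seed=42))
>>> for name, cm in result.axes.items():
...     print(name, cm.agreement_pct)
field_observed_provincial 22.0
field_observed_national 22.0
field_decision_tree 24.0
forest_inventory 75.0
scaling 99.0
>>> round(result.attribute_tests["canopy_cover"].t, 2)
4.99
```

Here 22 % of simulated plots keep the same (collapsed) fuel type between the
subjective field call and the provincial map, while the paired one-sided
*t*-test detects the injected cover underprediction (t ≈ 5.0, df = 75). The
same run from the shell, writing tables, grids, confusion matrices, and a
digest manifest:

```
fueltyping run-all --seed 42 --out-dir out/
```

Closed-form reproduction of a paired *t* from published summaries:

```python
>>> ft.paired_t_from_summary(9.4, 19.7, 76).t
4.159761428353537
```

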