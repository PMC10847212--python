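# Default decision-tree fixture for FBP fuel-type assignment.
#
# This is NOT the official provincial (BCWS) decision tree: only branches the
# provincial process is publicly documented to contain, plus structural
# fall-through rules derived from the FBP fuel-type descriptions, are encoded.
# First matching rule wins; process numbers are local to this rule set.
#
# Boundary conventions: thresholds phrased "greater than" are strict (>);
# ranges ("20 to 80%") are closed on both ends.  "Recently harvested" means a
# harvest year within slash_window years of reference_year.
name: default-field-fixture
reference_year: 2022
larch_as_deciduous: true
mixedwood_bounds: [20, 80]
slash_window: [0, 7]
fallback: NF
rules:
  - rule_id: slash-pine
    process_number: "6.1"
    when:
      - {attribute: recent_harvest, op: eq, value: true}
      - {attribute: leading_species, op: in, value: [PL, PY]}
    outcome: S-1
  - rule_id: slash-spruce-fir
    process_number: "6.2"
    when:
      - {attribute: recent_harvest, op: eq, value: true}
      - {attribute: leading_species, op: in, value: [SE, SX, BL]}
    outcome: S-2
  - rule_id: slash-cedar-hemlock-fir
    process_number: "6.3"
    when:
      - {attribute: recent_harvest, op: eq, value: true}
      - {attribute: leading_species, op: in, value: [CW, HW, FD]}
    outcome: S-3
  - rule_id: slash-unattributed
    process_number: "6.4"
    when:
      - {attribute: recent_harvest, op: eq, value: true}
    outcome: S-1
  - rule_id: grass-non-treed
    process_number: "1.1"
    when:
      - {attribute: density_label, op: eq, value: non-treed}
    outcome: O-1b
  - rule_id: deciduous
    process_number: "3.1"
    when:
      - {attribute: deciduous_pct, op: gt, value: 80}
    outcome: D-2
  - rule_id: mixedwood
    process_number: "4.1"
    when:
      - {attribute: mixedwood, op: eq, value: true}
    outcome: M-2
  - rule_id: c7-dry-dense-composition
    process_number: "5.1"
    when:
      - {attribute: bec_zone, op: in, value: [IDF, PP]}
      - {attribute: leading_species, op: in, value: [FD, PY]}
      - {attribute: years_since_harvest_or_inf, op: gt, value: 6}
      - {attribute: canopy_height, op: gt, value: 12}
      - {attribute: canopy_cover, op: gt, value: 55}
    outcome: C-7
  - rule_id: c7-dry-fir-pine
    process_number: "5.2"
    when:
      - {attribute: leading_species, op: in, value: [FD, PY]}
    outcome: C-7
  - rule_id: pine-immature
    process_number: "2.2"
    when:
      - {attribute: leading_species, op: eq, value: PL}
      - {attribute: canopy_height, op: le, value: 12}
    outcome: C-4
  - rule_id: pine-mature
    process_number: "2.1"
    when:
      - {attribute: leading_species, op: eq, value: PL}
    outcome: C-3
  - rule_id: spruce-fir-boreal
    process_number: "2.3"
    when:
      - {attribute: leading_species, op: in, value: [SE, SX, BL]}
    outcome: C-2
  - rule_id: cedar-hemlock
    process_number: "2.4"
    when:
      - {attribute: leading_species, op: in, value: [CW, HW]}
    outcome: C-5
  - rule_id: larch-as-conifer
    process_number: "2.5"
    when:
      - {attribute: leading_species, op: eq, value: LW}
    outcome: C-3
  - rule_id: broadleaf-minor
    process_number: "3.2"
    when:
      - {attribute: leading_species, op: in, value: [AT, ACT, EP]}
    outcome: D-2
  - rule_id: treed-residual
    process_number: "7.1"
    when:
      - {attribute: treed, op: eq, value: true}
    outcome: C-3
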