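"""Decision-tree engine: derivations, classification, static validation."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from fueltyping.errors import RangeError, TotalityError
from fueltyping.fuel_rules import (
    Predicate,
    Rule,
    RuleSet,
    classify,
    classify_all,
    derive_deciduous_pct,
    landcover_density,
    stratification_class,
    validate_ruleset,
)
from fueltyping.plot_model import FUEL_GROUPS, group_of

from conftest import make_plot


class TestLandcoverDensity:
    @pytest.mark.parametrize(
        "cover,label",
        [(75, "dense"), (61, "dense"), (26, "open"), (60, "open"),
         (10, "sparse"), (25, "sparse"), (4, "non-treed"), (0, "non-treed")],
    )
    def test_bins(self, cover, label):
        assert landcover_density(cover) == label

    def test_out_of_range(self):
        with pytest.raises(RangeError):
            landcover_density(101)
        with pytest.raises(RangeError):
            landcover_density(-1)


class TestStratification:
    @pytest.mark.parametrize(
        "cover,harvest,expected",
        [(3, None, "grassland"), (80, 2005, "harvested"), (60, None, "dense"),
         (59, None, "closed"), (15, None, "woodland"), (35, None, "open"),
         (80, 1995, "dense")],  # old harvest does not pre-empt the cover bin
    )
    def test_classes(self, cover, harvest, expected):
        assert stratification_class(cover, harvest) == expected


class TestDeciduousPct:
    def test_larch_counts_as_deciduous_when_flagged(self):
        plot = make_plot(species1="FD", species1_pct=70.0, species2="LW", species2_pct=30.0)
        assert derive_deciduous_pct(plot, larch_as_deciduous=True) == 30.0
        assert derive_deciduous_pct(plot, larch_as_deciduous=False) == 0.0

    def test_pure_aspen_is_fully_deciduous(self):
        plot = make_plot(species1="AT", species1_pct=100.0)
        assert derive_deciduous_pct(plot, True) == 100.0
        assert derive_deciduous_pct(plot, False) == 100.0


class TestClassify:
    def test_dry_dense_douglas_fir_composition_branch(self, ruleset):
        # The contested branch: unlogged dry-zone fir, tall and dense, goes to
        # C-7 on composition even though its structure is closed.
        plot = make_plot(bec_zone="IDF", species1="FD", canopy_height=14.0,
                         canopy_cover=60.0)
        res = classify(plot, ruleset)
        assert res.fuel_type == "C-7"
        assert res.rule_id == "c7-dry-dense-composition"

    def test_mixed_fir_larch_becomes_mixedwood(self, ruleset):
        plot = make_plot(species1="FD", species1_pct=70.0,
                         species2="LW", species2_pct=30.0)
        assert classify(plot, ruleset).fuel_type == "M-2"

    def test_pure_larch_becomes_leafed_deciduous(self, ruleset):
        plot = make_plot(species1="LW", species1_pct=100.0)
        assert classify(plot, ruleset).fuel_type == "D-2"

    def test_recent_clearcut_pine_becomes_slash(self, ruleset):
        plot = make_plot(species1="PL", harvest_year=ruleset.reference_year - 3)
        res = classify(plot, ruleset)
        assert res.fuel_type == "S-1"
        assert res.rule_id == "slash-pine"

    def test_old_harvest_is_not_slash(self, ruleset):
        plot = make_plot(species1="PL", canopy_height=20.0,
                         harvest_year=ruleset.reference_year - 15)
        assert classify(plot, ruleset).fuel_type == "C-3"

    def test_audit_trail_ends_with_fired_rule(self, ruleset):
        plot = make_plot(species1="PL", canopy_height=8.0)
        res = classify(plot, ruleset)
        assert res.fuel_type == "C-4"
        assert res.audit[-1] == res.rule_id
        # every rule before the fired one was evaluated, in order
        ids = [r.rule_id for r in ruleset.rules]
        assert list(res.audit) == ids[: ids.index(res.rule_id) + 1]

    def test_classify_is_deterministic(self, ruleset, survey76):
        a = classify_all(survey76, ruleset)
        b = classify_all(survey76, ruleset)
        assert a == b

    def test_order_sensitivity(self, ruleset):
        # Moving the generic dry fir/pine rule ahead of the dense-stand branch
        # changes which rule fires (same outcome class family is irrelevant:
        # the audit proves the traversal).
        plot = make_plot(bec_zone="IDF", species1="FD", canopy_height=14.0,
                         canopy_cover=60.0)
        ids = {r.rule_id: r for r in ruleset.rules}
        reordered = list(ruleset.rules)
        a, b = reordered.index(ids["c7-dry-dense-composition"]), reordered.index(
            ids["c7-dry-fir-pine"]
        )
        reordered[a], reordered[b] = reordered[b], reordered[a]
        permuted = dataclasses.replace(ruleset, rules=tuple(reordered))
        assert classify(plot, permuted).rule_id == "c7-dry-fir-pine"
        assert classify(plot, ruleset).rule_id == "c7-dry-dense-composition"

    @given(
        larch_pct=st.floats(0.0, 50.0),
        conifer=st.sampled_from(["FD", "PL", "SE", "PY"]),
        cover=st.floats(10.0, 100.0),
        height=st.floats(0.0, 40.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_larch_toggle_blocks_deciduous_codes(self, larch_pct, conifer, cover, height):
        """With larch grouped as a conifer, no conifer+larch stand can reach
        a deciduous or mixedwood fuel type."""
        plot = make_plot(
            species1=conifer, species1_pct=max(50.0, larch_pct),
            species2="LW" if larch_pct > 0 else None,
            species2_pct=min(larch_pct, max(50.0, larch_pct)),
            canopy_cover=cover, canopy_height=height,
        )
        rs = dataclasses.replace(default_rs(), larch_as_deciduous=False)
        code = classify(plot, rs).fuel_type
        assert group_of(code) not in ("deciduous", "mixedwood")

    def test_slash_depends_only_on_harvest_recency(self, ruleset):
        lo, hi = ruleset.slash_window
        base = dict(species1="PL")
        inside = make_plot(harvest_year=int(ruleset.reference_year - hi), **base)
        outside = make_plot(harvest_year=int(ruleset.reference_year - hi - 1),
                            canopy_height=20.0, **base)
        assert group_of(classify(inside, ruleset).fuel_type) == "slash"
        assert group_of(classify(outside, ruleset).fuel_type) != "slash"


def default_rs():
    from fueltyping.fuel_rules import default_ruleset

    return default_ruleset()


class TestValidateRuleset:
    def test_default_fixture_is_clean_over_attribute_sweep(self, ruleset, survey76):
        # Gridded sweep of attribute space plus a generated survey: every plot
        # classifies to a valid code and the fixture shows no static defects.
        sweep = []
        for cover in (0, 4, 10, 26, 55, 56, 61, 100):
            for species, pct in (("FD", 90.0), ("PL", 90.0), ("SE", 90.0),
                                 ("LW", 90.0), ("AT", 90.0), (None, 0.0)):
                for height in (2.0, 12.0, 13.0, 30.0):
                    for harvest in (None, 2019, 2001):
                        if species is None and cover >= 10:
                            continue
                        if cover < 10 and species is not None:
                            continue
                        sweep.append(make_plot(
                            canopy_cover=float(cover), species1=species,
                            species1_pct=pct, canopy_height=height,
                            harvest_year=harvest,
                        ))
        report = validate_ruleset(ruleset, sweep=sweep + list(survey76))
        assert report.clean
        assert report.total
        for res in classify_all(sweep, ruleset):
            assert res.fuel_type in FUEL_GROUPS

    def test_contained_rule_flagged_unreachable(self, ruleset):
        wide = Rule("wide", "1", (Predicate("canopy_cover", "gt", 20.0),), "C-3")
        narrow = Rule("narrow", "2", (Predicate("canopy_cover", "gt", 40.0),
                                      Predicate("canopy_cover", "le", 60.0)), "C-4")
        rs = dataclasses.replace(ruleset, rules=(wide, narrow))
        assert validate_ruleset(rs).unreachable_rules == ("narrow",)

    def test_set_containment_flagged(self, ruleset):
        wide = Rule("wide", "1", (Predicate("leading_species", "in", ["FD", "PY", "PL"]),), "C-7")
        narrow = Rule("narrow", "2", (Predicate("leading_species", "eq", "FD"),), "C-3")
        rs = dataclasses.replace(ruleset, rules=(wide, narrow))
        assert "narrow" in validate_ruleset(rs).unreachable_rules

    def test_attribute_typo_flagged(self, ruleset):
        typo = Rule("t", "1", (Predicate("canopy_heihgt", "gt", 5.0),), "C-3")
        rs = dataclasses.replace(ruleset, rules=ruleset.rules + (typo,))
        assert validate_ruleset(rs).unknown_attributes == ("canopy_heihgt",)

    def test_missing_fallback_fails_at_load(self, ruleset):
        with pytest.raises(TotalityError):
            dataclasses.replace(ruleset, fallback=None)
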