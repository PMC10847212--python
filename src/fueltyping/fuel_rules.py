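"""Ordered, declarative decision-tree engine for FBP fuel-type assignment.

The provincial fuel-typing process walks a decision tree over forest-inventory
attributes (landcover, biogeoclimatic zone, harvest history, canopy cover and
height, species composition, stem densities) and emits a fuel type plus a
process number identifying the branch that fired.  This module re-implements
that mechanism as a first-match-wins rule list read from config, so the full
official tree can be transcribed later without code changes.  The shipped
default rule set encodes only publicly documented branches and is a fixture,
not the official tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, RangeError, TotalityError
from .plot_model import PlotRecord, load_species_registry, validate_code

# --- attribute derivations --------------------------------------------------


def landcover_density(canopy_cover: float) -> str:
    """Landcover density label from canopy cover.

    Bins: dense 61-100%, open 26-60%, sparse 10-25%, non-treed below 10%.
    Covers falling between stated integer bin edges resolve to the upper bin.
    """
    if not 0.0 <= canopy_cover <= 100.0:
        raise RangeError(f"canopy cover {canopy_cover} outside [0, 100]")
    if canopy_cover < 10.0:
        return "non-treed"
    if canopy_cover <= 25.0:
        return "sparse"
    if canopy_cover <= 60.0:
        return "open"
    return "dense"


def stratification_class(
    canopy_cover: float,
    harvest_year: int | None = None,
    min_harvest_year: int = 2000,
) -> str:
    """Survey stratum of a plot; recent harvest takes precedence over cover.

    Cover bins: grassland 0-5%, woodland 6-15%, open 16-35%, closed 36-59%,
    dense >= 60%.  Plots harvested in or after ``min_harvest_year`` fall in
    the recently-harvested stratum regardless of cover.
    """
    if not 0.0 <= canopy_cover <= 100.0:
        raise RangeError(f"canopy cover {canopy_cover} outside [0, 100]")
    if harvest_year is not None and harvest_year >= min_harvest_year:
        return "harvested"
    if canopy_cover <= 5.0:
        return "grassland"
    if canopy_cover <= 15.0:
        return "woodland"
    if canopy_cover <= 35.0:
        return "open"
    if canopy_cover < 60.0:
        return "closed"
    return "dense"


def derive_deciduous_pct(
    plot: PlotRecord,
    larch_as_deciduous: bool = True,
    registry: Mapping[str, Mapping[str, str]] | None = None,
) -> float:
    """Percent deciduous composition from the two leading species.

    Sums the composition percentages of broadleaf species; western larch (a
    deciduous conifer) is added iff ``larch_as_deciduous`` — the provincial
    convention under critique, which groups larch with trembling aspen on the
    assumption it cannot support crown fire.
    """
    if registry is None:
        registry = load_species_registry()
    total = 0.0
    for sp, pct in ((plot.species1, plot.species1_pct), (plot.species2, plot.species2_pct)):
        if sp is None:
            continue
        habit = registry.get(sp, {}).get("habit", "conifer")
        if habit == "broadleaf" or (habit == "deciduous_conifer" and larch_as_deciduous):
            total += pct
    return total


# --- rule model -------------------------------------------------------------

_OPS = ("eq", "ne", "lt", "le", "gt", "ge", "in", "not_in", "absent", "present")


@dataclass(frozen=True)
class Predicate:
    attribute: str
    op: str
    value: Any = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigurationError(f"unknown comparator {self.op!r}")

    def matches(self, env: Mapping[str, Any]) -> bool:
        v = env.get(self.attribute)
        if self.op == "absent":
            return v is None
        if self.op == "present":
            return v is not None
        if v is None:
            return False  # missing values fail every value comparison
        if self.op == "eq":
            return v == self.value
        if self.op == "ne":
            return v != self.value
        if self.op == "lt":
            return v < self.value
        if self.op == "le":
            return v <= self.value
        if self.op == "gt":
            return v > self.value
        if self.op == "ge":
            return v >= self.value
        if self.op == "in":
            return v in self.value
        return v not in self.value  # not_in


@dataclass(frozen=True)
class Rule:
    rule_id: str
    process_number: str
    predicates: tuple[Predicate, ...]
    outcome: str

    def __post_init__(self) -> None:
        validate_code(self.outcome, collapsed_ok=False)

    def matches(self, env: Mapping[str, Any]) -> bool:
        return all(p.matches(env) for p in self.predicates)


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules plus the knobs the provincial process parameterizes.

    ``slash_window`` is the post-harvest interval (years) during which stands
    are treated as clear-cut slash; the provincial process applies it during
    the first 5 to 10 years after harvesting, so the default upper bound is a
    config value inside [5, 10].
    """

    rules: tuple[Rule, ...]
    name: str = "unnamed"
    reference_year: int = 2022
    larch_as_deciduous: bool = True
    mixedwood_bounds: tuple[float, float] = (20.0, 80.0)
    slash_window: tuple[float, float] = (0.0, 7.0)
    fallback: str | None = "NF"
    registry: Mapping[str, Mapping[str, str]] = field(default_factory=load_species_registry)

    def __post_init__(self) -> None:
        if self.fallback is None:
            raise TotalityError(
                "rule set has no fallback outcome and cannot be proven total"
            )
        validate_code(self.fallback, collapsed_ok=False)
        lo, hi = self.mixedwood_bounds
        if not 0 <= lo <= hi <= 100:
            raise ConfigurationError(f"bad mixedwood bounds {self.mixedwood_bounds}")
        if self.slash_window[0] > self.slash_window[1]:
            raise ConfigurationError(f"bad slash window {self.slash_window}")

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RuleSet":
        rules = tuple(
            Rule(
                rule_id=r["rule_id"],
                process_number=str(r["process_number"]),
                predicates=tuple(
                    Predicate(p["attribute"], p["op"], p.get("value"))
                    for p in r.get("when", [])
                ),
                outcome=r["outcome"],
            )
            for r in raw.get("rules", [])
        )
        return cls(
            rules=rules,
            name=raw.get("name", "unnamed"),
            reference_year=int(raw.get("reference_year", 2022)),
            larch_as_deciduous=bool(raw.get("larch_as_deciduous", True)),
            mixedwood_bounds=tuple(raw.get("mixedwood_bounds", (20.0, 80.0))),
            slash_window=tuple(raw.get("slash_window", (0.0, 7.0))),
            fallback=raw.get("fallback", "NF"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_ruleset() -> RuleSet:
    """The rule-set fixture shipped with the package."""
    ref = resources.files("fueltyping.data").joinpath("default_ruleset.yaml")
    with ref.open(encoding="utf-8") as fh:
        return RuleSet.from_mapping(yaml.safe_load(fh))


# --- evaluation environment -------------------------------------------------


def derive_attributes(plot: PlotRecord, ruleset: RuleSet) -> dict[str, Any]:
    """Flat predicate-evaluation namespace: record fields plus derivations.

    Derived attributes: ``density_label`` (cover bin), ``years_since_harvest``
    (None when never harvested) and its infinity-padded twin
    ``years_since_harvest_or_inf``, ``recent_harvest`` (inside the slash
    window), ``deciduous_pct`` (larch grouping applied), ``mixedwood``, and
    ``stratum``.
    """
    ysh: float | None = None
    if plot.harvest_year is not None:
        ysh = float(ruleset.reference_year - plot.harvest_year)
    deciduous = derive_deciduous_pct(plot, ruleset.larch_as_deciduous, ruleset.registry)
    lo, hi = ruleset.mixedwood_bounds
    env: dict[str, Any] = {
        "plot_id": plot.plot_id,
        "x": plot.x,
        "y": plot.y,
        "bec_zone": plot.bec_zone,
        "bec_subzone": plot.bec_subzone,
        "vegetated": plot.landcover.vegetated,
        "treed": plot.landcover.treed,
        "site": plot.landcover.site,
        "density_class": plot.landcover.density_class,
        "canopy_cover": plot.canopy_cover,
        "canopy_height": plot.canopy_height,
        "canopy_age": plot.canopy_age,
        "live_density": plot.live_density,
        "dead_density": plot.dead_density,
        "pct_dead_overstory": plot.pct_dead_overstory,
        "species1": plot.species1,
        "species2": plot.species2,
        "species1_pct": plot.species1_pct,
        "species2_pct": plot.species2_pct,
        "harvest_year": plot.harvest_year,
        "pct_deciduous": plot.pct_deciduous,
        "disturbance_type": plot.disturbance.type if plot.disturbance else None,
        "disturbance_years_since": (
            plot.disturbance.years_since if plot.disturbance else None
        ),
        "leading_species": plot.species1,
        "density_label": landcover_density(plot.canopy_cover),
        "stratum": stratification_class(plot.canopy_cover, plot.harvest_year),
        "years_since_harvest": ysh,
        "years_since_harvest_or_inf": ysh if ysh is not None else math.inf,
        "recent_harvest": (
            ysh is not None and ruleset.slash_window[0] <= ysh <= ruleset.slash_window[1]
        ),
        "deciduous_pct": deciduous,
        "mixedwood": plot.landcover.treed and lo <= deciduous <= hi,
    }
    return env


def _known_attributes() -> frozenset[str]:
    # Derive the canonical namespace from a representative record.
    from .plot_model import Landcover

    probe = PlotRecord(
        plot_id="_probe",
        x=0.0,
        y=0.0,
        bec_zone="IDF",
        bec_subzone="dk",
        landcover=Landcover(True, False, "upland", "non-treed"),
        canopy_cover=0.0,
        canopy_height=0.0,
        canopy_age=0.0,
        live_density=0.0,
        dead_density=0.0,
        pct_dead_overstory=0.0,
    )
    return frozenset(derive_attributes(probe, default_ruleset()))


KNOWN_ATTRIBUTES = _known_attributes()


# --- classification ---------------------------------------------------------


@dataclass(frozen=True)
class ClassificationResult:
    fuel_type: str
    process_number: str
    rule_id: str
    audit: tuple[str, ...]  # every rule evaluated, in order; last one fired
    fallback_used: bool = False


def classify(plot: PlotRecord, ruleset: RuleSet) -> ClassificationResult:
    """Assign a fuel type by first-match-wins traversal of the rule list.

    Pure function of (plot, ruleset).  The audit trail lists every rule
    evaluated in order; the fallback outcome is used only when no rule
    matches.
    """
    env = derive_attributes(plot, ruleset)
    audit: list[str] = []
    for rule in ruleset.rules:
        audit.append(rule.rule_id)
        if rule.matches(env):
            return ClassificationResult(
                fuel_type=rule.outcome,
                process_number=rule.process_number,
                rule_id=rule.rule_id,
                audit=tuple(audit),
            )
    return ClassificationResult(
        fuel_type=ruleset.fallback,  # type: ignore[arg-type]
        process_number="fallback",
        rule_id="fallback",
        audit=tuple(audit) + ("fallback",),
        fallback_used=True,
    )


def classify_all(plots: Iterable[PlotRecord], ruleset: RuleSet) -> list[ClassificationResult]:
    return [classify(p, ruleset) for p in plots]


# --- static validation ------------------------------------------------------


@dataclass(frozen=True)
class RulesetReport:
    total: bool
    unreachable_rules: tuple[str, ...]
    unknown_attributes: tuple[str, ...]
    fallback_fraction: float | None = None  # over the supplied sweep, if any

    @property
    def clean(self) -> bool:
        return self.total and not self.unreachable_rules and not self.unknown_attributes


def _constraints(rule: Rule) -> dict[str, list[Predicate]]:
    by_attr: dict[str, list[Predicate]] = {}
    for p in rule.predicates:
        by_attr.setdefault(p.attribute, []).append(p)
    return by_attr


def _interval(preds: Sequence[Predicate]) -> tuple[float, float] | None:
    """Closed numeric interval implied by lt/le/gt/ge/eq predicates, if any."""
    lo, hi = -math.inf, math.inf
    numeric = False
    for p in preds:
        if p.op in ("lt", "le") and isinstance(p.value, (int, float)):
            hi = min(hi, float(p.value))
            numeric = True
        elif p.op in ("gt", "ge") and isinstance(p.value, (int, float)):
            lo = max(lo, float(p.value))
            numeric = True
        elif p.op == "eq" and isinstance(p.value, (int, float)) and not isinstance(p.value, bool):
            lo, hi = max(lo, float(p.value)), min(hi, float(p.value))
            numeric = True
    return (lo, hi) if numeric else None


def _allowed_set(preds: Sequence[Predicate]) -> set | None:
    allowed: set | None = None
    for p in preds:
        if p.op == "eq" and not isinstance(p.value, float):
            s = {p.value}
        elif p.op == "in":
            s = set(p.value)
        else:
            continue
        allowed = s if allowed is None else allowed & s
    return allowed


def _implies(later: Rule, earlier: Rule) -> bool:
    """Conservatively prove match(later) is contained in match(earlier).

    True only when, for every attribute the earlier rule constrains, the later
    rule's constraints provably imply it (interval containment for numeric
    predicates, set containment for categorical ones).  Unprovable cases
    return False, so only certain shadowing is reported.
    """
    later_c = _constraints(later)
    for attr, e_preds in _constraints(earlier).items():
        l_preds = later_c.get(attr)
        if not l_preds:
            return False
        e_set, l_set = _allowed_set(e_preds), _allowed_set(l_preds)
        e_iv, l_iv = _interval(e_preds), _interval(l_preds)
        ok = False
        if e_set is not None and l_set is not None and l_set <= e_set:
            ok = True
        elif e_iv is not None and l_iv is not None and e_iv[0] <= l_iv[0] and l_iv[1] <= e_iv[1]:
            ok = True
        elif e_iv is not None and l_set is not None and all(
            isinstance(v, (int, float)) and e_iv[0] <= v <= e_iv[1] for v in l_set
        ):
            ok = True
        if not ok:
            return False
    return True


def validate_ruleset(
    ruleset: RuleSet, sweep: Iterable[PlotRecord] | None = None
) -> RulesetReport:
    """Static rule-set report: totality, shadowed rules, attribute typos.

    A rule is flagged unreachable when its match set is provably contained in
    an earlier rule's.  Unknown attributes catch predicate typos against the
    documented evaluation namespace.  With a ``sweep`` of plots, the fraction
    classified by the fallback is measured empirically.
    """
    unknown = tuple(
        sorted(
            {
                p.attribute
                for r in ruleset.rules
                for p in r.predicates
                if p.attribute not in KNOWN_ATTRIBUTES
            }
        )
    )
    unreachable = []
    for i, later in enumerate(ruleset.rules):
        if any(_implies(later, earlier) for earlier in ruleset.rules[:i]):
            unreachable.append(later.rule_id)
    fallback_fraction = None
    if sweep is not None:
        results = classify_all(sweep, ruleset)
        if results:
            fallback_fraction = sum(r.fallback_used for r in results) / len(results)
    return RulesetReport(
        total=ruleset.fallback is not None,
        unreachable_rules=tuple(unreachable),
        unknown_attributes=unknown,
        fallback_fraction=fallback_fraction,
    )
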