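"""Domain types, fuel-type label vocabulary, and delimited-text plot I/O.

The Canadian Fire Behavior Prediction (FBP) System describes 16 categorical
fuel types (17 codes once the O-1a/O-1b grass split is counted) grouped into
coniferous, deciduous, mixedwood, slash, and open classes, plus an NF
(non-fuel) label used by map products for unburnable cells.  Every module in
this package speaks this vocabulary; plots are 1-ha field survey units whose
attributes mirror the provincial forest-inventory fields consumed by the
fuel-typing decision tree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import LabelError, SchemaError, TraitError, ValidationError

# --- fuel-type vocabulary ---------------------------------------------------

#: Group membership for every representable code.
FUEL_GROUPS: dict[str, str] = {
    "C-1": "coniferous",
    "C-2": "coniferous",
    "C-3": "coniferous",
    "C-4": "coniferous",
    "C-5": "coniferous",
    "C-6": "coniferous",
    "C-7": "coniferous",
    "D-1": "deciduous",
    "D-2": "deciduous",
    "M-1": "mixedwood",
    "M-2": "mixedwood",
    "M-3": "mixedwood",
    "M-4": "mixedwood",
    "S-1": "slash",
    "S-2": "slash",
    "S-3": "slash",
    "O-1a": "open",
    "O-1b": "open",
    "NF": "non-fuel",
}

#: The 17 fuel codes plus NF.
FUEL_CODES: tuple[str, ...] = tuple(FUEL_GROUPS)

#: Collapsed reporting vocabulary: O-1a and O-1b are reported as a single O-1.
COLLAPSED_CODES: tuple[str, ...] = tuple(
    c for c in FUEL_CODES if not c.startswith("O-1")
) + ("O-1",)

#: Provincial confidence labels attached to the provincial fuel-type layer.
CONFIDENCE_LEVELS: tuple[str, ...] = (
    "low",
    "medium",
    "medium/high",
    "high",
    "not_described",
)


def validate_code(code: str, *, collapsed_ok: bool = True) -> str:
    """Return *code* unchanged if it is a known fuel-type label."""
    if code in FUEL_GROUPS or (collapsed_ok and code == "O-1"):
        return code
    raise LabelError(f"unknown fuel-type code: {code!r}")


def group_of(code: str) -> str:
    """Group (coniferous/deciduous/mixedwood/slash/open/non-fuel) of a code."""
    if code == "O-1":
        return "open"
    try:
        return FUEL_GROUPS[code]
    except KeyError:
        raise LabelError(f"unknown fuel-type code: {code!r}") from None


def collapse_code(code: str) -> str:
    """Map O-1a/O-1b to the undivided O-1 reporting label.

    All other codes map to themselves; the function is idempotent, so O-1 is
    also accepted.
    """
    validate_code(code)
    return "O-1" if code in ("O-1a", "O-1b") else code


def deseasonalize_code(code: str) -> str:
    """Collapse leafless/green seasonal pairs: D-1/D-2 -> D, M-1..M-4 -> M.

    The analysis compares aseasonal map products with field calls made in one
    season, so seasonal variants are never distinguished in reports; the
    leafed (green) variants D-2/M-2 are used as the reporting representatives.
    """
    validate_code(code)
    if code in ("D-1", "D-2"):
        return "D"
    if code in ("M-1", "M-2", "M-3", "M-4"):
        return "M"
    return collapse_code(code)


# --- plot records -----------------------------------------------------------


@dataclass(frozen=True)
class Landcover:
    """Field landcover call: the four customary classification variables."""

    vegetated: bool
    treed: bool
    site: str  # alpine | wetland | upland
    density_class: str  # dense | open | sparse | non-treed

    _SITES = ("alpine", "wetland", "upland")
    _DENSITY = ("dense", "open", "sparse", "non-treed")

    def __post_init__(self) -> None:
        if self.site not in self._SITES:
            raise ValidationError(f"landcover site {self.site!r} not in {self._SITES}")
        if self.density_class not in self._DENSITY:
            raise ValidationError(
                f"density class {self.density_class!r} not in {self._DENSITY}"
            )


@dataclass(frozen=True)
class Disturbance:
    """Most recent non-harvest disturbance recorded at a plot."""

    type: str
    years_since: float

    _TYPES = (
        "clear-cut",
        "selective",
        "seed-tree",
        "thinning",
        "wildfire",
        "prescribed fire",
        "windthrow",
        "insect",
    )

    def __post_init__(self) -> None:
        if self.type not in self._TYPES:
            raise ValidationError(f"disturbance type {self.type!r} not in {self._TYPES}")
        if self.years_since < 0:
            raise ValidationError("years_since must be >= 0")


def _check_pct(name: str, value: float, plot_id: str) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValidationError(f"plot {plot_id}: {name}={value} outside [0, 100]")


def _check_nonneg(name: str, value: float, plot_id: str) -> None:
    if value < 0:
        raise ValidationError(f"plot {plot_id}: {name}={value} must be >= 0")


@dataclass(frozen=True)
class PlotRecord:
    """One 1-ha plot's fuel-relevant attributes.

    Units: coordinates in metres (planar/projected), canopy_cover and all
    percentages in [0, 100], canopy_height in m, canopy_age in years, stem
    densities in stems/ha.  ``harvest_year`` and ``disturbance`` are absent
    (None) when the plot carries no record of that history.
    """

    plot_id: str
    x: float
    y: float
    bec_zone: str
    bec_subzone: str
    landcover: Landcover
    canopy_cover: float
    canopy_height: float
    canopy_age: float
    live_density: float
    dead_density: float
    pct_dead_overstory: float
    species1: str | None = None
    species2: str | None = None
    species1_pct: float = 0.0
    species2_pct: float = 0.0
    harvest_year: int | None = None
    disturbance: Disturbance | None = None
    pct_deciduous: float = 0.0

    def __post_init__(self) -> None:
        pid = self.plot_id
        _check_pct("canopy_cover", self.canopy_cover, pid)
        _check_pct("pct_dead_overstory", self.pct_dead_overstory, pid)
        _check_pct("pct_deciduous", self.pct_deciduous, pid)
        for name in ("canopy_height", "canopy_age", "live_density", "dead_density"):
            _check_nonneg(name, getattr(self, name), pid)
        if self.species1_pct < self.species2_pct:
            raise ValidationError(
                f"plot {pid}: species1_pct ({self.species1_pct}) < "
                f"species2_pct ({self.species2_pct})"
            )
        if self.species1_pct + self.species2_pct > 100.0 + 1e-9:
            raise ValidationError(f"plot {pid}: species percents sum over 100")
        if not self.landcover.treed and (self.species1 or self.species2):
            raise ValidationError(f"plot {pid}: non-treed plot carries species fields")
        if self.species2 is not None and self.species1 is None:
            raise ValidationError(f"plot {pid}: species2 present without species1")


_CSV_COLUMNS = (
    "plot_id",
    "x",
    "y",
    "bec_zone",
    "bec_subzone",
    "vegetated",
    "treed",
    "site",
    "density_class",
    "canopy_cover",
    "canopy_height",
    "canopy_age",
    "live_density",
    "dead_density",
    "pct_dead_overstory",
    "species1",
    "species1_pct",
    "species2",
    "species2_pct",
    "harvest_year",
    "disturbance_type",
    "disturbance_years_since",
    "pct_deciduous",
)


def _parse_bool(raw: str) -> bool:
    if raw.lower() in ("true", "1", "yes"):
        return True
    if raw.lower() in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean field value {raw!r}")


def read_plots(path: str | Path) -> list[PlotRecord]:
    """Read a comma-delimited plot table into validated PlotRecords.

    The file must carry a header row naming every column of the documented
    schema; absent optional values (harvest_year, disturbance, species2) are
    empty fields.  Row order is preserved.
    """
    records: list[PlotRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            records.append(_record_from_row(row))
    return records


def _record_from_row(row: Mapping[str, str]) -> PlotRecord:
    def opt(name: str) -> str | None:
        v = row[name].strip()
        return v or None

    disturbance = None
    if opt("disturbance_type") is not None:
        disturbance = Disturbance(
            type=row["disturbance_type"].strip(),
            years_since=float(row["disturbance_years_since"]),
        )
    harvest = opt("harvest_year")
    return PlotRecord(
        plot_id=row["plot_id"].strip(),
        x=float(row["x"]),
        y=float(row["y"]),
        bec_zone=row["bec_zone"].strip(),
        bec_subzone=row["bec_subzone"].strip(),
        landcover=Landcover(
            vegetated=_parse_bool(row["vegetated"]),
            treed=_parse_bool(row["treed"]),
            site=row["site"].strip(),
            density_class=row["density_class"].strip(),
        ),
        canopy_cover=float(row["canopy_cover"]),
        canopy_height=float(row["canopy_height"]),
        canopy_age=float(row["canopy_age"]),
        live_density=float(row["live_density"]),
        dead_density=float(row["dead_density"]),
        pct_dead_overstory=float(row["pct_dead_overstory"]),
        species1=opt("species1"),
        species2=opt("species2"),
        species1_pct=float(row["species1_pct"] or 0.0),
        species2_pct=float(row["species2_pct"] or 0.0),
        harvest_year=int(harvest) if harvest is not None else None,
        disturbance=disturbance,
        pct_deciduous=float(row["pct_deciduous"]),
    )


def write_plots(records: Iterable[PlotRecord], path: str | Path) -> None:
    """Write PlotRecords as comma-delimited UTF-8 text (round-trips read_plots)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.plot_id,
                    repr(r.x),
                    repr(r.y),
                    r.bec_zone,
                    r.bec_subzone,
                    str(r.landcover.vegetated).lower(),
                    str(r.landcover.treed).lower(),
                    r.landcover.site,
                    r.landcover.density_class,
                    repr(r.canopy_cover),
                    repr(r.canopy_height),
                    repr(r.canopy_age),
                    repr(r.live_density),
                    repr(r.dead_density),
                    repr(r.pct_dead_overstory),
                    r.species1 or "",
                    repr(r.species1_pct),
                    r.species2 or "",
                    repr(r.species2_pct),
                    r.harvest_year if r.harvest_year is not None else "",
                    r.disturbance.type if r.disturbance else "",
                    repr(r.disturbance.years_since) if r.disturbance else "",
                    repr(r.pct_deciduous),
                ]
            )


# --- plot labels ------------------------------------------------------------

SUITABILITY_CATEGORIES = (
    "acceptable",
    "composition_mismatch",
    "structure_mismatch",
    "structure_and_composition_mismatch",
)


@dataclass(frozen=True)
class PlotLabels:
    """Fuel-type labels for one plot from each of the four sources.

    ``structure_match`` / ``composition_match`` score whether any FBP fuel
    type suitably describes the plot's extant structure and composition (the
    field applicability call); ``confidence`` is the provider's confidence in
    the provincial label only.
    """

    plot_id: str
    field_assigned: str
    field_decision_tree: str
    provincial: str
    national: str
    structure_match: bool = True
    composition_match: bool = True
    confidence: str = "not_described"

    def __post_init__(self) -> None:
        for src in ("field_assigned", "field_decision_tree", "provincial", "national"):
            validate_code(getattr(self, src))
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"plot {self.plot_id}: confidence {self.confidence!r} "
                f"not in {CONFIDENCE_LEVELS}"
            )

    @property
    def suitability_category(self) -> str:
        """One of the four structure/composition applicability categories."""
        if self.structure_match and self.composition_match:
            return "acceptable"
        if self.structure_match:
            return "composition_mismatch"
        if self.composition_match:
            return "structure_mismatch"
        return "structure_and_composition_mismatch"

    def source(self, name: str) -> str:
        """Label from one of the four sources by its short name."""
        try:
            return getattr(self, name)
        except AttributeError:
            raise SchemaError(f"unknown label source {name!r}") from None


# --- trait table ------------------------------------------------------------


@dataclass(frozen=True)
class TraitTable:
    """Structural and compositional class per fuel-type code.

    Used to type a mismatch between two codes as differing in structure,
    composition, or both.  The shipped default derives classes from the FBP
    System's descriptive fuel-type names and is a synthetic rubric,
    overridable by config.
    """

    traits: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def structural(self, code: str) -> str:
        return self._get(code)[0]

    def compositional(self, code: str) -> str:
        return self._get(code)[1]

    def _get(self, code: str) -> tuple[str, str]:
        c = collapse_code(code)
        try:
            return self.traits[c]
        except KeyError:
            raise TraitError(f"fuel-type code {c!r} absent from trait table") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitTable":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping[str, str]]) -> "TraitTable":
        traits = {}
        for code, entry in raw.items():
            validate_code(code)
            traits[code] = (entry["structural_class"], entry["compositional_class"])
        return cls(traits=traits)


def default_traits() -> TraitTable:
    """Trait table shipped with the package (collapsed vocabulary)."""
    ref = resources.files("fueltyping.data").joinpath("default_traits.yaml")
    with ref.open(encoding="utf-8") as fh:
        return TraitTable.from_mapping(yaml.safe_load(fh))


def load_species_registry() -> dict[str, dict[str, str]]:
    """Provincial species letter-code registry: code -> {name, habit}.

    ``habit`` is conifer, broadleaf, or deciduous_conifer (western larch) —
    the distinction the deciduous-percent derivation hinges on.
    """
    ref = resources.files("fueltyping.data").joinpath("species_codes.yaml")
    with ref.open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)
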