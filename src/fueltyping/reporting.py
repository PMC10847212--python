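"""Result surfaces and the end-to-end synthetic pipeline.

Emits the study's reporting tables from any label collection: fuel-type
frequency by source (table 3 style), per-type mismatch frequency by
comparison axis with an overall row (table 4 style), suitability and
confidence summaries, and the three inventory-attribute paired t-tests.
``run_synthetic`` wires the whole pipeline — survey generation, inventory
bias, rule-engine classification, 50-m/250-m map building and sampling,
agreement statistics — from a single seeded config and writes plain-text
outputs plus a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from .errors import SchemaError
from .fuel_rules import RuleSet, classify_all, default_ruleset
from .map_sampler import FuelGrid, rasterize_polygons, sample_at, square_patch, write_ascii_grid
from .plot_model import COLLAPSED_CODES, PlotLabels, collapse_code, write_plots
from .synthetic_survey import (
    BiasModel,
    SurveyDesign,
    apply_inventory_bias,
    default_bias,
    default_design,
    generate_field_plots,
)

_SOURCES = ("field_assigned", "field_decision_tree", "provincial", "national")


def table3(labels: Sequence[PlotLabels]) -> pd.DataFrame:
    """Fuel-type frequency per source over the collapsed vocabulary.

    Rows are collapsed fuel codes (canonical order, restricted to codes that
    occur), columns the four sources; integer counts, column sums equal n.
    """
    counts = {
        src: pd.Series([collapse_code(l.source(src)) for l in labels]).value_counts()
        for src in _SOURCES
    }
    observed = set().union(*(c.index for c in counts.values())) if labels else set()
    order = [c for c in COLLAPSED_CODES if c in observed]
    df = pd.DataFrame(
        {src: [int(counts[src].get(code, 0)) for code in order] for src in _SOURCES},
        index=pd.Index(order, name="fuel_type"),
    )
    return df


def format_table3(df: pd.DataFrame) -> pd.DataFrame:
    """Render zero counts as the dash convention of the printed table."""
    return df.map(lambda v: "-" if v == 0 else str(int(v)))


def table4(axes: Mapping[str, ag.ConfusionMatrix]) -> pd.DataFrame:
    """Per-type mismatch "count (pct%)" cells per axis, plus an Overall row.

    The overall row is the sum of per-type mismatch counts with its percent
    taken over each axis's n — a derived quantity, never independently
    stored.
    """
    mismatches = {name: ag.per_type_mismatch(cm) for name, cm in axes.items()}
    observed = set().union(*(set(m) for m in mismatches.values())) if axes else set()
    order = [c for c in COLLAPSED_CODES if c in observed]
    data: dict[str, list[str]] = {}
    for name, cm in axes.items():
        col = []
        for code in order:
            entry = mismatches[name].get(code)
            col.append("-" if entry is None else f"{entry[0]} ({entry[1]}%)")
        total = sum(c for c, _ in mismatches[name].values())
        pct = int(ag.round_half_away(100.0 * total / cm.n)) if cm.n else 0
        col.append(f"{total} ({pct}%)")
        data[name] = col
    return pd.DataFrame(data, index=pd.Index(order + ["Overall"], name="fuel_type"))


# --- end-to-end synthetic run ----------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a seeded end-to-end synthetic run.

    ``field_agreement_rate`` controls how often the simulated subjective
    field call matches the field decision-tree label (1.0 makes them
    identical, the closed-loop setting); ``patch_half_side`` is the half-side
    (m) of the square map polygon drawn around each plot.
    """

    seed: int = 0
    design: SurveyDesign = dc_field(default_factory=default_design)
    bias: BiasModel = dc_field(default_factory=default_bias)
    ruleset: RuleSet = dc_field(default_factory=default_ruleset)
    grid_cell_sizes: tuple[float, float] = (50.0, 250.0)
    patch_half_side: float = 150.0
    field_agreement_rate: float = 0.25
    axes: tuple[ag.ComparisonAxis, ...] = ag.DEFAULT_AXES
    output_dir: str | Path | None = None


@dataclass(frozen=True)
class RunResult:
    field_plots: list
    inventory_plots: list
    labels: list[PlotLabels]
    axes: dict[str, ag.ConfusionMatrix]
    attribute_tests: dict[str, ag.PairedTestResult]
    table3: pd.DataFrame
    table4: pd.DataFrame
    provincial_grid: FuelGrid
    national_grid: FuelGrid
    manifest: dict


def _perturb_labels(
    codes: list[str], rate: float, rng: np.random.Generator, vocabulary: Sequence[str]
) -> list[str]:
    out = []
    for c in codes:
        if rng.random() < rate or len(vocabulary) < 2:
            out.append(c)
        else:
            out.append(str(rng.choice([v for v in vocabulary if v != c])))
    return out


def run_synthetic(config: RunConfig) -> RunResult:
    """Run the full synthetic pipeline; byte-identical under a fixed config.

    Stages: generate the stratified survey; simulate the inventory view under
    the bias model; classify both views through the rule set (the inventory
    classification becomes the provincial map, rasterized at the finer cell
    size and re-extracted at plot locations; the same polygons rasterized at
    the coarser cell size become the national map); perturb the decision-tree
    labels into a subjective field call; compute the five comparison axes,
    the reporting tables, and the three attribute t-tests.
    """
    ss = np.random.SeedSequence(config.seed)
    s_survey, s_bias, s_field, s_suit = ss.spawn(4)
    field_plots = generate_field_plots(
        config.design, seed=int(s_survey.generate_state(1)[0] % (2**31))
    )
    bias_app = apply_inventory_bias(
        field_plots, config.bias, seed=int(s_bias.generate_state(1)[0] % (2**31))
    )
    inventory_plots = bias_app.records

    fdt = [r.fuel_type for r in classify_all(field_plots, config.ruleset)]
    inv_codes = [r.fuel_type for r in classify_all(inventory_plots, config.ruleset)]

    patches = [
        square_patch(p.x, p.y, config.patch_half_side, code)
        for p, code in zip(inventory_plots, inv_codes)
    ]
    pad = max(config.grid_cell_sizes)
    extent = (
        min(p.x for p in field_plots) - pad,
        min(p.y for p in field_plots) - pad,
        max(p.x for p in field_plots) + pad,
        max(p.y for p in field_plots) + pad,
    )
    fine, coarse = sorted(config.grid_cell_sizes)
    provincial_grid = rasterize_polygons(patches, fine, extent=extent)
    national_grid = rasterize_polygons(patches, coarse, extent=extent)
    provincial = [sample_at(provincial_grid, p.x, p.y) for p in field_plots]
    national = [sample_at(national_grid, p.x, p.y) for p in field_plots]

    rng_field = np.random.default_rng(s_field)
    vocab = sorted({*fdt, *provincial, *national})
    field_assigned = _perturb_labels(fdt, config.field_agreement_rate, rng_field, vocab)

    from .synthetic_survey import (
        DEFAULT_CONFIDENCE_WEIGHTS,
        DEFAULT_SUITABILITY_WEIGHTS,
    )

    rng_suit = np.random.default_rng(s_suit)
    sw_labels, sw_p = zip(*DEFAULT_SUITABILITY_WEIGHTS.items())
    cw_labels, cw_p = zip(*DEFAULT_CONFIDENCE_WEIGHTS.items())
    sw_p = np.array(sw_p, float) / sum(sw_p)
    cw_p = np.array(cw_p, float) / sum(cw_p)

    labels = []
    for i, p in enumerate(field_plots):
        cat = str(rng_suit.choice(sw_labels, p=sw_p))
        labels.append(
            PlotLabels(
                plot_id=p.plot_id,
                field_assigned=field_assigned[i],
                field_decision_tree=fdt[i],
                provincial=provincial[i],
                national=national[i],
                structure_match=cat in ("acceptable", "composition_mismatch"),
                composition_match=cat in ("acceptable", "structure_mismatch"),
                confidence=str(rng_suit.choice(cw_labels, p=cw_p)),
            )
        )

    axes = ag.compute_axes(labels, config.axes)
    tests = {
        attr: ag.paired_t_one_sided(
            [getattr(f, attr) for f in field_plots],
            [getattr(i, attr) for i in inventory_plots],
            direction="greater",
        )
        for attr in ("canopy_cover", "canopy_height", "live_density")
        if any(e.attribute == attr for e in config.bias.entries)
    }
    t3 = table3(labels)
    t4 = table4(axes)

    manifest = {
        "seed": config.seed,
        "n_plots": len(field_plots),
        "ruleset": config.ruleset.name,
        "grid_cell_sizes": list(config.grid_cell_sizes),
        "axes": {name: {"n": cm.n, "agreement_pct": cm.agreement_pct}
                 for name, cm in axes.items()},
        "attribute_tests": {
            attr: {"mean_diff": r.mean_diff, "sd_diff": r.sd_diff, "n": r.n,
                   "t": r.t, "df": r.df, "p_one_sided": r.p_one_sided}
            for attr, r in tests.items()
        },
        "clipped_fraction": bias_app.clipped_fraction,
    }

    result = RunResult(
        field_plots=field_plots,
        inventory_plots=inventory_plots,
        labels=labels,
        axes=axes,
        attribute_tests=tests,
        table3=t3,
        table4=t4,
        provincial_grid=provincial_grid,
        national_grid=national_grid,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_plots(result.field_plots, out_dir / "plots_field.csv")
    write_plots(result.inventory_plots, out_dir / "plots_inventory.csv")
    labels_df = pd.DataFrame(
        [
            {
                "plot_id": l.plot_id,
                **{src: l.source(src) for src in _SOURCES},
                "suitability": l.suitability_category,
                "confidence": l.confidence,
            }
            for l in result.labels
        ]
    )
    labels_df.to_csv(out_dir / "labels.csv", index=False)
    format_table3(result.table3).to_csv(out_dir / "table3.csv")
    result.table4.to_csv(out_dir / "table4.csv")
    for name, cm in result.axes.items():
        pd.DataFrame(cm.to_rows()[1:], columns=cm.to_rows()[0]).to_csv(
            out_dir / f"confusion_{name}.csv", index=False
        )
    write_ascii_grid(result.provincial_grid, out_dir / "grid_provincial.asc")
    write_ascii_grid(result.national_grid, out_dir / "grid_national.asc")
    manifest = dict(result.manifest)
    digests = {}
    for f in sorted(out_dir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["file_digests"] = digests
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_labels(path: str | Path) -> list[PlotLabels]:
    """Read a labels.csv written by :func:`run_synthetic` back into objects."""
    df = pd.read_csv(path)
    required = {"plot_id", *_SOURCES}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"labels file missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cat = getattr(row, "suitability", "acceptable")
        out.append(
            PlotLabels(
                plot_id=str(row.plot_id),
                field_assigned=row.field_assigned,
                field_decision_tree=row.field_decision_tree,
                provincial=row.provincial,
                national=row.national,
                structure_match=cat in ("acceptable", "composition_mismatch"),
                composition_match=cat in ("acceptable", "structure_mismatch"),
                confidence=getattr(row, "confidence", "not_described"),
            )
        )
    return out
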