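import pytest

from fueltyping import default_design, default_ruleset, default_traits, generate_field_plots
from fueltyping.plot_model import Landcover, PlotRecord
from fueltyping.fuel_rules import landcover_density


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def traits():
    return default_traits()


@pytest.fixture(scope="session")
def survey76():
    """One default 76-plot stratified survey (fixed seed)."""
    return generate_field_plots(default_design(), seed=20)


def make_plot(**overrides) -> PlotRecord:
    """A valid treed upland plot; any field overridable per test."""
    cover = overrides.pop("canopy_cover", 50.0)
    defaults = dict(
        plot_id="T001",
        x=500.0,
        y=500.0,
        bec_zone="IDF",
        bec_subzone="dk",
        landcover=Landcover(
            vegetated=True,
            treed=cover >= 10.0,
            site="upland",
            density_class=landcover_density(min(max(cover, 0.0), 100.0)),
        ),
        canopy_cover=cover,
        canopy_height=15.0,
        canopy_age=90.0,
        live_density=900.0,
        dead_density=60.0,
        pct_dead_overstory=5.0,
        species1="FD" if cover >= 10.0 else None,
        species1_pct=80.0 if cover >= 10.0 else 0.0,
    )
    defaults.update(overrides)
    return PlotRecord(**defaults)
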