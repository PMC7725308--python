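import pytest

from honeyassay.plate_model import (
    HONEY_CONCENTRATIONS,
    ORGANISMS,
    RelativeGrowthGrid,
)


def make_grid(fill=None, per_condition=None, occasion_id="occ1"):
    """Complete 4x6 relative-growth grid from a constant or a mapping."""
    values = {}
    for org in ORGANISMS:
        for conc in HONEY_CONCENTRATIONS:
            key = (org, float(conc))
            if per_condition is not None:
                values[key] = per_condition[key]
            else:
                values[key] = float(fill)
    return RelativeGrowthGrid(values=values, occasion_id=occasion_id)


@pytest.fixture
def grid_factory():
    return make_grid
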