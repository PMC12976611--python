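import pytest

import annuflow as af


@pytest.fixture(scope="session")
def preset():
    return af.validate_params(af.PRESETS["paper-default"])


@pytest.fixture(scope="session")
def trough(preset):
    # narrowest station: moderate favourable wall forcing
    return af.make_section(preset, 0.75, 0.0)


@pytest.fixture(scope="session")
def crest(preset):
    return af.make_section(preset, 0.25, 0.0)


@pytest.fixture()
def grid(preset, trough):
    return af.make_radial_grid(preset, trough)


def solve_all(params, zt=0.75, n=257):
    """Full pipeline at one station; shared helper for the suite."""
    section = af.make_section(params, zt, 0.0)
    grid = af.make_radial_grid(params, section, n)
    H = af.solve_temperature(params, section, grid)
    xi = af.solve_concentration(params, section, grid, H)
    vel = af.solve_orders(params, section, grid, H, xi)
    return section, grid, H, xi, vel
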