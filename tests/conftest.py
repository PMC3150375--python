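import numpy as np
import pytest

from perfuse import chamber_sim as cs
from perfuse import transport as tr


@pytest.fixture(scope="session")
def design_point():
    """Reference chamber design: setting, geometry, ligand, receptor."""
    return tr.reference_design_point()


@pytest.fixture(scope="session")
def design_solution(design_point):
    """Converged steady field + budget at the reference design point."""
    setting, geom, ligand, receptor = design_point
    grid = cs.default_grid()
    uptake = tr.uptake_velocity(receptor)
    floor = cs.FloorModel.uniform(grid.nx, qs=1.0, uptake=uptake)
    v = tr.mean_velocity(setting, geom) * 1e-3  # m/s
    d = ligand.diffusivity_m2_s
    field = cs.solve_steady(grid, v, d, floor)
    summary = cs.capture_fraction(field, floor, v, d)
    return {"grid": grid, "floor": floor, "v": v, "d": d,
            "uptake": uptake, "field": field, "summary": summary}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
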