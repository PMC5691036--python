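import numpy as np
import pytest

import wetlandch4 as w
from wetlandch4.io import read_tables
from wetlandch4.pipeline import run_all


@pytest.fixture(scope="session")
def grid():
    return w.DepthGrid()


@pytest.fixture(scope="session")
def surface_scenario():
    return w.make_scenario("surface_source", seed=0)


@pytest.fixture(scope="session")
def surface_tables(surface_scenario, tmp_path_factory):
    """Simulated campaign CSVs for the surface_source scenario, read back."""
    d = tmp_path_factory.mktemp("surface_data")
    frames = w.simulate_measurements(surface_scenario)
    for name, df in frames.items():
        df.to_csv(d / f"{name}.csv", index=False)
    return read_tables({name: d / f"{name}.csv" for name in frames})


@pytest.fixture(scope="session")
def pipeline_report(surface_scenario, surface_tables):
    """One full-pipeline run at the package defaults (seed 0, 40k iterations)."""
    sc = surface_scenario
    cfg = w.InversionConfig(rng_seed=0)
    return run_all(
        surface_tables, cfg, sc.do_threshold, sc.areas,
        grid=sc.grid, dmodel=sc.dmodel, seed=0,
    )


def constant_diffusivity(grid, d=1.0):
    return w.DiffusivityModel(fixed_profile=np.full(grid.n_layers, d))
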