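"""Shared fixtures: small synthetic worlds and a scaled pipeline config.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from channelfauna import pipeline
from channelfauna.grids import GridSpec, RasterLayer
from channelfauna.synthetic_world import WorldConfig, make_world


@pytest.fixture(scope="session")
def small_world():
    """A 16x20 world: (monthly layers, bathymetry, land) at seed 7."""
    cfg = WorldConfig(n_rows=16, n_cols=20, cell_size=2.0)
    return make_world(cfg, seed=7), cfg


@pytest.fixture(scope="session")
def tiny_spec() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, cell_size=1.0, origin_x=0.0, origin_y=10.0)


@pytest.fixture
def flat_sea(tiny_spec) -> RasterLayer:
    """All-sea uniform layer on the 10x10 grid."""
    return RasterLayer(spec=tiny_spec, name="flat", values=np.ones(tiny_spec.shape))


def scaled_config(seed: int, out: str, **extra) -> dict:
    """Pipeline config small enough for the test suite's time budget."""
    overrides = {
        "seed": seed,
        "output_dir": out,
        # the analysis grid must resolve the observer-bias bump relative to
        # the KDE bandwidth; 30x40 is the smallest grid that does
        "grid": {"n_rows": 30, "n_cols": 40, "cell_size": 4.0},
        "background": {"n": 1000},
        "simulate": {
            "n_plankton": 120,
            "strandings": {"n": 120},
            "targets": [
                {
                    "name": "shelf_cetacean",
                    "guild": "cetaceans",
                    "species": "Phocoena phocoena",
                    "coefficients": {"dist_200m": -4.0},
                    "n_per_season": {"spring": 100, "summer": 100,
                                     "autumn": 100, "winter": 100},
                },
                {
                    "name": "summer_turtle",
                    "guild": "marine turtles",
                    "species": "Dermochelys coriacea",
                    "coefficients": {"sst": 3.0},
                    "n_per_season": {"spring": 1, "summer": 40,
                                     "autumn": 23, "winter": 2},
                },
            ],
        },
        "maxent": {"k_folds": 3, "jackknife": False, "max_sweeps": 200,
                   "n_knots": 5},
    }
    for k, v in extra.items():
        overrides[k] = v
    return pipeline.load_config(overrides=overrides)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full scaled pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("run")
    cfg = scaled_config(5, str(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ws = pipeline.simulate(cfg)
        manifest = pipeline.run_analysis(cfg, ws)
        hot = pipeline.run_hotspots(cfg, ws)
        summ = pipeline.run_strandings(cfg, ws)
    return {"cfg": cfg, "ws": ws, "manifest": manifest, "hotspots": hot,
            "strandings": summ, "out": out}
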