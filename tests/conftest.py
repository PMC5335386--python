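"""Shared fixtures: scenes and the full-scale multi-seed simulation runs.

The 30-seed control / PAR1-activated / half-density simulation campaign is
expensive enough to share session-wide; every test that needs full-scale
engine output draws from :func:`fig4_results`.
"""

import numpy as np
import pytest

from gluclear import geometry as G
from gluclear import mcsim as M

N_SEEDS = 30


@pytest.fixture(scope="session")
def control_scene():
    return G.build_simplified_scene(G.CONTROL_SPEC)


@pytest.fixture(scope="session")
def tfllr_scene():
    return G.build_simplified_scene(G.TFLLR_SPEC)


@pytest.fixture(scope="session")
def quick_config():
    """Small engine configuration for fast unit tests."""
    return M.SimConfig(n_iterations=400, n_molecules=400, record_stride=4)


@pytest.fixture(scope="session")
def fig4_results(control_scene, tfllr_scene):
    """Full-condition runs (2,000 molecules, 5,000 × 10 μs steps, 30 seeds)
    for the three headline conditions, recorded at every step."""
    cfg = M.SimConfig(record_stride=1)
    out = {}
    out["control"] = [M.run_simulation(control_scene, cfg, seed=s)
                      for s in range(N_SEEDS)]
    out["tfllr"] = [M.run_simulation(tfllr_scene, cfg, seed=s)
                    for s in range(N_SEEDS)]
    out["half_density"] = [
        M.run_simulation(control_scene, cfg, seed=s,
                         transporter_density=5400.0)
        for s in range(N_SEEDS)
    ]
    return out


def centroids_of(results, series):
    return np.array([M.count_centroid(r.time_ms, getattr(r, series))
                     for r in results])
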