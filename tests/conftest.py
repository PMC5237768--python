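"""Shared fixtures.

The femur baseline adaptation is expensive (~150 simulated days), so it is
computed once per session and shared; individual defect experiments are
cached per (implant modulus, degradation period) cell.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteoadapt import (
    ImplantState,
    MaterialState,
    RemodelConfig,
    generate_femur_domain,
    generate_plate_fixture,
    run_baseline,
    run_defect_experiment,
)
from osteoadapt.config import LoadCase, PointLoad


@pytest.fixture(scope="session")
def cfg() -> RemodelConfig:
    return RemodelConfig()


@pytest.fixture(scope="session")
def femur_mesh(cfg):
    return generate_femur_domain(cfg)


@pytest.fixture(scope="session")
def femur_baseline(femur_mesh, cfg):
    """Converged intact-femur state plus its trace."""
    state, trace = run_baseline(femur_mesh, cfg)
    return state, trace


@pytest.fixture(scope="session")
def femur_cell(femur_mesh, femur_baseline, cfg):
    """Cached femur defect experiments keyed by (E1_0, T)."""
    state, _ = femur_baseline
    cache: dict[tuple[float, float], object] = {}

    def run(E1_0: float, T: float):
        key = (float(E1_0), float(T))
        if key not in cache:
            implant = ImplantState(E1_0=key[0], T=key[1], config=cfg)
            cache[key] = run_defect_experiment(femur_mesh, state, implant, cfg)
        return cache[key]

    return run


def tip_loaded_plate(nx: int, ny: int, force: float = 50.0, h: float = 1.0):
    """Cantilever plate with a vertical tip load, used across FEM tests."""
    mesh = generate_plate_fixture(nx, ny, h=h)
    case = LoadCase(loads=(PointLoad(force, 90.0, "tip", sense=(1.0, -1.0)),))
    return mesh, case


def uniaxial_plate(nx: int, ny: int, force: float = 100.0, h: float = 1.0):
    """Plate with roller supports (left edge x-fixed, one corner y-fixed) and
    a horizontal end load, realizing a pure uniaxial stress state."""
    mesh = generate_plate_fixture(nx, ny, h=h)
    left = mesh.node_sets.pop("fixed")
    mesh.node_sets["fixed_x"] = left
    corner = left[np.argmin(mesh.nodes[left, 1])]
    mesh.node_sets["fixed_y"] = np.array([corner])
    case = LoadCase(loads=(PointLoad(force, 0.0, "tip", sense=(1.0, 1.0)),))
    return mesh, case


@pytest.fixture
def plate_state(cfg):
    def make(mesh, rho=1.0):
        if np.isscalar(rho):
            return MaterialState.uniform(mesh, rho, cfg)
        return MaterialState.from_density(mesh, np.asarray(rho, float), cfg)

    return make
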