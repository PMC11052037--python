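"""Shared fixtures: reduced-scale vesicles and synthetic scenarios.

Everything is generated programmatically at session scope so the expensive
constructions (vesicle builds, scenario trajectories) are reused across
tests.
"""
from __future__ import annotations

import numpy as np
import pytest

import vesiclegas as vg


@pytest.fixture(scope="session")
def reduced_spec() -> vg.VesicleSpec:
    return vg.default_vesicle_spec()


@pytest.fixture(scope="session")
def reduced_vesicle(reduced_spec) -> vg.Frame:
    return vg.build_vesicle(reduced_spec, 18.0, seed=0)


@pytest.fixture(scope="session")
def full_scale_spec() -> vg.VesicleSpec:
    """The full-sized vesicle: 1188 outer / 495 inner DOPC lipids."""
    return vg.VesicleSpec(n_outer=1188, n_inner=495,
                          apl_outer=0.95, apl_inner=0.50)


@pytest.fixture(scope="session")
def full_scale_vesicle(full_scale_spec) -> vg.Frame:
    return vg.build_vesicle(full_scale_spec, 26.0, seed=1)


@pytest.fixture(scope="session")
def schedule_scenario_run():
    """Trajectory with a planted bulk-to-everywhere transfer schedule."""
    sc = vg.Scenario(
        n_frames=4, n_gas=60,
        gas_plan=[(0.0, {"bulk": 1.0}),
                  (3.0, {"bulk": 0.2, "outer": 0.2, "gap": 0.2,
                         "inner": 0.2, "confined": 0.2})],
        seed=11)
    frames, truth = vg.generate(sc)
    return sc, frames, truth


@pytest.fixture(scope="session")
def bubble_scenario_run():
    """One bulk nanobubble (r = 1.2 nm) plus a small droplet in the gap."""
    sc = vg.Scenario(
        box=20.0, n_frames=1, n_gas=24, species="argon",
        bubbles=[vg.BubblePlan("bulk", 1.2, "argon"),
                 vg.BubblePlan("gap", 0.45, "argon")],
        seed=5)
    frames, truth = vg.generate(sc)
    return sc, frames, truth


@pytest.fixture(scope="session")
def tilted_scenario_run():
    """Lipids tilted 30 degrees from the radial director, no noise."""
    sc = vg.Scenario(n_frames=2, n_gas=10, chain_tilt=30.0, seed=3)
    frames, truth = vg.generate(sc)
    return sc, frames, truth
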