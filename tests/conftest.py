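"""Shared fixtures.

The expensive Langevin runs are session-scoped and shared between the unit
tests and the acceptance tests; all seeds are fixed so every run is
bit-reproducible.
"""

from __future__ import annotations

import warnings

import pytest

from gomotor import (ScenarioConfig, ToyMotorSpec, build_toy_system,
                     run_scenario)
from gomotor.dynamics import LangevinConfig, constant_force_check

warnings.filterwarnings("ignore", message=".*CA-CA distances.*")


@pytest.fixture(scope="session")
def toy_system():
    """Toy motor + filament + contact maps + Pi subset (default spec)."""
    return build_toy_system()


@pytest.fixture(scope="session")
def toy_structures():
    spec = ToyMotorSpec()
    from gomotor import make_toy_motor
    return make_toy_motor(spec)


@pytest.fixture(scope="session")
def demo_bundle():
    """Leading + trailing toy simulations (the toy_demo scenario)."""
    cfg = ScenarioConfig(scenario="toy_demo", seed=11, n_sample=1_000_000)
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def powerstroke_populations():
    """Pooled pre/post basin populations with and without the Pi subset.

    Populations of a two-state system with dwell times of order 10^5 steps
    carry large single-trajectory variance, so each condition pools three
    independent replicas started from the pre conformation after a long
    relaxation — the same protocol the acceptance script uses.
    """
    out = {}
    for scen in ("powerstroke_with_pi", "powerstroke_without_pi"):
        cfg = ScenarioConfig(scenario=scen, seed=9000, replicas=3,
                             n_sample=2_000_000,
                             langevin={"n_relax": 100_000})
        bundle = run_scenario(cfg)
        out[scen] = {
            "fraction_pre": bundle["fraction_pre"],
            "replicas": bundle["replica_fractions_pre"],
            "n_samples": int(bundle["summaries"]["converter_rmsd"].samples.size),
        }
    return out


@pytest.fixture(scope="session")
def strain_bundle():
    """Trailing-head strain scan at 0/3/5 kJ mol^-1 nm^-1."""
    cfg = ScenarioConfig(scenario="strain_scan", seed=11, replicas=3,
                         n_sample=700_000)
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def tether_free():
    """Single tethered bead, no external force: trap statistics."""
    return constant_force_check(
        k=100.0, F=0.0,
        config=LangevinConfig(zeta=5.0, h=0.0025, n_relax=20_000,
                              n_sample=2_000_000, save_every=10, seed=3))


@pytest.fixture(scope="session")
def tether_forced():
    """Single tethered bead under a constant force F = 0.3 k."""
    return constant_force_check(
        k=100.0, F=30.0,
        config=LangevinConfig(zeta=5.0, h=0.0025, n_relax=20_000,
                              n_sample=2_000_000, save_every=10, seed=4))
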