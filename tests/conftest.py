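"""Shared fixtures: protocol ensembles are expensive, so they are simulated
once per session at the study's protocol size (5 replicas x 20 runs) and
reused by the classifier, kinetics and acceptance tests."""

import time

import numpy as np
import pytest

from ramdpath.ramd_engine import (LangevinParams, RAMDParams, run_protocol,
                                  unit_convert_force)
from ramdpath.toy_system import apply_modification, build_archetype

# the protocol constants used throughout: defaults except for the time budget,
# which is cut from 100 ns to 2 ns — the slowest archetype dissociates in
# ~0.2 ns, so this censors nothing while bounding runtime
PROTOCOL_RAMD = RAMDParams(max_time=2000.0)
LANG = LangevinParams()


@pytest.fixture(scope="session")
def protocol_ramd():
    return PROTOCOL_RAMD


@pytest.fixture(scope="session")
def lang():
    return LANG


@pytest.fixture(scope="session")
def agonist_protocol():
    return run_protocol(build_archetype("agonist_like", 1), PROTOCOL_RAMD, LANG,
                        n_replicas=5, n_runs=20, base_seed=101)


@pytest.fixture(scope="session")
def cationic_protocol():
    return run_protocol(build_archetype("cationic_like", 1), PROTOCOL_RAMD, LANG,
                        n_replicas=5, n_runs=20, base_seed=202)


@pytest.fixture(scope="session")
def neutral_protocol_timed():
    t0 = time.perf_counter()
    result = run_protocol(build_archetype("neutral_like", 1), PROTOCOL_RAMD, LANG,
                          n_replicas=5, n_runs=20, base_seed=303)
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def neutral_protocol(neutral_protocol_timed):
    return neutral_protocol_timed[0]


@pytest.fixture(scope="session")
def anchor_removed_protocol():
    system = apply_modification(build_archetype("neutral_like", 1),
                                "remove_all_anchor_interactions")
    return run_protocol(system, PROTOCOL_RAMD, LANG,
                        n_replicas=5, n_runs=20, base_seed=404)


@pytest.fixture(scope="session")
def symmetric_protocol():
    # 10 x 20 = 200 events for the balanced-exit check
    return run_protocol(build_archetype("symmetric", 1), PROTOCOL_RAMD, LANG,
                        n_replicas=10, n_runs=20, base_seed=505)


@pytest.fixture(scope="session")
def force_scan():
    """100 trajectories at 0.5x / 1x / 2x the default force, common seeds."""
    system = build_archetype("symmetric", 1)
    base = unit_convert_force(9.0)
    out = {}
    for mult in (0.5, 1.0, 2.0):
        ramd = RAMDParams(force_magnitude=base * mult, max_time=2000.0)
        out[mult] = run_protocol(system, ramd, LANG, n_replicas=5, n_runs=20,
                                 base_seed=606)
    return out


def marker_sets(system):
    return {"external": system.markers["external_marker"][None, :],
            "internal": system.markers["internal_marker"][None, :]}
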