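"""Shared fixtures: one mid-sized simulation and calibrated profiles,
generated once per session and reused by the module test files."""

from __future__ import annotations

import pytest

from pleomine.markerdb import (
    build_profile,
    calibrate_threshold,
    calibration_set_from_sequences,
)
from pleomine.simulate import (
    CORE_MARKERS,
    HALLMARK_FAMILIES,
    Halovirome,
    SimulationConfig,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=7,
        n_genomes_per_genus={"alpha": 5, "beta": 5, "gamma": 3, "delta": 4, "epsilon": 4},
        n_decoy_contigs=8,
        n_hosts=4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_small() -> Halovirome:
    return Halovirome.generate(small_config())


@pytest.fixture(scope="session")
def profiles_small(sim_small):
    """Profiles built directly from the planted families (true positives)
    and calibrated against the decoy families (true negatives)."""
    profiles = {}
    tn = sim_small.calibration_tn()
    for fam in CORE_MARKERS + HALLMARK_FAMILIES:
        tp = sim_small.calibration_tp(fam)
        if not tp:
            continue
        prof = build_profile(tp, name=fam)
        calibrate_threshold(prof, calibration_set_from_sequences(prof, tp, tn))
        profiles[fam] = prof
    return profiles
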