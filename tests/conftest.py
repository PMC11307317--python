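"""Shared fixtures: cached simulations of the packaged study conditions."""

from __future__ import annotations

import numpy as np
import pytest

from calorimix.calorimetry import baseline_and_integrate
from calorimix.fixtures import community_params, simulate_condition
from calorimix.simulate import simulate_serial_passages


@pytest.fixture(scope="session")
def mono_runs():
    """Noiseless 5-passage monoculture runs (central lineage) per condition."""
    out = {}
    for cond in ("am", "bt", "fp"):
        params = community_params(cond)
        out[cond] = simulate_serial_passages(params, 5, dt=0.02)
    return out


@pytest.fixture(scope="session")
def mono_curves(mono_runs):
    """Baseline-corrected heat curves of the last (steady-state) passage."""
    return {
        cond: baseline_and_integrate(runs[-1].heat_flow_series(condition=cond), 0.0)
        for cond, runs in mono_runs.items()
    }


@pytest.fixture(scope="session")
def consortium_run():
    """Noiseless 5-passage consortium run (central lineage)."""
    params = community_params("consortium")
    return simulate_serial_passages(params, 5, dt=0.02)


@pytest.fixture(scope="session")
def stability_series():
    """Drift-scheduled 7-passage, 3-lineage heat-flow series per condition."""
    out = {}
    for cond in ("consortium", "am", "bt", "fp"):
        series, _ = simulate_condition(cond, seed=0, drift=True)
        out[cond] = series
    return out


@pytest.fixture(scope="session")
def resilience_runs():
    """Reference + three 100x under-inoculation scenarios (3 lineages each)."""
    out = {"reference": simulate_condition("consortium", seed=0)}
    for victim in ("AM", "BT", "FP"):
        out[victim] = simulate_condition(
            "consortium", seed=0, per_strain_dilution={victim: 0.01}
        )
    return out


@pytest.fixture(scope="session")
def pca_grid():
    return np.arange(0.0, 24.0 + 1e-9, 0.1)
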