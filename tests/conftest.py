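"""Shared fixtures.

The heavy ensemble fixtures are session-scoped and shared between the
motility-trend, fractional-order and cluster-morphology tests, so each
study condition is simulated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from adhact.experiments import analyze_condition, preset_params, simulate_condition
from adhact.lattice import LatticeState
from adhact.params import ModelParams

# replicate counts for the session ensembles: large enough for the ensemble
# MSD fits to resolve the published fractional orders, small enough to keep
# the suite fast
N_TABLE2 = 30
N_FIG8 = 24


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Small fast lattice for unit-level dynamics tests."""
    return ModelParams(width=80, height=80, A_target=200, P_target=160,
                       duration_mcs=200, burn_in_mcs=0)


@pytest.fixture
def small_state(small_params):
    return LatticeState.initialize(small_params)


def _run_condition(name, n, base_seed, fit_models=(), snapshot_interval=0):
    params = preset_params(name)
    results = simulate_condition(params, n, base_seed,
                                 snapshot_interval=snapshot_interval)
    summary = analyze_condition(results, fit_models=fit_models)
    return params, results, summary


@pytest.fixture(scope="session")
def table2_ensembles():
    """The four no-feedback study conditions (weak/strong adhesion at low/high
    de novo formation rate), with extended-Fürth and FKK fits."""
    out = {}
    for i, name in enumerate(
        ("table2-weak", "table2-weak-high-ps", "table2-strong-low-ps", "table2-pivoting")
    ):
        params, results, summary = _run_condition(
            name, N_TABLE2, base_seed=1000 * (i + 1), fit_models=("furth_dt", "fkk")
        )
        out[name] = {"params": params, "results": results, "summary": summary}
    return out


@pytest.fixture(scope="session")
def fig8_ensembles():
    """The two equal-area cluster-morphology conditions: many small clusters
    (blue) vs few large clusters (orange), with adhesion snapshots."""
    out = {}
    for i, name in enumerate(("fig8-blue", "fig8-orange")):
        params, results, summary = _run_condition(
            name, N_FIG8, base_seed=7000 * (i + 1), fit_models=("furth_dt",),
            snapshot_interval=100,
        )
        out[name] = {"params": params, "results": results, "summary": summary}
    return out
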