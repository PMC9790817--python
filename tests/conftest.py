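"""Shared fixtures.

``ref_params`` is the packaged full-scale reference configuration;
``small_params`` scales its referral volume down ~20x so stochastic tests
run in seconds while keeping every mechanism (groups, regimens, retention,
resources, costs) intact.
"""

from __future__ import annotations

import numpy as np
import pytest

from dvtflow import reference_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture()
def small_params(ref_params):
    p = ref_params.copy_deep()
    p.demand.referral_rate = ref_params.demand.referral_rate / 20.0
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(20221226)


def run_kpis(params, scenario, seed):
    """One replication -> merged KPI dict (helper used across test modules)."""
    from dvtflow import compute_financial_kpis, compute_operational_kpis, run_scenario
    from dvtflow.accounting import kpi_dict

    log = run_scenario(params, scenario, seed)
    op = compute_operational_kpis(log)
    fin, _ = compute_financial_kpis(log, params.costs, params.regimens)
    return kpi_dict(op, fin)
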