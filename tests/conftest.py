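import numpy as np
import pytest

from selfreplicator import (
    NondimParams,
    OCPProblem,
    StrategySpec,
    UpshiftScenario,
    run_upshift,
    solve_ocp,
)


@pytest.fixture(scope="session")
def ref_params() -> NondimParams:
    """Reference environment: E_M = 1, K = 0.003."""
    return NondimParams(E_M=1.0, K=0.003)


@pytest.fixture(scope="session")
def upshift_scenario() -> UpshiftScenario:
    """The canonical upshift: 0.2*E_M -> E_M = 1, K = 0.003, horizon 30."""
    return UpshiftScenario(E_M_post=1.0, K=0.003, pre_factor=0.2, horizon=30.0)


@pytest.fixture(scope="session")
def upshift_trajectories(upshift_scenario):
    """Closed-loop upshift runs for the three feedback strategies."""
    return {
        kind: run_upshift(upshift_scenario, StrategySpec(kind))
        for kind in ("nutrient_only", "precursor_only", "on_off")
    }


@pytest.fixture(scope="session")
def upshift_ocp(ref_params, upshift_scenario):
    """Direct solution of the growth-maximization problem on the canonical
    upshift (N = 1000, horizon 30), shared across tests."""
    problem = OCPProblem(
        params=ref_params, init=upshift_scenario.initial_state, horizon=30.0, N=1000
    )
    return solve_ocp(problem)
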