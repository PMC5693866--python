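import numpy as np
import pytest

from togglectl import (CellState, ExchangeParams, ToggleModel, ToggleParams,
                       default_exchange, default_params)


@pytest.fixture(scope="session")
def params() -> ToggleParams:
    return default_params()


@pytest.fixture(scope="session")
def exchange() -> ExchangeParams:
    return default_exchange()


@pytest.fixture(scope="session")
def exchange_sym() -> ExchangeParams:
    return default_exchange("symmetric")


@pytest.fixture(scope="session")
def model() -> ToggleModel:
    return ToggleModel.default()


@pytest.fixture(scope="session")
def reference_u() -> tuple[float, float]:
    return (20.0, 0.25)


@pytest.fixture(scope="session")
def symmetric_params(params) -> ToggleParams:
    """Mirror-symmetric circuit: L and T branches identical."""
    return params.replace(
        k_m0_T=params.k_m0_L, k_m_T=params.k_m_L, k_p_T=params.k_p_L,
        g_m_T=params.g_m_L, g_p_T=params.g_p_L,
        theta_TetR=params.theta_LacI, theta_IPTG=params.theta_aTc,
        eta_TetR=params.eta_LacI, eta_IPTG=params.eta_aTc,
    )


@pytest.fixture(scope="session")
def saddle_state(model, reference_u) -> CellState:
    return model.equilibria(reference_u).saddle().state


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
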