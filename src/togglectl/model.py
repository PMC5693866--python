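"""High-level model object tying together simulation, analysis and control.

:class:`ToggleModel` bundles a parameter set with an inducer-exchange model
and exposes every analysis as a method, so a session reads like::

    model = ToggleModel.default()
    report = model.equilibria((20, 0.25))
    traj = model.simulate(state0, schedule, t_end=600)
    record = model.control("ssa", cfg, t_end=1500, seed=1)
"""

from __future__ import annotations

import numpy as np

from . import control as _control
from . import deterministic as _det
from . import stochastic as _ssa
from .params import (REFERENCE_INPUTS, CellState, ExchangeParams,
                     InducerSchedule, ToggleParams, default_exchange,
                     default_params)

__all__ = ["ToggleModel"]


class ToggleModel:
    """A parameterised toggle-switch circuit with an exchange model."""

    def __init__(self, params: ToggleParams | None = None,
                 exchange: ExchangeParams | None = None):
        self.params = params if params is not None else default_params()
        self.exchange = exchange if exchange is not None else default_exchange()

    @classmethod
    def default(cls) -> "ToggleModel":
        """The fitted reference circuit with asymmetric inducer exchange."""
        return cls()

    @classmethod
    def from_yaml(cls, params_path, exchange: ExchangeParams | None = None,
                  ) -> "ToggleModel":
        return cls(ToggleParams.from_yaml(params_path), exchange)

    # -- deterministic ----------------------------------------------------
    def simulate(self, state0: CellState, schedule: InducerSchedule,
                 t_end: float, **kwargs) -> _det.Trajectory:
        return _det.integrate(state0, schedule, self.params, self.exchange,
                              t_end, **kwargs)

    def equilibria(self, u: tuple[float, float] = REFERENCE_INPUTS,
                   **kwargs) -> _det.EquilibriumReport:
        return _det.find_equilibria(u, self.params, self.exchange, **kwargs)

    def nullclines(self, u: tuple[float, float] = REFERENCE_INPUTS,
                   **kwargs) -> dict[str, np.ndarray]:
        return _det.nullclines(u, self.params, self.exchange, **kwargs)

    def separatrix(self, u: tuple[float, float] = REFERENCE_INPUTS,
                   **kwargs) -> np.ndarray:
        return _det.separatrix(u, self.params, self.exchange, **kwargs)

    def averaged_field(self, schedule: InducerSchedule,
                       **kwargs) -> _det.AveragedField:
        return _det.time_averaged_field(schedule, self.params, self.exchange,
                                        **kwargs)

    # -- stochastic -------------------------------------------------------
    def simulate_ssa(self, state0: CellState, schedule: InducerSchedule,
                     t_end: float, seed, **kwargs) -> _ssa.StochasticRun:
        return _ssa.simulate_ssa(state0, schedule, self.params, self.exchange,
                                 t_end, seed, **kwargs)

    def simulate_population(self, n: int, schedule: InducerSchedule,
                            t_end: float, seed, **kwargs,
                            ) -> list[_ssa.StochasticRun]:
        return _ssa.simulate_population(n, schedule, self.params,
                                        self.exchange, t_end, seed, **kwargs)

    # -- control ----------------------------------------------------------
    def control(self, plant: str, cfg: _control.ControllerConfig,
                t_end: float, state0: CellState | None = None,
                seed: int | None = None, **kwargs,
                ) -> _control.ClosedLoopRecord:
        if state0 is None:
            state0 = self.equilibria((cfg.u0_aTc, cfg.u0_IPTG)).saddle().state
        return _control.run_closed_loop(plant, state0, cfg, self.params,
                                        self.exchange, t_end, seed=seed,
                                        **kwargs)

    def forcing(self, forcing_schedule: InducerSchedule, t_end: float,
                t_release: float, seed, plant: str = "ssa",
                n_cells: int = 16, **kwargs) -> _control.ForcingResult:
        return _control.run_periodic_forcing(
            forcing_schedule, plant, n_cells, self.params, self.exchange,
            t_end, t_release, seed, **kwargs)
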