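"""In-silico feedback control and open-loop periodic forcing of a virtual cell.

Two independent single-input single-output controllers act on the circuit:
one adjusts external aTc to steer LacI-RFP toward its target, the other
adjusts external IPTG to steer TetR-GFP.  Both a proportional-integral (PI)
law and an on/off (bang-bang) law are provided.  Control inputs are
zero-order-held between fluorescence measurements, and the integral term
ignores the first ``t_d`` minutes of error to avoid start-up windup.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import deterministic, stochastic
from .params import (REFERENCE_INPUTS, CellState, ExchangeParams,
                     InducerSchedule, ToggleParams)

__all__ = [
    "ControllerConfig",
    "ClosedLoopRecord",
    "ForcingResult",
    "pi_law",
    "bangbang_law",
    "run_closed_loop",
    "run_periodic_forcing",
    "commitment_label",
]


def per_second(gain: float) -> float:
    """Convert an integral gain printed in 1/s to the internal 1/min."""
    return gain * 60.0


@dataclass
class ControllerConfig:
    """Targets, gains, bounds and timing of the dual controller.

    Integral gains multiply the error integral accumulated on the
    minute-scale measurement grid.  The defaults are the published gain
    values (K_I_L = 1.32e-4, K_I_T = 4.6e-4) applied on that grid: scaling
    them by 60 (as a literal per-second reading would require) destabilises
    the loop into a full-range limit cycle, inconsistent with the reported
    closed-loop behaviour — see the methods note.  Use :func:`per_second`
    if you do want the dimensional conversion.  ``target_LacI`` /
    ``target_TetR`` default to ``None``, meaning "use the
    unstable-equilibrium coordinates under basal inputs", resolved when the
    closed loop starts.
    """

    mode: str = "pi"  # "pi" | "bangbang"
    target_LacI: float | None = None
    target_TetR: float | None = None
    K_P_L: float = 3.3e-2
    K_I_L: float = 1.32e-4
    K_P_T: float = 1.65e-2
    K_I_T: float = 4.6e-4
    u0_aTc: float = REFERENCE_INPUTS[0]
    u0_IPTG: float = REFERENCE_INPUTS[1]
    u_min_aTc: float = 0.0
    u_max_aTc: float = 50.0
    u_min_IPTG: float = 0.0
    u_max_IPTG: float = 0.5
    t_d: float = 120.0       # integral window start (min)
    dt_meas: float = 5.0     # measurement / actuation interval (min)

    def __post_init__(self) -> None:
        if self.mode not in ("pi", "bangbang"):
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if not (0.0 <= self.u_min_aTc < self.u_max_aTc):
            raise ValueError("aTc bounds must satisfy 0 <= u_min < u_max")
        if not (0.0 <= self.u_min_IPTG < self.u_max_IPTG):
            raise ValueError("IPTG bounds must satisfy 0 <= u_min < u_max")
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if self.dt_meas <= 0:
            raise ValueError("dt_meas must be > 0")


def pi_law(t: float, LacI_meas: float, TetR_meas: float, integ_L: float,
           integ_T: float, cfg: ControllerConfig) -> tuple[float, float]:
    """Dual PI law: inputs from current and accumulated tracking errors.

    ``integ_L``/``integ_T`` are the error integrals accumulated by the caller
    (trapezoidal rule on the measurement grid, starting at ``t_d``).  The
    integral contribution is exactly zero while ``t <= t_d``.  Outputs are
    clamped to the admissible bounds.
    """
    e_L = cfg.target_LacI - LacI_meas
    e_T = cfg.target_TetR - TetR_meas
    i_L = integ_L if t > cfg.t_d else 0.0
    i_T = integ_T if t > cfg.t_d else 0.0
    u_aTc = cfg.u0_aTc + cfg.K_P_L * e_L + cfg.K_I_L * i_L
    u_IPTG = cfg.u0_IPTG + cfg.K_P_T * e_T + cfg.K_I_T * i_T
    return (
        float(np.clip(u_aTc, cfg.u_min_aTc, cfg.u_max_aTc)),
        float(np.clip(u_IPTG, cfg.u_min_IPTG, cfg.u_max_IPTG)),
    )


def bangbang_law(LacI_meas: float, TetR_meas: float,
                 cfg: ControllerConfig) -> tuple[float, float]:
    """On/off law: maximal input when below target, minimal otherwise.

    Equality takes the minimal branch.
    """
    u_aTc = cfg.u_max_aTc if cfg.target_LacI > LacI_meas else cfg.u_min_aTc
    u_IPTG = cfg.u_max_IPTG if cfg.target_TetR > TetR_meas else cfg.u_min_IPTG
    return float(u_aTc), float(u_IPTG)


@dataclass
class ClosedLoopRecord:
    """Everything a closed-loop run measured, decided and applied."""

    config: ControllerConfig
    times: np.ndarray            # measurement times (min)
    measured: np.ndarray         # (n, 2) (LacI, TetR) read at each time
    applied: np.ndarray          # (n, 2) (u_aTc, u_IPTG) held after each time
    integrals: np.ndarray        # (n, 2) accumulated error integrals
    plant_times: np.ndarray
    plant_states: np.ndarray     # (m, 6)
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.times,
            "LacI_meas": self.measured[:, 0],
            "TetR_meas": self.measured[:, 1],
            "u_aTc": self.applied[:, 0],
            "u_IPTG": self.applied[:, 1],
            "integral_L": self.integrals[:, 0],
            "integral_T": self.integrals[:, 1],
        })

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# seed: {self.seed}\n")
            self.to_dataframe().to_csv(fh, index=False)


def _resolve_targets(cfg: ControllerConfig, p: ToggleParams,
                     ex: ExchangeParams) -> ControllerConfig:
    if cfg.target_LacI is not None and cfg.target_TetR is not None:
        return cfg
    report = deterministic.find_equilibria((cfg.u0_aTc, cfg.u0_IPTG), p, ex)
    saddle = report.saddle()
    return replace(cfg,
                   target_LacI=cfg.target_LacI or saddle.LacI,
                   target_TetR=cfg.target_TetR or saddle.TetR)


def run_closed_loop(plant: str, state0: CellState, cfg: ControllerConfig,
                    p: ToggleParams, ex: ExchangeParams, t_end: float,
                    seed: int | None = None,
                    measurement_hook=None) -> ClosedLoopRecord:
    """Couple a controller to a virtual cell and run to ``t_end``.

    ``plant`` is ``"ode"`` (deterministic cell) or ``"ssa"`` (stochastic
    cell).  At every multiple of ``cfg.dt_meas`` the protein levels are read
    (optionally transformed by ``measurement_hook(t, LacI, TetR)``, e.g. to
    add observation noise), the law is evaluated, and the inputs are held
    constant until the next measurement.
    """
    if plant not in ("ode", "ssa"):
        raise ValueError(f"unknown plant {plant!r}")
    cfg = _resolve_targets(cfg, p, ex)
    if plant == "ssa":
        cell = stochastic.SSACell(state0, p, ex,
                                  seed if seed is not None else 0)
    else:
        cur = state0

    times, measured, applied, integrals = [], [], [], []
    plant_times: list[float] = [state0.t]
    plant_states: list[np.ndarray] = [state0.as_array()]
    integ_L = integ_T = 0.0
    prev_e: tuple[float, float] | None = None
    t = state0.t
    while t < t_end - 1e-9:
        if plant == "ssa":
            L_raw, T_raw = float(cell.L), float(cell.T)
        else:
            L_raw, T_raw = cur.LacI, cur.TetR
        if measurement_hook is not None:
            L_meas, T_meas = measurement_hook(t, L_raw, T_raw)
        else:
            L_meas, T_meas = L_raw, T_raw
        e = (cfg.target_LacI - L_meas, cfg.target_TetR - T_meas)
        if prev_e is not None:
            t_prev = t - cfg.dt_meas
            lo = max(t_prev, cfg.t_d)
            if t > cfg.t_d:
                # trapezoid on the overlap of [t_prev, t] with [t_d, inf)
                w = (t - lo) / cfg.dt_meas
                e_lo = (prev_e[0] + (e[0] - prev_e[0]) * (lo - t_prev) / cfg.dt_meas,
                        prev_e[1] + (e[1] - prev_e[1]) * (lo - t_prev) / cfg.dt_meas)
                integ_L += 0.5 * (e_lo[0] + e[0]) * cfg.dt_meas * w
                integ_T += 0.5 * (e_lo[1] + e[1]) * cfg.dt_meas * w
        prev_e = e
        if cfg.mode == "pi":
            u = pi_law(t, L_meas, T_meas, integ_L, integ_T, cfg)
        else:
            u = bangbang_law(L_meas, T_meas, cfg)
        times.append(t)
        measured.append((L_meas, T_meas))
        applied.append(u)
        integrals.append((integ_L, integ_T))

        t_next = min(t + cfg.dt_meas, t_end)
        if plant == "ssa":
            cell.advance(t_next, *u)
            plant_times.append(t_next)
            plant_states.append(cell.state6())
        else:
            traj = deterministic.integrate(
                cur, InducerSchedule.constant(*u), p, ex, t_next,
                t_eval=np.array([t, t_next]))
            cur = traj.final_state()
            plant_times.extend(traj.times[1:])
            plant_states.extend(traj.states[1:])
        t = t_next

    return ClosedLoopRecord(
        config=cfg, times=np.asarray(times), measured=np.asarray(measured),
        applied=np.asarray(applied), integrals=np.asarray(integrals),
        plant_times=np.asarray(plant_times),
        plant_states=np.asarray(plant_states), seed=seed)


# ---------------------------------------------------------------------------
# Open-loop periodic forcing
# ---------------------------------------------------------------------------

def commitment_label(LacI: float, TetR: float,
                     report: deterministic.EquilibriumReport,
                     rel_tol: float = 0.1) -> tuple[str, bool]:
    """Label a protein state by its nearest stable equilibrium in log space.

    Returns ``(label, committed)`` where label is ``"rfp"`` (LacI-dominant)
    or ``"gfp"`` (TetR-dominant) and ``committed`` is True when the relative
    log-space distance to that equilibrium is below ``rel_tol``.
    """
    z = np.log10([max(LacI, 1e-6), max(TetR, 1e-6)])
    best = None
    for eq in report.stable:
        zq = np.log10([eq.LacI, eq.TetR])
        d = np.linalg.norm(z - zq) / np.linalg.norm(zq)
        lab = "rfp" if eq.LacI > eq.TetR else "gfp"
        if best is None or d < best[1]:
            best = (lab, d)
    return best[0], bool(best[1] < rel_tol)


def release_schedule(forcing: InducerSchedule, t_release: float,
                     basal: tuple[float, float] = REFERENCE_INPUTS,
                     ) -> InducerSchedule:
    """Forcing until ``t_release``, then constant basal inputs."""
    bps, ua, ui = [], [], []
    for t0, _t1, a, i in forcing.segments(t_release):
        bps.append(t0); ua.append(a); ui.append(i)
    bps.append(t_release); ua.append(basal[0]); ui.append(basal[1])
    return InducerSchedule(bps, ua, ui)


@dataclass
class ForcingResult:
    """Outcome of a periodic-forcing run with post-release fate labels."""

    schedule: InducerSchedule     # full schedule incl. release
    t_release: float
    runs: list                    # StochasticRun or Trajectory per cell
    labels: list[str]             # "rfp" / "gfp" at t_end
    committed: list[bool]
    logratio_bands: list[tuple[float, float]]  # (min, max) of log10(L/T) during forcing
    equilibria: deterministic.EquilibriumReport

    @property
    def fraction_rfp(self) -> float:
        return sum(1 for lab in self.labels if lab == "rfp") / len(self.labels)


def run_periodic_forcing(forcing: InducerSchedule, plant: str, n_cells: int,
                         p: ToggleParams, ex: ExchangeParams, t_end: float,
                         t_release: float, seed,
                         basal: tuple[float, float] = REFERENCE_INPUTS,
                         state0: CellState | None = None,
                         param_sampler=None, sample_dt: float = 5.0,
                         t_burn: float | None = None) -> ForcingResult:
    """Drive cells open-loop with periodic inducer pulses, then release.

    After ``t_release`` the inputs revert to the basal concentrations and
    each cell falls into one of the two basins; cells are labelled by their
    nearest stable equilibrium at ``t_end``.  ``logratio_bands`` record the
    per-cell range of ``log10(LacI/TetR)`` during forcing (after ``t_burn``,
    default two periods) — a bounded band means no commitment while forced.
    """
    if t_release > t_end:
        raise ValueError("t_release must be <= t_end")
    if forcing.period is None:
        raise ValueError("forcing schedule must be periodic")
    full = release_schedule(forcing, t_release, basal=basal)
    report = deterministic.find_equilibria(basal, p, ex)
    if state0 is None:
        # cells start pre-equilibrated in the TetR/GFP-dominant state
        gfp = max(report.stable, key=lambda e: e.TetR)
        state0 = gfp.state
    if t_burn is None:
        t_burn = 2.0 * forcing.period

    if plant == "ssa":
        runs = stochastic.simulate_population(
            n_cells, full, p, ex, t_end, seed,
            param_sampler=param_sampler, state0=state0, sample_dt=sample_dt)
        get = lambda r: (r.times, r.states)
    elif plant == "ode":
        runs = []
        for c in range(n_cells):
            p_c = p if param_sampler is None else param_sampler(c)
            runs.append(deterministic.integrate(
                state0, full, p_c, ex, t_end,
                t_eval=np.arange(0.0, t_end + 1e-9, sample_dt)))
        get = lambda r: (r.times, r.states)
    else:
        raise ValueError(f"unknown plant {plant!r}")

    labels, committed, bands = [], [], []
    for r in runs:
        times, states = get(r)
        lab, com = commitment_label(states[-1, 2], states[-1, 3], report)
        labels.append(lab)
        committed.append(com)
        mask = (times >= t_burn) & (times <= t_release)
        L = np.clip(states[mask, 2], 1e-6, None)
        T = np.clip(states[mask, 3], 1e-6, None)
        ratio = np.log10(L / T)
        bands.append((float(ratio.min()), float(ratio.max())))
    return ForcingResult(full, t_release, runs, labels, committed, bands,
                         report)
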