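"""Continuous-time Markov chain simulation via the first-reaction method.

The CTMC covers the four pseudo-reaction species (two mRNAs, two proteins)
with propensities equal to the deterministic rate laws.  Internal inducer
levels are not CTMC species: they evolve deterministically between events
through the exact exponential relaxation of the exchange model.  Propensities
are held constant between events and recomputed after every event and at
every input change; candidate jumps that would cross an input breakpoint are
rejected and the clock advanced to the breakpoint (valid by memorylessness
of the exponential clocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import dynamics
from .params import CellState, ExchangeParams, InducerSchedule, ToggleParams

__all__ = [
    "StochasticRun",
    "SSACell",
    "first_reaction_step",
    "simulate_ssa",
    "simulate_population",
    "FROZEN",
]

#: Reaction index returned when every propensity is zero.
FROZEN = -1


def first_reaction_step(state, u: tuple[float, float], p: ToggleParams,
                        rng: np.random.Generator) -> tuple[float, int]:
    """Draw (waiting time, reaction index) by the first-reaction method.

    One exponential candidate time ``tau_j = E_j / a_j`` is drawn per
    reaction with positive propensity; the earliest fires.  When all
    propensities vanish the state is frozen: returns ``(inf, FROZEN)`` and
    the caller should advance to the next input breakpoint.
    """
    if isinstance(state, CellState):
        props = dynamics.propensities(state, p)
    else:
        y = np.asarray(state, dtype=float)
        props = dynamics.propensities(y, p, inducers=(y[4], y[5]) if y.size >= 6 else u)
    active = props > 0.0
    if not active.any():
        return math.inf, FROZEN
    taus = np.full(props.shape, math.inf)
    taus[active] = rng.standard_exponential(int(active.sum())) / props[active]
    j = int(np.argmin(taus))
    return float(taus[j]), j


@dataclass
class StochasticRun:
    """One stochastic single-cell trajectory resampled on a uniform grid."""

    seed: int
    times: np.ndarray            # uniform sample grid (min)
    states: np.ndarray           # (n, 6); species columns are integer counts
    n_events: int
    jump_times: np.ndarray | None = None
    jump_states: np.ndarray | None = None  # (m, 4) post-jump species counts

    @property
    def LacI(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def TetR(self) -> np.ndarray:
        return self.states[:, 3]

    def final_state(self) -> CellState:
        return CellState.from_array(self.states[-1], t=float(self.times[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states,
                          columns=["mRNA_L", "mRNA_T", "LacI", "TetR",
                                   "aTc_in", "IPTG_in"])
        df.insert(0, "t_min", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed: {self.seed}\n")
            self.to_dataframe().to_csv(fh, index=False)


class SSACell:
    """A virtual cell advanced event-by-event under piecewise-constant inputs.

    Keeps integer species counts, continuous internal inducers, and a private
    RNG.  :meth:`advance` runs the first-reaction loop up to a stop time
    under constant external inputs; closed-loop controllers call it one
    measurement interval at a time.
    """

    def __init__(self, state0: CellState, p: ToggleParams, ex: ExchangeParams,
                 seed, record_jumps: bool = False):
        self.p = p
        self.ex = ex
        self.mL = int(round(state0.mRNA_L))
        self.mT = int(round(state0.mRNA_T))
        self.L = int(round(state0.LacI))
        self.T = int(round(state0.TetR))
        self.a = float(state0.aTc_in)
        self.i = float(state0.IPTG_in)
        self.t = float(state0.t)
        self.rng = np.random.default_rng(seed)
        self.n_events = 0
        self.record_jumps = record_jumps
        self.jump_times: list[float] = []
        self.jump_states: list[tuple[int, int, int, int]] = []
        self._buf = self.rng.standard_exponential(8 * 2048)
        self._pos = 0

    def _exp8(self) -> np.ndarray:
        if self._pos + 8 > self._buf.size:
            self._buf = self.rng.standard_exponential(8 * 2048)
            self._pos = 0
        out = self._buf[self._pos:self._pos + 8]
        self._pos += 8
        return out

    def state6(self) -> np.ndarray:
        return np.array([self.mL, self.mT, self.L, self.T, self.a, self.i],
                        dtype=float)

    def cell_state(self) -> CellState:
        return CellState.from_array(self.state6(), t=self.t)

    def advance(self, t1: float, u_aTc: float, u_IPTG: float) -> None:
        """Simulate events until ``t1`` under constant external inputs."""
        p, ex = self.p, self.ex
        # Hoist parameters into locals: the event loop is pure Python.
        k_m0_L, k_m_L, k_m0_T, k_m_T = p.k_m0_L, p.k_m_L, p.k_m0_T, p.k_m_T
        k_p_L, k_p_T = p.k_p_L, p.k_p_T
        g_m_L, g_m_T, g_p_L, g_p_T = p.g_m_L, p.g_m_T, p.g_p_L, p.g_p_T
        th_aTc, et_aTc = p.theta_aTc, p.eta_aTc
        th_IPTG, et_IPTG = p.theta_IPTG, p.eta_IPTG
        th_TetR, et_TetR = p.theta_TetR, p.eta_TetR
        th_LacI, et_LacI = p.theta_LacI, p.eta_LacI
        symmetric = ex.variant == "symmetric"
        if symmetric:
            k_a = math.inf
            k_i = ex.k_IPTG
            self.a = u_aTc
        else:
            k_a = ex.k_aTc_in if u_aTc > self.a else ex.k_aTc_out
            k_i = ex.k_IPTG_in if u_IPTG > self.i else ex.k_IPTG_out
        mL, mT, L, T = self.mL, self.mT, self.L, self.T
        a, i = self.a, self.i
        t = self.t
        record = self.record_jumps
        jt, js = self.jump_times, self.jump_states
        n_events = 0
        while t < t1:
            ha = 1.0 / (1.0 + (a / th_aTc) ** et_aTc)
            hi = 1.0 / (1.0 + (i / th_IPTG) ** et_IPTG)
            a0 = k_m0_L + k_m_L / (1.0 + (T * ha / th_TetR) ** et_TetR)
            a1 = k_m0_T + k_m_T / (1.0 + (L * hi / th_LacI) ** et_LacI)
            a2 = k_p_L * mL
            a3 = k_p_T * mT
            a4 = g_m_L * mL
            a5 = g_m_T * mT
            a6 = g_p_L * L
            a7 = g_p_T * T
            E = self._exp8()
            # transcription propensities are always positive (leakage > 0)
            tau = E[0] / a0
            j = 0
            t_cand = E[1] / a1
            if t_cand < tau:
                tau, j = t_cand, 1
            if a2 > 0.0:
                t_cand = E[2] / a2
                if t_cand < tau:
                    tau, j = t_cand, 2
            if a3 > 0.0:
                t_cand = E[3] / a3
                if t_cand < tau:
                    tau, j = t_cand, 3
            if a4 > 0.0:
                t_cand = E[4] / a4
                if t_cand < tau:
                    tau, j = t_cand, 4
            if a5 > 0.0:
                t_cand = E[5] / a5
                if t_cand < tau:
                    tau, j = t_cand, 5
            if a6 > 0.0:
                t_cand = E[6] / a6
                if t_cand < tau:
                    tau, j = t_cand, 6
            if a7 > 0.0:
                t_cand = E[7] / a7
                if t_cand < tau:
                    tau, j = t_cand, 7
            if t + tau >= t1:
                # reject the candidate jump: advance the clock and inducers
                dt = t1 - t
                if not symmetric:
                    a = u_aTc + (a - u_aTc) * math.exp(-k_a * dt)
                i = u_IPTG + (i - u_IPTG) * math.exp(-k_i * dt)
                t = t1
                break
            t += tau
            if not symmetric:
                a = u_aTc + (a - u_aTc) * math.exp(-k_a * tau)
            i = u_IPTG + (i - u_IPTG) * math.exp(-k_i * tau)
            if j == 0:
                mL += 1
            elif j == 1:
                mT += 1
            elif j == 2:
                L += 1
            elif j == 3:
                T += 1
            elif j == 4:
                mL -= 1
            elif j == 5:
                mT -= 1
            elif j == 6:
                L -= 1
            else:
                T -= 1
            n_events += 1
            if record:
                jt.append(t)
                js.append((mL, mT, L, T))
        self.mL, self.mT, self.L, self.T = mL, mT, L, T
        self.a, self.i = a, i
        self.t = t1
        self.n_events += n_events


def simulate_ssa(state0: CellState, schedule: InducerSchedule, p: ToggleParams,
                 ex: ExchangeParams, t_end: float, seed,
                 sample_dt: float = 5.0,
                 record_jumps: bool = False) -> StochasticRun:
    """Simulate one cell with the first-reaction Gillespie method.

    The initial a.u. values are rounded to the nearest integer counts.  The
    trajectory is resampled every ``sample_dt`` minutes; between samples the
    event loop runs with propensities recomputed after every event.
    """
    if t_end <= state0.t:
        raise ValueError("t_end must exceed the initial time")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0")
    cell = SSACell(state0, p, ex, seed, record_jumps=record_jumps)
    sample_times = np.arange(state0.t, t_end + 1e-9, sample_dt)
    if sample_times[-1] < t_end:
        sample_times = np.append(sample_times, t_end)
    samples = np.empty((sample_times.size, 6))
    samples[0] = cell.state6()
    k = 1
    for t0, t1, ua, ui in schedule.segments(t_end):
        if t1 <= state0.t:
            continue
        while k < sample_times.size and sample_times[k] <= t1 + 1e-12:
            cell.advance(float(sample_times[k]), ua, ui)
            samples[k] = cell.state6()
            k += 1
        if cell.t < t1:
            cell.advance(t1, ua, ui)
    try:
        seed_repr = int(seed)
    except (TypeError, ValueError):
        # SeedSequence etc.: record a deterministic fingerprint
        seed_repr = int(np.random.default_rng(seed).integers(2 ** 31))
    return StochasticRun(
        seed=seed_repr, times=sample_times, states=samples,
        n_events=cell.n_events,
        jump_times=np.asarray(cell.jump_times) if record_jumps else None,
        jump_states=np.asarray(cell.jump_states) if record_jumps else None,
    )


def simulate_population(n: int, schedule: InducerSchedule, p: ToggleParams,
                        ex: ExchangeParams, t_end: float, seed,
                        param_sampler: Callable[[int], ToggleParams] | None = None,
                        state0: CellState | None = None,
                        sample_dt: float = 5.0) -> list[StochasticRun]:
    """Simulate ``n`` independent stochastic cells under a shared schedule.

    Per-cell seeds are spawned deterministically from the master seed.
    ``param_sampler(cell_index)`` supplies per-cell kinetic parameters
    (phenotypic heterogeneity); ``None`` gives a homogeneous population.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if state0 is None:
        state0 = CellState()
    children = np.random.SeedSequence(seed).spawn(n)
    runs = []
    for c in range(n):
        p_c = p if param_sampler is None else param_sampler(c)
        runs.append(simulate_ssa(state0, schedule, p_c, ex, t_end,
                                 seed=children[c], sample_dt=sample_dt))
    return runs
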