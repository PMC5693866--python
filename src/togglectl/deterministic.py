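"""Deterministic simulation and phase-plane analysis.

Stiff ODE integration of the six-state model, protein-plane nullclines,
equilibrium finding with stability classification, separatrix tracing, and
the time-averaged vector field that explains stabilization of the circuit
under fast periodic forcing.

Phase-plane objects live in the (LacI, TetR) plane of the reduced system:
mRNA at quasi-steady state and internal inducers at their input-determined
level.  Stability of equilibria is always classified on the full 4x4
mRNA/protein Jacobian (the inducer states are slaved to the inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from . import dynamics
from .params import CellState, ExchangeParams, InducerSchedule, ToggleParams

__all__ = [
    "Trajectory",
    "Equilibrium",
    "EquilibriumReport",
    "AveragedField",
    "IntegrationError",
    "BistabilityError",
    "integrate",
    "nullclines",
    "find_equilibria",
    "separatrix",
    "time_averaged_field",
    "protein_ceilings",
    "steady_mRNA",
]

#: Eigenvalue threshold: stable iff all real parts < -STABILITY_TOL (1/min).
STABILITY_TOL = 1e-9
#: Relative distance below which two roots are considered the same point.
DEDUP_RTOL = 1e-3


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_t: float):
        super().__init__(message)
        self.last_t = last_t


class BistabilityError(RuntimeError):
    """Raised when an operation requires bistability and the system is not."""


@dataclass
class Trajectory:
    """A deterministic solution sampled on an increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # (n, 6) rows [mRNA_L, mRNA_T, LacI, TetR, aTc_in, IPTG_in]
    inputs: np.ndarray  # (n, 2) external (u_aTc, u_IPTG) at each time
    schedule: InducerSchedule

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
        df["u_aTc"] = self.inputs[:, 0]
        df["u_IPTG"] = self.inputs[:, 1]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate(state0: CellState, schedule: InducerSchedule, p: ToggleParams,
              ex: ExchangeParams, t_end: float, t_eval: np.ndarray | None = None,
              rtol: float = 1e-6, atol: float = 1e-9,
              method: str = "LSODA") -> Trajectory:
    """Integrate the full model over ``[t0, t_end]`` with a stiff solver.

    Integration restarts at every schedule breakpoint so input discontinuities
    are never stepped over.  ``t_eval`` selects output times (defaults to a
    1-minute grid); schedule breakpoints are always included.
    """
    t0 = state0.t
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")
    if t_eval is None:
        t_eval = np.arange(t0, t_end + 1e-9, 1.0)
    t_eval = np.asarray(t_eval, dtype=float)

    times: list[float] = []
    states: list[np.ndarray] = []
    inputs: list[tuple[float, float]] = []
    y = state0.as_array()
    for seg_t0, seg_t1, ua, ui in schedule.segments(t_end):
        if seg_t1 <= t0:
            continue
        seg_t0 = max(seg_t0, t0)
        if ex.variant == "symmetric":
            y[4] = ua
        pts = t_eval[(t_eval >= seg_t0) & (t_eval <= seg_t1)]
        pts = np.unique(np.concatenate([[seg_t0], pts, [seg_t1]]))
        sol = solve_ivp(dynamics.ode_rhs, (seg_t0, seg_t1), y, method=method,
                        t_eval=pts, rtol=rtol, atol=atol, args=((ua, ui), p, ex))
        if not sol.success:
            reached = sol.t[-1] if sol.t.size else seg_t0
            raise IntegrationError(
                f"ODE solver failed at t = {reached:.3f} min: {sol.message}",
                last_t=float(reached))
        y = sol.y[:, -1].copy()
        if times:
            # boundary sample belongs to the new (half-open) segment
            times.pop(); states.pop(); inputs.pop()
        times.extend(sol.t)
        states.extend(sol.y.T)
        inputs.extend([(ua, ui)] * len(sol.t))
    states_arr = np.clip(np.asarray(states), 0.0, None)
    return Trajectory(np.asarray(times), states_arr, np.asarray(inputs), schedule)


# ---------------------------------------------------------------------------
# Phase-plane machinery
# ---------------------------------------------------------------------------

def steady_mRNA(LacI, TetR, inducers: tuple[float, float], p: ToggleParams):
    """Quasi-steady mRNA levels given proteins and internal inducers."""
    a, i = inducers
    mL = dynamics.transcription_rate_L(TetR, a, p) / p.g_m_L
    mT = dynamics.transcription_rate_T(LacI, i, p) / p.g_m_T
    return mL, mT


def protein_ceilings(p: ToggleParams) -> tuple[float, float]:
    """Fully induced steady protein levels (LacI_max, TetR_max) in a.u."""
    L = p.k_p_L * (p.k_m0_L + p.k_m_L) / (p.g_m_L * p.g_p_L)
    T = p.k_p_T * (p.k_m0_T + p.k_m_T) / (p.g_m_T * p.g_p_T)
    return L, T


def _lacI_nullcline_level(TetR, inducers, p: ToggleParams):
    """LacI value on the LacI-nullcline as an explicit function of TetR."""
    a, _ = inducers
    return p.k_p_L * dynamics.transcription_rate_L(TetR, a, p) / (p.g_m_L * p.g_p_L)


def _tetR_nullcline_level(LacI, inducers, p: ToggleParams):
    """TetR value on the TetR-nullcline as an explicit function of LacI."""
    _, i = inducers
    return p.k_p_T * dynamics.transcription_rate_T(LacI, i, p) / (p.g_m_T * p.g_p_T)


def nullclines(u: tuple[float, float], p: ToggleParams, ex: ExchangeParams,
               n_grid: int = 400, bounds: tuple[float, float] | None = None,
               inducers: tuple[float, float] | None = None,
               ) -> dict[str, np.ndarray]:
    """Zero-level curves of the reduced field in the (LacI, TetR) plane.

    Each component of the reduced field is affine in its own variable, so the
    nullcline is an explicit curve: the LacI-nullcline is
    ``L = k_p_L f_L(T, aTc) / (g_m_L g_p_L)`` parameterised by TetR, and
    symmetrically for TetR.  Returns polylines as (n, 2) arrays of
    (LacI, TetR) vertices, keys ``"LacI"`` and ``"TetR"``.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if inducers is None:
        inducers = u
    Lmax, Tmax = protein_ceilings(p)
    hi = bounds[1] if bounds is not None else 10.0 * max(Lmax, Tmax)
    lo = bounds[0] if bounds is not None else 1e-2
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    L_on = _lacI_nullcline_level(grid, inducers, p)
    T_on = _tetR_nullcline_level(grid, inducers, p)
    return {
        "LacI": np.column_stack([L_on, grid]),   # parameterised by TetR
        "TetR": np.column_stack([grid, T_on]),   # parameterised by LacI
    }


@dataclass
class Equilibrium:
    """One equilibrium of the full model at fixed inputs."""

    state: CellState
    eigenvalues: np.ndarray  # of the 4x4 mRNA/protein Jacobian
    label: str  # "stable" | "unstable"

    @property
    def LacI(self) -> float:
        return self.state.LacI

    @property
    def TetR(self) -> float:
        return self.state.TetR


@dataclass
class EquilibriumReport:
    """All equilibria found at fixed external inputs."""

    points: list[Equilibrium]
    u: tuple[float, float]

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.points if e.label == "stable"]

    @property
    def unstable(self) -> list[Equilibrium]:
        return [e for e in self.points if e.label == "unstable"]

    @property
    def n_stable(self) -> int:
        return len(self.stable)

    @property
    def n_unstable(self) -> int:
        return len(self.unstable)

    @property
    def is_bistable(self) -> bool:
        return self.n_stable == 2 and self.n_unstable == 1

    def saddle(self) -> Equilibrium:
        if self.n_unstable != 1:
            raise BistabilityError(
                f"expected one unstable point, found {self.n_unstable}")
        return self.unstable[0]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.points:
            rows.append({
                "LacI": e.LacI, "TetR": e.TetR,
                "mRNA_L": e.state.mRNA_L, "mRNA_T": e.state.mRNA_T,
                "aTc_in": e.state.aTc_in, "IPTG_in": e.state.IPTG_in,
                "label": e.label,
                "max_re_eig": float(np.max(e.eigenvalues.real)),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _jacobian4(L: float, T: float, inducers: tuple[float, float],
               p: ToggleParams) -> np.ndarray:
    """4x4 Jacobian of the (mRNA_L, mRNA_T, LacI, TetR) subsystem.

    Inducer levels are input-slaved, so only the regulation derivatives
    enter.  The transcription terms are differentiated numerically (central
    differences on the protein arguments).
    """
    a, i = inducers

    def dfL_dT(T):
        h = 1e-6 * max(T, 1.0)
        return (dynamics.transcription_rate_L(T + h, a, p)
                - dynamics.transcription_rate_L(max(T - h, 0.0), a, p)) / (T + h - max(T - h, 0.0))

    def dfT_dL(L):
        h = 1e-6 * max(L, 1.0)
        return (dynamics.transcription_rate_T(L + h, i, p)
                - dynamics.transcription_rate_T(max(L - h, 0.0), i, p)) / (L + h - max(L - h, 0.0))

    J = np.zeros((4, 4))
    J[0, 0] = -p.g_m_L
    J[0, 3] = dfL_dT(T)
    J[1, 1] = -p.g_m_T
    J[1, 2] = dfT_dL(L)
    J[2, 0] = p.k_p_L
    J[2, 2] = -p.g_p_L
    J[3, 1] = p.k_p_T
    J[3, 3] = -p.g_p_T
    return J


def reduced_jacobian(L: float, T: float, inducers: tuple[float, float],
                     p: ToggleParams) -> np.ndarray:
    """2x2 Jacobian of the reduced protein field at (L, T)."""
    def f(x):
        return dynamics.reduced_rhs(x[0], x[1], inducers, p, None,
                                    inducers=inducers)

    x0 = np.array([L, T], dtype=float)
    J = np.zeros((2, 2))
    f0 = f(x0)
    for j in range(2):
        h = 1e-6 * max(x0[j], 1.0)
        xp = x0.copy(); xp[j] += h
        J[:, j] = (f(xp) - f0) / h
    return J


def find_equilibria(u: tuple[float, float], p: ToggleParams, ex: ExchangeParams,
                    n_starts: int = 49, seed: int = 0,
                    inducers: tuple[float, float] | None = None,
                    ) -> EquilibriumReport:
    """Locate all equilibria of the model at fixed external inputs.

    Multi-start Newton-type root finding on the reduced protein field, in
    log10 coordinates (levels span orders of magnitude and must stay
    positive), from a log-spaced grid of ``n_starts`` points plus a few
    jittered extras.  Roots are deduplicated at relative distance
    ``DEDUP_RTOL``, lifted to the full six-state point, and classified by the
    eigenvalues of the 4x4 mRNA/protein Jacobian.
    """
    if n_starts < 25:
        raise ValueError("n_starts must be >= 25")
    if inducers is None:
        inducers = u  # steady internal level equals the input in both variants
    Lmax, Tmax = protein_ceilings(p)
    side = int(np.ceil(np.sqrt(n_starts)))
    Ls = np.logspace(-2, np.log10(10 * Lmax), side)
    Ts = np.logspace(-2, np.log10(10 * Tmax), side)
    starts = [(L, T) for L in Ls for T in Ts][:n_starts]
    rng = np.random.default_rng(seed)
    jitter = 10 ** rng.uniform(-2, np.log10(10 * max(Lmax, Tmax)), size=(5, 2))
    starts += [tuple(row) for row in jitter]

    def f_log(z):
        L, T = 10.0 ** np.clip(z, -12.0, 12.0)
        dL, dT = dynamics.reduced_rhs(L, T, u, p, ex, inducers=inducers)
        return [dL, dT]

    roots: list[np.ndarray] = []
    for L0, T0 in starts:
        sol = root(f_log, np.log10([L0, T0]), method="hybr",
                   options={"xtol": 1e-12})
        if not sol.success:
            continue
        pt = 10.0 ** sol.x
        res = dynamics.reduced_rhs(pt[0], pt[1], u, p, ex, inducers=inducers)
        if np.max(np.abs(res)) > 1e-6 * max(1.0, p.g_p_L * pt[0], p.g_p_T * pt[1]):
            continue
        if any(np.linalg.norm(pt - q) <= DEDUP_RTOL * (np.linalg.norm(q) + 1e-12)
               for q in roots):
            continue
        roots.append(pt)

    if not roots:
        raise RuntimeError(
            "no equilibria found; parameters or inputs are likely invalid")

    points = []
    for L, T in sorted(roots, key=lambda r: -r[0]):
        mL, mT = steady_mRNA(L, T, inducers, p)
        state = CellState(mL, mT, L, T, inducers[0], inducers[1])
        eig = np.linalg.eigvals(_jacobian4(L, T, inducers, p))
        label = "stable" if np.all(eig.real < -STABILITY_TOL) else "unstable"
        points.append(Equilibrium(state, eig, label))
    return EquilibriumReport(points, (float(u[0]), float(u[1])))


def equilibria_scan(u: tuple[float, float], p: ToggleParams,
                    ex: ExchangeParams, n_scan: int = 400,
                    inducers: tuple[float, float] | None = None,
                    ) -> EquilibriumReport:
    """Fast equilibrium location via the scalar nullcline reduction.

    On the LacI-nullcline the fixed-point condition collapses to the scalar
    equation ``T = Tss(Lss(T))``; a dense log-grid sign-change scan with
    Brent polishing finds every root.  Equivalent to :func:`find_equilibria`
    (which multi-starts a Newton solver in 2-D) but roughly two orders of
    magnitude cheaper — used internally where equilibria are recomputed in
    inner loops, e.g. calibration initial states.
    """
    if inducers is None:
        inducers = u

    def g(T):
        L = _lacI_nullcline_level(T, inducers, p)
        return float(_tetR_nullcline_level(L, inducers, p)) - T

    _, Tmax = protein_ceilings(p)
    Ts = np.logspace(-3, np.log10(10 * Tmax), n_scan)
    gs = _tetR_nullcline_level(
        _lacI_nullcline_level(Ts, inducers, p), inducers, p) - Ts
    points = []
    for j in range(n_scan - 1):
        if gs[j] == 0.0 or gs[j] * gs[j + 1] < 0:
            T = brentq(g, Ts[j], Ts[j + 1], xtol=1e-12, rtol=1e-14)
            L = float(_lacI_nullcline_level(T, inducers, p))
            mL, mT = steady_mRNA(L, T, inducers, p)
            state = CellState(mL, mT, L, float(T), inducers[0], inducers[1])
            eig = np.linalg.eigvals(_jacobian4(L, float(T), inducers, p))
            label = "stable" if np.all(eig.real < -STABILITY_TOL) else "unstable"
            points.append(Equilibrium(state, eig, label))
    if not points:
        raise RuntimeError("no equilibria found in scan range")
    points.sort(key=lambda e: -e.LacI)
    return EquilibriumReport(points, (float(u[0]), float(u[1])))


def separatrix(u: tuple[float, float], p: ToggleParams, ex: ExchangeParams,
               s_max: float = 4000.0, eps: float = 1e-3,
               n_starts: int = 49, seed: int = 0) -> np.ndarray:
    """Stable manifold of the saddle: the basin boundary in the protein plane.

    Traced by integrating the reduced field backward in time from small
    offsets along the saddle's stable eigenvector.  Returns an (n, 2)
    polyline of (LacI, TetR) vertices with the saddle in the middle.
    Raises :class:`BistabilityError` when the system is not bistable at ``u``.
    """
    report = find_equilibria(u, p, ex, n_starts=n_starts, seed=seed)
    if not report.is_bistable:
        raise BistabilityError(
            f"separatrix needs bistability; found {report.n_stable} stable and "
            f"{report.n_unstable} unstable equilibria at u = {u}")
    sd = report.saddle()
    J = reduced_jacobian(sd.LacI, sd.TetR, u, p)
    eigval, eigvec = np.linalg.eig(J)
    stable_dir = eigvec[:, np.argmin(eigval.real)].real
    stable_dir /= np.linalg.norm(stable_dir)

    Lmax, Tmax = protein_ceilings(p)
    box_hi = 20.0 * max(Lmax, Tmax)

    def backward(s, x):
        # the solver may probe slightly past the admissible quadrant
        return -dynamics.reduced_rhs(max(x[0], 0.0), max(x[1], 0.0), u, p, ex)

    def leave_box(s, x):
        return min(min(x) - 1e-4, box_hi - max(x))
    leave_box.terminal = True

    x0 = np.array([sd.LacI, sd.TetR])
    branches = []
    for sign in (+1.0, -1.0):
        start = x0 + sign * eps * np.linalg.norm(x0) * stable_dir
        sol = solve_ivp(backward, (0.0, s_max), start, method="LSODA",
                        events=leave_box, rtol=1e-8, atol=1e-10, max_step=20.0)
        branches.append(sol.y.T)
    return np.vstack([branches[0][::-1], x0[None, :], branches[1]])


# ---------------------------------------------------------------------------
# Time-averaged vector field under periodic forcing
# ---------------------------------------------------------------------------

@dataclass
class AveragedField:
    """Reduced protein field averaged over one period of inducer forcing."""

    schedule: InducerSchedule
    orbit_t: np.ndarray          # sample times within one period
    orbit_aTc: np.ndarray        # periodic internal aTc along the orbit
    orbit_IPTG: np.ndarray       # periodic internal IPTG along the orbit
    grid_L: np.ndarray           # (nL,) LacI grid
    grid_T: np.ndarray           # (nT,) TetR grid
    U: np.ndarray                # (nT, nL) dLacI/dt averaged
    V: np.ndarray                # (nT, nL) dTetR/dt averaged
    null_points: list[tuple[float, float]] = field(default_factory=list)
    _p: ToggleParams | None = None

    def field_at(self, L, T) -> np.ndarray:
        """Averaged reduced field at arbitrary (L, T); broadcasts."""
        p = self._p
        fL = np.mean(dynamics.transcription_rate_L(
            np.asarray(T, dtype=float)[..., None], self.orbit_aTc, p), axis=-1)
        fT = np.mean(dynamics.transcription_rate_T(
            np.asarray(L, dtype=float)[..., None], self.orbit_IPTG, p), axis=-1)
        dL = p.k_p_L * fL / p.g_m_L - p.g_p_L * np.asarray(L, dtype=float)
        dT = p.k_p_T * fT / p.g_m_T - p.g_p_T * np.asarray(T, dtype=float)
        return np.array([dL, dT])

    def to_dataframe(self) -> pd.DataFrame:
        LL, TT = np.meshgrid(self.grid_L, self.grid_T)
        return pd.DataFrame({
            "LacI": LL.ravel(), "TetR": TT.ravel(),
            "dLacI_dt": self.U.ravel(), "dTetR_dt": self.V.ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def periodic_inducer_orbit(schedule: InducerSchedule, ex: ExchangeParams,
                           n_t: int = 240, tol: float = 1e-6,
                           min_periods: int = 5, max_periods: int = 50,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relax the input-driven inducer subsystem onto its periodic orbit.

    The internal-inducer dynamics are autonomous (independent of proteins)
    and piecewise linear, so each segment is advanced with the exact
    exponential relaxation.  The period map is iterated from (0, 0) until the
    start-of-period state changes by less than ``tol`` in relative sup norm
    (at least ``min_periods`` periods).  Returns ``(t, aTc, IPTG)`` sampled
    at ``n_t`` uniform times within one period.
    """
    if schedule.period is None:
        raise ValueError("time averaging requires a periodic schedule")
    period = schedule.period
    a, i = 0.0, 0.0
    for n in range(max_periods):
        a_prev, i_prev = a, i
        for t0, t1, ua, ui in schedule.segments(period):
            a, i = dynamics.inducer_step(a, i, ua, ui, t1 - t0, ex)
        change = max(abs(a - a_prev) / (abs(a) + 1e-12),
                     abs(i - i_prev) / (abs(i) + 1e-12))
        if n + 1 >= min_periods and change < tol:
            break
    ts = np.linspace(0.0, period, n_t, endpoint=False)
    aa = np.empty(n_t)
    ii = np.empty(n_t)
    k = 0
    for t0, t1, ua, ui in schedule.segments(period):
        while k < n_t and ts[k] < t1 - 1e-12:
            dt = ts[k] - t0
            aa[k], ii[k] = dynamics.inducer_step(a, i, ua, ui, dt, ex)
            k += 1
        a, i = dynamics.inducer_step(a, i, ua, ui, t1 - t0, ex)
    return ts, aa, ii


def time_averaged_field(schedule: InducerSchedule, p: ToggleParams,
                        ex: ExchangeParams, n_grid: int = 200,
                        bounds: tuple[float, float] | None = None,
                        n_t: int = 240) -> AveragedField:
    """Average the reduced protein field over one forcing period.

    The circuit's commitment dynamics (hours) are slow relative to the
    forcing period, so cells effectively follow this averaged field; its null
    points are the effective attractors of the forced system.  Null points
    are found exactly on the averaged nullcline intersection (1-D sign-change
    scan with Brent polishing), exploiting that each averaged component is
    affine in its own variable.
    """
    ts, aa, ii = periodic_inducer_orbit(schedule, ex, n_t=n_t)
    Lmax, Tmax = protein_ceilings(p)
    lo = bounds[0] if bounds is not None else 1e-2
    hi = bounds[1] if bounds is not None else 10.0 * max(Lmax, Tmax)
    grid_L = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    grid_T = np.logspace(np.log10(lo), np.log10(hi), n_grid)

    # Averaged regulation functions: 1-D in the opposing protein.
    fL_bar = np.mean(dynamics.transcription_rate_L(grid_T[:, None], aa, p), axis=1)
    fT_bar = np.mean(dynamics.transcription_rate_T(grid_L[:, None], ii, p), axis=1)
    U = (p.k_p_L / p.g_m_L) * fL_bar[:, None] - p.g_p_L * grid_L[None, :]
    V = (p.k_p_T / p.g_m_T) * fT_bar[None, :] - p.g_p_T * grid_T[:, None]

    def Lss_bar(T):
        fL = np.mean(dynamics.transcription_rate_L(np.atleast_1d(T)[:, None], aa, p),
                     axis=1)
        return p.k_p_L * fL / (p.g_m_L * p.g_p_L)

    def Tss_bar(L):
        fT = np.mean(dynamics.transcription_rate_T(np.atleast_1d(L)[:, None], ii, p),
                     axis=1)
        return p.k_p_T * fT / (p.g_m_T * p.g_p_T)

    def g(T):
        return float(Tss_bar(Lss_bar(np.atleast_1d(T)))[0] - T)

    T_scan = np.logspace(np.log10(lo), np.log10(hi), 2000)
    g_scan = Tss_bar(Lss_bar(T_scan)) - T_scan
    nulls: list[tuple[float, float]] = []
    for j in range(len(T_scan) - 1):
        if g_scan[j] == 0.0 or g_scan[j] * g_scan[j + 1] < 0:
            T_root = brentq(g, T_scan[j], T_scan[j + 1], xtol=1e-10, rtol=1e-12)
            L_root = float(Lss_bar(np.atleast_1d(T_root))[0])
            if not any(abs(T_root - t) <= DEDUP_RTOL * t for _, t in nulls):
                nulls.append((L_root, float(T_root)))

    return AveragedField(schedule, ts, aa, ii, grid_L, grid_T, U, V,
                         null_points=nulls, _p=p)
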