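"""Rate laws, ODE right-hand sides and stochastic propensities.

The deterministic model is four ODEs for the two mRNAs and two repressor
proteins, closed by an inducer-exchange model for the two intracellular
inducer levels.  Transcription of each operon is a decreasing Hill function
of the *free* repressor, itself the total repressor scaled by a decreasing
Hill function of its allosteric inducer:

    f_L(TetR, aTc)  = k_m0_L + k_m_L * h-( TetR * h-(aTc,  th_aTc,  n_aTc),  th_TetR, n_TetR )
    f_T(LacI, IPTG) = k_m0_T + k_m_T * h-( LacI * h-(IPTG, th_IPTG, n_IPTG), th_LacI, n_LacI )

with h-(x, th, n) = 1 / (1 + (x/th)^n).  The stochastic interpretation is a
continuous-time Markov chain over the same eight pseudo-reactions, with
propensities equal to the deterministic rate laws.
"""

from __future__ import annotations

import numpy as np

from .params import CellState, ExchangeParams, ToggleParams

__all__ = [
    "hill_neg",
    "transcription_rate_L",
    "transcription_rate_T",
    "ode_rhs",
    "reduced_rhs",
    "propensities",
    "STOICHIOMETRY",
    "REACTION_NAMES",
    "inducer_derivatives",
    "inducer_step",
]


def hill_neg(x, theta: float, eta: float):
    """Decreasing Hill function ``1 / (1 + (x/theta)**eta)``.

    Accepts scalars or arrays in ``x``.  Monotone non-increasing in ``x``,
    with value 1 at ``x = 0`` and 1/2 at ``x = theta``.
    """
    x = np.asarray(x, dtype=float)
    if theta <= 0:
        raise ValueError(f"Hill threshold must be > 0, got {theta}")
    if np.any(x < 0):
        raise ValueError("Hill function argument must be non-negative")
    with np.errstate(over="ignore"):  # (x/theta)**eta -> inf saturates to 0
        out = 1.0 / (1.0 + (x / theta) ** eta)
    return out if out.ndim else float(out)


def transcription_rate_L(TetR, aTc_in, p: ToggleParams):
    """Transcription rate of the *lacI* operon (a.u./min).

    TetR represses; aTc sequesters TetR and relieves repression.
    """
    free = np.asarray(TetR, dtype=float) * hill_neg(aTc_in, p.theta_aTc, p.eta_aTc)
    return p.k_m0_L + p.k_m_L * hill_neg(free, p.theta_TetR, p.eta_TetR)


def transcription_rate_T(LacI, IPTG_in, p: ToggleParams):
    """Transcription rate of the *tetR* operon (a.u./min)."""
    free = np.asarray(LacI, dtype=float) * hill_neg(IPTG_in, p.theta_IPTG, p.eta_IPTG)
    return p.k_m0_T + p.k_m_T * hill_neg(free, p.theta_LacI, p.eta_LacI)


def inducer_derivatives(aTc_in: float, IPTG_in: float, u_aTc: float,
                        u_IPTG: float, ex: ExchangeParams) -> tuple[float, float]:
    """Time derivatives of the internal inducer levels.

    Symmetric variant: aTc is slaved to the input (derivative 0; the state
    slot mirrors ``u_aTc``), IPTG relaxes with a single rate.  Asymmetric
    variant: both relax first-order toward the input, with the rate constant
    selected by the sign of (u - x); the boundary ``u == x`` takes the export
    branch (where the derivative vanishes anyway).
    """
    if ex.variant == "symmetric":
        return 0.0, ex.k_IPTG * (u_IPTG - IPTG_in)
    k_a = ex.k_aTc_in if u_aTc > aTc_in else ex.k_aTc_out
    k_i = ex.k_IPTG_in if u_IPTG > IPTG_in else ex.k_IPTG_out
    return k_a * (u_aTc - aTc_in), k_i * (u_IPTG - IPTG_in)


def ode_rhs(t: float, y: np.ndarray, u: tuple[float, float], p: ToggleParams,
            ex: ExchangeParams) -> np.ndarray:
    """Full 6-state right-hand side: [mRNA_L, mRNA_T, LacI, TetR, aTc_in, IPTG_in].

    Transcription is driven by the *internal* inducer levels.  In the
    symmetric variant the aTc slot must equal ``u_aTc`` (the integrator pins
    it at segment starts); its derivative is reported as 0.
    """
    u_aTc, u_IPTG = u
    mL, mT, L, T, a, i = y
    a = max(a, 0.0)
    i = max(i, 0.0)
    if ex.variant == "symmetric":
        a = u_aTc
    fL = transcription_rate_L(max(T, 0.0), a, p)
    fT = transcription_rate_T(max(L, 0.0), i, p)
    da, di = inducer_derivatives(a, i, u_aTc, u_IPTG, ex)
    return np.array([
        fL - p.g_m_L * mL,
        fT - p.g_m_T * mT,
        p.k_p_L * mL - p.g_p_L * L,
        p.k_p_T * mT - p.g_p_T * T,
        da,
        di,
    ])


def reduced_rhs(LacI, TetR, u: tuple[float, float], p: ToggleParams,
                ex: ExchangeParams, inducers: tuple[float, float] | None = None):
    """Protein-plane vector field with mRNA at quasi-steady state.

    With mRNA at its instantaneous fixed point ``m = f/g_m`` and the internal
    inducers at the level set by the input (their steady state is ``u`` for
    both exchange variants), the protein dynamics reduce to

        dLacI/dt = k_p_L * f_L(TetR, aTc) / g_m_L - g_p_L * LacI

    and symmetrically for TetR.  ``inducers`` overrides the internal levels
    (used when averaging over a forcing period).  Broadcasts over arrays.
    """
    if inducers is None:
        inducers = u
    a, i = inducers
    dL = p.k_p_L * transcription_rate_L(TetR, a, p) / p.g_m_L \
        - p.g_p_L * np.asarray(LacI, dtype=float)
    dT = p.k_p_T * transcription_rate_T(LacI, i, p) / p.g_m_T \
        - p.g_p_T * np.asarray(TetR, dtype=float)
    return np.array([dL, dT])


# Pseudo-reactions of the CTMC over [mRNA_L, mRNA_T, LacI, TetR]:
REACTION_NAMES = (
    "transcription_L", "transcription_T",
    "translation_L", "translation_T",
    "mRNA_decay_L", "mRNA_decay_T",
    "protein_decay_L", "protein_decay_T",
)

STOICHIOMETRY = np.array([
    [+1, 0, 0, 0],
    [0, +1, 0, 0],
    [0, 0, +1, 0],
    [0, 0, 0, +1],
    [-1, 0, 0, 0],
    [0, -1, 0, 0],
    [0, 0, -1, 0],
    [0, 0, 0, -1],
], dtype=int)


def propensities(state, p: ToggleParams,
                 inducers: tuple[float, float] | None = None) -> np.ndarray:
    """Propensities of the eight pseudo-reactions.

    ``state`` is a :class:`CellState` or a length >= 4 array ordered
    [mRNA_L, mRNA_T, LacI, TetR, (aTc_in, IPTG_in)].  ``inducers`` overrides
    the internal inducer levels when the array form carries none.
    Propensities equal the deterministic rate laws.
    """
    if isinstance(state, CellState):
        mL, mT, L, T = state.mRNA_L, state.mRNA_T, state.LacI, state.TetR
        if inducers is None:
            inducers = (state.aTc_in, state.IPTG_in)
    else:
        y = np.asarray(state, dtype=float)
        mL, mT, L, T = y[:4]
        if inducers is None:
            if y.size < 6:
                raise ValueError("array state without inducers needs 6 entries")
            inducers = (y[4], y[5])
    if min(mL, mT, L, T) < 0 or min(inducers) < 0:
        raise ValueError("propensities need a non-negative state")
    a, i = inducers
    return np.array([
        transcription_rate_L(T, a, p),
        transcription_rate_T(L, i, p),
        p.k_p_L * mL,
        p.k_p_T * mT,
        p.g_m_L * mL,
        p.g_m_T * mT,
        p.g_p_L * L,
        p.g_p_T * T,
    ])


def inducer_step(aTc_in: float, IPTG_in: float, u_aTc: float, u_IPTG: float,
                 dt: float, ex: ExchangeParams) -> tuple[float, float]:
    """Advance the internal inducer levels by ``dt`` under constant input.

    The exchange ODEs are linear toward the input level, so the step is the
    exact exponential relaxation ``x(t+dt) = u + (x - u) exp(-k dt)``.  The
    approach is monotone, so the asymmetric branch selected at the start of
    the step applies throughout it.
    """
    if ex.variant == "symmetric":
        return u_aTc, u_IPTG + (IPTG_in - u_IPTG) * np.exp(-ex.k_IPTG * dt)
    k_a, k_i = ex.rates_at(aTc_in, IPTG_in, u_aTc, u_IPTG)
    a = u_aTc + (aTc_in - u_aTc) * np.exp(-k_a * dt)
    i = u_IPTG + (IPTG_in - u_IPTG) * np.exp(-k_i * dt)
    return a, i
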