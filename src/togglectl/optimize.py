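"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
rank-one and rank-mu covariance updates and cumulative step-size adaptation,
suitable for the moderate-dimension, multimodal landscapes of ODE model
fitting.  Box constraints are handled by evaluating the projection onto the
box and adding a quadratic penalty on the projection distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["CMAESResult", "cma_es"]


@dataclass
class CMAESResult:
    """Best-ever point of a CMA-ES run and its convergence log."""

    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    log: list[dict] = field(default_factory=list)
    converged: bool = False


def cma_es(f: Callable[[np.ndarray], float], x0: Sequence[float],
           sigma0: float, seed, max_evals: int = 10_000,
           popsize: int | None = None,
           bounds: tuple[np.ndarray, np.ndarray] | None = None,
           ftol: float = 1e-12, penalty: float = 1e4) -> CMAESResult:
    """Minimise ``f`` starting from ``x0`` with initial step size ``sigma0``.

    ``bounds = (lower, upper)`` are optional box constraints; candidates are
    evaluated at their projection onto the box with a quadratic penalty
    ``penalty * ||x - proj(x)||^2`` added.  Deterministic given ``seed``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    rng = np.random.default_rng(seed)
    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    if bounds is not None:
        lower = np.asarray(bounds[0], dtype=float)
        upper = np.asarray(bounds[1], dtype=float)

    def evaluate(x: np.ndarray) -> float:
        if bounds is None:
            return f(x)
        xp = np.clip(x, lower, upper)
        pen = penalty * float(np.sum((x - xp) ** 2))
        return f(xp) + pen

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    best_x = np.clip(x0, lower, upper) if bounds is not None else x0.copy()
    best_f = evaluate(x0)
    n_evals = 1
    log: list[dict] = []
    it = 0
    converged = False
    while n_evals + lam <= max_evals:
        it += 1
        D2, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(D2, 1e-30))
        Z = rng.standard_normal((lam, n))
        Y = Z * D  # rows: D*z in eigenbasis
        X = mean + sigma * Y @ B.T
        F = np.array([evaluate(x) for x in X])
        n_evals += lam
        order = np.argsort(F)
        if F[order[0]] < best_f:
            best_f = float(F[order[0]])
            xb = X[order[0]]
            best_x = np.clip(xb, lower, upper) if bounds is not None else xb.copy()
        y_sel = (X[order[:mu]] - mean) / sigma
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        # cumulative paths
        C_inv_sqrt = B @ np.diag(1.0 / D) @ B.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (C_inv_sqrt @ y_w)
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * it)) / chi_n) < 1.4 + 2 / (n + 1)
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        # covariance update (rank-1 + rank-mu)
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
             + cmu * (y_sel.T * w) @ y_sel)
        C = (C + C.T) / 2
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(np.clip(sigma, 1e-12, 1e6))

        log.append({"iter": it, "evals": n_evals, "fbest": best_f,
                    "fmedian": float(np.median(F)), "sigma": sigma})
        f_spread = float(F.max() - F.min())
        if f_spread < ftol and it > 10:
            converged = True
            break
    return CMAESResult(x=best_x, fun=best_f, n_evals=n_evals, n_iter=it,
                       log=log, converged=converged)
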