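"""Synthetic calibration data: heterogeneous cells, step inputs, noise.

Emulates the study's calibration experiments — step changes in aTc and IPTG
applied to a small population of phenotypically heterogeneous cells, with
fluorescence read every few minutes — so the whole pipeline runs without any
external data.  Heterogeneity and measurement noise are both multiplicative
log-normal with median 1 (biology is multiplicative and fluorescence is
positive); defaults are a 10% cell-to-cell coefficient of variation and a 5%
read noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import deterministic, stochastic
from .calibration import CalibrationDataset, CalibrationExperiment
from .params import ExchangeParams, InducerSchedule, ToggleParams

__all__ = [
    "PopulationSpec",
    "sample_cell_params",
    "add_measurement_noise",
    "gen_calibration_experiment",
    "default_calibration_dataset",
    "SCHEDULE_KINDS",
]

#: ToggleParams fields jittered across cells by default (production rates).
DEFAULT_JITTERED = ("k_m_L", "k_m_T", "k_p_L", "k_p_T")

SCHEDULE_KINDS = ("step_up_aTc", "step_up_IPTG", "alternating")


@dataclass
class PopulationSpec:
    """Size, heterogeneity and read-noise of a simulated cell population."""

    n_cells: int = 9
    heterogeneity_cv: float = 0.1
    jittered_params: tuple[str, ...] = DEFAULT_JITTERED
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.heterogeneity_cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.heterogeneity_cv > 0 and not self.jittered_params:
            raise ValueError("heterogeneity_cv > 0 needs a non-empty "
                             "jittered_params subset")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal multiplicative factors with median 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def sample_cell_params(p: ToggleParams, spec: PopulationSpec,
                       cell_index: int) -> ToggleParams:
    """Per-cell kinetic parameters: independent log-normal jitter.

    Deterministic in ``(spec.seed, cell_index)``; a zero heterogeneity CV
    returns ``p`` unchanged.
    """
    if spec.heterogeneity_cv == 0:
        return p
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(spec.seed), int(cell_index)]))
    factors = _lognormal_factors(rng, spec.heterogeneity_cv,
                                 len(spec.jittered_params))
    return p.replace(**{name: getattr(p, name) * f
                        for name, f in zip(spec.jittered_params, factors)})


def add_measurement_noise(trace: np.ndarray, noise_cv: float,
                          seed) -> np.ndarray:
    """Multiply each sample by an independent log-normal factor (median 1)."""
    trace = np.asarray(trace, dtype=float)
    if np.any(trace <= 0):
        raise ValueError("measurement noise requires a strictly positive trace")
    rng = np.random.default_rng(seed)
    return trace * _lognormal_factors(rng, noise_cv, trace.shape)


def _schedule_for(kind: str) -> tuple[InducerSchedule, float]:
    """Calibration input schedule and duration for a named design.

    Each design pre-equilibrates the cells for 60 min under the first medium
    and exercises at least one switching direction with saturating inducer
    (1 mM IPTG / 100 ng/mL aTc reservoir concentrations).
    """
    if kind == "step_up_aTc":
        return InducerSchedule([0.0, 60.0], [0.0, 100.0], [1.0, 0.0]), 420.0
    if kind == "step_up_IPTG":
        return InducerSchedule([0.0, 60.0], [100.0, 0.0], [0.0, 1.0]), 420.0
    if kind == "alternating":
        return InducerSchedule([0.0, 60.0, 300.0],
                               [0.0, 100.0, 0.0], [1.0, 0.0, 1.0]), 540.0
    raise ValueError(f"unknown schedule kind {kind!r}; "
                     f"choose from {SCHEDULE_KINDS}")


def gen_calibration_experiment(p: ToggleParams, ex: ExchangeParams,
                               schedule_kind: str, spec: PopulationSpec,
                               seed: int,
                               plant: Literal["ode", "ssa"] = "ode",
                               sample_dt: float = 5.0,
                               ) -> tuple[CalibrationExperiment, dict]:
    """Simulate one calibration experiment and average it across cells.

    Each cell gets jittered parameters (when ``spec.heterogeneity_cv > 0``),
    starts pre-equilibrated at the stable state of the first input condition,
    and is simulated deterministically (``plant="ode"``) or stochastically
    (``plant="ssa"``).  Channel means over cells receive multiplicative read
    noise.  Returns the dataset entry plus a sidecar manifest holding the
    generating truth for recovery tests.
    """
    schedule, t_end = _schedule_for(schedule_kind)
    t = np.arange(0.0, t_end + 1e-9, sample_dt)
    kind_tag = zlib.crc32(schedule_kind.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([int(seed), kind_tag])
    cell_seeds = ss.spawn(spec.n_cells + 2)
    rfp = np.zeros_like(t)
    gfp = np.zeros_like(t)
    for c in range(spec.n_cells):
        p_c = sample_cell_params(p, spec, c)
        report = deterministic.equilibria_scan(schedule.u_at(0.0), p_c, ex)
        cands = report.stable or report.points
        state0 = max(cands, key=lambda e: max(e.LacI, e.TetR)).state
        if plant == "ode":
            traj = deterministic.integrate(state0, schedule, p_c, ex, t_end,
                                           t_eval=t)
            idx = np.clip(np.searchsorted(traj.times, t), 0,
                          traj.times.size - 1)
            L, T = traj.states[idx, 2], traj.states[idx, 3]
        else:
            run = stochastic.simulate_ssa(state0, schedule, p_c, ex, t_end,
                                          seed=cell_seeds[c],
                                          sample_dt=sample_dt)
            L, T = run.states[:t.size, 2], run.states[:t.size, 3]
        rfp += L
        gfp += T
    rfp /= spec.n_cells
    gfp /= spec.n_cells
    rfp = np.clip(rfp, 1e-6, None)
    gfp = np.clip(gfp, 1e-6, None)
    if spec.noise_cv > 0:
        rfp = add_measurement_noise(rfp, spec.noise_cv, cell_seeds[-2])
        gfp = add_measurement_noise(gfp, spec.noise_cv, cell_seeds[-1])
    exp = CalibrationExperiment(schedule, t, rfp, gfp,
                                n_cells=spec.n_cells,
                                experiment_id=schedule_kind)
    truth = {
        "schedule_kind": schedule_kind,
        "plant": plant,
        "seed": int(seed),
        "population": {
            "n_cells": spec.n_cells,
            "heterogeneity_cv": spec.heterogeneity_cv,
            "jittered_params": list(spec.jittered_params),
            "noise_cv": spec.noise_cv,
            "seed": spec.seed,
        },
        "true_params": p.to_dict(),
        "exchange": ex.to_dict(),
    }
    return exp, truth


def default_calibration_dataset(p: ToggleParams, ex: ExchangeParams,
                                spec: PopulationSpec | None = None,
                                seed: int = 0,
                                plant: Literal["ode", "ssa"] = "ode",
                                ) -> tuple[CalibrationDataset, dict]:
    """Two step experiments exercising both switch directions (n=9 cells)."""
    if spec is None:
        spec = PopulationSpec()
    entries = []
    truths = {}
    for kind in ("step_up_aTc", "step_up_IPTG"):
        exp, truth = gen_calibration_experiment(p, ex, kind, spec, seed,
                                                plant=plant)
        entries.append(exp)
        truths[kind] = truth
    return CalibrationDataset(entries), truths
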