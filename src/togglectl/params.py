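"""Parameter containers, state vectors and inducer schedules for the toggle switch.

The circuit is the classic two-repressor toggle: *lacI* and *tetR* in mutual
transcriptional repression, read out through RFP/GFP fusions.  External aTc
sequesters TetR and external IPTG sequesters LacI, so each inducer relieves
repression of one branch.  All rates are per minute; protein and mRNA levels
are expressed in arbitrary fluorescence units (a.u.), aTc in ng/mL and IPTG
in mM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ToggleParams",
    "ExchangeParams",
    "CellState",
    "InducerSchedule",
    "default_params",
    "default_exchange",
    "REFERENCE_INPUTS",
]

#: Reference (basal) external inducer concentrations: (aTc ng/mL, IPTG mM).
REFERENCE_INPUTS = (20.0, 0.25)

# Canonical ordering used wherever parameters are vectorised (calibration).
PARAM_NAMES = (
    "k_m0_L", "k_m0_T", "k_m_L", "k_m_T", "k_p_L", "k_p_T",
    "g_m_L", "g_m_T", "g_p_L", "g_p_T",
    "theta_LacI", "theta_TetR", "theta_aTc", "theta_IPTG",
    "eta_LacI", "eta_TetR", "eta_aTc", "eta_IPTG",
)

_HILL_EXPONENTS = ("eta_LacI", "eta_TetR", "eta_aTc", "eta_IPTG")


@dataclass
class ToggleParams:
    """Kinetic and regulatory parameters of the toggle-switch gene circuit.

    ``_L`` quantities belong to the *lacI* operon (repressed by TetR, relieved
    by aTc), ``_T`` to the *tetR* operon (repressed by LacI, relieved by IPTG).

    Parameters
    ----------
    k_m0_L, k_m0_T : float
        Leakage transcription rates (a.u./min).
    k_m_L, k_m_T : float
        Maximal regulated transcription rates (a.u./min).
    k_p_L, k_p_T : float
        Translation rates (1/min).
    g_m_L, g_m_T : float
        mRNA degradation/dilution rates (1/min).
    g_p_L, g_p_T : float
        Protein degradation/dilution rates (1/min).
    theta_LacI, theta_TetR : float
        Repression half-way thresholds on free repressor (a.u.).
    theta_aTc : float
        aTc sequestration threshold (ng/mL).
    theta_IPTG : float
        IPTG sequestration threshold (mM).
    eta_* : float
        Hill exponents (dimensionless, >= 1).
    """

    k_m0_L: float = 3.20e-2
    k_m0_T: float = 1.19e-1
    k_m_L: float = 8.30
    k_m_T: float = 2.06
    k_p_L: float = 9.726e-1
    k_p_T: float = 1.170
    g_m_L: float = 1.386e-1
    g_m_T: float = 1.386e-1
    g_p_L: float = 1.65e-2
    g_p_T: float = 1.65e-2
    theta_LacI: float = 31.94
    theta_TetR: float = 30.00
    theta_aTc: float = 11.65
    theta_IPTG: float = 9.06e-2
    eta_LacI: float = 2.0
    eta_TetR: float = 2.0
    eta_aTc: float = 2.0
    eta_IPTG: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite: {value!r}")
            if name in _HILL_EXPONENTS:
                if value < 1.0:
                    raise ValueError(f"Hill exponent {name} must be >= 1, got {value}")
            elif value <= 0.0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")

    def replace(self, **changes: float) -> "ToggleParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ToggleParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown toggle parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToggleParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ExchangeParams:
    """Inducer membrane-exchange model.

    Two variants are supported.  ``symmetric``: internal aTc instantaneously
    mirrors the external concentration while IPTG relaxes with a single rate
    ``k_IPTG`` (d IPTG/dt = k_IPTG (u - IPTG)).  ``asymmetric``: both inducers
    relax toward the external level, with a different first-order rate for
    import (u above the internal level) and export (u at or below it).  The
    asymmetric variant is the reference model; its strongly unequal aTc
    rates capture apparent intracellular retention of the drug.
    """

    variant: str = "asymmetric"
    k_IPTG: float | None = None
    k_aTc_in: float | None = 1.62e-1
    k_aTc_out: float | None = 2.00e-2
    k_IPTG_in: float | None = 2.75e-2
    k_IPTG_out: float | None = 1.11e-1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sym = ("k_IPTG",)
        asym = ("k_aTc_in", "k_aTc_out", "k_IPTG_in", "k_IPTG_out")
        if self.variant == "symmetric":
            required, forbidden = sym, asym
        elif self.variant == "asymmetric":
            required, forbidden = asym, sym
        else:
            raise ValueError(f"unknown exchange variant {self.variant!r}")
        for name in required:
            value = getattr(self, name)
            if value is None or value < 0:
                raise ValueError(f"{self.variant} variant requires {name} >= 0")
        for name in forbidden:
            if getattr(self, name) is not None:
                raise ValueError(
                    f"{self.variant} variant must not set {name}"
                )

    @classmethod
    def symmetric(cls, k_IPTG: float = 2.75e-2) -> "ExchangeParams":
        return cls(variant="symmetric", k_IPTG=k_IPTG,
                   k_aTc_in=None, k_aTc_out=None,
                   k_IPTG_in=None, k_IPTG_out=None)

    @classmethod
    def asymmetric(cls, k_aTc_in: float = 1.62e-1, k_aTc_out: float = 2.00e-2,
                   k_IPTG_in: float = 2.75e-2, k_IPTG_out: float = 1.11e-1,
                   ) -> "ExchangeParams":
        return cls(variant="asymmetric", k_IPTG=None,
                   k_aTc_in=k_aTc_in, k_aTc_out=k_aTc_out,
                   k_IPTG_in=k_IPTG_in, k_IPTG_out=k_IPTG_out)

    def rates_at(self, aTc_in: float, IPTG_in: float,
                 u_aTc: float, u_IPTG: float) -> tuple[float, float]:
        """First-order relaxation rates (k_aTc, k_IPTG) for the current branch.

        The symmetric variant returns ``inf`` for aTc, meaning the internal
        level is slaved algebraically to the input.
        """
        if self.variant == "symmetric":
            return np.inf, self.k_IPTG
        k_a = self.k_aTc_in if u_aTc > aTc_in else self.k_aTc_out
        k_i = self.k_IPTG_in if u_IPTG > IPTG_in else self.k_IPTG_out
        return k_a, k_i

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        for name in ("k_IPTG", "k_aTc_in", "k_aTc_out", "k_IPTG_in", "k_IPTG_out"):
            value = getattr(self, name)
            if value is not None:
                d[name] = float(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeParams":
        variant = d.get("variant", "asymmetric")
        if variant == "symmetric":
            return cls.symmetric(float(d["k_IPTG"]))
        return cls.asymmetric(
            float(d["k_aTc_in"]), float(d["k_aTc_out"]),
            float(d["k_IPTG_in"]), float(d["k_IPTG_out"]),
        )


# State vector layout: [mRNA_L, mRNA_T, LacI, TetR, aTc_in, IPTG_in]
STATE_NAMES = ("mRNA_L", "mRNA_T", "LacI", "TetR", "aTc_in", "IPTG_in")


@dataclass
class CellState:
    """The six dynamic variables of one cell (plus its clock).

    ``LacI`` and ``TetR`` are protein levels proxied one-to-one by RFP/GFP
    fluorescence; ``aTc_in``/``IPTG_in`` are intracellular inducer levels.
    """

    mRNA_L: float = 0.0
    mRNA_T: float = 0.0
    LacI: float = 0.0
    TetR: float = 0.0
    aTc_in: float = 0.0
    IPTG_in: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.as_array()) < 0:
            raise ValueError("cell state variables must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.mRNA_L, self.mRNA_T, self.LacI, self.TetR,
                         self.aTc_in, self.IPTG_in], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float = 0.0) -> "CellState":
        y = np.asarray(y, dtype=float)
        return cls(*np.clip(y, 0.0, None), t=float(t))


class InducerSchedule:
    """Piecewise-constant external inducer concentrations over time.

    Intervals are half-open ``[t_i, t_{i+1})``.  Beyond the last breakpoint
    the final value holds, unless ``period`` is set, in which case the
    schedule repeats cyclically with that period (breakpoints must then all
    lie inside ``[0, period)``).
    """

    def __init__(self, breakpoints: Iterable[float], u_aTc: Iterable[float],
                 u_IPTG: Iterable[float], period: float | None = None):
        self.breakpoints = np.asarray(list(breakpoints), dtype=float)
        self.u_aTc = np.asarray(list(u_aTc), dtype=float)
        self.u_IPTG = np.asarray(list(u_IPTG), dtype=float)
        self.period = None if period is None else float(period)
        if self.breakpoints.size == 0 or self.breakpoints[0] != 0.0:
            raise ValueError("schedule must start at t = 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not (self.breakpoints.size == self.u_aTc.size == self.u_IPTG.size):
            raise ValueError("breakpoints and concentration arrays must align")
        if np.any(self.u_aTc < 0) or np.any(self.u_IPTG < 0):
            raise ValueError("inducer concentrations must be non-negative")
        if self.period is not None and self.breakpoints[-1] >= self.period:
            raise ValueError("breakpoints must lie inside [0, period)")

    # -- constructors -----------------------------------------------------
    @classmethod
    def constant(cls, u_aTc: float, u_IPTG: float) -> "InducerSchedule":
        return cls([0.0], [u_aTc], [u_IPTG])

    @classmethod
    def reference(cls) -> "InducerSchedule":
        return cls.constant(*REFERENCE_INPUTS)

    @classmethod
    def step(cls, t_step: float, before: tuple[float, float],
             after: tuple[float, float]) -> "InducerSchedule":
        return cls([0.0, t_step], [before[0], after[0]], [before[1], after[1]])

    @classmethod
    def periodic_two_phase(cls, t_IPTG: float = 120.0, c_IPTG: float = 0.5,
                           t_aTc: float = 30.0, c_aTc: float = 50.0,
                           ) -> "InducerSchedule":
        """Alternating forcing: ``t_IPTG`` min of IPTG then ``t_aTc`` min of aTc."""
        return cls([0.0, t_IPTG], [0.0, c_aTc], [c_IPTG, 0.0],
                   period=t_IPTG + t_aTc)

    # -- evaluation -------------------------------------------------------
    def u_at(self, t: float) -> tuple[float, float]:
        if t < 0:
            raise ValueError("schedule is defined for t >= 0 only")
        if self.period is not None:
            t = t % self.period
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.u_aTc[idx]), float(self.u_IPTG[idx])

    def segments(self, t_end: float):
        """Yield ``(t0, t1, u_aTc, u_IPTG)`` covering ``[0, t_end]``."""
        if t_end <= 0:
            raise ValueError("t_end must be > 0")
        edges = [float(b) for b in self.breakpoints]
        if self.period is not None:
            base = list(edges)
            k = 1
            while k * self.period < t_end:
                edges.extend(k * self.period + b for b in base)
                k += 1
        edges = [e for e in edges if e < t_end] + [t_end]
        for t0, t1 in zip(edges[:-1], edges[1:]):
            ua, ui = self.u_at(t0)
            yield t0, t1, ua, ui

    @property
    def duty_ratio(self) -> float:
        """Phase-duration ratio of a two-phase periodic schedule.

        Defined as the duration of the IPTG-bearing phase over the duration of
        the aTc-bearing phase (e.g. the 120/30 protocol has ratio 4).
        """
        if self.period is None or self.breakpoints.size != 2:
            raise ValueError("duty_ratio is defined for two-phase periodic schedules")
        d0 = self.breakpoints[1] - self.breakpoints[0]
        d1 = self.period - self.breakpoints[1]
        iptg_first = self.u_IPTG[0] > 0 and self.u_aTc[0] == 0
        return float(d0 / d1) if iptg_first else float(d1 / d0)

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "t_start_min": self.breakpoints,
            "u_aTc_ng_per_ml": self.u_aTc,
            "u_IPTG_mM": self.u_IPTG,
        })
        with open(path, "w") as fh:
            if self.period is not None:
                fh.write(f"# period_min: {self.period}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "InducerSchedule":
        period = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# period_min:"):
                period = float(first.split(":", 1)[1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        return cls(df["t_start_min"], df["u_aTc_ng_per_ml"], df["u_IPTG_mM"],
                   period=period)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        per = f", period={self.period}" if self.period is not None else ""
        return (f"InducerSchedule({len(self.breakpoints)} segments"
                f"{per})")


def default_params() -> ToggleParams:
    """Fitted kinetic parameters of the reference toggle-switch circuit.

    Loaded from the packaged ``data/default_params.yaml``, which is the
    single source of truth; pass your own YAML to :meth:`ToggleParams.from_yaml`
    to override.
    """
    from importlib.resources import files

    path = files("togglectl").joinpath("data/default_params.yaml")
    return ToggleParams.from_dict(yaml.safe_load(path.read_text()))


def default_exchange(variant: str = "asymmetric") -> ExchangeParams:
    """Fitted inducer-exchange parameters (asymmetric reference model)."""
    if variant == "symmetric":
        return ExchangeParams.symmetric()
    return ExchangeParams.asymmetric()
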