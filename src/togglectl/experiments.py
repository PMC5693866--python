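"""Named, seeded, reproducible in-silico experiments with CSV outputs.

Each registered experiment reproduces one in-silico analysis of the study
system — equilibrium structure, closed-loop single-cell control, population
forcing, averaged vector fields, duty-ratio scans and parameter recovery —
and writes its outputs, a YAML manifest (full configuration echo plus seed)
and a plain-text log into an output directory.  Re-running a manifest with
the same seed reproduces the outputs bit-for-bit.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import ToggleCalibration, default_bounds
from .control import ControllerConfig
from .deterministic import find_equilibria, nullclines
from .model import ToggleModel
from .params import (REFERENCE_INPUTS, InducerSchedule, default_exchange,
                     default_params)
from .stochastic import simulate_population
from .synthetic import (PopulationSpec, default_calibration_dataset,
                        sample_cell_params)

__all__ = ["EXPERIMENTS", "run_experiment", "list_experiments"]


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        self.lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _write_manifest(outdir: Path, name: str, seed: int, config: dict) -> None:
    manifest = {
        "experiment": name,
        "seed": int(seed),
        "togglectl_version": __version__,
        "config": config,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _model(config: dict) -> ToggleModel:
    params = default_params()
    if "params_file" in config:
        from .params import ToggleParams
        params = ToggleParams.from_yaml(config["params_file"])
    variant = config.get("exchange_variant", "asymmetric")
    return ToggleModel(params, default_exchange(variant))


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def fig1c_calibration(outdir: Path, seed: int, config: dict, log) -> None:
    """Generate the default synthetic calibration dataset and model overlay."""
    m = _model(config)
    spec = PopulationSpec(
        n_cells=int(config.get("n_cells", 9)),
        heterogeneity_cv=float(config.get("heterogeneity_cv", 0.1)),
        noise_cv=float(config.get("noise_cv", 0.05)),
        seed=seed,
    )
    dataset, truth = default_calibration_dataset(m.params, m.exchange,
                                                 spec=spec, seed=seed)
    dataset.to_csv(outdir / "calibration_dataset.csv")
    with open(outdir / "generating_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    log(f"wrote {len(dataset)} calibration experiments (n={spec.n_cells} cells)")


def fig1f_equilibria(outdir: Path, seed: int, config: dict, log) -> None:
    """Equilibria and nullclines of the fitted model at reference inputs."""
    m = _model(config)
    u = tuple(config.get("u", REFERENCE_INPUTS))
    report = find_equilibria(u, m.params, m.exchange, seed=seed)
    report.to_csv(outdir / "equilibria.csv")
    nc = nullclines(u, m.params, m.exchange)
    for key, poly in nc.items():
        pd.DataFrame(poly, columns=["LacI", "TetR"]).to_csv(
            outdir / f"nullcline_{key}.csv", index=False)
    log(f"u={u}: {report.n_stable} stable, {report.n_unstable} unstable")


def fig2c_pi_ssa(outdir: Path, seed: int, config: dict, log) -> None:
    """Dual PI control of a stochastic cell, targets at the saddle."""
    m = _model(config)
    cfg = ControllerConfig(mode="pi")
    t_end = float(config.get("t_end", 1500.0))
    record = m.control("ssa", cfg, t_end=t_end, seed=seed)
    record.to_csv(outdir / "closed_loop.csv")
    pd.DataFrame(record.plant_states,
                 columns=["mRNA_L", "mRNA_T", "LacI", "TetR",
                          "aTc_in", "IPTG_in"]).assign(
        t_min=record.plant_times).to_csv(outdir / "plant.csv", index=False)
    err = np.abs(record.measured[:, 0] - record.config.target_LacI)
    log(f"PI/ssa t_end={t_end}: mean |LacI error| = {err.mean():.1f} a.u.")


def fig3ef_population(outdir: Path, seed: int, config: dict, log) -> None:
    """Controlled cell plus an independent follower population.

    The follower cells are not fed back on: they passively experience the
    input sequence the controller applied to the controlled cell.
    """
    m = _model(config)
    cfg = ControllerConfig(mode=str(config.get("mode", "bangbang")))
    t_end = float(config.get("t_end", 1200.0))
    n = int(config.get("n_cells", 16))
    record = m.control("ssa", cfg, t_end=t_end, seed=seed)
    record.to_csv(outdir / "controlled_cell.csv")
    schedule = InducerSchedule(record.times, record.applied[:, 0],
                               record.applied[:, 1])
    spec = PopulationSpec(n_cells=n, seed=seed)
    sampler = lambda c: sample_cell_params(m.params, spec, c)
    state0 = m.equilibria((cfg.u0_aTc, cfg.u0_IPTG)).saddle().state
    runs = simulate_population(n, schedule, m.params, m.exchange, t_end,
                               seed=seed + 1, param_sampler=sampler,
                               state0=state0)
    frames = []
    for c, r in enumerate(runs):
        frames.append(pd.DataFrame({
            "cell": c, "t_min": r.times,
            "LacI": r.states[:, 2], "TetR": r.states[:, 3]}))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "follower_population.csv", index=False)
    log(f"{cfg.mode} controlled cell + {n} followers, t_end={t_end}")


def _forcing(outdir: Path, seed: int, config: dict, log, t_IPTG: float) -> None:
    m = _model(config)
    schedule = InducerSchedule.periodic_two_phase(
        t_IPTG=t_IPTG, c_IPTG=float(config.get("c_IPTG", 0.5)),
        t_aTc=float(config.get("t_aTc", 30.0)),
        c_aTc=float(config.get("c_aTc", 50.0)))
    t_release = float(config.get("t_release", 10 * schedule.period))
    t_end = float(config.get("t_end", t_release + 600.0))
    n = int(config.get("n_cells", 16))
    result = m.forcing(schedule, t_end=t_end, t_release=t_release, seed=seed,
                       n_cells=n)
    frames = []
    for c, r in enumerate(result.runs):
        frames.append(pd.DataFrame({
            "cell": c, "t_min": r.times,
            "LacI": r.states[:, 2], "TetR": r.states[:, 3]}))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "population.csv", index=False)
    pd.DataFrame({
        "cell": range(n), "label": result.labels,
        "committed": result.committed,
        "logratio_min": [b[0] for b in result.logratio_bands],
        "logratio_max": [b[1] for b in result.logratio_bands],
    }).to_csv(outdir / "fates.csv", index=False)
    log(f"{t_IPTG:g}/{schedule.period - t_IPTG:g} forcing, n={n}: "
        f"{result.fraction_rfp:.2f} RFP-dominant after release")


def fig4b_forcing_120_30(outdir: Path, seed: int, config: dict, log) -> None:
    """120 min IPTG / 30 min aTc forcing of 16 stochastic cells."""
    _forcing(outdir, seed, config, log, t_IPTG=120.0)


def fig4fg_forcing_180_30(outdir: Path, seed: int, config: dict, log) -> None:
    """180 min IPTG / 30 min aTc forcing of 16 stochastic cells."""
    _forcing(outdir, seed, config, log, t_IPTG=180.0)


def fig4d_avg_field(outdir: Path, seed: int, config: dict, log) -> None:
    """Time-averaged vector field of the 120/30 protocol."""
    m = _model(config)
    schedule = InducerSchedule.periodic_two_phase(
        t_IPTG=float(config.get("t_IPTG", 120.0)),
        t_aTc=float(config.get("t_aTc", 30.0)))
    field = m.averaged_field(schedule,
                             n_grid=int(config.get("n_grid", 200)))
    field.to_csv(outdir / "averaged_field.csv")
    pd.DataFrame(field.null_points, columns=["LacI", "TetR"]).to_csv(
        outdir / "null_points.csv", index=False)
    log(f"averaged field: {len(field.null_points)} null point(s) at "
        f"{[(round(L), round(T)) for L, T in field.null_points]}")


def duty_ratio_scan(outdir: Path, seed: int, config: dict, log) -> None:
    """Averaged-field null point versus IPTG/aTc phase-duration ratio."""
    m = _model(config)
    t_aTc = float(config.get("t_aTc", 30.0))
    ratios = config.get("ratios", [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    rows = []
    for r in ratios:
        schedule = InducerSchedule.periodic_two_phase(
            t_IPTG=r * t_aTc, t_aTc=t_aTc)
        field = m.averaged_field(schedule, n_grid=50)
        for L, T in field.null_points:
            rows.append({"duty_ratio": r, "LacI": L, "TetR": T,
                         "n_null": len(field.null_points)})
        log(f"ratio {r:g}: null points {field.null_points}")
    pd.DataFrame(rows).to_csv(outdir / "duty_ratio_scan.csv", index=False)


def recovery(outdir: Path, seed: int, config: dict, log) -> None:
    """End-to-end parameter recovery on noiseless synthetic data."""
    m = _model(config)
    spec = PopulationSpec(n_cells=1, heterogeneity_cv=0.0, noise_cv=0.0,
                          seed=seed)
    dataset, _ = default_calibration_dataset(m.params, m.exchange, spec=spec,
                                             seed=seed)
    free = tuple(config.get("free", ("k_m_L", "k_m_T")))
    calib = ToggleCalibration(dataset, free, base=m.params,
                              exchange=m.exchange,
                              bounds=default_bounds(m.params, free))
    result = calib.fit(seed=seed, budget=int(config.get("budget", 600)))
    report = result.recovery_report(m.params)
    report.to_csv(outdir / "recovery_report.csv", index=False)
    result.convergence_log().to_csv(outdir / "convergence.csv", index=False)
    (outdir / "summary.txt").write_text(result.summary() + "\n")
    log(f"recovered {free}: max rel error "
        f"{report['rel_error'].max():.2%}, MSRD {result.objective:.3g}")


EXPERIMENTS = {
    "fig1c_calibration": fig1c_calibration,
    "fig1f_equilibria": fig1f_equilibria,
    "fig2c_pi_ssa": fig2c_pi_ssa,
    "fig3ef_population": fig3ef_population,
    "fig4b_forcing_120_30": fig4b_forcing_120_30,
    "fig4d_avg_field": fig4d_avg_field,
    "fig4fg_forcing_180_30": fig4fg_forcing_180_30,
    "duty_ratio_scan": duty_ratio_scan,
    "recovery": recovery,
}


def list_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


def run_experiment(name: str, outdir: str | Path, seed: int = 0,
                   config: dict | None = None) -> Path:
    """Run a registered experiment; returns the output directory."""
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; registered: {list_experiments()}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    log = _Logger(outdir / "run.log")
    log(f"experiment {name} seed={seed}")
    EXPERIMENTS[name](outdir, int(seed), config, log)
    _write_manifest(outdir, name, seed, config)
    log.flush()
    return outdir
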