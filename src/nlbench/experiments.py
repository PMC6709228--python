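"""Benchmark sweeps: SNR x time lag, power ratio x phase lag, and depth.

Each sweep cell simulates one (task, baseline) dataset, localizes it with
the methods appropriate to the signal family — eLORETA and DICS at 40 Hz
for the steady-state arm, eLORETA, MNE and LCMV on the +/-25 ms
evoked-peak window for the transient arm — and scores every method with
the four cluster metrics.  Rows accumulate into a tidy table, one row per
(method, condition, replicate), fully deterministic under the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .evaluation import evaluate_estimate
from .head_model import (
    HeadModelSpec,
    LeadField,
    build_sensor_array,
    build_source_grid,
    compute_leadfield,
)
from .solvers import (
    contrast_power,
    dics_solve,
    eloreta_solve,
    estimate_covariance,
    estimate_csd,
    lcmv_solve,
    mne_solve,
)
from .synthetic import (
    DipoleConfiguration,
    EpochedEEG,
    GroundTruth,
    NoiseModelSpec,
    SNRSpec,
    SourceSignalSpec,
    bandpass_epoch,
    simulate_dataset,
)

__all__ = [
    "SweepConfig",
    "ResultsTable",
    "SimulationContext",
    "build_context",
    "localize_frequency",
    "localize_time",
    "run_frequency_sweep",
    "run_time_sweep",
    "run_depth_sweep",
    "summarize",
    "AUDITORY_SEEDS",
    "DEPTH_TRACK_START",
]

log = logging.getLogger("nlbench")

#: auditory-cortex seed coordinates (head-centered mm)
AUDITORY_SEEDS = {"left": (-60.0, -28.0, 6.0), "right": (64.0, -24.0, 6.0)}

#: most superficial points of the depth tracks; depth d moves x inward by d
DEPTH_TRACK_START = {"left": (-60.0, -28.0, 6.0), "right": (60.0, -24.0, 6.0)}

ERP_PEAK_HALFWINDOW_S = 0.025
ASSR_FREQUENCY_HZ = 40.0
ASSR_BAND = (5.0, 48.0)


@dataclass(frozen=True)
class SweepConfig:
    """Design of the benchmark sweeps (defaults match the study conditions)."""

    dipole_modes: tuple = ("single", "two_point", "distributed")
    snr_db_list: tuple = (19.0, 22.0, 25.0, 28.0, 31.0)
    power_ratio_list: tuple = (0.5, 0.75, 1.0, 1.25, 1.5)
    phase_lags: tuple = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    time_lags_ms: tuple = (0.0, 15.0, 30.0, 45.0)
    depth_steps_mm: tuple = tuple(range(0, 21))
    n_replicates: int = 5
    methods: tuple = ("eloreta", "dics", "lcmv", "mne")
    master_seed: int = 0
    # dataset shape
    n_epochs: int = 30
    assr_epoch_s: float = 5.0
    erp_epoch_s: float = 1.0
    fs: float = 1000.0
    bandpass_assr: bool = True
    grid_spacing: float = 5.0
    montage: str = "biosemi64"
    n_tapers: int = 2
    reg: float = 0.0

    @classmethod
    def from_file(cls, path: str | Path) -> "SweepConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        for key in ("dipole_modes", "snr_db_list", "power_ratio_list", "phase_lags",
                    "time_lags_ms", "depth_steps_mm", "methods"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ResultsTable:
    """Tidy metric rows plus provenance (config hash, per-row seeds)."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)
        Path(str(path) + ".json").write_text(json.dumps(self.provenance, indent=2))


@dataclass
class SimulationContext:
    """Shared head model artifacts for a sweep."""

    head: HeadModelSpec
    leadfield: LeadField
    noise_model: NoiseModelSpec


def build_context(
    config: SweepConfig | None = None,
    head: HeadModelSpec | None = None,
    noise_model: NoiseModelSpec | None = None,
) -> SimulationContext:
    config = config or SweepConfig()
    head = head or HeadModelSpec()
    sensors = build_sensor_array(config.montage, head)
    grid = build_source_grid(head, config.grid_spacing)
    leadfield = compute_leadfield(sensors, grid, head)
    noise_model = noise_model or NoiseModelSpec()
    if noise_model.n_noise_dipoles > grid.n_voxels:
        # coarse grids cannot host the default 500 noise dipoles
        noise_model = replace(noise_model, n_noise_dipoles=grid.n_voxels)
    return SimulationContext(head=head, leadfield=leadfield, noise_model=noise_model)


def _shrink_into_brain(seed: np.ndarray, head: HeadModelSpec) -> np.ndarray:
    """Radially shrink a seed onto the grid ball if it falls outside."""
    from .head_model import GRID_CLIP_FRACTION

    rel = seed - head.center_array
    r = np.linalg.norm(rel)
    r_max = GRID_CLIP_FRACTION * head.brain_radius
    if r > r_max:
        factor = r_max / r
        log.warning("seed %s outside brain shell; shrunk by %.3f", seed, factor)
        return head.center_array + rel * factor
    return seed


def _seeds_for_mode(mode: str, head: HeadModelSpec) -> tuple:
    seeds = (
        (AUDITORY_SEEDS["left"],)
        if mode == "single"
        else (AUDITORY_SEEDS["left"], AUDITORY_SEEDS["right"])
    )
    return tuple(tuple(_shrink_into_brain(np.asarray(s, float), head)) for s in seeds)


_MODE_CODE = {"single": 1, "two_point": 2, "distributed": 3}


def _cell_seed(master: int, *key: float) -> int:
    entropy = [int(master)] + [int(round(1000 * k)) % (2**31) for k in key]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# per-dataset localization


def localize_frequency(
    task: EpochedEEG,
    baseline: EpochedEEG,
    ctx: SimulationContext,
    methods: tuple = ("eloreta", "dics"),
    frequency: float = ASSR_FREQUENCY_HZ,
    n_tapers: int = 2,
    reg: float = 0.0,
    bandpass: bool = True,
    contrast: str = "difference",
):
    """40 Hz steady-state localization: DICS and eLORETA on the CSD.

    The benchmark scores the task-baseline power difference for every
    method (``contrast="relative"`` switches the current-density maps to
    the (task - baseline)/baseline form an empirical analysis would use).
    """
    if bandpass:
        task = bandpass_epoch(task, *ASSR_BAND)
        baseline = bandpass_epoch(baseline, *ASSR_BAND)
    csd_t = estimate_csd(task, frequency, n_tapers)
    csd_b = estimate_csd(baseline, frequency, n_tapers)
    out = {}
    for method in methods:
        if method == "dics":
            _, est = dics_solve(csd_t, csd_b, ctx.leadfield, reg)
        elif method == "eloreta":
            _, est_t = eloreta_solve(csd_t, ctx.leadfield, reg)
            _, est_b = eloreta_solve(csd_b, ctx.leadfield, reg)
            est = _apply_contrast(est_t, est_b, contrast)
        else:
            raise ConfigurationError(f"method {method!r} not in the frequency arm")
        out[method] = est
    return out


def _apply_contrast(est_t, est_b, contrast: str):
    from .solvers import SourceEstimate

    if contrast == "relative":
        return contrast_power(est_t, est_b)
    if contrast == "difference":
        return SourceEstimate(
            values=est_t.values - est_b.values,
            grid=est_t.grid,
            method=est_t.method,
            condition="contrast",
        )
    raise ConfigurationError(f"unknown contrast {contrast!r}")


def _peak_window(task: EpochedEEG, half: float = ERP_PEAK_HALFWINDOW_S) -> tuple[float, float]:
    """+/-``half`` s window centered on the global-field-power peak of the evoked."""
    evoked = task.evoked()
    t = task.times()
    gfp = evoked.std(axis=0)
    lo = t[0] + half
    hi = t[-1] - half
    sel = (t >= lo) & (t <= hi)
    center = t[sel][int(np.argmax(gfp[sel]))]
    return float(center - half), float(center + half)


def localize_time(
    task: EpochedEEG,
    baseline: EpochedEEG,
    ctx: SimulationContext,
    methods: tuple = ("eloreta", "mne", "lcmv"),
    reg: float = 0.0,
    contrast: str = "difference",
):
    """Evoked-peak localization: LCMV, MNE and eLORETA on the +/-25 ms window."""
    window = _peak_window(task)
    cov_t = estimate_covariance(task, window)
    cov_b = estimate_covariance(baseline, window)
    t = task.times()
    sel = (t >= window[0]) & (t <= window[1])
    out = {}
    for method in methods:
        if method == "lcmv":
            _, est = lcmv_solve(cov_t, cov_b, ctx.leadfield, reg)
        elif method == "mne":
            est_t = mne_solve(cov_b, ctx.leadfield, reg, task.evoked()[:, sel])
            est_b = mne_solve(cov_b, ctx.leadfield, reg, baseline.evoked()[:, sel])
            est = _apply_contrast(est_t, est_b, contrast)
        elif method == "eloreta":
            _, est_t = eloreta_solve(cov_t, ctx.leadfield, reg)
            _, est_b = eloreta_solve(cov_b, ctx.leadfield, reg)
            est = _apply_contrast(est_t, est_b, contrast)
        else:
            raise ConfigurationError(f"method {method!r} not in the time arm")
        out[method] = est
    return out


# ---------------------------------------------------------------------------
# sweeps


def _score(
    estimates: dict,
    truth: GroundTruth,
    condition: dict,
    cell_seed: int,
) -> list[dict]:
    rows = []
    for method, est in estimates.items():
        rec = evaluate_estimate(
            est,
            truth.seeds,
            cluster_seed=cell_seed % (2**31),
            condition={**condition, "method_seed": cell_seed},
        )
        row = rec.as_row()
        row["method"] = method
        rows.append(row)
    return rows


def _provenance(config: SweepConfig, arm: str) -> dict:
    return {
        "arm": arm,
        "config_hash": config.config_hash(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }


def run_frequency_sweep(
    config: SweepConfig, ctx: SimulationContext | None = None
) -> ResultsTable:
    """Power ratio x phase lag sweep with the 40 Hz sinusoidal source."""
    ctx = ctx or build_context(config)
    methods = tuple(m for m in config.methods if m in ("eloreta", "dics"))
    rows = []
    for mode in config.dipole_modes:
        seeds = _seeds_for_mode(mode, ctx.head)
        lags = (0.0,) if mode == "single" else config.phase_lags
        for ratio in config.power_ratio_list:
            for lag in lags:
                for rep in range(config.n_replicates):
                    cell = _cell_seed(config.master_seed, _MODE_CODE[mode], ratio, lag, rep)
                    cond = {
                        "arm": "frequency",
                        "dipole_mode": mode,
                        "power_ratio": ratio,
                        "phase_lag": lag,
                        "replicate": rep,
                    }
                    try:
                        task, base, truth = simulate_dataset(
                            DipoleConfiguration(mode=mode, seeds=seeds),
                            SourceSignalSpec(
                                kind="sinusoid",
                                frequency=ASSR_FREQUENCY_HZ,
                                duration=config.assr_epoch_s,
                                fs=config.fs,
                            ),
                            lag,
                            SNRSpec(mode="power_ratio", power_ratio=ratio),
                            ctx.noise_model,
                            ctx.leadfield,
                            n_epochs=config.n_epochs,
                            seed=cell,
                        )
                        ests = localize_frequency(
                            task, base, ctx, methods,
                            n_tapers=config.n_tapers, reg=config.reg,
                            bandpass=config.bandpass_assr,
                        )
                        rows.extend(_score(ests, truth, cond, cell))
                    except Exception:  # noqa: BLE001 - sweep must survive cell failures
                        log.exception("frequency sweep cell failed: %s", cond)
                        rows.append({**cond, "method": "FAILED"})
    return ResultsTable(pd.DataFrame(rows), _provenance(config, "frequency"))


def run_time_sweep(
    config: SweepConfig, ctx: SimulationContext | None = None
) -> ResultsTable:
    """SNR x time lag sweep with the Gaussian-pulse (ERP-like) source."""
    ctx = ctx or build_context(config)
    methods = tuple(m for m in config.methods if m in ("eloreta", "mne", "lcmv"))
    rows = []
    for mode in config.dipole_modes:
        seeds = _seeds_for_mode(mode, ctx.head)
        lags = (0.0,) if mode == "single" else config.time_lags_ms
        for snr in config.snr_db_list:
            for lag_ms in lags:
                for rep in range(config.n_replicates):
                    cell = _cell_seed(config.master_seed, 7 + _MODE_CODE[mode], snr, lag_ms, rep)
                    cond = {
                        "arm": "time",
                        "dipole_mode": mode,
                        "snr_db": snr,
                        "time_lag_ms": lag_ms,
                        "replicate": rep,
                    }
                    try:
                        task, base, truth = simulate_dataset(
                            DipoleConfiguration(mode=mode, seeds=seeds),
                            SourceSignalSpec(
                                kind="gaussian_mixture",
                                duration=config.erp_epoch_s,
                                fs=config.fs,
                            ),
                            lag_ms / 1000.0,
                            SNRSpec(mode="snr_db", snr_db=snr),
                            ctx.noise_model,
                            ctx.leadfield,
                            n_epochs=config.n_epochs,
                            seed=cell,
                        )
                        ests = localize_time(task, base, ctx, methods, reg=config.reg)
                        rows.extend(_score(ests, truth, cond, cell))
                    except Exception:  # noqa: BLE001
                        log.exception("time sweep cell failed: %s", cond)
                        rows.append({**cond, "method": "FAILED"})
    return ResultsTable(pd.DataFrame(rows), _provenance(config, "time"))


def run_depth_sweep(
    config: SweepConfig,
    ctx: SimulationContext | None = None,
    arms: tuple = ("frequency", "time"),
) -> ResultsTable:
    """Depth sweep: distributed clusters moved 0-20 mm inward along x.

    Both signal families run at the physiological level only (power ratio
    1.0 / 25 dB), with zero phase/time lag.
    """
    ctx = ctx or build_context(config)
    if "distributed" not in config.dipole_modes:
        raise ConfigurationError("depth sweep requires the distributed dipole mode")
    rows = []
    for depth in config.depth_steps_mm:
        left = np.asarray(DEPTH_TRACK_START["left"], float) + (depth, 0.0, 0.0)
        right = np.asarray(DEPTH_TRACK_START["right"], float) - (depth, 0.0, 0.0)
        seeds = (tuple(left), tuple(right))
        dip = DipoleConfiguration(mode="distributed", seeds=seeds)
        for rep in range(config.n_replicates):
            if "frequency" in arms:
                cell = _cell_seed(config.master_seed, 11, depth, 0, rep)
                cond = {
                    "arm": "frequency",
                    "dipole_mode": "distributed",
                    "depth_mm": depth,
                    "replicate": rep,
                }
                methods = tuple(m for m in config.methods if m in ("eloreta", "dics"))
                try:
                    task, base, truth = simulate_dataset(
                        dip,
                        SourceSignalSpec(
                            kind="sinusoid", frequency=ASSR_FREQUENCY_HZ,
                            duration=config.assr_epoch_s, fs=config.fs,
                        ),
                        0.0,
                        SNRSpec(mode="power_ratio", power_ratio=1.0),
                        ctx.noise_model, ctx.leadfield,
                        n_epochs=config.n_epochs, seed=cell,
                    )
                    ests = localize_frequency(
                        task, base, ctx, methods,
                        n_tapers=config.n_tapers, reg=config.reg,
                        bandpass=config.bandpass_assr,
                    )
                    rows.extend(_score(ests, truth, cond, cell))
                except Exception:  # noqa: BLE001
                    log.exception("depth sweep cell failed: %s", cond)
                    rows.append({**cond, "method": "FAILED"})
            if "time" in arms:
                cell = _cell_seed(config.master_seed, 13, depth, 0, rep)
                cond = {
                    "arm": "time",
                    "dipole_mode": "distributed",
                    "depth_mm": depth,
                    "replicate": rep,
                }
                methods = tuple(m for m in config.methods if m in ("eloreta", "mne", "lcmv"))
                try:
                    task, base, truth = simulate_dataset(
                        dip,
                        SourceSignalSpec(
                            kind="gaussian_mixture",
                            duration=config.erp_epoch_s, fs=config.fs,
                        ),
                        0.0,
                        SNRSpec(mode="snr_db", snr_db=25.0),
                        ctx.noise_model, ctx.leadfield,
                        n_epochs=config.n_epochs, seed=cell,
                    )
                    ests = localize_time(task, base, ctx, methods, reg=config.reg)
                    rows.extend(_score(ests, truth, cond, cell))
                except Exception:  # noqa: BLE001
                    log.exception("depth sweep cell failed: %s", cond)
                    rows.append({**cond, "method": "FAILED"})
    return ResultsTable(pd.DataFrame(rows), _provenance(config, "depth"))


# ---------------------------------------------------------------------------


METRIC_COLUMNS = (
    "localization_error_mm",
    "max_seed_error_mm",
    "focal_width_mm",
    "fp_percent",
    "hit_rate",
)


def summarize(results: ResultsTable, group_by: list[str] | None = None) -> pd.DataFrame:
    """Mean/sd per metric per condition cell."""
    df = results.frame
    if df.empty:
        raise ConfigurationError("empty results table")
    df = df[df["method"] != "FAILED"]
    metrics = [c for c in METRIC_COLUMNS if c in df.columns]
    if not group_by:
        out = df[metrics].agg(["mean", "std"]).T
        out.columns = ["mean", "sd"]
        return out.reset_index(names="metric")
    missing = [k for k in group_by if k not in df.columns]
    if missing:
        raise ConfigurationError(f"unknown grouping keys {missing}")
    g = df.groupby(list(group_by))[metrics].agg(["mean", "std"])
    g.columns = [f"{m}_{s}" for m, s in g.columns]
    return g.reset_index()
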