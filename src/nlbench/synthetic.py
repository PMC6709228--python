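"""Synthetic EEG generation: source dynamics, background noise, SNR control.

Two families of source time courses are simulated.  Steady-state
oscillations are unit sinusoids, by default at 40 Hz (the auditory
steady-state driving frequency), optionally with additive white noise on
the dipole moment itself:

    q(t) = sin(2 pi f t + phi) + eps,   eps ~ N(0, sigma^2).

Transient (ERP-like) responses are mixtures of Gaussian pulses; the
default mixture has a negative deflection at 110 ms (N100-like) and a
smaller positive deflection at 400 ms.

The background is a resting-EEG surrogate: several hundred randomly
placed brain dipoles carrying 1/f^alpha noise with a narrowband alpha-band
(8-12 Hz) excess, forward-projected through the same lead field as the
signal.  Signal level is controlled either as a sensor-space SNR in dB,

    SNR_dB = 10 log10( (1/U) sum_u <v_u^2> / eta_u^2 ),

with eta_u^2 the per-sensor baseline variance, or as the ratio of 40 Hz
scalp power to a physiological reference (a multiple of the baseline's
own 40 Hz power; see :class:`SNRSpec`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import json
import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    ShapeError,
)
from .head_model import LeadField, SensorArray, project_sparse

__all__ = [
    "SourceSignalSpec",
    "DipoleConfiguration",
    "NoiseModelSpec",
    "SNRSpec",
    "EpochedEEG",
    "sinusoid_source",
    "gaussian_pulse_source",
    "resting_noise",
    "compute_snr_db",
    "scale_to_snr",
    "scale_to_power_ratio",
    "simulate_dataset",
    "bandpass_epoch",
    "PHYSIOLOGICAL_SNR_DB",
]

#: sensor-space SNR treated as physiological; power ratio 1.0 maps to it
PHYSIOLOGICAL_SNR_DB = 25.0

#: default ERP-like mixture: (amplitude a.u., center s, width s)
DEFAULT_PULSES = ((-1.0, 0.110, 0.020), (0.6, 0.400, 0.040))


@dataclass(frozen=True)
class SourceSignalSpec:
    """Parameters of a single source time course."""

    kind: str = "sinusoid"  # "sinusoid" | "gaussian_mixture"
    frequency: float = 40.0  # Hz, sinusoid only
    phase_lag: float = 0.0  # radians, sinusoid only
    pulse_params: tuple = DEFAULT_PULSES  # gaussian_mixture only
    noise_sd: float = 0.0  # sigma of additive white moment noise
    duration: float = 1.0  # s
    fs: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "gaussian_mixture"):
            raise ConfigurationError(f"unknown signal kind {self.kind!r}")
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("duration and fs must be positive")
        if self.kind == "sinusoid" and self.fs <= 2 * self.frequency:
            raise ConfigurationError(
                f"fs={self.fs} Hz aliases a {self.frequency} Hz sinusoid"
            )
        if self.kind == "gaussian_mixture" and any(w <= 0 for _, _, w in self.pulse_params):
            raise ConfigurationError("pulse widths must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class DipoleConfiguration:
    """Single / two-point / distributed dipole placement.

    Distributed mode places up to ``n_points`` grid dipoles within
    ``radius`` mm of each seed (default 12 mm radius, 100 points).
    """

    mode: str = "single"
    seeds: tuple = ((-60.0, -28.0, 6.0),)
    radius: float = 12.0
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("single", "two_point", "distributed"):
            raise ConfigurationError(f"unknown dipole mode {self.mode!r}")
        n = len(self.seeds)
        if self.mode == "single" and n != 1:
            raise ConfigurationError("single mode requires exactly one seed")
        if self.mode in ("two_point", "distributed") and n != 2:
            raise ConfigurationError(f"{self.mode} mode requires exactly two seeds")

    @property
    def seed_array(self) -> np.ndarray:
        return np.asarray(self.seeds, dtype=float)


@dataclass(frozen=True)
class NoiseModelSpec:
    """Resting-EEG surrogate: 1/f^alpha brain noise with an alpha-band peak."""

    spectral_exponent: float = 1.0
    alpha_peak_freq: float = 10.0
    alpha_peak_gain: float = 3.0  # power ratio of the peak over the 1/f floor
    alpha_peak_width: float = 1.5  # Hz, Gaussian bump on the power spectrum
    n_noise_dipoles: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.spectral_exponent <= 2.0:
            raise ConfigurationError("spectral exponent must be in [0.5, 2]")
        if self.alpha_peak_gain < 1:
            raise ConfigurationError("alpha peak gain must be >= 1")


@dataclass(frozen=True)
class SNRSpec:
    """Target signal level: an SNR in dB or a 40 Hz power ratio.

    Power-ratio mode measures the sinusoid's sensor-averaged 40 Hz power
    against a physiological reference defined as ``reference_gain`` times
    the baseline's own 40 Hz power — an oscillatory steady-state response
    stands roughly an order of magnitude above the resting spectrum at the
    driving frequency, so ratio 1.0 puts the simulated oscillation at that
    realistic level rather than at an arbitrary amplitude.
    """

    mode: str = "snr_db"  # "snr_db" | "power_ratio"
    snr_db: float = PHYSIOLOGICAL_SNR_DB
    power_ratio: float = 1.0
    reference_gain: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("snr_db", "power_ratio"):
            raise ConfigurationError(f"unknown SNR mode {self.mode!r}")
        if self.mode == "power_ratio" and self.power_ratio <= 0:
            raise ConfigurationError("power ratio must be positive")
        if not np.isfinite(self.snr_db):
            raise ConfigurationError("snr_db must be finite")


@dataclass
class EpochedEEG:
    """Epochs x sensors x time array of scalp potentials (microvolt)."""

    data: np.ndarray
    fs: float
    sensors: SensorArray
    t0: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("EpochedEEG data must be (epochs, sensors, times)")
        if self.data.shape[0] < 1:
            raise ShapeError("at least one epoch required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in epoched data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.fs

    def evoked(self) -> np.ndarray:
        """Across-epoch average, sensors x time."""
        return self.data.mean(axis=0)


# ---------------------------------------------------------------------------
# source time courses


def sinusoid_source(spec: SourceSignalSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit sinusoid sin(2 pi f t + phase_lag) plus optional white moment noise."""
    if spec.kind != "sinusoid":
        raise ConfigurationError("spec.kind must be 'sinusoid'")
    t = spec.times()
    s = np.sin(2 * np.pi * spec.frequency * t + spec.phase_lag)
    if spec.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        s = s + rng.normal(0.0, spec.noise_sd, size=s.shape)
    return s


def gaussian_pulse_source(spec: SourceSignalSpec, time_lag: float = 0.0) -> np.ndarray:
    """Mixture of Gaussian pulses, each shifted by ``time_lag`` seconds."""
    if spec.kind != "gaussian_mixture":
        raise ConfigurationError("spec.kind must be 'gaussian_mixture'")
    t = spec.times()
    s = np.zeros_like(t)
    for amp, center, width in spec.pulse_params:
        c = center + time_lag
        if not 0 <= c <= spec.duration:
            warnings.warn(
                f"pulse center {c * 1e3:.0f} ms falls outside the {spec.duration} s epoch",
                stacklevel=2,
            )
        s += amp * np.exp(-((t - c) ** 2) / (2 * width**2))
    return s


# ---------------------------------------------------------------------------
# background noise


def _shaped_noise(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    fs: float,
    model: NoiseModelSpec,
) -> np.ndarray:
    """1/f^alpha Gaussian noise with an alpha-band power bump, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-model.spectral_exponent / 2)
    bump = 1.0 + (model.alpha_peak_gain - 1.0) * np.exp(
        -((freqs - model.alpha_peak_freq) ** 2) / (2 * model.alpha_peak_width**2)
    )
    amp *= np.sqrt(bump)
    spec = rng.normal(size=(n_series, freqs.size)) + 1j * rng.normal(size=(n_series, freqs.size))
    x = np.fft.irfft(spec * amp[None, :], n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def resting_noise(
    model: NoiseModelSpec,
    leadfield: LeadField,
    n_epochs: int,
    duration: float,
    fs: float,
    seed: int | None = None,
) -> EpochedEEG:
    """Forward-projected resting brain noise, deterministic under the seed.

    ``n_noise_dipoles`` grid voxels are drawn uniformly (without
    replacement) and each carries an independent shaped-noise moment per
    epoch.  Output inherits the average reference of the lead field.
    """
    if model.n_noise_dipoles > leadfield.n_voxels:
        raise ConfigurationError(
            f"{model.n_noise_dipoles} noise dipoles exceed {leadfield.n_voxels} grid voxels"
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    idx = rng.choice(leadfield.n_voxels, size=model.n_noise_dipoles, replace=False)
    n_samples = int(round(duration * fs))
    gain = leadfield.gain[:, idx]
    data = np.empty((n_epochs, leadfield.n_sensors, n_samples))
    for e in range(n_epochs):
        moments = _shaped_noise(rng, model.n_noise_dipoles, n_samples, fs, model)
        data[e] = gain @ moments
    return EpochedEEG(data=data, fs=fs, sensors=leadfield.sensors, condition="baseline")


# ---------------------------------------------------------------------------
# SNR control


def compute_snr_db(signal_scalp: np.ndarray, eta_sq: np.ndarray) -> float:
    """Sensor-space SNR in dB: 10 log10 of mean over sensors of <v^2>/eta^2."""
    v = np.asarray(signal_scalp, dtype=float)
    eta_sq = np.asarray(eta_sq, dtype=float)
    if v.ndim != 2 or v.shape[0] != eta_sq.shape[0]:
        raise ShapeError("signal must be (sensors, times) matching eta_sq")
    if np.any(eta_sq <= 0):
        raise ConfigurationError("eta_sq must be strictly positive")
    mean_ratio = float(np.mean(np.mean(v**2, axis=1) / eta_sq))
    if mean_ratio == 0:
        warnings.warn("all-zero signal: SNR is -inf (degenerate)", stacklevel=2)
        return -np.inf
    return 10.0 * np.log10(mean_ratio)


def baseline_sensor_variance(noise: EpochedEEG) -> np.ndarray:
    """Per-sensor variance of the baseline across epochs and time."""
    return noise.data.transpose(1, 0, 2).reshape(noise.data.shape[1], -1).var(axis=1)


def scale_to_snr(
    signal_moments: np.ndarray,
    voxel_indices: np.ndarray,
    leadfield: LeadField,
    noise: EpochedEEG,
    target: SNRSpec,
) -> float:
    """Closed-form scale factor bringing the projected signal to target dB.

    Scaling the moments by k adds 20 log10 k to the SNR, so
    k = 10**((target - current) / 20).
    """
    if target.mode != "snr_db":
        raise ConfigurationError("scale_to_snr requires an snr_db target")
    v = project_sparse(leadfield, voxel_indices, signal_moments)
    eta_sq = baseline_sensor_variance(noise)
    current = compute_snr_db(v, eta_sq)
    if not np.isfinite(current):
        raise DegenerateDataError("cannot scale an all-zero signal to a target SNR")
    return float(10.0 ** ((target.snr_db - current) / 20.0))


def sensor_band_power(scalp: np.ndarray, fs: float, frequency: float) -> float:
    """Sensor-averaged periodogram power density at the bin nearest ``frequency``."""
    freqs, pxx = sps.periodogram(scalp, fs=fs, axis=-1)
    k = int(np.argmin(np.abs(freqs - frequency)))
    return float(pxx[..., k].mean())


def scale_to_power_ratio(
    sinusoid_scalp: np.ndarray,
    reference_power: float,
    fs: float,
    ratio: float,
    frequency: float = 40.0,
) -> float:
    """Amplitude scale k so scaled 40 Hz scalp power = ratio x reference."""
    if reference_power <= 0:
        raise ConfigurationError("reference power must be positive")
    current = sensor_band_power(np.atleast_2d(sinusoid_scalp), fs, frequency)
    if current <= 0:
        raise DegenerateDataError(f"signal has no power at {frequency} Hz")
    return float(np.sqrt(ratio * reference_power / current))


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class GroundTruth:
    """Exact simulated-source bookkeeping attached to each dataset."""

    seeds: np.ndarray  # (n_seeds, 3) mm, exact requested coordinates
    seed_hemispheres: list[str]
    member_indices: list[np.ndarray]  # grid voxels carrying each seed's waveform
    scale: float  # amplitude factor applied to the unit waveforms
    lag: float  # phase (rad) or time lag (s) on right-hemisphere sources


def _members_for_seed(
    config: DipoleConfiguration, leadfield: LeadField, seed_pos: np.ndarray
) -> np.ndarray:
    grid = leadfield.grid
    if config.mode in ("single", "two_point"):
        return np.asarray([grid.nearest_voxel(seed_pos)])
    d = np.linalg.norm(grid.voxel_positions - seed_pos, axis=1)
    inside = np.flatnonzero(d <= config.radius)
    if inside.size == 0:
        raise ConfigurationError(
            f"no grid voxels within {config.radius} mm of seed {seed_pos}"
        )
    order = inside[np.argsort(d[inside], kind="stable")]
    return order[: config.n_points]


def simulate_dataset(
    config: DipoleConfiguration,
    signal: SourceSignalSpec,
    lag: float,
    level: SNRSpec,
    noise_model: NoiseModelSpec,
    leadfield: LeadField,
    n_epochs: int = 30,
    seed: int = 0,
    independent_noise: bool = False,
) -> tuple[EpochedEEG, EpochedEEG, GroundTruth]:
    """Simulate one (task, baseline) pair with exact ground truth.

    Left-hemisphere sources carry zero lag; right-hemisphere sources carry
    ``lag`` (radians for sinusoids, seconds for pulse mixtures).  The unit
    waveforms are forward-projected, scaled to the requested level, and
    added onto the baseline noise epochs — the same realization by default,
    mirroring an empirical baseline recording reused under the task
    (``independent_noise=True`` draws fresh task noise instead).
    """
    ss = np.random.SeedSequence([int(seed), 2025])
    s_base, s_task, s_eps = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    seeds = config.seed_array
    hemis = ["left" if p[0] <= 0 else "right" for p in seeds]
    if config.mode == "single" and lag not in (0, 0.0):
        warnings.warn("single-dipole mode has no second source: lag ignored", stacklevel=2)

    members, waves = [], []
    rng_eps = np.random.default_rng(s_eps)
    for pos, hemi in zip(seeds, hemis):
        members.append(_members_for_seed(config, leadfield, np.asarray(pos, float)))
        this_lag = 0.0 if hemi == "left" else float(lag)
        if signal.kind == "sinusoid":
            w = sinusoid_source(replace(signal, phase_lag=signal.phase_lag + this_lag), rng_eps)
        else:
            w = gaussian_pulse_source(signal, time_lag=this_lag)
        waves.append(w)

    active = np.concatenate(members)
    moments = np.vstack(
        [np.tile(w, (len(m), 1)) for m, w in zip(members, waves)]
    )

    baseline = resting_noise(
        noise_model, leadfield, n_epochs, signal.duration, signal.fs, seed=s_base
    )
    if independent_noise:
        task_noise = resting_noise(
            noise_model, leadfield, n_epochs, signal.duration, signal.fs, seed=s_task
        )
    else:
        task_noise = baseline

    if level.mode == "snr_db":
        k = scale_to_snr(moments, active, leadfield, baseline, replace(level, mode="snr_db"))
    else:
        v = project_sparse(leadfield, active, moments)
        baseline_40 = sensor_band_power(baseline.data, signal.fs, signal.frequency)
        reference = level.reference_gain * baseline_40
        k = scale_to_power_ratio(v, reference, signal.fs, level.power_ratio, signal.frequency)

    projected = project_sparse(leadfield, active, k * moments)
    task = EpochedEEG(
        data=task_noise.data + projected[None, :, :],
        fs=signal.fs,
        sensors=leadfield.sensors,
        condition="task",
    )
    truth = GroundTruth(
        seeds=seeds,
        seed_hemispheres=hemis,
        member_indices=members,
        scale=float(k),
        lag=float(lag),
    )
    return task, baseline, truth


# ---------------------------------------------------------------------------
# filtering


def bandpass_epoch(eeg: EpochedEEG, low: float, high: float, order: int = 10) -> EpochedEEG:
    """Zero-phase Butterworth band-pass applied epoch-wise along time.

    The order-10 design (run forward and backward) keeps a 40 Hz carrier
    within 1% through the 5-48 Hz analysis band while suppressing
    out-of-band content by orders of magnitude.
    """
    if not 0 < low < high < eeg.fs / 2:
        raise ConfigurationError(
            f"invalid band ({low}, {high}) Hz for fs={eeg.fs} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=eeg.fs, output="sos")
    data = sps.sosfiltfilt(sos, eeg.data, axis=-1)
    return EpochedEEG(
        data=data, fs=eeg.fs, sensors=eeg.sensors, t0=eeg.t0, condition=eeg.condition
    )


# ---------------------------------------------------------------------------
# persistence


def save_dataset(path, task: EpochedEEG, baseline: EpochedEEG, truth: GroundTruth, config_echo: dict | None = None) -> None:
    """Persist a simulated dataset (task, baseline, truth) to HDF5."""
    with h5py.File(path, "w") as f:
        for name, eeg in (("task", task), ("baseline", baseline)):
            g = f.create_group(name)
            g.create_dataset("data", data=eeg.data)
            g.attrs["fs"] = eeg.fs
            g.attrs["t0"] = eeg.t0
            g.attrs["condition"] = eeg.condition
        g = f.create_group("truth")
        g.create_dataset("seeds", data=truth.seeds)
        g.attrs["seed_hemispheres"] = json.dumps(truth.seed_hemispheres)
        g.attrs["scale"] = truth.scale
        g.attrs["lag"] = truth.lag
        for i, m in enumerate(truth.member_indices):
            g.create_dataset(f"members_{i}", data=m)
        f.create_dataset("sensor_positions", data=task.sensors.positions)
        f.create_dataset(
            "sensor_labels", data=np.asarray([s.encode() for s in task.sensors.labels])
        )
        f.attrs["config_echo"] = json.dumps(config_echo or {})


def load_dataset(path) -> tuple[EpochedEEG, EpochedEEG, GroundTruth]:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            labels=[s.decode() for s in f["sensor_labels"][()]],
            positions=f["sensor_positions"][()],
        )
        eegs = {}
        for name in ("task", "baseline"):
            g = f[name]
            eegs[name] = EpochedEEG(
                data=g["data"][()],
                fs=float(g.attrs["fs"]),
                sensors=sensors,
                t0=float(g.attrs["t0"]),
                condition=str(g.attrs["condition"]),
            )
        g = f["truth"]
        n_seeds = g["seeds"].shape[0]
        truth = GroundTruth(
            seeds=g["seeds"][()],
            seed_hemispheres=json.loads(g.attrs["seed_hemispheres"]),
            member_indices=[g[f"members_{i}"][()] for i in range(n_seeds)],
            scale=float(g.attrs["scale"]),
            lag=float(g.attrs["lag"]),
        )
    return eegs["task"], eegs["baseline"], truth
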