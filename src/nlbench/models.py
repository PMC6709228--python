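"""Model/Results surface over the inverse solvers.

Each model class is constructed from data (epoched task and baseline EEG
plus a lead field), and ``fit()`` returns a
:class:`SourceLocalizationResults` carrying the contrasted source map,
the spatial filter, fit diagnostics and a ``summary()`` table.  Scoring
against known simulated dipoles hangs off the results object.

    >>> model = DICSBeamformer(task, baseline, leadfield, frequency=40.0)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.evaluate(true_seeds)  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import MetricsRecord, evaluate_estimate
from .head_model import LeadField
from .solvers import (
    SourceEstimate,
    SpatialFilter,
    contrast_power,
    dics_solve,
    eloreta_solve,
    estimate_covariance,
    estimate_csd,
    lcmv_solve,
    mne_solve,
)
from .synthetic import EpochedEEG

__all__ = [
    "SourceLocalizationResults",
    "LCMVBeamformer",
    "DICSBeamformer",
    "ELORETA",
    "MinimumNorm",
]


@dataclass
class SourceLocalizationResults:
    """Fitted source map with diagnostics."""

    estimate: SourceEstimate
    filter: SpatialFilter | None
    model: "BaseLocalizer"
    diagnostics: dict

    @property
    def values(self) -> np.ndarray:
        return self.estimate.values

    def peak(self) -> tuple[int, np.ndarray]:
        """(voxel index, position mm) of the global maximum."""
        i = int(np.nanargmax(self.estimate.values))
        return i, self.estimate.grid.voxel_positions[i]

    def top_table(self, n: int = 10) -> pd.DataFrame:
        g = self.estimate.grid
        order = np.argsort(np.nan_to_num(self.estimate.values, nan=-np.inf))[::-1][:n]
        return pd.DataFrame(
            {
                "voxel": order,
                "x": g.voxel_positions[order, 0],
                "y": g.voxel_positions[order, 1],
                "z": g.voxel_positions[order, 2],
                "hemisphere": g.hemisphere_labels[order],
                "value": self.estimate.values[order],
            }
        )

    def evaluate(self, true_seeds, **kwargs) -> MetricsRecord:
        """Score against known dipole seeds (cluster metrics)."""
        return evaluate_estimate(self.estimate, true_seeds, **kwargs)

    def summary(self) -> str:
        i, pos = self.peak()
        lines = [
            f"{self.model.method.upper()} source localization",
            "=" * 40,
            f"voxels:            {self.estimate.grid.n_voxels}",
            f"sensors:           {self.model.leadfield.n_sensors}",
            f"regularization:    {self.model.reg}",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"{k + ':':<19}{v}")
        lines += [
            f"peak voxel:        {i} at ({pos[0]:.0f}, {pos[1]:.0f}, {pos[2]:.0f}) mm",
            f"peak value:        {self.estimate.values[i]:.4g}",
            "",
            self.top_table(5).to_string(index=False),
        ]
        return "\n".join(lines)


class BaseLocalizer:
    """Common constructor state for the four localizer models."""

    method = "base"

    def __init__(
        self,
        task: EpochedEEG,
        baseline: EpochedEEG,
        leadfield: LeadField,
        reg: float = 0.0,
    ) -> None:
        if task.data.shape[1] != leadfield.n_sensors:
            raise ConfigurationError("task sensor count does not match lead field")
        self.task = task
        self.baseline = baseline
        self.leadfield = leadfield
        self.reg = reg

    def fit(self) -> SourceLocalizationResults:  # pragma: no cover - abstract
        raise NotImplementedError


class LCMVBeamformer(BaseLocalizer):
    """Time-domain adaptive beamformer; value = task - baseline output power."""

    method = "lcmv"

    def __init__(self, task, baseline, leadfield, reg=0.0, window=None):
        super().__init__(task, baseline, leadfield, reg)
        self.window = window

    def fit(self) -> SourceLocalizationResults:
        cov_t = estimate_covariance(self.task, self.window)
        cov_b = estimate_covariance(self.baseline, self.window)
        filt, est = lcmv_solve(cov_t, cov_b, self.leadfield, self.reg)
        diag = {"cov rank (task)": cov_t.rank, "cov rank (baseline)": cov_b.rank}
        return SourceLocalizationResults(est, filt, self, diag)


class DICSBeamformer(BaseLocalizer):
    """Frequency-domain beamformer on the cross-spectral density."""

    method = "dics"

    def __init__(self, task, baseline, leadfield, frequency=40.0, n_tapers=2, reg=0.0):
        super().__init__(task, baseline, leadfield, reg)
        self.frequency = frequency
        self.n_tapers = n_tapers

    def fit(self) -> SourceLocalizationResults:
        csd_t = estimate_csd(self.task, self.frequency, self.n_tapers)
        csd_b = estimate_csd(self.baseline, self.frequency, self.n_tapers)
        filt, est = dics_solve(csd_t, csd_b, self.leadfield, self.reg)
        diag = {"frequency (Hz)": self.frequency, "tapers": self.n_tapers}
        return SourceLocalizationResults(est, filt, self, diag)


class ELORETA(BaseLocalizer):
    """eLORETA current density; value = relative task/baseline power contrast.

    ``frequency=None`` works on the broadband covariance (optionally over
    ``window``); a frequency selects the CSD at that frequency.
    """

    method = "eloreta"

    def __init__(self, task, baseline, leadfield, reg=0.0, frequency=None, window=None, n_tapers=2):
        super().__init__(task, baseline, leadfield, reg)
        self.frequency = frequency
        self.window = window
        self.n_tapers = n_tapers

    def fit(self) -> SourceLocalizationResults:
        if self.frequency is None:
            stat_t = estimate_covariance(self.task, self.window)
            stat_b = estimate_covariance(self.baseline, self.window)
        else:
            stat_t = estimate_csd(self.task, self.frequency, self.n_tapers)
            stat_b = estimate_csd(self.baseline, self.frequency, self.n_tapers)
        filt, est_t = eloreta_solve(stat_t, self.leadfield, self.reg)
        _, est_b = eloreta_solve(stat_b, self.leadfield, self.reg)
        est = contrast_power(est_t, est_b)
        diag = {"domain": "broadband" if self.frequency is None else f"{self.frequency} Hz"}
        return SourceLocalizationResults(est, filt, self, diag)


class MinimumNorm(BaseLocalizer):
    """Minimum-norm estimate on the evoked response over a time window."""

    method = "mne"

    def __init__(self, task, baseline, leadfield, reg_lambda=0.0, window=None):
        super().__init__(task, baseline, leadfield, reg_lambda)
        self.window = window

    def _window_sel(self, eeg: EpochedEEG) -> np.ndarray:
        t = eeg.times()
        if self.window is None:
            return np.ones(t.size, dtype=bool)
        return (t >= self.window[0]) & (t <= self.window[1])

    def fit(self) -> SourceLocalizationResults:
        cov_b = estimate_covariance(self.baseline, self.window)
        sel = self._window_sel(self.task)
        est_t = mne_solve(cov_b, self.leadfield, self.reg, self.task.evoked()[:, sel])
        est_b = mne_solve(cov_b, self.leadfield, self.reg, self.baseline.evoked()[:, sel])
        est = contrast_power(est_t, est_b)
        diag = {"window samples": int(sel.sum())}
        return SourceLocalizationResults(est, None, self, diag)
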