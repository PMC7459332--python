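"""Configuration objects for session synthesis and analysis.

All durations are seconds, rates Hz, and fluorescence in arbitrary units
unless noted. Defaults are the task conditions of the study being emulated:
head-fixed go-no go olfactory discrimination with a 1-1.5 s odor delay after
the trial-initiating lick, two 2-s lick segments, a 22.3-22.8 s inter-trial
interval (+10 s timeout after a false alarm) and 5.3 Hz two-photon imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SessionConfig:
    """Trial-timing and task-structure parameters of one behavioral session."""

    n_trials: int = 100
    p_splus: float = 0.5
    odor_delay_range: tuple[float, float] = (1.0, 1.5)
    lick_segment_s: float = 2.0
    n_lick_segments: int = 2
    iti_range: tuple[float, float] = (22.3, 22.8)
    fa_penalty_s: float = 10.0
    imaging_rate: float = 5.3
    lick_rate_hz: float = 100.0
    reward_volume: float = 1.0
    go_go: bool = False            # both odorants rewarded (reward-value control)
    reversal_trial: int | None = None  # valence swap at this trial index
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not 0.0 <= self.p_splus <= 1.0:
            raise ConfigurationError("p_splus must be in [0, 1]")
        for name in ("lick_segment_s", "fa_penalty_s", "imaging_rate",
                     "lick_rate_hz", "reward_volume"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("odor_delay_range", "iti_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < low <= high")

    @property
    def odor_duration_s(self) -> float:
        return self.lick_segment_s * self.n_lick_segments


@dataclass
class EnsembleConfig:
    """Statistical structure of the synthetic ROI ensemble.

    The ensemble is built from ``n_latents`` shared factors mixed into
    ``n_rois`` ROIs so that the participation-ratio dimensionality of the
    noiseless signal equals ``n_latents`` (the study reports 2-6). One factor
    carries the valence signal whose amplitude scales with the instantaneous
    behavioral performance; ``rho_reinforcement`` sets the target Pearson
    coupling between ensemble-mean dF/F and the lick rate within the
    reinforcement window of rewarded trials.
    """

    n_rois: int = 50
    n_latents: int = 4
    amp_splus: float = 0.30        # peak valence dF/F at proficient performance
    amp_sminus: float = 0.12       # early shared transient amplitude
    amp_reinforcement: float = 0.15
    indicator_decay_s: float = 0.6  # GCaMP-like exponential decay
    noise_sd: float = 0.05
    rho_reinforcement: float = 0.73
    frac_responsive: float = 0.9
    latent_sd: float = 0.05        # per-latent shared-noise dF/F scale
    baseline_f: float = 100.0      # raw fluorescence offset (a.u.)

    def validate(self) -> None:
        if not 1 <= self.n_latents <= self.n_rois:
            raise ConfigurationError("need 1 <= n_latents <= n_rois")
        if abs(self.rho_reinforcement) > 1:
            raise ConfigurationError("|rho_reinforcement| must be <= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.frac_responsive <= 1.0:
            raise ConfigurationError("frac_responsive must be in [0, 1]")
        if self.indicator_decay_s <= 0:
            raise ConfigurationError("indicator_decay_s must be > 0")


@dataclass
class LearningCurve:
    """Sigmoid percent-correct trajectory crossing naive to proficient."""

    start_pc: float = 50.0
    asymptote_pc: float = 95.0
    inflection_trial: int = 40
    slope: float = 0.15

    def validate(self) -> None:
        if not 0 <= self.start_pc <= self.asymptote_pc <= 100:
            raise ConfigurationError("need 0 <= start_pc <= asymptote_pc <= 100")

    def percent_correct(self, trial_index):
        """Expected percent correct at a (0-based) trial index."""
        import numpy as np

        i = np.asarray(trial_index, dtype=float)
        span = self.asymptote_pc - self.start_pc
        return self.start_pc + span / (1.0 + np.exp(-self.slope * (i - self.inflection_trial)))


@dataclass
class PeriodWindows:
    """Analysis windows within a trial.

    ``pre_odorant`` is relative to odor onset, ``odorant`` is the last second
    of odor application (relative to odor onset for a 4-s application), and
    ``reinforcement`` is relative to reward delivery.
    """

    pre_odorant: tuple[float, float] = (-1.0, 0.0)
    odorant: tuple[float, float] = (3.0, 4.0)
    reinforcement: tuple[float, float] = (0.0, 1.5)

    def validate(self) -> None:
        for name in ("pre_odorant", "odorant", "reinforcement"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"window {name} must have low < high")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (stage toggles and printed constants)."""

    session: SessionConfig = field(default_factory=SessionConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    learning: LearningCurve = field(default_factory=LearningCurve)
    windows: PeriodWindows = field(default_factory=PeriodWindows)
    proficient_threshold: float = 80.0
    naive_threshold: float = 65.0
    responsive_sd: float = 2.5
    onset_derivative_threshold: float = 0.03
    pc_window: int = 20
    run_decode: bool = True
    run_glm: bool = True
    run_circuit: bool = False
    n_shuffles: int = 10
    out_dir: str = "mlipop_out"
    seed: int = 0

    def validate(self) -> None:
        self.session.validate()
        self.ensemble.validate()
        self.learning.validate()
        self.windows.validate()
        for name in ("proficient_threshold", "naive_threshold",
                     "responsive_sd", "onset_derivative_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


def _coerce(cls, data: dict):
    kwargs = dict(data)
    for key, val in list(kwargs.items()):
        if isinstance(val, list):
            kwargs[key] = tuple(val)
    return cls(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file; missing keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sub = {
        "session": SessionConfig,
        "ensemble": EnsembleConfig,
        "learning": LearningCurve,
        "windows": PeriodWindows,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in sub:
            kwargs[key] = _coerce(sub[key], val)
        else:
            kwargs[key] = val
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
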