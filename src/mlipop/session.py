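"""In-memory containers for a trial-structured imaging/behavior session."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPLUS = "S+"
SMINUS = "S-"
HIT, MISS, CR, FA = "Hit", "Miss", "CR", "FA"
OUTCOMES = (HIT, MISS, CR, FA)
CORRECT_OUTCOMES = frozenset({HIT, CR})


@dataclass
class Trial:
    """One go-no go trial.

    ``t_start`` is the trial-initiating lick; the odorant turns on a random
    1-1.5 s later and stays on for two 2-s lick segments. ``t_reinforcement``
    is set only on rewarded (Hit) trials.
    """

    index: int
    t_start: float
    t_odor_on: float
    t_odor_off: float
    valence: str
    outcome: str | None = None
    t_reinforcement: float | None = None
    reversal_phase: str = "forward"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_odor_on < self.t_odor_off:
            raise ValueError(
                f"trial {self.index}: require t_start < t_odor_on < t_odor_off"
            )
        if self.valence not in (SPLUS, SMINUS):
            raise ValueError(f"trial {self.index}: unknown valence {self.valence!r}")

    @property
    def is_rewarded(self) -> bool:
        return self.t_reinforcement is not None


@dataclass
class Session:
    """Raw fluorescence, licks, kinematics and trial records of one session."""

    F: np.ndarray                      # frames x ROIs, arbitrary units, >= 0
    lick_times: np.ndarray             # seconds
    trials: list[Trial]
    imaging_rate: float = 5.3
    lick_rate_hz: float = 100.0
    dff: np.ndarray | None = None      # frames x ROIs, filled by compute_dff
    body_velocity: np.ndarray | None = None      # on the lick-channel grid
    body_acceleration: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be frames x ROIs")
        if np.any(self.F < 0):
            raise ValueError("F must be nonnegative")
        starts = [tr.t_start for tr in self.trials]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("trials must be ordered and non-overlapping")
        for prev, nxt in zip(self.trials, self.trials[1:]):
            if nxt.t_start < prev.t_odor_off:
                raise ValueError("trials must be non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.F.shape[0]

    @property
    def n_rois(self) -> int:
        return self.F.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.imaging_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.imaging_rate

    def outcomes(self) -> list[str | None]:
        return [tr.outcome for tr in self.trials]

    def trials_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            rows.append({
                "index": tr.index,
                "t_start": tr.t_start,
                "t_odor_on": tr.t_odor_on,
                "t_odor_off": tr.t_odor_off,
                "valence": tr.valence,
                "outcome": tr.outcome,
                "t_reinforcement": (np.nan if tr.t_reinforcement is None
                                    else tr.t_reinforcement),
                "reversal_phase": tr.reversal_phase,
            })
        return pd.DataFrame(rows)


def trials_from_dataframe(df: pd.DataFrame) -> list[Trial]:
    trials = []
    for _, row in df.iterrows():
        t_r = row["t_reinforcement"]
        trials.append(Trial(
            index=int(row["index"]),
            t_start=float(row["t_start"]),
            t_odor_on=float(row["t_odor_on"]),
            t_odor_off=float(row["t_odor_off"]),
            valence=str(row["valence"]),
            outcome=None if pd.isna(row["outcome"]) else str(row["outcome"]),
            t_reinforcement=None if pd.isna(t_r) else float(t_r),
            reversal_phase=str(row["reversal_phase"]),
        ))
    return trials
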