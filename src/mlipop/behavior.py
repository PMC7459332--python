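"""Trial scoring, sliding-window percent correct, and lick statistics.

Scoring follows the task rule: on rewarded-odorant (S+) trials the mouse must
lick at least once in each of the two 2-s lick segments (Hit; otherwise Miss);
on unrewarded (S-) trials licking in both segments is a False Alarm and
anything else a Correct Rejection. Segments are half-open, so a lick exactly
on a boundary belongs to the later segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import Trial, HIT, MISS, CR, FA, SPLUS, CORRECT_OUTCOMES

NAIVE, INTERMEDIATE, PROFICIENT = "naive", "intermediate", "proficient"


def _segment_bounds(trial: Trial, segment_s: float = 2.0, n_segments: int = 2):
    on = trial.t_odor_on
    return [(on + k * segment_s, on + (k + 1) * segment_s) for k in range(n_segments)]


def licked_each_segment(lick_times: np.ndarray, trial: Trial,
                        segment_s: float = 2.0, n_segments: int = 2) -> bool:
    """True when at least one lick falls in every lick segment (half-open)."""
    t = np.asarray(lick_times, dtype=float)
    return all(np.any((t >= lo) & (t < hi))
               for lo, hi in _segment_bounds(trial, segment_s, n_segments))


def score_trial(lick_times: np.ndarray, trial: Trial,
                segment_s: float = 2.0, n_segments: int = 2) -> str:
    """Assign Hit/Miss/CR/FA from the lick train and trial valence."""
    if trial.t_odor_on is None or trial.t_odor_off is None:
        raise ValueError("trial odor marks must be set before scoring")
    both = licked_each_segment(lick_times, trial, segment_s, n_segments)
    if trial.valence == SPLUS:
        return HIT if both else MISS
    return FA if both else CR


def percent_correct(outcomes, window: int = 20) -> np.ndarray:
    """Sliding-window percent correct, value assigned to the last trial.

    Entry ``i`` (0-based) is 100 x (correct count over trials ``i-window+1..i``)
    / ``window``; entries before the first full window are NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    correct = np.array([o in CORRECT_OUTCOMES for o in outcomes], dtype=float)
    n = correct.size
    pc = np.full(n, np.nan)
    if n >= window:
        csum = np.concatenate([[0.0], np.cumsum(correct)])
        pc[window - 1:] = 100.0 * (csum[window:] - csum[:-window]) / window
    return pc


def classify_epoch(percent: np.ndarray, naive_threshold: float = 65.0,
                   proficient_threshold: float = 80.0) -> np.ndarray:
    """Label each trial naive (<=65), proficient (>=80) or intermediate."""
    pc = np.asarray(percent, dtype=float)
    labels = np.full(pc.shape, INTERMEDIATE, dtype=object)
    labels[pc <= naive_threshold] = NAIVE
    labels[pc >= proficient_threshold] = PROFICIENT
    labels[np.isnan(pc)] = "undefined"
    return labels


@dataclass
class LickRateTrace:
    t: np.ndarray
    rate: np.ndarray
    smoothing: str


def lick_rate(lick_times: np.ndarray, t_grid: np.ndarray,
              kernel: str = "gaussian", width_s: float = 2.0) -> LickRateTrace:
    """Lick rate (Hz) on a uniform time grid.

    ``kernel='gaussian'`` convolves the binned lick count with a Gaussian of
    SD ``width_s`` truncated at +/-3 SD and renormalized (the smoothing used
    for imaging sessions); ``kernel='none'`` returns the binned rate, whose
    integral over the grid equals the lick count.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2:
        raise ValueError("t_grid must have at least two points")
    dt = t[1] - t[0]
    edges = np.concatenate([t - dt / 2, [t[-1] + dt / 2]])
    counts, _ = np.histogram(np.asarray(lick_times, dtype=float), bins=edges)
    rate = counts / dt
    if kernel == "none":
        return LickRateTrace(t, rate, "none")
    if kernel != "gaussian":
        raise ValueError(f"unknown kernel {kernel!r}")
    half = int(np.ceil(3.0 * width_s / dt))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * dt / width_s) ** 2)
    k /= k.sum()
    smooth = np.convolve(rate, k, mode="same")
    return LickRateTrace(t, smooth, f"gaussian(sd={width_s}s)")


def lick_divergence_pvalues(rates_splus: np.ndarray, rates_sminus: np.ndarray
                            ) -> np.ndarray:
    """Per-timepoint Wilcoxon rank-sum p for S+ vs S- per-trial lick rates.

    Inputs are trials x timepoints matrices on a common trial-relative grid.
    Timepoints where both samples are identical yield p = 1.
    """
    a = np.atleast_2d(np.asarray(rates_splus, dtype=float))
    b = np.atleast_2d(np.asarray(rates_sminus, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per class")
    if a.shape[1] != b.shape[1]:
        raise ValueError("classes must share the time grid")
    p = np.ones(a.shape[1])
    for j in range(a.shape[1]):
        x, y = a[:, j], b[:, j]
        if np.ptp(np.concatenate([x, y])) == 0:
            p[j] = 1.0
            continue
        p[j] = stats.ranksums(x, y).pvalue
    return p


def dry_wet_lick_metrics(trial: Trial, lick_times: np.ndarray,
                         wet_window_s: float = 1.5) -> tuple[float, float | None]:
    """Lick frequency before (dry) and after (wet) reward delivery.

    Dry licking spans odor onset to reinforcement; wet licking spans the
    ``wet_window_s`` consumption window after reinforcement. Returns
    ``(dry_hz, wet_hz)``; ``wet_hz`` is None on unrewarded trials.
    """
    t = np.asarray(lick_times, dtype=float)
    if trial.t_reinforcement is None:
        dry_span = trial.t_odor_off - trial.t_odor_on
        dry = np.sum((t >= trial.t_odor_on) & (t < trial.t_odor_off)) / dry_span
        return float(dry), None
    t_r = trial.t_reinforcement
    dry_span = t_r - trial.t_odor_on
    if dry_span <= 0:
        raise ValueError("reinforcement precedes odor onset")
    dry = np.sum((t >= trial.t_odor_on) & (t < t_r)) / dry_span
    wet = np.sum((t >= t_r) & (t < t_r + wet_window_s)) / wet_window_s
    return float(dry), float(wet)
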