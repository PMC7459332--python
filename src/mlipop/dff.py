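"""Fluorescence normalization, trial alignment and eventization.

dF/F uses the per-trial baseline convention: F0 is the mean raw fluorescence
of each ROI over the 2 s preceding the trial-initiating lick, and
dF/F = (F - F0) / F0. Trials are aligned to trial start, odorant onset,
reward delivery, or the detected dF/F onset, by nearest frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PeriodWindows
from .session import Session, Trial

log = logging.getLogger(__name__)

ALIGNMENTS = ("trial_start", "odor_on", "reinforcement", "dff_onset")


@dataclass
class TrialTensor:
    """Trial-aligned dF/F: ``values`` is trials x ROIs x timepoints."""

    values: np.ndarray
    t_rel: np.ndarray
    alignment: str
    trial_indices: np.ndarray      # session trial index of each kept trial
    imaging_rate: float

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def labels(self, session: Session) -> np.ndarray:
        """Valence label of each kept trial."""
        by_index = {tr.index: tr.valence for tr in session.trials}
        return np.array([by_index[i] for i in self.trial_indices])


def compute_dff(F: np.ndarray, trial_start_times: np.ndarray,
                imaging_rate: float, baseline_s: float = 2.0) -> np.ndarray:
    """Per-trial-baseline dF/F = (F - F0) / F0 for a frames x ROIs matrix.

    F0 for the block of frames from each trial start to the next is the mean
    fluorescence over ``baseline_s`` seconds before that trial start (frames
    before the first trial use the first trial's baseline). Raises if any
    baseline mean is <= 0, naming the offending ROI and trial.
    """
    F = np.asarray(F, dtype=float)
    starts = np.asarray(trial_start_times, dtype=float)
    n_frames = F.shape[0]
    dff = np.empty_like(F)
    start_frames = np.round(starts * imaging_rate).astype(int)
    bl_frames = max(int(round(baseline_s * imaging_rate)), 1)
    block_edges = np.concatenate([start_frames, [n_frames]])
    for i, s0 in enumerate(start_frames):
        lo = max(s0 - bl_frames, 0)
        if lo >= s0:
            raise ValueError(f"trial {i}: no baseline frames before start")
        f0 = F[lo:s0].mean(axis=0)
        bad = np.nonzero(f0 <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive baseline F0 for ROI {bad[0]} "
                             f"at trial {i}")
        a = 0 if i == 0 else block_edges[i]
        b = block_edges[i + 1]
        dff[a:b] = (F[a:b] - f0) / f0
    return dff


def _alignment_time(trial: Trial, alignment: str) -> float | None:
    if alignment == "trial_start":
        return trial.t_start
    if alignment == "odor_on":
        return trial.t_odor_on
    if alignment == "reinforcement":
        return trial.t_reinforcement
    raise ValueError(f"unknown alignment {alignment!r}")


def align_trials(dff: np.ndarray, trials: list[Trial], alignment: str,
                 t_range: tuple[float, float], imaging_rate: float
                 ) -> TrialTensor:
    """Cut nearest-frame trial snippets aligned to an event.

    Trials lacking the event (e.g. reinforcement on a CR trial) or whose
    window leaves the recording are dropped; the drop count is logged.
    Raises when no trial survives.
    """
    dff = np.asarray(dff, dtype=float)
    lo, hi = t_range
    n_lo = int(np.round(lo * imaging_rate))
    n_hi = int(np.round(hi * imaging_rate))
    t_rel = np.arange(n_lo, n_hi + 1) / imaging_rate
    kept, slabs = [], []
    dropped = 0
    for tr in trials:
        t0 = _alignment_time(tr, alignment)
        if t0 is None:
            dropped += 1
            continue
        c = int(np.round(t0 * imaging_rate))
        a, b = c + n_lo, c + n_hi + 1
        if a < 0 or b > dff.shape[0]:
            dropped += 1
            continue
        kept.append(tr.index)
        slabs.append(dff[a:b].T)       # ROIs x timepoints
    if dropped:
        log.info("align_trials(%s): dropped %d of %d trials",
                 alignment, dropped, len(trials))
    if not kept:
        raise ValueError(f"no trial has a valid window for alignment {alignment!r}")
    return TrialTensor(values=np.stack(slabs), t_rel=t_rel,
                       alignment=alignment, trial_indices=np.array(kept),
                       imaging_rate=imaging_rate)


def period_means(tensor: TrialTensor, window: tuple[float, float]) -> np.ndarray:
    """Mean dF/F per trial per ROI over frames with t_rel in [lo, hi)."""
    lo, hi = window
    m = (tensor.t_rel >= lo) & (tensor.t_rel < hi)
    if not np.any(m):
        raise ValueError(f"window {window} contains no frames of the tensor")
    return tensor.values[:, :, m].mean(axis=2)


def classify_responsive(trial_traces: np.ndarray, t_rel: np.ndarray,
                        odor_window: tuple[float, float] = (0.0, 4.0),
                        baseline_window: tuple[float, float] = (-10.0, -2.0),
                        n_sd: float = 2.5) -> bool:
    """Responsiveness of one ROI from its trials x timepoints dF/F traces.

    Baseline mean and SD are pooled over all (trial, frame) samples in the
    10-2 s pre-odor interval; the ROI is responsive when any odor-period
    frame of the trial-averaged trace deviates from the baseline mean by
    strictly more than ``n_sd`` baseline SDs (increase or decrease). Pooling
    the baseline over single trials keeps the criterion scaled to
    trial-to-trial variability, so averaged-trace noise alone does not
    trigger it. With zero baseline SD, any nonzero deviation counts.
    """
    traces = np.atleast_2d(np.asarray(trial_traces, dtype=float))
    bl = (t_rel >= baseline_window[0]) & (t_rel < baseline_window[1])
    if bl.sum() < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    pool = traces[:, bl]
    mu, sd = pool.mean(), pool.std(ddof=0)
    od = (t_rel >= odor_window[0]) & (t_rel < odor_window[1])
    dev = np.abs(traces.mean(axis=0)[od] - mu)
    if sd == 0:
        return bool(np.any(dev > 0))
    return bool(np.any(dev > n_sd * sd))


def responsive_fraction(tensor: TrialTensor, **kwargs) -> float:
    """Fraction of ROIs responsive in the tensor (per-trial baselines)."""
    flags = [classify_responsive(tensor.values[:, r, :], tensor.t_rel,
                                 **kwargs)
             for r in range(tensor.values.shape[1])]
    return float(np.mean(flags))


def align_to_dff_onset(tensor: TrialTensor, derivative_threshold: float = 0.03,
                       t_range: tuple[float, float] | None = None
                       ) -> TrialTensor:
    """Re-align trials to the detected onset of the ensemble dF/F rise.

    The per-trial onset is the first frame at or after odor onset where the
    per-frame first difference of the ensemble-mean dF/F exceeds the
    threshold (0.03 per frame at 5.3 Hz). Trials without a crossing are
    dropped; raises when none crosses.
    """
    if derivative_threshold <= 0:
        raise ValueError("derivative_threshold must be > 0")
    if tensor.alignment != "odor_on":
        raise ValueError("onset alignment expects an odor_on-aligned tensor")
    if t_range is None:
        t_range = (tensor.t_rel[0] + 1.0, 2.0)
    n_lo = int(np.round(t_range[0] * tensor.imaging_rate))
    n_hi = int(np.round(t_range[1] * tensor.imaging_rate))
    t_rel = np.arange(n_lo, n_hi + 1) / tensor.imaging_rate
    post = tensor.t_rel >= 0
    kept, slabs = [], []
    for k in range(tensor.n_trials):
        mean_trace = tensor.values[k].mean(axis=0)
        deriv = np.diff(mean_trace)
        cand = np.nonzero(post[1:] & (deriv > derivative_threshold))[0]
        if cand.size == 0:
            continue
        c = cand[0] + 1                    # first frame after the crossing step
        a, b = c + n_lo, c + n_hi + 1
        if a < 0 or b > tensor.values.shape[2]:
            continue
        kept.append(tensor.trial_indices[k])
        slabs.append(tensor.values[k][:, a:b])
    if not kept:
        raise ValueError("no trial crosses the dF/F onset threshold")
    return TrialTensor(values=np.stack(slabs), t_rel=t_rel,
                       alignment="dff_onset", trial_indices=np.array(kept),
                       imaging_rate=tensor.imaging_rate)


def standard_period_means(tensor: TrialTensor, windows: PeriodWindows,
                          session: Session) -> dict[str, np.ndarray]:
    """Period means for the three canonical windows.

    Pre-odorant and odorant come from an odor-aligned tensor; reinforcement
    requires reward-aligned timing, so it is computed per rewarded trial via
    the reinforcement offset relative to odor onset (reward at odor offset).
    Unrewarded trials get NaN in the reinforcement column.
    """
    out = {
        "pre_odorant": period_means(tensor, windows.pre_odorant),
        "odorant": period_means(tensor, windows.odorant),
    }
    by_index = {tr.index: tr for tr in session.trials}
    rein = np.full(out["odorant"].shape, np.nan)
    for k, idx in enumerate(tensor.trial_indices):
        tr = by_index[idx]
        if tr.t_reinforcement is None:
            continue
        off = tr.t_reinforcement - tr.t_odor_on
        lo = off + windows.reinforcement[0]
        hi = off + windows.reinforcement[1]
        m = (tensor.t_rel >= lo) & (tensor.t_rel < hi)
        if np.any(m):
            rein[k] = tensor.values[k][:, m].mean(axis=1)
    out["reinforcement"] = rein
    return out
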