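"""Synthetic go-no go (and go-go) session generator.

Emulates the statistical structure of head-fixed olfactory discrimination
sessions with simultaneous two-photon Ca2+ imaging of a molecular-layer
interneuron ensemble:

* trial timing — trial-initiating lick, odorant 1-1.5 s later, two 2-s lick
  segments, inter-trial interval 22.3-22.8 s with a 10-s timeout after a
  false alarm;
* behavior — a sigmoid learning curve crossing the naive (<=65% correct) to
  proficient (>=80%) regimes, with outcome-specific lick trains that score
  back to the intended outcome exactly;
* ensemble dF/F — a shared valence factor whose amplitude grows with
  performance, mixed with orthogonalized shared-noise factors of matched
  variance so the participation-ratio dimensionality of the noiseless signal
  equals ``n_latents``; within the reinforcement window of rewarded trials
  the valence factor is coupled to the session's smoothed lick rate at a
  configurable Pearson coefficient;
* kinematics — a smooth nonnegative body-velocity trace with lick-locked
  transients, and its discrete derivative.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import behavior
from .config import ConfigurationError, EnsembleConfig, LearningCurve, SessionConfig
from .session import CR, FA, HIT, MISS, SMINUS, SPLUS, Session, Trial

__all__ = ["generate_session", "generate_lick_train", "generate_kinematics",
           "performance_scale"]


def _jittered_train(rng, t0: float, t1: float, rate_hz: float,
                    guarantee: bool = False) -> np.ndarray:
    """Near-regular lick train in [t0, t1) at ``rate_hz`` with timing jitter.

    With ``guarantee`` the span always contains at least one lick even when
    the expected count rounds to zero.
    """
    span = t1 - t0
    if span <= 0 or rate_hz <= 0:
        return np.empty(0)
    n = int(np.floor(span * rate_hz))
    if n == 0:
        if not guarantee:
            return np.empty(0)
        n = 1
    isi = span / n
    base = t0 + (np.arange(n) + 0.5) * isi
    jitter = rng.uniform(-0.3, 0.3, size=n) * isi
    t = np.sort(base + jitter)
    return t[(t >= t0) & (t < t1)]


def generate_lick_train(trial: Trial, outcome_target: str, rng,
                        cfg: SessionConfig,
                        pre_rate_hz: float = 4.0,
                        segment_rate_hz: float = 6.0,
                        wet_window_s: float = 1.5) -> np.ndarray:
    """Lick times for one trial realizing ``outcome_target``.

    Hit: licks in every segment plus a post-reward burst whose frequency
    grows with ``cfg.reward_volume`` (>8 Hz at the default volume).
    CR: licking ceases within ~0.8 s of odor onset. FA: licks in both
    segments without a reward burst. Miss: one segment left empty.
    Scoring the returned train with :func:`behavior.score_trial` reproduces
    ``outcome_target`` by construction.
    """
    if not cfg.go_go:
        valence_ok = {HIT: SPLUS, MISS: SPLUS, CR: SMINUS, FA: SMINUS}
        if valence_ok[outcome_target] != trial.valence:
            raise ValueError(
                f"outcome {outcome_target} inconsistent with valence {trial.valence}")
    on, off = trial.t_odor_on, trial.t_odor_off
    seg = cfg.lick_segment_s
    licks = [np.array([trial.t_start])]          # trial-initiating lick
    licks.append(_jittered_train(rng, trial.t_start + 0.15, on, pre_rate_hz))

    if outcome_target in (HIT, FA):
        for k in range(cfg.n_lick_segments):
            lo, hi = on + k * seg, on + (k + 1) * seg
            # keep jittered licks strictly inside the half-open segment
            licks.append(_jittered_train(rng, lo + 0.05, hi - 0.05,
                                         segment_rate_hz, guarantee=True))
        if outcome_target == HIT:
            wet_rate = 6.0 + 3.0 * cfg.reward_volume
            t_r = off  # reward delivered at odor offset
            licks.append(_jittered_train(rng, t_r, t_r + wet_window_s,
                                         wet_rate, guarantee=True))
    elif outcome_target == CR:
        stop = on + rng.uniform(0.4, 0.8)
        licks.append(_jittered_train(rng, on, stop, pre_rate_hz))
    elif outcome_target == MISS:
        empty = rng.integers(cfg.n_lick_segments)
        for k in range(cfg.n_lick_segments):
            if k == empty:
                continue
            lo, hi = on + k * seg, on + (k + 1) * seg
            licks.append(_jittered_train(rng, lo + 0.05, hi - 0.05, 2.0))
    else:
        raise ValueError(f"unknown outcome target {outcome_target!r}")
    return np.sort(np.concatenate(licks))


def performance_scale(pc: np.ndarray, asymptote_pc: float) -> np.ndarray:
    """Map percent correct onto the [0, 1] valence-divergence scale.

    Chance (50%) maps to 0 and the learning-curve asymptote to 1, so naive
    ensembles show no S+/S- divergence and proficient ones the full response.
    """
    denom = max(asymptote_pc - 50.0, 1e-9)
    return np.clip((np.asarray(pc, dtype=float) - 50.0) / denom, 0.0, 1.0)


def _build_trials(cfg: SessionConfig, lc: LearningCurve, rng):
    """Draw valences, target outcomes, timing marks and lick trains."""
    trials: list[Trial] = []
    lick_chunks: list[np.ndarray] = []
    t_cursor = 12.0   # pre-session baseline (covers the 10-2 s baseline window)
    pc_expected = lc.percent_correct(np.arange(cfg.n_trials))
    for i in range(cfg.n_trials):
        phase = "forward"
        if cfg.reversal_trial is not None and i >= cfg.reversal_trial:
            phase = "reverse"
        valence = SPLUS if rng.random() < cfg.p_splus else SMINUS
        correct = rng.random() < pc_expected[i] / 100.0
        if cfg.go_go:
            target = HIT if correct else MISS
        elif valence == SPLUS:
            target = HIT if correct else MISS
        else:
            target = CR if correct else FA
        t_start = t_cursor
        t_on = t_start + rng.uniform(*cfg.odor_delay_range)
        t_off = t_on + cfg.odor_duration_s
        trial = Trial(index=i, t_start=t_start, t_odor_on=t_on, t_odor_off=t_off,
                      valence=valence, outcome=target, reversal_phase=phase)
        if target == HIT:
            trial.t_reinforcement = t_off
        lt = generate_lick_train(trial, target, rng, cfg)
        if not cfg.go_go:
            scored = behavior.score_trial(lt, trial, cfg.lick_segment_s,
                                          cfg.n_lick_segments)
            if scored != target:   # construction guarantees this never fires
                raise RuntimeError(f"trial {i}: generated {scored}, wanted {target}")
        trials.append(trial)
        lick_chunks.append(lt)
        iti = rng.uniform(*cfg.iti_range) + (cfg.fa_penalty_s if target == FA else 0.0)
        t_cursor = t_off + iti
    return trials, np.concatenate(lick_chunks)


def _indicator_kernel(tau_s: float, rate_hz: float) -> np.ndarray:
    """Unit-area exponential Ca2+-indicator kernel on the imaging grid."""
    dt = 1.0 / rate_hz
    n = max(int(np.ceil(5.0 * tau_s * rate_hz)), 2)
    k = np.exp(-np.arange(n) * dt / tau_s)
    return k / k.sum()


def _valence_factor(trials, frame_t, ens: EnsembleConfig, scale_per_trial,
                    rate_hz: float) -> np.ndarray:
    """Raw (pre-indicator) shared valence factor on the imaging grid."""
    s = np.zeros(frame_t.size)
    for tr, scale in zip(trials, scale_per_trial):
        on, off = tr.t_odor_on, tr.t_odor_off
        # early shared transient: both valences, first ~0.8 s of odor
        m = (frame_t >= on) & (frame_t < on + 0.8)
        s[m] += ens.amp_sminus
        if tr.valence == SPLUS:
            # ramp from trial start to reward (or odor offset), scaled by
            # the instantaneous behavioral performance
            peak_t = tr.t_reinforcement if tr.t_reinforcement is not None else off
            m = (frame_t >= tr.t_start) & (frame_t < peak_t)
            frac = (frame_t[m] - tr.t_start) / max(peak_t - tr.t_start, 1e-9)
            s[m] += ens.amp_splus * scale * frac
    return s


def _inject_lick_coupling(s: np.ndarray, trials, frame_t, lick_times,
                          ens: EnsembleConfig, rate_hz: float, rng,
                          rein_window_s: float = 1.5) -> np.ndarray:
    """Overwrite the valence factor inside reinforcement windows.

    The factor there becomes a standardized mixture of the session's
    2-s-Gaussian-smoothed lick rate (weight rho) and white noise
    (weight sqrt(1-rho^2)), so the pooled Pearson correlation between the
    ensemble mean and the lick rate over reinforcement-window timepoints
    targets ``ens.rho_reinforcement``.
    """
    rho = ens.rho_reinforcement
    rewarded = [tr for tr in trials if tr.t_reinforcement is not None]
    if not rewarded or ens.amp_reinforcement == 0:
        return s
    lr = behavior.lick_rate(lick_times, frame_t, kernel="gaussian", width_s=2.0).rate
    pool = np.zeros(frame_t.size, dtype=bool)
    for tr in rewarded:
        t_r = tr.t_reinforcement
        pool |= (frame_t >= t_r) & (frame_t <= t_r + rein_window_s)
    lz = lr[pool]
    sd = lz.std()
    if sd == 0:
        return s
    z = (lz - lz.mean()) / sd
    eta = rng.standard_normal(z.size)
    base = s[pool].max() if np.any(pool) else 0.0
    s[pool] = base + ens.amp_reinforcement * (
        rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eta)
    return s


def _mixing_matrix(ens: EnsembleConfig, rng) -> np.ndarray:
    """ROI loading matrix (n_rois x n_latents) with equal-norm orthogonal
    columns; column 0 carries the valence signal on the responsive subset."""
    n, k = ens.n_rois, ens.n_latents
    w1 = np.zeros(n)
    n_resp = max(int(round(ens.frac_responsive * n)), 1)
    resp = rng.choice(n, size=n_resp, replace=False)
    w1[resp] = rng.uniform(0.6, 1.4, size=n_resp)
    norm1 = np.linalg.norm(w1)
    if norm1 == 0:
        w1[0] = 1.0
        norm1 = 1.0
    W = np.empty((n, k))
    W[:, 0] = w1
    if k > 1:
        G = rng.standard_normal((n, k - 1))
        # orthogonalize against w1 and mutually; rescale to ||w1||
        Q, _ = np.linalg.qr(np.column_stack([w1 / norm1, G]))
        W[:, 1:] = Q[:, 1:k] * norm1
    return W


def _orthogonalized_noise_latents(signal: np.ndarray, k: int, rng,
                                  rate_hz: float) -> np.ndarray:
    """Smooth shared-noise factors, orthogonalized in time against the signal
    factor and each other, rescaled to the signal's empirical SD."""
    T = signal.size
    sig_sd = signal.std()
    Z = np.empty((T, k))
    if k == 0:
        return Z
    raw = rng.standard_normal((T, k))
    raw = gaussian_filter1d(raw, sigma=max(rate_hz * 0.5, 1.0), axis=0)
    s_c = signal - signal.mean()
    basis = [s_c / np.linalg.norm(s_c)] if np.linalg.norm(s_c) > 0 else []
    for j in range(k):
        v = raw[:, j] - raw[:, j].mean()
        for b in basis:
            v = v - (v @ b) * b
        nv = np.linalg.norm(v)
        if nv == 0:
            Z[:, j] = 0.0
            continue
        basis.append(v / nv)
        v = v / v.std() * sig_sd
        Z[:, j] = v
    return Z


def generate_session(cfg: SessionConfig, ens: EnsembleConfig,
                     lc: LearningCurve, *, with_kinematics: bool = True
                     ) -> Session:
    """Generate a complete synthetic session (deterministic given cfg.seed)."""
    cfg.validate()
    ens.validate()
    lc.validate()
    rng = np.random.default_rng(cfg.seed)

    trials, lick_times = _build_trials(cfg, lc, rng)
    duration = trials[-1].t_odor_off + 15.0
    n_frames = int(np.ceil(duration * cfg.imaging_rate))
    frame_t = np.arange(n_frames) / cfg.imaging_rate

    scale = performance_scale(lc.percent_correct(np.arange(cfg.n_trials)),
                              lc.asymptote_pc)
    s = _valence_factor(trials, frame_t, ens, scale, cfg.imaging_rate)
    kern = _indicator_kernel(ens.indicator_decay_s, cfg.imaging_rate)
    s = np.convolve(s, kern)[:n_frames]
    # lick coupling enters after indicator filtering: it is built from the
    # already-smooth lick-rate trace, which is what the analysis correlates
    s = _inject_lick_coupling(s, trials, frame_t, lick_times, ens,
                              cfg.imaging_rate, rng)

    W = _mixing_matrix(ens, rng)
    Z = _orthogonalized_noise_latents(s, ens.n_latents - 1, rng, cfg.imaging_rate)
    dff = np.outer(s, W[:, 0])
    if ens.n_latents > 1:
        dff += Z @ W[:, 1:].T
    if ens.noise_sd > 0:
        dff += rng.normal(0.0, ens.noise_sd, size=dff.shape)

    F = ens.baseline_f * (1.0 + dff)
    np.clip(F, 1e-3, None, out=F)

    session = Session(F=F, lick_times=lick_times, trials=trials,
                      imaging_rate=cfg.imaging_rate,
                      lick_rate_hz=cfg.lick_rate_hz, seed=cfg.seed,
                      meta={"generator": "mlipop.synth", "go_go": cfg.go_go,
                            "n_latents": ens.n_latents})
    if with_kinematics:
        v, a = generate_kinematics(session, rng=rng)
        session.body_velocity = v
        session.body_acceleration = a
    return session


def generate_kinematics(session: Session, rng=None, baseline: float = 0.3,
                        lick_amp: float = 1.0, noise_sd: float = 0.05,
                        bump_sd_s: float = 0.15):
    """Body velocity/acceleration on the lick-channel grid.

    Velocity is a smooth nonnegative trace: a tonic baseline plus
    Gaussian-shaped transients locked to each lick plus low-pass noise.
    Acceleration is the discrete time derivative of velocity.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    fs = session.lick_rate_hz
    n = int(np.ceil(session.duration_s * fs))
    v = np.zeros(n)
    if lick_amp != 0.0:
        idx = np.round(session.lick_times * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        impulses = np.zeros(n)
        np.add.at(impulses, idx, lick_amp)
        v += gaussian_filter1d(impulses, sigma=bump_sd_s * fs) * (bump_sd_s * fs)
    if noise_sd > 0:
        v += gaussian_filter1d(rng.normal(0.0, noise_sd, size=n), sigma=fs * 0.5)
    v += baseline
    np.clip(v, 0.0, None, out=v)
    a = np.diff(v, prepend=v[:1]) * fs
    return v, a
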