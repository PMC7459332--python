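"""Encoding model of the ensemble-mean dF/F trace, plus the shared
statistics layer (linear-model tests, normality-gated post-hoc pairs with
FDR correction, bootstrap CIs).

The encoding model regresses the per-trial ensemble-mean dF/F time course on
event variables (S+/S- odorant indicators active during application),
whole-trial variables (accuracy, reinforcement history, 20-trial windowed
percent correct) and continuous variables (lick rate and its derivative,
body velocity and acceleration). Continuous predictors and the response are
low-pass filtered with a 0.59-s Hamming-window FIR applied zero-phase.
Identity link, Gaussian noise: the fit is ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior
from .config import PeriodWindows
from .session import CORRECT_OUTCOMES, HIT, SPLUS, Session

log = logging.getLogger(__name__)

GROUPS = {
    "odorants": ["odor_splus", "odor_sminus"],
    "licks": ["lick_rate", "lick_rate_deriv"],
    "kinematics": ["body_velocity", "body_acceleration"],
    "reinforcement_history": ["reinforcement_history"],
    "accuracy": ["accuracy"],
    "performance": ["percent_correct"],
}


def hamming_lowpass(x: np.ndarray, rate_hz: float, time_constant_s: float = 0.59
                    ) -> np.ndarray:
    """Zero-phase Hamming-window FIR low-pass.

    The window length is round(time_constant_s x rate_hz) taps (minimum 1);
    the symmetric unit-sum kernel applied with 'same' convolution introduces
    no phase shift.
    """
    n = max(int(round(time_constant_s * rate_hz)), 1)
    if n == 1:
        return np.asarray(x, dtype=float).copy()
    k = np.hamming(n)
    k /= k.sum()
    return np.convolve(np.asarray(x, dtype=float), k, mode="same")


@dataclass
class DesignMatrix:
    X: np.ndarray                  # rows x columns, intercept excluded
    columns: list[str]
    y: np.ndarray                  # filtered ensemble-mean dF/F per row
    row_trial: np.ndarray          # session trial index per row
    row_t_rel: np.ndarray          # seconds relative to odor onset per row
    groups: dict[str, list[str]] = field(default_factory=lambda: dict(GROUPS))
    filter_desc: str = "hamming(0.59s), zero-phase"


def _resample_to_frames(trace: np.ndarray, src_rate: float, frame_t: np.ndarray
                        ) -> np.ndarray:
    src_t = np.arange(trace.size) / src_rate
    return np.interp(frame_t, src_t, trace)


def build_design(session: Session, dff: np.ndarray,
                 t_range: tuple[float, float] = (-2.0, 5.7),
                 pc_window: int = 20,
                 epoch: str | None = "proficient",
                 proficient_threshold: float = 80.0,
                 naive_threshold: float = 65.0) -> DesignMatrix:
    """Assemble the encoding-model design for (trial, timepoint) rows.

    Rows are frames within ``t_range`` seconds of odor onset for every
    selected trial (default: proficient-epoch trials only). Raises if any
    trial is unscored. Missing kinematics are zero-filled with a log note.
    """
    if any(tr.outcome is None for tr in session.trials):
        raise ValueError("all trials must be scored before building the design")
    fs = session.imaging_rate
    frame_t = np.arange(dff.shape[0]) / fs
    mean_dff = dff.mean(axis=1)

    pc = behavior.percent_correct(session.outcomes(), window=pc_window)
    epochs = behavior.classify_epoch(pc, naive_threshold, proficient_threshold)

    lr = behavior.lick_rate(session.lick_times, frame_t,
                            kernel="gaussian", width_s=2.0).rate
    lr_d = np.diff(lr, prepend=lr[:1]) * fs
    if session.body_velocity is None:
        log.info("build_design: kinematics absent, zero-filled")
        vel = np.zeros(frame_t.size)
        acc = np.zeros(frame_t.size)
    else:
        vel = _resample_to_frames(session.body_velocity, session.lick_rate_hz,
                                  frame_t)
        acc = _resample_to_frames(session.body_acceleration,
                                  session.lick_rate_hz, frame_t)

    cont = {"lick_rate": hamming_lowpass(lr, fs),
            "lick_rate_deriv": hamming_lowpass(lr_d, fs),
            "body_velocity": hamming_lowpass(vel, fs),
            "body_acceleration": hamming_lowpass(acc, fs)}
    y_full = hamming_lowpass(mean_dff, fs)

    rows_X, rows_y, row_trial, row_trel = [], [], [], []
    prev_rewarded = 0.0
    for i, tr in enumerate(session.trials):
        keep = epoch is None or epochs[i] == epoch
        if keep:
            m = (frame_t >= tr.t_odor_on + t_range[0]) & \
                (frame_t < tr.t_odor_on + t_range[1])
            idx = np.nonzero(m)[0]
            t_rel = frame_t[idx] - tr.t_odor_on
            odor_on = (frame_t[idx] >= tr.t_odor_on) & \
                      (frame_t[idx] < tr.t_odor_off)
            splus = odor_on.astype(float) * (tr.valence == SPLUS)
            sminus = odor_on.astype(float) * (tr.valence != SPLUS)
            acc_tr = float(tr.outcome in CORRECT_OUTCOMES)
            pc_tr = pc[i] if np.isfinite(pc[i]) else 50.0
            block = np.column_stack([
                splus, sminus,
                np.full(idx.size, acc_tr),
                np.full(idx.size, prev_rewarded),
                np.full(idx.size, pc_tr),
                cont["lick_rate"][idx], cont["lick_rate_deriv"][idx],
                cont["body_velocity"][idx], cont["body_acceleration"][idx],
            ])
            rows_X.append(block)
            rows_y.append(y_full[idx])
            row_trial.append(np.full(idx.size, tr.index))
            row_trel.append(t_rel)
        prev_rewarded = float(tr.outcome == HIT)
    if not rows_X:
        raise ValueError("no trials selected for the design (epoch filter)")
    columns = ["odor_splus", "odor_sminus", "accuracy",
               "reinforcement_history", "percent_correct",
               "lick_rate", "lick_rate_deriv",
               "body_velocity", "body_acceleration"]
    return DesignMatrix(X=np.vstack(rows_X), columns=columns,
                        y=np.concatenate(rows_y),
                        row_trial=np.concatenate(row_trial),
                        row_t_rel=np.concatenate(row_trel))


@dataclass
class GLMEncodingFit:
    coefficients: dict[str, float]
    intercept: float
    fitted: np.ndarray
    y: np.ndarray
    row_trial: np.ndarray
    row_t_rel: np.ndarray
    design: DesignMatrix
    dropped_columns: list[str]

    def r_squared(self, mask=None) -> float:
        """Percent variance explained over (optionally masked) rows,
        clipped to [0, 100]."""
        m = slice(None) if mask is None else mask
        y, f = self.y[m], self.fitted[m]
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            return 0.0
        r2 = 1.0 - np.sum((y - f) ** 2) / ss_tot
        return float(np.clip(r2, 0.0, 1.0) * 100.0)


def _lstsq_with_pruning(X: np.ndarray, y: np.ndarray, columns: list[str]):
    """OLS with greedy removal of aliased (rank-deficient) columns."""
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0 or j == 0]
    dropped = [columns[j] for j in range(X.shape[1]) if j not in keep]
    Xk = X[:, keep]
    A = np.column_stack([np.ones(X.shape[0]), Xk])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR to identify dependent columns (intercept always kept)
        from scipy.linalg import qr
        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad_piv = piv[diag <= tol] if diag.size == A.shape[1] else piv[rank:]
        bad = sorted(int(p) for p in set(piv[rank:]) | set(np.atleast_1d(bad_piv)))
        bad_cols = [keep[j - 1] for j in bad if j > 0]
        dropped += [columns[j] for j in bad_cols]
        keep = [j for j in keep if j not in bad_cols]
        Xk = X[:, keep]
        A = np.column_stack([np.ones(X.shape[0]), Xk])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    coefs = {columns[j]: 0.0 for j in range(X.shape[1])}
    for j, cj in enumerate(keep):
        coefs[columns[cj]] = float(beta[j + 1])
    if dropped:
        log.info("encoding GLM: dropped aliased/constant columns %s", dropped)
    return float(beta[0]), coefs, fitted, dropped


def fit_encoding_glm(design: DesignMatrix) -> GLMEncodingFit:
    """Least-squares fit of the filtered ensemble-mean dF/F (identity link,
    Gaussian noise). Aliased columns are dropped with a log message."""
    if design.X.shape[0] != design.y.size:
        raise ValueError("design rows must match response length")
    intercept, coefs, fitted, dropped = _lstsq_with_pruning(
        design.X, design.y, design.columns)
    return GLMEncodingFit(coefficients=coefs, intercept=intercept,
                          fitted=fitted, y=design.y,
                          row_trial=design.row_trial,
                          row_t_rel=design.row_t_rel,
                          design=design, dropped_columns=dropped)


def period_masks(row_t_rel: np.ndarray, windows: PeriodWindows,
                 reward_offset_s: float = 4.0) -> dict[str, np.ndarray]:
    """Row masks for the pre-odorant, odorant and outcome periods (times
    relative to odor onset; reward delivered ``reward_offset_s`` after)."""
    lo, hi = windows.reinforcement
    return {
        "pre_odorant": (row_t_rel >= windows.pre_odorant[0])
                       & (row_t_rel < windows.pre_odorant[1]),
        "odorant": (row_t_rel >= windows.odorant[0])
                   & (row_t_rel < windows.odorant[1]),
        "outcome": (row_t_rel >= reward_offset_s + lo)
                   & (row_t_rel < reward_offset_s + hi),
    }


def variance_explained(fit: GLMEncodingFit, windows: PeriodWindows
                       ) -> dict[str, float]:
    """Percent variance explained per trial period (NaN when <3 rows)."""
    out = {}
    for period, m in period_masks(fit.row_t_rel, windows).items():
        out[period] = fit.r_squared(m) if m.sum() >= 3 else float("nan")
    return out


def group_contributions(design: DesignMatrix, windows: PeriodWindows,
                        groups: dict[str, list[str]] | None = None
                        ) -> pd.DataFrame:
    """Leave-group-out contribution of each variable group per period.

    contribution(g) = max(R2_full - R2_without_g, 0), normalized within each
    period to sum to 100%. When every raw drop is zero the contributions are
    uniform and a warning is logged.
    """
    groups = dict(GROUPS) if groups is None else groups
    if len(groups) < 2:
        raise ValueError("need at least two variable groups")
    full = fit_encoding_glm(design)
    masks = period_masks(design.row_t_rel, windows)
    drops = pd.DataFrame(index=list(groups), columns=list(masks), dtype=float)
    for gname, cols in groups.items():
        keep = [j for j, c in enumerate(design.columns) if c not in cols]
        sub = DesignMatrix(X=design.X[:, keep],
                           columns=[design.columns[j] for j in keep],
                           y=design.y, row_trial=design.row_trial,
                           row_t_rel=design.row_t_rel)
        reduced = fit_encoding_glm(sub)
        for period, m in masks.items():
            if m.sum() < 3:
                drops.loc[gname, period] = np.nan
                continue
            drops.loc[gname, period] = max(
                full.r_squared(m) - reduced.r_squared(m), 0.0)
    contrib = drops.copy()
    for period in contrib.columns:
        tot = contrib[period].sum()
        if not np.isfinite(tot) or tot == 0:
            log.warning("group_contributions: all drops zero in %s, "
                        "uniform contributions", period)
            contrib[period] = 100.0 / len(groups)
        else:
            contrib[period] = 100.0 * contrib[period] / tot
    return contrib


def glm_test(values, factors: dict[str, object], interactions: bool = True):
    """Linear-model omnibus test with per-term p-values.

    ``values`` is the response, ``factors`` maps factor names to per-
    observation level arrays. Returns (F, p, per-term table from a type-II
    ANOVA). Raises on a saturated model (no residual degrees of freedom).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float)})
    for name, levels in factors.items():
        df[name] = pd.Categorical(np.asarray(levels))
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name} needs >=2 levels")
    op = " * " if interactions else " + "
    formula = "value ~ " + op.join(f"C({n})" for n in factors)
    res = smf.ols(formula, data=df).fit()
    if res.df_resid <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    table = sm.stats.anova_lm(res, typ=2)
    return float(res.fvalue), float(res.f_pvalue), table


def anderson_darling_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when the Anderson-Darling test does not reject normality."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level) / 100.0
    crit = res.critical_values[np.argmin(np.abs(levels - alpha))]
    return bool(res.statistic < crit)


def gated_pairwise_pvalue(x, y, alpha: float = 0.05) -> float:
    """Two-sided p for one pair: t test when both samples pass the
    Anderson-Darling normality gate, Wilcoxon rank-sum otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if anderson_darling_normal(x, alpha) and anderson_darling_normal(y, alpha):
        return float(stats.ttest_ind(x, y).pvalue)
    return float(stats.ranksums(x, y).pvalue)


def posthoc_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up at level q.

    Returns (significant flags, pFDR) where pFDR is the largest p-value
    declared significant (0 when none is).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    p_fdr = float(p[reject].max()) if np.any(reject) else 0.0
    return reject, p_fdr


def posthoc_pairwise_fdr(samples: dict[str, np.ndarray], q: float = 0.05,
                         alpha_normal: float = 0.05):
    """Normality-gated pairwise tests over all sample pairs, BH-corrected.

    Returns a DataFrame of pairs with raw p and significance, plus pFDR.
    """
    names = list(samples)
    pairs, ps = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j]))
            ps.append(gated_pairwise_pvalue(samples[names[i]],
                                            samples[names[j]], alpha_normal))
    reject, p_fdr = posthoc_fdr(ps, q)
    table = pd.DataFrame({"a": [a for a, _ in pairs],
                          "b": [b for _, b in pairs],
                          "p": ps, "significant": reject})
    return table, p_fdr


def bootstrap_ci(sample, n_boot: int = 1000, level: float = 95.0,
                 seed: int = 0, method: str = "bca") -> tuple[float, float]:
    """Bootstrap CI of the mean (1000 resamples by default).

    The default is the bias-corrected and accelerated (BCa) interval — the
    convention of the standard bootstrap-CI routines — with a plain
    percentile interval available via ``method='percentile'``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("sample must have >=2 values")
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    means = x[rng.integers(0, x.size, size=(n_boot, x.size))].mean(axis=1)
    alpha = (100.0 - level) / 200.0
    if method == "percentile":
        lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)
    if method != "bca":
        raise ValueError(f"unknown bootstrap method {method!r}")
    theta = x.mean()
    # bias correction from the bootstrap distribution
    p0 = np.clip(np.mean(means < theta), 1.0 / n_boot, 1.0 - 1.0 / n_boot)
    z0 = stats.norm.ppf(p0)
    # acceleration from the jackknife skewness of the mean
    jack = (x.sum() - x) / (x.size - 1)
    d = jack.mean() - jack
    denom = np.sum(d ** 2) ** 1.5
    a_hat = np.sum(d ** 3) / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for z in (stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)):
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a_hat * (z0 + z)))
        out.append(np.percentile(means, 100.0 * adj))
    return float(out[0]), float(out[1])
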