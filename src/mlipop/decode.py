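"""Population analyses: leave-one-out LDA decoding with shuffle nulls,
ROI subsampling, participation-ratio dimensionality, PCA projection and
dF/F-lick correlations.

The decoder is Fisher's linear discriminant with equal class priors and a
pooled within-class covariance, ridge-regularized with gamma = 1e-6 x
trace/M x I so it stays defined when ROIs outnumber trials. Accuracy is
leave-one-out: the held-out trial is classified by the discriminant fit to
all remaining trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .config import PeriodWindows
from .dff import TrialTensor
from .session import Session

log = logging.getLogger(__name__)

REG_GAMMA = 1e-6


@dataclass
class DecodingResult:
    t_rel: np.ndarray
    accuracy: np.ndarray
    shuffled_ci: np.ndarray | None     # 2 x timepoints [low, high]
    n_trials: int
    n_rois: int


@dataclass
class SubsampleCurve:
    subset_sizes: np.ndarray
    accuracy_mean: np.ndarray
    accuracy_ci: np.ndarray            # 2 x sizes
    n_draws: int


def _fit_lda(X: np.ndarray, y: np.ndarray):
    """Fisher discriminant weights for binary labels, equal priors."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    mus, n = [], X.shape[1]
    S = np.zeros((n, n))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        mus.append(mu)
        D = Xc - mu
        S += D.T @ D
    S /= max(X.shape[0] - 2, 1)
    S = S + REG_GAMMA * (np.trace(S) / n if np.trace(S) > 0 else 1.0) * np.eye(n)
    w = np.linalg.solve(S, mus[1] - mus[0])
    b = -0.5 * (mus[0] + mus[1]) @ w
    return classes, w, b


def _predict_lda(classes, w, b, X: np.ndarray):
    score = X @ w + b
    return np.where(score > 0, classes[1], classes[0])


def loo_lda_accuracy(X: np.ndarray, labels) -> float:
    """Leave-one-out LDA decoding accuracy at one timepoint.

    ``X`` is trials x ROIs; labels binary (e.g. S+/S-). Requires at least
    two trials per class and finite data; deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or np.any(counts < 2):
        raise ValueError("need two classes with >=2 trials each")
    correct = 0
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        cl, w, b = _fit_lda(X[mask], y[mask])
        if _predict_lda(cl, w, b, X[i:i + 1])[0] == y[i]:
            correct += 1
    return correct / X.shape[0]


def _shuffle_band(X_t: np.ndarray, y: np.ndarray, rng, n_shuffles: int,
                  n_boot: int = 1000, level: float = 95.0) -> np.ndarray:
    """Bootstrap 95% band of the shuffled-label accuracy distribution.

    ``X_t`` is timepoints x trials x ROIs. The band brackets where a
    shuffled-label accuracy falls (not its mean): shuffle accuracies are
    bootstrap-resampled and the percentiles taken over the resampled
    distribution. Returns 2 x timepoints.
    """
    T = X_t.shape[0]
    acc = np.empty((n_shuffles, T))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        for t in range(T):
            acc[s, t] = loo_lda_accuracy(X_t[t], ys)
    idx = rng.integers(0, n_shuffles, size=(n_boot, n_shuffles))
    boot = acc[idx].reshape(n_boot * n_shuffles, T)
    a = (100.0 - level) / 2.0
    return np.percentile(boot, [a, 100.0 - a], axis=0)


def decoding_timecourse(tensor: TrialTensor, labels, n_shuffles: int = 10,
                        seed: int = 0) -> DecodingResult:
    """Per-timepoint LOO-LDA accuracy with a shuffled-label 95% band."""
    y = np.asarray(labels)
    X_t = np.transpose(tensor.values, (2, 0, 1))   # time x trials x ROIs
    acc = np.array([loo_lda_accuracy(X_t[t], y) for t in range(X_t.shape[0])])
    band = None
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        band = _shuffle_band(X_t, y, rng, n_shuffles)
    else:
        log.info("decoding_timecourse: n_shuffles=0, no null band computed")
    return DecodingResult(t_rel=tensor.t_rel, accuracy=acc, shuffled_ci=band,
                          n_trials=tensor.n_trials,
                          n_rois=tensor.values.shape[1])


def subsample_decoding(X: np.ndarray, labels,
                       sizes=(1, 2, 5, 10, 20, 50, 100), n_draws: int = 50,
                       seed: int = 0) -> SubsampleCurve:
    """LOO-LDA accuracy for pseudorandom unique ROI subsets of each size.

    ``X`` is trials x ROIs (e.g. odorant-window period means). Sizes larger
    than the ROI count are skipped with a log message; the number of draws
    is capped at the number of distinct subsets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n_rois = X.shape[1]
    kept_sizes, means, ci = [], [], []
    for size in sizes:
        if size > n_rois:
            log.info("subsample_decoding: size %d > %d ROIs, skipped",
                     size, n_rois)
            continue
        from math import comb
        draws = min(n_draws, comb(n_rois, size))
        seen: set[tuple] = set()
        accs = []
        while len(seen) < draws:
            subset = tuple(sorted(rng.choice(n_rois, size=size, replace=False)))
            if subset in seen:
                continue
            seen.add(subset)
            accs.append(loo_lda_accuracy(X[:, list(subset)], y))
        accs = np.asarray(accs)
        kept_sizes.append(size)
        means.append(accs.mean())
        if accs.size > 1:
            boot = accs[rng.integers(0, accs.size,
                                     size=(1000, accs.size))].mean(axis=1)
            ci.append(np.percentile(boot, [2.5, 97.5]))
        else:
            ci.append(np.array([accs[0], accs[0]]))
    return SubsampleCurve(subset_sizes=np.array(kept_sizes),
                          accuracy_mean=np.array(means),
                          accuracy_ci=np.array(ci).T, n_draws=n_draws)


def dimensionality(X: np.ndarray) -> float:
    """Participation-ratio dimensionality of an observations x ROIs matrix.

    dim = (sum lambda_i)^2 / sum lambda_i^2 over the eigenvalues of the
    ROI-covariance; equals M for independent equal-variance ROIs and 1 for
    rank-one data. Raises on zero covariance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be observations x ROIs with >=2 observations")
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    s2 = np.sum(lam ** 2)
    if s2 == 0:
        raise ValueError("zero covariance: dimensionality undefined")
    return float(np.sum(lam) ** 2 / s2)


def pca_projection(X: np.ndarray) -> np.ndarray:
    """Scores of trials on the first two principal components of the ROI
    covariance (PC1 variance >= PC2). Raises on constant data."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >=2 trials")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant data: PCA undefined")
    n_comp = min(2, min(X.shape[0] - 1, X.shape[1]))
    return PCA(n_components=n_comp).fit_transform(X)


def _pool_window(trace: np.ndarray, frame_t: np.ndarray, t0: float,
                 window: tuple[float, float]) -> np.ndarray:
    m = (frame_t >= t0 + window[0]) & (frame_t < t0 + window[1])
    return trace[m]


def dff_lick_correlation(mean_dff: np.ndarray, lick_rate: np.ndarray,
                         session: Session, windows: PeriodWindows,
                         use_derivatives: bool = False
                         ) -> dict[str, tuple[float, float]]:
    """Pearson correlation of ensemble-mean dF/F vs lick rate per period.

    Both traces live on the imaging frame grid. Points are pooled over
    (trial, timepoint) pairs: pre-odorant and odorant windows relative to
    odor onset on every trial, the reinforcement window relative to reward
    on rewarded trials. With ``use_derivatives`` both traces are replaced by
    their discrete time derivative before pooling. Returns
    ``{period: (rho, p)}``; zero-variance pools yield (nan, nan).
    """
    x = np.asarray(mean_dff, dtype=float)
    l = np.asarray(lick_rate, dtype=float)
    if x.shape != l.shape:
        raise ValueError("traces must share the imaging grid")
    if use_derivatives:
        x = np.diff(x, prepend=x[:1]) * session.imaging_rate
        l = np.diff(l, prepend=l[:1]) * session.imaging_rate
    frame_t = np.arange(x.size) / session.imaging_rate
    out = {}
    spans = {
        "pre_odorant": [(tr.t_odor_on, windows.pre_odorant) for tr in session.trials],
        "odorant": [(tr.t_odor_on, windows.odorant) for tr in session.trials],
        "reinforcement": [(tr.t_reinforcement, windows.reinforcement)
                          for tr in session.trials
                          if tr.t_reinforcement is not None],
    }
    for period, pairs in spans.items():
        xs, ls = [], []
        for t0, win in pairs:
            xs.append(_pool_window(x, frame_t, t0, win))
            ls.append(_pool_window(l, frame_t, t0, win))
        if not xs:
            out[period] = (float("nan"), float("nan"))
            continue
        xv, lv = np.concatenate(xs), np.concatenate(ls)
        if xv.size < 3 or xv.std() == 0 or lv.std() == 0:
            log.info("dff_lick_correlation: degenerate pool for %s", period)
            out[period] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(xv, lv)
        out[period] = (float(r), float(p))
    return out
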