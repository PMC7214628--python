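"""Time-resolved target/non-target decoding and accuracy-curve segmentation.

A sliding window is moved across the epoch; inside each window, common
spatial pattern (CSP) filters are fitted on the training folds of a
stratified cross-validation, log-variance features are extracted, and a
shrinkage-regularised linear discriminant (LDA) is scored on the held-out
fold.  The group-mean accuracy as a function of window centre traces how
discriminative information evolves over the epoch; the time points where
that curve changes behaviour — found by an exact dynamic-programming
piecewise-linear segmentation with a BIC model-size choice — become the
boundaries of the variable window scheme.

CSP solves the generalised eigenproblem ``S_1 w = mu (S_1 + S_2) w`` of
the two class-mean spatial covariances; eigenvectors with extreme
eigenvalues maximise the variance ratio between classes and are invariant
(up to sign/scale) to any common invertible linear mixing of the sensors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .data_model import NONTARGET, TARGET, EpochedEEG, MultiSubjectDataset
from .errors import ParameterError, StratificationError

__all__ = [
    "ClassifierCurve",
    "ChangePointSet",
    "csp_from_covariances",
    "csp_fit",
    "csp_features",
    "time_resolved_accuracy",
    "detect_change_points",
]


@dataclass
class ClassifierCurve:
    """Cross-validated decoding accuracy per sliding-window centre."""

    times: np.ndarray
    accuracy: np.ndarray
    per_subject: np.ndarray | None = None  # (M, n_windows)
    window_length: float = np.nan
    step: float = np.nan
    folds: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.times.shape != self.accuracy.shape:
            raise ParameterError("times and accuracy must align")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ParameterError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class ChangePointSet:
    """Interior segment boundaries of a segmented accuracy curve."""

    times: tuple[float, ...]
    n_segments: int
    max_segments: int
    method: str = "dp_bic"


# ---------------------------------------------------------------------------
# CSP

def _class_covariance(data: np.ndarray) -> np.ndarray:
    """Trace-normalised spatial covariance averaged over trials.

    ``data`` is (n_trials, C, n_samples).
    """
    covs = np.einsum("ncs,nds->ncd", data, data) / data.shape[2]
    tr = np.trace(covs, axis1=1, axis2=2)
    tr = np.where(tr > 0, tr, 1.0)
    return (covs / tr[:, None, None]).mean(axis=0)


def csp_from_covariances(S1: np.ndarray, S2: np.ndarray, k: int = 3,
                         reg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """CSP filters from two class covariances.

    Solves ``S1 w = mu (S1 + S2) w``; returns ``(filters, eigenvalues)``
    with the ``2k`` rows of ``filters`` ordered (top-k descending, then
    bottom-k ascending) and scaled so that the filtered variance under the
    composite covariance is 1 per filter (``w^T (S1+S2) w = 1``).  ``reg``
    shrinks each covariance toward the scaled identity before solving.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    C = S1.shape[0]
    if S1.shape != (C, C) or S2.shape != (C, C):
        raise ParameterError("covariances must be square and same size")
    if k < 1 or 2 * k > C:
        raise ParameterError(f"need 1 <= 2k <= C, got k={k} for C={C}")
    if reg:
        S1 = (1 - reg) * S1 + reg * np.trace(S1) / C * np.eye(C)
        S2 = (1 - reg) * S2 + reg * np.trace(S2) / C * np.eye(C)
    comp = S1 + S2
    eigvals_comp = linalg.eigvalsh(comp)
    if eigvals_comp[0] <= 1e-10 * max(eigvals_comp[-1], 1e-300):
        raise ParameterError(
            "rank-deficient composite covariance; pass reg > 0 (shrinkage)"
        )
    mu, W = linalg.eigh(S1, comp)  # ascending; columns satisfy w^T comp w = 1
    top = W[:, ::-1][:, :k]
    bot = W[:, :k]
    filters = np.concatenate([top.T, bot.T], axis=0)
    eigenvalues = np.concatenate([mu[::-1][:k], mu[:k]])
    return filters, eigenvalues


def csp_fit(data: np.ndarray, labels: np.ndarray, k: int = 3,
            reg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Fit CSP filters on trial data ``(n_trials, C, n_samples)``."""
    labels = np.asarray(labels)
    covs = {}
    for cond in (TARGET, NONTARGET):
        idx = np.flatnonzero(labels == cond)
        if idx.size < 2:
            raise ParameterError(f"condition {cond} needs at least 2 trials")
        covs[cond] = _class_covariance(data[idx])
    return csp_from_covariances(covs[TARGET], covs[NONTARGET], k=k, reg=reg)


def csp_features(data: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Log-variance of CSP-filtered trials -> (n_trials, n_filters)."""
    filtered = np.einsum("fc,ncs->nfs", filters, data)
    var = filtered.var(axis=2)
    if np.any(var == 0):
        warnings.warn("zero-variance filtered signal; degenerate feature",
                      stacklevel=2)
    return np.log(var + 1e-30)


# ---------------------------------------------------------------------------
# Time-resolved accuracy

def time_resolved_accuracy(x: "MultiSubjectDataset | EpochedEEG",
                           win: float = 0.1, step: float = 0.02,
                           k: int = 3, folds: int = 10, reg: float = 0.05,
                           scoring: str = "balanced_accuracy",
                           random_state: int = 0) -> ClassifierCurve:
    """Sliding-window CSP+LDA cross-validated accuracy, group-averaged.

    For each window centre and each subject, a stratified ``folds``-fold
    cross-validation is run: CSP filters are fitted on the training folds
    only, log-variance features feed an LDA with Ledoit-Wolf shrinkage
    ('lsqr' solver), and the held-out fold is scored.  The returned curve
    is the mean over folds and subjects.

    With the rare-target design (20% targets) plain accuracy is dominated
    by the majority class, so the default score is *balanced* accuracy
    (mean of per-class accuracies), whose chance level is 0.5 at any class
    ratio; ``scoring="accuracy"`` restores the plain fraction correct.
    """
    if scoring not in ("balanced_accuracy", "accuracy"):
        raise ParameterError(f"unknown scoring {scoring!r}")
    subjects = list(x) if isinstance(x, MultiSubjectDataset) else [x]
    fs = subjects[0].fs
    n_win_samp = int(round(win * fs))
    if n_win_samp < 10:
        raise ParameterError("window must span at least 10 samples")
    if folds < 2:
        raise ParameterError("need at least 2 folds")
    times = subjects[0].times
    n_samples = subjects[0].n_samples
    step_samp = max(int(round(step * fs)), 1)
    starts = np.arange(0, n_samples - n_win_samp + 1, step_samp)
    if starts.size == 0:
        raise ParameterError("window longer than the epoch")
    centers = times[starts] + win / 2.0

    acc = np.zeros((len(subjects), starts.size))
    for mi, sub in enumerate(subjects):
        trials = np.transpose(sub.data, (2, 0, 1))  # (N, C, T)
        labels = sub.labels
        counts = np.bincount(labels, minlength=2)
        if counts.min() < folds:
            raise StratificationError(
                f"{folds}-fold stratification impossible: class counts {counts}"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=random_state)
        splits = list(skf.split(trials, labels))
        for wi, s0 in enumerate(starts):
            sl = trials[:, :, s0:s0 + n_win_samp]
            fold_scores = []
            for train, test in splits:
                filters, _ = csp_fit(sl[train], labels[train], k=k, reg=reg)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ftr = csp_features(sl[train], filters)
                    fte = csp_features(sl[test], filters)
                clf = LinearDiscriminantAnalysis(solver="lsqr",
                                                 shrinkage="auto")
                clf.fit(ftr, labels[train])
                pred = clf.predict(fte)
                if scoring == "balanced_accuracy":
                    fold_scores.append(
                        balanced_accuracy_score(labels[test], pred))
                else:
                    fold_scores.append(np.mean(pred == labels[test]))
            acc[mi, wi] = np.mean(fold_scores)
    return ClassifierCurve(times=centers, accuracy=acc.mean(axis=0),
                           per_subject=acc, window_length=win, step=step,
                           folds=folds)


# ---------------------------------------------------------------------------
# Change-point detection

def _prefix_sums(t: np.ndarray, y: np.ndarray):
    z = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    return z(t), z(t * t), z(y), z(y * y), z(t * y)


def _segment_rss(ps, i: int, j: int) -> float:
    """RSS of the least-squares line over points i..j-1 (j - i >= 2)."""
    St, Stt, Sy, Syy, Sty = ps
    n = j - i
    st = St[j] - St[i]
    stt = Stt[j] - Stt[i]
    sy = Sy[j] - Sy[i]
    syy = Syy[j] - Syy[i]
    sty = Sty[j] - Sty[i]
    sxx = stt - st * st / n
    sxy = sty - st * sy / n
    ss_tot = syy - sy * sy / n
    if sxx <= 1e-30:
        return max(ss_tot, 0.0)
    return max(ss_tot - sxy * sxy / sxx, 0.0)


def segment_piecewise_linear(t: np.ndarray, y: np.ndarray, n_segments: int,
                             min_size: int = 2) -> tuple[list[int], float]:
    """Optimal boundaries (interior start indices) for a fixed segment
    count, by dynamic programming over the exact per-segment RSS."""
    n = len(t)
    if n_segments < 1 or n < n_segments * min_size:
        raise ParameterError("too few points for the requested segments")
    ps = _prefix_sums(np.asarray(t, float), np.asarray(y, float))
    INF = np.inf
    # D[k][j]: best RSS for first j points in k segments
    D = np.full((n_segments + 1, n + 1), INF)
    back = np.zeros((n_segments + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, n_segments + 1):
        for j in range(kk * min_size, n + 1):
            best, arg = INF, 0
            for i in range((kk - 1) * min_size, j - min_size + 1):
                if D[kk - 1, i] == INF:
                    continue
                c = D[kk - 1, i] + _segment_rss(ps, i, j)
                if c < best:
                    best, arg = c, i
            D[kk, j], back[kk, j] = best, arg
    bounds = []
    j = n
    for kk in range(n_segments, 0, -1):
        i = back[kk, j]
        if kk > 1:
            bounds.append(i)
        j = i
    return sorted(bounds), float(D[n_segments, n])


def detect_change_points(curve: ClassifierCurve, max_segments: int = 8,
                         min_size: int = 2,
                         smooth_s: float = 0.05,
                         method: str = "dp_bic") -> ChangePointSet:
    """Change points of the accuracy curve.

    The curve is first smoothed with a moving average of width
    ``smooth_s`` seconds (0 disables), then segmented.  The default
    method fits every segment count up to ``max_segments`` by exact
    dynamic programming on piecewise-linear residuals and picks the count
    with the lowest BIC; change points are the interior boundaries.  A
    smoothed-derivative-extrema detector (``method="derivative"``) exists
    as an alternative.
    """
    if max_segments < 2:
        raise ParameterError("max_segments must be at least 2")
    t = curve.times
    y = curve.accuracy.copy()
    n = len(t)
    if n < 3 * max_segments:
        raise ParameterError(
            f"need at least {3 * max_segments} samples, got {n}"
        )
    if smooth_s and len(t) > 1:
        dt = float(np.median(np.diff(t)))
        w = max(int(round(smooth_s / dt)), 1)
        if w > 1:
            y = ndimage.uniform_filter1d(y, size=w, mode="nearest")

    if method == "derivative":
        dy = np.gradient(y, t)
        # extrema of the derivative: sign changes of its own gradient
        d2 = np.diff(np.sign(np.gradient(dy, t)))
        idx = np.flatnonzero(d2 != 0) + 1
        idx = idx[(idx > 0) & (idx < n - 1)][: max_segments - 1]
        return ChangePointSet(tuple(t[sorted(idx)]), len(idx) + 1,
                              max_segments, method="derivative")

    best = None
    for kk in range(1, max_segments + 1):
        if n < kk * min_size:
            break
        bounds, rss = segment_piecewise_linear(t, y, kk, min_size=min_size)
        n_par = 3 * kk - 1  # slope+intercept per segment, k-1 boundaries
        bic = n * np.log(max(rss, 1e-12 * n) / n) + n_par * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, kk, bounds)
    _, n_seg, bounds = best
    return ChangePointSet(tuple(float(t[b]) for b in bounds), n_seg,
                          max_segments)


def brute_force_segmentation(t, y, n_segments, min_size=2):
    """Exhaustive search over all boundary placements (test oracle)."""
    n = len(t)
    ps = _prefix_sums(np.asarray(t, float), np.asarray(y, float))
    best = (np.inf, [])
    for bounds in itertools.combinations(range(min_size, n - min_size + 1),
                                         n_segments - 1):
        edges = [0, *bounds, n]
        if any(b - a < min_size for a, b in zip(edges, edges[1:])):
            continue
        rss = sum(_segment_rss(ps, a, b) for a, b in zip(edges, edges[1:]))
        if rss < best[0]:
            best = (rss, list(bounds))
    return best[1], best[0]
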