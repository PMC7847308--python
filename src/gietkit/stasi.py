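"""Step-transition and state identification (STaSI) for intensity traces.

A piecewise-constant description of a noisy trace is built in three
stages: (i) recursive change-point detection using the Student-t
statistic of the mean difference across each candidate split, with the
noise scale estimated robustly from successive differences; (ii)
agglomerative merging of segment means into nested candidate state sets;
(iii) selection of the state count by minimum description length, which
balances the Gaussian fit cost of the residuals against the cost of
encoding the model (state means and change-point positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .localize import Trace

__all__ = [
    "Segmentation",
    "estimate_noise_sd",
    "stasi_segment",
    "goodness_of_fit",
    "select_training_traces",
]


@dataclass
class Segmentation:
    """Piecewise-constant fit of a trace grouped into states.

    ``change_points`` are the start indices of segments after the first
    (strictly increasing); segment ``i`` covers
    ``[boundaries[i], boundaries[i+1])``.  ``state_labels`` assigns each
    segment to a state (0-based, states sorted by ascending mean).
    """

    change_points: np.ndarray
    segment_means: np.ndarray
    state_labels: np.ndarray
    state_means: np.ndarray
    noise_sd: float
    mdl_score: float
    n_frames: int

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate(([0], self.change_points, [self.n_frames]))

    def framewise_fit(self) -> np.ndarray:
        """Fitted (segment-mean) value for every frame."""
        out = np.empty(self.n_frames)
        b = self.boundaries
        for i, mu in enumerate(self.segment_means):
            out[b[i] : b[i + 1]] = mu
        return out

    def framewise_states(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=int)
        b = self.boundaries
        for i, s in enumerate(self.state_labels):
            out[b[i] : b[i + 1]] = s
        return out


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise scale from successive differences.

    sigma = median(|y_{t+1} - y_t|) / (sqrt(2) * 0.6745); the sqrt(2)
    removes the variance doubling of differencing and 0.6745 converts the
    median absolute deviation to a Gaussian standard deviation.
    """
    dy = np.diff(np.asarray(y, dtype=float))
    if len(dy) == 0:
        return 0.0
    return float(np.median(np.abs(dy)) / (np.sqrt(2.0) * 0.6745))


def _best_split(y: np.ndarray, sigma: float) -> tuple[int, float]:
    """Best split index and its t statistic for a segment.

    The statistic at split k is |mean(y[:k]) - mean(y[k:])| /
    (sigma * sqrt(1/k + 1/(n-k))), evaluated for all admissible k.
    """
    n = len(y)
    cs = np.cumsum(y)
    k = np.arange(1, n)
    mean_left = cs[:-1] / k
    mean_right = (cs[-1] - cs[:-1]) / (n - k)
    tstat = np.abs(mean_left - mean_right) / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))
    i = int(np.argmax(tstat))
    return i + 1, float(tstat[i])


def _detect_change_points(
    y: np.ndarray, sigma: float, min_seg: int = 2, alpha: float = 0.01
) -> list[int]:
    """Recursive bisection; a split must pass a Bonferroni-corrected
    two-sided Student-t critical value to be accepted."""
    n_total = len(y)
    cps: list[int] = []

    def recurse(a: int, b: int) -> None:
        n = b - a
        if n < 2 * min_seg:
            return
        k, t = _best_split(y[a:b], sigma)
        if k < min_seg or n - k < min_seg:
            # best split too close to an edge; try the best admissible one
            kk, tt = max(
                ((k2, t2) for k2, t2 in _admissible_splits(y[a:b], sigma, min_seg)),
                key=lambda p: p[1],
                default=(None, 0.0),
            )
            if kk is None:
                return
            k, t = kk, tt
        crit = stats.t.ppf(1.0 - alpha / (2.0 * n_total), df=max(n - 2, 1))
        if t > crit:
            cps.append(a + k)
            recurse(a, a + k)
            recurse(a + k, b)

    recurse(0, n_total)
    return sorted(cps)


def _admissible_splits(y: np.ndarray, sigma: float, min_seg: int):
    n = len(y)
    cs = np.cumsum(y)
    for k in range(min_seg, n - min_seg + 1):
        ml = cs[k - 1] / k
        mr = (cs[-1] - cs[k - 1]) / (n - k)
        yield k, abs(ml - mr) / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))


def _mdl(y, boundaries, labels, state_means, sigma) -> float:
    """Description length in bits: Gaussian residual code + model code."""
    n = len(y)
    fit = np.empty(n)
    for i in range(len(labels)):
        fit[boundaries[i] : boundaries[i + 1]] = state_means[labels[i]]
    ssr = float(np.sum((y - fit) ** 2))
    f_bits = ssr / (2.0 * np.log(2.0) * sigma**2)
    k = len(state_means)
    n_cp = len(boundaries) - 2
    g_bits = 0.5 * k * np.log2(n) + n_cp * np.log2(n)
    return f_bits + g_bits


def stasi_segment(trace: Trace | np.ndarray) -> Segmentation:
    """Segment one intensity trace into steps and group them into states.

    Accepts a :class:`Trace` or a bare intensity array.  A constant or
    pure-noise trace yields a single state with no change points.
    """
    y = np.asarray(
        trace.intensity if isinstance(trace, Trace) else trace, dtype=float
    )
    if len(y) < 10:
        raise ValueError("trace too short to segment (need >= 10 frames)")
    sigma = estimate_noise_sd(y)
    if sigma <= 0:
        # noise-free steps: any nonzero scale recovers exact change points
        sigma = max(1e-12 * max(np.ptp(y), 1.0), np.finfo(float).tiny)

    cps = _detect_change_points(y, sigma)
    boundaries = np.concatenate(([0], cps, [len(y)])).astype(int)
    seg_means = np.array(
        [np.mean(y[a:b]) for a, b in zip(boundaries[:-1], boundaries[1:])]
    )
    seg_counts = boundaries[1:] - boundaries[:-1]

    # agglomerative merge of segment means -> nested groupings, MDL choice
    groups = [[i] for i in range(len(seg_means))]
    group_mean = seg_means.copy().tolist()
    group_n = seg_counts.copy().tolist()
    best = None
    while True:
        k = len(groups)
        labels = np.empty(len(seg_means), dtype=int)
        order = np.argsort(group_mean, kind="stable")
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        for gi, g in enumerate(groups):
            for seg in g:
                labels[seg] = rank[gi]
        state_means = np.asarray(group_mean)[order]
        score = _mdl(y, boundaries, labels, state_means, sigma)
        if best is None or score < best[0]:
            best = (score, labels.copy(), state_means.copy())
        if k == 1:
            break
        # merge the closest pair of group means
        gm = np.asarray(group_mean)
        idx = np.argsort(gm, kind="stable")
        diffs = np.diff(gm[idx])
        j = int(np.argmin(diffs))
        a, b = sorted((int(idx[j]), int(idx[j + 1])))
        na, nb = group_n[a], group_n[b]
        group_mean[a] = (group_mean[a] * na + group_mean[b] * nb) / (na + nb)
        group_n[a] = na + nb
        groups[a] = groups[a] + groups[b]
        del groups[b], group_mean[b], group_n[b]

    score, labels, state_means = best
    return Segmentation(
        change_points=np.asarray(cps, dtype=int),
        segment_means=seg_means,
        state_labels=labels,
        state_means=state_means,
        noise_sd=float(sigma),
        mdl_score=float(score),
        n_frames=len(y),
    )


def goodness_of_fit(trace: Trace, seg: Segmentation) -> float:
    """Normalized residual variance of the piecewise-constant fit.

    var(y - fit) / var(y); lower is better.  Invariant under global
    intensity rescaling.  A constant trace scores 0.
    """
    y = np.asarray(trace.intensity, dtype=float)
    vy = float(np.var(y))
    if vy == 0:
        return 0.0
    return float(np.var(y - seg.framewise_fit()) / vy)


def select_training_traces(
    traces: list[Trace],
    segmentations: list[Segmentation],
    fraction: float = 0.33,
) -> list[int]:
    """Indices of the best-fitting fraction of traces (for HMM seeding).

    Traces are ranked by :func:`goodness_of_fit`; ties are broken by
    trace id for a deterministic order.  With fewer than 3 traces all are
    returned with a warning.
    """
    if len(traces) != len(segmentations):
        raise ValueError("traces and segmentations must align")
    if len(traces) < 3:
        warnings.warn("fewer than 3 traces; using all for training", stacklevel=2)
        return list(range(len(traces)))
    scores = [goodness_of_fit(tr, sg) for tr, sg in zip(traces, segmentations)]
    order = sorted(range(len(traces)), key=lambda i: (scores[i], traces[i].id))
    n_keep = max(1, int(round(fraction * len(traces))))
    return order[:n_keep]
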