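"""Gaussian-emission hidden Markov model over single-molecule traces.

The K-state model (per-frame transition probabilities, Gaussian state
emissions) is trained by Baum-Welch on the pooled traces, each trace
entering as an independent sequence.  Initial parameters come from the
STaSI segmentations of the best-fitting traces; training runs one EM
sweep at a time so the full log-likelihood history is available and the
relative-change convergence criterion is exact.  The heavy lifting
(forward-backward, M-step, Viterbi) is delegated to hmmlearn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans

from .localize import Trace
from .stasi import Segmentation, estimate_noise_sd

__all__ = ["StateModel", "hmm_fit", "viterbi_decode"]


@dataclass
class StateModel:
    """K-state Gaussian-emission Markov model.

    States are sorted by ascending mean (the low/medium/high convention);
    ``transition_matrix`` holds per-frame probabilities (rows sum to 1).
    """

    means: np.ndarray
    sds: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    log_likelihood: float = np.nan
    log_likelihood_history: np.ndarray = field(
        default_factory=lambda: np.array([]), repr=False
    )
    variance_floored: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        k = len(self.means)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix must be K x K")
        if len(self.initial_distribution) != k or len(self.sds) != k:
            raise ValueError("parameter lengths must agree")
        if np.any(self.sds <= 0):
            raise ValueError("state standard deviations must be > 0")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("state means must be sorted ascending")

    @property
    def n_states(self) -> int:
        return len(self.means)

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(
            n_components=self.n_states,
            covariance_type="diag",
            init_params="",
            params="",
        )
        m.n_features = 1
        m.startprob_ = self.initial_distribution.copy()
        m.transmat_ = self.transition_matrix.copy()
        m.means_ = self.means.reshape(-1, 1).copy()
        m.covars_ = (self.sds**2).reshape(-1, 1).copy()
        return m

    def expected_dwell_frames(self) -> np.ndarray:
        """Mean dwell (frames) implied by the chain: 1 / (1 - p_ii)."""
        p_stay = np.diag(self.transition_matrix)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 - p_stay)


def _sorted_by_mean(means, sds, transmat, startprob):
    order = np.argsort(means, kind="stable")
    perm = np.ix_(order, order)
    return means[order], sds[order], transmat[perm], startprob[order]


def _initial_parameters(
    traces: list[Trace],
    segmentations: list[Segmentation],
    k: int,
    seed: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seed the HMM from STaSI fits: global state means by 1-D k-means on
    the framewise piecewise-constant values, transition matrix from
    pseudo-counted nearest-state label sequences."""
    fits = [sg.framewise_fit() for sg in segmentations]
    pooled = np.concatenate(fits)
    uniq = np.unique(pooled)
    if len(uniq) >= k:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(pooled.reshape(-1, 1))
        means = np.sort(km.cluster_centers_.ravel())
    else:
        # fewer distinct levels than states: spread over the data range
        lo, hi = float(pooled.min()), float(pooled.max())
        means = np.linspace(lo, hi if hi > lo else lo + 1.0, k)
    sigma = float(np.median([estimate_noise_sd(tr.intensity) for tr in traces]))
    if sigma <= 0:
        sigma = max(1e-3 * max(abs(means).max(), 1.0), 1e-6)
    sds = np.full(k, sigma)

    counts = np.ones((k, k))  # one pseudo-count per pair
    start = np.ones(k)
    for fit in fits:
        labels = np.argmin(np.abs(fit[:, None] - means[None, :]), axis=1)
        start[labels[0]] += 1
        np.add.at(counts, (labels[:-1], labels[1:]), 1)
    transmat = counts / counts.sum(axis=1, keepdims=True)
    startprob = start / start.sum()
    return means, sds, transmat, startprob


def hmm_fit(
    traces: list[Trace],
    k: int = 3,
    *,
    init_traces: list[Trace] | None = None,
    init_segmentations: list[Segmentation] | None = None,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> StateModel:
    """Baum-Welch fit of a K-state Gaussian HMM to pooled traces.

    Parameters
    ----------
    traces : list of Trace
        Training sequences (each an independent realization).
    k : int
        Number of states.
    init_traces, init_segmentations : optional
        STaSI-segmented subset used for initialization; defaults to
        segmenting all of ``traces``.
    seed : int, optional
        Seeds the k-means initialization.
    tol : float
        Convergence when the relative log-likelihood change drops below
        this value.
    max_iter : int
        EM iteration cap.

    Returns
    -------
    StateModel
        With states re-sorted ascending by mean and the per-iteration
        log-likelihood history attached.
    """
    if k < 1:
        raise ValueError("need k >= 1 states")
    lengths = [len(tr) for tr in traces]
    if sum(lengths) < 10 * k:
        raise ValueError("pooled trace length must be >= 10 * K")
    x = np.concatenate([tr.intensity for tr in traces]).reshape(-1, 1)

    if init_traces is None or init_segmentations is None:
        from .stasi import stasi_segment

        init_traces = traces
        init_segmentations = [stasi_segment(tr) for tr in traces]
    means, sds, transmat, startprob = _initial_parameters(
        init_traces, init_segmentations, k, seed
    )

    var_floor = max(1e-12, 1e-6 * float(np.var(x)))
    model = GaussianHMM(
        n_components=k,
        covariance_type="diag",
        init_params="",
        params="stmc",
        n_iter=1,
        tol=-np.inf,  # convergence handled by the outer loop
        min_covar=0.0,
    )
    model.n_features = 1
    model.startprob_ = startprob
    model.transmat_ = transmat
    model.means_ = means.reshape(-1, 1)
    model.covars_ = np.maximum(sds**2, var_floor).reshape(-1, 1)

    floored = False
    history = [float(model.score(x, lengths))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn warns about n_iter=1
        for _ in range(max_iter):
            model.fit(x, lengths)
            cov = np.asarray(model.covars_).reshape(k, -1)[:, 0]
            if np.any(cov < var_floor):
                floored = True
                model.covars_ = np.maximum(cov, var_floor).reshape(-1, 1)
            ll = float(model.score(x, lengths))
            history.append(ll)
            if abs(ll - history[-2]) <= tol * abs(ll):
                break
    if floored:
        warnings.warn(
            "degenerate state variance hit the floor during EM", stacklevel=2
        )

    means_f = model.means_.ravel()
    sds_f = np.sqrt(np.asarray(model.covars_).reshape(k, -1)[:, 0])
    means_f, sds_f, transmat_f, startprob_f = _sorted_by_mean(
        means_f, sds_f, model.transmat_, model.startprob_
    )
    # renormalize against accumulated round-off
    transmat_f = transmat_f / transmat_f.sum(axis=1, keepdims=True)
    startprob_f = startprob_f / startprob_f.sum()
    return StateModel(
        means=means_f,
        sds=sds_f,
        transition_matrix=transmat_f,
        initial_distribution=startprob_f,
        log_likelihood=history[-1],
        log_likelihood_history=np.asarray(history),
        variance_floored=floored,
    )


def viterbi_decode(trace: Trace | np.ndarray, model: StateModel) -> np.ndarray:
    """Most probable state path for one trace under a fitted model.

    Ties are broken toward the lower state index (the argmax convention
    of the underlying implementation).
    """
    y = np.asarray(
        trace.intensity if isinstance(trace, Trace) else trace, dtype=float
    ).reshape(-1, 1)
    _, path = model.to_hmmlearn().decode(y, algorithm="viterbi")
    return path.astype(int)
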