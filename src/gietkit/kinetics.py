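"""State occupancies, dwell-time kinetics and axial observables.

Decoded Viterbi paths are reduced to the quantities reported for
conformational-state analyses: pooled state occupancies with bootstrap
s.e.m., per-state dwell times and exit rates from mono-exponential
survival fits (censored first/last dwells excluded), pairwise transition
rates, transition-density histograms, per-state heights via curve
inversion, and the relative axial localization precision implied by
intensity noise on a quenching-free substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DistanceEstimate, GietCurve, invert_ratio
from .localize import Trace
from .statemodel import StateModel

__all__ = [
    "KineticsSummary",
    "PrecisionEstimate",
    "occupancies",
    "transition_kinetics",
    "transition_density",
    "states_to_heights",
    "axial_precision",
]


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (state, start, length)."""
    path = np.asarray(path)
    if len(path) == 0:
        return []
    change = np.nonzero(np.diff(path))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(path)]))
    return [(int(path[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def occupancies(
    paths: list[np.ndarray],
    n_states: int | None = None,
    *,
    seed: int | None = None,
    n_boot: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-state occupancy fractions with bootstrap s.e.m.

    The fractions pool all frames of all paths; the s.e.m. comes from a
    seeded bootstrap over whole traces (resampling frames within a trace
    would ignore their correlation).
    """
    if len(paths) == 0:
        raise ValueError("need at least one decoded path")
    paths = [np.asarray(p, dtype=int) for p in paths]
    k = n_states if n_states is not None else max(int(p.max()) for p in paths) + 1
    counts = np.zeros(k)
    for p in paths:
        counts += np.bincount(p, minlength=k)
    frac = counts / counts.sum()

    if len(paths) == 1:
        sem = np.zeros(k)
    else:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, k))
        for b in range(n_boot):
            idx = rng.integers(0, len(paths), size=len(paths))
            c = np.zeros(k)
            for i in idx:
                c += np.bincount(paths[i], minlength=k)
            reps[b] = c / c.sum()
        sem = reps.std(axis=0, ddof=1)
    return frac, sem


@dataclass
class KineticsSummary:
    """Dwell-time and transition-rate summary of decoded paths.

    ``exit_rate_per_s[i]`` is NaN when fewer than ``min_dwells`` complete
    dwells were observed for state i (the count is still reported).
    """

    occupancy: np.ndarray
    occupancy_sem: np.ndarray
    dwell_mean_s: np.ndarray
    exit_rate_per_s: np.ndarray
    pair_rates_per_s: np.ndarray     # (K, K), diagonal NaN
    transition_counts: np.ndarray    # (K, K) integer
    n_complete_dwells: np.ndarray
    frame_interval_s: float

    @property
    def n_states(self) -> int:
        return len(self.occupancy)


def _fit_exit_rate(dwells_s: np.ndarray, method: str) -> float:
    """Exit rate 1/tau from a mono-exponential dwell-time model.

    'survival' fits ln S(t) of the empirical survival function by least
    squares; 'mle' is the exponential maximum-likelihood rate 1/mean.
    """
    if method == "mle":
        return 1.0 / float(np.mean(dwells_s))
    # empirical survival at the unique observed dwell times (frame-discrete
    # data repeats values; one point per distinct time avoids overweighting
    # the short-dwell end)
    t_u, counts = np.unique(dwells_s, return_counts=True)
    n = counts.sum()
    surv = 1.0 - np.cumsum(counts) / n
    keep = surv > 0
    if keep.sum() < 2:
        return 1.0 / float(np.mean(dwells_s))
    t_k, s_k = t_u[keep], surv[keep]
    # variance of ln S_hat is ~ (1 - S) / (n S); weight accordingly so the
    # noisy deep tail does not dominate the slope
    w = np.sqrt(n * s_k / (1.0 - s_k + 1e-12))
    slope = np.polyfit(t_k, np.log(s_k), 1, w=w)[0]
    if slope >= 0:
        return 1.0 / float(np.mean(dwells_s))
    return float(-slope)


def transition_kinetics(
    paths: list[np.ndarray],
    frame_interval_s: float,
    n_states: int | None = None,
    *,
    method: str = "survival",
    min_dwells: int = 5,
    occupancy_seed: int | None = None,
) -> KineticsSummary:
    """Dwell times, exit rates and pairwise transition rates from paths.

    Dwell times are the lengths of maximal constant runs; the first and
    last run of every trace are censored (their true length is unknown)
    and excluded from the exponential fits.  The rate from state i to j
    splits the exit rate by the observed branching fractions:
    k_ij = k_exit(i) * N(i->j) / sum_j N(i->j).
    """
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be > 0")
    if method not in ("survival", "mle"):
        raise ValueError("method must be 'survival' or 'mle'")
    paths = [np.asarray(p, dtype=int) for p in paths]
    k = n_states if n_states is not None else max(int(p.max()) for p in paths) + 1

    dwells: list[list[int]] = [[] for _ in range(k)]
    counts = np.zeros((k, k), dtype=int)
    for p in paths:
        runs = _runs(p)
        for (s_a, _, _), (s_b, _, _) in zip(runs[:-1], runs[1:]):
            counts[s_a, s_b] += 1
        for s, _, length in runs[1:-1]:  # censor first and last run
            dwells[s].append(length)

    dwell_mean = np.full(k, np.nan)
    exit_rate = np.full(k, np.nan)
    n_complete = np.zeros(k, dtype=int)
    for s in range(k):
        d = np.asarray(dwells[s], dtype=float) * frame_interval_s
        n_complete[s] = len(d)
        if len(d) > 0:
            dwell_mean[s] = float(np.mean(d))
        if len(d) >= min_dwells:
            exit_rate[s] = _fit_exit_rate(d, method)

    pair = np.full((k, k), np.nan)
    for i in range(k):
        tot = counts[i].sum()
        if tot > 0 and np.isfinite(exit_rate[i]):
            pair[i] = exit_rate[i] * counts[i] / tot
            pair[i, i] = np.nan

    occ, sem = occupancies(paths, k, seed=occupancy_seed)
    return KineticsSummary(
        occupancy=occ,
        occupancy_sem=sem,
        dwell_mean_s=dwell_mean,
        exit_rate_per_s=exit_rate,
        pair_rates_per_s=pair,
        transition_counts=counts,
        n_complete_dwells=n_complete,
        frame_interval_s=frame_interval_s,
    )


def transition_density(
    paths: list[np.ndarray],
    traces: list[Trace],
    bins: int | np.ndarray = 40,
    range_: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of (intensity before, intensity after) transitions.

    For every state change the mean measured intensity of the preceding
    and following constant segment is recorded.  Returns (hist, xedges,
    yedges, points) with ``points`` of shape (n_transitions, 2); the
    histogram is empty when no transitions occur.
    """
    if len(paths) != len(traces):
        raise ValueError("paths and traces must align")
    pts = []
    for p, tr in zip(paths, traces):
        y = np.asarray(tr.intensity, dtype=float)
        runs = _runs(np.asarray(p))
        for (_, s_a, l_a), (_, s_b, l_b) in zip(runs[:-1], runs[1:]):
            pts.append(
                (float(np.mean(y[s_a : s_a + l_a])), float(np.mean(y[s_b : s_b + l_b])))
            )
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        edges = np.linspace(0.0, 1.0, (bins if np.isscalar(bins) else 2) + 1)
        return np.zeros((len(edges) - 1, len(edges) - 1)), edges, edges, points
    hist, xe, ye = np.histogram2d(
        points[:, 0], points[:, 1], bins=bins, range=range_
    )
    return hist, xe, ye, points


def states_to_heights(
    model: StateModel,
    reference_mean_on_glass: float,
    curve: GietCurve,
) -> list[DistanceEstimate]:
    """Convert state intensity means to heights via curve inversion.

    Per state, I_G/I_0 = state mean / on-glass reference mean; the state
    s.d. propagates as an asymmetric bracket by inverting ratio -/+ s.d.
    """
    if reference_mean_on_glass <= 0:
        raise ValueError("on-glass reference mean must be > 0")
    out = []
    for mu, sd in zip(model.means, model.sds):
        ratio = mu / reference_mean_on_glass
        out.append(invert_ratio(curve, ratio, sd / reference_mean_on_glass))
    return out


@dataclass(frozen=True)
class PrecisionEstimate:
    """Relative axial precision from on-glass intensity stability.

    The intensity ratio divides two intensities with the pooled relative
    error each, so its relative error is sqrt(2) times larger.
    """

    per_trace_relative_rmsd: np.ndarray
    pooled_relative_error: float

    @property
    def ratio_relative_error(self) -> float:
        return float(np.sqrt(2.0) * self.pooled_relative_error)

    def distance_precision_nm(self, curve: GietCurve, d_nm: float) -> float:
        """Axial precision at distance d: ratio error / local curve slope."""
        r = curve(d_nm)
        eps = 1e-3
        slope = (curve(d_nm + eps) - curve(d_nm - eps)) / (2 * eps)
        return float(self.ratio_relative_error * r / slope)


def axial_precision(traces_on_glass: list[Trace]) -> PrecisionEstimate:
    """Relative intensity error of single-molecule detections.

    Per trace, RMSD of the intensity about its mean divided by the mean;
    the pooled estimate is the average across traces.  Traces on a
    quenching-free (glass) support isolate detection noise from genuine
    GIET fluctuations.
    """
    if len(traces_on_glass) == 0:
        raise ValueError("need at least one trace")
    rel = []
    for tr in traces_on_glass:
        y = np.asarray(tr.intensity, dtype=float)
        mu = float(np.mean(y))
        if mu == 0:
            raise ValueError(f"trace {tr.id} has zero mean intensity")
        rel.append(float(np.std(y)) / abs(mu))
    rel = np.asarray(rel)
    return PrecisionEstimate(
        per_trace_relative_rmsd=rel,
        pooled_relative_error=float(np.mean(rel)),
    )
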