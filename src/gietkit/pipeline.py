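"""Model/results interface for the single-molecule GIET state analysis.

:class:`SmGietModel` is built from a set of intensity traces (plus the
optional ingredients to express states as heights); ``fit()`` runs the
full two-stage analysis -- STaSI segmentation of every trace, selection
of the best-fitting third for initialization, Baum-Welch training of the
Gaussian-emission HMM, Viterbi decoding -- and returns a
:class:`SmGietResults` carrying the state model, occupancies, transition
kinetics, per-state heights and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DistanceEstimate, GietCurve
from .kinetics import (
    KineticsSummary,
    occupancies,
    states_to_heights,
    transition_density,
    transition_kinetics,
)
from .localize import Trace
from .stasi import Segmentation, select_training_traces, stasi_segment
from .statemodel import StateModel, hmm_fit, viterbi_decode

__all__ = ["SmGietModel", "SmGietResults"]


class SmGietModel:
    """Hidden-state analysis of single-molecule GIET intensity traces.

    Parameters
    ----------
    traces : list of Trace
        Immobilized-emitter intensity traces (graphene side).
    k_states : int
        Number of conformational states to fit (no automatic selection
        beyond the STaSI initialization; the published analyses use 3).
    curve : GietCurve, optional
        Distance-ratio curve of the label; enables height estimates.
    reference_mean_on_glass : float, optional
        Mean single-molecule intensity on the quenching-free substrate
        (I_0); required for height estimates.
    training_fraction : float
        Fraction of best-fitting traces used to initialize the HMM.
    """

    def __init__(
        self,
        traces: list[Trace],
        k_states: int = 3,
        *,
        curve: GietCurve | None = None,
        reference_mean_on_glass: float | None = None,
        training_fraction: float = 0.33,
    ):
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.k_states = int(k_states)
        self.curve = curve
        self.reference_mean_on_glass = reference_mean_on_glass
        self.training_fraction = float(training_fraction)
        self.frame_interval_s = float(traces[0].frame_interval_s)

    def fit(self, *, seed: int | None = None) -> "SmGietResults":
        segmentations = [stasi_segment(tr) for tr in self.traces]
        train_idx = select_training_traces(
            self.traces, segmentations, self.training_fraction
        )
        model = hmm_fit(
            self.traces,
            self.k_states,
            init_traces=[self.traces[i] for i in train_idx],
            init_segmentations=[segmentations[i] for i in train_idx],
            seed=seed,
        )
        paths = [viterbi_decode(tr, model) for tr in self.traces]
        kin = transition_kinetics(
            paths,
            self.frame_interval_s,
            self.k_states,
            occupancy_seed=seed,
        )
        heights = None
        if self.curve is not None and self.reference_mean_on_glass is not None:
            heights = states_to_heights(
                model, self.reference_mean_on_glass, self.curve
            )
        return SmGietResults(
            model=self,
            segmentations=segmentations,
            training_indices=train_idx,
            state_model=model,
            paths=paths,
            kinetics=kin,
            heights=heights,
        )


@dataclass
class SmGietResults:
    """Fitted state model, decoded paths and derived observables."""

    model: SmGietModel
    segmentations: list[Segmentation]
    training_indices: list[int]
    state_model: StateModel
    paths: list[np.ndarray]
    kinetics: KineticsSummary
    heights: list[DistanceEstimate] | None = None

    @property
    def occupancy(self) -> np.ndarray:
        return self.kinetics.occupancy

    def transition_density(self, bins: int = 40):
        return transition_density(self.paths, self.model.traces, bins)

    def plot_transition_density(self, ax=None, bins: int = 40):
        """Heat map of segment-mean intensities before vs after transitions."""
        import matplotlib.pyplot as plt

        hist, xe, ye, _ = self.transition_density(bins)
        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(xe, ye, hist.T, cmap="viridis")
        ax.set_xlabel("intensity before transition (a.u.)")
        ax.set_ylabel("intensity after transition (a.u.)")
        return ax

    def to_report(self) -> dict:
        """JSON-serializable summary of the fitted state analysis."""
        sm = self.state_model
        kin = self.kinetics
        out = {
            "k_states": sm.n_states,
            "state_means": sm.means.tolist(),
            "state_sds": sm.sds.tolist(),
            "transition_matrix": sm.transition_matrix.tolist(),
            "initial_distribution": sm.initial_distribution.tolist(),
            "log_likelihood": sm.log_likelihood,
            "occupancy": kin.occupancy.tolist(),
            "occupancy_sem": kin.occupancy_sem.tolist(),
            "dwell_mean_s": kin.dwell_mean_s.tolist(),
            "exit_rate_per_s": kin.exit_rate_per_s.tolist(),
            "pair_rates_per_s": kin.pair_rates_per_s.tolist(),
            "transition_counts": kin.transition_counts.tolist(),
            "n_traces": len(self.paths),
            "n_frames_total": int(sum(len(p) for p in self.paths)),
        }
        if self.heights is not None:
            out["heights"] = [
                {
                    "d_nm": h.d_nm,
                    "h_nm": h.h_nm,
                    "h_low_nm": h.h_low_nm,
                    "h_high_nm": h.h_high_nm,
                }
                for h in self.heights
            ]
        return out

    def summary(self) -> str:
        sm = self.state_model
        kin = self.kinetics
        names = (
            ["L", "M", "H"][: sm.n_states]
            if sm.n_states <= 3
            else [f"S{i}" for i in range(sm.n_states)]
        )
        lines = [
            "Single-molecule GIET state analysis",
            "===================================",
            f"traces: {len(self.paths)}   frames: {sum(len(p) for p in self.paths)}   "
            f"states: {sm.n_states}   logL: {sm.log_likelihood:.1f}",
            "",
            "state   mean(a.u.)   sd(a.u.)   occupancy        dwell(s)   exit rate(1/s)",
        ]
        for i, nm in enumerate(names):
            occ = f"{100 * kin.occupancy[i]:5.1f} +- {100 * kin.occupancy_sem[i]:.1f}%"
            dwell = f"{kin.dwell_mean_s[i]:8.3f}" if np.isfinite(kin.dwell_mean_s[i]) else "     n/a"
            rate = f"{kin.exit_rate_per_s[i]:8.3f}" if np.isfinite(kin.exit_rate_per_s[i]) else "     n/a"
            lines.append(
                f"{nm:>5}   {sm.means[i]:10.1f}   {sm.sds[i]:8.1f}   {occ}   {dwell}   {rate}"
            )
        if self.heights is not None:
            lines.append("")
            lines.append("state   h (nm)   bracket (nm)")
            for nm, h in zip(names, self.heights):
                lines.append(
                    f"{nm:>5}   {h.h_nm:6.1f}   ({h.h_low_nm:.1f}-{h.h_high_nm:.1f})"
                )
        return "\n".join(lines)
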