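"""Single-emitter localization and intensity-trace assembly.

Spots in TIRF movies are detected as local maxima of a PSF-matched
smoothed frame and refined by iterative Gaussian-mask centroiding; their
background-subtracted, mask-weighted intensities feed the downstream
state analysis.  Localizations are linked into single-molecule traces by
proximity to a running anchor position, with crowding rejected by a
mutual-exclusion radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter

__all__ = [
    "Localization",
    "Trace",
    "localize_spots",
    "build_traces",
    "read_localization_table",
    "write_localization_table",
    "read_trace_table",
    "write_trace_table",
    "DEFAULT_PIXEL_SIZE_NM",
    "DEFAULT_FRAME_INTERVAL_S",
]

DEFAULT_PIXEL_SIZE_NM = 107.0
DEFAULT_FRAME_INTERVAL_S = 0.032


@dataclass(frozen=True)
class Localization:
    """One detected emitter in one frame.

    Positions are continuous, in nm, on a 0-based pixel grid with the
    origin at the centre of the top-left pixel.  ``intensity`` is the
    background-corrected spot intensity (a.u.).
    """

    x_nm: float
    y_nm: float
    frame: int
    intensity: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")
        if not np.isfinite(self.intensity):
            raise ValueError("intensity must be finite")


@dataclass
class Trace:
    """Time-ordered intensity record of one immobilized emitter."""

    id: int
    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    intensity: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frames)
        if not (len(self.x_nm) == len(self.y_nm) == len(self.intensity) == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("trace frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def anchor(self) -> tuple[float, float]:
        return float(np.mean(self.x_nm)), float(np.mean(self.y_nm))

    @property
    def duration_s(self) -> float:
        return len(self) * self.frame_interval_s


def _gaussian_mask_refine(
    frame: np.ndarray,
    x0: float,
    y0: float,
    sigma_px: float,
    *,
    tol_px: float = 0.01,
    max_iter: int = 50,
) -> tuple[float, float, float] | None:
    """Iterative Gaussian-mask centroid (x, y, flux) in pixel units.

    The centroid is re-estimated with a Gaussian weight centred on the
    current position until the shift falls below ``tol_px``.  The flux is
    the least-squares amplitude of a unit Gaussian times its area, i.e.
    the background-subtracted photon sum of the fitted spot.  Returns
    None when the fit wanders out of the frame.
    """
    h, w = frame.shape
    half = max(3, int(np.ceil(3 * sigma_px)))
    x, y = float(x0), float(y0)
    for _ in range(max_iter):
        cx, cy = int(round(x)), int(round(y))
        if not (half <= cx < w - half and half <= cy < h - half):
            return None
        roi = frame[cy - half : cy + half + 1, cx - half : cx + half + 1].astype(float)
        yy, xx = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1]
        # local background from the ROI border
        border = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
        bg = float(np.median(border))
        sub = roi - bg
        g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2))
        norm = float(np.sum(sub * g))
        if norm <= 0:
            return None
        x_new = float(np.sum(sub * g * xx) / norm)
        y_new = float(np.sum(sub * g * yy) / norm)
        shift = np.hypot(x_new - x, y_new - y)
        x, y = x_new, y_new
        if shift < tol_px:
            break
    amp = float(np.sum(sub * g) / np.sum(g * g))
    flux = amp * 2 * np.pi * sigma_px**2
    return x, y, flux


def localize_spots(
    image_stack: np.ndarray,
    psf_sigma_px: float,
    detection_threshold: float = 5.0,
    *,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> list[Localization]:
    """Detect and localize point emitters in every frame of a stack.

    Parameters
    ----------
    image_stack : array, shape (n_frames, h, w) or (h, w)
        Raw camera frames.
    psf_sigma_px : float
        Gaussian PSF standard deviation in pixels.
    detection_threshold : float
        Candidate maxima must rise this many noise standard deviations
        above background in the PSF-smoothed frame.
    pixel_size_nm : float
        Physical pixel size used to convert positions to nm.

    Returns
    -------
    list of Localization
    """
    stack = np.asarray(image_stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("image stack must be 2-D or 3-D (frames, h, w)")
    if stack.size == 0:
        raise ValueError("empty image stack")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")

    sat = None
    if np.issubdtype(stack.dtype, np.integer):
        sat = np.iinfo(stack.dtype).max

    out: list[Localization] = []
    footprint = max(3, 2 * int(np.ceil(psf_sigma_px)) + 1)
    for t, frame in enumerate(stack):
        if sat is not None and np.any(frame == sat):
            warnings.warn(f"frame {t} contains saturated pixels", stacklevel=2)
        f = frame.astype(float)
        smooth = gaussian_filter(f, psf_sigma_px)
        bg = np.median(smooth)
        # robust noise scale of the smoothed frame
        noise = np.median(np.abs(smooth - bg)) / 0.6745
        if noise <= 0:
            noise = np.finfo(float).tiny
        peaks = (smooth == maximum_filter(smooth, size=footprint)) & (
            smooth - bg > detection_threshold * noise
        )
        ys, xs = np.nonzero(peaks)
        # brightest-first, suppress duplicates closer than 2 sigma
        order = np.argsort(-smooth[ys, xs], kind="stable")
        kept: list[tuple[float, float]] = []
        for i in order:
            x0, y0 = float(xs[i]), float(ys[i])
            if any(np.hypot(x0 - kx, y0 - ky) < 2 * psf_sigma_px for kx, ky in kept):
                continue
            refined = _gaussian_mask_refine(f, x0, y0, psf_sigma_px)
            if refined is None:
                continue
            x, y, flux = refined
            kept.append((x, y))
            out.append(
                Localization(
                    x_nm=x * pixel_size_nm,
                    y_nm=y * pixel_size_nm,
                    frame=t,
                    intensity=flux,
                )
            )
    return out


def build_traces(
    locs: list[Localization],
    search_radius_nm: float = 150.0,
    min_frames: int = 100,
    exclusion_nm: float = 500.0,
    *,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> list[Trace]:
    """Link localizations into traces of immobilized emitters.

    Frame by frame, each localization is assigned to the nearest existing
    trace whose running-mean anchor lies within ``search_radius_nm``
    (globally greedy by distance, so the result does not depend on the
    input order within a frame); unmatched localizations seed new traces.
    Traces shorter than ``min_frames`` are discarded, and any pair of
    surviving traces with anchors closer than ``exclusion_nm`` is removed
    entirely to avoid intensity crosstalk.
    """
    by_frame: dict[int, list[Localization]] = {}
    for loc in locs:
        by_frame.setdefault(loc.frame, []).append(loc)

    # running traces: lists of locs plus anchor sums
    anchors_x: list[float] = []
    anchors_y: list[float] = []
    counts: list[int] = []
    members: list[list[Localization]] = []

    for frame in sorted(by_frame):
        frame_locs = sorted(by_frame[frame], key=lambda l: (l.x_nm, l.y_nm))
        pairs = []
        for j, loc in enumerate(frame_locs):
            for ti in range(len(members)):
                ax = anchors_x[ti] / counts[ti]
                ay = anchors_y[ti] / counts[ti]
                dist = np.hypot(loc.x_nm - ax, loc.y_nm - ay)
                if dist <= search_radius_nm:
                    pairs.append((dist, ti, j))
        pairs.sort()
        used_traces: set[int] = set()
        used_locs: set[int] = set()
        for dist, ti, j in pairs:
            if ti in used_traces or j in used_locs:
                continue
            used_traces.add(ti)
            used_locs.add(j)
            loc = frame_locs[j]
            members[ti].append(loc)
            anchors_x[ti] += loc.x_nm
            anchors_y[ti] += loc.y_nm
            counts[ti] += 1
        for j, loc in enumerate(frame_locs):
            if j not in used_locs:
                members.append([loc])
                anchors_x.append(loc.x_nm)
                anchors_y.append(loc.y_nm)
                counts.append(1)

    survivors = [m for m in members if len(m) >= min_frames]
    anchors = [
        (np.mean([l.x_nm for l in m]), np.mean([l.y_nm for l in m]))
        for m in survivors
    ]
    crowded: set[int] = set()
    for i in range(len(survivors)):
        for j in range(i + 1, len(survivors)):
            d = np.hypot(
                anchors[i][0] - anchors[j][0], anchors[i][1] - anchors[j][1]
            )
            if d < exclusion_nm:
                crowded.update((i, j))

    traces = []
    tid = 0
    for i, m in enumerate(survivors):
        if i in crowded:
            continue
        traces.append(
            Trace(
                id=tid,
                frames=np.array([l.frame for l in m]),
                x_nm=np.array([l.x_nm for l in m]),
                y_nm=np.array([l.y_nm for l in m]),
                intensity=np.array([l.intensity for l in m]),
                frame_interval_s=frame_interval_s,
            )
        )
        tid += 1
    return traces


# ---------------------------------------------------------------------------
# delimited-text schemas

def write_localization_table(locs: list[Localization], path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_nm": [l.x_nm for l in locs],
            "y_nm": [l.y_nm for l in locs],
            "frame": [l.frame for l in locs],
            "intensity": [l.intensity for l in locs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_localization_table(path: str | Path) -> list[Localization]:
    df = pd.read_csv(path, sep="\t")
    required = {"x_nm", "y_nm", "frame", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"localization table must have columns {sorted(required)}")
    return [
        Localization(float(r.x_nm), float(r.y_nm), int(r.frame), float(r.intensity))
        for r in df.itertuples()
    ]


def write_trace_table(traces: list[Trace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i in range(len(tr)):
            rows.append(
                {
                    "trace_id": tr.id,
                    "x_nm": tr.x_nm[i],
                    "y_nm": tr.y_nm[i],
                    "frame": tr.frames[i],
                    "intensity": tr.intensity[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trace_table(
    path: str | Path, *, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
) -> list[Trace]:
    df = pd.read_csv(path, sep="\t")
    required = {"trace_id", "x_nm", "y_nm", "frame", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    traces = []
    for tid, grp in df.groupby("trace_id"):
        grp = grp.sort_values("frame")
        traces.append(
            Trace(
                id=int(tid),
                frames=grp["frame"].to_numpy(),
                x_nm=grp["x_nm"].to_numpy(),
                y_nm=grp["y_nm"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                frame_interval_s=frame_interval_s,
            )
        )
    return traces
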