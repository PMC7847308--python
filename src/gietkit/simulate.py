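"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end: 3-state Markov intensity
traces with GIET-modulated Gaussian emissions (continuous-time chain
sampled at the camera frame interval), TIRF-like image stacks of
immobilized Gaussian spots with Poisson photon noise, and nanoruler
ratio datasets at a known tilt angle.  Every generator takes an explicit
seed (or Generator) and returns the ground truth needed to score the
downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .curves import GietCurve
from .localize import (
    DEFAULT_FRAME_INTERVAL_S,
    DEFAULT_PIXEL_SIZE_NM,
    Trace,
)
from .photometry import RulerMeasurement

__all__ = [
    "TraceSimSpec",
    "ImageSimSpec",
    "simulate_traces",
    "simulate_image_stack",
    "simulate_ruler_dataset",
]


@dataclass
class TraceSimSpec:
    """Design of a synthetic single-molecule GIET trace ensemble.

    ``heights_nm`` are per-state heights above the membrane; the state
    intensity means follow as on_glass_mean * curve(h + lipid thickness).
    ``rate_matrix_per_s`` is a continuous-time generator (rows sum to 0);
    the per-frame transition matrix is its exponential at the frame
    interval.  ``noise_cv`` is the constant coefficient of variation of
    the Gaussian emission noise (default mirrors the 7.5% relative
    intensity error of single-molecule detections on glass).
    """

    heights_nm: tuple[float, ...]
    curve: GietCurve
    rate_matrix_per_s: np.ndarray
    on_glass_mean: float = 1000.0
    noise_cv: float = 0.075
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    n_traces: int = 100
    n_frames: int = 500
    bleach_rate_per_s: float = 0.0
    background_sd: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.rate_matrix_per_s, dtype=float)
        k = len(self.heights_nm)
        if q.shape != (k, k):
            raise ValueError("rate matrix must be K x K for K heights")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0) or not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError(
                "rate matrix must have non-negative off-diagonals and zero row sums"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        self.rate_matrix_per_s = q

    @property
    def n_states(self) -> int:
        return len(self.heights_nm)

    def state_means(self) -> np.ndarray:
        """Design intensity means: on-glass mean quenched by the curve."""
        l_ml = self.curve.lipid_thickness_nm
        return np.array(
            [self.on_glass_mean * self.curve(h + l_ml) for h in self.heights_nm]
        )


def _stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_traces(
    spec: TraceSimSpec, seed: int | np.random.Generator | None = None
) -> tuple[list[Trace], list[np.ndarray]]:
    """Sample the trace ensemble; returns (traces, ground-truth paths).

    The Markov chain starts from its stationary distribution.  With a
    nonzero bleach rate each molecule photobleaches in a single step at
    an exponential time, after which the intensity drops to background
    (mean 0, s.d. ``background_sd``); the ground-truth path marks
    bleached frames as -1.
    """
    rng = np.random.default_rng(seed)
    k = spec.n_states
    means = spec.state_means()
    p = expm(spec.rate_matrix_per_s * spec.frame_interval_s)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    pi = _stationary_distribution(p)

    traces: list[Trace] = []
    paths: list[np.ndarray] = []
    n = spec.n_frames
    for tid in range(spec.n_traces):
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(k, p=pi)
        for t in range(1, n):
            states[t] = rng.choice(k, p=p[states[t - 1]])
        mu = means[states]
        y = mu * (1.0 + spec.noise_cv * rng.standard_normal(n))
        if spec.bleach_rate_per_s > 0:
            t_bleach = rng.exponential(1.0 / spec.bleach_rate_per_s)
            f_bleach = int(t_bleach / spec.frame_interval_s)
            if f_bleach < n:
                y[f_bleach:] = spec.background_sd * rng.standard_normal(n - f_bleach)
                states = states.copy()
                states[f_bleach:] = -1
        x0, y0 = rng.uniform(0, 50_000, size=2)
        traces.append(
            Trace(
                id=tid,
                frames=np.arange(n),
                x_nm=np.full(n, x0),
                y_nm=np.full(n, y0),
                intensity=y,
                frame_interval_s=spec.frame_interval_s,
            )
        )
        paths.append(states)
    return traces, paths


@dataclass
class ImageSimSpec:
    """Design of a synthetic TIRF image stack of immobilized spots.

    Spot density defaults to the sparse single-molecule regime
    (~0.5 molecules per square micron); ``min_separation_nm`` enforces a
    center-to-center distance so crowding is configurable.
    """

    frame_size_px: int = 64
    n_frames: int = 1
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    psf_sigma_px: float = 1.3
    spot_density_per_um2: float = 0.5
    photon_budget: float = 2000.0
    background: float = 100.0
    read_noise_sd: float = 2.0
    min_separation_nm: float = 0.0
    n_spots: int | None = None  # overrides density when set

    def __post_init__(self) -> None:
        if self.frame_size_px < 8:
            raise ValueError("frame must be at least 8 px")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")


def _draw_positions(spec: ImageSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform spot positions (px) honouring the minimum separation."""
    area_um2 = (spec.frame_size_px * spec.pixel_size_nm / 1000.0) ** 2
    if spec.n_spots is not None:
        n = spec.n_spots
    else:
        n = int(rng.poisson(spec.spot_density_per_um2 * area_um2))
    if n == 0:
        return np.empty((0, 2))
    margin = 4 * spec.psf_sigma_px
    lo, hi = margin, spec.frame_size_px - margin
    if hi <= lo:
        raise ValueError("frame too small for the PSF margin")
    min_sep_px = spec.min_separation_nm / spec.pixel_size_nm
    pos: list[np.ndarray] = []
    for _ in range(200 * n):
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - q)) >= min_sep_px for q in pos):
            pos.append(cand)
        if len(pos) == n:
            break
    else:
        raise ValueError(
            f"could not place {n} spots at {spec.min_separation_nm} nm "
            "separation; density/min-separation infeasible"
        )
    return np.asarray(pos)


def simulate_image_stack(
    spec: ImageSimSpec,
    seed: int | np.random.Generator | None = None,
    intensities: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 16-bit image stack of Gaussian spots with Poisson noise.

    ``intensities``, if given, has shape (n_spots, n_frames) and sets
    the per-frame photon budget of each spot (e.g. from simulated GIET
    traces); otherwise every spot emits ``photon_budget`` photons per
    frame.  Returns the stack and a ground-truth table with columns
    (spot, frame, x_px, y_px, x_nm, y_nm, photons).
    """
    rng = np.random.default_rng(seed)
    pos = _draw_positions(spec, rng)
    n_spots = len(pos)
    if intensities is None:
        intensities = np.full((n_spots, spec.n_frames), spec.photon_budget)
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape != (n_spots, spec.n_frames):
        raise ValueError("intensities must have shape (n_spots, n_frames)")

    size = spec.frame_size_px
    yy, xx = np.mgrid[0:size, 0:size]
    stack = np.empty((spec.n_frames, size, size), dtype=np.uint16)
    rows = []
    for t in range(spec.n_frames):
        photons = np.full((size, size), float(spec.background))
        for s in range(n_spots):
            x, y = pos[s]
            g = np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * spec.psf_sigma_px**2)
            )
            photons += intensities[s, t] * g / (2 * np.pi * spec.psf_sigma_px**2)
            rows.append(
                {
                    "spot": s,
                    "frame": t,
                    "x_px": x,
                    "y_px": y,
                    "x_nm": x * spec.pixel_size_nm,
                    "y_nm": y * spec.pixel_size_nm,
                    "photons": intensities[s, t],
                }
            )
        img = rng.poisson(photons).astype(float)
        if spec.read_noise_sd > 0:
            img += spec.read_noise_sd * rng.standard_normal(photons.shape)
        stack[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        rows, columns=["spot", "frame", "x_px", "y_px", "x_nm", "y_nm", "photons"]
    )
    return stack, truth


def simulate_ruler_dataset(
    alpha_deg: float,
    l_dna_list,
    curve: GietCurve,
    noise_cv: float = 0.03,
    seed: int | np.random.Generator | None = None,
    *,
    l_ml_nm: float = 2.5,
    mode: str = "intensity",
) -> list[RulerMeasurement]:
    """Nanoruler ratios at a known tilt with multiplicative Gaussian noise.

    ratio_i = curve(l_i sin(alpha) + l_ML) * (1 + noise_cv * N(0,1)),
    clipped to (0, 1).  The reported ratio_sd is noise_cv * ratio.
    """
    import math

    if not 0 < alpha_deg <= 90:
        raise ValueError("tilt angle must lie in (0, 90] degrees")
    rng = np.random.default_rng(seed)
    out = []
    for l in l_dna_list:
        d = l * math.sin(math.radians(alpha_deg)) + l_ml_nm
        r = curve(d)
        noisy = r * (1.0 + noise_cv * rng.standard_normal())
        noisy = float(np.clip(noisy, 1e-6, 1 - 1e-6))
        out.append(
            RulerMeasurement(
                l_dna_nm=float(l),
                label_end="lipid_dye" if l == 0 else "3prime",
                ratio=noisy,
                ratio_sd=noise_cv * r,
                mode=mode,
            )
        )
    return out
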