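"""Distance-dependent lifetime/intensity ratio curves and their inversion.

The relative fluorescence lifetime of a fluorophore with quantum yield
``phi`` at distance ``d`` from the graphene sheet is

    tau_G / tau_0 = S0 / [(1 - phi) S0 + phi S(d)]
                  = 1 / (1 - phi + phi * S(d)/S0),

with ``S(d)/S0`` the orientation-averaged normalized dissipated power
from :mod:`gietkit.emission`.  In the absence of static quenching the
intensity ratio I_G/I_0 follows the same relation, so one curve serves
both readouts.

Distance convention
-------------------
``d`` is the ruler distance from the graphene sheet as used by the
published nanoruler calibration: the dipole is placed at height ``d``
above the top surface of the lipid monolayer, and heights above the
membrane follow as ``h = d - 2.5 nm``.  This axis convention reproduces
the calibrated distance-ratio relation; see docs/methods.md for the
discussion of the alternative strictly geometric reading.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .emission import relative_emission_power
from .stacks import Fluorophore, OpticalStack, default_stack, FLUOROPHORES

__all__ = [
    "lifetime_ratio",
    "giet_efficiency",
    "GietCurve",
    "build_curve",
    "DistanceEstimate",
    "invert_ratio",
]


def lifetime_ratio(
    fluor: Fluorophore,
    stack: OpticalStack,
    d_nm: float,
    *,
    orientation: str = "isotropic_average",
) -> float:
    """tau_G/tau_0 (= I_G/I_0) at ruler distance ``d_nm`` from graphene."""
    phi = fluor.quantum_yield
    if not 0 < phi <= 1:
        raise ValueError("quantum yield must lie in (0, 1]")
    s_rel = relative_emission_power(stack, d_nm, orientation)
    return 1.0 / (1.0 - phi + phi * s_rel)


def giet_efficiency(
    fluor: Fluorophore,
    stack: OpticalStack,
    d_nm: float,
    *,
    orientation: str = "isotropic_average",
) -> float:
    """Energy-transfer efficiency 1 - tau_G/tau_0 at distance ``d_nm``."""
    return 1.0 - lifetime_ratio(fluor, stack, d_nm, orientation=orientation)


@dataclass(frozen=True)
class DistanceEstimate:
    """A ratio inverted to a distance with an asymmetric uncertainty band.

    ``d_nm`` counts from the graphene sheet, ``h_nm = d - lipid thickness``
    from the membrane surface.  ``d_low``/``d_high`` come from inverting
    ratio -/+ one standard deviation (smaller ratio means closer).
    """

    d_nm: float
    h_nm: float
    d_low_nm: float
    d_high_nm: float

    @property
    def h_low_nm(self) -> float:
        return self.h_nm - (self.d_nm - self.d_low_nm)

    @property
    def h_high_nm(self) -> float:
        return self.h_nm + (self.d_high_nm - self.d_nm)


class GietCurve:
    """Tabulated, strictly monotone map distance -> lifetime/intensity ratio.

    Built from first principles by :func:`build_curve` or loaded from a
    two-column table.  Interpolation is shape-preserving (monotone
    piecewise cubic), so the curve inherits strict monotonicity from its
    samples and is invertible on its valid range.
    """

    def __init__(
        self,
        d_nm: np.ndarray,
        ratio: np.ndarray,
        *,
        fluorophore: Fluorophore | None = None,
        stack: OpticalStack | None = None,
        lipid_thickness_nm: float = 2.5,
    ):
        d = np.asarray(d_nm, dtype=float)
        r = np.asarray(ratio, dtype=float)
        if d.ndim != 1 or d.size < 4 or d.shape != r.shape:
            raise ValueError("curve needs matching 1-D arrays with >= 4 samples")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if np.any(np.diff(r) <= 0):
            raise ValueError(
                "ratio samples are not strictly increasing with distance; "
                "this indicates a quadrature failure upstream"
            )
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("ratios must lie in (0, 1]")
        self.d_nm = d
        self.ratio = r
        self.fluorophore = fluorophore
        self.stack = stack
        self.lipid_thickness_nm = float(lipid_thickness_nm)
        self._interp = PchipInterpolator(d, r, extrapolate=False)

    # -- evaluation ----------------------------------------------------
    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.d_nm[0]), float(self.d_nm[-1])

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.ratio[0]), float(self.ratio[-1])

    def __call__(self, d_nm):
        lo, hi = self.valid_range
        d = np.asarray(d_nm, dtype=float)
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError(
                f"distance outside the curve's valid range [{lo}, {hi}] nm"
            )
        out = self._interp(d)
        return float(out) if np.ndim(d_nm) == 0 else out

    def invert(self, ratio: float, tol_nm: float = 1e-3) -> float:
        """Distance whose curve value equals ``ratio`` (root bracketing on
        the monotone interpolant, tolerance ``tol_nm``)."""
        rlo, rhi = self.ratio_range
        if not rlo <= ratio <= rhi:
            raise ValueError(
                f"ratio {ratio:.4g} outside the attainable interval "
                f"[{rlo:.4g}, {rhi:.4g}] for this curve"
            )
        lo, hi = self.valid_range
        if ratio == rlo:
            return lo
        if ratio == rhi:
            return hi
        return float(brentq(lambda d: self._interp(d) - ratio, lo, hi, xtol=tol_nm))

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d_nm": self.d_nm, "ratio": self.ratio})

    def to_tsv(self, path: str | Path | io.IOBase) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path | io.IOBase, *, lipid_thickness_nm: float = 2.5
    ) -> "GietCurve":
        df = pd.read_csv(path, sep="\t")
        if not {"d_nm", "ratio"}.issubset(df.columns):
            raise ValueError("curve table must have columns 'd_nm' and 'ratio'")
        return cls(
            df["d_nm"].to_numpy(),
            df["ratio"].to_numpy(),
            lipid_thickness_nm=lipid_thickness_nm,
        )


def build_curve(
    fluor: Fluorophore | str,
    stack: OpticalStack | None = None,
    d_min: float = 2.5,
    d_max: float = 30.0,
    step: float = 0.05,
) -> GietCurve:
    """Tabulate the lifetime-ratio curve of ``fluor`` on ``stack``.

    The grid step must be <= 0.1 nm so that the shape-preserving
    interpolation error stays below 0.5% of the ratio.  Monotonicity of
    the samples is verified at construction time.
    """
    if isinstance(fluor, str):
        fluor = FLUOROPHORES[fluor]
    if stack is None:
        stack = default_stack(fluor)
    if not (0 < d_min < d_max):
        raise ValueError("need 0 < d_min < d_max")
    if step > 0.1:
        raise ValueError("grid step must be <= 0.1 nm")
    n = int(round((d_max - d_min) / step)) + 1
    grid = d_min + step * np.arange(n)
    grid[-1] = min(grid[-1], d_max)
    ratios = np.array([lifetime_ratio(fluor, stack, d) for d in grid])
    return GietCurve(
        grid,
        ratios,
        fluorophore=fluor,
        stack=stack,
        lipid_thickness_nm=stack.lipid_thickness_nm,
    )


def invert_ratio(
    curve: GietCurve, ratio: float, ratio_sd: float = 0.0
) -> DistanceEstimate:
    """Invert a measured ratio (+- s.d.) to a distance estimate.

    The uncertainty band comes from inverting ``ratio -/+ ratio_sd``
    with the endpoints clipped to the curve's valid range (asymmetric
    interval, matching the bracket convention used for reported heights).
    """
    if ratio_sd < 0:
        raise ValueError("ratio_sd must be >= 0")
    d = curve.invert(ratio)
    rlo, rhi = curve.ratio_range
    d_low = curve.invert(max(ratio - ratio_sd, rlo)) if ratio_sd else d
    d_high = curve.invert(min(ratio + ratio_sd, rhi)) if ratio_sd else d
    return DistanceEstimate(
        d_nm=d,
        h_nm=d - curve.lipid_thickness_nm,
        d_low_nm=d_low,
        d_high_nm=d_high,
    )
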