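"""Ratiometric and FRAP normalizations and the DNA-nanoruler geometry.

Membrane-anchored DNA duplexes of known contour length place a dye at a
defined height above the lipid monolayer; with a tilt angle ``alpha``
between duplex and surface the dye sits at

    d = l_DNA * sin(alpha) + l_ML,

where ``l_ML`` is the monolayer thickness (2.5 nm by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MassNormalizedRatio",
    "FrapRecord",
    "RulerMeasurement",
    "TiltModel",
    "normalize_intensity",
    "frap_normalize",
    "ruler_distance",
    "label_separation",
    "read_ruler_table",
    "write_ruler_table",
    "RULER_CONTOUR_LENGTHS_NM",
]

#: Contour lengths (nm) of the calibrated FAM label positions.
RULER_CONTOUR_LENGTHS_NM = (1.7, 5.1, 6.8, 8.5, 10.2, 11.9, 17.0)


@dataclass(frozen=True)
class MassNormalizedRatio:
    """Raw intensities on graphene/reference plus label-free mass signals."""

    m0: float   # mass on reference substrate, ng/mm^2
    mG: float   # mass on graphene, ng/mm^2
    I0_raw: float
    IG_raw: float

    def __post_init__(self) -> None:
        for f in ("m0", "mG", "I0_raw", "IG_raw"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be > 0")


def normalize_intensity(rec: MassNormalizedRatio) -> float:
    """Mass-normalized intensity ratio I_G/I_0 = (m0/mG) * (IG_raw/I0_raw)."""
    return (rec.m0 / rec.mG) * (rec.IG_raw / rec.I0_raw)


@dataclass(frozen=True)
class FrapRecord:
    """One FRAP time point: bleached-ROI, reference-ROI and background."""

    I_ROI_inside: float
    I_ROI_outside: float
    I_BG: float
    time_s: float = 0.0


def frap_normalize(rec: FrapRecord) -> float:
    """Background-corrected, reference-normalized FRAP signal.

    (I_inside - I_BG) / (I_outside - I_BG); a time series of these values
    is the recovery curve.
    """
    denom = rec.I_ROI_outside - rec.I_BG
    if denom <= 0:
        raise ValueError(
            "degenerate FRAP record: reference intensity must exceed background"
        )
    return (rec.I_ROI_inside - rec.I_BG) / denom


@dataclass(frozen=True)
class RulerMeasurement:
    """One nanoruler ratio measurement.

    ``l_dna_nm`` is the contour length from the membrane anchor to the
    label (0 for a lipid-conjugated dye); ``mode`` records whether the
    ratio is an intensity or a lifetime ratio.
    """

    l_dna_nm: float
    label_end: str          # {'3prime', '5prime', 'lipid_dye'}
    ratio: float
    ratio_sd: float = 0.0
    mode: str = "intensity"  # {'intensity', 'lifetime'}

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must lie in (0, 1)")
        if self.l_dna_nm < 0:
            raise ValueError("contour length must be >= 0")
        if self.ratio_sd < 0:
            raise ValueError("ratio_sd must be >= 0")
        if self.mode not in ("intensity", "lifetime"):
            raise ValueError("mode must be 'intensity' or 'lifetime'")


@dataclass(frozen=True)
class TiltModel:
    """Global tilt of the DNA rulers relative to the membrane plane."""

    alpha_deg: float
    l_ml_nm: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha_deg <= 90:
            raise ValueError("tilt angle must lie in (0, 90] degrees")


def ruler_distance(l_dna_nm: float, model: TiltModel) -> float:
    """Dye distance from graphene: d = l_DNA sin(alpha) + l_ML."""
    if l_dna_nm < 0:
        raise ValueError("contour length must be >= 0")
    return l_dna_nm * math.sin(math.radians(model.alpha_deg)) + model.l_ml_nm


def label_separation(l_dna_a: float, l_dna_b: float, model: TiltModel) -> float:
    """Vertical separation of two label positions under a common tilt."""
    return abs(l_dna_a - l_dna_b) * math.sin(math.radians(model.alpha_deg))


_RULER_COLUMNS = ["l_dna_nm", "label_end", "ratio", "ratio_sd", "mode"]


def read_ruler_table(path: str | Path) -> list[RulerMeasurement]:
    """Read a tab-delimited ruler table (l_dna_nm, label_end, ratio, ratio_sd, mode)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_RULER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ruler table missing columns: {sorted(missing)}")
    return [
        RulerMeasurement(
            l_dna_nm=float(r.l_dna_nm),
            label_end=str(r.label_end),
            ratio=float(r.ratio),
            ratio_sd=float(r.ratio_sd),
            mode=str(r.mode),
        )
        for r in df.itertuples()
    ]


def write_ruler_table(measurements, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "l_dna_nm": m.l_dna_nm,
                "label_end": m.label_end,
                "ratio": m.ratio,
                "ratio_sd": m.ratio_sd,
                "mode": m.mode,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)
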