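"""Optical stack and fluorophore definitions for GIET modelling.

The reference geometry is a glass coverslip carrying a single graphene
sheet, coated by a lipid monolayer and topped by aqueous buffer.  A
fluorophore tethered above the monolayer is modelled as an ideal electric
dipole emitting at its emission maximum; the stack below it is described
by complex refractive indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "OpticalLayer",
    "OpticalStack",
    "Fluorophore",
    "FLUOROPHORES",
    "GRAPHENE_INDEX",
    "make_stack",
    "default_stack",
]


@dataclass(frozen=True)
class OpticalLayer:
    """One layer of a planar stratified medium.

    ``thickness_nm`` is ``None`` for the two bounding half-spaces
    (substrate below, superstrate above).
    """

    name: str
    refractive_index: complex
    thickness_nm: float | None = None

    def __post_init__(self) -> None:
        n = complex(self.refractive_index)
        if n.real <= 0 or n.imag < 0:
            raise ValueError(
                f"layer {self.name!r}: refractive index must have Re > 0 and "
                f"Im >= 0, got {n}"
            )
        if self.thickness_nm is not None and not self.thickness_nm > 0:
            raise ValueError(
                f"layer {self.name!r}: finite layer thickness must be > 0"
            )

    @property
    def is_halfspace(self) -> bool:
        return self.thickness_nm is None


@dataclass(frozen=True)
class OpticalStack:
    """Ordered planar stack from substrate (bottom) to superstrate (top).

    The emitter lives in the top half-space.  ``emission_wavelength_nm``
    fixes the vacuum wavenumber k0 = 2*pi/lambda used throughout.
    """

    layers: tuple[OpticalLayer, ...]
    emission_wavelength_nm: float

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise ValueError("a stack needs at least two half-space layers")
        if not (layers[0].is_halfspace and layers[-1].is_halfspace):
            raise ValueError("bottom and top layers must be half-spaces")
        if any(l.is_halfspace for l in layers[1:-1]):
            raise ValueError("interior layers must have finite thickness")
        if not self.emission_wavelength_nm > 0:
            raise ValueError("emission wavelength must be > 0")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber in 1/nm."""
        import math

        return 2.0 * math.pi / self.emission_wavelength_nm

    @property
    def top_index(self) -> complex:
        return complex(self.layers[-1].refractive_index)

    @property
    def finite_thickness_nm(self) -> float:
        return sum(l.thickness_nm for l in self.layers[1:-1])

    @property
    def lipid_thickness_nm(self) -> float:
        """Thickness of the topmost finite layer (the lipid monolayer)."""
        interior = self.layers[1:-1]
        return interior[-1].thickness_nm if interior else 0.0

    def with_wavelength(self, wavelength_nm: float) -> "OpticalStack":
        return replace(self, emission_wavelength_nm=wavelength_nm)


@dataclass(frozen=True)
class Fluorophore:
    """Photophysical parameters entering the lifetime-ratio model."""

    name: str
    emission_max_nm: float
    quantum_yield: float
    free_space_lifetime_ns: float

    def __post_init__(self) -> None:
        if not 0 < self.quantum_yield <= 1:
            raise ValueError("quantum yield must lie in (0, 1]")
        if not self.free_space_lifetime_ns > 0:
            raise ValueError("free-space lifetime must be > 0")
        if not self.emission_max_nm > 0:
            raise ValueError("emission maximum must be > 0")


#: Bundled fluorophores (emission max / quantum yield / lifetime on glass).
FLUOROPHORES: dict[str, Fluorophore] = {
    "FAM": Fluorophore("FAM", 518.0, 0.75, 3.0),
    "EGFP": Fluorophore("EGFP", 507.0, 0.60, 2.1),
    "mNeonGreen": Fluorophore("mNeonGreen", 517.0, 0.80, 2.8),
    "Dy647P1": Fluorophore("Dy647P1", 667.0, 0.27, 1.3),
}

#: Graphene slab index at the two calibrated emission bands.
GRAPHENE_INDEX: dict[str, complex] = {
    "giet520": 2.68 + 1.21j,
    "giet670": 2.76 + 1.40j,
}

_GLASS = 1.52
_LIPID = 1.44
_WATER = 1.33
_GRAPHENE_THICKNESS = 0.34
LIPID_THICKNESS_NM = 2.5


def make_stack(
    emission_wavelength_nm: float,
    graphene_index: complex,
    *,
    lipid_thickness_nm: float = LIPID_THICKNESS_NM,
    lipid_index: float = _LIPID,
    glass_index: float = _GLASS,
    water_index: float = _WATER,
    graphene_thickness_nm: float = _GRAPHENE_THICKNESS,
) -> OpticalStack:
    """Build the four-layer glass | graphene | lipid monolayer | water stack."""
    return OpticalStack(
        layers=(
            OpticalLayer("glass", glass_index),
            OpticalLayer("graphene", graphene_index, graphene_thickness_nm),
            OpticalLayer("lipid", lipid_index, lipid_thickness_nm),
            OpticalLayer("water", water_index),
        ),
        emission_wavelength_nm=emission_wavelength_nm,
    )


def default_stack(fluor: Fluorophore | str) -> OpticalStack:
    """Default stack for a bundled fluorophore.

    The graphene index is tabulated at two emission bands only; green
    emitters (FAM, EGFP, mNeonGreen) use the 520 nm value and Dy647P1 the
    670 nm value.  Other wavelengths need a user-supplied index via
    :func:`make_stack` -- there is no silent interpolation.
    """
    if isinstance(fluor, str):
        try:
            fluor = FLUOROPHORES[fluor]
        except KeyError:
            raise KeyError(
                f"unknown fluorophore {fluor!r}; bundled: "
                f"{sorted(FLUOROPHORES)}"
            ) from None
    if fluor.name in ("FAM", "EGFP", "mNeonGreen"):
        n_gr = GRAPHENE_INDEX["giet520"]
    elif fluor.name == "Dy647P1":
        n_gr = GRAPHENE_INDEX["giet670"]
    else:
        raise ValueError(
            f"no tabulated graphene index for {fluor.name!r}; build the stack "
            "explicitly with make_stack(wavelength, graphene_index)"
        )
    return make_stack(fluor.emission_max_nm, n_gr)
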