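"""Membrane-curvature model of presenilin shape and processing bias.

Presenilin-1 embedded in a flat membrane is idealised as a cylinder
(footprint diameter D ≈ 4.0 nm, membrane span t ≈ 4.5 nm, averaged from
solved γ-secretase structures).  In a spherical vesicle the protein instead
occupies a truncated cone whose apex sits at the vesicle centre: the
luminal footprint of diameter D sits on the inner-leaflet sphere of radius
R_lum = R_cyt − t, and the same cone meets the cytosolic leaflet (radius
R_cyt = Ω/2, with Ω the stated organelle diameter) with a proportionally
wider footprint.  The cytosolic expansion is therefore

    d = D · R_cyt / R_lum − D = D · t / (Ω/2 − t)

(footprint diameters measured as chords; chords along one cone scale
linearly with radius, so the closed form is exact).

Highly curved early-endosome membranes (Ω ≈ 40–100 nm) give d ≈ 12–4 Å and
favour the M1 conformation of the APP/γ-secretase complex (rotation of TM6
and the post-TM6 perimembrane region); nearly flat membranes — plasma
membrane, large late endosomes — give d below about 1 Å and favour the M2
conformation (stretching of TM7).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError, GeometryError

NM_TO_ANGSTROM = 10.0

#: default d thresholds (Å) separating M1-biased from M2-biased environments,
#: taken from the model's own d ranges for early vs late endosomes.
DEFAULT_M1_MIN_D = 4.0
DEFAULT_M2_MAX_D = 1.0


@dataclass(frozen=True)
class ProteinShape:
    """Cylinder idealisation of a polytopic membrane protein, in nm."""

    footprint_diameter: float = 4.0
    membrane_span: float = 4.5

    def __post_init__(self) -> None:
        if self.footprint_diameter <= 0 or self.membrane_span <= 0:
            raise GeometryError("footprint_diameter and membrane_span must be positive")


@dataclass(frozen=True)
class MembraneGeometry:
    """A flat sheet or a spherical vesicle.

    For spheres, ``outer_diameter`` (nm) is the diameter of the cytosolic
    surface — the conventional organelle diameter.
    """

    kind: str  # flat | spherical
    outer_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"flat", "spherical"}:
            raise GeometryError(f"membrane kind must be flat or spherical, got {self.kind!r}")
        if self.kind == "spherical":
            if self.outer_diameter is None or self.outer_diameter <= 0:
                raise GeometryError("spherical membrane requires positive outer_diameter")
        elif self.outer_diameter is not None:
            raise GeometryError("flat membrane takes no outer_diameter")

    @classmethod
    def flat(cls) -> "MembraneGeometry":
        return cls("flat")

    @classmethod
    def sphere(cls, outer_diameter_nm: float) -> "MembraneGeometry":
        return cls("spherical", outer_diameter_nm)


@dataclass(frozen=True)
class BiasCall:
    d: float  # Å
    bias: str  # M1-biased | M2-biased | intermediate
    thresholds: tuple[float, float]  # (m1_min_d, m2_max_d), Å


def cytosolic_expansion(shape: ProteinShape, mem: MembraneGeometry) -> float:
    """Cytosolic-side footprint expansion d in Å (0 for flat membranes)."""
    if mem.kind == "flat":
        return 0.0
    r_cyt = mem.outer_diameter / 2.0  # type: ignore[operator]
    r_lum = r_cyt - shape.membrane_span
    if r_lum <= 0:
        raise GeometryError(
            f"membrane thicker than vesicle radius (span {shape.membrane_span} nm, "
            f"outer radius {r_cyt} nm)"
        )
    d_nm = shape.footprint_diameter * shape.membrane_span / r_lum
    return d_nm * NM_TO_ANGSTROM


def classify_processing_bias(
    d: float,
    thresholds: tuple[float, float] = (DEFAULT_M1_MIN_D, DEFAULT_M2_MAX_D),
) -> BiasCall:
    """Label an expansion distance as M1-biased, M2-biased or intermediate."""
    m1_min_d, m2_max_d = thresholds
    if not (m1_min_d > m2_max_d >= 0):
        raise ConfigurationError(
            f"thresholds must satisfy m1_min_d > m2_max_d >= 0, got {thresholds}"
        )
    if d < 0:
        raise GeometryError(f"expansion distance must be non-negative, got {d}")
    if d >= m1_min_d:
        bias = "M1-biased"
    elif d <= m2_max_d:
        bias = "M2-biased"
    else:
        bias = "intermediate"
    return BiasCall(d=d, bias=bias, thresholds=(m1_min_d, m2_max_d))


@dataclass(frozen=True)
class DiameterRow:
    diameter: float  # nm
    d: float | None  # Å; None if geometry invalid
    bias: str  # bias label or "invalid"
    error: str = ""


def scan_diameters(
    shape: ProteinShape,
    diameters: Sequence[float],
    thresholds: tuple[float, float] = (DEFAULT_M1_MIN_D, DEFAULT_M2_MAX_D),
) -> list[DiameterRow]:
    """Evaluate d and the bias call across a list of vesicle diameters (nm)."""
    rows = []
    for omega in diameters:
        try:
            d = cytosolic_expansion(shape, MembraneGeometry.sphere(omega))
            call = classify_processing_bias(d, thresholds)
            rows.append(DiameterRow(diameter=omega, d=d, bias=call.bias))
        except GeometryError as exc:
            rows.append(DiameterRow(diameter=omega, d=None, bias="invalid", error=str(exc)))
    return rows
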