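"""Uniaxial incompressible kinematics for tensile tests.

Converts raw machine measurements (length, force, crosshead speed) to
engineering (nominal) strain, stress, and strain rate, and provides the
deformation quantities every constitutive model consumes: the axial
stretch ``lambda``, the lateral stretches implied by incompressibility,
and the invariants ``I1`` (isotropic) and ``I4`` (squared stretch along
the fiber direction).

Under uniaxial extension of an incompressible material with traction-free
lateral faces the full deformation gradient reduces to a single scalar:
``lambda1 = lambda`` and ``lambda2 = lambda3 = lambda**-0.5`` so that
``det F = 1`` holds exactly. The tensors themselves are never built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SpecimenGeometry",
    "UniaxialState",
    "nominal_strain",
    "nominal_stress",
    "strain_rate",
    "uniaxial_state",
]

I4Mode = Literal["fiber_vector", "loading_axis"]


@dataclass(frozen=True)
class SpecimenGeometry:
    """Reference geometry of a clamped tensile specimen.

    Parameters
    ----------
    initial_length_L0 : float
        Grip-to-grip gauge length in mm.
    width : float
        Specimen width in mm.
    thickness : float
        Specimen thickness in mm.
    """

    initial_length_L0: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("initial_length_L0", "width", "thickness"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"SpecimenGeometry.{name} must be > 0, got {v!r}")

    @property
    def cross_section_A0(self) -> float:
        """Initial cross-sectional area in mm^2 (width x thickness)."""
        return self.width * self.thickness

    @property
    def aspect_ratio(self) -> float:
        """Gauge length over width; large values keep clamping end effects small."""
        return self.initial_length_L0 / self.width


@dataclass(frozen=True)
class UniaxialState:
    """Deformation state of an incompressible uniaxial extension.

    ``stretch_lambda`` is the axial stretch; lateral stretches follow from
    volume conservation. ``I4`` is the squared stretch of a fiber making
    angle ``fiber_angle_theta`` with the loading axis.
    """

    stretch_lambda: float
    fiber_angle_theta: float = 0.0
    lateral_stretch: float = field(init=False)
    I1: float = field(init=False)
    I4: float = field(init=False)

    def __post_init__(self) -> None:
        lam = self.stretch_lambda
        theta = self.fiber_angle_theta
        if not lam > 0:
            raise ValueError(f"stretch must be positive, got {lam!r}")
        if not 0.0 <= theta <= math.pi / 2:
            raise ValueError(f"fiber angle must lie in [0, pi/2], got {theta!r}")
        object.__setattr__(self, "lateral_stretch", lam ** -0.5)
        object.__setattr__(self, "I1", lam**2 + 2.0 / lam)
        c2 = math.cos(theta) ** 2
        object.__setattr__(self, "I4", lam**2 * c2 + (1.0 - c2) / lam)


def nominal_strain(length_L: float, length_L0: float) -> float:
    """Engineering strain (L - L0) / L0, dimensionless.

    Raises
    ------
    ValueError
        If the reference length is not positive.
    """
    if not length_L0 > 0:
        raise ValueError(f"reference length L0 must be > 0, got {length_L0!r}")
    if length_L < 0:
        raise ValueError(f"current length must be >= 0, got {length_L!r}")
    return (length_L - length_L0) / length_L0


def nominal_stress(force_F: float, area_A0: float) -> float:
    """Engineering stress F / A0 in kPa.

    Force is given in N and area in mm^2, so F/A0 is in MPa; the result is
    converted to kPa, the working stress unit of the package.
    """
    if not area_A0 > 0:
        raise ValueError(f"reference area A0 must be > 0, got {area_A0!r}")
    return force_F / area_A0 * 1000.0


def strain_rate(speed: float, length_L0: float) -> float:
    """Nominal strain rate (1/s) of a test at constant crosshead speed (mm/s)."""
    if not speed > 0:
        raise ValueError(f"crosshead speed must be > 0, got {speed!r}")
    if not length_L0 > 0:
        raise ValueError(f"reference length L0 must be > 0, got {length_L0!r}")
    return speed / length_L0


def uniaxial_state(
    strain_eps: float,
    theta: float = 0.0,
    i4_mode: I4Mode = "fiber_vector",
) -> UniaxialState:
    """Build the incompressible uniaxial deformation state at a given strain.

    Parameters
    ----------
    strain_eps : float
        Engineering strain; the axial stretch is ``1 + strain_eps``. Must
        exceed -1 (a specimen cannot have non-positive length).
    theta : float
        Fiber angle from the loading axis, radians in [0, pi/2]. With
        ``theta = 0`` the fibers are loaded axially (``I4 = lambda**2``);
        with ``theta = pi/2`` they ride the lateral contraction
        (``I4 = 1/lambda``).
    i4_mode : {"fiber_vector", "loading_axis"}
        ``fiber_vector`` (default) computes I4 as the A.C.A contraction of
        a unit fiber vector at angle ``theta``; ``loading_axis`` ignores
        the lateral component and uses ``I4 = lambda**2`` regardless of
        ``theta`` (the two agree at ``theta = 0``).
    """
    if not strain_eps > -1.0:
        raise ValueError(f"strain must exceed -1, got {strain_eps!r}")
    state = UniaxialState(stretch_lambda=1.0 + strain_eps, fiber_angle_theta=theta)
    if i4_mode == "loading_axis":
        object.__setattr__(state, "I4", state.stretch_lambda**2)
    elif i4_mode != "fiber_vector":
        raise ValueError(f"unknown i4_mode {i4_mode!r}")
    return state


def curve_from_raw(
    displacement_mm: np.ndarray,
    force_N: np.ndarray,
    geometry: SpecimenGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw displacement/force records to (strain, stress_kPa) arrays."""
    displacement_mm = np.asarray(displacement_mm, dtype=float)
    force_N = np.asarray(force_N, dtype=float)
    if displacement_mm.shape != force_N.shape:
        raise ValueError("displacement and force arrays must have the same shape")
    strain = displacement_mm / geometry.initial_length_L0
    stress = force_N / geometry.cross_section_A0 * 1000.0
    return strain, stress
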