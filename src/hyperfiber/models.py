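"""Strain-energy densities and analytic uniaxial nominal stresses.

Five constitutive families are implemented, each as a parameter record plus
an energy ``W(state)`` and its analytic stretch derivative, the engineering
stress ``sigma_n = dW/dlambda`` of incompressible uniaxial extension:

* Neo-Hookean        ``W = C1 (I1 - 3)``
* Yeoh               ``W = C1 x + C2 x^2 + C3 x^3``,  ``x = I1 - 3``
* Ogden              ``W = sum mu_n/alpha_n (l^a + 2 l^(-a/2) - 3)``
* Gasser-Ogden-Holzapfel (GOH)
                     ``W = C (I1-3) + k1/(2 k2) (exp(k2 E^2) - 1)`` with
                     ``E = kappa (I1-3) + (1-3 kappa)(I4-1)`` for a single
                     fiber family with dispersion ``kappa``
* fiber-matrix model ``W = (1-phi) W_yeoh + phi cos(theta) E_f/2
                     (exp(k (I4-1)) - 1)`` — a physically parametrised
                     transversely isotropic model whose constants are the
                     fiber modulus ``E_f``, volume fraction ``phi``,
                     stiffening exponent ``k`` and orientation ``theta``.

All stresses and moduli are held in kPa internally; the fiber modulus,
conventionally quoted in MPa for collagen, is converted on construction via
:meth:`FiberParams.with_modulus_mpa`.

A central finite difference of the energy, :func:`finite_difference_stress`,
serves as the independent oracle for every analytic derivative.

Two documented quirks of the fiber and GOH families:

* The GOH anisotropic exponent is implemented by default in its standard
  form (``variant="standard"``), which leaves the reference configuration
  stress-free. An alternative ``variant="as_printed"`` inserts an extra
  ``-1`` inside the squared exponent; it is retained for audit but yields
  nonzero stress at zero strain and is not the default.
* The fiber-matrix model's exponential term has a nonzero stretch
  derivative at ``lambda = 1`` (the derivative of ``exp(k (I4-1))`` is
  ``k`` there), so for ``theta < pi/2`` it predicts a small residual stress
  at zero strain. This is a property of the functional form and is left
  as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from hyperfiber.kinematics import UniaxialState, uniaxial_state

__all__ = [
    "NeoHookeanParams",
    "YeohParams",
    "OgdenParams",
    "GOHParams",
    "FiberParams",
    "ModelParams",
    "energy",
    "nominal_stress_model",
    "nominal_stress_curve",
    "finite_difference_stress",
    "MODEL_NAMES",
]


class ParameterValidationError(ValueError):
    """A material constant violates its physical admissibility condition."""


def _check(condition: bool, message: str, validate: bool) -> None:
    if validate and not condition:
        raise ParameterValidationError(message)


@dataclass(frozen=True)
class NeoHookeanParams:
    """Neo-Hookean constant C1 (kPa); the shear modulus is mu = 2 C1."""

    C1: float
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check(self.C1 > 0, f"Neo-Hookean C1 must be > 0, got {self.C1}", self.validate)


@dataclass(frozen=True)
class YeohParams:
    """Yeoh constants C1..C3 in kPa.

    C1 must be positive (ground-state shear modulus 2*C1); C2 and C3 are
    unrestricted in sign — fitted soft-tissue sets routinely carry C3 < 0.
    """

    C1: float
    C2: float = 0.0
    C3: float = 0.0
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check(self.C1 > 0, f"Yeoh C1 must be > 0, got {self.C1}", self.validate)


@dataclass(frozen=True)
class OgdenParams:
    """Ogden series: list of (mu_n [kPa], alpha_n [-]) pairs.

    Admissibility requires a positive ground-state shear modulus,
    ``sum mu_n alpha_n > 0``.
    """

    terms: tuple[tuple[float, float], ...]
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        terms = tuple((float(m), float(a)) for m, a in self.terms)
        object.__setattr__(self, "terms", terms)
        _check(len(terms) >= 1, "Ogden model needs at least one term", True)
        gs = sum(m * a for m, a in terms)
        _check(gs > 0, f"sum(mu_n * alpha_n) must be > 0, got {gs}", self.validate)

    @classmethod
    def single(cls, mu: float, alpha: float, validate: bool = True) -> "OgdenParams":
        return cls(terms=((mu, alpha),), validate=validate)


@dataclass(frozen=True)
class GOHParams:
    """Gasser-Ogden-Holzapfel constants for one fiber family.

    C_iso [kPa] scales the Neo-Hookean matrix; k1 [kPa] and k2 [-] control
    the exponential fiber stiffening; kappa in [0, 1/3] is the in-plane
    fiber-dispersion measure (0 = perfectly aligned, 1/3 = isotropic).
    ``tension_only=True`` switches the anisotropic term off when the fiber
    pseudo-invariant drops below 1 (fibers in compression).
    """

    C_iso: float
    k1: float
    k2: float
    kappa: float
    fiber_angle_alpha: float = 0.0
    variant: str = "standard"
    tension_only: bool = False
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = self.validate
        _check(self.C_iso > 0, f"GOH C_iso must be > 0, got {self.C_iso}", v)
        _check(self.k1 > 0, f"GOH k1 must be > 0, got {self.k1}", v)
        _check(self.k2 > 0, f"GOH k2 must be > 0, got {self.k2}", v)
        _check(0.0 <= self.kappa <= 1.0 / 3.0,
               f"GOH kappa must lie in [0, 1/3], got {self.kappa}", v)
        _check(0.0 <= self.fiber_angle_alpha <= math.pi / 2,
               f"GOH fiber angle must lie in [0, pi/2], got {self.fiber_angle_alpha}", v)
        if self.variant not in ("standard", "as_printed"):
            raise ParameterValidationError(
                f"GOH variant must be 'standard' or 'as_printed', got {self.variant!r}")


@dataclass(frozen=True)
class FiberParams:
    """Fiber-matrix model constants.

    The matrix is a Yeoh solid; the fibers contribute an exponential term
    weighted by volume fraction ``phi`` and projected onto the loading
    axis through ``cos(theta)``. ``E_f`` is stored in kPa; use
    :meth:`with_modulus_mpa` to construct from an MPa-quoted collagen
    modulus. ``theta`` is the default operating fiber angle (0 =
    longitudinal loading, pi/2 = circumferential).
    """

    matrix: YeohParams
    E_f: float
    phi: float
    k_stiffening: float
    theta: float = 0.0
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = self.validate
        _check(self.E_f > 0, f"fiber modulus E_f must be > 0, got {self.E_f}", v)
        _check(0.0 <= self.phi <= 1.0,
               f"fiber volume fraction phi must lie in [0, 1], got {self.phi}", v)
        _check(self.k_stiffening > 0,
               f"stiffening exponent k must be > 0, got {self.k_stiffening}", v)
        _check(0.0 <= self.theta <= math.pi / 2,
               f"fiber angle theta must lie in [0, pi/2], got {self.theta}", v)

    @classmethod
    def with_modulus_mpa(cls, matrix: YeohParams, E_f_mpa: float, phi: float,
                         k_stiffening: float, theta: float = 0.0,
                         validate: bool = True) -> "FiberParams":
        """Construct with the fiber modulus given in MPa (converted to kPa)."""
        return cls(matrix=matrix, E_f=E_f_mpa * 1000.0, phi=phi,
                   k_stiffening=k_stiffening, theta=theta, validate=validate)


ModelParams = Union[NeoHookeanParams, YeohParams, OgdenParams, GOHParams, FiberParams]

MODEL_NAMES = ("neo", "yeoh", "ogden", "goh", "fiber")


def _yeoh_energy(p: YeohParams, I1: float) -> float:
    x = I1 - 3.0
    return p.C1 * x + p.C2 * x**2 + p.C3 * x**3


def _yeoh_stress(p: YeohParams, lam: float, I1: float) -> float:
    x = I1 - 3.0
    dI1 = 2.0 * lam - 2.0 / lam**2
    return (p.C1 + 2.0 * p.C2 * x + 3.0 * p.C3 * x**2) * dI1


def _goh_exponent_arg(p: GOHParams, I1: float, I4: float) -> float:
    e = p.kappa * (I1 - 3.0) + (1.0 - 3.0 * p.kappa) * (I4 - 1.0)
    if p.variant == "as_printed":
        e -= 1.0
    return e


def energy(params: ModelParams, state: UniaxialState) -> float:
    """Strain-energy density W in kPa at the given uniaxial state.

    The fiber-direction dependence enters through ``state.I4`` and, for the
    fiber-matrix model, the ``cos(theta)`` projection uses the state's own
    fiber angle so that prefactor and invariant stay consistent.
    """
    lam, I1, I4 = state.stretch_lambda, state.I1, state.I4
    if isinstance(params, NeoHookeanParams):
        return params.C1 * (I1 - 3.0)
    if isinstance(params, YeohParams):
        return _yeoh_energy(params, I1)
    if isinstance(params, OgdenParams):
        return sum(m / a * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)
                   for m, a in params.terms)
    if isinstance(params, GOHParams):
        w = params.C_iso * (I1 - 3.0)
        if not (params.tension_only and I4 < 1.0):
            e = _goh_exponent_arg(params, I1, I4)
            w += params.k1 / (2.0 * params.k2) * math.expm1(params.k2 * e**2)
        return w
    if isinstance(params, FiberParams):
        w_matrix = _yeoh_energy(params.matrix, I1)
        k = params.k_stiffening
        w_fibers = (math.cos(state.fiber_angle_theta) * params.E_f / 2.0
                    * math.expm1(k * (I4 - 1.0)))
        return (1.0 - params.phi) * w_matrix + params.phi * w_fibers
    raise TypeError(f"unsupported parameter record {type(params).__name__}")


def nominal_stress_model(params: ModelParams, strain_eps: float,
                         theta: float = 0.0) -> float:
    """Analytic engineering stress dW/dlambda in kPa.

    ``theta`` is the fiber angle of the loading configuration (0 for
    longitudinal specimens, pi/2 for circumferential); it is ignored by
    the isotropic families.
    """
    state = uniaxial_state(strain_eps, theta)
    lam, I1, I4 = state.stretch_lambda, state.I1, state.I4
    dI1 = 2.0 * lam - 2.0 / lam**2
    c2 = math.cos(theta) ** 2
    dI4 = 2.0 * lam * c2 - (1.0 - c2) / lam**2
    if isinstance(params, NeoHookeanParams):
        return params.C1 * dI1
    if isinstance(params, YeohParams):
        return _yeoh_stress(params, lam, I1)
    if isinstance(params, OgdenParams):
        return sum(m * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
                   for m, a in params.terms)
    if isinstance(params, GOHParams):
        s = params.C_iso * dI1
        if not (params.tension_only and I4 < 1.0):
            e = _goh_exponent_arg(params, I1, I4)
            dE = params.kappa * dI1 + (1.0 - 3.0 * params.kappa) * dI4
            s += params.k1 * e * math.exp(params.k2 * e**2) * dE
        return s
    if isinstance(params, FiberParams):
        k = params.k_stiffening
        s_fibers = (math.cos(theta) * params.E_f / 2.0
                    * k * math.exp(k * (I4 - 1.0)) * dI4)
        return ((1.0 - params.phi) * _yeoh_stress(params.matrix, lam, I1)
                + params.phi * s_fibers)
    raise TypeError(f"unsupported parameter record {type(params).__name__}")


def nominal_stress_curve(params: ModelParams, strain: np.ndarray,
                         theta: float = 0.0) -> np.ndarray:
    """Vectorised :func:`nominal_stress_model` over a strain array."""
    strain = np.asarray(strain, dtype=float)
    return np.array([nominal_stress_model(params, float(e), theta)
                     for e in strain.ravel()]).reshape(strain.shape)


def finite_difference_stress(params: ModelParams, strain_eps: float,
                             theta: float = 0.0, h: float = 1e-6) -> float:
    """Central finite difference [W(lam+h) - W(lam-h)] / (2h).

    Independent numerical oracle for the analytic stress derivatives; the
    step acts on the stretch, identical to the strain step since
    lam = 1 + eps.
    """
    if not 0.0 < h <= 1e-3:
        raise ValueError(f"step h must lie in (0, 1e-3], got {h!r}")
    w_plus = energy(params, uniaxial_state(strain_eps + h, theta))
    w_minus = energy(params, uniaxial_state(strain_eps - h, theta))
    return (w_plus - w_minus) / (2.0 * h)


# ---------------------------------------------------------------------------
# serialization — flat key/value dictionaries, lossless round trip
# ---------------------------------------------------------------------------

def params_to_dict(params: ModelParams) -> dict:
    """Flatten a parameter record to a plain dict with a ``model`` tag."""
    if isinstance(params, NeoHookeanParams):
        return {"model": "neo", "C1": params.C1}
    if isinstance(params, YeohParams):
        return {"model": "yeoh", "C1": params.C1, "C2": params.C2, "C3": params.C3}
    if isinstance(params, OgdenParams):
        return {"model": "ogden",
                "mu": [m for m, _ in params.terms],
                "alpha": [a for _, a in params.terms]}
    if isinstance(params, GOHParams):
        return {"model": "goh", "C_iso": params.C_iso, "k1": params.k1,
                "k2": params.k2, "kappa": params.kappa,
                "fiber_angle_alpha": params.fiber_angle_alpha,
                "variant": params.variant, "tension_only": params.tension_only}
    if isinstance(params, FiberParams):
        return {"model": "fiber", "C1": params.matrix.C1, "C2": params.matrix.C2,
                "C3": params.matrix.C3, "E_f": params.E_f, "phi": params.phi,
                "k": params.k_stiffening, "theta": params.theta}
    raise TypeError(f"unsupported parameter record {type(params).__name__}")


def params_from_dict(d: dict, validate: bool = True) -> ModelParams:
    """Inverse of :func:`params_to_dict`."""
    model = d.get("model")
    if model == "neo":
        return NeoHookeanParams(C1=d["C1"], validate=validate)
    if model == "yeoh":
        return YeohParams(C1=d["C1"], C2=d.get("C2", 0.0), C3=d.get("C3", 0.0),
                          validate=validate)
    if model == "ogden":
        terms = tuple(zip(d["mu"], d["alpha"]))
        return OgdenParams(terms=terms, validate=validate)
    if model == "goh":
        return GOHParams(C_iso=d["C_iso"], k1=d["k1"], k2=d["k2"], kappa=d["kappa"],
                         fiber_angle_alpha=d.get("fiber_angle_alpha", 0.0),
                         variant=d.get("variant", "standard"),
                         tension_only=d.get("tension_only", False),
                         validate=validate)
    if model == "fiber":
        matrix = YeohParams(C1=d["C1"], C2=d.get("C2", 0.0), C3=d.get("C3", 0.0),
                            validate=validate)
        return FiberParams(matrix=matrix, E_f=d["E_f"], phi=d["phi"],
                           k_stiffening=d["k"], theta=d.get("theta", 0.0),
                           validate=validate)
    raise ValueError(f"unknown model tag {model!r}; expected one of {MODEL_NAMES}")


def with_theta(params: ModelParams, theta: float) -> ModelParams:
    """Return a copy of an anisotropic record with its operating angle set."""
    if isinstance(params, FiberParams):
        return replace(params, theta=theta)
    if isinstance(params, GOHParams):
        return replace(params, fiber_angle_alpha=theta)
    return params
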