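"""Forward force-indentation laws for rigid axisymmetric indenters.

Supported tip shapes: flat cylinder, cone, paraboloid (the small-depth sphere
approximation) and the exact sphere, whose contact radius is defined
implicitly and solved by bracketed root finding.

All quantities are strict SI: depths in metres, forces in newtons, moduli in
pascals.  For the cylinder / cone / paraboloid laws the force is linear in
the modulus, ``F = E * g(h)``, and :func:`shape_function` exposes the purely
geometric factor ``g`` used by the closed-form fitting routines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (
    ConfigurationError,
    DomainError,
    GeometryMismatchError,
    NumericalError,
    ParameterError,
)

__all__ = [
    "IndenterGeometry",
    "ElasticParams",
    "SneddonSeriesCorrection",
    "force_cylindrical",
    "force_conical",
    "force_paraboloid",
    "force_sneddon_sphere",
    "force_sphere_series",
    "sneddon_contact_radius",
    "shape_function",
]

_KINDS = ("cylinder", "cone", "paraboloid", "sphere")
_RADIUS_KINDS = ("cylinder", "paraboloid", "sphere")


@dataclass(frozen=True)
class IndenterGeometry:
    """Tip shape: ``kind`` plus radius (m) or cone half-angle (rad).

    Exactly the field required by ``kind`` must be set: ``radius`` for
    cylinder / paraboloid / sphere, ``half_angle`` for cone.
    """

    kind: str
    radius: float | None = None
    half_angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown indenter kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind in _RADIUS_KINDS:
            if self.radius is None or not self.radius > 0:
                raise ParameterError(f"{self.kind} indenter requires radius > 0, got {self.radius}")
            if self.half_angle is not None:
                raise ParameterError(f"{self.kind} indenter must not set half_angle")
        else:  # cone
            if self.half_angle is None or not 0 < self.half_angle < math.pi / 2:
                raise ParameterError(
                    f"cone indenter requires half_angle in (0, pi/2) rad, got {self.half_angle}"
                )
            if self.radius is not None:
                raise ParameterError("cone indenter must not set radius")

    @classmethod
    def cylinder(cls, radius: float) -> "IndenterGeometry":
        return cls("cylinder", radius=radius)

    @classmethod
    def cone(cls, half_angle: float) -> "IndenterGeometry":
        return cls("cone", half_angle=half_angle)

    @classmethod
    def paraboloid(cls, radius: float) -> "IndenterGeometry":
        return cls("paraboloid", radius=radius)

    @classmethod
    def sphere(cls, radius: float) -> "IndenterGeometry":
        return cls("sphere", radius=radius)


@dataclass(frozen=True)
class ElasticParams:
    """Elastic half-space parameters: modulus (Pa) and Poisson's ratio.

    For the cylinder / cone / paraboloid laws the modulus is interpreted as
    the depth-averaged Young's modulus; for the exact sphere it is the
    half-space Young's modulus.  Poisson's ratio defaults to 0.5
    (incompressible), the convention for hydrated biological samples.
    """

    modulus: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 < self.poisson_ratio <= 0.5:
            raise ParameterError(f"poisson_ratio must be in (-1, 0.5], got {self.poisson_ratio}")
        if not self.modulus >= 0:
            raise ParameterError(f"modulus must be >= 0, got {self.modulus}")


@dataclass(frozen=True)
class SneddonSeriesCorrection:
    """Caller-supplied coefficients for the series-corrected sphere law.

    The coefficient values are not bundled with the package; the series form
    is opt-in and fully parameterized by the caller.
    """

    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ConfigurationError("SneddonSeriesCorrection requires at least one coefficient")

    def factor(self, radius: float, h: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the dimensionless correction factor Z(h).

        Z = c1 + sum_{M=2..N} 3/(2M) * c_M * R^(3/2-M) * h^(M-3/2).
        """
        h = np.asarray(h, dtype=float)
        z = np.full_like(h, self.coefficients[0], dtype=float)
        for m, c in enumerate(self.coefficients[1:], start=2):
            z = z + (3.0 / (2.0 * m)) * c * radius ** (1.5 - m) * h ** (m - 1.5)
        return z


def _check_depth(h) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise DomainError("indentation depth must be >= 0")
    return h


def _check_kind(geometry: IndenterGeometry, kind: str) -> None:
    if geometry.kind != kind:
        raise GeometryMismatchError(f"expected {kind} geometry, got {geometry.kind!r}")


def _prefactor(v: float) -> float:
    return 1.0 - v * v


def force_cylindrical(params: ElasticParams, geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Force on a flat cylindrical punch: F = 2*E*R*h / (1 - v^2)."""
    _check_kind(geometry, "cylinder")
    h = _check_depth(h)
    out = 2.0 * params.modulus * geometry.radius * h / _prefactor(params.poisson_ratio)
    return out if out.ndim else float(out)


def force_conical(params: ElasticParams, geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Force on a conical tip: F = (2*tan(theta) / (pi*(1 - v^2))) * E * h^2."""
    _check_kind(geometry, "cone")
    h = _check_depth(h)
    out = (
        2.0
        * math.tan(geometry.half_angle)
        / (math.pi * _prefactor(params.poisson_ratio))
        * params.modulus
        * h**2
    )
    return out if out.ndim else float(out)


def force_paraboloid(params: ElasticParams, geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Force on a paraboloid (sphere at small depth): F = (4*sqrt(R)*E / (3*(1-v^2))) * h^(3/2)."""
    _check_kind(geometry, "paraboloid")
    h = _check_depth(h)
    out = (
        4.0
        * math.sqrt(geometry.radius)
        * params.modulus
        / (3.0 * _prefactor(params.poisson_ratio))
        * h**1.5
    )
    return out if out.ndim else float(out)


def _contact_radius_scalar(radius: float, h: float) -> float:
    if h == 0.0:
        return 0.0

    def resid(rc: float) -> float:
        return math.log((radius + rc) / (radius - rc)) - 2.0 * h / rc

    eps = 1e-15 * radius
    lo, hi = eps, radius * (1.0 - 1e-15)
    try:
        # resid -> -inf as rc -> 0+ and +inf as rc -> R-, and is strictly
        # increasing, so the bracket is globally safe.
        rc = brentq(resid, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as exc:
        raise NumericalError(
            f"contact-radius solve failed for R={radius!r}, h={h!r}: {exc}"
        ) from exc
    return float(rc)


def sneddon_contact_radius(geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Contact radius of the exact sphere solution.

    Solves ln((R + rc)/(R - rc)) = 2*h/rc for rc in (0, R) by Brent's method;
    returns 0 at h = 0.  Accepts scalar or array depths.
    """
    _check_kind(geometry, "sphere")
    h = _check_depth(h)
    if h.ndim == 0:
        return _contact_radius_scalar(geometry.radius, float(h))
    return np.array([_contact_radius_scalar(geometry.radius, float(hi)) for hi in h.ravel()]).reshape(
        h.shape
    )


def force_sneddon_sphere(params: ElasticParams, geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Exact sphere force law.

    F = E / (2*(1 - v^2)) * [(rc^2 + R^2) * ln((R + rc)/(R - rc)) - 2*rc*R]
    with rc from :func:`sneddon_contact_radius`.
    """
    _check_kind(geometry, "sphere")
    h = _check_depth(h)
    rc = np.asarray(sneddon_contact_radius(geometry, h), dtype=float)
    R = geometry.radius
    with np.errstate(divide="ignore", invalid="ignore"):
        core = (rc**2 + R**2) * np.log((R + rc) / (R - rc)) - 2.0 * rc * R
    core = np.where(rc == 0.0, 0.0, core)
    out = params.modulus / (2.0 * _prefactor(params.poisson_ratio)) * core
    return out if out.ndim else float(out)


def force_sphere_series(
    params: ElasticParams,
    geometry: IndenterGeometry,
    h,
    corr: SneddonSeriesCorrection,
) -> np.ndarray | float:
    """Series-corrected sphere law: the paraboloid force times the factor Z(h).

    Coefficients must be supplied by the caller; a computed Z exceeding 1
    (beyond round-off) violates the correction's stated bound and triggers a
    warning, not an error.
    """
    _check_kind(geometry, "sphere")
    h = _check_depth(h)
    z = np.asarray(corr.factor(geometry.radius, h), dtype=float)
    if np.any(z > 1.0 + 1e-9):
        warnings.warn(
            f"series correction factor Z exceeds 1 (max {float(np.max(z)):.6g}); "
            "the supplied coefficients violate the Z <= 1 bound",
            stacklevel=2,
        )
    out = (
        4.0
        * params.modulus
        * math.sqrt(geometry.radius)
        / (3.0 * _prefactor(params.poisson_ratio))
        * h**1.5
        * z
    )
    return out if out.ndim else float(out)


def shape_function(geometry: IndenterGeometry, v: float, h) -> np.ndarray | float:
    """Geometric factor g(h) such that F = E * g(h) for the closed-form laws.

    Defined for cylinder, cone and paraboloid (the laws linear in the
    modulus).  The exact sphere is also linear in E but has no elementary
    g(h); fitting code handles it via a unit-modulus force basis instead.
    """
    if geometry.kind == "sphere":
        raise GeometryMismatchError(
            "shape_function is undefined for the exact sphere; use a unit-modulus "
            "force_sneddon_sphere basis instead"
        )
    unit = ElasticParams(modulus=1.0, poisson_ratio=v)
    if geometry.kind == "cylinder":
        return force_cylindrical(unit, geometry, h)
    if geometry.kind == "cone":
        return force_conical(unit, geometry, h)
    return force_paraboloid(unit, geometry, h)


def unit_force_basis(geometry: IndenterGeometry, v: float, h) -> np.ndarray | float:
    """Force at unit modulus (1 Pa) for any geometry, exact sphere included.

    This is the basis vector used by linear least-squares modulus fitting:
    F = E * unit_force_basis(geometry, v, h) holds exactly for every
    supported geometry because all the laws are linear in the modulus.
    """
    if geometry.kind == "sphere":
        return force_sneddon_sphere(ElasticParams(1.0, v), geometry, h)
    return shape_function(geometry, v, h)


def forward_force(params: ElasticParams, geometry: IndenterGeometry, h) -> np.ndarray | float:
    """Dispatch to the force law matching ``geometry.kind``."""
    dispatch = {
        "cylinder": force_cylindrical,
        "cone": force_conical,
        "paraboloid": force_paraboloid,
        "sphere": force_sneddon_sphere,
    }
    return dispatch[geometry.kind](params, geometry, h)
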