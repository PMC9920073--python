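"""Synthetic force curves and force-volume grids with retained ground truth.

The generator inverts the analysis model: a prescribed depth-dependent
average modulus E(h) — from a constant, a power law a*h**b + c, a stack of
homogeneous slices, or an arbitrary continuous modulus-versus-depth
function — is pushed through the forward force law F(h) = g(h) * E(h),
optionally corrupted with seeded force noise, and emitted together with the
exact ground truth so that recovery tests can close the loop.

Seeding scheme: a master seed plus the (row, col) pixel coordinates form
the entropy sequence of each pixel's generator
(``np.random.default_rng([seed, row, col])``), so any pixel can be
regenerated independently and grids are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .contact_models import ElasticParams, IndenterGeometry, force_sneddon_sphere, shape_function
from .curve_io import ForceCurve, ForceVolumeGrid
from .errors import ConfigurationError, DataError, DomainError
from .map_stack import DepthMap, MapStack
from .units import KPA, NM

__all__ = [
    "ConstantModulus",
    "PowerLawModulus",
    "LayeredSample",
    "ContinuousSample",
    "NoiseModel",
    "SyntheticFieldSpec",
    "average_modulus_of_sample",
    "simulate_curve",
    "simulate_force_volume",
]


# ---------------------------------------------------------------------------
# ground-truth modulus structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantModulus:
    """Homogeneous sample: E(h) = e for every depth."""

    e: float

    def __post_init__(self) -> None:
        if self.e < 0:
            raise DomainError(f"modulus must be >= 0, got {self.e}")

    def average_modulus(self, h: float) -> float:
        return self.e

    @property
    def max_depth(self) -> float:
        return math.inf


@dataclass(frozen=True)
class PowerLawModulus:
    """Average-modulus profile E(h) = a * h**b + c (SI; a > 0, c > 0, b < 0)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.b < 0):
            raise DomainError(
                f"power-law profile requires a > 0, c > 0, b < 0; got a={self.a}, "
                f"b={self.b}, c={self.c}"
            )

    def average_modulus(self, h: float) -> float:
        if h <= 0:
            raise DomainError("power-law profile is undefined at h <= 0")
        return self.a * h**self.b + self.c

    @property
    def max_depth(self) -> float:
        return math.inf


@dataclass(frozen=True)
class LayeredSample:
    """N homogeneous slices of equal thickness; E(h) is their running mean.

    The average over a window [0, h] weights every fully covered slice by
    the slice thickness and the last, partially covered slice by the
    remaining depth — the exact discrete-sum value.
    """

    slice_thickness: float                # m
    slice_moduli: tuple[float, ...]       # Pa

    def __post_init__(self) -> None:
        if not self.slice_thickness > 0:
            raise DomainError(f"slice thickness must be > 0, got {self.slice_thickness}")
        if len(self.slice_moduli) < 1:
            raise DataError("layered sample needs at least one slice")
        if any(e < 0 for e in self.slice_moduli):
            raise DomainError("slice moduli must be >= 0")

    @property
    def max_depth(self) -> float:
        return self.slice_thickness * len(self.slice_moduli)

    def average_modulus(self, h: float) -> float:
        if h < 0 or h > self.max_depth * (1 + 1e-12):
            raise DomainError(
                f"depth {h:.4g} m outside layered sample range [0, {self.max_depth:.4g}] m"
            )
        if h == 0:
            return float(self.slice_moduli[0])
        dh = self.slice_thickness
        e = np.asarray(self.slice_moduli, dtype=float)
        n_full = min(int(h // dh), e.size)
        partial = min(h - n_full * dh, dh)
        total = float(np.sum(e[:n_full]) * dh)
        if partial > 0 and n_full < e.size:
            total += float(e[n_full]) * partial
        return total / h

    @classmethod
    def from_function(
        cls, fn: Callable[[float], float], n_slices: int, h_max: float, where: str = "mid"
    ) -> "LayeredSample":
        """Discretize a continuous modulus function into n equal slices.

        ``where`` picks the sampling point inside each slice: "mid" (second
        order) or "left" (first order, the plain Riemann discretization).
        """
        if n_slices < 1:
            raise DataError("need at least one slice")
        dh = h_max / n_slices
        offset = 0.5 if where == "mid" else 0.0
        moduli = tuple(float(fn((i + offset) * dh)) for i in range(n_slices))
        return cls(slice_thickness=dh, slice_moduli=moduli)


@dataclass(frozen=True)
class ContinuousSample:
    """Continuous modulus-versus-depth function; averages by quadrature."""

    modulus_fn: Callable[[float], float]
    h_max: float
    epsrel: float = 1e-10

    def __post_init__(self) -> None:
        if not self.h_max > 0:
            raise DomainError(f"h_max must be > 0, got {self.h_max}")

    @property
    def max_depth(self) -> float:
        return self.h_max

    def average_modulus(self, h: float) -> float:
        if h < 0 or h > self.h_max * (1 + 1e-12):
            raise DomainError(f"depth {h:.4g} m outside sample range [0, {self.h_max:.4g}] m")
        if h == 0:
            return float(self.modulus_fn(0.0))
        integral, _ = quad(self.modulus_fn, 0.0, h, epsrel=self.epsrel, epsabs=0.0, limit=200)
        return integral / h


def average_modulus_of_sample(sample, h: float) -> float:
    """Depth-averaged modulus of any supported sample / profile object."""
    try:
        return float(sample.average_modulus(h))
    except AttributeError:
        raise DataError(
            f"object of type {type(sample).__name__} does not define average_modulus"
        ) from None


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Seeded force noise: F <- F * (1 + eps_m) + eps_a.

    ``multiplicative`` is the standard deviation of the relative error;
    ``additive`` is the standard deviation of the absolute error expressed
    as a fraction of the curve's maximum force.  Noise touches force only,
    never depth, so model inversion stays well defined.
    """

    multiplicative: float = 0.0
    additive: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicative < 0 or self.additive < 0:
            raise ConfigurationError("noise levels must be >= 0")

    def apply(self, F: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(F, dtype=float).copy()
        if self.multiplicative > 0:
            out *= 1.0 + rng.normal(0.0, self.multiplicative, size=out.shape)
        if self.additive > 0:
            scale = self.additive * float(np.max(np.abs(F))) if F.size else 0.0
            if scale > 0:
                out += rng.normal(0.0, scale, size=out.shape)
        return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_curve(
    sample,
    geometry: IndenterGeometry,
    v: float,
    depth_grid,
    noise: NoiseModel | None = None,
    seed=None,
    use_exact_sphere: bool = False,
) -> tuple[ForceCurve, np.ndarray]:
    """Generate one force curve from a modulus structure; returns ground truth.

    The force at each grid depth is g(h) * E(h), where E(h) is the sample's
    depth-averaged modulus.  Spherical tips use the paraboloid shape factor
    (the form the averaging theory prescribes); ``use_exact_sphere=True``
    switches to the exact sphere law and is valid only for constant-modulus
    samples.  Returns ``(curve, e_avg)`` with the noiseless ground truth
    E(h) at every grid depth.
    """
    depth_grid = np.asarray(depth_grid, dtype=float)
    if depth_grid.ndim != 1 or depth_grid.size < 8:
        raise DataError("depth grid must be 1-D with >= 8 samples")
    if np.any(np.diff(depth_grid) <= 0) or np.any(depth_grid < 0):
        raise DataError("depth grid must be non-negative and strictly increasing")
    max_depth = getattr(sample, "max_depth", math.inf)
    if depth_grid[-1] > max_depth * (1 + 1e-12):
        raise DomainError(
            f"depth grid reaches {depth_grid[-1]:.4g} m beyond the sample's "
            f"defined range {max_depth:.4g} m"
        )

    e_avg = np.array(
        [
            average_modulus_of_sample(sample, float(h)) if h > 0 else _surface_modulus(sample)
            for h in depth_grid
        ]
    )
    if use_exact_sphere:
        if geometry.kind != "sphere":
            raise ConfigurationError("use_exact_sphere requires sphere geometry")
        if not isinstance(sample, ConstantModulus):
            raise ConfigurationError(
                "the exact sphere law applies to constant-modulus samples only"
            )
        F = np.asarray(
            force_sneddon_sphere(ElasticParams(sample.e, v), geometry, depth_grid), dtype=float
        )
    else:
        geom_eff = (
            IndenterGeometry.paraboloid(geometry.radius)
            if geometry.kind == "sphere"
            else geometry
        )
        g = np.asarray(shape_function(geom_eff, v, depth_grid), dtype=float)
        with np.errstate(invalid="ignore"):
            F = np.where(depth_grid == 0.0, 0.0, g * e_avg)  # F(0) = 0 even when E diverges

    noise = noise or NoiseModel()
    F = noise.apply(F, _as_rng(seed))
    curve = ForceCurve(
        depth_grid.copy(),
        F,
        metadata={
            "synthetic": "true",
            "noise_multiplicative": noise.multiplicative,
            "noise_additive": noise.additive,
        },
    )
    return curve, e_avg


def _surface_modulus(sample) -> float:
    """E at h -> 0+, used only when the grid includes the contact point itself."""
    if isinstance(sample, PowerLawModulus):
        return math.inf  # diverges at the surface; F = g*E is still 0 * inf guarded below
    return average_modulus_of_sample(sample, 0.0)


# ---------------------------------------------------------------------------
# force-volume generation
# ---------------------------------------------------------------------------

FIELD_KINDS = ("uniform", "inclusion", "random_normal_constant", "per_pixel")


@dataclass
class SyntheticFieldSpec:
    """Full description of a synthetic force-volume acquisition.

    ``field_kind`` selects how per-pixel modulus structures are assigned:

    * ``uniform`` — every pixel carries ``base_profile``;
    * ``inclusion`` — ``base_profile`` everywhere except a rectangular
      region (row0, col0, height, width) carrying ``inclusion_profile``;
    * ``random_normal_constant`` — per-pixel constant moduli drawn from
      N(random_mu, random_sigma**2), clipped below at ``random_floor``,
      using each pixel's own seeded stream;
    * ``per_pixel`` — an explicit (ny, nx) nested list in ``profiles``.
    """

    ny: int
    nx: int
    geometry: IndenterGeometry
    sample_depths: np.ndarray                   # m, curve sampling grid
    poisson_ratio: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    pixel_size: float | None = None
    field_kind: str = "uniform"
    base_profile: object | None = None
    inclusion_profile: object | None = None
    inclusion_region: tuple[int, int, int, int] | None = None
    random_mu: float | None = None
    random_sigma: float | None = None
    random_floor: float = 100.0                 # Pa
    profiles: list | None = None

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nx < 1:
            raise ConfigurationError(f"grid dims must be >= 1, got ny={self.ny}, nx={self.nx}")
        self.sample_depths = np.asarray(self.sample_depths, dtype=float)
        if self.field_kind not in FIELD_KINDS:
            raise ConfigurationError(
                f"unknown field kind {self.field_kind!r}; expected one of {FIELD_KINDS}"
            )
        if self.field_kind in ("uniform", "inclusion") and self.base_profile is None:
            raise ConfigurationError(f"field kind {self.field_kind!r} needs base_profile")
        if self.field_kind == "inclusion" and (
            self.inclusion_profile is None or self.inclusion_region is None
        ):
            raise ConfigurationError("inclusion field needs inclusion_profile and inclusion_region")
        if self.field_kind == "random_normal_constant" and (
            self.random_mu is None or self.random_sigma is None
        ):
            raise ConfigurationError("random_normal_constant field needs random_mu and random_sigma")
        if self.field_kind == "per_pixel":
            if (
                self.profiles is None
                or len(self.profiles) != self.ny
                or any(len(row) != self.nx for row in self.profiles)
            ):
                raise ConfigurationError("per_pixel field needs an (ny, nx) 'profiles' list")

    def pixel_rng(self, row: int, col: int) -> np.random.Generator:
        """Independent per-pixel stream: entropy = (seed, row, col)."""
        return np.random.default_rng([self.seed, row, col])

    def profile_at(self, row: int, col: int, rng: np.random.Generator):
        if self.field_kind == "uniform":
            return self.base_profile
        if self.field_kind == "inclusion":
            r0, c0, hgt, wid = self.inclusion_region
            if r0 <= row < r0 + hgt and c0 <= col < c0 + wid:
                return self.inclusion_profile
            return self.base_profile
        if self.field_kind == "random_normal_constant":
            e = max(float(rng.normal(self.random_mu, self.random_sigma)), self.random_floor)
            return ConstantModulus(e)
        return self.profiles[row][col]

    @classmethod
    def from_dict(cls, cfg: dict) -> "SyntheticFieldSpec":
        """Build a spec from a plain dict (CLI config files; nm/kPa units)."""
        try:
            return cls._from_dict(cfg)
        except KeyError as exc:
            raise ConfigurationError(f"synthetic config missing required field {exc}") from None

    @classmethod
    def _from_dict(cls, cfg: dict) -> "SyntheticFieldSpec":
        geom_cfg = cfg["geometry"]
        kind = geom_cfg["kind"]
        if kind == "cone":
            geometry = IndenterGeometry.cone(math.radians(float(geom_cfg["half_angle_deg"])))
        else:
            geometry = IndenterGeometry(kind, radius=float(geom_cfg["radius_nm"]) * NM)
        curve_cfg = cfg.get("curve", {})
        h_max = float(curve_cfg.get("h_max_nm", 1000.0)) * NM
        n_samples = int(curve_cfg.get("n_samples", 128))
        depths = np.linspace(h_max / n_samples, h_max, n_samples)
        noise_cfg = cfg.get("noise", {})
        field_cfg = cfg.get(
            "field", {"kind": "uniform", "profile": {"type": "constant", "E_kPa": 20.0}}
        )

        def parse_profile(p: dict):
            ptype = p.get("type", "constant")
            if ptype == "constant":
                return ConstantModulus(float(p["E_kPa"]) * KPA)
            if ptype == "power_law":
                b = float(p["b"])
                a = float(p["a_kPa"]) * KPA * NM ** (-b)  # a quoted in kPa * nm**(-b)
                return PowerLawModulus(a=a, b=b, c=float(p["c_kPa"]) * KPA)
            if ptype == "layered":
                return LayeredSample(
                    slice_thickness=float(p["slice_thickness_nm"]) * NM,
                    slice_moduli=tuple(float(e) * KPA for e in p["slice_moduli_kPa"]),
                )
            raise ConfigurationError(f"unknown profile type {ptype!r}")

        kwargs: dict = {}
        fkind = field_cfg.get("kind", "uniform")
        if fkind in ("uniform", "inclusion"):
            kwargs["base_profile"] = parse_profile(field_cfg["profile"])
        if fkind == "inclusion":
            kwargs["inclusion_profile"] = parse_profile(field_cfg["inclusion_profile"])
            kwargs["inclusion_region"] = tuple(int(i) for i in field_cfg["region"])
        if fkind == "random_normal_constant":
            kwargs["random_mu"] = float(field_cfg["mu_kPa"]) * KPA
            kwargs["random_sigma"] = float(field_cfg["sigma_kPa"]) * KPA
            kwargs["random_floor"] = float(field_cfg.get("floor_kPa", 0.1)) * KPA
        grid_cfg = cfg.get("grid", {})
        pixel_size = grid_cfg.get("pixel_size_nm")
        return cls(
            ny=int(grid_cfg.get("ny", 8)),
            nx=int(grid_cfg.get("nx", 8)),
            geometry=geometry,
            sample_depths=depths,
            poisson_ratio=float(cfg.get("poisson_ratio", 0.5)),
            noise=NoiseModel(
                multiplicative=float(noise_cfg.get("multiplicative", 0.0)),
                additive=float(noise_cfg.get("additive", 0.0)),
            ),
            seed=int(cfg.get("seed", 0)),
            pixel_size=float(pixel_size) * NM if pixel_size is not None else None,
            field_kind=fkind,
            **kwargs,
        )


def simulate_force_volume(
    spec: SyntheticFieldSpec,
    truth_depths=None,
) -> tuple[ForceVolumeGrid, MapStack]:
    """Simulate every pixel of a grid; returns (grid, ground-truth stack).

    ``truth_depths`` defaults to the curve sampling grid; the returned
    stack holds the exact (noiseless) average modulus of each pixel at
    those depths.
    """
    truth_depths = (
        np.asarray(truth_depths, dtype=float)
        if truth_depths is not None
        else spec.sample_depths[spec.sample_depths > 0]
    )
    curves: list[list[ForceCurve | None]] = [[None] * spec.nx for _ in range(spec.ny)]
    truth = np.empty((truth_depths.size, spec.ny, spec.nx))
    for r in range(spec.ny):
        for c in range(spec.nx):
            rng = spec.pixel_rng(r, c)
            profile = spec.profile_at(r, c, rng)
            curve, _ = simulate_curve(
                profile,
                spec.geometry,
                spec.poisson_ratio,
                spec.sample_depths,
                noise=spec.noise,
                seed=rng,
            )
            curve.pixel_index = (r, c)
            curves[r][c] = curve
            truth[:, r, c] = [average_modulus_of_sample(profile, float(h)) for h in truth_depths]
    grid = ForceVolumeGrid(
        curves,
        pixel_size=spec.pixel_size,
        metadata={"synthetic": True, "seed": spec.seed, "field_kind": spec.field_kind},
    )
    stack = MapStack(
        [
            DepthMap(
                depth=float(d),
                values=truth[j],
                mask=np.zeros((spec.ny, spec.nx), dtype=bool),
                metadata={"ground_truth": True, "seed": spec.seed},
            )
            for j, d in enumerate(truth_depths)
        ],
        metadata={"ground_truth": True, "seed": spec.seed},
    )
    return grid, stack
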