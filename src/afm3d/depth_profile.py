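"""Depth-dependent average Young's modulus estimation from one force curve.

The central quantity is the best-fitting constant modulus over a truncated
window of the curve: refitting with a growing window 0 <= h <= h_j turns a
single force-indentation record into a modulus-versus-depth profile, which
for cells is well described by E(h) = a * h**b + c with a, c > 0 and b < 0.

Two estimators are provided:

* ``windowed_ls`` (default) — closed-form least squares of F = E * g(h)
  over the window, i.e. "best constant-modulus fit over [0, h]";
* ``pointwise`` — the direct ratio F(h) / g(h) at one depth.

They agree exactly on constant-modulus data and differ on depth-varying
samples; the windowed estimate is always a g^2-weighted average of the
pointwise values inside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .contact_models import IndenterGeometry, unit_force_basis
from .curve_io import ForceCurve
from .errors import DataError, DomainError, WindowError

__all__ = [
    "ModulusProfile",
    "PowerLawProfileFit",
    "ESTIMATORS",
    "fit_average_modulus",
    "pointwise_average_modulus",
    "modulus_depth_profile",
    "fit_power_law_profile",
]

ESTIMATORS = ("windowed_ls", "pointwise")

MIN_WINDOW_POINTS = 5
_DEPTH_SLACK = 1.0 + 1e-9  # tolerate round-off at the window edge

POWER_LAW_B_BOUNDS = (-3.0, -1e-3)


@dataclass
class ModulusProfile:
    """Per-depth average modulus estimates for one curve.

    Masked entries mark depths where estimation failed (e.g. beyond the
    curve range); their modulus value is NaN.  ``diagnostics`` holds one
    dict per depth with at least ``n_points`` and ``residual_norm``.
    """

    depths: np.ndarray            # m, strictly increasing
    e_avg: np.ndarray             # Pa, NaN where masked
    estimator: str
    mask: np.ndarray              # True = entry invalid
    diagnostics: list[dict] = field(default_factory=list)
    pixel_index: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.e_avg = np.asarray(self.e_avg, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.depths.shape == self.e_avg.shape == self.mask.shape):
            raise DataError("depths, e_avg and mask must have equal shapes")
        if np.any(np.diff(self.depths) <= 0):
            raise DataError("profile depths must be strictly increasing")
        valid = self.e_avg[~self.mask]
        if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid < 0)):
            raise DataError("unmasked modulus values must be finite and >= 0")

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())


@dataclass(frozen=True)
class PowerLawProfileFit:
    """Fit of E(h) = a * h**b + c in SI units (a in Pa * m**(-b), c in Pa).

    ``degenerate`` marks profiles with no resolvable depth dependence, in
    which case c is the profile mean and a -> 0 by convention.
    """

    a: float
    b: float
    c: float
    rss: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def _window(curve: ForceCurve, depth: float) -> np.ndarray:
    if depth <= 0:
        raise DomainError(f"window depth must be > 0, got {depth}")
    if depth > curve.max_depth * _DEPTH_SLACK:
        raise DomainError(
            f"window depth {depth:.4g} m exceeds curve maximum {curve.max_depth:.4g} m"
        )
    return curve.h <= depth * _DEPTH_SLACK


def fit_average_modulus(
    curve: ForceCurve,
    geometry: IndenterGeometry,
    v: float,
    depth: float,
) -> float:
    """Best constant modulus (Pa) over the window 0 <= h <= depth.

    All supported force laws are linear in the modulus, F = E * g(h), so the
    least-squares problem has the closed-form solution
    E = sum(F_i * g_i) / sum(g_i**2); for the exact sphere g is the
    unit-modulus Sneddon force.  A negative estimate (possible on noisy
    near-contact data) is clipped to 0 with a warning.
    """
    inside = _window(curve, depth)
    n = int(inside.sum())
    if n < MIN_WINDOW_POINTS:
        raise WindowError(
            f"only {n} samples with h <= {depth:.4g} m; need >= {MIN_WINDOW_POINTS}"
        )
    h, F = curve.h[inside], curve.F[inside]
    g = np.asarray(unit_force_basis(geometry, v, h), dtype=float)
    denom = float(np.dot(g, g))
    if denom == 0.0:
        raise WindowError("shape function vanishes over the whole window (all depths 0?)")
    e = float(np.dot(F, g)) / denom
    if e < 0:
        warnings.warn(
            f"negative fitted modulus {e:.4g} Pa clipped to 0 (window <= {depth:.4g} m)",
            stacklevel=2,
        )
        e = 0.0
    return e


def pointwise_average_modulus(
    curve: ForceCurve,
    geometry: IndenterGeometry,
    v: float,
    depth: float,
) -> float:
    """Direct ratio estimate F(depth) / g(depth), interpolating F linearly.

    At a sampled depth this is exactly F_i / g(h_i); between samples the
    force is linearly interpolated.  Requires g(depth) > 0, i.e. a depth
    above the first positive sample.
    """
    _window(curve, depth)  # range validation
    positive = curve.h[curve.h > 0]
    if positive.size == 0 or depth < positive[0]:
        raise DomainError(
            f"depth {depth:.4g} m is below the first positive sample; pointwise ratio undefined"
        )
    g = float(np.asarray(unit_force_basis(geometry, v, depth), dtype=float))
    if not g > 0:
        raise DomainError(f"shape function is not positive at depth {depth:.4g} m")
    F = float(np.interp(depth, curve.h, curve.F))
    return F / g


_ESTIMATOR_FUNCS = {
    "windowed_ls": fit_average_modulus,
    "pointwise": pointwise_average_modulus,
}


def modulus_depth_profile(
    curve: ForceCurve,
    geometry: IndenterGeometry,
    v: float,
    depth_grid,
    estimator: str = "windowed_ls",
) -> ModulusProfile:
    """Estimate the modulus at every grid depth; failures become masked entries.

    Per-depth errors (depth beyond range, too-thin windows) do not abort the
    profile — the entry is masked, a warning is emitted, and the remaining
    depths are still computed.
    """
    depth_grid = np.asarray(depth_grid, dtype=float)
    if depth_grid.ndim != 1 or depth_grid.size == 0:
        raise DataError("depth grid must be a non-empty 1-D array")
    if np.any(np.diff(depth_grid) <= 0):
        raise DataError("depth grid must be strictly increasing")
    if estimator not in _ESTIMATOR_FUNCS:
        raise DataError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    func = _ESTIMATOR_FUNCS[estimator]

    e = np.full(depth_grid.shape, np.nan)
    mask = np.zeros(depth_grid.shape, dtype=bool)
    diags: list[dict] = []
    for j, depth in enumerate(depth_grid):
        try:
            e[j] = func(curve, geometry, v, float(depth))
        except (DomainError, WindowError) as exc:
            mask[j] = True
            warnings.warn(f"depth {depth:.4g} m masked: {exc}", stacklevel=2)
            diags.append({"n_points": 0, "residual_norm": np.nan, "error": str(exc)})
            continue
        inside = curve.h <= depth * _DEPTH_SLACK
        g = np.asarray(unit_force_basis(geometry, v, curve.h[inside]), dtype=float)
        resid = curve.F[inside] - e[j] * g
        diags.append(
            {"n_points": int(inside.sum()), "residual_norm": float(np.linalg.norm(resid))}
        )
    return ModulusProfile(
        depths=depth_grid,
        e_avg=e,
        estimator=estimator,
        mask=mask,
        diagnostics=diags,
        pixel_index=curve.pixel_index,
    )


def default_depth_grid(max_depth: float, m: int = 8, h_min_fraction: float = 0.1) -> np.ndarray:
    """M equally spaced window depths between h_min_fraction*max and max."""
    if m < 1:
        raise DataError(f"need at least one depth, got m={m}")
    if not max_depth > 0:
        raise DomainError(f"max_depth must be > 0, got {max_depth}")
    return np.linspace(h_min_fraction * max_depth, max_depth, m)


def _power_law_rss(b: float, h: np.ndarray, e: np.ndarray) -> tuple[float, float, float]:
    """Inner non-negative linear solve of E ~ a*h**b + c at fixed b."""
    design = np.column_stack([h**b, np.ones_like(h)])
    # column scaling keeps NNLS well conditioned across the ~1e9 span of h**b
    scale = np.linalg.norm(design, axis=0)
    coef, _ = nnls(design / scale, e)
    a, c = coef / scale
    rss = float(np.sum((design @ np.array([a, c]) - e) ** 2))
    return rss, float(a), float(c)


def fit_power_law_profile(
    profile: ModulusProfile,
    b_bounds: tuple[float, float] = POWER_LAW_B_BOUNDS,
    n_grid: int = 60,
) -> PowerLawProfileFit:
    """Constrained fit of E(h) = a*h**b + c with a, c >= 0 and b < 0.

    The exponent is found by a coarse grid over ``b_bounds`` followed by
    bounded scalar minimization; at each candidate b the amplitudes (a, c)
    come from an exact non-negative linear solve.  Deterministic.  A
    profile with no resolvable depth dependence returns a degenerate fit
    with c = mean and a -> 0.
    """
    valid = ~profile.mask
    h = profile.depths[valid]
    e = profile.e_avg[valid]
    if h.size < 4:
        raise DataError(f"power-law fit needs >= 4 unmasked points, got {h.size}")
    mean_e = float(np.mean(e))
    tss = float(np.sum((e - mean_e) ** 2))
    if tss <= (1e-8 * max(mean_e, 1e-300)) ** 2 * h.size:
        return PowerLawProfileFit(
            a=0.0, b=np.nan, c=mean_e, rss=tss, r_squared=1.0, n_points=int(h.size),
            degenerate=True,
        )

    b_lo, b_hi = b_bounds
    grid = np.linspace(b_lo, b_hi, n_grid)
    rss_grid = np.array([_power_law_rss(b, h, e)[0] for b in grid])
    k = int(np.argmin(rss_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda b: _power_law_rss(b, h, e)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    b_best = float(res.x)
    rss, a, c = _power_law_rss(b_best, h, e)
    # the bounded search can stall on a flat basin edge; keep the grid best
    if rss_grid[k] < rss:
        b_best = float(grid[k])
        rss, a, c = _power_law_rss(b_best, h, e)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    degenerate = a == 0.0
    if degenerate:
        c = mean_e
    return PowerLawProfileFit(
        a=a, b=b_best, c=c, rss=rss, r_squared=r2, n_points=int(h.size), degenerate=degenerate
    )
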