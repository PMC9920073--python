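"""Gaussian summaries of depth maps, (mu, sigma, h) vectors and trend labels.

Each depth slice of a map stack is condensed into a Gaussian (mu, sigma)
fitted to its unmasked modulus values, then into the dimensionless triple
(x, y, z) = (mu in kPa, sigma in kPa, h in nm).  Comparing the triples
across depths classifies the sample as softening / stiffening (trend of mu)
and homogenizing / heterogenizing (trend of sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, DegenerateDistributionError
from .map_stack import MapStack
from .units import KPA, NM

__all__ = [
    "GaussianSummary",
    "MixtureSpec",
    "MuSigmaHVector",
    "DepthBehavior",
    "fit_gaussian",
    "gaussian_density",
    "mixture_density",
    "musigmah_vector",
    "classify_depth_behavior",
    "summarize_stack",
    "summaries_to_frame",
]

FIT_METHODS = ("moments", "histogram_ls")

# scale constants of the dimensionless vector components
VECTOR_A = 1.0  # per kPa, x = A * mu
VECTOR_B = 1.0  # per kPa, y = B * sigma
VECTOR_C = 1.0  # per nm,  z = C * h


@dataclass(frozen=True)
class GaussianSummary:
    """Gaussian (mu, sigma) in Pa fitted to one depth map's value distribution."""

    mu: float
    sigma: float
    depth: float          # m
    n: int
    method: str = "moments"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataError(f"sigma must be >= 0, got {self.sigma}")
        if self.n < 2:
            raise DataError(f"a Gaussian summary needs n >= 2 values, got {self.n}")
        if not self.depth > 0:
            raise DataError(f"depth must be > 0, got {self.depth}")


@dataclass(frozen=True)
class MuSigmaHVector:
    """Dimensionless (x, y, z) = (mu/kPa, sigma/kPa, h/nm) summary triple."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise DataError("x and y components must be >= 0")
        if not self.z > 0:
            raise DataError("z component (depth) must be > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class MixtureSpec:
    """Indicator-weighted family of per-depth Gaussians.

    At any selected depth exactly one component has weight 1 and all others
    0, so the mixture reduces to that depth's single Gaussian — a compact
    notation for plotting the per-depth distributions comparatively.
    """

    components: tuple[GaussianSummary, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise DataError("mixture needs at least one component")
        depths = [c.depth for c in self.components]
        if len(set(depths)) != len(depths):
            raise DataError("mixture component depths must be distinct")

    def component_at(self, depth: float, rtol: float = 1e-9) -> GaussianSummary:
        for comp in self.components:
            if abs(comp.depth - depth) <= rtol * max(abs(depth), abs(comp.depth)):
                return comp
        known = [c.depth / NM for c in self.components]
        raise LookupError(
            f"no mixture component at depth {depth / NM:.6g} nm; known depths (nm): {known}"
        )


@dataclass(frozen=True)
class DepthBehavior:
    """Trend labels across depths: modulus trend and spread trend."""

    modulus_trend: str   # softening | stiffening | depth-independent
    sigma_trend: str     # homogenizing | heterogenizing | stable-sigma
    note: str = ""


def _gauss_pdf(e: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((e - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def fit_gaussian(
    values,
    method: str = "moments",
    depth: float | None = None,
) -> GaussianSummary:
    """Fit a Gaussian to a set of modulus values.

    ``moments`` (default): mu = sample mean, sigma = sample standard
    deviation with the n-1 denominator — exact and deterministic.
    ``histogram_ls``: nonlinear least squares of the Gaussian density
    against a density-normalized histogram with Freedman-Diaconis bins,
    provided for parity with curve-fitting workflows; it falls back to
    moments (with a warning) when fewer than 5 bins are available.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DataError(f"Gaussian fit needs >= 2 finite values, got {values.size}")
    if method not in FIT_METHODS:
        raise DataError(f"unknown fit method {method!r}; expected one of {FIT_METHODS}")
    depth = float(depth) if depth is not None else np.nan

    mu_m = float(np.mean(values))
    sigma_m = float(np.std(values, ddof=1))
    if method == "histogram_ls" and sigma_m > 0:
        counts, edges = np.histogram(values, bins="fd", density=True)
        if counts.size < 5:
            warnings.warn(
                f"histogram_ls: only {counts.size} Freedman-Diaconis bins; "
                "falling back to moments",
                stacklevel=2,
            )
        else:
            centers = 0.5 * (edges[:-1] + edges[1:])
            try:
                popt, _ = curve_fit(
                    _gauss_pdf, centers, counts, p0=[mu_m, sigma_m], maxfev=10000
                )
                return GaussianSummary(
                    mu=float(popt[0]),
                    sigma=abs(float(popt[1])),
                    depth=depth,
                    n=int(values.size),
                    method="histogram_ls",
                )
            except RuntimeError:
                warnings.warn(
                    "histogram_ls curve fit did not converge; falling back to moments",
                    stacklevel=2,
                )
    return GaussianSummary(
        mu=mu_m, sigma=sigma_m, depth=depth, n=int(values.size), method="moments"
    )


def gaussian_density(e, summary: GaussianSummary):
    """Evaluate the Gaussian density (1/Pa) of a summary; requires sigma > 0."""
    if summary.sigma == 0:
        raise DegenerateDistributionError(
            "density undefined for sigma = 0 (homogeneous distribution)"
        )
    e = np.asarray(e, dtype=float)
    out = _gauss_pdf(e, summary.mu, summary.sigma)
    return out if out.ndim else float(out)


def mixture_density(e, spec: MixtureSpec, depth: float):
    """Evaluate the indicator mixture at one depth.

    Selecting a depth keeps exactly that component (weight 1) and drops the
    rest, so the result equals :func:`gaussian_density` of the matching
    component and still integrates to 1.
    """
    comp = spec.component_at(depth)
    return gaussian_density(e, comp)


def musigmah_vector(summary: GaussianSummary) -> MuSigmaHVector:
    """Map a summary to its (x, y, z) triple: mu and sigma in kPa, depth in nm."""
    return MuSigmaHVector(
        x=VECTOR_A * summary.mu / KPA,
        y=VECTOR_B * summary.sigma / KPA,
        z=VECTOR_C * summary.depth / NM,
    )


def _trend(series: np.ndarray, rel_tol: float) -> tuple[str, str]:
    """Classify one component series as 'down', 'up' or 'flat' + a note.

    The call is based on the overall relative change from first to last
    depth, vetoed when any consecutive step moves significantly the other
    way — this makes the label invariant under refinement with intermediate
    depths that follow the same monotone trend.
    """
    start, end = series[0], series[-1]
    ref = max(abs(start), 1e-300)
    overall = (end - start) / ref
    steps = np.diff(series) / np.maximum(np.abs(series[:-1]), 1e-300)
    sig_up = bool(np.any(steps > rel_tol))
    sig_down = bool(np.any(steps < -rel_tol))
    if overall < -rel_tol:
        if sig_up:
            return "flat", "mixed trend: overall decrease with significant increasing steps"
        return "down", ""
    if overall > rel_tol:
        if sig_down:
            return "flat", "mixed trend: overall increase with significant decreasing steps"
        return "up", ""
    if sig_up and sig_down:
        return "flat", "mixed trend: significant steps in both directions"
    return "flat", ""


def classify_depth_behavior(
    vectors,
    rel_tol: float = 0.05,
) -> DepthBehavior:
    """Label the depth dependence of an ordered (mu, sigma, h) vector list.

    The modulus trend follows the x components (softening when mu drops by
    more than ``rel_tol`` relative, stiffening when it grows, otherwise
    depth-independent); the spread trend follows y analogously with labels
    homogenizing / heterogenizing / stable-sigma.
    """
    vectors = list(vectors)
    if len(vectors) < 2:
        raise DataError(f"classification needs >= 2 vectors, got {len(vectors)}")
    z = np.array([v.z for v in vectors])
    if np.any(np.diff(z) <= 0):
        raise DataError("vectors must be ordered by strictly increasing depth")
    x = np.array([v.x for v in vectors])
    y = np.array([v.y for v in vectors])

    x_label, x_note = _trend(x, rel_tol)
    y_label, y_note = _trend(y, rel_tol)
    modulus_trend = {"down": "softening", "up": "stiffening", "flat": "depth-independent"}[x_label]
    sigma_trend = {"down": "homogenizing", "up": "heterogenizing", "flat": "stable-sigma"}[y_label]
    note = "; ".join(s for s in (x_note, y_note) if s)
    return DepthBehavior(modulus_trend=modulus_trend, sigma_trend=sigma_trend, note=note)


def summarize_stack(stack: MapStack, method: str = "moments") -> list[GaussianSummary]:
    """One Gaussian summary per depth slice, from unmasked values only."""
    summaries = []
    for dmap in stack:
        vals = dmap.unmasked_values()
        summaries.append(fit_gaussian(vals, method=method, depth=dmap.depth))
    return summaries


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabulate summaries + vectors: depth_nm, mu_kPa, sigma_kPa, n, x, y, z."""
    rows = []
    for s in summaries:
        vec = musigmah_vector(s)
        rows.append(
            {
                "depth_nm": s.depth / NM,
                "mu_kPa": s.mu / KPA,
                "sigma_kPa": s.sigma / KPA,
                "n": s.n,
                "x": vec.x,
                "y": vec.y,
                "z": vec.z,
            }
        )
    return pd.DataFrame(rows, columns=["depth_nm", "mu_kPa", "sigma_kPa", "n", "x", "y", "z"])
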