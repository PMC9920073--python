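"""Depth-sliced average-modulus maps and their 3D stack.

One :class:`DepthMap` holds the per-pixel average modulus fitted over a
single window depth; an ordered set of M of them forms the
:class:`MapStack`, the 3D mechanical characterization of the scanned area.
Substrate-affected (or otherwise unwanted) regions are excluded by explicit
threshold masking — the cut is always a declared user choice, never a
silent default — and masked pixels stay out of every downstream
distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .contact_models import IndenterGeometry
from .curve_io import ForceVolumeGrid
from .depth_profile import modulus_depth_profile
from .errors import ConfigurationError, DataError, DomainError
from .units import KPA, NM

__all__ = [
    "DepthMap",
    "MapStack",
    "MaskRule",
    "build_depth_maps",
    "mask_by_threshold",
    "export_stack",
    "load_stack_long_csv",
]

NA_TOKEN = "NA"


@dataclass
class DepthMap:
    """One depth slice: values (Pa) and an exclusion mask on an (ny, nx) grid."""

    depth: float                       # m, > 0
    values: np.ndarray                 # Pa
    mask: np.ndarray                   # True = excluded
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise DataError("values and mask must be 2-D arrays of equal shape")
        if not self.depth > 0:
            raise DomainError(f"map depth must be > 0, got {self.depth}")
        valid = self.values[~self.mask]
        if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid < 0)):
            raise DataError("unmasked map values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def unmasked_values(self) -> np.ndarray:
        """Flat array of the values that survive the mask."""
        return self.values[~self.mask]


@dataclass
class MapStack:
    """M depth maps of identical shape, ordered by strictly increasing depth."""

    maps: list[DepthMap]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maps:
            raise DataError("a map stack needs at least one map")
        shape = self.maps[0].shape
        if any(m.shape != shape for m in self.maps):
            raise DataError("all maps in a stack must share one shape")
        depths = np.array([m.depth for m in self.maps])
        if np.any(np.diff(depths) <= 0):
            raise DataError("stack depths must be strictly increasing")

    @property
    def depths(self) -> np.ndarray:
        return np.array([m.depth for m in self.maps])

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i: int) -> DepthMap:
        return self.maps[i]


@dataclass(frozen=True)
class MaskRule:
    """Threshold rule: exclude values < min, > max, or above a quantile.

    Exactly one criterion must be set.  ``quantile`` q in (0, 1) masks the
    top (1-q) fraction of values — ties broken by value order then flat
    index, so exactly round(n*(1-q)) pixels go when n*q is integral.
    """

    min: float | None = None
    max: float | None = None
    quantile: float | None = None

    def __post_init__(self) -> None:
        set_fields = [f for f in (self.min, self.max, self.quantile) if f is not None]
        if len(set_fields) != 1:
            raise ConfigurationError("mask rule must set exactly one of min, max, quantile")
        if self.min is not None and not np.isfinite(self.min):
            raise ConfigurationError("min threshold must be finite")
        if self.max is not None and not np.isfinite(self.max):
            raise ConfigurationError("max threshold must be finite")
        if self.quantile is not None and not 0.0 < self.quantile < 1.0:
            raise ConfigurationError(f"quantile must be in (0, 1), got {self.quantile}")


def build_depth_maps(
    grid: ForceVolumeGrid,
    geometry: IndenterGeometry,
    v: float,
    depth_grid,
    estimator: str = "windowed_ls",
) -> MapStack:
    """Fit every pixel at every requested depth and assemble the stack.

    Pixels are processed independently (the result is identical for any
    evaluation order); empty or failed pixels are masked in the affected
    slices.  If no requested depth is reachable by at least half of the
    pixels the configuration is rejected up front, with the per-pixel
    maximum depths in the error message.
    """
    depth_grid = np.asarray(depth_grid, dtype=float)
    if depth_grid.ndim != 1 or depth_grid.size == 0:
        raise DataError("depth grid must be a non-empty 1-D array")
    if np.any(np.diff(depth_grid) <= 0):
        raise DataError("depth grid must be strictly increasing")
    ny, nx = grid.shape

    max_depths = np.full((ny, nx), np.nan)
    for r, c, curve in grid.iter_pixels():
        if curve is not None:
            max_depths[r, c] = curve.max_depth
    n_present = int(np.isfinite(max_depths).sum())
    if n_present == 0:
        raise ConfigurationError("force volume contains no curves")
    reach = np.array(
        [np.sum(max_depths[np.isfinite(max_depths)] >= d) for d in depth_grid]
    )
    if np.all(reach < 0.5 * grid.n_pixels):
        raise ConfigurationError(
            "no requested depth is reachable by >= 50% of pixels; "
            f"requested depths (nm): {np.round(depth_grid / NM, 3).tolist()}, "
            f"per-pixel max depths (nm): {np.round(max_depths / NM, 3).tolist()}"
        )

    values = np.full((depth_grid.size, ny, nx), np.nan)
    mask = np.ones((depth_grid.size, ny, nx), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-depth mask warnings are summarized below
        for r, c, curve in grid.iter_pixels():
            if curve is None:
                continue
            profile = modulus_depth_profile(curve, geometry, v, depth_grid, estimator=estimator)
            values[:, r, c] = profile.e_avg
            mask[:, r, c] = profile.mask
    n_failed = int(mask.sum()) - grid.n_missing * depth_grid.size
    if grid.n_missing or n_failed:
        warnings.warn(
            f"stack built with {grid.n_missing} empty pixel(s) and "
            f"{n_failed} failed pixel-depth fit(s) masked",
            stacklevel=2,
        )

    meta = {
        "estimator": estimator,
        "geometry_kind": geometry.kind,
        "poisson_ratio": v,
    }
    maps = [
        DepthMap(depth=float(d), values=values[j], mask=mask[j], metadata=dict(meta))
        for j, d in enumerate(depth_grid)
    ]
    return MapStack(maps, metadata=dict(meta))


def _apply_rule(dmap: DepthMap, rule: MaskRule) -> DepthMap:
    new_mask = dmap.mask.copy()
    vals = dmap.values
    if rule.min is not None:
        new_mask |= ~dmap.mask & (vals < rule.min)
    elif rule.max is not None:
        new_mask |= ~dmap.mask & (vals > rule.max)
    else:
        flat = vals[~dmap.mask]
        n = flat.size
        k = n - int(np.floor(rule.quantile * n))
        if k > 0 and n > 0:
            # mask the k largest; ties broken by value then flat index
            cand = np.flatnonzero(~dmap.mask.ravel())
            order = np.lexsort((cand, -vals.ravel()[cand]))
            chosen = cand[order[:k]]
            new_mask.ravel()[chosen] = True
    if new_mask.all():
        warnings.warn(
            f"mask rule {rule} excluded every pixel of the {dmap.depth / NM:.0f} nm map",
            stacklevel=3,
        )
    return replace(dmap, mask=new_mask, metadata={**dmap.metadata, "mask_rule": repr(rule)})


def mask_by_threshold(obj: DepthMap | MapStack, rule: MaskRule) -> DepthMap | MapStack:
    """Return a copy with the rule's exclusions OR-ed into the mask.

    Values are never modified, only masks, so successive (stricter) rules
    can only grow the excluded set.  Applied to a stack the rule acts
    per slice.
    """
    if isinstance(obj, DepthMap):
        return _apply_rule(obj, rule)
    if isinstance(obj, MapStack):
        return MapStack(
            [_apply_rule(m, rule) for m in obj.maps],
            metadata={**obj.metadata, "mask_rule": repr(rule)},
        )
    raise DataError(f"mask_by_threshold expects DepthMap or MapStack, got {type(obj).__name__}")


def export_stack(stack: MapStack, out_dir) -> dict[str, Path]:
    """Write the stack as TSV matrices + one long CSV + a JSON sidecar.

    Per depth: ``depth_<nm>nm.tsv`` with masked cells as the literal "NA".
    ``stack_long.csv`` holds (row, col, depth_nm, E_avg_kPa) for unmasked
    pixels only.  The sidecar records depths, units, estimator and mask
    counts.  Returns a name -> path map of everything written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    long_rows = []
    for dmap in stack:
        depth_nm = dmap.depth / NM
        tsv = out_dir / f"depth_{depth_nm:08.1f}nm.tsv"
        with tsv.open("w", encoding="utf-8") as fh:
            for r in range(dmap.shape[0]):
                cells = [
                    NA_TOKEN if dmap.mask[r, c] else f"{dmap.values[r, c] / KPA:.12g}"
                    for c in range(dmap.shape[1])
                ]
                fh.write("\t".join(cells) + "\n")
        written[tsv.name] = tsv
        rr, cc = np.nonzero(~dmap.mask)
        for r, c in zip(rr, cc):
            long_rows.append(
                {
                    "row": int(r),
                    "col": int(c),
                    "depth_nm": depth_nm,
                    "E_avg_kPa": dmap.values[r, c] / KPA,
                }
            )
    long_csv = out_dir / "stack_long.csv"
    pd.DataFrame(
        long_rows, columns=["row", "col", "depth_nm", "E_avg_kPa"]
    ).to_csv(long_csv, index=False, float_format="%.12g")
    written[long_csv.name] = long_csv

    sidecar = out_dir / "stack.json"
    sidecar.write_text(
        json.dumps(
            {
                "depths_nm": (stack.depths / NM).tolist(),
                "shape": list(stack.shape),
                "units": {"depth": "nm", "modulus": "kPa"},
                "estimator": stack.metadata.get("estimator"),
                "mask_counts": [m.n_masked for m in stack],
                "metadata": {
                    k: v for k, v in stack.metadata.items() if _json_safe(v)
                },
            },
            indent=1,
        )
        + "\n",
        encoding="utf-8",
    )
    written[sidecar.name] = sidecar
    return written


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_stack_long_csv(csv_path, shape: tuple[int, int]) -> MapStack:
    """Rebuild a stack from an exported long CSV (absent pixels -> masked)."""
    df = pd.read_csv(csv_path)
    ny, nx = shape
    maps = []
    for depth_nm, sub in df.groupby("depth_nm", sort=True):
        values = np.full((ny, nx), np.nan)
        mask = np.ones((ny, nx), dtype=bool)
        values[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["E_avg_kPa"].to_numpy() * KPA
        mask[sub["row"].to_numpy(), sub["col"].to_numpy()] = False
        maps.append(DepthMap(depth=float(depth_nm) * NM, values=values, mask=mask))
    return MapStack(maps)
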