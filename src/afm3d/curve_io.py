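"""Reading, writing and validation of force curves and force-volume grids.

On-disk dialect (UTF-8 delimited text, diff-able, instrument agnostic):

* header lines start with ``#`` and carry ``key: value`` pairs;
* a ``units:`` line is mandatory and names the column units, e.g.
  ``# units: nm nN`` for (h, F) columns or ``# units: nm nm`` for raw
  (z, d) piezo/deflection columns;
* an optional ``columns:`` line selects ``h F`` (default) or ``z d``;
* data rows are whitespace- or comma-separated numbers, two per line.

Grids are described by a JSON or YAML manifest (fields ``nx``, ``ny``,
optional ``pixel_size_nm`` and either ``paths`` — per-pixel curve files —
or ``packed_table`` — one long table with row/col columns).  Pixel
coordinates are 0-based (row, col), row-major, top-left origin.

Everything returned by the readers is in strict SI regardless of the
on-disk units.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .errors import (
    ConsistencyError,
    DataError,
    FormatError,
    ParameterError,
)
from .units import NM, NN, force_to_si, length_to_si

logger = logging.getLogger(__name__)

MIN_CURVE_SAMPLES = 8
_DIALECT_TAG = "afm3d force curve v1"

__all__ = [
    "ForceCurve",
    "ForceVolumeGrid",
    "ContactPoint",
    "read_force_curve",
    "write_force_curve",
    "read_force_volume",
    "write_force_volume",
    "deflection_to_force_indentation",
    "detect_contact_point",
]


@dataclass
class ForceCurve:
    """A single force-indentation record in SI units.

    ``h`` (m) must be non-negative and strictly increasing, ``F`` (N) finite,
    both at least :data:`MIN_CURVE_SAMPLES` long.  Use
    :meth:`from_samples` to build a curve from possibly unsorted /
    duplicated raw samples.
    """

    h: np.ndarray
    F: np.ndarray
    pixel_index: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.h.ndim != 1 or self.F.ndim != 1 or self.h.shape != self.F.shape:
            raise DataError("h and F must be 1-D arrays of equal length")
        if self.h.size < MIN_CURVE_SAMPLES:
            raise DataError(
                f"force curve needs >= {MIN_CURVE_SAMPLES} samples, got {self.h.size}"
            )
        if not np.all(np.isfinite(self.h)) or not np.all(np.isfinite(self.F)):
            raise DataError("force curve contains non-finite values")
        if np.any(self.h < 0):
            raise DataError("indentation depths must be >= 0")
        if np.any(np.diff(self.h) <= 0):
            raise DataError(
                "indentation depths must be strictly increasing; "
                "use ForceCurve.from_samples to repair raw data"
            )

    @classmethod
    def from_samples(
        cls,
        h,
        F,
        pixel_index: tuple[int, int] | None = None,
        metadata: dict | None = None,
    ) -> "ForceCurve":
        """Build a curve from raw samples, repairing order and duplicates.

        Rows are stably sorted by depth and duplicate depths are averaged
        (fixed-z dwell points carry force information, so they are merged,
        never dropped).  The number of repairs is logged.
        """
        h = np.asarray(h, dtype=float)
        F = np.asarray(F, dtype=float)
        order = np.argsort(h, kind="stable")
        n_moved = int(np.sum(order != np.arange(h.size)))
        h, F = h[order], F[order]
        uniq, inverse, counts = np.unique(h, return_inverse=True, return_counts=True)
        n_dup = int(h.size - uniq.size)
        if n_dup:
            F = np.bincount(inverse, weights=F) / counts
            h = uniq
        if n_moved or n_dup:
            logger.info(
                "repaired raw curve: %d rows reordered, %d duplicate depths averaged",
                n_moved,
                n_dup,
            )
        return cls(h, F, pixel_index=pixel_index, metadata=dict(metadata or {}))

    @property
    def max_depth(self) -> float:
        return float(self.h[-1])

    def __len__(self) -> int:
        return int(self.h.size)


@dataclass
class ForceVolumeGrid:
    """Row-major (ny, nx) grid of force curves; missing pixels are None.

    Coordinates are 0-based (row, col) with a top-left origin, matching
    array indexing.  ``pixel_size`` is the lateral step in metres, if known.
    """

    curves: list[list[ForceCurve | None]]
    pixel_size: float | None = None
    origin: str = "top-left"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.curves or not self.curves[0]:
            raise DataError("grid must have at least one row and one column")
        nx = len(self.curves[0])
        if any(len(row) != nx for row in self.curves):
            raise DataError("all grid rows must have the same length")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.curves), len(self.curves[0])

    def __getitem__(self, rc: tuple[int, int]) -> ForceCurve | None:
        r, c = rc
        return self.curves[r][c]

    def iter_pixels(self) -> Iterator[tuple[int, int, ForceCurve | None]]:
        for r, row in enumerate(self.curves):
            for c, curve in enumerate(row):
                yield r, c, curve

    @property
    def n_pixels(self) -> int:
        ny, nx = self.shape
        return ny * nx

    @property
    def n_missing(self) -> int:
        return sum(1 for _, _, cu in self.iter_pixels() if cu is None)


@dataclass(frozen=True)
class ContactPoint:
    """Result of contact-point detection: split index, x-offset, confidence."""

    index: int
    offset: float
    confident: bool


# ---------------------------------------------------------------------------
# single-curve text I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*(?P<key>[^:]+?)\s*:\s*(?P<value>.*?)\s*$")


def _parse_header_line(line: str, lineno: int, path: Path) -> tuple[str, str] | None:
    if ":" not in line:
        return None  # plain comment / dialect tag line
    m = _HEADER_RE.match(line)
    if m is None:
        raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
    return m.group("key").strip(), m.group("value").strip()


def _split_row(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_force_curve(path, format_hint: str | None = None) -> ForceCurve:
    """Read a single curve file, returning SI arrays.

    ``format_hint`` may force the column interpretation (``"h F"`` or
    ``"z d"``) when the file lacks a ``columns:`` line.  Raw (z, d) files
    additionally need a ``spring_constant_N_per_m`` header entry.
    """
    path = Path(path)
    meta: dict = {"source_file": str(path)}
    units_line: str | None = None
    columns = format_hint
    rows: list[tuple[float, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parsed = _parse_header_line(line, lineno, path)
                if parsed is None:
                    continue
                key, value = parsed
                if key == "units":
                    units_line = value
                elif key == "columns":
                    columns = value
                else:
                    meta[key] = value
                continue
            parts = _split_row(line)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric data {line!r}") from None
    if units_line is None:
        raise FormatError(f"{path}: missing mandatory '# units: ...' header line")
    unit_tokens = units_line.split()
    if len(unit_tokens) != 2:
        raise FormatError(f"{path}: 'units:' line must name two units, got {units_line!r}")
    if len(rows) < MIN_CURVE_SAMPLES:
        raise DataError(f"{path}: only {len(rows)} samples; need >= {MIN_CURVE_SAMPLES}")

    columns = (columns or "h F").strip()
    col_tokens = tuple(columns.split())
    data = np.asarray(rows, dtype=float)
    pixel = None
    if "pixel" in meta:
        r, c = (int(tok) for tok in str(meta.pop("pixel")).split())
        pixel = (r, c)
    if "spring_constant_N_per_m" in meta:
        meta["spring_constant_N_per_m"] = float(meta["spring_constant_N_per_m"])

    if col_tokens == ("h", "F"):
        h = data[:, 0] * length_to_si(unit_tokens[0])
        F = data[:, 1] * force_to_si(unit_tokens[1])
        return ForceCurve.from_samples(h, F, pixel_index=pixel, metadata=meta)
    if col_tokens == ("z", "d"):
        z = data[:, 0] * length_to_si(unit_tokens[0])
        d = data[:, 1] * length_to_si(unit_tokens[1])
        k = meta.get("spring_constant_N_per_m")
        if k is None:
            raise FormatError(
                f"{path}: raw (z, d) file needs a 'spring_constant_N_per_m:' header entry"
            )
        curve = deflection_to_force_indentation(z, d, k)
        curve.pixel_index = pixel
        curve.metadata.update(meta)
        return curve
    raise FormatError(f"{path}: unsupported columns spec {columns!r} (use 'h F' or 'z d')")


def write_force_curve(curve: ForceCurve, path) -> None:
    """Write a curve in the documented dialect (nm / nN columns).

    The round trip through :func:`read_force_curve` is lossless to better
    than 1e-12 relative.
    """
    path = Path(path)
    lines = [f"# {_DIALECT_TAG}", "# units: nm nN", "# columns: h F"]
    if curve.pixel_index is not None:
        lines.append(f"# pixel: {curve.pixel_index[0]} {curve.pixel_index[1]}")
    for key, value in curve.metadata.items():
        if key == "source_file":
            continue
        lines.append(f"# {key}: {value}")
    for h, f in zip(curve.h, curve.F):
        lines.append(f"{h / NM:.17g}\t{f / NN:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# force-volume grid I/O
# ---------------------------------------------------------------------------


def _load_manifest(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        manifest = yaml.safe_load(text)
    else:
        manifest = json.loads(text)
    if not isinstance(manifest, dict):
        raise FormatError(f"{path}: manifest must be a mapping")
    return manifest


def read_force_volume(manifest_path) -> ForceVolumeGrid:
    """Assemble a grid from a manifest (per-pixel files or a packed table)."""
    manifest_path = Path(manifest_path)
    manifest = _load_manifest(manifest_path)
    try:
        nx, ny = int(manifest["nx"]), int(manifest["ny"])
    except KeyError as exc:
        raise FormatError(f"{manifest_path}: manifest missing field {exc}") from None
    if nx < 1 or ny < 1:
        raise FormatError(f"{manifest_path}: grid dims must be >= 1, got ny={ny}, nx={nx}")
    pixel_size = manifest.get("pixel_size_nm")
    pixel_size = float(pixel_size) * NM if pixel_size is not None else None
    base = manifest_path.parent

    curves: list[list[ForceCurve | None]] = [[None] * nx for _ in range(ny)]
    if "packed_table" in manifest:
        _fill_from_packed(curves, base / manifest["packed_table"], ny, nx)
    elif "paths" in manifest:
        entries = manifest["paths"]
        if (
            isinstance(entries, list)
            and entries
            and isinstance(entries[0], list)
        ):  # nested [ny][nx] layout
            if len(entries) != ny or any(len(row) != nx for row in entries):
                raise ConsistencyError(
                    f"{manifest_path}: nested 'paths' shape does not match ny={ny}, nx={nx}"
                )
            flat = [
                {"row": r, "col": c, "path": p}
                for r, row in enumerate(entries)
                for c, p in enumerate(row)
            ]
        else:
            flat = entries
        for entry in flat:
            r, c = int(entry["row"]), int(entry["col"])
            if not (0 <= r < ny and 0 <= c < nx):
                raise ConsistencyError(
                    f"{manifest_path}: pixel ({r}, {c}) outside ny={ny}, nx={nx} grid"
                )
            p = base / entry["path"]
            if not p.exists():
                warnings.warn(f"missing pixel file {p}; pixel ({r}, {c}) left empty", stacklevel=2)
                continue
            curve = read_force_curve(p)
            curve.pixel_index = (r, c)
            curves[r][c] = curve
    else:
        raise FormatError(f"{manifest_path}: manifest needs either 'paths' or 'packed_table'")

    grid = ForceVolumeGrid(
        curves,
        pixel_size=pixel_size,
        metadata={"manifest": str(manifest_path), **manifest.get("metadata", {})},
    )
    if grid.n_missing:
        warnings.warn(
            f"force volume loaded with {grid.n_missing} empty pixel(s)", stacklevel=2
        )
    return grid


def _fill_from_packed(
    curves: list[list[ForceCurve | None]], table_path: Path, ny: int, nx: int
) -> None:
    units_line = None
    rows: list[tuple[int, int, float, float]] = []
    with table_path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parsed = _parse_header_line(line, lineno, table_path)
                if parsed and parsed[0] == "units":
                    units_line = parsed[1]
                continue
            parts = _split_row(line)
            if len(parts) != 4:
                raise FormatError(
                    f"{table_path}:{lineno}: packed table expects 4 columns (row col h F)"
                )
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])))
    if units_line is None:
        raise FormatError(f"{table_path}: missing mandatory '# units: ...' header line")
    lu, fu = units_line.split()
    lscale, fscale = length_to_si(lu), force_to_si(fu)
    by_pixel: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for r, c, h, f in rows:
        if not (0 <= r < ny and 0 <= c < nx):
            raise ConsistencyError(f"{table_path}: pixel ({r}, {c}) outside ny={ny}, nx={nx} grid")
        by_pixel.setdefault((r, c), []).append((h * lscale, f * fscale))
    for (r, c), samples in by_pixel.items():
        arr = np.asarray(samples)
        curves[r][c] = ForceCurve.from_samples(
            arr[:, 0], arr[:, 1], pixel_index=(r, c), metadata={"source_file": str(table_path)}
        )


def write_force_volume(grid: ForceVolumeGrid, out_dir, packed: bool = False) -> Path:
    """Write a grid plus manifest under ``out_dir``; returns the manifest path.

    ``packed=True`` emits one long (row, col, h, F) table instead of
    per-pixel files — more compact for large grids.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ny, nx = grid.shape
    manifest: dict = {"nx": nx, "ny": ny}
    if grid.pixel_size is not None:
        manifest["pixel_size_nm"] = grid.pixel_size / NM
    if packed:
        table = out_dir / "curves_packed.tsv"
        with table.open("w", encoding="utf-8") as fh:
            fh.write("# afm3d packed force volume v1\n# units: nm nN\n# columns: row col h F\n")
            for r, c, curve in grid.iter_pixels():
                if curve is None:
                    continue
                for h, f in zip(curve.h, curve.F):
                    fh.write(f"{r}\t{c}\t{h / NM:.17g}\t{f / NN:.17g}\n")
        manifest["packed_table"] = table.name
    else:
        entries = []
        for r, c, curve in grid.iter_pixels():
            if curve is None:
                continue
            name = f"pixel_r{r:03d}_c{c:03d}.txt"
            write_force_curve(curve, out_dir / name)
            entries.append({"row": r, "col": c, "path": name})
        manifest["paths"] = entries
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n", encoding="utf-8")
    return manifest_path


# ---------------------------------------------------------------------------
# raw deflection handling
# ---------------------------------------------------------------------------


def deflection_to_force_indentation(z, d, k: float, contact_offset: float = 0.0) -> ForceCurve:
    """Convert piezo displacement / deflection pairs to a force curve.

    F = k * d and h = (z - contact_offset) - d; samples with h < 0
    (pre-contact) are discarded.  ``k`` is the cantilever spring constant in
    N/m.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if z.shape != d.shape or z.ndim != 1:
        raise DataError("z and d must be 1-D arrays of equal length")
    if not k > 0:
        raise ParameterError(f"spring constant must be > 0, got {k}")
    F = k * d
    h = (z - contact_offset) - d
    keep = h >= 0
    if int(keep.sum()) < MIN_CURVE_SAMPLES:
        raise DataError(
            f"only {int(keep.sum())} samples at h >= 0 after conversion; "
            f"need >= {MIN_CURVE_SAMPLES}"
        )
    return ForceCurve.from_samples(h[keep], F[keep], metadata={"spring_constant_N_per_m": k})


def _seg_rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def detect_contact_point(
    x, signal, min_segment: int = 4, min_improvement: float = 0.10
) -> ContactPoint:
    """Locate the contact point by a two-segment residual-variance scan.

    Every candidate split divides the record into a pre-contact segment,
    modelled by a least-squares line, and a contact segment, modelled by an
    offset plus a (x - x_split)^(3/2) contact-law term; the split minimizing
    the pooled residual variance wins.  If the best split does not reduce
    the residual variance of the single-line (null) fit by at least
    ``min_improvement`` the result is flagged low-confidence with offset 0.
    Deterministic for fixed input; invariant under constant signal offsets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(signal, dtype=float)
    n = x.size
    if y.shape != x.shape or x.ndim != 1:
        raise DataError("x and signal must be 1-D arrays of equal length")
    if n < 32:
        raise DataError(f"contact-point detection needs >= 32 samples, got {n}")

    ones = np.ones(n)
    rss_null = _seg_rss(np.column_stack([ones, x]), y)
    splits = np.arange(min_segment, n - min_segment + 1)
    rss_two = np.empty(splits.size)
    for j, i in enumerate(splits):
        before = _seg_rss(np.column_stack([ones[:i], x[:i]]), y[:i])
        shifted = np.clip(x[i:] - x[i], 0.0, None)
        after = _seg_rss(np.column_stack([ones[i:], shifted**1.5]), y[i:])
        rss_two[j] = before + after

    best = int(np.argmin(rss_two))
    improvement = 0.0 if rss_null == 0.0 else 1.0 - rss_two[best] / rss_null
    if improvement <= min_improvement:
        return ContactPoint(index=0, offset=0.0, confident=False)
    idx = int(splits[best])
    return ContactPoint(index=idx, offset=float(x[idx]), confident=True)
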