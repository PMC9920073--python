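#!/usr/bin/env python
"""Convert exported AtomicJ-style force curves into the afm3d text dialect.

The deposited fibroblast test files are distributed as per-curve text
exports (two numeric columns per file: indentation depth and force, or
piezo displacement and deflection).  This helper walks a directory of such
files, parses every two-column numeric table it finds (header lines and
non-numeric rows are skipped), converts to the afm3d dialect and writes a
force-volume manifest so the dataset can be consumed by ``afm3d maps`` and
``scripts/acceptance.py``.

Pixels are assigned row-major in sorted-filename order unless the filenames
carry explicit indices.  Units of the source columns must be stated on the
command line (the deposited files do not embed them).

Example:
    python scripts/convert_atomicj.py downloaded/TestFiles \\
        --ny 64 --nx 64 --length-unit um --force-unit nN \\
        --out data/fibroblast
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

REPO_ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO_ROOT / "src"))

from afm3d.curve_io import (  # noqa: E402
    ForceCurve,
    ForceVolumeGrid,
    deflection_to_force_indentation,
    write_force_volume,
)
from afm3d.units import force_to_si, length_to_si  # noqa: E402


def parse_two_column(path: Path) -> np.ndarray | None:
    rows = []
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            continue
    if len(rows) < 8:
        return None
    return np.asarray(rows)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("src", type=Path, help="directory of downloaded curve files")
    parser.add_argument("--ny", type=int, required=True)
    parser.add_argument("--nx", type=int, required=True)
    parser.add_argument("--length-unit", default="nm")
    parser.add_argument("--force-unit", default="nN")
    parser.add_argument("--columns", choices=["h F", "z d"], default="h F",
                        help="interpretation of the two source columns")
    parser.add_argument("--spring-constant", type=float, default=0.01,
                        help="cantilever spring constant (N/m), used for z/d columns")
    parser.add_argument("--glob", default="*", help="filename pattern to include")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    lscale = length_to_si(args.length_unit)
    fscale = force_to_si(args.force_unit)
    files = sorted(p for p in args.src.glob(args.glob) if p.is_file())
    curves: list[ForceCurve] = []
    for path in files:
        data = parse_two_column(path)
        if data is None:
            print(f"skipping {path} (no parseable two-column table)", file=sys.stderr)
            continue
        if args.columns == "h F":
            curve = ForceCurve.from_samples(
                np.clip(data[:, 0] * lscale, 0, None), data[:, 1] * fscale,
                metadata={"source_file": str(path)},
            )
        else:
            curve = deflection_to_force_indentation(
                data[:, 0] * lscale, data[:, 1] * lscale, args.spring_constant
            )
            curve.metadata["source_file"] = str(path)
        curves.append(curve)

    expected = args.ny * args.nx
    if len(curves) != expected:
        print(
            f"warning: found {len(curves)} curves for a {args.ny}x{args.nx} grid "
            f"({expected} expected); missing pixels will be empty",
            file=sys.stderr,
        )
    grid_rows: list[list[ForceCurve | None]] = [
        [None] * args.nx for _ in range(args.ny)
    ]
    for i, curve in enumerate(curves[:expected]):
        r, c = divmod(i, args.nx)
        curve.pixel_index = (r, c)
        grid_rows[r][c] = curve
    manifest = write_force_volume(
        ForceVolumeGrid(grid_rows), args.out, packed=True
    )
    print(f"wrote {manifest}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
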