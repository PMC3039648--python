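"""Reading and writing lattice landscapes as plain-text grids.

Three formats are supported:

``csv``
    Comma-separated matrix for 2-D landscapes, rows = y, columns = x.
``asc``
    ESRI ASCII grid for 2-D landscapes (ncols/nrows/xllcorner/yllcorner/
    cellsize/NODATA_value header followed by the matrix).
``flat``
    Whitespace format for any dimensionality: first line the extents,
    then one value per line in row-major order.

Values are written with 17 significant digits, so csv and flat round-trips
reproduce a float64 landscape bit-exactly.  Binary landscapes are written as
0/1 integers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classic import BinaryLandscape
from .types import Landscape

__all__ = ["write_grid", "read_grid", "FORMATS"]

FORMATS = ("csv", "asc", "flat")

_NODATA = -9999


class GridParseError(ValueError):
    """Malformed grid file; the message names the offending line."""


def _array_of(land: "Landscape | BinaryLandscape") -> np.ndarray:
    if isinstance(land, BinaryLandscape):
        return land.suitability.astype(int)
    return land.values


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_grid(
    land: "Landscape | BinaryLandscape", path: "str | Path", format: str = "csv"
) -> Path:
    """Serialise a landscape to ``path`` in one of :data:`FORMATS`."""
    path = Path(path)
    arr = _array_of(land)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; use one of {FORMATS}")
    if format in ("csv", "asc") and arr.ndim != 2:
        raise ValueError(f"format {format!r} requires a 2-D landscape, got {arr.ndim}-D")

    lines: list[str] = []
    if format == "csv":
        for row in arr:
            lines.append(",".join(_fmt(v) for v in row))
    elif format == "asc":
        nrows, ncols = arr.shape
        lines += [
            f"ncols {ncols}",
            f"nrows {nrows}",
            "xllcorner 0.0",
            "yllcorner 0.0",
            "cellsize 1.0",
            f"NODATA_value {_NODATA}",
        ]
        for row in arr:
            lines.append(" ".join(_fmt(v) for v in row))
    else:  # flat
        lines.append(" ".join(str(e) for e in arr.shape))
        lines.extend(_fmt(v) for v in arr.ravel())
    path.write_text("\n".join(lines) + "\n")
    return path


def read_grid(path: "str | Path", format: str = "csv") -> Landscape:
    """Parse a grid file written by :func:`write_grid`.

    The inverse of ``write_grid`` for the csv and flat formats (bit-exact
    round trip); asc files are read back as their value matrix.  Binary
    landscapes come back as 0/1-valued real landscapes.  Read landscapes are
    flagged non-periodic, since periodicity cannot be inferred from a file.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; use one of {FORMATS}")
    lines = path.read_text().splitlines()

    def parse_row(line: str, lineno: int, sep: str | None) -> list[float]:
        try:
            return [float(t) for t in line.split(sep)]
        except ValueError as exc:
            raise GridParseError(f"{path}:{lineno}: unparsable value ({exc})") from None

    if format == "csv":
        rows = [parse_row(ln, i + 1, ",") for i, ln in enumerate(lines) if ln.strip()]
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise GridParseError(f"{path}: rows have inconsistent lengths {sorted(widths)}")
        return Landscape(np.asarray(rows, dtype=float), periodic=False)

    if format == "asc":
        header: dict[str, float] = {}
        body_start = 0
        for i, ln in enumerate(lines):
            toks = ln.split()
            if len(toks) == 2 and toks[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                try:
                    header[toks[0].lower()] = float(toks[1])
                except ValueError:
                    raise GridParseError(f"{path}:{i + 1}: bad header value {toks[1]!r}") from None
                body_start = i + 1
            else:
                break
        for key in ("ncols", "nrows"):
            if key not in header:
                raise GridParseError(f"{path}: missing required header field {key!r}")
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        rows = [
            parse_row(ln, body_start + j + 1, None)
            for j, ln in enumerate(lines[body_start:])
            if ln.strip()
        ]
        if len(rows) != nrows or any(len(r) != ncols for r in rows):
            raise GridParseError(
                f"{path}: body does not match header ({nrows} x {ncols})"
            )
        return Landscape(np.asarray(rows, dtype=float), periodic=False)

    # flat
    if not lines:
        raise GridParseError(f"{path}:1: empty file")
    try:
        extent = tuple(int(t) for t in lines[0].split())
    except ValueError:
        raise GridParseError(f"{path}:1: bad extent line {lines[0]!r}") from None
    ncells = int(np.prod(extent))
    vals = []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        try:
            vals.append(float(ln))
        except ValueError:
            raise GridParseError(f"{path}:{i}: unparsable value {ln!r}") from None
    if len(vals) != ncells:
        raise GridParseError(
            f"{path}: expected {ncells} values for extent {extent}, found {len(vals)}"
        )
    return Landscape(np.asarray(vals, dtype=float).reshape(extent), periodic=False)
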