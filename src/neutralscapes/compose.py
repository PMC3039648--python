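"""Landscape composition: gradients, normalisation, cropping, time slices.

Periodic fractal surfaces are building blocks; realistic study landscapes are
often assembled from them.  This module provides the standard assembly steps:
a piecewise-linear environmental gradient, min-max normalisation to [0, 1],
weighted linear combination (gradient + local fractal heterogeneity),
cropping to arbitrary (non-power-of-two) extents — which also removes
periodicity — and 2-D sections through higher-dimensional landscapes, e.g.
time slices of a 3-D spatio-temporal field.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .spectral import generate_symmetric
from .types import GridShape, HurstSpec, Landscape

__all__ = [
    "gradient_surface",
    "normalize01",
    "combine",
    "crop",
    "slice_axis",
    "next_power_of_two",
    "generate_for_extent",
]


def gradient_surface(extent: Sequence[int], axis: int = 0) -> Landscape:
    """Piecewise-linear gradient peaking at the centre of one axis.

    Cell ``i`` along the gradient axis (centre at integer coordinate ``i``,
    landscape middle at ``(n - 1) / 2``) takes value
    ``1 - |i - (n - 1)/2| / (n / 2)``: peaking at the centre and decreasing
    symmetrically towards (but not reaching) 0 at the edges, constant along
    the other axis.  All values lie in (0, 1]; for even ``n`` the two cells
    nearest the continuum centre attain the maximum ``1 - 1/n``.
    """
    extent = tuple(int(e) for e in extent)
    if len(extent) != 2:
        raise ValueError("gradient surfaces are 2-D")
    if not (0 <= axis < 2):
        raise ValueError(f"axis must be 0 or 1, got {axis}")
    n = extent[axis]
    if n < 2:
        raise ValueError("gradient axis needs at least 2 cells")
    coord = np.arange(n, dtype=float)
    profile = 1.0 - np.abs(coord - (n - 1) / 2.0) / (n / 2.0)
    values = profile[:, None] if axis == 0 else profile[None, :]
    values = np.broadcast_to(values, extent).copy()
    return Landscape(values=values, periodic=False)


def normalize01(land: Landscape) -> Landscape:
    """Affine rescaling so the minimum maps to 0 and the maximum to 1."""
    lo = float(land.values.min())
    hi = float(land.values.max())
    if hi == lo:
        raise ValueError("cannot normalise a constant landscape")
    return Landscape(
        values=(land.values - lo) / (hi - lo),
        periodic=land.periodic,
        hurst=land.hurst,
        seed=land.seed,
    )


def combine(a: Landscape, b: Landscape, w: float) -> Landscape:
    """Cellwise weighted sum ``w * a + (1 - w) * b``.

    Preserves [0, 1] bounds when both inputs respect them; used e.g. to
    overlay local fractal heterogeneity on a macro-scale gradient.
    """
    if a.extent != b.extent:
        raise ValueError(f"extent mismatch: {a.extent} vs {b.extent}")
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"weight must lie in [0, 1], got {w}")
    return Landscape(
        values=w * a.values + (1.0 - w) * b.values,
        periodic=a.periodic and b.periodic,
    )


def crop(land: Landscape, extent: Sequence[int]) -> Landscape:
    """Keep the first cells in each dimension (pure windowing, values untouched).

    Cropping below the source extent in any dimension breaks the seamless
    tiling, so the result is flagged non-periodic in that case.
    """
    extent = tuple(int(e) for e in extent)
    if len(extent) != land.ndim:
        raise ValueError(f"expected {land.ndim} extents, got {len(extent)}")
    for want, have in zip(extent, land.extent):
        if not (1 <= want <= have):
            raise ValueError(f"requested extent {want} exceeds source extent {have}")
    if extent == land.extent:
        return land
    window = tuple(slice(0, e) for e in extent)
    return Landscape(
        values=land.values[window].copy(),
        periodic=False,
        hurst=land.hurst,
        seed=land.seed,
    )


def slice_axis(land: Landscape, axis: int, index: int) -> Landscape:
    """Section of a landscape at one position along one axis.

    For a 3-D spatio-temporal field with the time axis last, successive
    slices are snapshots whose similarity is governed by the temporal Hurst
    exponent.
    """
    if not (0 <= axis < land.ndim):
        raise ValueError(f"axis {axis} outside [0, {land.ndim})")
    if not (0 <= index < land.extent[axis]):
        raise ValueError(f"index {index} outside [0, {land.extent[axis]})")
    return Landscape(
        values=np.take(land.values, index, axis=axis).copy(),
        periodic=land.periodic,
        hurst=land.hurst,
        seed=land.seed,
    )


def next_power_of_two(x: int) -> int:
    """Smallest power of two >= x (and >= 2)."""
    if x < 1:
        raise ValueError(f"extent must be positive, got {x}")
    return max(2, 1 << (int(x) - 1).bit_length())


def generate_for_extent(
    extent: Sequence[int],
    hurst: "float | HurstSpec",
    seed: int | None = None,
) -> Landscape:
    """Fractal landscape of an arbitrary extent.

    Generates a conjugate-symmetric landscape at the smallest power-of-two
    side length covering the largest requested extent, then crops to the
    requested window.  The result is non-periodic unless the extent happens
    to be the full power-of-two cube.
    """
    extent = tuple(int(e) for e in extent)
    n = next_power_of_two(max(extent))
    land = generate_symmetric(GridShape(n, len(extent)), hurst, seed=seed)
    return crop(land, extent)
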