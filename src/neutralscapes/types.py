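"""Core container types for lattice landscapes and their spectral representations.

Conventions used throughout the package:

* Lattices are stored as numpy arrays in row-major order. For 2-D landscapes
  axis 0 is the y-axis (rows) and axis 1 the x-axis (columns); cell ``i`` has
  its centre at integer coordinate ``i`` (0-based).
* Spectral lattices index Fourier coefficients by the integer wavenumber
  vector ``k`` with ``0 <= k_d < n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridShape",
    "HurstSpec",
    "SpectralField",
    "Landscape",
]


@dataclass(frozen=True)
class GridShape:
    """Shape of a hyper-cubic lattice: side length ``n`` in each of ``ndim`` dimensions.

    The side length must be a power of two so that the fast Fourier transform
    used by the spectral-synthesis generators is exact and efficient.
    """

    n: int
    ndim: int

    def __post_init__(self) -> None:
        if self.ndim < 1:
            raise ValueError(f"ndim must be >= 1, got {self.ndim}")
        if self.n < 2 or (self.n & (self.n - 1)) != 0:
            raise ValueError(f"side length must be a power of two >= 2, got {self.n}")

    @property
    def dims(self) -> tuple[int, ...]:
        return (self.n,) * self.ndim

    @property
    def ncells(self) -> int:
        return self.n**self.ndim


@dataclass(frozen=True)
class HurstSpec:
    """One Hurst exponent per dimension.

    An isotropic field is represented by ``ndim`` equal entries.  Each
    exponent must lie strictly in (0, 1): values near 0 give rough,
    heterogeneous surfaces, values near 1 smooth, self-similar ones.
    """

    per_dimension: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.per_dimension) == 0:
            raise ValueError("HurstSpec needs at least one exponent")
        for h in self.per_dimension:
            if not (0.0 < h < 1.0):
                raise ValueError(f"Hurst exponent must lie strictly in (0, 1), got {h}")

    @classmethod
    def isotropic(cls, h: float, ndim: int) -> "HurstSpec":
        return cls((float(h),) * ndim)

    @classmethod
    def of(cls, h: "float | Sequence[float] | HurstSpec", ndim: int) -> "HurstSpec":
        """Coerce a scalar, sequence, or HurstSpec to a spec of length ``ndim``."""
        if isinstance(h, HurstSpec):
            spec = h
        elif np.isscalar(h):
            spec = cls.isotropic(float(h), ndim)  # type: ignore[arg-type]
        else:
            spec = cls(tuple(float(x) for x in h))  # type: ignore[union-attr]
        if len(spec.per_dimension) != ndim:
            raise ValueError(
                f"expected {ndim} Hurst exponents, got {len(spec.per_dimension)}"
            )
        return spec

    @property
    def ndim(self) -> int:
        return len(self.per_dimension)

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.per_dimension)) == 1


@dataclass
class SpectralField:
    """Complex Fourier-coefficient lattice from which a landscape is synthesised."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        dims = self.coefficients.shape
        if len(set(dims)) != 1:
            raise ValueError(f"spectral lattice must be hyper-cubic, got shape {dims}")

    @property
    def shape(self) -> GridShape:
        return GridShape(self.coefficients.shape[0], self.coefficients.ndim)


@dataclass
class Landscape:
    """A real-valued lattice landscape.

    ``periodic`` records whether the landscape tiles seamlessly (true for
    uncropped spectral-synthesis output, which is periodic by construction of
    the discrete Fourier transform).  ``hurst`` and ``seed`` are provenance
    metadata; ``meta`` carries generator diagnostics such as the imaginary
    residual discarded after the inverse transform.
    """

    values: np.ndarray
    periodic: bool = True
    hurst: HurstSpec | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must all be finite")

    @property
    def extent(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def ncells(self) -> int:
        return int(self.values.size)
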