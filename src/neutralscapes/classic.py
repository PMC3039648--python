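"""Binary neutral landscape models: percolation maps, curdling, rank thresholding.

These are the classic habitat/non-habitat generators.  All three conserve the
requested number of suitable cells exactly: selection at every level draws an
exact count uniformly without replacement rather than running independent
Bernoulli trials, so the realised habitat proportion never fluctuates around
the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import Landscape

__all__ = [
    "BinaryLandscape",
    "CurdlingPlan",
    "random_percolation",
    "curdle",
    "threshold_by_rank",
]


@dataclass
class BinaryLandscape:
    """A boolean habitat map; ``h`` is the realised proportion of suitable cells."""

    suitability: np.ndarray

    def __post_init__(self) -> None:
        self.suitability = np.asarray(self.suitability, dtype=bool)

    @property
    def extent(self) -> tuple[int, ...]:
        return self.suitability.shape

    @property
    def ncells(self) -> int:
        return int(self.suitability.size)

    @property
    def count(self) -> int:
        return int(self.suitability.sum())

    @property
    def h(self) -> float:
        return self.count / self.ncells


def _round_half_even(x: float) -> int:
    # numpy.rint rounds half to even, the convention documented for all
    # exact-count selections in this module
    return int(np.rint(x))


@dataclass(frozen=True)
class CurdlingPlan:
    """Stage list for hierarchical curdling: (tile side length, selection proportion).

    Tile sides must be strictly decreasing, each dividing the previous, with
    the last stage at single-cell resolution (side 1).  The overall habitat
    proportion is the product of the stage proportions.
    """

    stages: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("curdling plan needs at least one stage")
        prev = None
        for side, p in self.stages:
            if side < 1:
                raise ValueError(f"tile side must be >= 1, got {side}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"stage proportion must lie in [0, 1], got {p}")
            if prev is not None:
                if side >= prev:
                    raise ValueError("tile sides must be strictly decreasing")
                if prev % side != 0:
                    raise ValueError(
                        f"tile side {side} does not divide the previous side {prev}"
                    )
            prev = side
        if self.stages[-1][0] != 1:
            raise ValueError("the final curdling stage must operate on single cells")

    @classmethod
    def of(cls, stages: Sequence[tuple[int, float]]) -> "CurdlingPlan":
        return cls(tuple((int(s), float(p)) for s, p in stages))

    @property
    def overall_proportion(self) -> float:
        out = 1.0
        for _, p in self.stages:
            out *= p
        return out


def random_percolation(
    extent: Sequence[int], h: float, seed: int | None = None
) -> BinaryLandscape:
    """Uniform-random habitat map with an exact suitable-cell count.

    Exactly ``round(h * ncells)`` cells are chosen suitable, uniformly
    without replacement.  Equivalent to flipping unsuitable cells one at a
    time until the target proportion is reached.
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"habitat proportion must lie in [0, 1], got {h}")
    extent = tuple(int(e) for e in extent)
    ncells = int(np.prod(extent))
    k = _round_half_even(h * ncells)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(ncells, size=k, replace=False)
    suit = np.zeros(ncells, dtype=bool)
    suit[chosen] = True
    return BinaryLandscape(suit.reshape(extent))


def curdle(
    extent: Sequence[int],
    plan: "CurdlingPlan | Sequence[tuple[int, float]]",
    seed: int | None = None,
) -> BinaryLandscape:
    """Hierarchical curdling: habitat assigned at successively finer tilings.

    At each stage every tile selected at the previous (coarser) stage is
    divided into child tiles of the stage's side length, and an exact count
    ``round(p * children)`` of those children is selected uniformly at
    random.  Cells inside tiles selected at the final (cell-resolution)
    stage are suitable.  Because every selection is an exact count, the
    total number of suitable cells is deterministic: the product of the
    per-parent counts across stages.
    """
    plan = plan if isinstance(plan, CurdlingPlan) else CurdlingPlan.of(plan)
    extent = tuple(int(e) for e in extent)
    ndim = len(extent)
    first_side = plan.stages[0][0]
    for e in extent:
        if e % first_side != 0:
            raise ValueError(
                f"extent {e} is not a multiple of the first-stage tile side {first_side}"
            )

    rng = np.random.default_rng(seed)
    suit = np.zeros(extent, dtype=bool)

    # selected tiles tracked as corner coordinates at the current resolution
    prev_side = None
    selected = [tuple(0 for _ in extent)]
    for side, p in plan.stages:
        if prev_side is None:
            # stage 1: tile the full landscape
            grids = [np.arange(0, e, side) for e in extent]
            mesh = np.meshgrid(*grids, indexing="ij")
            children_all = np.stack([m.ravel() for m in mesh], axis=1)
            groups = [children_all]
        else:
            factor = prev_side // side
            offsets = np.arange(factor) * side
            mesh = np.meshgrid(*([offsets] * ndim), indexing="ij")
            rel = np.stack([m.ravel() for m in mesh], axis=1)
            groups = [np.asarray(c) + rel for c in selected]

        new_selected: list[tuple[int, ...]] = []
        for children in groups:
            n_children = len(children)
            k = _round_half_even(p * n_children)
            if k == n_children:
                picked = np.arange(n_children)
            else:
                picked = rng.choice(n_children, size=k, replace=False)
            for i in picked:
                new_selected.append(tuple(int(c) for c in children[i]))
        selected = new_selected
        prev_side = side

    if selected:
        corners = np.asarray(selected)
        suit[tuple(corners.T)] = True
    return BinaryLandscape(suit)


def threshold_by_rank(land: Landscape, k: int) -> BinaryLandscape:
    """Binarise a continuous landscape by marking its ``k`` highest cells suitable.

    Ties at the cut are broken by flattened (row-major) cell index, a stable
    deterministic order; with continuous-valued inputs ties essentially
    never occur.
    """
    n = land.ncells
    if not (0 <= k <= n):
        raise ValueError(f"suitable-cell count {k} outside [0, {n}]")
    flat = land.values.ravel()
    suit = np.zeros(n, dtype=bool)
    if k > 0:
        # stable sort descending by value, ascending by index among ties
        order = np.lexsort((np.arange(n), -flat))
        suit[order[:k]] = True
    return BinaryLandscape(suit.reshape(land.extent))
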