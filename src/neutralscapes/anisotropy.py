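"""Directional Moran's I correlograms on the torus and anisotropy statistics.

Spectral-synthesis landscapes are periodic, so spatial autocorrelation is
assessed on connectivity networks wrapped into a torus.  Four networks are
used, one per direction: links at 0° (vertical), 45° (bottom-left to
upper-right diagonal), 90° (horizontal) and 135° (bottom-right to upper-left
diagonal), with the angle measured clockwise from the x-axis.  Each network
partitions the n x n lattice into n disjoint cycles of length n, and distance
between two cells is the hop count along their shared cycle (minimal of the
two wrap directions), so distance class d on a diagonal network means d
diagonal steps.

Moran's I for distance class d is

    I(d) = N / S0 * sum_ij w_ij(d) (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with w_ij(d) = 1 exactly when cells i and j are d hops apart on the network
and 0 otherwise.  Positive values indicate positive autocorrelation; the
expectation under random relabelling of cell values is -1/(N-1).

Anisotropy is summarised by differences of Moran's I in perpendicular
directions: the cardinal difference I(0°) - I(90°) (positive when the
north-south autocorrelation exceeds east-west) and the diagonal difference
I(45°) - I(135°).  An isotropic process gives both statistics a median of
zero over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Landscape

__all__ = [
    "DIRECTIONS",
    "DirectionalNetwork",
    "build_network",
    "morans_i",
    "morans_i_profile",
    "permutation_significance",
    "correlogram",
    "delta_statistics",
]

#: Direction labels (degrees clockwise from the x-axis) mapped to the lattice
#: step of one link, in (row, column) = (y, x) order.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (1, 0),  # vertical
    45: (1, 1),  # bottom-left to upper-right diagonal
    90: (0, 1),  # horizontal
    135: (1, -1),  # bottom-right to upper-left diagonal
}


@dataclass(frozen=True)
class DirectionalNetwork:
    """Cycle cover of the n x n torus along one direction.

    ``cycles`` is an (n, n) integer array: row c lists the flat (row-major)
    cell indices of cycle c, in traversal order of the direction's step.
    Every cell appears in exactly one cycle.
    """

    theta: int
    n: int
    cycles: np.ndarray

    @property
    def ncells(self) -> int:
        return self.n * self.n


def build_network(n: int, theta: int) -> DirectionalNetwork:
    """Build the toroidal cycle network for one of the four directions."""
    if n < 2:
        raise ValueError(f"side length must be >= 2, got {n}")
    if theta not in DIRECTIONS:
        raise ValueError(f"unsupported direction {theta}; use one of {sorted(DIRECTIONS)}")
    dr, dc = DIRECTIONS[theta]
    steps = np.arange(n)
    if theta == 0:
        # cycle c = column c, traversed down the rows
        rows = np.tile(steps, (n, 1))
        cols = np.tile(steps[:, None], (1, n))
    elif theta == 90:
        rows = np.tile(steps[:, None], (1, n))
        cols = np.tile(steps, (n, 1))
    else:
        # diagonal steps: cycle c starts at (0, c) and advances (dr, dc) mod n
        t = steps[None, :]
        rows = np.broadcast_to((t * dr) % n, (n, n))
        cols = (steps[:, None] + t * dc) % n
    flat = rows * n + cols
    return DirectionalNetwork(theta=theta, n=n, cycles=flat.astype(np.intp))


def _centered(land: Landscape) -> np.ndarray:
    x = np.asarray(land.values, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("directional Moran's I requires a square 2-D landscape")
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("Moran's I is undefined for a constant landscape")
    return z


def _morans_from_z(z: np.ndarray, net: DirectionalNetwork, d: int) -> float:
    # On a cycle cover every cell has one neighbour d hops forward; summing
    # z_i * z_{i+d} over all cells counts each unordered pair once for
    # d < n/2 and twice for d = n/2, matching S0 (2N and N links
    # respectively), so I reduces to the same ratio in both cases.
    zc = z.ravel()[net.cycles]
    sdir = float(np.sum(zc * np.roll(zc, -d, axis=1)))
    return sdir / float(np.sum(z * z))


def morans_i(land: Landscape, net: DirectionalNetwork, d: int) -> float:
    """Moran's I of a landscape at hop-distance class ``d`` on one network."""
    n = net.n
    if not (1 <= d <= n // 2):
        raise ValueError(f"distance class {d} outside [1, {n // 2}]")
    z = _centered(land)
    if z.shape[0] != n:
        raise ValueError("network side length does not match the landscape")
    return _morans_from_z(z, net, d)


def morans_i_profile(land: Landscape, net: DirectionalNetwork) -> np.ndarray:
    """Moran's I for every distance class 1..n/2 (index 0 holds class 1)."""
    z = _centered(land)
    n = net.n
    if z.shape[0] != n:
        raise ValueError("network side length does not match the landscape")
    zc = z.ravel()[net.cycles]
    denom = float(np.sum(z * z))
    out = np.empty(n // 2)
    for d in range(1, n // 2 + 1):
        out[d - 1] = float(np.sum(zc * np.roll(zc, -d, axis=1))) / denom
    return out


def permutation_significance(
    land: Landscape,
    net: DirectionalNetwork,
    d: int,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, str]:
    """Permutation test of Moran's I against the random-relabelling null.

    Cell values are randomly permuted over the lattice ``permutations``
    times; the empirical p-value is ``(r + 1) / (M + 1)`` with ``r`` the
    count of permuted statistics at least as extreme as the observed one in
    its smaller tail.  The flag is ``"high"`` if the observed I exceeds the
    upper ``1 - alpha/2`` empirical quantile of the null, ``"low"`` if it
    falls below the ``alpha/2`` quantile, else ``"ns"``.
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    z = _centered(land)
    n = net.n
    if not (1 <= d <= n // 2):
        raise ValueError(f"distance class {d} outside [1, {n // 2}]")
    observed = _morans_from_z(z, net, d)
    rng = np.random.default_rng(seed)
    flat = z.ravel()
    null = np.empty(permutations)
    for m in range(permutations):
        zp = rng.permutation(flat).reshape(z.shape)
        null[m] = _morans_from_z(zp, net, d)
    r_hi = int(np.sum(null >= observed))
    r_lo = int(np.sum(null <= observed))
    p = (min(r_hi, r_lo) + 1) / (permutations + 1)
    if observed > np.quantile(null, 1.0 - alpha / 2.0):
        flag = "high"
    elif observed < np.quantile(null, alpha / 2.0):
        flag = "low"
    else:
        flag = "ns"
    return float(p), flag


def correlogram(
    land: Landscape,
    directions: tuple[int, ...] = (0, 45, 90, 135),
    max_distance: int | None = None,
    permutations: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Directional correlogram table for a square 2-D landscape.

    Returns a tidy frame with columns ``direction``, ``distance``, ``I`` and,
    when ``permutations > 0``, ``p`` and ``flag`` from the permutation test.
    Distance classes run from 1 to ``max_distance`` (default n/2).
    """
    z = _centered(land)
    n = z.shape[0]
    dmax = n // 2 if max_distance is None else int(max_distance)
    if not (1 <= dmax <= n // 2):
        raise ValueError(f"max distance {dmax} outside [1, {n // 2}]")
    rows = []
    for theta in directions:
        net = build_network(n, theta)
        prof = morans_i_profile(land, net)
        for d in range(1, dmax + 1):
            row: dict = {"direction": theta, "distance": d, "I": prof[d - 1]}
            if permutations > 0:
                p, flag = permutation_significance(
                    land, net, d, permutations=permutations, alpha=alpha, seed=seed
                )
                row["p"] = p
                row["flag"] = flag
            rows.append(row)
    return pd.DataFrame(rows)


def delta_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Perpendicular-direction differences of Moran's I per distance class.

    ``delta_cardinal = I(0°) - I(90°)`` and
    ``delta_diagonal = I(45°) - I(135°)``.  The input is a correlogram table
    containing all four directions.
    """
    present = set(table["direction"].unique())
    missing = set(DIRECTIONS) - present
    if missing:
        raise ValueError(f"correlogram table is missing directions {sorted(missing)}")
    wide = table.pivot_table(index="distance", columns="direction", values="I")
    out = pd.DataFrame(
        {
            "distance": wide.index,
            "delta_cardinal": (wide[0] - wide[90]).to_numpy(),
            "delta_diagonal": (wide[45] - wide[135]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out
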