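import numpy as np
import pytest

from neutralscapes.anisotropy import DIRECTIONS
from neutralscapes.types import Landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def checkerboard4():
    """4x4 lattice of alternating +1/-1 values."""
    vals = (np.indices((4, 4)).sum(axis=0) % 2) * 2.0 - 1.0
    return Landscape(vals)


def brute_force_morans(values: np.ndarray, theta: int, d: int) -> float:
    """Literal double-loop Moran's I on the directional torus network.

    Independent oracle: enumerates every ordered cell pair, walks the
    direction's step map to find the pair's minimal wrap hop distance, and
    applies the Moran's I formula with identity weights directly.
    """
    n = values.shape[0]
    dr, dc = DIRECTIONS[theta]
    z = values - values.mean()
    ncells = n * n
    num = 0.0
    s0 = 0
    cells = [(r, c) for r in range(n) for c in range(n)]
    for r1, c1 in cells:
        for r2, c2 in cells:
            if (r1, c1) == (r2, c2):
                continue
            dist = None
            for t in range(1, n):
                if ((r1 + t * dr) % n, (c1 + t * dc) % n) == (r2, c2):
                    dist = min(t, n - t)
                    break
            if dist == d:
                num += z[r1, c1] * z[r2, c2]
                s0 += 1
    return ncells * num / (s0 * float(np.sum(z * z)))
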