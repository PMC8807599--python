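"""D3Q19 lattice stencil: discrete velocities, weights, and opposites.

Lattice units use c = dx/dt = 1, so particles traverse exactly one cell per
step.  The sound speed of the D3Q19 model is c_s = c/sqrt(3).
"""

from __future__ import annotations

import numpy as np

#: lattice speed (dx = dt = 1)
C = 1.0
#: lattice sound speed
CS = C / np.sqrt(3.0)
#: c_s^2, appears in equilibria and the equation of state
CS2 = C * C / 3.0

#: the 19 discrete velocities: rest, 6 axis, 12 edge directions
E = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

#: quadrature weights: 1/3 rest, 1/18 axis, 1/36 edge
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

Q = len(E)


def _build_opposites() -> np.ndarray:
    opp = np.empty(Q, dtype=np.int64)
    for i, e in enumerate(E):
        (j,) = np.where((E == -e).all(axis=1))[0]
        opp[i] = j
    return opp


#: index map to the opposite direction, e[OPP[i]] == -e[i]
OPP = _build_opposites()
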