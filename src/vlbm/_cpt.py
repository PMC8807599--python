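"""Closest-point transform kernel for the far signed-distance field.

Vertices outside the exact interface band are processed in order of
increasing distance to the interface; each takes the exact surface foot
point of whichever already-finalized 26-neighbor yields the smallest
Euclidean distance, then a reverse relaxation pass polishes ordering
artifacts.  Feet are genuine surface points, so every value is an upper
bound on the true distance; for smooth surfaces the inherited foot is
within O(dx^2) of the optimal one.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def _relax_pass(order, done, foot, phi, xs, ys, zs, nx, ny, nz):
    for m in range(order.shape[0]):
        f = order[m]
        k = f % nz
        j = (f // nz) % ny
        i = f // (nz * ny)
        px = xs[i]
        py = ys[j]
        pz = zs[k]
        best = phi[f] if done[f] else np.inf
        bq0 = foot[f, 0]
        bq1 = foot[f, 1]
        bq2 = foot[f, 2]
        for di in (-1, 0, 1):
            ii = i + di
            if ii < 0 or ii >= nx:
                continue
            for dj in (-1, 0, 1):
                jj = j + dj
                if jj < 0 or jj >= ny:
                    continue
                for dk in (-1, 0, 1):
                    kk = k + dk
                    if kk < 0 or kk >= nz:
                        continue
                    g = (ii * ny + jj) * nz + kk
                    if not done[g] or g == f:
                        continue
                    q0 = foot[g, 0]
                    q1 = foot[g, 1]
                    q2 = foot[g, 2]
                    d = np.sqrt((px - q0) ** 2 + (py - q1) ** 2
                                + (pz - q2) ** 2)
                    if d < best:
                        best = d
                        bq0 = q0
                        bq1 = q1
                        bq2 = q2
        if best < np.inf:
            phi[f] = best
            foot[f, 0] = bq0
            foot[f, 1] = bq1
            foot[f, 2] = bq2
            done[f] = 1


def propagate_feet(order, done, foot, phi, xs, ys, zs, nx, ny, nz) -> None:
    """Outward sweep + reverse polish; operates on flat arrays in place."""
    _relax_pass(order, done, foot, phi, xs, ys, zs, nx, ny, nz)
    _relax_pass(order[::-1].copy(), done, foot, phi, xs, ys, zs, nx, ny, nz)
    _relax_pass(order, done, foot, phi, xs, ys, zs, nx, ny, nz)
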