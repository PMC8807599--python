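"""Fused numba kernels for the hot loop (collision + streaming).

Numerically identical to the NumPy reference path in :mod:`vlbm.core`
(cross-checked in the test suite); exists purely for speed on desk-scale
benchmark runs.  The streaming gather uses a precomputed flat-offset table
``delta[z, i]`` (valid for x, y away from the domain border, any z — the
periodic z wrap is folded into the table); border columns take the general
wrapped-index path.
"""

from __future__ import annotations

import numba
import numpy as np

from .stencil import E, OPP, W

_EX = np.ascontiguousarray(E[:, 0].astype(np.float64))
_EY = np.ascontiguousarray(E[:, 1].astype(np.float64))
_EZ = np.ascontiguousarray(E[:, 2].astype(np.float64))
_EI = np.ascontiguousarray(E)
_W = np.ascontiguousarray(W)
_OPP = np.ascontiguousarray(OPP)
Q = len(W)


def make_delta(shape) -> np.ndarray:
    """Flat upwind-gather offsets: delta[z, i] for interior x, y columns."""
    nx, ny, nz, q = shape
    delta = np.empty((nz, Q), dtype=np.int64)
    for z in range(nz):
        for i in range(Q):
            ex, ey, ez = E[i]
            delta[z, i] = ((-ex) * ny * nz + (-ey) * nz
                           + ((z - ez) % nz - z)) * q
    return delta


@numba.njit(cache=True, fastmath=True)
def collide_kernel(n, n_post, P, tau, ax, ay, az):
    nx, ny, nz, q = n.shape
    inv_tau = 1.0 / tau
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if P[x, y, z] >= 1.0:
                    for i in range(q):
                        n_post[x, y, z, i] = 0.0
                    continue
                N = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    v = n[x, y, z, i]
                    N += v
                    mx += v * _EX[i]
                    my += v * _EY[i]
                    mz += v * _EZ[i]
                if N > 1e-300:
                    ux = mx / N
                    uy = my / N
                    uz = mz / N
                else:
                    ux = uy = uz = 0.0
                usq = ux * ux + uy * uy + uz * uz
                for i in range(q):
                    eu = _EX[i] * ux + _EY[i] * uy + _EZ[i] * uz
                    neq = N * _W[i] * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
                    ea = _EX[i] * ax + _EY[i] * ay + _EZ[i] * az
                    F = 3.0 * _W[i] * N * ea
                    n_post[x, y, z, i] = n[x, y, z, i] - inv_tau * (n[x, y, z, i] - neq) + F


@numba.njit(cache=True, fastmath=True)
def stream_kernel(n_post, n_out, P, cA, cB, simple, delta):
    """Gather streaming with periodic wrap on every axis.

    ``simple[x, y, z]`` marks cells whose full upwind stencil is pure fluid
    (weights 1/0): those use the flat-offset fast path when their x, y
    column is interior.  Solid cells are skipped — ``n_out`` must hold
    zeros there already (guaranteed by the initialization).
    """
    nx, ny, nz, q = n_post.shape
    flat = n_post.reshape(nx * ny * nz * q)
    for x in range(nx):
        for y in range(ny):
            inner = 0 < x < nx - 1 and 0 < y < ny - 1
            for z in range(nz):
                if P[x, y, z] >= 1.0:
                    continue
                if simple[x, y, z] and inner:
                    base = ((x * ny + y) * nz + z) * q
                    for i in range(q):
                        n_out[x, y, z, i] = flat[base + delta[z, i] + i]
                elif simple[x, y, z]:
                    for i in range(q):
                        xu = (x - _EI[i, 0]) % nx
                        yu = (y - _EI[i, 1]) % ny
                        zu = (z - _EI[i, 2]) % nz
                        n_out[x, y, z, i] = n_post[xu, yu, zu, i]
                else:
                    for i in range(q):
                        xu = (x - _EI[i, 0]) % nx
                        yu = (y - _EI[i, 1]) % ny
                        zu = (z - _EI[i, 2]) % nz
                        n_out[x, y, z, i] = (cA[x, y, z, i] * n_post[xu, yu, zu, i]
                                             + cB[x, y, z, i] * n_post[x, y, z, _OPP[i]])


@numba.njit(cache=True, fastmath=True)
def fused_step_kernel(n_post_old, n_post_new, P, cA, cB, simple,
                      tau, ax, ay, az, delta):
    """One pull-scheme update: gather (stream) + BGK collide + forcing.

    Operates on post-collision states; numerically identical to
    ``stream_kernel`` followed by ``collide_kernel`` but in one memory pass.
    Solid cells are never touched (their populations stay zero).
    """
    nx, ny, nz, q = n_post_old.shape
    flat = n_post_old.reshape(nx * ny * nz * q)
    inv_tau = 1.0 / tau
    n_loc = np.empty(Q)
    for x in range(nx):
        for y in range(ny):
            inner = 0 < x < nx - 1 and 0 < y < ny - 1
            for z in range(nz):
                if P[x, y, z] >= 1.0:
                    continue
                if simple[x, y, z] and inner:
                    base = ((x * ny + y) * nz + z) * q
                    for i in range(q):
                        n_loc[i] = flat[base + delta[z, i] + i]
                elif simple[x, y, z]:
                    for i in range(q):
                        xu = (x - _EI[i, 0]) % nx
                        yu = (y - _EI[i, 1]) % ny
                        zu = (z - _EI[i, 2]) % nz
                        n_loc[i] = n_post_old[xu, yu, zu, i]
                else:
                    for i in range(q):
                        xu = (x - _EI[i, 0]) % nx
                        yu = (y - _EI[i, 1]) % ny
                        zu = (z - _EI[i, 2]) % nz
                        n_loc[i] = (cA[x, y, z, i] * n_post_old[xu, yu, zu, i]
                                    + cB[x, y, z, i] * n_post_old[x, y, z, _OPP[i]])
                N = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    v = n_loc[i]
                    N += v
                    mx += v * _EX[i]
                    my += v * _EY[i]
                    mz += v * _EZ[i]
                if N > 1e-300:
                    ux = mx / N
                    uy = my / N
                    uz = mz / N
                else:
                    ux = uy = uz = 0.0
                usq = ux * ux + uy * uy + uz * uz
                for i in range(q):
                    eu = _EX[i] * ux + _EY[i] * uy + _EZ[i] * uz
                    neq = N * _W[i] * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
                    ea = _EX[i] * ax + _EY[i] * ay + _EZ[i] * az
                    n_post_new[x, y, z, i] = (n_loc[i] - inv_tau * (n_loc[i] - neq)
                                              + 3.0 * _W[i] * N * ea)
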