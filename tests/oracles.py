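"""Independent reference implementations used only to cross-check the solver.

Deliberately written in a different style (push streaming via np.roll, no
shared helpers) so they exercise none of the package's own code paths.
"""

import numpy as np

# an independently typed D3Q19 table (same convention: rest, axis, edge)
E_ORACLE = np.array(
    [[0, 0, 0],
     [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
     [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
     [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
     [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1]])
W_ORACLE = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)


def node_bgk_step(f, tau, accel=(0.0, 0.0, 0.0)):
    """One collide-and-stream update of a standard node-based D3Q19 BGK
    lattice on a fully periodic box.  ``f``: (nx, ny, nz, 19)."""
    rho = f.sum(axis=-1)
    mom = np.einsum("xyzq,qa->xyza", f, E_ORACLE.astype(float))
    u = np.where((rho > 0)[..., None], mom / np.where(rho > 0, rho, 1.0)[..., None], 0.0)
    usq = (u * u).sum(axis=-1)
    f_post = np.empty_like(f)
    a = np.asarray(accel, float)
    for q in range(19):
        eu = u @ E_ORACLE[q]
        feq = rho * W_ORACLE[q] * (1 + 3 * eu + 4.5 * eu**2 - 1.5 * usq)
        F = 3.0 * W_ORACLE[q] * rho * (E_ORACLE[q] @ a)
        f_post[..., q] = f[..., q] - (f[..., q] - feq) / tau + F
    out = np.empty_like(f)
    for q in range(19):
        out[..., q] = np.roll(f_post[..., q], shift=tuple(E_ORACLE[q]),
                              axis=(0, 1, 2))
    return out


def monte_carlo_solid_fraction(cell_lo, dx, is_solid, npts=1_000_000, seed=0):
    """MC estimate of the solid volume fraction of one cubic cell."""
    rng = np.random.default_rng(seed)
    pts = cell_lo + rng.random((npts, 3)) * dx
    return is_solid(pts).mean()


def monte_carlo_fluid_centroid(cell_lo, dx, is_solid, npts=1_000_000, seed=0):
    """MC estimate of the fluid-part centroid of one cubic cell."""
    rng = np.random.default_rng(seed)
    pts = cell_lo + rng.random((npts, 3)) * dx
    keep = ~is_solid(pts)
    return pts[keep].mean(axis=0)
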