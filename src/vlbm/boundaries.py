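"""Driving and open-boundary handling.

Two driving modes are supported, matching how pulsatile vessel flows are
specified in practice:

* **body force** — a pulsatile pressure gradient ``P(t) = P_s + Re(P_o e^{iwt})``
  applied as a uniform acceleration with periodic ends (the classic pulsatile
  pipe set-up);
* **velocity profiles** — measured-style space-time velocity profiles imposed
  at the inlet and outlet slices through a non-equilibrium extrapolation
  scheme adapted to volumetric populations.

Coarse measured profiles (a handful of slices x time points per cycle) are
interpolated to solver resolution: monotone piecewise-cubic Hermite (PCHIP)
in time with periodic wrap, bilinear in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .stencil import E

__all__ = [
    "PressureWaveform",
    "ProfileSet",
    "apply_periodic",
    "body_force_from_waveform",
    "velocity_bc_noneq_extrapolation",
    "interpolate_profiles",
]


@dataclass(frozen=True)
class PressureWaveform:
    """Pulsatile pressure gradient ``P(t) = P_s + Re(P_o e^{i omega t})``.

    ``P_s``/``P_o`` in Pa/m (steady magnitude / oscillatory amplitude),
    ``omega`` in 1/s.
    """

    P_s: float
    P_o: float
    omega: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def __call__(self, t):
        return self.P_s + self.P_o * np.cos(self.omega * np.asarray(t))

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega


def body_force_from_waveform(w: PressureWaveform, rho: float, t: float,
                             axis: int = 2) -> np.ndarray:
    """Acceleration vector a(t) = P(t)/rho along the pipe axis (SI units).

    The caller converts to lattice units (multiply by dt^2/dx)."""
    a = np.zeros(3)
    a[axis] = w(t) / rho
    return a


def apply_periodic(n_post: np.ndarray, axis: int) -> np.ndarray:
    """Wrap-around upwind reads across both ends of ``axis``.

    The streaming operators in :mod:`vlbm.core` gather with periodic index
    arithmetic on every axis, so a periodic end needs no ghost fill — this
    helper exists for explicit ghost-layer workflows and simply returns the
    field (the wrap is the identity on the stored array).
    """
    del axis
    return n_post


class ProfileSet:
    """Measured-style velocity profiles: slices x time points x in-plane grid.

    ``u[s, t, i, j]`` is the axial velocity (m/s) at axial station
    ``axial_positions[s]``, sample time ``times[t]`` (within one ``period``)
    and in-plane coordinates ``(x[i], y[j])``.
    """

    def __init__(self, axial_positions, times, period, x, y, u):
        self.axial_positions = np.asarray(axial_positions, float)
        self.times = np.asarray(times, float)
        self.period = float(period)
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.u = np.asarray(u, float)
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if self.u.shape != (len(self.axial_positions), len(self.times),
                            len(self.x), len(self.y)):
            raise ValueError("u shape inconsistent with axes")
        self._interp: dict[int, PchipInterpolator] = {}

    # -- plain-text round trip: one CSV per slice + a small manifest --------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        def fmt(arr):
            return ",".join(repr(float(v)) for v in arr)

        with open(d / "manifest.txt", "w") as fh:
            fh.write(f"period = {self.period!r}\n")
            fh.write("axial_positions = " + fmt(self.axial_positions) + "\n")
            fh.write("times = " + fmt(self.times) + "\n")
            fh.write("x = " + fmt(self.x) + "\n")
            fh.write("y = " + fmt(self.y) + "\n")
        for s in range(len(self.axial_positions)):
            flat = self.u[s].reshape(len(self.times), -1)
            np.savetxt(d / f"slice_{s:03d}.csv", flat, delimiter=",")

    @classmethod
    def load(cls, directory) -> "ProfileSet":
        d = Path(directory)
        kv = {}
        for line in open(d / "manifest.txt"):
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        period = float(kv["period"])
        axial = np.array([float(v) for v in kv["axial_positions"].split(",")])
        times = np.array([float(v) for v in kv["times"].split(",")])
        x = np.array([float(v) for v in kv["x"].split(",")])
        y = np.array([float(v) for v in kv["y"].split(",")])
        u = np.stack([
            np.loadtxt(d / f"slice_{s:03d}.csv", delimiter=",", ndmin=2)
            .reshape(len(times), len(x), len(y))
            for s in range(len(axial))
        ])
        return cls(axial, times, period, x, y, u)

    def _time_interpolator(self, s: int) -> PchipInterpolator:
        # periodic wrap: append the first sample at t0 + period so the PCHIP
        # segment covering the cycle seam is well-defined
        if s not in self._interp:
            t_ext = np.r_[self.times, self.times[0] + self.period]
            u_ext = np.concatenate([self.u[s], self.u[s, :1]], axis=0)
            self._interp[s] = PchipInterpolator(t_ext, u_ext, axis=0)
        return self._interp[s]


def interpolate_profiles(ps: ProfileSet, t: float, axial_position: float,
                         x_out=None, y_out=None) -> np.ndarray:
    """Velocity cross-section at arbitrary time (periodic wrap) and station.

    Time: monotone cubic Hermite over the sample instants (no overshoot of
    sample extrema).  Axial station: nearest sampled slice (stations are
    sparse; measured slices are treated as exact).  In-plane: bilinear onto
    ``(x_out, y_out)`` if given, else the native sample grid.
    """
    lo, hi = ps.axial_positions.min(), ps.axial_positions.max()
    span = max(hi - lo, np.spacing(hi))
    if axial_position < lo - 1e-9 * span or axial_position > hi + 1e-9 * span:
        raise ValueError("axial position outside the sampled slice range")
    s = int(np.argmin(np.abs(ps.axial_positions - axial_position)))
    t_wrapped = ps.times[0] + (t - ps.times[0]) % ps.period
    plane = ps._time_interpolator(s)(t_wrapped)
    if x_out is None:
        return plane
    itp = RegularGridInterpolator((ps.x, ps.y), plane, bounds_error=False,
                                  fill_value=0.0)
    X, Y = np.meshgrid(np.asarray(x_out), np.asarray(y_out), indexing="ij")
    return itp(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)


def velocity_bc_noneq_extrapolation(n: np.ndarray, P: np.ndarray,
                                    u_wall: np.ndarray, slice_index: int,
                                    neighbor_index: int, axis: int = 2) -> None:
    """Impose a velocity profile on one boundary slice, in place.

    Guo-style non-equilibrium extrapolation adapted to volumetric
    populations: the slice populations are set to the equilibrium at the
    imposed velocity with the interior neighbor's density, plus the
    neighbor's non-equilibrium part, all scaled by the cell's fluid fraction,

        n_i(bc) = (1 - P_bc) [ f_i^eq(rho_nb, u_w) + f_i(nb) - f_i^eq(rho_nb, u_nb) ]

    ``u_wall``: (mx, my, 3) lattice-unit velocity on the slice.  Solid cells
    on the slice are left untouched.
    """
    from .core import equilibrium_f

    if not (-n.shape[axis] <= neighbor_index < n.shape[axis]):
        raise ValueError("missing interior neighbor slice")
    sl = [slice(None)] * 3
    sl[axis] = slice_index
    nb = [slice(None)] * 3
    nb[axis] = neighbor_index
    sl, nb = tuple(sl), tuple(nb)

    P_bc, P_nb = P[sl], P[nb]
    open_bc = P_bc < 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_nb = n[nb] / (1.0 - P_nb)[..., None]
    f_nb = np.where((P_nb < 1.0)[..., None], f_nb, 0.0)
    rho_nb = f_nb.sum(axis=-1)
    mom = np.einsum("xyq,qa->xya", f_nb, E.astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        u_nb = mom / rho_nb[..., None]
    u_nb = np.where((rho_nb > 0)[..., None], u_nb, 0.0)

    feq_wall = equilibrium_f(rho_nb, u_wall)
    feq_nb = equilibrium_f(rho_nb, u_nb)
    new = (1.0 - P_bc)[..., None] * (feq_wall + f_nb - feq_nb)
    n[sl] = np.where(open_bc[..., None], new, n[sl])
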