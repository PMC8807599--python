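"""The D3Q19 volumetric lattice Boltzmann engine.

Cell-based populations ``n_i = (1 - P) f_i`` evolve by BGK collision and a
volumetric streaming step in which the bounce-back no-slip condition is
embedded: the solid fraction ``P`` of each cell regulates how many particles
a cell can emit or accept, so arbitrarily oriented walls need no special
boundary logic.  Two streaming operators are provided:

* ``stream_original`` — the first-formulation operator
  ``n_i(x, t+dt) = (1-P(x)) n'_i(x - e_i dt) + P(x + e_{i*} dt) n'_{i*}(x)``,
  retained for comparison;
* ``stream_generalized`` — the operator that distinguishes the two
  boundary-to-boundary scenarios with a switch ``G_i(x) = [P(upwind) < P(x)]``
  and is exactly mass-conserving pairwise for any pair of fluid fractions.

All functions here are straightforward vectorized NumPy and serve as the
readable reference; :class:`Simulation` transparently switches to the fused
numba kernels in :mod:`vlbm._kernels` for production runs (the two paths are
cross-checked in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry, SOLID
from .stencil import CS2, E, OPP, Q, W

__all__ = [
    "equilibrium",
    "equilibrium_f",
    "forcing_term",
    "collide",
    "macroscopic",
    "stream_generalized",
    "stream_original",
    "streaming_coefficients",
    "Simulation",
]

_EF = E.astype(float)


def equilibrium(N, u) -> np.ndarray:
    """Equilibrium populations for incompressible flow (c = 1).

    ``n_i^eq = N w_i [1 + 3 e_i.u + 9/2 (e_i.u)^2 - 3/2 u.u]``; satisfies
    ``sum n^eq = N`` and ``sum e_i n^eq = N u`` identically.
    """
    N = np.asarray(N, float)
    u = np.asarray(u, float)
    eu = u @ _EF.T                     # (..., 19)
    usq = (u * u).sum(axis=-1)[..., None]
    return N[..., None] * W * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)


# the same quadratic equilibrium applies to node-based distributions f_i
equilibrium_f = equilibrium


def forcing_term(N, a) -> np.ndarray:
    """Forcing populations for a uniform acceleration ``a`` (lattice units).

    ``F_i = 3 w_i N (e_i . a) dt`` with dt = 1; the sign is fixed so the
    injected momentum is ``sum_i e_i F_i = +N a`` per step while
    ``sum_i F_i = 0``.
    """
    N = np.asarray(N, float)
    a = np.asarray(a, float)
    return 3.0 * N[..., None] * W * (a @ _EF.T)


def collide(n: np.ndarray, tau: float, F: np.ndarray | None = None) -> np.ndarray:
    """BGK relaxation toward the local equilibrium, plus optional forcing.

    ``n' = n - (n - n^eq)/tau + F`` with ``n^eq`` built from this cell's own
    moments N and u.  ``tau`` must exceed 1/2 (positive viscosity).
    """
    if tau <= 0.5:
        raise ValueError("relaxation time tau must be > 1/2")
    N = n.sum(axis=-1)
    mom = n @ _EF
    with np.errstate(divide="ignore", invalid="ignore"):
        u = mom / N[..., None]
    u = np.where((N > 1e-300)[..., None], u, 0.0)
    out = n - (n - equilibrium(N, u)) / tau
    if F is not None:
        out = out + F
    return out


def macroscopic(n: np.ndarray, P: np.ndarray, rho0: float = 1.0):
    """Density, velocity and pressure fields from the populations.

    ``rho = sum n_i / (1 - P)``, ``u = sum e_i n_i / sum n_i``,
    ``p - p0 = c_s^2 (rho - rho0)``.  Solid cells report rho = u = 0.
    """
    Nf = n.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = Nf / (1.0 - P)
        u = (n @ _EF) / Nf[..., None]
    rho = np.where(P < 1.0, rho, 0.0)
    u = np.where((Nf > 1e-300)[..., None], u, 0.0)
    dp = CS2 * (rho - rho0)
    return rho, u, dp


def streaming_coefficients(P: np.ndarray, mode: str = "generalized"):
    """Precompute the per-direction gather weights of the streaming step.

    For every receiving cell x and direction i (upwind cell A = x - e_i) the
    update is ``n_i(x) = cA[..., i] n'_i(A) + cB[..., i] n'_{i*}(x)``:

    * generalized, G=1 (P(A) < P(x)): cA = (1-P(x))/(1-P(A)), cB = 0
    * generalized, G=0 (P(A) >= P(x)): cA = 1, cB = (P(A)-P(x))/(1-P(x))
    * original: cA = 1-P(x), cB = P(A)

    Solid receiving cells carry zero weights.  P is static, so these arrays
    are computed once per run.
    """
    shape = P.shape + (Q,)
    cA = np.zeros(shape)
    cB = np.zeros(shape)
    fluid_side = P < 1.0
    cA[..., 0] = np.where(fluid_side, 1.0, 0.0)
    for i in range(1, Q):
        PA = np.roll(P, shift=tuple(E[i]), axis=(0, 1, 2))
        if mode == "generalized":
            G = PA < P
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(G, (1.0 - P) / (1.0 - PA), 1.0)
                b = np.where(G, 0.0, (PA - P) / (1.0 - P))
        elif mode == "original":
            a = 1.0 - P
            b = PA
        else:
            raise ValueError("mode must be 'generalized' or 'original'")
        cA[..., i] = np.where(fluid_side, a, 0.0)
        cB[..., i] = np.where(fluid_side, b, 0.0)
    return cA, cB


def _stream(n_post: np.ndarray, coeffs) -> np.ndarray:
    cA, cB = coeffs
    out = np.empty_like(n_post)
    out[..., 0] = cA[..., 0] * n_post[..., 0]
    for i in range(1, Q):
        nA = np.roll(n_post[..., i], shift=tuple(E[i]), axis=(0, 1, 2))
        out[..., i] = cA[..., i] * nA + cB[..., i] * n_post[..., OPP[i]]
    return out


def stream_generalized(n_post: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Volumetric streaming with the G-switch (exact pairwise conservation).

    Upwind reads wrap periodically on every axis; a closed domain must carry
    at least one solid padding layer so the wrap is inert, and an open axis
    is either genuinely periodic or overwritten by a velocity boundary
    condition after the step.
    """
    return _stream(n_post, streaming_coefficients(P, "generalized"))


def stream_original(n_post: np.ndarray, P: np.ndarray) -> np.ndarray:
    """The first-formulation streaming operator (comparison only)."""
    return _stream(n_post, streaming_coefficients(P, "original"))


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

@dataclass
class StepDiagnostics:
    step: int
    total_mass: float
    max_speed: float


class Simulation:
    """Owns the populations and advances them in time (lattice units).

    Parameters
    ----------
    cells : voxelized geometry (solid fractions et al.)
    tau : BGK relaxation time, > 1/2 (a warning is issued below 0.505,
        where stability becomes the user's responsibility)
    streaming : "generalized" (default) or "original"
    force : callable ``step -> (3,) lattice acceleration`` or constant
        vector or None
    velocity_bc : optional callable ``(n, step) -> None`` applied in place
        after streaming (e.g. inlet/outlet profile imposition)
    prefer : "numba" (fused kernels; default) or "numpy" (reference path)
    """

    def __init__(self, cells: CellGeometry, tau: float,
                 streaming: str = "generalized", force=None,
                 velocity_bc=None, prefer: str = "numba"):
        if tau <= 0.5:
            raise ValueError("tau must exceed 1/2")
        if tau < 0.505:
            warnings.warn("tau < 0.505: stability is marginal at this "
                          "relaxation time", stacklevel=2)
        self.cells = cells
        self.P = np.ascontiguousarray(cells.P)
        self.tau = float(tau)
        self.streaming = streaming
        self._coeffs = streaming_coefficients(self.P, streaming)
        # cells whose whole upwind stencil is pure fluid: plain advection
        simple = self.P == 0.0
        for i in range(1, Q):
            simple &= np.roll(self.P, shift=tuple(E[i]), axis=(0, 1, 2)) == 0.0
        self._simple = simple
        self.force = force
        self.velocity_bc = velocity_bc
        self.t = 0
        self.n = equilibrium(1.0 - self.P, np.zeros(self.P.shape + (3,)))
        self.n[cells.cls == SOLID] = 0.0
        self._kern = None
        self._delta = None
        if prefer == "numba":
            try:
                from . import _kernels
                self._kern = _kernels
                self._delta = _kernels.make_delta(self.n.shape)
            except Exception:  # pragma: no cover - numba always present here
                self._kern = None
        self._scratch = np.zeros_like(self.n)
        self._scratch2: np.ndarray | None = None

    # -- initialization ----------------------------------------------------
    def set_velocity_field(self, u_lat: np.ndarray) -> None:
        """Start from equilibrium at a prescribed lattice velocity field."""
        self.n = equilibrium(1.0 - self.P, u_lat)
        self.n[self.cells.cls == SOLID] = 0.0

    # -- stepping ----------------------------------------------------------
    def _accel(self, step: int) -> np.ndarray:
        if self.force is None:
            return np.zeros(3)
        if callable(self.force):
            return np.asarray(self.force(step), float)
        return np.asarray(self.force, float)

    def step(self) -> None:
        """One update: collide -> stream -> velocity BCs."""
        a = self._accel(self.t)
        if self._kern is not None:
            self._kern.collide_kernel(self.n, self._scratch, self.P,
                                      self.tau, a[0], a[1], a[2])
            self._kern.stream_kernel(self._scratch, self.n, self.P,
                                     self._coeffs[0], self._coeffs[1],
                                     self._simple, self._delta)
        else:
            N = self.n.sum(axis=-1)
            F = forcing_term(N, a) if a.any() else None
            n_post = collide(self.n, self.tau, F)
            n_post[self.P >= 1.0] = 0.0
            self.n = _stream(n_post, self._coeffs)
        if self.velocity_bc is not None:
            self.velocity_bc(self.n, self.t)
        self.t += 1

    def run_cycle(self, steps: int, sample_steps=(), callback=None) -> None:
        """Advance one pulsation cycle, sampling pre-collision states.

        ``callback(j, n_pre)`` is invoked for the j-th entry of
        ``sample_steps`` with the pre-collision populations at that step.
        When the fused numba kernel is available (and no velocity BC is
        active) the cycle runs on post-collision buffers in a single memory
        pass per step, materializing pre-collision states only at the
        sampled instants; results are identical to repeated :meth:`step`.
        """
        sample = sorted(set(sample_steps))
        if self._kern is None or self.velocity_bc is not None:
            si = 0
            for k in range(steps):
                if si < len(sample) and k == sample[si]:
                    callback(si, self.n)
                    si += 1
                self.step()
            return
        K = self._kern
        cA, cB = self._coeffs
        if self._scratch2 is None:
            # solid cells must be zero: the kernels never write them but the
            # streaming gather reads them as upwind neighbors
            self._scratch2 = np.zeros_like(self.n)
        post_old, post_new = self._scratch, self._scratch2
        si = 0
        if sample and sample[0] == 0:
            callback(0, self.n)
            si = 1
        a = self._accel(self.t)
        K.collide_kernel(self.n, post_old, self.P, self.tau, a[0], a[1], a[2])
        for k in range(1, steps):
            a = self._accel(self.t + k)
            if si < len(sample) and k == sample[si]:
                K.stream_kernel(post_old, self.n, self.P, cA, cB,
                                self._simple, self._delta)
                callback(si, self.n)
                si += 1
                K.collide_kernel(self.n, post_new, self.P, self.tau,
                                 a[0], a[1], a[2])
            else:
                K.fused_step_kernel(post_old, post_new, self.P, cA, cB,
                                    self._simple, self.tau, a[0], a[1], a[2],
                                    self._delta)
            post_old, post_new = post_new, post_old
        K.stream_kernel(post_old, self.n, self.P, cA, cB, self._simple,
                        self._delta)
        self._scratch, self._scratch2 = post_old, post_new
        self.t += steps

    def run(self, nsteps: int, check_every: int = 0) -> list[StepDiagnostics]:
        """Advance ``nsteps``; optionally record and sanity-check diagnostics.

        Raises ``RuntimeError`` on NaN or negative total particle count;
        warns once if the flow leaves the low-Mach regime (max |u| > 0.1 c).
        """
        log: list[StepDiagnostics] = []
        warned = False
        for _ in range(nsteps):
            self.step()
            if check_every and self.t % check_every == 0:
                mass = self.total_mass()
                if not np.isfinite(mass):
                    raise RuntimeError(f"non-finite mass at step {self.t}")
                Nf = self.n.sum(axis=-1)
                if (Nf < -1e-9).any():
                    raise RuntimeError(f"negative particle count at step {self.t}")
                _, u, _ = macroscopic(self.n, self.P)
                smax = float(np.sqrt((u * u).sum(-1)).max())
                if smax > 0.1 and not warned:
                    warnings.warn(f"max lattice speed {smax:.3f} exceeds 0.1 c "
                                  "(low-Mach assumption strained)", stacklevel=2)
                    warned = True
                log.append(StepDiagnostics(self.t, mass, smax))
        return log

    # -- observables -------------------------------------------------------
    def total_mass(self) -> float:
        return float(self.n.sum())

    def moments(self):
        """Current (rho, u, p - p0) fields."""
        return macroscopic(self.n, self.P)
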