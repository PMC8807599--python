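"""Closed-form pulsatile laminar pipe flow (Womersley flow).

The axial velocity in a rigid circular pipe of radius ``R`` driven by the
pressure gradient ``P(t) = P_s + Re(P_o e^{i w t})`` (force per unit volume,
Pa/m, applied along the axis) is

    u(r, t) = P_s R^2 / (4 mu) (1 - r^2/R^2)
            + Re{ P_o R^2 / (i mu a^2) [1 - J0(a (r/R) i^{3/2}) / J0(a i^{3/2})] e^{i w t} }

where ``a = R sqrt(w / nu)`` is the Womersley number and ``J0`` the Bessel
function of the first kind of order zero at complex argument.  This module is
the analytic reference ("oracle") the solver benchmarks compare against: it
also provides the analytic shear stress ``sigma = mu du/dr`` (and the doubled
``2 mu du/dr`` variant some texts use) and the wall value sigma_w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

__all__ = ["WomersleyParams", "womersley_number", "womersley_velocity", "womersley_shear"]

#: i^{3/2} on the principal branch, e^{i 3 pi / 4}
I32 = np.exp(1j * 3.0 * np.pi / 4.0)


def womersley_number(R: float, omega: float, nu: float) -> float:
    """Womersley number ``alpha = R sqrt(omega / nu)``."""
    if R <= 0 or omega <= 0 or nu <= 0:
        raise ValueError("R, omega and nu must be positive")
    return R * np.sqrt(omega / nu)


@dataclass(frozen=True)
class WomersleyParams:
    """Everything the analytic solution needs, SI units.

    Parameters
    ----------
    R : pipe radius (m)
    P_s : steady pressure-gradient magnitude (Pa/m)
    P_o : oscillatory pressure-gradient amplitude (Pa/m)
    omega : angular frequency (1/s)
    mu : dynamic viscosity (Pa s)
    rho : fluid density (kg/m^3)

    Derived quantities (never trusted from input): the Womersley number
    ``alpha``, the spatial-mean steady velocity ``u0 = P_s R^2 / (8 mu)`` and
    the base-flow Reynolds number ``Re0 = 2 R u0 / nu``.
    """

    R: float
    P_s: float
    P_o: float
    omega: float
    mu: float
    rho: float
    alpha: float = field(init=False)
    nu: float = field(init=False)
    u0: float = field(init=False)
    Re0: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("R", "omega", "mu", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nu = self.mu / self.rho
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "alpha", womersley_number(self.R, self.omega, nu))
        object.__setattr__(self, "u0", self.P_s * self.R**2 / (8.0 * self.mu))
        object.__setattr__(self, "Re0", 2.0 * self.R * self.u0 / nu)

    @classmethod
    def from_alpha(cls, R: float, P_s: float, P_o: float, omega: float,
                   alpha: float, rho: float) -> "WomersleyParams":
        """Build parameters from a target Womersley number, inferring viscosity.

        ``alpha = R sqrt(omega/nu)`` fixes ``nu = (R/alpha)^2 omega``.
        """
        nu = (R / alpha) ** 2 * omega
        return cls(R=R, P_s=P_s, P_o=P_o, omega=omega, mu=nu * rho, rho=rho)

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    def pressure_gradient(self, t):
        """Driving gradient ``P(t) = P_s + Re(P_o e^{i w t})`` in Pa/m."""
        return self.P_s + self.P_o * np.cos(self.omega * np.asarray(t))


def _check_radius(r, R: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > R * (1 + 1e-12)):
        raise ValueError("radius outside [0, R]")
    return np.minimum(r, R)


def womersley_velocity(r, t, params: WomersleyParams):
    """Axial velocity u(r, t) in m/s; broadcasts over ``r`` and ``t``."""
    p = params
    r = _check_radius(r, p.R)
    t = np.asarray(t, dtype=float)
    steady = p.P_s * p.R**2 / (4.0 * p.mu) * (1.0 - (r / p.R) ** 2)
    lam = p.alpha * I32
    osc_profile = (p.P_o * p.R**2 / (1j * p.mu * p.alpha**2)) * (
        1.0 - jv(0, lam * r / p.R) / jv(0, lam)
    )
    return steady + np.real(osc_profile * np.exp(1j * p.omega * t))


def womersley_shear(r, t, params: WomersleyParams, convention: str = "tensor"):
    """Analytic shear stress sigma(r, t) in Pa, from the exact derivative.

    ``convention="tensor"`` returns ``mu du/dr`` (the off-diagonal component
    ``sigma_rz = 2 mu S_rz`` with ``S_rz = du/dr / 2``); ``"double"`` returns
    ``2 mu du/dr``.  With the inward velocity gradient the wall value of the
    steady component is ``-P_s R / 2``.
    """
    p = params
    r = _check_radius(r, p.R)
    t = np.asarray(t, dtype=float)
    dudr_steady = -p.P_s * r / (2.0 * p.mu)
    lam = p.alpha * I32
    # d/dr of the oscillatory profile: J0' = -J1
    dudr_osc = (p.P_o * p.R**2 / (1j * p.mu * p.alpha**2)) * (
        (lam / p.R) * jv(1, lam * r / p.R) / jv(0, lam)
    )
    dudr = dudr_steady + np.real(dudr_osc * np.exp(1j * p.omega * t))
    if convention == "tensor":
        return p.mu * dudr
    if convention == "double":
        return 2.0 * p.mu * dudr
    raise ValueError("convention must be 'tensor' or 'double'")
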