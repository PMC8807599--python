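import numpy as np
import pytest

from vlbm.core import Simulation
from vlbm.experiments import UnitMap, build_unit_map
from vlbm.fixtures import make_cylinder_stl
from vlbm.geometry import voxelize
from vlbm.stencil import CS2

R = 9.525e-3
L = 19.05e-3
RHO = 1.0e3
NU = 3.0e-6
P_S = 0.3  # Pa/m, steady pressure gradient used by the shared steady run


@pytest.fixture(scope="session")
def cylinder_mesh():
    return make_cylinder_stl(R, L, facets=128)


@pytest.fixture(scope="session")
def slab_cells():
    """Short periodic mid-pipe slab at N_D=41 (shared by solver tests)."""
    mesh = make_cylinder_stl(R, L, facets=128)
    nd = 41
    dx = 2 * R / nd
    z0 = L / 2 - 2 * dx
    bounds = np.array([[-R, -R, z0], [R, R, z0 + 4 * dx]])
    return voxelize(mesh, nd, q=8, margin=(2, 2, 0), ref_diameter=2 * R,
                    bounds=bounds)


@pytest.fixture(scope="session")
def steady_poiseuille(slab_cells):
    """Body-forced pipe run to steady state; returns (sim, units)."""
    g = slab_cells.grid
    units0 = build_unit_map(NU, 2 * R, g.nd, 0.95, rho=RHO)
    dt = units0.dt
    tau = 0.5 + NU * dt / (CS2 * g.dx**2)
    a = np.array([0.0, 0.0, P_S / RHO * dt**2 / g.dx])
    sim = Simulation(slab_cells, tau, force=a)
    sim.run(12000)
    return sim, UnitMap(dx=g.dx, dt=dt, tau=tau, nd=g.nd, rho=RHO)
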