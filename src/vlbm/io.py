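"""File output and run configuration.

Field snapshots go out as VTK legacy structured-points files (ASCII, cell
centers as points) for inspection in ParaView, and as ``.npz`` containers for
programmatic round trips.  Run configurations are flat ``key = value`` text
files; the schema is documented in :data:`CONFIG_SCHEMA`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Simulation
from .geometry import GridSpec
from .stresses import wall_stress_report

__all__ = ["write_vtk", "write_fields", "save_state", "load_state",
           "RunConfig", "CONFIG_SCHEMA"]


def write_vtk(path, grid: GridSpec, scalars: dict | None = None,
              vectors: dict | None = None, comment: str = "vlbm fields") -> None:
    """Legacy VTK STRUCTURED_POINTS writer (one point per lattice cell)."""
    scalars = scalars or {}
    vectors = vectors or {}
    npts = grid.nx * grid.ny * grid.nz
    o = np.asarray(grid.origin) + 0.5 * grid.dx
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx} {grid.ny} {grid.nz}\n")
        fh.write(f"ORIGIN {o[0]:.9e} {o[1]:.9e} {o[2]:.9e}\n")
        fh.write(f"SPACING {grid.dx:.9e} {grid.dx:.9e} {grid.dx:.9e}\n")
        fh.write(f"POINT_DATA {npts}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.asarray(arr).transpose(2, 1, 0).ravel().tofile(fh, sep="\n")
            fh.write("\n")
        for name, arr in vectors.items():
            fh.write(f"VECTORS {name} double\n")
            flat = np.asarray(arr).transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.9e")


def write_fields(sim: Simulation, units, outdir, basename: str = "fields") -> None:
    """Snapshot rho, u, p, P and |WSS| in physical units + unit metadata.

    Writes ``<basename>.vtk``, a per-boundary-cell WSS/WNS CSV and a small
    ``units.txt`` recording the lattice-to-physical map used.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cells = sim.cells
    rho, u, dp = sim.moments()
    wns, wss = wall_stress_report(sim.n, cells, sim.tau)
    wss_mag = np.zeros(cells.grid.shape)
    bi = cells.bindex
    wss_mag[bi[:, 0], bi[:, 1], bi[:, 2]] = (
        np.linalg.norm(wss, axis=-1) * units.stress_scale)
    write_vtk(out / f"{basename}.vtk", cells.grid,
              scalars={"rho": rho * units.rho,
                       "p": dp * units.stress_scale,
                       "P": cells.P,
                       "wss_mag": wss_mag},
              vectors={"u": u * units.velocity_scale})
    rec = np.column_stack([
        cells.xb, cells.normal,
        wss * units.stress_scale, wns * units.stress_scale,
        np.linalg.norm(wss, axis=-1) * units.stress_scale,
        np.linalg.norm(wns, axis=-1) * units.stress_scale,
    ])
    np.savetxt(out / f"{basename}_wall.csv", rec, delimiter=",",
               header="xb_x,xb_y,xb_z,n_x,n_y,n_z,wss_x,wss_y,wss_z,"
                      "wns_x,wns_y,wns_z,wss_mag,wns_mag", comments="")
    with open(out / "units.txt", "w") as fh:
        fh.write(f"dx_m = {float(units.dx)!r}\ndt_s = {float(units.dt)!r}\n"
                 f"tau = {float(units.tau)!r}\nrho_kg_m3 = {float(units.rho)!r}\n"
                 f"normal_orientation = into_fluid\n"
                 f"step = {sim.t}\n")


def save_state(path, sim: Simulation) -> None:
    """Portable array container for a simulation state."""
    g = sim.cells.grid
    np.savez_compressed(path, n=sim.n, t=sim.t, tau=sim.tau,
                        dx=g.dx, origin=np.asarray(g.origin))


def load_state(path) -> dict:
    d = np.load(path)
    return {k: d[k] for k in d.files}


CONFIG_SCHEMA = """\
# vlbm run configuration: flat `key = value` lines, '#' comments.
# geometry
mesh            path to an STL file, or fixture spec 'cylinder' / 'bifurcation'
nd              cells across the reference diameter (int)
q               sub-cell divisions per axis for solid fractions (int, default 8)
margin          solid padding cells around the mesh bounding box (default 2)
# fluid
rho             density, kg/m^3
nu              kinematic viscosity, m^2/s
tau             BGK relaxation time (> 0.5)
# driving (exactly one mode)
driving         'body-force' or 'velocity-profiles'
P_s, P_o        steady / oscillatory pressure-gradient magnitude, Pa/m
omega           angular frequency, 1/s
profiles        directory holding a ProfileSet (velocity-profiles mode)
streaming       'generalized' (default) or 'original'
# run control
cycles          number of pulsation cycles to run
output_every    write fields every k-th cycle (0: final only)
seed            RNG seed for synthetic inputs (default 0)
"""

_DEFAULTS = dict(q=8, margin=2, streaming="generalized", output_every=0,
                 seed=0, P_s=0.0, P_o=0.0, omega=1.0, profiles="")


@dataclass
class RunConfig:
    """Parsed flat-text run configuration (see :data:`CONFIG_SCHEMA`)."""

    mesh: str
    nd: int
    tau: float
    rho: float
    nu: float
    driving: str
    cycles: int
    q: int = 8
    margin: int = 2
    P_s: float = 0.0
    P_o: float = 0.0
    omega: float = 1.0
    profiles: str = ""
    streaming: str = "generalized"
    output_every: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.driving not in ("body-force", "velocity-profiles"):
            raise ValueError("driving must be 'body-force' or 'velocity-profiles'")
        if self.driving == "velocity-profiles" and not self.profiles:
            raise ValueError("velocity-profiles driving needs a profiles directory")
        for name in ("rho", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = dict(_DEFAULTS)
        for raw in open(path):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, val = line.partition("=")
            if not sep:
                raise ValueError(f"malformed config line: {raw!r}")
            kv[key.strip()] = val.strip()
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        args, extra = {}, {}
        for k, v in kv.items():
            (args if k in known else extra)[k] = v
        conv = {"nd": int, "q": int, "margin": int, "cycles": int,
                "output_every": int, "seed": int,
                "tau": float, "rho": float, "nu": float,
                "P_s": float, "P_o": float, "omega": float}
        for k, fn in conv.items():
            if k in args:
                args[k] = fn(args[k])
        return cls(extra=extra, **args)
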