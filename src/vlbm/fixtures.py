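"""Parametric synthetic inputs: vessel surfaces and coarse pulsatile profiles.

These generators stand in for the two kinds of measured input the pipeline
consumes in practice — a segmented vessel surface (STL) and coarse
phase-contrast MRA velocity profiles — so every benchmark and test is fully
reproducible from code.  All generators are deterministic given their
arguments (and seed, where noise is requested).
"""

from __future__ import annotations

import numpy as np
import trimesh

from .boundaries import ProfileSet
from .womersley import WomersleyParams, womersley_velocity

__all__ = ["make_cylinder_stl", "make_bifurcation_stl", "make_synthetic_pcmra_profiles"]

#: benchmark pipe dimensions (m): right-circular pipe, L = D
DEFAULT_RADIUS = 9.525e-3
DEFAULT_LENGTH = 19.05e-3


def cylinder_cap_rings(facets: int) -> int:
    """Default concentric-ring count of the cap triangulation (chord-sized)."""
    return max(1, int(np.ceil(facets / (2.0 * np.pi))))


def cylinder_triangle_count(facets: int, cap_rings: int | None = None) -> int:
    """Triangle count of :func:`make_cylinder_stl`: 2k sides + 2 k(2m-1) caps."""
    m = cylinder_cap_rings(facets) if cap_rings is None else cap_rings
    return 2 * facets + 2 * facets * (2 * m - 1)


def make_cylinder_stl(R: float = DEFAULT_RADIUS, L: float = DEFAULT_LENGTH,
                      facets: int = 256, cap_rings: int | None = None,
                      path=None) -> trimesh.Trimesh:
    """Closed right-circular cylinder along +z, axis through the origin,
    spanning z in [0, L], with ``facets`` side panels.

    Caps are triangulated with ``cap_rings`` concentric rings (default:
    chord-sized, ``ceil(k / 2 pi)``) so every triangle is well-shaped —
    large fan triangles would degrade the spatial search structures used
    during voxelization.  The faceted solid has volume
    ``(k/2) R^2 L sin(2 pi / k)`` -> pi R^2 L as the facet count k grows.
    Outward-oriented normals; watertight.
    """
    if facets < 16:
        raise ValueError("need at least 16 facets")
    k = int(facets)
    m = cylinder_cap_rings(k) if cap_rings is None else int(cap_rings)
    ang = 2.0 * np.pi * np.arange(k) / k
    unit = np.column_stack([np.cos(ang), np.sin(ang)])

    verts = [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, L]])]  # cap centers
    # cap rings j = 1..m at radius R j/m (ring m is the shared rim)
    for z_id, z in enumerate((0.0, L)):
        for j in range(1, m + 1):
            verts.append(np.column_stack(
                [R * j / m * unit, np.full(k, z)]))
    verts = np.vstack(verts)

    def ring_off(z_id: int, j: int) -> int:
        return 2 + (z_id * m + (j - 1)) * k

    faces = []
    for z_id, inward in ((0, True), (1, False)):
        # bottom cap faces -z (reversed winding), top cap faces +z
        center = z_id
        for i in range(k):
            jn = (i + 1) % k
            tri = [center, ring_off(z_id, 1) + i, ring_off(z_id, 1) + jn]
            faces.append(tri[::-1] if inward else tri)
        for j in range(1, m):
            a, b = ring_off(z_id, j), ring_off(z_id, j + 1)
            for i in range(k):
                jn = (i + 1) % k
                t1 = [a + i, b + i, b + jn]
                t2 = [a + i, b + jn, a + jn]
                faces.append(t1[::-1] if inward else t1)
                faces.append(t2[::-1] if inward else t2)
    rim0, rim1 = ring_off(0, m), ring_off(1, m)
    for i in range(k):
        jn = (i + 1) % k
        faces.append([rim0 + i, rim0 + jn, rim1 + i])
        faces.append([rim0 + jn, rim1 + jn, rim1 + i])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if path is not None:
        mesh.export(str(path))
    return mesh


def _tube_sdf(points: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> np.ndarray:
    """Signed distance to a capsule-less finite cylinder (capped tube)."""
    axis = p1 - p0
    L = np.linalg.norm(axis)
    axis = axis / L
    rel = points - p0
    s = rel @ axis
    radial = np.linalg.norm(rel - s[:, None] * axis, axis=1)
    dr = radial - r
    dz = np.maximum(-s, s - L)
    outside = np.sqrt(np.maximum(dr, 0) ** 2 + np.maximum(dz, 0) ** 2)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return outside + inside


def make_bifurcation_stl(parent_radius: float = 4e-3,
                         daughter_radii: tuple[float, float] = (3e-3, 3e-3),
                         angle: float = np.pi / 5,
                         parent_length: float = 12e-3,
                         daughter_length: float = 12e-3,
                         resolution: int = 64,
                         path=None) -> trimesh.Trimesh:
    """Watertight Y-junction of capped tubes for qualitative WSS runs.

    Built implicitly (union of three tube distance fields) and triangulated by
    marching cubes, which guarantees a closed surface even at the junction;
    ``angle`` is each daughter's half-opening from the parent axis.  A zero
    angle with equal radii degenerates to a straight tube.
    """
    if parent_radius <= 0 or min(daughter_radii) <= 0:
        raise ValueError("radii must be positive")
    from skimage.measure import marching_cubes

    p_base = np.array([0.0, 0.0, 0.0])
    junction = np.array([0.0, 0.0, parent_length])
    d_dirs = [np.array([np.sin(a), 0.0, np.cos(a)]) for a in (angle, -angle)]
    tubes = [(p_base, junction, parent_radius)] + [
        (junction, junction + d * daughter_length, r)
        for d, r in zip(d_dirs, daughter_radii)
    ]
    pts = np.vstack([np.vstack([p0, p1]) for p0, p1, _ in tubes])
    rmax = max(parent_radius, *daughter_radii)
    lo = pts.min(axis=0) - 2.0 * rmax
    hi = pts.max(axis=0) + 2.0 * rmax
    n = resolution
    axes = [np.linspace(lo[a], hi[a], n) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sdf = np.min([_tube_sdf(grid_pts, p0, p1, r) for p0, p1, r in tubes], axis=0)
    spacing = [(hi[a] - lo[a]) / (n - 1) for a in range(3)]
    verts, faces, _, _ = marching_cubes(sdf.reshape(n, n, n), level=0.0,
                                        spacing=spacing)
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise ValueError("bifurcation surface generation failed (not watertight); "
                         "try a higher resolution")
    if mesh.is_volume and mesh.volume < 0:
        mesh.invert()
    if path is not None:
        mesh.export(str(path))
    return mesh


def make_synthetic_pcmra_profiles(params: WomersleyParams,
                                  slices: int = 10,
                                  timepoints: int = 20,
                                  samples_across: int = 16,
                                  slice_spacing: float | None = None,
                                  noise_level: float = 0.0,
                                  seed: int = 0) -> ProfileSet:
    """Coarse space-time velocity profiles emulating a PC-MRA acquisition.

    Analytic pulsatile-pipe velocities sampled on a ``samples_across`` square
    in-plane grid, at ``slices`` axial stations and ``timepoints`` instants in
    one period, plus optional zero-mean Gaussian noise of standard deviation
    ``noise_level * max |u|`` (phase-contrast data are by nature noisy).
    """
    R = params.R
    if slice_spacing is None:
        slice_spacing = 2.0 * R
    zs = np.arange(slices) * slice_spacing
    ts = np.arange(timepoints) * params.period / timepoints
    xy = np.linspace(-R, R, samples_across)
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    rr = np.sqrt(X**2 + Y**2)
    inside = rr <= R
    u = np.zeros((slices, timepoints, samples_across, samples_across))
    prof = np.zeros_like(rr)
    for it, t in enumerate(ts):
        prof[inside] = womersley_velocity(rr[inside], t, params)
        u[:, it] = prof  # axially invariant base flow: same on every slice
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise_level * np.abs(u).max(), size=u.shape)
        u[:, :, ~inside] = 0.0
    return ProfileSet(axial_positions=zs, times=ts, period=params.period,
                      x=xy, y=xy, u=u)
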