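"""D3Q19 engine: equilibria, forcing, collision and volumetric streaming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlbm.core import (Simulation, collide, equilibrium, forcing_term,
                       macroscopic, stream_generalized, stream_original,
                       streaming_coefficients, _stream)
from vlbm.geometry import CellGeometry, GridSpec
from vlbm.stencil import CS2, E, OPP, Q, W

from .oracles import node_bgk_step


def test_stencil_invariants():
    assert W.sum() == pytest.approx(1.0, abs=1e-15)
    assert np.allclose(W @ E.astype(float), 0.0)
    second = np.einsum("i,ia,ib->ab", W, E.astype(float), E.astype(float))
    assert np.allclose(second, CS2 * np.eye(3))
    assert np.all(OPP[OPP] == np.arange(Q))
    assert np.all(E[OPP] == -E)


def _cells_from_P(P, nd=None):
    """Minimal CellGeometry wrapper around a raw solid-fraction array."""
    from vlbm.geometry import BOUNDARY, FLUID, SOLID

    cls = np.full(P.shape, BOUNDARY, np.uint8)
    cls[P == 0.0] = FLUID
    cls[P == 1.0] = SOLID
    grid = GridSpec(*P.shape, dx=1.0, origin=(0, 0, 0), nd=nd)
    b = np.argwhere(cls == BOUNDARY)
    return CellGeometry(grid, P, cls, b, np.zeros((len(b), 3)),
                        np.tile([1.0, 0, 0], (len(b), 1)), np.zeros(len(b)))


class TestEquilibrium:
    def test_rest_state_is_weighted(self):
        neq = equilibrium(np.array(2.5), np.zeros(3))
        assert np.allclose(neq, 2.5 * W)

    def test_frozen_value_axis_direction(self):
        # direct evaluation: N=1, u=(0.1,0,0), direction e=(+1,0,0):
        # (1/18)(1 + 0.3 + 0.045 - 0.015)
        neq = equilibrium(np.array(1.0), np.array([0.1, 0.0, 0.0]))
        i = int(np.flatnonzero((E == [1, 0, 0]).all(axis=1))[0])
        assert neq[i] == pytest.approx((1 + 0.3 + 0.045 - 0.015) / 18, rel=1e-14)
        assert neq[i] == pytest.approx(0.0738888888888889, rel=1e-12)

    @given(st.floats(0.1, 10.0),
           st.lists(st.floats(-0.1, 0.1), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_moment_identities(self, N, u):
        neq = equilibrium(np.array(N), np.array(u))
        assert neq.sum() == pytest.approx(N, rel=1e-12)
        assert np.allclose(E.T @ neq, np.array(u) * N, atol=1e-13 * max(1, N))


class TestForcing:
    def test_zero_acceleration(self):
        assert np.allclose(forcing_term(np.array(1.0), np.zeros(3)), 0.0)

    @given(st.lists(st.floats(-1e-2, 1e-2), min_size=3, max_size=3))
    @settings(max_examples=30, deadline=None)
    def test_moments(self, a):
        F = forcing_term(np.array(2.0), np.array(a))
        assert F.sum() == pytest.approx(0.0, abs=1e-16)
        # injected momentum is +N a dt per step
        assert np.allclose(E.T @ F, 2.0 * np.array(a), atol=1e-15)


class TestCollision:
    def test_equilibrium_is_fixed_point(self):
        neq = equilibrium(np.array(1.0), np.array([0.02, -0.01, 0.03]))
        assert np.allclose(collide(neq, tau=0.8), neq, atol=1e-15)

    def test_tau_one_projects_to_equilibrium(self):
        rng = np.random.default_rng(3)
        n = rng.random(Q) * 0.1 + W
        out = collide(n, tau=1.0)
        N = n.sum()
        u = E.T @ n / N
        assert np.allclose(out, equilibrium(np.array(N), u), atol=1e-14)

    def test_mass_momentum_bookkeeping(self):
        rng = np.random.default_rng(4)
        n = rng.random((5, Q)) * 0.1 + W
        a = np.array([1e-3, 0, -2e-3])
        F = forcing_term(n.sum(-1), a)
        out = collide(n, tau=0.7, F=F)
        assert np.allclose(out.sum(-1), n.sum(-1), atol=1e-14)
        assert np.allclose(out @ E.astype(float),
                           n @ E.astype(float) + n.sum(-1)[:, None] * a,
                           atol=1e-14)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            collide(W.copy(), tau=0.5)


class TestStreaming:
    def test_pure_fluid_is_advection(self):
        rng = np.random.default_rng(0)
        n = rng.random((4, 5, 6, Q))
        P = np.zeros((4, 5, 6))
        out = stream_generalized(n, P)
        for i in range(Q):
            assert np.allclose(out[..., i],
                               np.roll(n[..., i], tuple(E[i]), axis=(0, 1, 2)))
        assert np.allclose(stream_original(n, P), out)

    def test_equal_fraction_pair_is_pass_through(self):
        # two boundary cells with the same P exchange populations unchanged
        P = np.full((3, 1, 1), 0.4)
        rng = np.random.default_rng(1)
        n = rng.random((3, 1, 1, Q))
        out = stream_generalized(n, P)
        i = int(np.flatnonzero((E == [1, 0, 0]).all(axis=1))[0])
        assert out[1, 0, 0, i] == pytest.approx(n[0, 0, 0, i], rel=1e-14)

    def test_solid_upwind_full_bounce_back(self):
        P = np.zeros((3, 3, 3))
        P[0, :, :] = 1.0  # solid slab on the -x side
        rng = np.random.default_rng(2)
        n = rng.random((3, 3, 3, Q))
        n[0] = 0.0
        out = stream_generalized(n, P)
        i = int(np.flatnonzero((E == [1, 0, 0]).all(axis=1))[0])
        # receiving cell adjacent to the solid: gets its own opposite back
        assert out[1, 1, 1, i] == pytest.approx(n[1, 1, 1, OPP[i]], rel=1e-14)

    @pytest.mark.parametrize("PA", [0.0, 0.2, 0.5, 0.9])
    @pytest.mark.parametrize("PB", [0.0, 0.2, 0.5, 0.9])
    def test_pairwise_mass_conservation(self, PA, PB):
        """Particles leaving A toward B + the bounce must balance exactly."""
        P = np.array([PA, PB]).reshape(2, 1, 1)
        rng = np.random.default_rng(5)
        n = rng.random((2, 1, 1, Q))
        i = int(np.flatnonzero((E == [1, 0, 0]).all(axis=1))[0])
        out = stream_generalized(n, P)
        before = n[0, 0, 0, i] + n[1, 0, 0, OPP[i]]
        after = out[1, 0, 0, i] + out[0, 0, 0, OPP[i]]
        assert after == pytest.approx(before, rel=1e-14)

    def test_original_differs_at_equal_fractions(self):
        # the defect the generalization fixes: P=0.5 pair is not pass-through
        P = np.full((3, 1, 1), 0.5)
        rng = np.random.default_rng(6)
        n = rng.random((3, 1, 1, Q))
        gen = stream_generalized(n, P)
        orig = stream_original(n, P)
        i = int(np.flatnonzero((E == [1, 0, 0]).all(axis=1))[0])
        assert gen[1, 0, 0, i] == pytest.approx(n[0, 0, 0, i])
        assert orig[1, 0, 0, i] != pytest.approx(n[0, 0, 0, i])


class TestMacroscopic:
    def test_uniform_boundary_cell(self):
        n = np.tile(0.5 * W, (2, 2, 2, 1))
        P = np.full((2, 2, 2), 0.5)
        rho, u, dp = macroscopic(n, P)
        assert np.allclose(rho, 1.0)
        assert np.allclose(u, 0.0)
        assert np.allclose(dp, 0.0)

    def test_velocity_recovered_from_equilibrium(self):
        u0 = np.array([0.05, 0.0, 0.0])
        n = equilibrium(np.full((3, 3, 3), 0.7), np.tile(u0, (3, 3, 3, 1)))
        _, u, _ = macroscopic(n, np.full((3, 3, 3), 0.3))
        assert np.allclose(u, u0, atol=1e-14)

    def test_density_definition(self):
        rng = np.random.default_rng(7)
        n = rng.random((4, 4, 4, Q))
        P = np.full((4, 4, 4), 0.25)
        rho, _, _ = macroscopic(n, P)
        assert np.allclose(rho * (1 - P), n.sum(-1))


class TestSimulation:
    def _closed_box(self, seed=0):
        P = np.zeros((8, 8, 8))
        P[[0, -1], :, :] = 1.0
        P[:, [0, -1], :] = 1.0
        P[:, :, [0, -1]] = 1.0
        P[3:5, 3:5, 3:5] = 1.0  # interior obstacle
        cells = _cells_from_P(P)
        sim = Simulation(cells, tau=0.8)
        rng = np.random.default_rng(seed)
        sim.n[cells.P < 1.0] = rng.random((int((P < 1).sum()), Q)) * 0.1 + 0.5 * W
        sim.n[cells.P >= 1.0] = 0.0
        return sim

    def test_rest_state_is_stationary(self):
        sim = self._closed_box()
        sim.n = equilibrium(1.0 - sim.P, np.zeros(sim.P.shape + (3,)))
        sim.n[sim.P >= 1.0] = 0.0
        n0 = sim.n.copy()
        sim.run(20)
        # walls only rescale populations mass-conservingly; the state stays
        # an equilibrium at zero velocity
        _, u, _ = macroscopic(sim.n, sim.P)
        assert np.abs(u).max() < 1e-12
        assert sim.total_mass() == pytest.approx(n0.sum(), rel=1e-12)

    def test_global_mass_conservation_long_run(self):
        """Closed random box: total particle count exact over 1e4 steps."""
        sim = self._closed_box(seed=11)
        m0 = sim.total_mass()
        sim.run(10_000)
        assert abs(sim.total_mass() - m0) / m0 < 1e-12

    def test_reduces_to_node_based_oracle(self):
        """All-fluid periodic box: the volumetric engine is the standard
        node-based D3Q19 BGK stepper."""
        P = np.zeros((6, 5, 4))
        cells = _cells_from_P(P)
        rng = np.random.default_rng(12)
        f0 = rng.random((6, 5, 4, Q)) * 0.2 + W
        a = (1e-4, -2e-4, 3e-4)
        for prefer in ("numpy", "numba"):
            sim = Simulation(cells, tau=0.73, force=np.array(a), prefer=prefer)
            sim.n = f0.copy()
            sim.run(20)
            f = f0.copy()
            for _ in range(20):
                f = node_bgk_step(f, 0.73, a)
            assert np.allclose(sim.n, f, atol=1e-12)

    def test_numba_matches_numpy_path(self):
        P = np.zeros((6, 6, 6))
        P[[0, -1], :, :] = 1.0
        P[2, 2, 2] = 0.37  # a partial cell
        cells = _cells_from_P(P)
        rng = np.random.default_rng(13)
        n0 = rng.random((6, 6, 6, Q)) * 0.1 + 0.3
        n0[P >= 1.0] = 0.0
        sims = {}
        for prefer in ("numpy", "numba"):
            sim = Simulation(cells, tau=0.6, force=np.array([0, 1e-4, 0]),
                             prefer=prefer)
            sim.n = n0.copy()
            sim.run(15)
            sims[prefer] = sim.n
        assert np.allclose(sims["numpy"], sims["numba"], atol=1e-12)

    def test_tau_warnings_and_errors(self):
        cells = _cells_from_P(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            Simulation(cells, tau=0.49)
        with pytest.warns(UserWarning):
            Simulation(cells, tau=0.502)
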