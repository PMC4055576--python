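import numpy as np
import pytest

from polyspread import deterministic as det
from polyspread import modelspec as ms
from polyspread import netio

# ---------------------------------------------------------------------------
# hand-coded reference steppers for the named reductions (written directly
# from each model's closed-form update; the generic engine must match them
# to machine precision because none of these models needs the share
# approximation)
# ---------------------------------------------------------------------------


def _neighbor_sets(graph):
    return [graph.neighbors(i) for i in range(graph.n)]


def sis_step(P, graph, beta, delta):
    out = np.empty_like(P)
    for i, nbr in enumerate(_neighbor_sets(graph)):
        q = 1.0 - np.prod(1.0 - beta * P[nbr, 1])
        out[i, 1] = (1 - delta) * P[i, 1] + P[i, 0] * q
        out[i, 0] = delta * P[i, 1] + P[i, 0] * (1 - q)
    return out


def sir_step(P, graph, beta, delta):
    out = np.empty_like(P)
    for i, nbr in enumerate(_neighbor_sets(graph)):
        q = 1.0 - np.prod(1.0 - beta * P[nbr, 1])
        out[i, 0] = P[i, 0] * (1 - q)
        out[i, 1] = (1 - delta) * P[i, 1] + P[i, 0] * q
        out[i, 2] = P[i, 2] + delta * P[i, 1]
    return out


def sirs_step(P, graph, beta, delta, xi):
    out = np.empty_like(P)
    for i, nbr in enumerate(_neighbor_sets(graph)):
        q = 1.0 - np.prod(1.0 - beta * P[nbr, 1])
        out[i, 0] = P[i, 0] * (1 - q) + xi * P[i, 2]
        out[i, 1] = (1 - delta) * P[i, 1] + P[i, 0] * q
        out[i, 2] = (1 - xi) * P[i, 2] + delta * P[i, 1]
    return out


def maki_thompson_step(P, graph, lam, alpha, sigma):
    # states (I, S, R) = ignorant, spreader, stifler
    out = np.empty_like(P)
    for i, nbr in enumerate(_neighbor_sets(graph)):
        q_spread = 1.0 - np.prod(1.0 - lam * P[nbr, 1])
        h_spreader = np.prod(1.0 - alpha * (P[nbr, 1] + P[nbr, 2]))
        out[i, 0] = P[i, 0] * (1 - q_spread)
        out[i, 1] = P[i, 0] * q_spread + P[i, 1] * (1 - sigma) * h_spreader
        out[i, 2] = P[i, 2] + P[i, 1] * sigma \
            + P[i, 1] * (1 - sigma) * (1 - h_spreader)
    return out


def si1i2s_step(P, graph, b1, b2, d1, d2):
    # the approximated competition update: expected-share split of the
    # total adoption probability
    out = np.empty_like(P)
    for i, nbr in enumerate(_neighbor_sets(graph)):
        a1 = (b1 * P[nbr, 1]).sum()
        a2 = (b2 * P[nbr, 2]).sum()
        h = np.prod(1.0 - b1 * P[nbr, 1] - b2 * P[nbr, 2])
        tot = a1 + a2
        q1 = a1 / tot * (1 - h) if tot > 0 else 0.0
        q2 = a2 / tot * (1 - h) if tot > 0 else 0.0
        out[i, 0] = P[i, 0] * h + d1 * P[i, 1] + d2 * P[i, 2]
        out[i, 1] = (1 - d1) * P[i, 1] + P[i, 0] * q1
        out[i, 2] = (1 - d2) * P[i, 2] + P[i, 0] * q2
    return out


def multiplex_si1i2s_step(P, layers, b1, b2, d1, d2):
    # each contagion spreads only on its own layer; the no-adoption
    # probability is the product of the two per-layer product forms
    out = np.empty_like(P)
    n = P.shape[0]
    for i in range(n):
        nbr1 = layers[0].neighbors(i)
        nbr2 = layers[1].neighbors(i)
        a1 = (b1 * P[nbr1, 1]).sum()
        a2 = (b2 * P[nbr2, 2]).sum()
        h = np.prod(1.0 - b1 * P[nbr1, 1]) * np.prod(1.0 - b2 * P[nbr2, 2])
        tot = a1 + a2
        q1 = a1 / tot * (1 - h) if tot > 0 else 0.0
        q2 = a2 / tot * (1 - h) if tot > 0 else 0.0
        out[i, 0] = P[i, 0] * h + d1 * P[i, 1] + d2 * P[i, 2]
        out[i, 1] = (1 - d1) * P[i, 1] + P[i, 0] * q1
        out[i, 2] = (1 - d2) * P[i, 2] + P[i, 0] * q2
    return out


def _random_field(rng, n, m):
    return rng.dirichlet(np.ones(m), size=n)


class TestStepField:
    def test_frozen_dynamics_identity(self, star6, rng):
        spec = ms.ModelSpec(("a", "b"), np.zeros((2, 2)), np.eye(2))
        P = _random_field(rng, 6, 2)
        assert np.allclose(det.step_field(P, spec, star6), P, atol=1e-15)

    def test_sis_stationary_point_on_edge(self):
        """Two-node path, both nodes half infected, beta=0.4, delta=0.2:
        hand evaluation of the SIS update gives p_I' = 0.5 again."""
        g = netio.Network(2, ((0, 1),))
        spec = ms.preset_SIS(0.4, 0.2)
        P = np.full((2, 2), 0.5)
        assert np.allclose(det.step_field(P, spec, g), P, atol=1e-15)

    @pytest.mark.parametrize("backend", ["approx", "exact"])
    def test_rows_stay_stochastic(self, backend, complete6, rng):
        spec = ms.preset_three_innovations()
        P = _random_field(rng, 6, 3)
        for _ in range(20):
            P = det.step_field(P, spec, complete6, backend=backend)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(P >= -1e-12)

    def test_backend_agreement_moderate_gamma(self, lattice3x3, rng):
        """On graphs with degree <= 5 the approx and exact steps differ at
        most by the single-receiver approximation tolerance."""
        spec = ms.preset_SI1I2S(0.3, 0.25, 0.2, 0.2)
        P = _random_field(rng, 9, 3)
        a = det.step_field(P, spec, lattice3x3, backend="approx")
        e = det.step_field(P, spec, lattice3x3, backend="exact")
        assert np.max(np.abs(a - e)) <= 0.02

    def test_unknown_backend(self, star6):
        spec = ms.preset_SIS(0.4, 0.2)
        with pytest.raises(ValueError, match="backend"):
            det.step_field(det.uniform_field(6, 2), spec, star6,
                           backend="nope")


class TestReductionIdentities:
    """The generic engine must reproduce the closed-form updates of every
    named special case to machine precision over long trajectories."""

    @pytest.mark.parametrize("graph_name", ["star6", "lattice3x3"])
    def test_sis(self, graph_name, request, rng):
        g = request.getfixturevalue(graph_name)
        spec = ms.preset_SIS(0.4, 0.2)
        P = _random_field(rng, g.n, 2)
        Q = P.copy()
        for _ in range(100):
            P = det.step_field(P, spec, g)
            Q = sis_step(Q, g, 0.4, 0.2)
            assert np.max(np.abs(P - Q)) < 1e-12

    @pytest.mark.parametrize("graph_name", ["star6", "lattice3x3"])
    def test_sir(self, graph_name, request, rng):
        g = request.getfixturevalue(graph_name)
        spec = ms.preset_SIR(0.5, 0.25)
        P = _random_field(rng, g.n, 3)
        Q = P.copy()
        for _ in range(100):
            P = det.step_field(P, spec, g)
            Q = sir_step(Q, g, 0.5, 0.25)
            assert np.max(np.abs(P - Q)) < 1e-12

    @pytest.mark.parametrize("graph_name", ["star6", "lattice3x3"])
    def test_sirs(self, graph_name, request, rng):
        g = request.getfixturevalue(graph_name)
        spec = ms.preset_SIRS(0.5, 0.25, 0.1)
        P = _random_field(rng, g.n, 3)
        Q = P.copy()
        for _ in range(100):
            P = det.step_field(P, spec, g)
            Q = sirs_step(Q, g, 0.5, 0.25, 0.1)
            assert np.max(np.abs(P - Q)) < 1e-12

    @pytest.mark.parametrize("graph_name", ["star6", "lattice3x3"])
    def test_maki_thompson(self, graph_name, request, rng):
        g = request.getfixturevalue(graph_name)
        spec = ms.preset_MakiThompson(0.4, 0.3, 0.1)
        P = _random_field(rng, g.n, 3)
        Q = P.copy()
        for _ in range(100):
            P = det.step_field(P, spec, g)
            Q = maki_thompson_step(Q, g, 0.4, 0.3, 0.1)
            assert np.max(np.abs(P - Q)) < 1e-12

    @pytest.mark.parametrize("graph_name", ["star6", "lattice3x3"])
    def test_si1i2s(self, graph_name, request, rng):
        g = request.getfixturevalue(graph_name)
        spec = ms.preset_SI1I2S(0.5, 0.35, 0.2, 0.15)
        P = _random_field(rng, g.n, 3)
        Q = P.copy()
        for _ in range(100):
            P = det.step_field(P, spec, g)
            Q = si1i2s_step(Q, g, 0.5, 0.35, 0.2, 0.15)
            assert np.max(np.abs(P - Q)) < 1e-12

    def test_sir_monotone_observables(self, star6, rng):
        spec = ms.preset_SIR(0.5, 0.25)
        P = _random_field(rng, 6, 3)
        for _ in range(50):
            P_next = det.step_field(P, spec, star6)
            assert np.all(P_next[:, 2] >= P[:, 2] - 1e-12)
            assert np.all(P_next[:, 0] <= P[:, 0] + 1e-12)
            P = P_next


class TestFixedPoint:
    def test_sis_below_threshold_dies_out(self, star6):
        spec = ms.preset_SIS(0.02, 0.5)
        P0 = np.tile([0.5, 0.5], (6, 1))
        rep = det.iterate_to_fixed_point(P0, spec, star6, tol=1e-10)
        assert rep.converged
        assert rep.fractions[1] < 1e-8

    def test_winner_takes_all(self, complete6):
        spec = ms.preset_SI1I2S(0.6, 0.3, 0.2, 0.2)
        # both contagions present initially
        P0 = det.field_from_assignment([0, 1, 2, 0, 1, 2], 3)
        for backend in ("approx", "exact"):
            rep = det.iterate_to_fixed_point(P0, spec, complete6,
                                             backend=backend, tol=1e-10)
            assert rep.converged
            assert rep.fractions[2] < 1e-6

    def test_non_convergence_reported_not_raised(self, lattice3x3, rng):
        """While the cyclic three-innovation dynamics are still swinging,
        stopping early must report converged=False with a bounded residual
        instead of raising (with the bundled transmission matrix the
        deterministic oscillations are damped, so given enough iterations
        the field does settle; see the methods note)."""
        spec = ms.preset_three_innovations()
        P0 = det.field_from_assignment(rng.integers(0, 3, size=9), 3)
        rep = det.iterate_to_fixed_point(P0, spec, lattice3x3, tol=1e-10,
                                         max_iter=30)
        assert not rep.converged
        assert np.isfinite(rep.residual)
        assert rep.residual_history.size == 30


class TestMultiplex:
    def test_single_layer_degenerates(self, star6, rng):
        spec = ms.preset_SIS(0.4, 0.2)
        mspec = ms.MultiplexModelSpec(("S", "I"), (spec.gamma,), spec.delta)
        mx = netio.MultiplexNetwork((star6,))
        P = _random_field(rng, 6, 2)
        assert np.allclose(det.step_field_multiplex(P, mspec, mx),
                           det.step_field(P, spec, star6), atol=1e-14)

    def test_empty_second_layer_is_single_contagion(self, rng):
        ring = netio.make_graph("ring", 6)
        empty = netio.Network(6, ())
        mx = netio.MultiplexNetwork((ring, empty))
        mspec = ms.preset_multiplex_SI1I2S(0.5, 0.9, 0.2, 0.3)
        P = _random_field(rng, 6, 3)
        sis_like = ms.preset_SI1I2S(0.5, 0.0, 0.2, 0.3)
        assert np.allclose(det.step_field_multiplex(P, mspec, mx),
                           det.step_field(P, sis_like, ring), atol=1e-14)

    def test_matches_hand_coded_reduction(self, rng):
        """When each contagion lives on exactly one layer, the pooled
        multiplex step equals the per-layer product-form update."""
        lay1 = netio.make_graph("ring", 8)
        lay2 = netio.Network(8, tuple((i, (i + 2) % 8) for i in range(8)))
        mx = netio.MultiplexNetwork((lay1, lay2))
        mspec = ms.preset_multiplex_SI1I2S(0.5, 0.35, 0.2, 0.15)
        P = _random_field(rng, 8, 3)
        for _ in range(30):
            P_engine = det.step_field_multiplex(P, mspec, mx)
            P_hand = multiplex_si1i2s_step(P, mx.layers, 0.5, 0.35, 0.2, 0.15)
            assert np.max(np.abs(P_engine - P_hand)) < 1e-12
            P = P_engine


class TestHelpers:
    def test_field_from_assignment(self):
        P = det.field_from_assignment([2, 0, 1], 3)
        assert np.array_equal(P, np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]]))

    def test_check_field_rejects_bad_rows(self):
        with pytest.raises(ValueError, match="sum"):
            det.check_field(np.array([[0.5, 0.4]]))
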