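import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bistacert.network_model import (
    GAL_EQUILIBRIUM_HIGH,
    GAL_EQUILIBRIUM_LOW,
    GAL_MODEL_TEXT,
    ModelError,
    MultistartSpec,
    find_equilibria,
    gal_model,
    jacobian_p,
    jacobian_x,
    network_to_text,
    newton_refine,
    parse_model,
    quadratic_decomposition,
    rate_vector,
    rhs,
    simulate,
)


class TestParseModel:
    def test_gal_counts(self, gal):
        net, p = gal
        assert net.n_species == 9
        assert net.n_reactions == 23
        assert net.n_parameters == 23
        assert net.stoichiometry().shape == (9, 23)
        assert net.constant_inputs == {"Gex": 1000.0}

    def test_molecularity_error(self):
        text = """
species: [A, B, C, D]
parameters: {k: 1.0}
reactions: ["A + B + C -> D @ k"]
"""
        with pytest.raises(ModelError, match="molecularity"):
            parse_model(text)

    def test_simplest_network(self):
        net = parse_model(
            "species: [X]\nparameters: {k: 2.5}\nreactions: ['0 -> X @ k']\n"
        )
        assert net.stoichiometry().tolist() == [[1.0]]
        assert rate_vector(net, np.array([7.0])).tolist() == [2.5]

    def test_unknown_species(self):
        text = "species: [A]\nparameters: {k: 1.0}\nreactions: ['A -> Z @ k']\n"
        with pytest.raises(ModelError, match="Z"):
            parse_model(text)

    def test_nonpositive_rate(self):
        text = "species: [A]\nparameters: {k: 0.0}\nreactions: ['A -> 0 @ k']\n"
        with pytest.raises(ModelError, match="positive"):
            parse_model(text)

    def test_roundtrip_bit_exact(self, gal):
        net, _ = gal
        net2 = parse_model(network_to_text(net))
        assert net2.species_names == net.species_names
        np.testing.assert_array_equal(
            net2.nominal_parameters(), net.nominal_parameters()
        )
        assert [r.format() for r in net2.reactions] == [
            r.format() for r in net.reactions
        ]


class TestRhs:
    def test_printed_equilibria_near_zero(self, gal):
        # printed 4-decimal state values leave only rounding-level residuals
        net, p = gal
        assert np.max(np.abs(rhs(net, GAL_EQUILIBRIUM_LOW, p))) <= 2e-2
        assert np.max(np.abs(rhs(net, GAL_EQUILIBRIUM_HIGH, p))) <= 2.0

    def test_zero_state_only_zero_order_survives(self, gal):
        net, p = gal
        f = rhs(net, np.zeros(9), p)
        i_g4 = net.species_index("G4")
        assert f[i_g4] == pytest.approx(22.0604)
        mask = np.ones(9, dtype=bool)
        mask[i_g4] = False
        np.testing.assert_array_equal(f[mask], 0.0)

    def test_first_order_homogeneity(self, toys):
        net = toys["linear_2d"].network
        x = np.array([0.7, 1.9])
        np.testing.assert_allclose(
            rhs(net, 2 * x), 2 * rhs(net, x), rtol=1e-12
        )

    def test_dimension_mismatch(self, gal):
        net, p = gal
        with pytest.raises(ValueError):
            rhs(net, np.ones(5), p)
        with pytest.raises(ValueError):
            rhs(net, np.ones(9), np.ones(7))

    def test_stoichiometric_consistency(self, gal, rng):
        net, p = gal
        N = net.stoichiometry()
        for _ in range(5):
            x = rng.uniform(0.1, 100.0, size=9)
            np.testing.assert_allclose(
                rhs(net, x, p), N @ rate_vector(net, x, p), rtol=1e-13
            )


class TestJacobians:
    def _fd_jacobian_x(self, net, x, p, h=1e-6):
        J = np.zeros((net.n_species, net.n_species))
        for j in range(net.n_species):
            e = np.zeros(net.n_species)
            e[j] = h * max(1.0, abs(x[j]))
            J[:, j] = (rhs(net, x + e, p) - rhs(net, x - e, p)) / (2 * e[j])
        return J

    def test_gal_fd_agreement(self, gal, gal_xe):
        net, p = gal
        x1, _ = gal_xe
        J = jacobian_x(net, x1, p)
        Jfd = self._fd_jacobian_x(net, x1, p)
        assert np.max(np.abs(J - Jfd)) <= 1e-6 * np.max(np.abs(J))
        Jp = jacobian_p(net, x1, p)
        Jpfd = np.zeros_like(Jp)
        for j in range(net.n_parameters):
            e = np.zeros(net.n_parameters)
            e[j] = 1e-6 * p[j]
            Jpfd[:, j] = (rhs(net, x1, p + e) - rhs(net, x1, p - e)) / (2 * e[j])
        assert np.max(np.abs(Jp - Jpfd)) <= 1e-6 * np.max(np.abs(Jp))

    def test_linear_network_constant_jacobian(self, toys, rng):
        net = toys["linear_2d"].network
        J1 = jacobian_x(net, rng.uniform(0, 5, 2))
        J2 = jacobian_x(net, rng.uniform(0, 5, 2))
        np.testing.assert_allclose(J1, J2, atol=1e-14)

    def test_ineffective_parameter_column_zero(self):
        # catalytic self-loop: its rate constant moves nothing
        net = parse_model(
            """
species: [X]
parameters: {k: 1.0, idle: 5.0}
reactions:
  - "X -> 0 @ k"
  - "X -> X @ idle"
"""
        )
        Jp = jacobian_p(net, np.array([3.0]))
        assert Jp[0, net.parameter_index("idle")] == 0.0
        assert Jp[0, net.parameter_index("k")] != 0.0


class TestQuadraticDecomposition:
    def test_gal_hurwitz_at_low(self, gal, gal_xe):
        net, p = gal
        quad = quadratic_decomposition(net, p, gal_xe[0])
        assert np.max(np.linalg.eigvals(quad.A).real) < 0

    def test_exact_reconstruction(self, gal, gal_xe, rng):
        net, p = gal
        quad = quadratic_decomposition(net, p, gal_xe[0])
        scale = np.max(np.abs(gal_xe[0]))
        for _ in range(100):
            z = rng.normal(size=9) * 0.3 * scale
            ref = rhs(net, gal_xe[0] + z, p)
            err = np.max(np.abs(quad.rhs_shifted(z) - ref))
            assert err <= 1e-9 * max(1.0, np.max(np.abs(ref)))

    def test_symmetry_of_forms(self, gal, gal_xe):
        net, p = gal
        quad = quadratic_decomposition(net, p, gal_xe[0])
        for F in quad.F_list:
            np.testing.assert_allclose(F, F.T, atol=0)

    def test_linear_network_no_quadratic(self, toys):
        net = toys["linear_2d"].network
        quad = quadratic_decomposition(net, None, np.zeros(2))
        for F in quad.F_list:
            np.testing.assert_array_equal(F, 0.0)

    def test_1d_read_off(self, toys):
        net = toys["bistable_1d"].network
        quad = quadratic_decomposition(net, None, np.array([0.0]))
        np.testing.assert_allclose(quad.A, [[-1.0]])
        np.testing.assert_allclose(quad.F_list[0], [[1.0]])

    def test_rejects_non_equilibrium(self, gal):
        net, p = gal
        with pytest.raises(ValueError, match="not an equilibrium"):
            quadratic_decomposition(net, p, np.full(9, 7.0))


class TestFindEquilibria:
    def test_gal_three_equilibria(self, gal_equilibria):
        labels = [e.classification for e in gal_equilibria]
        assert labels == ["stable", "unstable", "stable"]
        low, saddle, high = gal_equilibria
        np.testing.assert_allclose(
            low.state, GAL_EQUILIBRIUM_LOW, rtol=1e-3
        )
        np.testing.assert_allclose(
            high.state, GAL_EQUILIBRIUM_HIGH, rtol=1e-3
        )
        # the saddle sits between the stable states along the expression axis
        i = 0  # G3
        assert low.state[i] < saddle.state[i] < high.state[i]

    def test_newton_from_printed_fast(self, gal):
        net, p = gal
        for guess in (GAL_EQUILIBRIUM_LOW, GAL_EQUILIBRIUM_HIGH):
            x, res, ok, n_iter = newton_refine(net, p, guess)
            assert ok and n_iter <= 5
            np.testing.assert_allclose(x, guess, rtol=1e-3)

    def test_birth_death_single(self, toys):
        toy = toys["birth_death"]
        eqs = find_equilibria(toy.network, None,
                              MultistartSpec(n_random=50, seed=0, lower=1e-2,
                                             upper=1e2))
        assert len(eqs) == 1
        assert eqs[0].stable
        np.testing.assert_allclose(eqs[0].state, [1.0], atol=1e-9)

    def test_bistable_1d(self, toys):
        toy = toys["bistable_1d"]
        eqs = find_equilibria(toy.network, None,
                              MultistartSpec(n_random=80, seed=0, lower=1e-3,
                                             upper=0.9))
        states = sorted(float(e.state[0]) for e in eqs)
        np.testing.assert_allclose(states, [0.0, 1.0], atol=1e-8)
        by_state = {round(float(e.state[0])): e for e in eqs}
        assert by_state[0].stable and not by_state[1].stable

    def test_bistable_2d_count_matches_cubic_oracle(self, toys):
        toy = toys["bistable_2d"]
        net = toy.network
        p = dict(zip(net.parameter_names, net.nominal_parameters()))
        # steady state: -(d e / f) x^3 + b x^2 - c x + a = 0, y = e x^2 / f
        coeffs = [-p["d"] * p["e"] / p["f"], p["b"], -p["c"], p["a"]]
        roots = np.roots(coeffs)
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0)
        eqs = find_equilibria(net, None,
                              MultistartSpec(n_random=120, seed=2, lower=1e-2,
                                             upper=1e2))
        assert len(eqs) == len(real) == 3
        np.testing.assert_allclose(
            sorted(e.state[0] for e in eqs), real, rtol=1e-8
        )
        assert [e.stable for e in sorted(eqs, key=lambda e: e.state[0])] == [
            True, False, True,
        ]


class TestSimulate:
    def test_equilibrium_is_fixed_point(self, gal, gal_xe):
        net, p = gal
        traj = simulate(net, p, gal_xe[0], 50.0, solver_tol=1e-10)
        assert np.max(np.abs(traj.endpoint - gal_xe[0])) <= 1e-5 * np.max(
            gal_xe[0]
        )

    def test_linear_decay_closed_form(self, toys):
        net = toys["linear_2d"].network
        traj = simulate(net, None, np.array([1.0, 0.0]), 5.0, solver_tol=1e-10)
        np.testing.assert_allclose(
            traj.y[0], np.exp(-traj.t), atol=1e-6
        )

    def test_nonnegative_initial_required(self, toys):
        net = toys["linear_2d"].network
        with pytest.raises(ValueError):
            simulate(net, None, np.array([-1.0, 0.0]), 1.0)

    def test_da_vertex_funnels_to_low_state(self, gal, gal_xe):
        from bistacert.network_model import GAL_DA_BOX_LOW

        net, p = gal
        x0 = GAL_DA_BOX_LOW[1]  # upper corner of the published low-state box
        traj = simulate(net, p, x0, 200.0)
        denom = np.maximum(np.abs(gal_xe[0]), 1.0)
        assert np.max(np.abs(traj.endpoint - gal_xe[0]) / denom) <= 0.01


class TestFixtures:
    def test_gal_table_values(self, gal):
        net, p = gal
        idx = net.parameter_index
        assert p[idx("k5")] == 22.0604
        assert p[idx("k8")] == 181.4157
        assert p[idx("kr19")] == 222.0536
        for name in ("mu3", "mu6", "mu12", "mu13", "mu14", "mu15", "mu16",
                     "mu17", "mu18"):
            assert p[idx(name)] == 1.0

    def test_gal_copy_is_independent(self):
        net1, p1 = gal_model()
        p1[0] = 99.0
        net2, p2 = gal_model()
        assert p2[0] == 0.1814

    def test_toy_catalog(self, toys):
        assert {"bistable_1d", "birth_death", "bistable_2d", "linear_2d"} <= set(
            toys
        )
        toy = toys["bistable_1d"]
        unstable = [s for s, stable in toy.equilibria if not stable]
        np.testing.assert_allclose(unstable[0], [1.0])


@settings(max_examples=25, deadline=None)
@given(st.floats(0.05, 50.0), st.floats(0.05, 50.0))
def test_rate_vector_positive_on_positive_states(x1, x2):
    net = toy_models_cached()["bistable_2d"].network
    v = rate_vector(net, np.array([x1, x2]))
    assert np.all(v >= 0)


_toy_cache = {}


def toy_models_cached():
    if not _toy_cache:
        from bistacert.network_model import toy_models

        _toy_cache.update(toy_models())
    return _toy_cache
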