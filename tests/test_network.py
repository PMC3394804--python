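"""Reaction-network construction, mass action, conservation, Jacobian."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import snarekin as sk
from snarekin.network import (
    NetworkError,
    Reaction,
    Species,
    build_network,
    format_reaction,
    parse_reaction,
)


def simple_abc():
    return build_network(
        [{"name": "A", "initial_concentration": 1.0},
         {"name": "B", "initial_concentration": 1.0},
         {"name": "C"}],
        [{"equation": "A + B <-> C", "k_forward": 1.0, "k_reverse": 1.0}],
    )


class TestBuildNetwork:
    def test_net_stoichiometry_column(self):
        net = simple_abc()
        assert net.stoichiometry.shape == (3, 1)
        assert list(net.stoichiometry[:, 0]) == [-1, -1, 1]

    def test_fundamental_shape(self, fundamental):
        net = fundamental.network
        assert net.n_species == 5
        assert net.n_reactions == 2
        assert all(r.reversible for r in net.reactions)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(reactants={"A": 1}, products={"B": 1}, k_forward=-1.0),
            dict(reactants={"A": 1}, products={"B": 1}, k_forward=1.0,
                 k_reverse=-0.1),
            dict(reactants={}, products={"B": 1}, k_forward=1.0),
            dict(reactants={"A": 0}, products={"B": 1}, k_forward=1.0),
        ],
    )
    def test_invalid_reactions_rejected(self, bad):
        with pytest.raises(NetworkError):
            Reaction(**bad)

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            build_network(
                [{"name": "A"}, {"name": "A"}],
                [{"equation": "A -> A", "k_forward": 1.0}],
            )

    def test_unknown_species_rejected(self):
        with pytest.raises(NetworkError, match="unknown species"):
            build_network(
                [{"name": "A"}],
                [{"equation": "A -> B", "k_forward": 1.0}],
            )

    def test_negative_initial_rejected(self):
        with pytest.raises(NetworkError):
            Species("A", initial_concentration=-0.1)


class TestMassActionRhs:
    def test_unit_bimolecular(self):
        net = build_network(
            [{"name": "A", "initial_concentration": 1.0},
             {"name": "B", "initial_concentration": 1.0},
             {"name": "C"}],
            [{"equation": "A + B -> C", "k_forward": 1.0}],
        )
        dx = sk.mass_action_rhs(net, np.array([1.0, 1.0, 0.0]))
        assert dx == pytest.approx([-1.0, -1.0, 1.0])

    def test_equilibrium_state_is_stationary(self):
        net = simple_abc()
        # [C]/([A][B]) = k_f/k_r = 2 at (0.5, 1.0, 1.0)
        net2 = build_network(
            [{"name": "A"}, {"name": "B"}, {"name": "C"}],
            [{"equation": "A + B <-> C", "k_forward": 2.0, "k_reverse": 1.0}],
        )
        dx = sk.mass_action_rhs(net2, np.array([0.5, 1.0, 1.0]))
        assert np.max(np.abs(dx)) < 1e-14

    @given(st.integers(0, 2**31 - 1))
    def test_rhs_orthogonal_to_conservation_laws(self, fundamental, seed):
        """dx/dt lies in the stoichiometric subspace: every conserved-moiety
        vector has zero time derivative at any state."""
        rng = np.random.default_rng(seed)
        state = rng.uniform(0.0, 10.0, 5)
        dx = sk.mass_action_rhs(fundamental.network, state)
        for law in fundamental.network.conservation_laws():
            assert abs(np.dot(law.coefficients, dx)) < 1e-10 * max(
                1.0, np.max(np.abs(dx))
            )

    def test_flux_homogeneity_in_reactants(self):
        """Doubling all concentrations scales a bimolecular forward flux 4x."""
        net = build_network(
            [{"name": "A"}, {"name": "B"}, {"name": "C"}],
            [{"equation": "A + B -> C", "k_forward": 0.7}],
        )
        x = np.array([1.3, 0.4, 0.0])
        f1 = net.fluxes(x)
        f2 = net.fluxes(2 * x)
        assert f2 == pytest.approx(4 * f1)

    def test_dimension_mismatch(self, fundamental):
        with pytest.raises(NetworkError):
            sk.mass_action_rhs(fundamental.network, np.zeros(3))


class TestConservationLaws:
    def test_fundamental_basis(self, fundamental):
        laws = sk.conservation_laws(fundamental.network)
        got = {tuple(l.coefficients) for l in laws}
        # SNAP25, syntaxin, VAMP2 moieties (canonical reduced form)
        assert got == {
            (1, 0, 0, 1, 1),
            (0, 1, 0, 1, 1),
            (0, 0, 1, 0, 1),
        }

    def test_munc18_moiety(self):
        net = sk.munc18_subsystem().network
        laws = sk.conservation_laws(net)
        idx = [net.index[s] for s in ("MUNC18", "Smc", "FHC**")]
        munc = [
            l for l in laws
            if all(l.coefficients[i] == 1 for i in idx)
            and sum(abs(c) for c in l.coefficients) == 3
        ]
        assert len(munc) == 1

    def test_single_irreversible_step(self):
        net = build_network(
            [{"name": "A", "initial_concentration": 2.0}, {"name": "B"}],
            [{"equation": "A -> B", "k_forward": 1.0}],
        )
        (law,) = sk.conservation_laws(net)
        assert tuple(law.coefficients) == (1, 1)
        assert law.total == pytest.approx(2.0)


class TestJacobian:
    def test_linear_decay(self):
        net = build_network(
            [{"name": "A"}, {"name": "B"}],
            [{"equation": "A -> B", "k_forward": 2.0}],
        )
        J = sk.jacobian(net, np.array([1.0, 0.0]))
        assert J == pytest.approx(np.array([[-2.0, 0.0], [2.0, 0.0]]))

    @pytest.mark.parametrize("model", ["fundamental", "full", "munc18"])
    def test_matches_finite_differences(self, model):
        variant = {
            "fundamental": sk.fundamental_subsystem,
            "full": lambda: sk.full_system(
                complexin=True, ca_mode="clamped", munc18=True
            ),
            "munc18": sk.munc18_subsystem,
        }[model]()
        net = variant.network
        rng = np.random.default_rng(123)
        for _ in range(20):
            x = rng.uniform(0.1, 5.0, net.n_species)
            J = net.jacobian(x)
            h = 1e-6
            for s in range(net.n_species):
                xp, xm = x.copy(), x.copy()
                xp[s] += h
                xm[s] -= h
                col = (net.rhs(xp) - net.rhs(xm)) / (2 * h)
                scale = max(1.0, np.max(np.abs(J)))
                assert np.max(np.abs(J[:, s] - col)) < 1e-5 * scale

    def test_conservation_weighted_columns_vanish(self, fundamental):
        net = fundamental.network
        x = np.array([0.3, 1.2, 0.8, 0.4, 0.6])
        J = net.jacobian(x)
        for law in net.conservation_laws():
            assert np.max(np.abs(np.asarray(law.coefficients) @ J)) < 1e-12


class TestSerialization:
    @pytest.mark.parametrize(
        "eq,reactants,products,rev",
        [
            ("A + B <-> C", {"A": 1, "B": 1}, {"C": 1}, True),
            ("2 A -> B", {"A": 2}, {"B": 1}, False),
            ("A + 2 B <-> C + D", {"A": 1, "B": 2}, {"C": 1, "D": 1}, True),
        ],
    )
    def test_parse_reaction(self, eq, reactants, products, rev):
        r, p, is_rev = parse_reaction(eq)
        assert (r, p, is_rev) == (reactants, products, rev)

    def test_parse_rejects_arrowless(self):
        with pytest.raises(NetworkError):
            parse_reaction("A + B = C")

    @pytest.mark.parametrize(
        "factory",
        [
            sk.fundamental_subsystem,
            lambda: sk.full_system(complexin=True, ca_mode="clamped",
                                   munc18=True, self_association=True),
            sk.munc18_subsystem,
        ],
    )
    def test_dict_round_trip_lossless(self, factory):
        net = factory().network
        back = type(net).from_dict(net.to_dict())
        assert back.species_names == net.species_names
        assert np.array_equal(back.stoichiometry, net.stoichiometry)
        assert np.array_equal(back.default_rates(), net.default_rates())
        assert back.clamped == net.clamped
        for a, b in zip(net.reactions, back.reactions):
            assert format_reaction(a) == format_reaction(b)
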