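"""Analytic/numeric steady states, classification, MUNC18 bistability."""

import numpy as np
import pytest

import snarekin as sk
from snarekin.models import ModelVariant
from snarekin.network import build_network
from snarekin.simulate import SimulationError

NEAR_IRREV = {"k1f": 0.7, "k1r": 0.7e-4, "k2f": 0.4, "k2r": 0.4e-4}


class TestAnalyticCaseA:
    def test_vamp2_limited_state(self):
        """S0=X0=2, V0=1: VAMP2 exhausts, leftover tSNARE = 1."""
        states = sk.analytic_steady_states(
            "A", {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 1.0}, NEAR_IRREV
        )
        st = max(states, key=lambda s: s["FHC"])
        assert st["FHC"] == pytest.approx(1.0, rel=1e-3)
        assert st["tSNARE"] == pytest.approx(1.0, rel=1e-2)
        assert st.classification in ("stable", "stable-node")

    def test_snap25_limited_state(self):
        """V0 > S0=X0: fusion level equals the SNARE-side total."""
        states = sk.analytic_steady_states(
            "A", {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 5.0}, NEAR_IRREV
        )
        st = max(states, key=lambda s: s["FHC"])
        assert st["FHC"] == pytest.approx(2.0, rel=1e-3)
        assert st["VAMP2"] == pytest.approx(3.0, rel=1e-2)

    def test_substitution_residual(self, fundamental):
        states = sk.analytic_steady_states(
            "A", {"SNAP25": 3.0, "syntaxin": 3.0, "VAMP2": 1.5}, NEAR_IRREV
        )
        params = fundamental.network.rates_from_mapping(NEAR_IRREV)
        for st in states:
            net = sk.fundamental_subsystem().network
            assert np.max(np.abs(net.rhs(st.state, params))) < 1e-6

    def test_unequal_initials_rejected(self):
        with pytest.raises(ValueError, match="case A"):
            sk.analytic_steady_states(
                "A", {"SNAP25": 1.0, "syntaxin": 2.0, "VAMP2": 1.0},
                NEAR_IRREV,
            )

    def test_reversible_regime_rejected_for_case_a(self):
        with pytest.raises(ValueError, match="near-irreversible"):
            sk.analytic_steady_states(
                "A", {"SNAP25": 1.0, "syntaxin": 1.0, "VAMP2": 1.0},
                {"k1f": 1.0, "k1r": 0.9, "k2f": 1.0, "k2r": 0.9},
            )

    def test_matches_long_time_integration(self, fundamental):
        rng = np.random.default_rng(5)
        cfg = sk.SimulationConfig(t_end=500.0, n_points=50)
        for _ in range(5):
            a = rng.uniform(0.5, 6)
            b = rng.uniform(0.5, 6)
            while abs(a - b) < 0.3:
                b = rng.uniform(0.5, 6)
            ini = {"SNAP25": a, "syntaxin": a, "VAMP2": b}
            states = sk.analytic_steady_states("A", ini, NEAR_IRREV)
            params = fundamental.network.rates_from_mapping(NEAR_IRREV)
            ss = sk.steady_state_by_integration(fundamental, params, ini, cfg)
            assert min(
                np.max(np.abs(st.state - ss.state)) for st in states
            ) < 1e-4


class TestCaseBandC:
    def test_case_b_enumerates_nonnegative_vertices(self):
        states = sk.analytic_steady_states(
            "B", {"SNAP25": 1.0, "syntaxin": 3.0, "VAMP2": 2.0}, NEAR_IRREV
        )
        assert len(states) >= 1
        st = max(states, key=lambda s: s["FHC"])
        assert st["FHC"] == pytest.approx(1.0, rel=1e-3)  # SNAP25 limiting
        assert st["syntaxin"] == pytest.approx(2.0, rel=1e-2)

    def test_case_c_accepts_comparable_rates(self, fundamental):
        params = {"k1f": 0.5, "k1r": 0.2, "k2f": 0.5, "k2r": 0.2}
        ini = {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 2.0}
        states = sk.analytic_steady_states("C", ini, params)
        assert states
        p = fundamental.network.rates_from_mapping(params)
        ss = sk.steady_state_by_integration(
            fundamental, p, ini, sk.SimulationConfig(t_end=200.0)
        )
        assert min(
            np.max(np.abs(st.state - ss.state)) for st in states
        ) < 1e-4


class TestNumericSteadyStates:
    def test_single_reversible_step_single_state(self):
        v = ModelVariant(
            "ab",
            build_network(
                [{"name": "A", "initial_concentration": 1.0}, {"name": "B"}],
                [{"equation": "A <-> B", "k_forward": 1.0, "k_reverse": 0.5}],
            ),
        )
        grid = [{"A": 1.0, "B": 0.0}, {"A": 0.2, "B": 0.8},
                {"A": 0.7, "B": 0.3}]
        states = sk.numeric_steady_states(v, None, grid)
        assert len(states) == 1

    def test_matches_analytic_in_case_a_regime(self, fundamental):
        ini = {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 1.0}
        analytic = sk.analytic_steady_states("A", ini, NEAR_IRREV)
        params = fundamental.network.rates_from_mapping(NEAR_IRREV)
        numeric = sk.numeric_steady_states(
            fundamental, params, [ini],
            sk.SimulationConfig(t_end=500.0, n_points=50),
        )
        d = min(
            np.max(np.abs(a.state - n.state))
            for a in analytic for n in numeric
        )
        assert d < 1e-4


class TestClassification:
    def test_linear_decay_projected_spectrum(self):
        v = ModelVariant(
            "ab",
            build_network(
                [{"name": "A"}, {"name": "B", "initial_concentration": 1.0}],
                [{"equation": "A -> B", "k_forward": 2.0}],
            ),
        )
        st = sk.classify_steady_state(v, None, np.array([0.0, 1.0]))
        assert len(st.eigenvalues) == 1
        assert st.eigenvalues[0].real == pytest.approx(-2.0)
        assert st.classification == "stable-node"

    def test_conserved_directions_excluded(self, fundamental):
        """The full-space Jacobian always has 3 zero eigenvalues along the
        moieties; the projected spectrum must not contain them."""
        ini = {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 1.0}
        (st,) = sk.analytic_steady_states("A", ini, NEAR_IRREV)
        assert len(st.eigenvalues) == 2  # 5 species - 3 conservation laws
        assert np.all(st.eigenvalues.real < 0)

    def test_nonstationary_state_rejected(self, fundamental):
        with pytest.raises(SimulationError, match="not stationary"):
            sk.classify_steady_state(
                fundamental, None, np.array([1.0, 1.0, 1.0, 0.0, 0.0])
            )


class TestFusionPredictor:
    @pytest.mark.parametrize(
        "initials,expected,regime",
        [
            ({"SNAP25": 1, "syntaxin": 2, "VAMP2": 3}, 1.0, "no-preformed"),
            ({"SNAP25": 1, "syntaxin": 2, "VAMP2": 3, "tSNARE": 2}, 3.0,
             "preformed"),
            ({"SNAP25": 0, "syntaxin": 5, "VAMP2": 5}, 0.0, "no-preformed"),
        ],
    )
    def test_min_rule(self, initials, expected, regime):
        pred = sk.fusion_level_predictor(initials)
        assert pred.predicted_fhc_infinity == expected
        assert pred.regime == regime

    def test_negative_initials_rejected(self):
        with pytest.raises(ValueError):
            sk.fusion_level_predictor({"SNAP25": -1, "syntaxin": 1,
                                       "VAMP2": 1})


class TestMunc18States:
    def test_no_munc18_single_state(self):
        states = sk.munc18_steady_states({"MUNC18": 1e-9})
        assert len(states) == 1

    def test_intermediate_m0_two_labeled_states(self):
        states = sk.munc18_steady_states({"MUNC18": 16.0}, seed=3)
        labels = {s.label for s in states}
        assert labels == {"high-fusion", "low-fusion"}
        tot = {"tSNARE": 20.0, "VAMP2": 8.0, "MUNC18": 16.0}
        for s in states:
            assert s["MUNC18"] < 1e-3 * tot["MUNC18"]
            if s.label == "high-fusion":
                assert s["VAMP2"] < 1e-3 * tot["VAMP2"]
            else:
                assert s["tSNARE"] < 1e-3 * tot["tSNARE"]

    def test_moiety_conservation_exact(self):
        for s in sk.munc18_steady_states({"MUNC18": 16.0}, seed=3):
            assert s["MUNC18"] + s["Smc"] + s["FHC**"] == pytest.approx(
                16.0, rel=1e-8
            )

    def test_nonzero_fhcstar2_rejected(self):
        with pytest.raises(ValueError, match="FHC"):
            sk.munc18_steady_states({"FHC**": 1.0})


class TestBistabilityScan:
    def test_window_and_monostable_flanks(self):
        scan = sk.bistability_scan(
            np.linspace(2, 28, 14), ic_samples=6, seed=1
        )
        assert scan.window is not None
        lo, hi = scan.window
        inside = (scan.m0_grid >= lo) & (scan.m0_grid <= hi)
        assert np.all(scan.n_stable_states[inside] == 2)
        assert np.all(scan.n_stable_states[~inside] == 1)

    def test_window_stable_under_grid_refinement(self):
        coarse = sk.bistability_scan(
            np.linspace(2, 28, 14), ic_samples=6, seed=1
        )
        fine = sk.bistability_scan(
            np.linspace(2, 28, 27), ic_samples=6, seed=1
        )
        step = coarse.m0_grid[1] - coarse.m0_grid[0]
        assert abs(coarse.window[0] - fine.window[0]) <= step
        assert abs(coarse.window[1] - fine.window[1]) <= step

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            sk.bistability_scan([-1.0, 2.0])
        with pytest.raises(ValueError):
            sk.bistability_scan([1.0, 2.0], ic_samples=1)
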