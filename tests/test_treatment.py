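"""Dose-response models: single drugs, JNK redirection, additive combos."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapkflow import (
    DrugSpec,
    Scenario,
    bach1_combo,
    bach1_hyperbolic,
    bach1_jnki,
    bach1_output,
    dose_response,
    get_scenario,
    hill_redirection,
    jnk_inflow,
    max_dose_for_cap,
    node_inhibition,
    propagate,
)
from mapkflow.constants import GAMMA3, K_JNK, K_MLK
from mapkflow.treatment import JNKI, MEKI, MLKI, P38I

doses = st.floats(0.0, 1.0, allow_nan=False)


class TestNodeInhibition:
    def test_zero_dose_gives_zero(self):
        assert node_inhibition(MEKI, 0.0, 0.2) == 0.0

    def test_dose_for_thirty_percent_inhibition(self):
        # MEKi with untreated inflow 0.2: xi(x) = 2x/(1+0.4x) = 0.3 at x=0.159574
        x = 0.3 / (2.0 - 0.4 * 0.3)
        assert x == pytest.approx(0.1596, abs=5e-5)
        assert node_inhibition(MEKI, x, 0.2) == pytest.approx(0.3)

    def test_zero_inflow_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            node_inhibition(MEKI, 0.5, 0.0)

    def test_incoherent_xi_warned_not_clipped(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            xi = node_inhibition(MEKI, 1.0, 0.2)
        assert xi == pytest.approx(2.0 / 1.4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.01, 10), st.floats(0.05, 1.0), doses)
    def test_removed_signal_identity(self, k, inflow, x):
        """xi * Y = K x / (1 + K x) exactly, independent of the inflow."""
        drug = DrugSpec("d", 3, k)
        xi = node_inhibition(drug, x, inflow)
        assert xi * inflow == pytest.approx(k * x / (1 + k * x), abs=1e-12)


class TestHyperbolic:
    @pytest.mark.parametrize(
        "k, x, expected",
        [
            (2.0, 0.0, 1.0),
            (2.0, 1.0, 1.0 / 3.0),
            (0.4, 1.0, 1.0 / 1.4),
            (0.0, 0.7, 1.0),
        ],
    )
    def test_closed_form(self, k, x, expected):
        assert bach1_hyperbolic(k, x) == pytest.approx(expected)

    def test_p38i_reaches_sixty_percent_suppression(self):
        assert 1.0 - bach1_hyperbolic(2.0, 1.0) >= 0.60


class TestJnkModel:
    def test_inflow_untreated_matches_propagation(self, n1):
        assert jnk_inflow(n1, 0.0) == pytest.approx(propagate(n1).inflow[6])

    def test_inflow_attenuation_at_full_dose(self, n1):
        y0 = propagate(n1).inflow[6]
        assert jnk_inflow(n1, 1.0) == pytest.approx(y0 / (1.0 + K_JNK))

    def test_inflow_strictly_decreasing(self, n1):
        grid = np.linspace(0, 1, 21)
        ys = [jnk_inflow(n1, x) for x in grid]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_mlki_coapplication_reduces_inflow(self, n1):
        assert jnk_inflow(n1, 0.5, mlki_active=True) < jnk_inflow(n1, 0.5)
        # node-5 share attenuated by 1/(1+K4 x)
        y0 = jnk_inflow(n1, 0.0, mlki_active=False)
        s = n1.splits
        mlk_share = s.alpha3 * s.alpha2 + s.A6 * s.A5 * s.A3 * s.alpha2
        x = 0.7
        expected = (y0 - mlk_share + mlk_share / (1 + K_MLK * x)) / (1 + K_JNK * x)
        assert jnk_inflow(n1, x, mlki_active=True) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gamma, y6, expected",
        [(GAMMA3, 0.0, 1.0), (2.0, 0.5, 0.5), (1.0, 1.0, 0.5)],
    )
    def test_hill_redirection_anchors(self, gamma, y6, expected):
        assert hill_redirection(gamma, y6) == pytest.approx(expected)

    def test_redirection_opens_under_treatment(self, n1):
        g0 = hill_redirection(GAMMA3, jnk_inflow(n1, 0.0))
        g1 = hill_redirection(GAMMA3, jnk_inflow(n1, 1.0))
        assert g0 < g1 < 1.0

    def test_jnki_untreated_and_minimal_suppression(self, n1):
        assert bach1_jnki(n1, 0.0) == pytest.approx(1.0)
        # the redirection model predicts only minimal BACH1 reduction on N1
        assert 0.8 < bach1_jnki(n1, 1.0) < 1.0

    def test_jnki_output_plus_surplus_is_one(self, n1):
        from mapkflow import surplus_node6

        for x in (0.1, 0.4, 0.9):
            assert bach1_jnki(n1, x) + surplus_node6(n1, x) == pytest.approx(1.0)

    def test_jnki_collapses_to_hyperbolic_without_crosstalk(self, n2):
        for x in (0.0, 0.3, 1.0):
            assert bach1_jnki(n2, x) == pytest.approx(
                float(bach1_hyperbolic(K_JNK, x))
            )


class TestCombo:
    def test_empty_scenario_is_untreated(self, n1):
        empty = Scenario("none", ())
        assert bach1_output(n1, empty, 0.7) == pytest.approx(1.0)

    def test_4d_at_restricted_dose(self, n1):
        # 1 - sum_i K_i*0.3/(1+K_i*0.3) over the four printed constants
        expected = 1.0 - sum(
            k * 0.3 / (1 + k * 0.3) for k in (2.0, 0.4, 0.475628, 0.1)
        )
        s4 = get_scenario("4d_mapki")
        assert bach1_combo(n1, s4, 0.3) == pytest.approx(expected)
        assert expected == pytest.approx(0.364, abs=5e-4)
        # at least 60% suppression under the restricted regimen
        assert 1.0 - bach1_combo(n1, s4, 0.3) >= 0.60

    def test_combo_clamped_at_zero(self, n1):
        assert bach1_combo(n1, get_scenario("4d_mapki"), 1.0) == 0.0

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Scenario("dup", (MEKI, DrugSpec("meki2", 3, 0.5)))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(doses)
    def test_combo_at_least_as_suppressive_as_components(self, n1, x):
        s4 = get_scenario("4d_mapki")
        phi4 = bach1_output(n1, s4, x)
        for name in ("p38i", "meki", "jnki", "mlki"):
            assert phi4 <= bach1_output(n1, get_scenario(name), x) + 1e-12


class TestDoseResponse:
    def test_p38i_grid_values(self, n1):
        curve = dose_response(n1, get_scenario("p38i"), [0.0, 0.5, 1.0])
        assert curve.phi == pytest.approx([1.0, 0.5, 1.0 / 3.0])

    def test_hyperbolic_curves_topology_independent(self, n1, n2):
        grid = np.linspace(0, 1, 11)
        for name in ("p38i", "meki", "mlki"):
            c1 = dose_response(n1, get_scenario(name), grid)
            c2 = dose_response(n2, get_scenario(name), grid)
            assert c1.phi == pytest.approx(c2.phi)

    def test_n2_jnki_variant_tagged(self, n2):
        curve = dose_response(n2, get_scenario("jnki"), [0.0, 1.0])
        assert "variant" in curve.metadata
        assert curve.phi[1] == pytest.approx(1.0 / (1.0 + K_JNK))

    @pytest.mark.parametrize("scenario", ["p38i", "meki", "jnki", "mlki", "4d_mapki"])
    @pytest.mark.parametrize("topo_fixture", ["n1", "n2"])
    def test_phi_starts_at_one_and_never_increases(
        self, scenario, topo_fixture, request
    ):
        topo = request.getfixturevalue(topo_fixture)
        grid = np.linspace(0, 1, 101)
        curve = dose_response(topo, get_scenario(scenario), grid)
        assert curve.phi[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(curve.phi) <= 1e-12)
        assert np.all((curve.phi >= 0) & (curve.phi <= 1))

    def test_unsorted_or_out_of_range_grid_rejected(self, n1):
        scen = get_scenario("p38i")
        with pytest.raises(ValueError):
            dose_response(n1, scen, [0.5, 0.2])
        with pytest.raises(ValueError):
            dose_response(n1, scen, [0.0, 1.5])

    def test_curve_frame_columns(self, n1):
        df = dose_response(n1, get_scenario("meki"), [0, 1]).to_frame()
        assert list(df.columns) == [
            "dose", "phi_bach1", "suppression_pct", "scenario", "topology",
        ]
        assert df["suppression_pct"].iloc[-1] == pytest.approx(100 * (1 - 1 / 1.4))


class TestDoseCap:
    def test_closed_form_solution(self):
        assert max_dose_for_cap(MEKI, 0.2, 0.3) == pytest.approx(
            0.3 / (2.0 - 0.4 * 0.3)
        )

    def test_zero_cap(self):
        assert max_dose_for_cap(P38I, 0.4, 0.0) == 0.0

    def test_unreachable_cap_diagnosed(self):
        # Delta = K/Y = 1.0 <= K*cap = 1.2: no finite dose reaches the cap
        with pytest.raises(ValueError, match="unreachable"):
            max_dose_for_cap(P38I, 2.0, 0.6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 5.0),
        st.floats(0.05, 1.0),
        st.floats(0.01, 0.6),
    )
    def test_round_trip_identity(self, k, inflow, cap):
        drug = DrugSpec("d", 3, k)
        delta = k / inflow
        if delta - k * cap <= 1e-9:
            return
        x_star = max_dose_for_cap(drug, inflow, cap)
        assert node_inhibition(drug, x_star, inflow) == pytest.approx(cap)
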