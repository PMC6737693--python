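"""Unit tests for the signaling-network model: topology, rate laws, simulation."""

import numpy as np
import pytest

from ernet.network import (
    NetworkModel,
    Reaction,
    Scenario,
    Species,
    Trajectory,
    SCENARIO_PRESETS,
    apply_treatment,
    build_reference_model,
    equilibrate,
    output_indicators,
    reaction_rate,
    rhs,
    simulate,
)

# The reference topology as (law, substrates, modifiers, products) tuples;
# every described signaling edge must appear exactly once.
EXPECTED_EDGES = {
    ("inducible_synthesis", (), ("E2",), ("ER",)),
    ("mass_action", ("ER",), (), ()),
    ("mass_action", ("ER",), ("E2",), ("ERa",)),
    ("mass_action", ("ERa",), (), ()),
    ("michaelis_menten", ("EGFR",), ("EGF",), ("pEGFR",)),
    ("michaelis_menten", ("EGFR",), ("ERa",), ("pEGFR",)),
    ("mass_action", ("pEGFR",), (), ("EGFR",)),
    ("michaelis_menten", ("ERK",), ("pEGFR",), ("pERK",)),
    ("mass_action", ("pERK",), (), ("ERK",)),
    ("mass_action", (), ("pEGFR",), ("PIP3",)),
    ("mass_action", ("PIP3",), (), ()),
    ("michaelis_menten", ("PIP3",), ("PTEN",), ()),
    ("michaelis_menten", ("Akt",), ("PIP3",), ("pAkt",)),
    ("mass_action", ("pAkt",), (), ("Akt",)),
    ("repressible_synthesis", (), ("Hes1",), ("PTEN",)),
    ("mass_action", ("PTEN",), (), ()),
    ("inducible_synthesis", (), ("ERa",), ("Notch1",)),
    ("mass_action", ("Notch1",), (), ()),
    ("mass_action", ("Notch1",), ("Dll1",), ("NICD",)),
    ("mass_action", ("NICD",), (), ()),
    ("inducible_synthesis", (), ("NICD",), ("Hes1",)),
    ("mass_action", ("Hes1",), (), ()),
    ("michaelis_menten", ("GSK3b",), ("pAkt",), ("pGSK3b",)),
    ("michaelis_menten", ("GSK3b",), ("pERK",), ("pGSK3b",)),
    ("mass_action", ("pGSK3b",), (), ("GSK3b",)),
    ("inducible_synthesis", (), ("ERa",), ("bCatenin",)),
    ("michaelis_menten", ("bCatenin",), ("GSK3b",), ()),
    ("mass_action", ("bCatenin",), (), ()),
}


class TestTopology:
    def test_conservation_pools_closed(self, model):
        assert model.pool_stoichiometry_closed()

    def test_edge_inventory(self, model):
        edges = [(r.law, r.substrates, r.modifiers, r.products) for r in model.reactions]
        assert len(edges) == len(set(edges)), "duplicate edges"
        assert set(edges) == EXPECTED_EDGES

    def test_no_erk_sos_feedback(self, model):
        # pERK must not feed back onto any EGFR/receptor-level reaction
        for r in model.reactions:
            if "pERK" in r.modifiers:
                assert set(r.substrates) == {"GSK3b"}

    def test_json_round_trip(self, model):
        assert NetworkModel.from_json(model.to_json()) == model

    def test_undeclared_species_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            NetworkModel(
                species=[Species("A")],
                reactions=[Reaction("r", "mass_action", substrates=("B",),
                                    parameters={"k": "k"})],
                conservation_pools={},
            )


class TestRateLaws:
    def test_michaelis_menten_half_saturation(self):
        r = Reaction("r", "michaelis_menten", substrates=("S",), modifiers=("M",),
                     parameters={"k": "k", "K": "K"})
        v = reaction_rate(r, {"S": 0.7, "M": 3.0}, {"k": 2.0, "K": 0.7})
        assert v == pytest.approx(2.0 * 3.0 / 2.0)

    def test_mass_action_product(self):
        r = Reaction("r", "mass_action", substrates=("S",), modifiers=("M",),
                     parameters={"k": "k"})
        assert reaction_rate(r, {"S": 2.0, "M": 3.0}, {"k": 0.1}) == pytest.approx(0.6)

    def test_repressible_half_and_limit(self):
        r = Reaction("r", "repressible_synthesis", modifiers=("M",),
                     parameters={"k": "k", "K": "K", "n": "n"})
        p = {"k": 1.0, "K": 1.0, "n": 2.0}
        assert reaction_rate(r, {"M": 1.0}, p) == pytest.approx(0.5)
        assert reaction_rate(r, {"M": 1e6}, p) == pytest.approx(0.0, abs=1e-11)

    def test_negative_state_rejected(self):
        r = Reaction("r", "mass_action", substrates=("S",), parameters={"k": "k"})
        with pytest.raises(ValueError, match="negative"):
            reaction_rate(r, {"S": -0.1}, {"k": 1.0})

    def test_gefitinib_scales_egfr_phosphorylation(self, model, params):
        r = model.reaction("egfr_phos_by_egf")
        state = {"EGFR": 1.0, "EGF": 1.0}
        sc0 = SCENARIO_PRESETS["High-EGF"]
        sc20 = apply_treatment(sc0, gefitinib_dose=20.0)
        v0 = reaction_rate(r, state, params, sc0)
        v20 = reaction_rate(r, state, params, sc20)
        assert v20 == pytest.approx(v0 / (1.0 + 20.0 / params["Ki_gef"]))
        # the printed dose suppresses its target by >= 90%
        assert v20 <= 0.1 * v0


class TestRHS:
    def test_zero_at_equilibrium(self, model, params, baseline_state):
        dx = rhs(model, baseline_state, SCENARIO_PRESETS["All-Low"], params)
        assert np.max(np.abs(dx)) < 1e-8

    def test_pool_closure_exact(self, model, params, rng):
        names = model.species_names
        for _ in range(5):
            x = rng.uniform(0.0, 2.0, len(names))
            dx = rhs(model, x, SCENARIO_PRESETS["All-High"], params)
            for members in model.conservation_pools.values():
                assert sum(dx[names.index(m)] for m in members) == 0.0

    def test_finite_difference_consistency(self, model, params, baseline_state, rng):
        sc = SCENARIO_PRESETS["All-High"]
        x = np.maximum(baseline_state + rng.uniform(0, 0.5, baseline_state.size), 1e-3)
        f0 = rhs(model, x, sc, params)
        h = 1e-6
        for i in rng.choice(len(x), size=6, replace=False):
            e = np.zeros_like(x)
            e[i] = h
            fd = (rhs(model, x + e, sc, params) - rhs(model, x - e, sc, params)) / (2 * h)
            # directional consistency: rhs is smooth, so the FD column must
            # match a refined FD to high accuracy
            fd2 = (rhs(model, x + e / 8, sc, params) - rhs(model, x - e / 8, sc, params)) / (h / 4)
            denom = np.maximum(np.abs(fd), 1e-6)
            assert np.max(np.abs(fd - fd2) / denom) < 1e-4

    def test_inputs_held_fixed(self, model, params, baseline_state):
        dx = rhs(model, baseline_state, SCENARIO_PRESETS["All-High"], params)
        for name in ("EGF", "E2", "Dll1"):
            assert dx[model.species_index(name)] == 0.0


def _single_decay_model(k_name="k_dec"):
    return NetworkModel(
        species=[Species("X", "scaffold", 1.0)],
        reactions=[Reaction("decay", "mass_action", substrates=("X",),
                            parameters={"k": k_name})],
        conservation_pools={},
        output_species=("X",),
    )


class TestSimulate:
    def test_frozen_system_constant(self):
        m = _single_decay_model()
        traj = simulate(m, Scenario("frozen"), {"k_dec": 0.0}, t_end=48.0,
                        x0=np.array([1.0]))
        assert np.allclose(traj.series("X"), 1.0, rtol=0, atol=1e-12)

    def test_first_order_decay_closed_form(self):
        m = _single_decay_model()
        traj = simulate(m, Scenario("decay"), {"k_dec": 0.1}, t_end=10.0,
                        x0=np.array([1.0]), rtol=1e-10, atol=1e-12)
        assert traj.value("X", 10.0) == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_tolerance_refinement(self, model, params, baseline_state):
        sc = SCENARIO_PRESETS["All-High"]
        t1 = simulate(model, sc, params, x0=baseline_state, rtol=1e-8, atol=1e-10)
        t2 = simulate(model, sc, params, x0=baseline_state, rtol=5e-9, atol=5e-11)
        for sp in model.output_species:
            a, b = t1.value(sp, 48.0), t2.value(sp, 48.0)
            assert abs(a - b) / abs(b) < 1e-4

    def test_two_stiff_integrators_agree(self, model, params, baseline_state):
        sc = SCENARIO_PRESETS["All-High"]
        t1 = simulate(model, sc, params, x0=baseline_state, method="LSODA")
        t2 = simulate(model, sc, params, x0=baseline_state, method="BDF")
        for sp in model.output_species:
            assert t1.value(sp, 48.0) == pytest.approx(t2.value(sp, 48.0), rel=1e-3)

    def test_conservation_and_nonnegativity_all_presets(self, model, params,
                                                        baseline_state):
        for sc in SCENARIO_PRESETS.values():
            traj = simulate(model, sc, params, x0=baseline_state)
            assert traj.states.min() >= -1e-9
            for members in model.conservation_pools.values():
                assert traj.pool_drift(members) < 1e-6

    def test_invalid_t_end(self, model, params):
        with pytest.raises(ValueError):
            simulate(model, SCENARIO_PRESETS["All-Low"], params, t_end=0.0)


class TestTreatment:
    def test_zero_dose_identity(self):
        sc = SCENARIO_PRESETS["All-High"]
        assert apply_treatment(sc, 0.0, 0.0) is sc

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            apply_treatment(SCENARIO_PRESETS["All-High"], -1.0, 0.0)

    def test_gefitinib_suppresses_all_high(self, model, params, baseline_state):
        sc = SCENARIO_PRESETS["All-High"]
        untreated = simulate(model, sc, params, x0=baseline_state)
        treated = simulate(model, apply_treatment(sc, gefitinib_dose=20.0), params,
                           x0=baseline_state)
        for sp in ("pAkt", "pERK"):
            assert treated.value(sp, 48.0) < untreated.value(sp, 48.0)


class TestOutputIndicators:
    def test_constant_trajectory(self):
        times = np.linspace(0, 48, 241)
        traj = Trajectory(times=times, states=np.full((1, 241), 2.5),
                          species_names=["pAkt"], scenario=Scenario("const"))
        row = output_indicators(traj, 48.0, outputs=("pAkt",))
        assert row["pAkt_readout"] == row["pAkt_peak"] == 2.5
        assert row["pAkt_peak_time"] == 0.0

    def test_peak_of_t_exp_minus_t(self):
        times = np.linspace(0, 48, 961)
        series = times * np.exp(-times)
        traj = Trajectory(times=times, states=series[None, :],
                          species_names=["Hes1"], scenario=Scenario("bump"))
        row = output_indicators(traj, 48.0, outputs=("Hes1",))
        assert abs(row["Hes1_peak_time"] - 1.0) <= times[1] - times[0]

    def test_readout_at_grid_point_exact(self, model, params, baseline_state):
        traj = simulate(model, SCENARIO_PRESETS["High-E2"], params, x0=baseline_state)
        k = 120
        row = output_indicators(traj, traj.times[k])
        assert row["pAkt_readout"] == traj.series("pAkt")[k]

    def test_readout_beyond_horizon_rejected(self, model, params, baseline_state):
        traj = simulate(model, SCENARIO_PRESETS["All-Low"], params, x0=baseline_state,
                        t_end=10.0)
        with pytest.raises(ValueError):
            output_indicators(traj, 48.0)
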