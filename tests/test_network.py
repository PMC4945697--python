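import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dissectflow.heart import ConvergenceError
from dissectflow.network import (BloodProperties, ConfigError, TearConnection,
                                 build_network, effective_diameter,
                                 lumen_flow_split, poiseuille_resistance,
                                 simulate, tear_resistance,
                                 tear_sensitivity_study)
from dissectflow.waveform import Waveform

BLOOD = BloodProperties()


class TestGeometry:
    @pytest.mark.parametrize("area,expected,digits", [
        (135.0, 13.0, 0),
        (68.0, 9.3, 1),
        (math.pi, 2.0, 6),
    ])
    def test_effective_diameter_examples(self, area, expected, digits):
        assert round(effective_diameter(area), digits) == pytest.approx(expected)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_diameter_area_scaling(self, area):
        assert effective_diameter(area / 2) == pytest.approx(
            effective_diameter(area) / math.sqrt(2), rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(0.0)

    def test_poiseuille_value(self):
        assert poiseuille_resistance(1.0, 1.0, BLOOD) == pytest.approx(
            1.0186e-2, rel=1e-3)

    def test_poiseuille_radius_scaling(self):
        r1 = poiseuille_resistance(1.0, 10.0, BLOOD)
        assert poiseuille_resistance(2.0, 10.0, BLOOD) == pytest.approx(
            r1 / 16.0, rel=1e-12)

    def test_poiseuille_zero_length_limit(self):
        assert poiseuille_resistance(1.0, 0.0, BLOOD) == 0.0

    def test_poiseuille_invalid_geometry(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(-1.0, 1.0, BLOOD)


class TestTearResistance:
    def test_entry_tear_value(self):
        tear = TearConnection("entry", "a", "b", area=135.0, channel_length=2.0)
        r = effective_diameter(135.0) / 2.0
        expected = 8.0 * BLOOD.mu * 2.0 / (math.pi * r ** 4)
        assert tear_resistance(tear, BLOOD) == pytest.approx(expected, rel=1e-12)
        assert tear_resistance(tear, BLOOD) == pytest.approx(1.104e-5, rel=1e-3)

    def test_area_scaling(self):
        big = TearConnection("t", "a", "b", area=40.0, channel_length=2.0)
        small = TearConnection("t", "a", "b", area=20.0, channel_length=2.0)
        assert tear_resistance(small, BLOOD) == pytest.approx(
            4.0 * tear_resistance(big, BLOOD), rel=1e-12)

    def test_exit_tear_more_resistive_than_entry(self):
        entry = TearConnection("e", "a", "b", area=135.0, channel_length=2.0)
        exit_ = TearConnection("x", "a", "b", area=68.0, channel_length=2.0)
        assert tear_resistance(exit_, BLOOD) > tear_resistance(entry, BLOOD)

    def test_orifice_term_adds_resistance(self):
        base = TearConnection("t", "a", "b", area=20.0, channel_length=2.0)
        orf = TearConnection("t", "a", "b", area=20.0, channel_length=2.0,
                             orifice=True)
        assert tear_resistance(orf, BLOOD, Q=1000.0) > tear_resistance(
            base, BLOOD, Q=1000.0)


class TestBuildNetwork:
    @pytest.mark.parametrize("variant,n_tears", [
        ("dissected_baseline", 17),
        ("maximal_tears", 19),
        ("minimal_tears", 2),
        ("undissected", 0),
    ])
    def test_variant_tear_counts(self, configs, variant, n_tears):
        topo = build_network(configs[variant])
        assert len(topo.tears) == n_tears
        assert len(topo.outlets) == 18

    def test_unknown_outlet_rejected(self, configs):
        cfg = {**configs["undissected"]}
        cfg["outlets"] = cfg["outlets"] + [{"name": "NotAnArtery", "node": "d1"}]
        with pytest.raises(ConfigError, match="NotAnArtery"):
            build_network(cfg)

    def test_tear_within_one_lumen_rejected(self, configs):
        cfg = dict(configs["dissected_baseline"])
        cfg["tears"] = cfg["tears"] + [
            {"name": "bad_tear", "from": "tl2", "to": "tl3", "area": 10.0}]
        with pytest.raises(ConfigError, match="bad_tear"):
            build_network(cfg)

    def test_disconnected_graph_rejected(self):
        cfg = {
            "name": "broken",
            "segments": [
                {"name": "s1", "from": "a", "to": "b", "R": 1.0},
                {"name": "s2", "from": "c", "to": "d", "R": 1.0},
            ],
            "outlets": [{"name": "o1", "node": "b", "R": 1.0},
                        {"name": "o2", "node": "d", "R": 1.0}],
            "inlet": {"node": "a"},
        }
        with pytest.raises(ConfigError, match="disconnected"):
            build_network(cfg)


def _single_outlet_config():
    return {
        "name": "single",
        "segments": [{"name": "s", "from": "in", "to": "n1", "R": 1e-4}],
        "outlets": [{"name": "RCCA", "node": "n1"}],
        "inlet": {"node": "in"},
    }


class TestSimulate:
    def test_single_windkessel_steady_state(self):
        topo = build_network(_single_outlet_config())
        q = 1000.0
        sol = simulate(topo, Waveform.constant(q, period=1.0, n=8))
        p = sol.node_pressure["n1"]
        expected = q * (0.80 + 4.53)  # RCCA Rp + Rd, Pd = 0
        assert p.mean() == pytest.approx(expected, rel=1e-8)
        assert sol.n_cycles <= 3

    def test_symmetric_branches_split_evenly(self):
        cfg = {
            "name": "sym",
            "segments": [
                {"name": "tl", "from": "in", "to": "m", "R": 2.0,
                 "lumen": "true_lumen"},
                {"name": "fl", "from": "in", "to": "m", "R": 2.0,
                 "lumen": "false_lumen"},
            ],
            "outlets": [{"name": "out", "node": "m", "R": 1.0}],
            "inlet": {"node": "in"},
            "probes": {"mid": ("tl", "fl")},
        }
        topo = build_network(cfg)
        sol = simulate(topo, Waveform.constant(2000.0, period=1.0, n=8))
        split = lumen_flow_split(sol, "mid")
        assert split["fraction_TL"] == pytest.approx(50.0, abs=1e-9)
        assert split["fraction_TL"] + split["fraction_FL"] == pytest.approx(
            100.0, abs=1e-9)

    def test_resistor_network_matches_direct_linear_solve(self):
        """Constant inflow through a pure-resistor mesh must agree with an
        independent nodal-conductance solve to near machine precision."""
        rng = np.random.default_rng(7)
        nodes = ["in", "a", "b", "c"]
        edges = [("in", "a"), ("in", "b"), ("a", "b"), ("a", "c"), ("b", "c")]
        rs = rng.uniform(0.5, 3.0, len(edges))
        grounds = {"c": 1.3, "b": 2.1}
        cfg = {
            "name": "mesh",
            "segments": [{"name": f"e{i}", "from": u, "to": v, "R": float(r)}
                         for i, ((u, v), r) in enumerate(zip(edges, rs))],
            "outlets": [{"name": f"g{n}", "node": n, "R": float(r)}
                        for n, r in grounds.items()],
            "inlet": {"node": "in"},
        }
        q_in = 10.0
        sol = simulate(build_network(cfg), Waveform.constant(q_in, period=1.0,
                                                             n=8))
        # independent oracle: assemble and solve the conductance system here
        idx = {n: i for i, n in enumerate(nodes)}
        G = np.zeros((4, 4))
        for (u, v), r in zip(edges, rs):
            i, j = idx[u], idx[v]
            G[i, i] += 1 / r
            G[j, j] += 1 / r
            G[i, j] -= 1 / r
            G[j, i] -= 1 / r
        for n, r in grounds.items():
            G[idx[n], idx[n]] += 1 / r
        rhs = np.zeros(4)
        rhs[idx["in"]] = q_in
        p_exact = np.linalg.solve(G, rhs)
        for n in nodes:
            np.testing.assert_allclose(sol.node_pressure[n].values,
                                       p_exact[idx[n]], rtol=1e-10)

    def test_mass_conservation_all_fixtures(self, variant_solutions):
        for name, sol in variant_solutions.items():
            total_out = sum(w.mean() for w in sol.outlet_flow.values())
            assert total_out == pytest.approx(sol.inlet_mean_flow, rel=1e-3), name

    def test_instantaneous_mass_conservation(self, variant_solutions):
        sol = variant_solutions["dissected_baseline"]
        q_out = np.sum([w.values for w in sol.outlet_flow.values()], axis=0)
        q_in = sol.element_flow["inlet"].values
        scale = np.abs(q_in).max()
        assert np.max(np.abs(q_out - q_in)) < 0.01 * scale

    def test_cyclic_convergence_within_seven_cycles(self, variant_solutions):
        for name, sol in variant_solutions.items():
            assert sol.converged and sol.n_cycles <= 7, name
            changes = [t["max_rel_change"] for t in sol.trace]
            assert all(b <= a * 1.01 for a, b in zip(changes[1:], changes[2:])), name

    def test_dt_refinement(self, configs, inflow):
        topo = build_network(configs["dissected_baseline"])
        coarse = simulate(topo, inflow, dt=1e-3)
        fine = simulate(topo, inflow, dt=5e-4)
        for o in topo.outlets:
            p0 = coarse.node_pressure[o.node].mean()
            p1 = fine.node_pressure[o.node].mean()
            assert p1 == pytest.approx(p0, rel=5e-3)

    def test_large_dt_rejected(self, configs, inflow):
        topo = build_network(configs["undissected"])
        with pytest.raises(ValueError):
            simulate(topo, inflow, dt=5e-3)

    def test_cycle_cap_raises_with_trace(self, configs, inflow):
        topo = build_network(configs["undissected"])
        with pytest.raises(ConvergenceError):
            simulate(topo, inflow, max_cycles=1)


class TestLumenSplit:
    def test_baseline_fraction_brackets_reference(self, variant_solutions):
        """The calibrated demonstration network carries 20-30 % of descending
        flow in the true lumen, bracketing the reference simulated 25 %."""
        sol = variant_solutions["dissected_baseline"]
        for station in ("proximal", "medial", "distal"):
            split = lumen_flow_split(sol, station)
            assert 20.0 <= split["fraction_TL"] <= 30.0

    def test_fractions_sum_to_hundred(self, variant_solutions):
        sol = variant_solutions["dissected_baseline"]
        s = lumen_flow_split(sol, "proximal")
        assert s["fraction_TL"] + s["fraction_FL"] == pytest.approx(100.0,
                                                                    abs=1e-9)

    def test_unknown_station_rejected(self, variant_solutions):
        with pytest.raises(KeyError):
            lumen_flow_split(variant_solutions["dissected_baseline"], "nowhere")

    def test_mismatched_elements_rejected(self, variant_solutions):
        sol = variant_solutions["dissected_baseline"]
        with pytest.raises(ValueError):
            lumen_flow_split(sol, ("fl_1_2", "fl_2_3"))


@pytest.fixture(scope="module")
def study(configs, inflow):
    return tear_sensitivity_study(
        configs["dissected_baseline"],
        {"minimal": configs["minimal_tears"],
         "maximal": configs["maximal_tears"]},
        inflow,
    )


class TestTearSensitivity:
    def test_base_changes_are_zero(self, study):
        base = study.loc["base"]
        for col in study.columns:
            if col.endswith("_pct_change"):
                assert base[col] == pytest.approx(0.0, abs=1e-9)

    def test_minimal_tears_directions(self, study):
        """Removing the secondary tears forces visceral demand through the
        narrow true lumen: TL flow rises, TL peak pressure falls."""
        minimal = study.loc["minimal"]
        assert minimal["TL_mean_flow_pct_change"] > 0.0
        assert minimal["TL_peak_flow_pct_change"] > 0.0
        assert minimal["TL_peak_pressure_pct_change"] < 0.0

    def test_maximal_perturbs_less_than_minimal(self, study):
        assert (abs(study.loc["maximal", "TL_mean_flow_pct_change"])
                < abs(study.loc["minimal", "TL_mean_flow_pct_change"]))


class TestPressureEqualisation:
    def test_adding_tears_weakly_equalises_lumina(self, variant_solutions):
        def max_dp(sol):
            worst = 0.0
            for i in range(1, 7):
                d = np.abs(sol.node_pressure[f"tl{i}"].values
                           - sol.node_pressure[f"fl{i}"].values)
                worst = max(worst, float(d.max()))
            return worst

        d_min = max_dp(variant_solutions["minimal_tears"])
        d_base = max_dp(variant_solutions["dissected_baseline"])
        d_max = max_dp(variant_solutions["maximal_tears"])
        assert d_base <= d_min * (1 + 1e-9)
        assert d_max <= d_base * (1 + 1e-9)


class TestHeartCoupling:
    def test_network_heart_matches_standalone_loop(self, heart_params,
                                                   reference_heart_run):
        """The monolithic network solver with the heart at the inlet must
        agree with the dedicated heart-afterload integrator."""
        from dissectflow.synthetic import single_rcr_afterload
        wk = single_rcr_afterload()
        cfg = {
            "name": "heart_rcr",
            "segments": [{"name": "root", "from": "aortic_root", "to": "n1",
                          "radius": 14.0, "length": 10.0}],
            "outlets": [{"name": "sys", "node": "n1", "Rp": wk.Rp, "C": wk.C,
                         "Rd": wk.Rd}],
            "inlet": {"node": "aortic_root"},
        }
        sol = simulate(build_network(cfg), heart_params, max_cycles=25)
        run = reference_heart_run
        assert sol.heart["Q_av"].mean() == pytest.approx(run.mean_co, rel=5e-3)
        assert sol.heart["Q_av"].metrics()["peak"] == pytest.approx(
            run.peak_co, rel=5e-3)
        assert sol.heart["V_LV"].values.max() == pytest.approx(run.V.max(),
                                                               rel=5e-3)
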