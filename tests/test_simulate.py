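"""Integration, events, steady states, and trajectory summaries."""

import numpy as np
import pytest

from conftest import make_toy_model
from picycle.model import ActivationScheme, apply_activation, binding_equilibrium
from picycle.simulate import TimeCourse, find_steady_state, simulate, summarize


class TestClosedForms:
    def test_exponential_decay_matches_closed_form(self):
        k, a0 = 0.1, 1000.0
        model = make_toy_model(
            {"A": a0, "B": 0.0},
            [("decay", [("A", 1)], [("B", 1)], "k")],
            {"k": k},
        )
        t = np.linspace(0.0, 60.0, 61)
        tc = simulate(model, 60.0, t)
        expected = a0 * np.exp(-k * t)
        assert np.max(np.abs(tc["A"] - expected) / a0) < 1e-6
        assert np.max(np.abs(tc["B"] - (a0 - expected)) / a0) < 1e-6

    def test_binding_equilibrium_reached(self):
        # L + B <-> C relaxes to the root of the conservation quadratic
        kon, koff = 1e-6, 0.1
        l0, b0 = 5e5, 3e5
        model = make_toy_model(
            {"L": l0, "B": b0, "C": 0.0},
            [
                ("on", [("L", 1), ("B", 1)], [("C", 1)], "kon"),
                ("off", [("C", 1)], [("L", 1), ("B", 1)], "koff"),
            ],
            {"kon": kon, "koff": koff},
        )
        ss = find_steady_state(model)
        assert ss.converged
        expected = binding_equilibrium(l0, b0, koff / kon)
        assert ss.amounts["C"] == pytest.approx(expected, rel=1e-6)
        # conservation respected
        assert ss.amounts["L"] + ss.amounts["C"] == pytest.approx(l0, rel=1e-9)


class TestSteadyState:
    def test_shipped_platelet_rests_at_homeostasis(self, platelet_basal):
        ss = find_steady_state(platelet_basal)
        assert ss.converged
        pip2 = ss.amounts["PI45P2"] + ss.amounts["PI45P2_BP"]
        pi4p = ss.amounts["PI4P"] + ss.amounts["PI4P_BP"]
        assert 1.2e6 <= pip2 <= 1.8e6
        assert 1.2e6 <= pi4p <= 1.8e6
        assert ss.amounts["PI_m"] == pytest.approx(6.0e6, rel=0.05)

    def test_unactivated_run_from_steady_state_is_flat(self, platelet_basal):
        tc = simulate(platelet_basal, 1000.0, np.linspace(0.0, 1000.0, 101))
        for i, name in enumerate(tc.species):
            col = tc.amounts[:, i]
            if col[0] > 0:
                assert np.max(np.abs(col - col[0])) / col[0] < 1e-3

    def test_near_zero_rates_keep_initial_state(self):
        model = make_toy_model(
            {"A": 10.0, "B": 1.0},
            [("r", [("A", 1)], [("B", 1)], "k")],
            {"k": 1e-30},
        )
        ss = find_steady_state(model)
        assert ss.amounts["A"] == pytest.approx(10.0)
        assert ss.amounts["B"] == pytest.approx(1.0)


class TestActivationDynamics:
    def test_pi4p_pip2_burst_within_20s_then_return(self, platelet_trajectory):
        tc = platelet_trajectory
        for obs in ("PI4P", "PI45P2"):
            v = tc.observable(obs)
            post = tc.times >= 100.0
            t_peak = tc.times[post][np.argmax(v[post])]
            assert 0.0 < t_peak - 100.0 <= 20.0
            assert v[post].max() > v[0]
            # relaxes back to a stable level near baseline (the residual
            # offset tracks the depleted membrane PI pool)
            assert 0.6 < v[-1] / v[0] < 1.1
            settled = np.interp(600.0, tc.times, v)
            assert abs(v[-1] - settled) / v[0] < 0.1

    def test_zero_receptor_activation_changes_nothing(self, platelet_basal):
        grid = np.linspace(0.0, 500.0, 201)
        base = simulate(platelet_basal, 500.0, grid)
        null = apply_activation(
            platelet_basal, ActivationScheme(100.0, 0.0)
        )
        tc = simulate(null, 500.0, grid)
        scale = np.abs(base.amounts).max()
        assert np.max(np.abs(tc.amounts - base.amounts)) / scale < 1e-8

    def test_empty_event_is_idempotent(self, platelet_basal):
        grid = np.linspace(0.0, 500.0, 201)
        base = simulate(platelet_basal, 500.0, grid)
        null = apply_activation(platelet_basal, ActivationScheme(100.0, 0.0, ()))
        tc = simulate(null, 500.0, grid)
        scale = np.abs(base.amounts).max()
        assert np.max(np.abs(tc.amounts - base.amounts)) / scale < 1e-8

    def test_grid_refinement_stability(self, platelet, platelet_trajectory):
        tight = simulate(platelet, 2000.0, np.linspace(0.0, 2000.0, 2001),
                         rtol=0.5e-8, atol=0.5e-6)
        for obs in ("IP3", "PI4P", "PI45P2", "DAG"):
            a = platelet_trajectory.observable(obs).max()
            b = tight.observable(obs).max()
            assert abs(a - b) / max(a, 1.0) < 1e-3


class TestConservation:
    REL = 1e-6

    def test_enzyme_totals_conserved(self, platelet_trajectory):
        tc = platelet_trajectory
        for pools in (("Gq", "Gq_a"), ("PLCb", "PLCb_a")):
            total = sum(tc[p] for p in pools)
            assert np.max(np.abs(total - total[0])) / total[0] < self.REL
        for enzyme in ("PI4K", "PIP5K", "OCRL1", "SAC1", "DGK", "LPP",
                       "CDIPT", "IP3E", "cPLA2", "smG"):
            v = tc[enzyme]
            assert np.max(np.abs(v - v[0])) / v[0] < self.REL

    def test_binding_protein_totals_conserved(self, platelet, platelet_trajectory):
        tc = platelet_trajectory
        for pair in platelet.binding_pairs:
            total = tc[pair.bp] + tc[pair.complex]
            assert np.max(np.abs(total - pair.bp_total)) / max(pair.bp_total, 1.0) < self.REL

    def test_inositol_moiety_conserved(self, platelet_trajectory):
        tc = platelet_trajectory
        total = sum(
            tc[name]
            for name in ("PI_m", "PI_o", "PI4P", "PI45P2", "IP3", "IPx", "Ins",
                         "PI4P_BP", "PI45P2_BP")
        )
        assert np.max(np.abs(total - total[0])) / total[0] < self.REL

    def test_glycerol_backbone_conserved(self, platelet_trajectory):
        tc = platelet_trajectory
        total = sum(
            tc[name]
            for name in ("PI_m", "PI_o", "PI4P", "PI45P2", "DAG", "PA",
                         "PI4P_BP", "PI45P2_BP", "DAG_BP", "PA_BP")
        )
        assert np.max(np.abs(total - total[0])) / total[0] < self.REL


class TestSummarize:
    def test_constant_trajectory(self):
        tc = TimeCourse(np.linspace(0, 10, 11), ["X"], np.full((11, 1), 7.0))
        s = summarize(tc, "X")
        assert s.peak == 7.0 and s.ratio_to_initial == 1.0

    def test_triangle_wave_against_array_scan(self):
        t = np.linspace(0.0, 10.0, 101)
        v = np.where(t <= 4.0, t, np.maximum(8.0 - t, 0.0)) + 1.0
        tc = TimeCourse(t, ["X"], v[:, None])
        s = summarize(tc, "X", (0.0, 10.0))
        i = int(np.argmax(v))  # direct scan oracle
        assert s.peak == v[i] and s.time_of_peak == t[i]
        assert s.ratio_to_initial == pytest.approx(v[i] / v[0])
        assert s.level_at(2.5) == pytest.approx(np.interp(2.5, t, v))

    def test_ip3_peaks_within_tens_of_seconds_of_activation(self, platelet_trajectory):
        s = summarize(platelet_trajectory, "IP3", (100.0, 2000.0))
        assert 100.0 < s.time_of_peak < 200.0

    def test_unknown_species_raises(self, platelet_trajectory):
        with pytest.raises(KeyError):
            summarize(platelet_trajectory, "NOPE")

    def test_window_outside_range_raises(self, platelet_trajectory):
        with pytest.raises(ValueError):
            summarize(platelet_trajectory, "IP3", (0.0, 99999.0))


class TestTimeCourseIO:
    def test_csv_round_trip(self, tmp_path, platelet_trajectory):
        path = tmp_path / "tc.csv"
        sub = TimeCourse(
            platelet_trajectory.times[:50],
            platelet_trajectory.species,
            platelet_trajectory.amounts[:50],
        )
        sub.to_csv(path)
        back = TimeCourse.from_csv(path)
        assert sorted(back.species) == sorted(sub.species)
        for name in sub.species:
            assert np.allclose(back[name], sub[name])
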