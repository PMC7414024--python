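"""Scan-based calibration: deviations, grids, recovery, staged fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picycle.calibrate import (
    CalibrationState,
    ScanSpec,
    deviation,
    fit_iteration,
    get_parameter,
    scan_binding_protein_number,
    scan_parameter,
    set_parameter,
    staged_model,
)
from picycle.model import Reaction, platelet_model
from picycle.simulate import simulate
from picycle.synthetic import ExperimentalDataset, SyntheticTruth, generate_timecourses

TIMES = np.array([0.0, 50.0, 100.0, 110.0, 125.0, 150.0, 200.0, 300.0, 450.0,
                  600.0, 900.0, 1200.0, 1800.0])


def _dataset(observable, times, values, n=10):
    return ExperimentalDataset(observable, times, np.asarray(values, float),
                               np.zeros(len(times)), n)


@pytest.fixture(scope="module")
def platelet_data(platelet):
    """Noise-free pseudo-data generated by the shipped model itself."""
    return generate_timecourses(SyntheticTruth(platelet, noise_sd=0.0), times=TIMES)


class TestDeviation:
    def test_perfect_match_is_accepted(self, platelet, platelet_data):
        tc = simulate(platelet, 1800.0, TIMES)
        devs = deviation(tc, platelet_data)
        assert all(d < 1e-6 for d in devs.values())

    def test_25_percent_excess_is_rejected(self):
        times = np.array([0.0, 1.0, 2.0])
        mean = np.array([4.0, 4.0, 4.0])
        from picycle.simulate import TimeCourse

        tc = TimeCourse(times, ["Ins"], (1.25 * mean)[:, None])
        devs = deviation(tc, {"Ins": _dataset("Ins", times, mean)})
        assert devs["Ins"] == pytest.approx(0.25)
        assert devs["Ins"] > 0.20  # rejected by the 20% rule

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0.0, 10.0, 5))
        times += np.arange(5) * 1e-6  # strictness
        sim = rng.uniform(0.0, 100.0, 5)
        mean = rng.uniform(0.0, 100.0, 5)
        from picycle.simulate import TimeCourse

        tc = TimeCourse(times, ["Ins"], sim[:, None])
        got = deviation(tc, {"Ins": _dataset("Ins", times, mean)})["Ins"]
        floor = 0.01 * np.max(np.abs(mean))
        expected = 0.0
        for s, m in zip(sim, mean):  # direct loop re-computation
            expected = max(expected, abs(s - m) / max(abs(m), floor))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_empty_dataset_raises(self, platelet_trajectory):
        with pytest.raises(ValueError, match="empty"):
            deviation(platelet_trajectory, {})


class TestScanSpec:
    def test_two_decade_scan_has_21_points(self):
        spec = ScanSpec("rate:k6", 1.0, span=2.0, points_per_decade=5)
        assert spec.grid().size == 21

    def test_grid_is_log_spaced_and_centred(self):
        spec = ScanSpec("rate:k6", 1e-3, span=1.0, points_per_decade=5)
        g = spec.grid()
        assert g[5] == pytest.approx(1e-3)
        assert np.allclose(np.diff(np.log10(g)), 0.2)


class TestScanParameter:
    def test_recovers_displaced_truth_within_one_step(self, platelet):
        spec = ScanSpec("rate:k6", get_parameter(platelet, "rate:k6"),
                        span=1.0, points_per_decade=5)
        k_star = spec.grid()[7]  # two grid steps above centre
        truth = set_parameter(platelet, "rate:k6", float(k_star))
        data = generate_timecourses(SyntheticTruth(truth, 0.0), ("IP3",), TIMES)
        ranked = scan_parameter(platelet, spec, data)
        best = ranked[0].parameters["rate:k6"]
        assert abs(np.log10(best / k_star)) <= np.log10(spec.step_factor) + 1e-9

    def test_insensitive_parameter_gives_flat_ranking(self, platelet):
        # IPx -> Ins rate has no effect on the membrane PI observable
        data = generate_timecourses(SyntheticTruth(platelet, 0.0), ("PI",), TIMES)
        spec = ScanSpec("rate:k7", get_parameter(platelet, "rate:k7"),
                        span=1.0, points_per_decade=3)
        ranked = scan_parameter(platelet, spec, data)
        worsts = [r.worst for r in ranked]
        assert max(worsts) - min(worsts) < 1e-6
        # ties broken toward the smaller parameter value
        values = [r.parameters["rate:k7"] for r in ranked]
        assert values == sorted(values)

    def test_unknown_parameter_raises(self, platelet, platelet_data):
        with pytest.raises(KeyError):
            scan_parameter(platelet, ScanSpec("rate:nope", 1.0, 1.0), platelet_data)


class TestBindingProteinScan:
    def test_recovers_shipped_pool_size(self, platelet):
        data = generate_timecourses(
            SyntheticTruth(platelet, 0.0), ("PI45P2", "IP3"), TIMES
        )
        pred = scan_binding_protein_number(
            platelet, "PI45P2", data, center=1.0e6, span=1.0,
            rate_grid_points=1, refine=True,
        )
        assert pred.accepted
        # shipped pool is 1.3e6; prediction within one coarse grid step
        assert 1.3e6 / 10 ** 0.2 <= pred.bp_total <= 1.3e6 * 10 ** 0.2

    def test_unbuffered_lipid_is_rejected(self, platelet):
        data = generate_timecourses(
            SyntheticTruth(platelet, 0.0), ("PI45P2", "IP3"), TIMES
        )
        zero = set_parameter(platelet, "bp:PI45P2:total", 0.0)
        tc = simulate(zero, 1800.0, TIMES)
        devs = deviation(tc, data)
        assert max(devs.values()) > 0.20


class TestFitIterations:
    def test_stage_out_of_order_raises(self, platelet_data):
        with pytest.raises(ValueError, match="stage 2"):
            fit_iteration(3, platelet_data, CalibrationState(stage_done=1))

    def test_stage1_recovers_basal_axis_rates(self):
        spec_step = 10 ** 0.2
        truth_model = staged_model(1)
        displaced = {
            "rate:k16": get_parameter(truth_model, "rate:k16") * spec_step**2,
            "rate:k14": get_parameter(truth_model, "rate:k14") / spec_step**2,
        }
        for address, value in displaced.items():
            truth_model = set_parameter(truth_model, address, value)
        data = generate_timecourses(
            SyntheticTruth(truth_model, 0.0), ("PI", "PI4P", "PI45P2"),
            np.linspace(0.0, 2000.0, 21),
        )
        model, state = fit_iteration(1, data, span=0.6, points_per_decade=5)
        for address, value in displaced.items():
            got = state.values[address]
            assert abs(np.log10(got / value)) <= np.log10(spec_step) + 1e-9

    def test_single_step_ip3_to_ins_cannot_fit(self, platelet, platelet_data):
        """A direct IP3 -> Ins reaction cannot reproduce both the fast IP3
        decay and the slow inositol rise produced by the two-step removal."""
        direct = platelet.copy()
        direct.reactions = [r for r in direct.reactions if r.id != "r_ipx"]
        for r in direct.reactions:
            if r.id == "r_ip3e":
                r.products = [("Ins", 1)]
        direct.validate()
        data = {k: v for k, v in platelet_data.items() if k in ("IP3", "Ins")}
        spec = ScanSpec("rate:k6", get_parameter(direct, "rate:k6"),
                        span=2.0, points_per_decade=3)
        ranked = scan_parameter(direct, spec, data)
        assert not ranked[0].accepted
        assert ranked[0].worst > 0.20

    def test_stage2_recovers_activated_rates(self):
        state = CalibrationState(stage_done=1)  # stage-1 values at defaults
        truth = staged_model(2)
        step = 10 ** 0.2
        k5_star = get_parameter(truth, "rate:k5") * step**2
        truth = set_parameter(truth, "rate:k5", k5_star)
        data = generate_timecourses(
            SyntheticTruth(truth, 0.0), ("PI", "PI4P", "PI45P2"), TIMES)
        model, out = fit_iteration(2, data, state, span=0.6, points_per_decade=5)
        assert out.stage_done == 2
        got = out.values["rate:k5"]
        assert abs(np.log10(got / k5_star)) <= 0.2 + 1e-9

    def test_stage4_recovers_downstream_rates(self):
        state = CalibrationState(stage_done=3)
        truth = staged_model(4)
        step = 10 ** 0.2
        k8_star = get_parameter(truth, "rate:k8") * step**2
        truth = set_parameter(truth, "rate:k8", k8_star)
        data = generate_timecourses(
            SyntheticTruth(truth, 0.0), ("IP3", "Ins", "DAG", "PA"), TIMES)
        model, out = fit_iteration(4, data, state, span=0.6, points_per_decade=5)
        got = out.values["rate:k8"]
        assert abs(np.log10(got / k8_star)) <= 0.2 + 1e-9

    def test_noisy_recovery_within_two_grid_steps(self):
        """With 10% multiplicative noise, stage-1 scans still land within
        two grid steps of the truth for >= 90% of parameters over 20 seeds."""
        truth = staged_model(1)
        step = np.log10(10 ** 0.2)
        hits = total = 0
        for seed in range(20):
            data = generate_timecourses(
                SyntheticTruth(truth, noise_sd=0.1, seed=seed),
                ("PI", "PI4P", "PI45P2"), np.linspace(0.0, 2000.0, 21))
            _, state = fit_iteration(1, data, span=0.6, points_per_decade=5,
                                     passes=1)
            for address, got in state.values.items():
                want = get_parameter(truth, address)
                total += 1
                if abs(np.log10(got / want)) <= 2 * step + 1e-9:
                    hits += 1
        assert hits / total >= 0.9
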