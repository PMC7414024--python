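"""Mosaic mix-and-match: enumeration, classification, and summaries."""

import numpy as np
import pytest

from picycle.celltypes import ProteomeTable
from picycle.datasets import load_proteome
from picycle.model import KEY_PROTEINS, PLATELET_PROTEOME, platelet_model
from picycle.mosaic import (
    BehaviourVerdict,
    ClassifierConfig,
    classify_behaviour,
    enumerate_combinations,
    mix_and_match,
)
from picycle.simulate import TimeCourse

T_ACT = 1000.0
GRID = np.linspace(0.0, 5000.0, 251)


def synthetic_reference(seed=0):
    """A hand-built reference: stable baselines with post-activation pulses
    (up for the messengers, down for PI)."""
    rng = np.random.default_rng(seed)
    cols, names = [], []
    pulse = np.exp(-((GRID - (T_ACT + 300.0)) / 400.0) ** 2) * (GRID > T_ACT)
    for obs, base, amp in [
        ("PI_m", 1e8, -5e7), ("PI4P", 2e7, 4e6), ("PI45P2", 8e6, 3e6),
        ("IP3", 0.0, 8e5), ("DAG", 0.0, 3e6), ("PA", 0.0, 3e6),
        ("Ins", 8e7, 4e6),
    ]:
        cols.append(base + amp * pulse)
        names.append(obs)
    return TimeCourse(GRID, names, np.column_stack(cols))


class TestEnumeration:
    def test_exhaustive_4096_unique_stable(self):
        combos = enumerate_combinations()
        assert len(combos) == 4096
        labels = [c.label() for c in combos]
        assert len(set(labels)) == 4096
        assert labels[0] == "A" * 12 and labels[-1] == "B" * 12
        # stable lexicographic order
        assert labels == sorted(labels)
        assert enumerate_combinations() == combos

    def test_smaller_protein_sets(self):
        assert len(enumerate_combinations(KEY_PROTEINS[:3])) == 8


class TestClassifier:
    def test_reference_against_itself_is_correct(self):
        ref = synthetic_reference()
        verdict = classify_behaviour(ref, ref, ClassifierConfig(), T_ACT)
        assert verdict.overall
        assert all(verdict.per_observable.values())

    def test_hundredfold_low_ip3_peak_is_incorrect(self):
        ref = synthetic_reference()
        sim = TimeCourse(GRID, ref.species, ref.amounts.copy())
        i = sim.species.index("IP3")
        sim.amounts[:, i] = sim.amounts[:, i] / 100.0
        verdict = classify_behaviour(sim, ref, ClassifierConfig(), T_ACT)
        assert not verdict.per_observable["IP3"]
        assert not verdict.overall

    def test_pre_activation_drift_is_incorrect(self):
        ref = synthetic_reference()
        sim = TimeCourse(GRID, ref.species, ref.amounts.copy())
        i = sim.species.index("PI4P")
        # 30% upward ramp across the pre-activation window
        sim.amounts[:, i] = sim.amounts[:, i] * (1.0 + 0.3 * np.minimum(GRID / T_ACT, 1.0))
        verdict = classify_behaviour(sim, ref, ClassifierConfig(), T_ACT)
        assert not verdict.per_observable["PI4P"]

    def test_opposite_direction_is_incorrect(self):
        ref = synthetic_reference()
        sim = TimeCourse(GRID, ref.species, ref.amounts.copy())
        i = sim.species.index("PI_m")  # reference PI falls; flip it to rise
        base = ref.amounts[0, i]
        sim.amounts[:, i] = 2 * base - ref.amounts[:, i]
        verdict = classify_behaviour(sim, ref, ClassifierConfig(), T_ACT)
        assert not verdict.per_observable["PI"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rule_by_rule_re_evaluation(self, seed):
        """Random perturbed fixtures classified identically by an
        independent re-implementation of the three rules."""
        rng = np.random.default_rng(seed)
        ref = synthetic_reference()
        sim = TimeCourse(GRID, ref.species, ref.amounts.copy())
        scales = {}
        for i, name in enumerate(sim.species):
            s = 10 ** rng.normal(0.0, 0.6)
            drift = rng.uniform(0.0, 0.2)
            sim.amounts[:, i] = sim.amounts[:, i] * s \
                + drift * max(sim.amounts[0, i], 1.0) * (GRID / GRID[-1])
            scales[name] = (s, drift)
        config = ClassifierConfig()
        verdict = classify_behaviour(sim, ref, config, T_ACT)
        from picycle.model import OBSERVABLES

        for obs in config.observables:
            # ---- independent oracle -------------------------------------
            names = [n for n in OBSERVABLES[obs] if n in sim.species]
            v = sum(sim[n] for n in names)
            r = sum(ref[n] for n in names)
            floor = config.floor_frac * max(np.abs(r).max(), 1e-300)
            pre, post = GRID <= T_ACT, GRID > T_ACT
            drift_ok = (v[pre].max() - v[pre].min()) <= \
                config.drift_threshold * max(abs(v[0]), floor)
            v_ext = (v[post] - v[pre][-1])[np.argmax(np.abs(v[post] - v[pre][-1]))]
            r_ext = (r[post] - r[pre][-1])[np.argmax(np.abs(r[post] - r[pre][-1]))]
            if abs(v_ext) <= floor and abs(r_ext) <= floor:
                dir_ok, mag_ok = True, abs(v_ext) <= config.fold_band * floor
            else:
                dir_ok = np.sign(v_ext) == np.sign(r_ext)
                if abs(r_ext) <= floor:
                    mag_ok = abs(v_ext) <= config.fold_band * floor
                else:
                    ratio = abs(v_ext) / abs(r_ext)
                    mag_ok = 1.0 / config.fold_band <= ratio <= config.fold_band
            assert verdict.per_observable[obs] == (drift_ok and dir_ok and mag_ok)

    def test_mismatched_grid_raises(self):
        ref = synthetic_reference()
        sim = TimeCourse(GRID[:-1], ref.species, ref.amounts[:-1])
        with pytest.raises(ValueError, match="grid"):
            classify_behaviour(sim, ref, ClassifierConfig(), T_ACT)


class TestMixAndMatch:
    SUBSET = KEY_PROTEINS[:3]

    def test_identical_sources_are_all_correct(self, platelet):
        hela = load_proteome("hela")
        summary = mix_and_match(platelet, hela, hela, proteins=KEY_PROTEINS[:4],
                                grid=GRID)
        assert summary.n_total == 16
        assert summary.n_incorrect == 0
        assert summary.fraction_incorrect == 0.0

    def test_relabelling_sources_leaves_fraction_invariant(self, platelet):
        """Against a fixed external reference and a common starting state,
        swapping the two source labels only permutes the combinations."""
        from picycle.celltypes import NUCLEATED_GEOMETRY, NUCLEATED_RECEPTOR_COUNT, \
            equilibrate_model, rescale_model
        from picycle.simulate import simulate

        hela = load_proteome("hela")
        scanned = load_proteome("u2os_scanned")
        ref_model = equilibrate_model(
            rescale_model(platelet, NUCLEATED_GEOMETRY, hela,
                          NUCLEATED_RECEPTOR_COUNT, t_activation=T_ACT))
        ref = simulate(ref_model, 5000.0, GRID)
        a = mix_and_match(platelet, hela, scanned, reference=ref,
                          proteins=self.SUBSET, grid=GRID, equilibrate=False)
        b = mix_and_match(platelet, scanned, hela, reference=ref,
                          proteins=self.SUBSET, grid=GRID, equilibrate=False)
        assert a.fraction_incorrect == b.fraction_incorrect
        # mirrored assignments carry identical verdicts
        va = {c.label(): v.overall for c, v in zip(a.combinations, a.verdicts)}
        vb = {c.label(): v.overall for c, v in zip(b.combinations, b.verdicts)}
        swap = str.maketrans("AB", "BA")
        for label, verdict in va.items():
            assert vb[label.translate(swap)] == verdict

    def test_failed_source_table_raises(self, platelet):
        bad = ProteomeTable("x", {"PI4K": 1.0})
        with pytest.raises(KeyError, match="missing"):
            mix_and_match(platelet, bad, bad)
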