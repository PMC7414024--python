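"""Mosaic-proteome robustness: exhaustive mix-and-match of protein numbers.

Copy numbers of the 12 key proteins are drawn per-protein from one of two
source proteomes, giving 2^12 = 4096 combinations.  Each combination is
simulated at nucleated-cell geometry and classified against a reference
trajectory by three rules: pre-activation stability, post-activation
response direction, and peak (or trough) magnitude within a fold band.
The fraction of combinations classified incorrect quantifies how fragile
the pathway's behaviour is to mosaic parameterisation.

The correct/incorrect criterion is this module's own definition (the
three-rule classifier below); the headline fraction is therefore reported
alongside a bracket across 3-/5-/10-fold bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._system import compile_model
from .calibrate import PROTEIN_SPECIES
from .celltypes import (
    CellGeometry,
    NUCLEATED_GEOMETRY,
    NUCLEATED_RECEPTOR_COUNT,
    ProteomeTable,
    equilibrate_model,
    rescale_model,
)
from .model import KEY_PROTEINS, ModelDefinition
from .simulate import SimulationError, TimeCourse, simulate_compiled

__all__ = [
    "ClassifierConfig",
    "MixCombination",
    "BehaviourVerdict",
    "MosaicSummary",
    "enumerate_combinations",
    "classify_behaviour",
    "mix_and_match",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Rules deciding whether an observable behaves like the reference.

    An observable is *correct* iff (i) its pre-activation drift is below
    ``drift_threshold`` (relative to its starting level), (ii) its dominant
    post-activation response has the same direction as the reference's, and
    (iii) the response magnitude is within ``fold_band`` of the reference's.
    ``floor_frac`` scales the reference maximum into an absolute floor that
    keeps near-zero baselines from generating spurious verdicts.
    """

    drift_threshold: float = 0.10
    fold_band: float = 5.0
    floor_frac: float = 0.01
    observables: tuple[str, ...] = ("PI", "PI4P", "PI45P2", "IP3", "DAG", "PA", "Ins")


@dataclass(frozen=True)
class MixCombination:
    """Assignment of each key protein to source A or B."""

    assignment: tuple[tuple[str, str], ...]  # ((protein, "A"|"B"), ...)

    @property
    def bitmask(self) -> int:
        return sum(1 << i for i, (_, src) in enumerate(self.assignment) if src == "B")

    def label(self) -> str:
        return "".join(src for _, src in self.assignment)


@dataclass
class BehaviourVerdict:
    """Per-observable correct/incorrect classification of one simulation."""

    per_observable: dict[str, bool]
    rules: dict[str, dict[str, bool]] = field(default_factory=dict)
    failed: bool = False  # integration failure (counted incorrect)

    @property
    def overall(self) -> bool:
        """True when every observable is correct."""
        return not self.failed and all(self.per_observable.values())


@dataclass
class MosaicSummary:
    n_total: int
    n_incorrect: int
    per_observable: dict[str, int]  # incorrect counts
    fold_band: float
    bracket: dict[float, float]  # fold band -> fraction incorrect
    verdicts: list[BehaviourVerdict]
    combinations: list[MixCombination]

    @property
    def fraction_incorrect(self) -> float:
        return self.n_incorrect / self.n_total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo, verdict in zip(self.combinations, self.verdicts):
            row = {"bitmask": combo.bitmask, "label": combo.label(),
                   "overall_correct": verdict.overall, "failed": verdict.failed}
            for obs, ok in verdict.per_observable.items():
                row[obs] = ok
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_combinations(proteins=KEY_PROTEINS) -> list[MixCombination]:
    """All 2^n source assignments, in stable lexicographic order.

    The first protein varies slowest; the all-A assignment comes first and
    the all-B assignment last.
    """
    proteins = tuple(proteins)
    n = len(proteins)
    out = []
    for mask in range(2 ** n):
        assignment = tuple(
            (p, "B" if (mask >> (n - 1 - i)) & 1 else "A")
            for i, p in enumerate(proteins)
        )
        out.append(MixCombination(assignment))
    return out


def _response_stats(values, times, t_activation, floor):
    pre = values[times <= t_activation]
    post = values[times > t_activation]
    baseline = pre[-1]
    drift = (pre.max() - pre.min()) / max(abs(pre[0]), floor)
    resp = post - baseline
    ext = resp[int(np.argmax(np.abs(resp)))]
    return drift, ext


def classify_behaviour(
    tc: TimeCourse,
    reference: TimeCourse,
    config: ClassifierConfig = ClassifierConfig(),
    t_activation: float = 1000.0,
    fold_bands: tuple[float, ...] | None = None,
) -> BehaviourVerdict | dict[float, BehaviourVerdict]:
    """Classify a trajectory against a reference, rule by rule.

    Both trajectories must share a grid spanning the pre- and
    post-activation phases.  With ``fold_bands`` a dict of verdicts (one
    per band) is returned from a single pass; otherwise a single verdict at
    ``config.fold_band``.
    """
    if tc.times.shape != reference.times.shape or not np.allclose(tc.times, reference.times):
        raise ValueError("trajectory and reference must share a common grid")
    if not (tc.times[0] < t_activation < tc.times[-1]):
        raise ValueError("grid must span pre- and post-activation phases")
    bands = fold_bands if fold_bands is not None else (config.fold_band,)
    per = {b: {} for b in bands}
    rules = {b: {} for b in bands}
    for obs in config.observables:
        ref_vals = reference.observable(obs)
        try:
            sim_vals = tc.observable(obs)
        except KeyError:
            raise KeyError(f"missing observable {obs!r}") from None
        floor = config.floor_frac * max(np.max(np.abs(ref_vals)), 1e-300)
        ref_drift, ref_ext = _response_stats(ref_vals, reference.times, t_activation, floor)
        drift, ext = _response_stats(sim_vals, tc.times, t_activation, floor)
        stable = drift <= config.drift_threshold
        if abs(ext) <= floor and abs(ref_ext) <= floor:
            direction = True
        else:
            direction = np.sign(ext) == np.sign(ref_ext)
        for band in bands:
            if abs(ref_ext) <= floor:
                in_band = abs(ext) <= band * floor
            else:
                ratio = abs(ext) / abs(ref_ext)
                in_band = (1.0 / band) <= ratio <= band
            rules[band][obs] = {"stable": stable, "direction": direction, "magnitude": in_band}
            per[band][obs] = stable and direction and in_band
    verdicts = {
        b: BehaviourVerdict(per_observable=per[b], rules=rules[b]) for b in bands
    }
    if fold_bands is None:
        return verdicts[bands[0]]
    return verdicts


def mix_and_match(
    core: ModelDefinition,
    source_a: ProteomeTable,
    source_b: ProteomeTable,
    reference: TimeCourse | None = None,
    geometry: CellGeometry = NUCLEATED_GEOMETRY,
    receptor_count: float = NUCLEATED_RECEPTOR_COUNT,
    t_activation: float = 1000.0,
    t_end: float = 5000.0,
    grid: np.ndarray | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    bracket_bands: tuple[float, ...] = (3.0, 5.0, 10.0),
    proteins=KEY_PROTEINS,
    limit: int | None = None,
    seed: int | None = None,
    equilibrate: bool = True,
) -> MosaicSummary:
    """Exhaustive mosaic scan over two source proteomes.

    Simulates every source assignment (all 2^n, or a seeded random sample
    of ``limit`` of them for larger protein sets) at the given geometry and
    classifies each against ``reference`` (default: the pure source-A
    simulation).  With ``equilibrate`` the source-A model is first relaxed
    to its basal steady state; every combination then starts from that same
    lipid state with only the protein numbers swapped, exactly as a
    parameter scan over initial concentrations would run.  Combinations
    that fail to integrate are flagged and counted incorrect.  The summary
    carries the fraction incorrect at ``config.fold_band`` plus the bracket
    across ``bracket_bands``.
    """
    for table, label in ((source_a, "A"), (source_b, "B")):
        gaps = [p for p in proteins if p not in table.entries]
        if gaps:
            raise KeyError(f"source {label} missing proteins: {gaps}")
    if grid is None:
        grid = np.linspace(0.0, t_end, 401)
    base = rescale_model(core, geometry, source_a, receptor_count,
                         t_activation=t_activation, name="mosaic")
    if equilibrate:
        base = equilibrate_model(base)
    cm = compile_model(base)
    idx = {p: cm.index[PROTEIN_SPECIES.get(p, p)] for p in proteins}

    def run(proteome_values: dict[str, float]) -> TimeCourse:
        y0 = cm.y0.copy()
        for p, v in proteome_values.items():
            y0[idx[p]] = v
        return simulate_compiled(cm, t_end, grid, y0=y0)

    if reference is None:
        reference = run({p: source_a.entries[p] for p in proteins})

    combos = enumerate_combinations(proteins)
    if limit is not None and limit < len(combos):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(combos), size=limit, replace=False)
        combos = [combos[i] for i in sorted(keep)]

    bands = tuple(sorted(set(bracket_bands) | {config.fold_band}))
    verdicts = []
    incorrect = {b: 0 for b in bands}
    per_obs = {obs: 0 for obs in config.observables}
    for combo in combos:
        values = {
            p: (source_a if src == "A" else source_b).entries[p]
            for p, src in combo.assignment
        }
        try:
            tc = run(values)
        except SimulationError:
            verdict = BehaviourVerdict(
                {obs: False for obs in config.observables}, failed=True
            )
            verdicts.append(verdict)
            for b in bands:
                incorrect[b] += 1
            for obs in per_obs:
                per_obs[obs] += 1
            continue
        banded = classify_behaviour(tc, reference, config, t_activation, fold_bands=bands)
        for b in bands:
            if not banded[b].overall:
                incorrect[b] += 1
        main = banded[config.fold_band]
        verdicts.append(main)
        for obs, ok in main.per_observable.items():
            if not ok:
                per_obs[obs] += 1

    n_total = len(combos)
    return MosaicSummary(
        n_total=n_total,
        n_incorrect=incorrect[config.fold_band],
        per_observable=per_obs,
        fold_band=config.fold_band,
        bracket={b: incorrect[b] / n_total for b in bands},
        verdicts=verdicts,
        combinations=combos,
    )
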