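"""Scan-based parameterisation of the PI-cycle model.

The calibration strategy mirrors COPASI-style practice: log-spaced parameter
scans (default +/- 4 orders of magnitude, 5 points per decade), acceptance of
a parameter set only when every observable stays within 20% of the
experimental time course, and a staged build-up of the network (iterations
1-4) in which each stage freezes the values fixed by earlier stages.  No
gradient or Bayesian estimation is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ActivationScheme,
    BOUND_LIPIDS,
    ModelDefinition,
    binding_equilibrium,
    build_core_model,
    PLATELET_PROTEOME,
)
from .simulate import SimulationError, TimeCourse, simulate

__all__ = [
    "ACCEPT_THRESHOLD",
    "ScanSpec",
    "FitResult",
    "BindingPrediction",
    "CalibrationState",
    "deviation",
    "set_parameter",
    "get_parameter",
    "scan_parameter",
    "scan_binding_protein_number",
    "staged_model",
    "fit_iteration",
    "STAGE_PARAMETERS",
    "STAGE_OBSERVABLES",
]

#: Parameter sets deviating more than this (relative) from the data are rejected.
ACCEPT_THRESHOLD = 0.20

#: Relative-deviation floor, as a fraction of each observable's largest mean;
#: guards near-zero baselines such as pre-activation IP3.
DEVIATION_FLOOR_FRAC = 0.01

#: Species holding each key protein's copy number.
PROTEIN_SPECIES = {"Gaq": "Gq"}


@dataclass
class ScanSpec:
    """A logarithmic grid around ``center``: ``span`` decades each way."""

    parameter: str
    center: float
    span: float = 4.0
    points_per_decade: int = 5

    def __post_init__(self):
        if not self.span > 0:
            raise ValueError("span must be > 0")
        if self.points_per_decade < 3:
            raise ValueError("at least 3 points per decade are required")
        if not self.center > 0:
            raise ValueError("center must be > 0")

    def grid(self) -> np.ndarray:
        n = int(round(2 * self.span * self.points_per_decade)) + 1
        lo = math.log10(self.center) - self.span
        hi = math.log10(self.center) + self.span
        return np.logspace(lo, hi, n)

    @property
    def step_factor(self) -> float:
        return 10.0 ** (1.0 / self.points_per_decade)


@dataclass
class FitResult:
    parameters: dict[str, float]
    deviations: dict[str, float]

    @property
    def worst(self) -> float:
        return max(self.deviations.values())

    @property
    def accepted(self) -> bool:
        return self.worst <= ACCEPT_THRESHOLD


@dataclass
class BindingPrediction:
    bp_total: float
    k_on: float
    k_off: float
    fit: FitResult

    @property
    def accepted(self) -> bool:
        return self.fit.accepted


def deviation(tc: TimeCourse, data, floor_frac: float = DEVIATION_FLOOR_FRAC) -> dict[str, float]:
    """Per-observable max relative deviation of a simulation from a dataset.

    ``data`` maps observable name -> ExperimentalDataset (times, mean).  For
    each observable the deviation is max over the data's time points of
    |sim - mean| / max(|mean|, floor), with floor = ``floor_frac`` times the
    largest |mean| of that observable.
    """
    if not data:
        raise ValueError("empty dataset")
    out: dict[str, float] = {}
    for name, ds in data.items():
        times = np.asarray(ds.times, float)
        mean = np.asarray(ds.mean, float)
        if times.size == 0:
            raise ValueError(f"dataset for {name} has no time points")
        if times[0] < tc.times[0] or times[-1] > tc.times[-1]:
            raise ValueError(f"dataset for {name} extends beyond the trajectory")
        sim = np.interp(times, tc.times, tc.observable(name))
        floor = floor_frac * np.max(np.abs(mean))
        denom = np.maximum(np.abs(mean), max(floor, 1e-300))
        out[name] = float(np.max(np.abs(sim - mean) / denom))
    return out


# ---------------------------------------------------------------------------
# Generic parameter addressing
# ---------------------------------------------------------------------------


def _repartition(model: ModelDefinition, lipid: str) -> None:
    """Re-equilibrate a binding pair's initial free/bound split in place."""
    pair = next(p for p in model.binding_pairs if p.lipid == lipid)
    total = (model.species[lipid].initial_amount
             + model.species[pair.complex].initial_amount)
    kd = (model.rate_constants[pair.k_off_id].basal_value
          / model.rate_constants[pair.k_on_id].basal_value)
    bound = binding_equilibrium(total, pair.bp_total, kd)
    model.species[lipid].initial_amount = total - bound
    model.species[pair.complex].initial_amount = bound
    model.species[pair.bp].initial_amount = pair.bp_total - bound


def set_parameter(model: ModelDefinition, address: str, value: float) -> ModelDefinition:
    """Return a copy of ``model`` with one addressed parameter replaced.

    Addresses: ``rate:<id>``, ``rate:<id>:activated``, ``bp:<lipid>:total``,
    ``bp:<lipid>:kon``, ``bp:<lipid>:koff``, ``protein:<name>``,
    ``lipid:<name>`` (bound-lipid totals re-partition between free and
    complexed pools).
    """
    out = model.copy()
    kind, _, rest = address.partition(":")
    if kind == "rate":
        rid, _, sub = rest.partition(":")
        if rid not in out.rate_constants:
            raise KeyError(f"unknown rate constant {rid!r}")
        if sub == "activated":
            out.rate_constants[rid].activated_value = float(value)
        elif sub == "":
            out.rate_constants[rid].basal_value = float(value)
        else:
            raise KeyError(f"bad rate address {address!r}")
    elif kind == "bp":
        lipid, _, sub = rest.partition(":")
        pair = next((p for p in out.binding_pairs if p.lipid == lipid), None)
        if pair is None:
            raise KeyError(f"no binding pair for {lipid!r}")
        if sub == "total":
            pair.bp_total = float(value)
        elif sub == "kon":
            out.rate_constants[pair.k_on_id].basal_value = float(value)
        elif sub == "koff":
            out.rate_constants[pair.k_off_id].basal_value = float(value)
        else:
            raise KeyError(f"bad binding address {address!r}")
        _repartition(out, lipid)
    elif kind == "protein":
        species = PROTEIN_SPECIES.get(rest, rest)
        if species not in out.species:
            raise KeyError(f"unknown protein {rest!r}")
        out.species[species].initial_amount = float(value)
    elif kind == "lipid":
        if rest not in out.species:
            raise KeyError(f"unknown lipid {rest!r}")
        if any(p.lipid == rest for p in out.binding_pairs):
            pair = next(p for p in out.binding_pairs if p.lipid == rest)
            bound = out.species[pair.complex].initial_amount
            out.species[rest].initial_amount = max(float(value) - bound, 0.0)
            _repartition(out, rest)
        else:
            out.species[rest].initial_amount = float(value)
    else:
        raise KeyError(f"bad parameter address {address!r}")
    out.validate()
    return out


def get_parameter(model: ModelDefinition, address: str) -> float:
    kind, _, rest = address.partition(":")
    if kind == "rate":
        rid, _, sub = rest.partition(":")
        rc = model.rate_constants[rid]
        return rc.activated_value if sub == "activated" else rc.basal_value
    if kind == "bp":
        lipid, _, sub = rest.partition(":")
        pair = next(p for p in model.binding_pairs if p.lipid == lipid)
        if sub == "total":
            return pair.bp_total
        if sub == "kon":
            return model.rate_constants[pair.k_on_id].basal_value
        if sub == "koff":
            return model.rate_constants[pair.k_off_id].basal_value
    if kind == "protein":
        return model.species[PROTEIN_SPECIES.get(rest, rest)].initial_amount
    if kind == "lipid":
        total = model.species[rest].initial_amount
        pair = next((p for p in model.binding_pairs if p.lipid == rest), None)
        if pair is not None:
            total += model.species[pair.complex].initial_amount
        return total
    raise KeyError(f"bad parameter address {address!r}")


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def scan_parameter(
    model: ModelDefinition,
    spec: ScanSpec,
    data,
    t_end: float | None = None,
    grid: np.ndarray | None = None,
    floor_frac: float = DEVIATION_FLOOR_FRAC,
) -> list[FitResult]:
    """One simulation per grid point, sorted by worst-observable deviation.

    Ordering is deterministic; ties break toward the smaller parameter
    value.  Grid points whose integration fails carry infinite deviation.
    Raises :class:`SimulationError` if every grid point fails.
    """
    get_parameter(model, spec.parameter)  # existence check
    if t_end is None:
        t_end = max(max(ds.times[-1] for ds in data.values()), 1.0)
    results = []
    n_failed = 0
    for value in spec.grid():
        trial = set_parameter(model, spec.parameter, float(value))
        try:
            tc = simulate(trial, t_end, grid)
            devs = deviation(tc, data, floor_frac)
        except SimulationError:
            n_failed += 1
            devs = {name: float("inf") for name in data}
        results.append(FitResult({spec.parameter: float(value)}, devs))
    if n_failed == len(results):
        raise SimulationError("every scan point failed to integrate", 0.0)
    results.sort(key=lambda r: (r.worst, r.parameters[spec.parameter]))
    return results


def scan_binding_protein_number(
    model: ModelDefinition,
    lipid: str,
    data,
    center: float = 1.0e6,
    span: float = 2.0,
    points_per_decade: int = 5,
    rate_grid_span: float = 1.5,
    rate_grid_points: int = 3,
    refine: bool = True,
    t_end: float | None = None,
    grid: np.ndarray | None = None,
) -> BindingPrediction:
    """Predict a lipid's binding-protein pool size from its time course.

    Scans ``bp_total`` on a log grid and the on/off rates on a coarse
    secondary grid (default 3 decades wide, 3 points each), returning the
    best accepted combination; if nothing is accepted the best-effort result
    is returned with ``accepted == False``.  With ``refine`` a second, finer
    bp_total pass (+/- one coarse step) polishes the prediction.
    """
    pair = next((p for p in model.binding_pairs if p.lipid == lipid), None)
    if pair is None:
        raise KeyError(f"no binding pair for {lipid!r}")
    kon0 = model.rate_constants[pair.k_on_id].basal_value
    koff0 = model.rate_constants[pair.k_off_id].basal_value
    half = rate_grid_span / 2.0

    def _grid(center, n):
        if n <= 1:
            return np.array([center])
        return np.logspace(math.log10(center) - half, math.log10(center) + half, n)

    kon_grid = _grid(kon0, rate_grid_points)
    koff_grid = _grid(koff0, rate_grid_points)

    best = None  # (worst, bp_total, kon, koff, FitResult)
    for kon in kon_grid:
        for koff in koff_grid:
            trial = set_parameter(model, f"bp:{lipid}:kon", float(kon))
            trial = set_parameter(trial, f"bp:{lipid}:koff", float(koff))
            spec = ScanSpec(f"bp:{lipid}:total", center, span, points_per_decade)
            ranked = scan_parameter(trial, spec, data, t_end, grid)
            top = ranked[0]
            key = (top.worst, top.parameters[spec.parameter], kon, koff)
            if best is None or key < best[0]:
                best = (key, trial, top)
    key, base, top = best
    bp_best = top.parameters[f"bp:{lipid}:total"]
    if refine:
        step = 10.0 ** (1.0 / points_per_decade)
        fine = ScanSpec(f"bp:{lipid}:total", bp_best,
                        math.log10(step), max(points_per_decade * 5, 15))
        ranked = scan_parameter(base, fine, data, t_end, grid)
        top = ranked[0]
        bp_best = top.parameters[fine.parameter]
    return BindingPrediction(bp_best, key[2], key[3], top)


# ---------------------------------------------------------------------------
# Staged model building (iterations 1-4)
# ---------------------------------------------------------------------------

#: Reactions absent before iteration 4 (PLC products handled as inert sinks).
_DOWNSTREAM_REACTIONS = ("r_ip3e", "r_ipx", "r_dgk", "r_lpp", "r_cdipt")

#: Parameters fitted at each stage (addresses).  Stages 1-2 fix the lipid
#: synthesis/recycling axis on the reduced network, stage 3 adds the
#: PI4P/PI45P2 binding pools, stage 4 adds the IP3 -> IPx -> Ins and
#: DAG/PA reactions together with the pools buffering the latter.
STAGE_PARAMETERS: dict[int, tuple[str, ...]] = {
    1: ("rate:k16", "rate:k17", "rate:k14", "rate:k15"),
    2: ("rate:k16:activated", "rate:k14:activated", "rate:k15:activated",
        "rate:k5", "rate:k12:activated"),
    3: ("bp:PI45P2:total", "bp:PI4P:total"),
    4: ("rate:k6", "rate:k7", "rate:k8", "rate:k9", "rate:k10",
        "bp:DAG:total", "bp:PA:total"),
}

STAGE_OBSERVABLES: dict[int, tuple[str, ...]] = {
    1: ("PI", "PI4P", "PI45P2"),
    2: ("PI", "PI4P", "PI45P2"),
    3: ("PI4P", "PI45P2"),
    4: ("IP3", "Ins", "DAG", "PA"),
}


@dataclass
class CalibrationState:
    """Frozen parameter values accumulated across iterations."""

    stage_done: int = 0
    values: dict[str, float] = field(default_factory=dict)


def staged_model(
    stage: int,
    proteome=None,
    overrides: dict[str, float] | None = None,
    receptor_count: float = 5000.0,
    t_activation: float = 100.0,
) -> ModelDefinition:
    """The reduced network used at a given iteration.

    Stage 1: basal lipid axis only (no binding pools, no activation, PLC
    products absent).  Stage 2: adds the activation event; IP3 and DAG
    accumulate as inert sinks.  Stage 3: adds the binding pairs.  Stage 4:
    the full core model.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    proteome = PLATELET_PROTEOME if proteome is None else proteome
    model = build_core_model(proteome, name=f"core_iteration_{stage}")
    if stage < 3:
        for lipid in BOUND_LIPIDS:
            model = set_parameter(model, f"bp:{lipid}:total", 0.0)
    if stage < 4:
        drop = set(_DOWNSTREAM_REACTIONS)
        model.reactions = [r for r in model.reactions if r.id not in drop]
    for address, value in (overrides or {}).items():
        try:
            model = set_parameter(model, address, value)
        except KeyError:
            pass  # e.g. a bp total frozen before its pair exists at this stage
    if stage >= 2:
        model.activation = ActivationScheme(t_activation, receptor_count)
    model.validate()
    return model


def fit_iteration(
    stage: int,
    data,
    state: CalibrationState | None = None,
    span: float = 4.0,
    points_per_decade: int = 5,
    passes: int = 2,
    t_end: float | None = None,
    grid: np.ndarray | None = None,
    proteome=None,
) -> tuple[ModelDefinition, CalibrationState]:
    """Run one calibration iteration, freezing earlier-stage values.

    Scans the stage's parameters coordinate-wise (``passes`` sweeps; the
    second sweep is the refinement pass) on the stage's reduced network,
    each parameter over ``span`` decades around its current value.  Raises
    ``ValueError`` when stages are run out of order.
    """
    state = CalibrationState() if state is None else state
    if state.stage_done != stage - 1:
        raise ValueError(
            f"stage {stage} requires stage {stage - 1} to be fitted first "
            f"(done: {state.stage_done})"
        )
    observables = STAGE_OBSERVABLES[stage]
    stage_data = {k: v for k, v in data.items() if k in observables}
    if not stage_data:
        raise ValueError(f"data contains none of the stage-{stage} observables")
    model = staged_model(stage, proteome, overrides=state.values)
    fitted = dict(state.values)
    for _ in range(passes):
        for address in STAGE_PARAMETERS[stage]:
            center = get_parameter(model, address)
            if center <= 0:  # a zeroed pool cannot anchor a log grid
                center = 1.0e6 if address.startswith("bp:") else 1.0
            spec = ScanSpec(address, center, span, points_per_decade)
            ranked = scan_parameter(model, spec, stage_data, t_end, grid)
            best = ranked[0].parameters[address]
            model = set_parameter(model, address, best)
            fitted[address] = best
    return model, CalibrationState(stage_done=stage, values=fitted)
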