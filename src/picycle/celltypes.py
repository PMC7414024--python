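"""Rescaling the core platelet model to other cell geometries and proteomes.

A rescaled model keeps the reaction structure and per-concentration kinetics
of the human-platelet core frozen: species initial amounts are replaced by
the target proteome, lipid and binding-protein pools scale with the
compartment volume ratio, and folded rate constants of kinetic order m are
multiplied by (V_ref / V_new)^(m-1) so that concentration trajectories are
invariant under uniform scaling (the pltx17 control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import DEVIATION_FLOOR_FRAC, ScanSpec, deviation, get_parameter, set_parameter
from .model import (
    BOUND_LIPIDS,
    COMPARTMENT_NAMES,
    KEY_PROTEINS,
    LIPID_POOLS,
    MissingDataError,
    ModelDefinition,
    build_core_model,
)
from .simulate import SimulationError, TimeCourse, find_steady_state, simulate

__all__ = [
    "ProteomeTable",
    "CellGeometry",
    "HUMAN_PLATELET_GEOMETRY",
    "MOUSE_PLATELET_GEOMETRY",
    "NUCLEATED_GEOMETRY",
    "NUCLEATED_RECEPTOR_COUNT",
    "rescale_model",
    "equilibrate_model",
    "complete_proteome",
    "scan_missing_proteins",
]

log = logging.getLogger(__name__)

PROTEOME_COLUMNS = ["cell_type", "protein", "copies_per_cell", "provenance"]


@dataclass
class ProteomeTable:
    """Copy numbers per cell for one cell type, with per-entry provenance.

    Provenance is ``native`` for values measured in that cell type,
    ``borrowed:<donor>`` for values copied from another table, and
    ``scanned`` for values estimated by parameter scans.
    """

    cell_type: str
    entries: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, copies in self.entries.items():
            if copies < 0:
                raise ValueError(f"{name}: copies must be >= 0")
        for name in self.entries:
            self.provenance.setdefault(name, "native")

    def missing(self, required=KEY_PROTEINS) -> list[str]:
        return [p for p in required if p not in self.entries]

    def copy(self) -> "ProteomeTable":
        return ProteomeTable(self.cell_type, dict(self.entries), dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "protein": list(self.entries),
                "copies_per_cell": [self.entries[p] for p in self.entries],
                "provenance": [self.provenance[p] for p in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProteomeTable":
        df = pd.read_csv(path)
        if list(df.columns) != PROTEOME_COLUMNS:
            raise ValueError(
                f"proteome CSV must have columns {PROTEOME_COLUMNS}, got {list(df.columns)}"
            )
        cell_types = df["cell_type"].unique()
        if len(cell_types) != 1:
            raise ValueError("proteome CSV must describe exactly one cell type")
        return cls(
            str(cell_types[0]),
            dict(zip(df["protein"], df["copies_per_cell"].astype(float))),
            dict(zip(df["protein"], df["provenance"])),
        )


@dataclass
class CellGeometry:
    """Reaction-compartment volumes, femtolitres."""

    membrane_volume: float
    cytosol_volume: float
    organelle_volume: float

    def __post_init__(self):
        if min(self.membrane_volume, self.cytosol_volume, self.organelle_volume) <= 0:
            raise ValueError("all volumes must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "plasma_membrane": self.membrane_volume,
            "cytosol": self.cytosol_volume,
            "organelles": self.organelle_volume,
        }


HUMAN_PLATELET_GEOMETRY = CellGeometry(1.0, 1.0, 1.0)
MOUSE_PLATELET_GEOMETRY = CellGeometry(0.25, 0.25, 0.25)
#: Generic nucleated cell: ~2000 fl overall, 17 fl reaction compartments.
NUCLEATED_GEOMETRY = CellGeometry(17.0, 17.0, 17.0)
#: Receptor count matching the platelet receptor *concentration* at
#: nucleated-cell membrane volume (17 x 5000).
NUCLEATED_RECEPTOR_COUNT = 85000.0


def rescale_model(
    core: ModelDefinition,
    geometry: CellGeometry,
    proteome: ProteomeTable,
    receptor_count: float,
    t_activation: float | None = None,
    name: str | None = None,
) -> ModelDefinition:
    """Swap volumes and protein numbers while freezing the kinetics.

    Lipid and binding-protein pools scale with the membrane-volume ratio
    from the core reference; folded rate constants are rescaled by the
    volume ratio of their reaction's compartment raised to (order - 1).
    Raises :class:`MissingDataError` naming absent proteins.
    """
    missing = proteome.missing()
    if missing:
        raise MissingDataError("protein", missing)

    ref = {c.name: c.volume for c in core.compartments.values()}
    new = geometry.as_dict()
    ratio = {n: new[n] / ref[n] for n in COMPARTMENT_NAMES}
    f_mem = ratio["plasma_membrane"]

    # every rate constant is owned by exactly one reaction, which fixes its
    # compartment and kinetic order for the rescaling
    owner = {}
    for rx in core.reactions:
        if rx.rate_constant_id in owner:
            raise ValueError(f"rate {rx.rate_constant_id} shared between reactions")
        owner[rx.rate_constant_id] = rx

    rates: dict[str, tuple[float, float | None]] = {}
    binding: dict[str, tuple[float, float, float]] = {}
    for rid, rc in core.rate_constants.items():
        rx = owner[rid]
        scale = (1.0 / ratio[rx.compartment]) ** (rx.molecularity - 1)
        rates[rid] = (
            rc.basal_value * scale,
            None if rc.activated_value is None else rc.activated_value * scale,
        )
    for pair in core.binding_pairs:
        binding[pair.lipid] = (
            pair.bp_total * f_mem,
            rates.pop(pair.k_on_id)[0],
            rates.pop(pair.k_off_id)[0],
        )

    lipids = {}
    for pool in LIPID_POOLS:
        if pool in BOUND_LIPIDS:
            pair = next(p for p in core.binding_pairs if p.lipid == pool)
            total = (core.species[pool].initial_amount
                     + core.species[pair.complex].initial_amount)
        else:
            total = core.species[pool].initial_amount
        comp = core.species[pool].compartment
        lipids[pool] = total * ratio[comp]

    label = name or proteome.cell_type
    model = build_core_model(
        proteome.entries, lipids, new, rates, binding, name=label
    )
    if core.activation is not None:
        scheme = replace(core.activation, receptor_count=float(receptor_count))
        if t_activation is not None:
            scheme = replace(scheme, t_activation=float(t_activation))
        model.activation = scheme
    model.metadata["provenance"] = {p: proteome.provenance[p] for p in KEY_PROTEINS}
    model.validate()
    return model


def equilibrate_model(model: ModelDefinition, tol: float = 1e-10) -> ModelDefinition:
    """Adapt pre-activation concentrations to the basal steady state.

    Returns a copy whose species initial amounts are the relaxed basal
    (event-free) steady state, so the pre-activation phase is flat.  This
    mirrors standard practice of running a steady-state analysis on the
    reactions preceding the activation event and adapting the
    concentrations accordingly when a model is moved to a new cell type.
    """
    ss = find_steady_state(model, tol=tol)
    out = model.copy()
    for name, amount in ss.amounts.items():
        out.species[name].initial_amount = max(float(amount), 0.0)
    for pair in out.binding_pairs:  # keep the book-kept totals consistent
        pair.bp_total = (out.species[pair.bp].initial_amount
                         + out.species[pair.complex].initial_amount)
    out.validate()
    return out


def complete_proteome(partial: ProteomeTable, donor: ProteomeTable) -> ProteomeTable:
    """Fill a table's gaps with donor values (mosaic construction).

    Borrowed entries are tagged ``borrowed:<donor cell type>``.  Raises
    :class:`MissingDataError` if the donor also lacks an entry; donor zeros
    are passed through with a log warning.
    """
    gaps = partial.missing()
    donor_missing = [p for p in gaps if p not in donor.entries]
    if donor_missing:
        raise MissingDataError("donor protein", donor_missing)
    out = partial.copy()
    for p in gaps:
        out.entries[p] = donor.entries[p]
        out.provenance[p] = f"borrowed:{donor.cell_type}"
        if donor.entries[p] == 0:
            log.warning("gap %s filled with zero copies from %s", p, donor.cell_type)
    return out


def scan_missing_proteins(
    partial: ProteomeTable,
    reference: TimeCourse,
    core: ModelDefinition,
    geometry: CellGeometry = NUCLEATED_GEOMETRY,
    receptor_count: float = NUCLEATED_RECEPTOR_COUNT,
    span: float = 2.0,
    points_per_decade: int = 5,
    passes: int = 2,
    observables=("PI", "PI4P", "PI45P2", "IP3", "DAG", "PA", "Ins"),
    flat_tol: float = 1e-3,
    base_model: ModelDefinition | None = None,
) -> ProteomeTable:
    """Estimate missing copy numbers by scans against a reference behaviour.

    Each gap protein is scanned on a log grid (centred on the core model's
    platelet value scaled to the target membrane volume) choosing the copy
    number minimising the summed max-relative deviation of the observables
    from ``reference``; estimated entries are tagged ``scanned``.

    Candidates are evaluated exactly as a parameter scan over initial
    protein concentrations runs them: the table's protein numbers (with
    the candidate value for the gap) are swapped into ``base_model`` —
    normally the equilibrated reference-cell model whose behaviour
    ``reference`` records — leaving every other initial amount untouched.
    If no base model is given, one is built from the partial table (gaps
    seeded with volume-scaled platelet values) and relaxed to its basal
    steady state.  A gap the monitored outputs do not depend on yields a
    flat objective: the tie breaks to the grid minimum and the entry is
    flagged in the log.
    """
    from ._system import compile_model
    from .simulate import simulate_compiled

    gaps = partial.missing()
    if not gaps:
        return partial.copy()

    ref = {c.name: c.volume for c in core.compartments.values()}
    f_mem = geometry.membrane_volume / ref["plasma_membrane"]
    data = {
        obs: _ReferenceSeries(reference.times, reference.observable(obs))
        for obs in observables
    }
    t_end = float(reference.times[-1])
    t_act = core.activation.t_activation if core.activation is not None else None

    out = partial.copy()
    work = partial.copy()
    for p in gaps:  # seed with volume-scaled platelet values
        work.entries[p] = core.species[
            {"Gaq": "Gq"}.get(p, p)
        ].initial_amount * f_mem
        work.provenance[p] = "scanned"

    if base_model is None:
        base_model = equilibrate_model(
            rescale_model(core, geometry, work, receptor_count, t_activation=t_act)
        )
    cm = compile_model(base_model)
    from .calibrate import PROTEIN_SPECIES

    idx = {p: cm.index[PROTEIN_SPECIES.get(p, p)] for p in KEY_PROTEINS}

    def objective_for(table: ProteomeTable) -> float:
        y0 = cm.y0.copy()
        for p in KEY_PROTEINS:
            y0[idx[p]] = table.entries[p]
        try:
            tc = simulate_compiled(cm, t_end, reference.times, y0=y0)
            return sum(deviation(tc, data).values())
        except SimulationError:
            return float("inf")

    for _ in range(passes):
        for p in gaps:
            spec = ScanSpec(f"protein:{p}", work.entries[p] or 1.0,
                            span, points_per_decade)
            objective = []
            for value in spec.grid():
                trial = work.copy()
                trial.entries[p] = float(value)
                objective.append(objective_for(trial))
            objective = np.asarray(objective)
            finite = objective[np.isfinite(objective)]
            if finite.size and (finite.max() - finite.min()) <= flat_tol * max(finite.max(), 1e-12):
                best = float(spec.grid()[0])
                log.warning("scan for %s is flat: outputs insensitive; using grid minimum", p)
            else:
                best = float(spec.grid()[int(np.argmin(objective))])
            work.entries[p] = best
    for p in gaps:
        out.entries[p] = work.entries[p]
        out.provenance[p] = "scanned"
    return out


class _ReferenceSeries:
    """Adapter giving a reference trajectory the dataset interface."""

    def __init__(self, times, mean):
        self.times = np.asarray(times, float)
        self.mean = np.asarray(mean, float)
        self.sem = np.zeros_like(self.mean)
        self.n = 1
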