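"""Declarative definition of the phosphoinositide-cycle reaction network.

The model tracks absolute molecule numbers per cell in three well-mixed
compartments (plasma membrane, cytosol, organelles).  All reactions follow
mass-action kinetics; enzymes enter rate laws multiplicatively and are
conserved by their reactions.  Bimolecular (and higher-order) rate constants
are stored already folded with their compartment volume, so their units are
per molecule per second and every state variable is a plain copy number.
Volumes therefore appear explicitly only when a model is rescaled to a
different cell geometry (see :mod:`picycle.celltypes`).

The network covers Gq-coupled GPCR signalling into phospholipase C beta:
the PI -> PI4P -> PI(4,5)P2 lipid kinase/phosphatase axis (PI4K, PIP5K,
OCRL1, SAC1), PLC cleavage of PI(4,5)P2 into IP3 + DAG, the fast two-step
removal of IP3 to inositol through a lumped intermediate, DAG/PA
interconversion (DGK, LPP), PI resynthesis from PA + inositol (CDIPT) on
organelle membranes, slow organelle-to-plasma-membrane PI transfer, and
reversible sequestration of each signalling lipid by its pool of
lipid-binding proteins.  The PI3K/PIP3 and G13 branches and calcium dynamics
are out of scope.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Compartment",
    "Species",
    "RateConstant",
    "Reaction",
    "BindingPair",
    "ActivationScheme",
    "ModelDefinition",
    "ModelValidationError",
    "MissingDataError",
    "KEY_PROTEINS",
    "LIPID_POOLS",
    "OBSERVABLES",
    "COMPARTMENT_NAMES",
    "PLATELET_VOLUMES",
    "PLATELET_LIPIDS",
    "PLATELET_PROTEOME",
    "DEFAULT_RATES",
    "DEFAULT_BINDING",
    "ACTIVATION_SWITCHES",
    "binding_equilibrium",
    "build_core_model",
    "mass_action_rate",
    "apply_activation",
    "platelet_model",
]

COMPARTMENT_NAMES = ("plasma_membrane", "cytosol", "organelles")

SPECIES_ROLES = (
    "lipid",
    "inositol_phosphate",
    "enzyme",
    "receptor",
    "g_protein",
    "binding_protein",
    "complex",
    "intermediate",
)

#: The twelve proteins whose copy numbers parameterise the network.
KEY_PROTEINS = (
    "Gaq",      # G alpha q
    "smG",      # small G protein pool assisting PLCbeta activation
    "PLCb",     # phospholipase C beta
    "IP3E",     # lumped IP3-modifying enzymes (IP3 3-kinase B + INPP5)
    "DGK",      # diacylglycerol kinase
    "LPP",      # lipid phosphate phosphatase
    "CDIPT",    # CDP-DAG--inositol 3-phosphatidyltransferase (PI synthase)
    "OCRL1",    # PI(4,5)P2 5-phosphatase
    "PI4K",     # PI 4-kinase
    "PIP5K",    # PI4P 5-kinase
    "SAC1",     # PI4P phosphatase
    "cPLA2",    # cytosolic phospholipase A2 (membrane PI recycling)
)

#: Lipid / inositol pools that must be supplied to the builder.
LIPID_POOLS = ("PI_m", "PI_o", "PI4P", "PI45P2", "DAG", "PA", "IP3", "Ins")

#: Lipids carrying a dedicated binding-protein pair.
BOUND_LIPIDS = ("PI45P2", "PI4P", "DAG", "PA")

#: Map from an experimentally observed quantity to the model species summed
#: to produce it (lipid observables include the protein-bound fraction).
OBSERVABLES = {
    "PI": ("PI_m",),
    "PI4P": ("PI4P", "PI4P_BP"),
    "PI45P2": ("PI45P2", "PI45P2_BP"),
    "IP3": ("IP3",),
    "DAG": ("DAG", "DAG_BP"),
    "PA": ("PA", "PA_BP"),
    "Ins": ("Ins",),
}

#: Rate constants switched to primed values while the activation event is live.
ACTIVATION_SWITCHES = ("k14", "k15", "k16", "k12")


class ModelValidationError(ValueError):
    """A model definition violates a structural invariant."""


class MissingDataError(KeyError):
    """An input table lacks required entries; ``missing`` lists them."""

    def __init__(self, kind: str, missing: list[str]):
        self.kind = kind
        self.missing = sorted(missing)
        super().__init__(f"missing {kind} entries: {', '.join(self.missing)}")


@dataclass
class Compartment:
    name: str
    volume: float  # femtolitres

    def validate(self) -> None:
        if self.name not in COMPARTMENT_NAMES:
            raise ModelValidationError(f"unknown compartment {self.name!r}")
        if not self.volume > 0:
            raise ModelValidationError(f"compartment {self.name}: volume must be > 0")


@dataclass
class Species:
    name: str
    compartment: str
    initial_amount: float  # molecules per cell
    role: str = "enzyme"
    lipid_parent: str | None = None  # for complexes
    bp_parent: str | None = None

    def validate(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ModelValidationError(f"species {self.name}: unknown role {self.role!r}")
        if self.initial_amount < 0:
            raise ModelValidationError(f"species {self.name}: negative initial amount")
        if self.role == "complex" and (self.lipid_parent is None or self.bp_parent is None):
            raise ModelValidationError(
                f"complex {self.name} must name one lipid and one binding-protein parent"
            )


@dataclass
class RateConstant:
    """A basal rate constant, optionally with a distinct post-activation value.

    ``activated_value is None`` means the constant is untouched by activation
    (serialised as the literal string ``"unchanged"``).
    """

    id: str
    basal_value: float
    activated_value: float | None = None

    def validate(self) -> None:
        if not self.basal_value > 0:
            raise ModelValidationError(f"rate {self.id}: basal value must be > 0")
        if self.activated_value is not None and not self.activated_value > 0:
            raise ModelValidationError(f"rate {self.id}: activated value must be > 0")
        if self.id == "k17" and self.activated_value is not None:
            raise ModelValidationError("SAC1 rate k17 must remain unchanged on activation")


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_constant_id: str
    enzyme: str | None = None
    compartment: str = "plasma_membrane"

    @property
    def molecularity(self) -> int:
        """Total kinetic order: reactant stoichiometries plus the enzyme."""
        return sum(s for _, s in self.reactants) + (1 if self.enzyme else 0)

    def net_stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for name, s in self.reactants:
            net[name] = net.get(name, 0) - s
        for name, s in self.products:
            net[name] = net.get(name, 0) + s
        return {k: v for k, v in net.items() if v != 0}


@dataclass
class BindingPair:
    """Reversible sequestration of a membrane lipid by its binding proteins."""

    lipid: str
    bp: str
    complex: str
    k_on_id: str
    k_off_id: str
    bp_total: float


@dataclass
class ActivationScheme:
    """GPCR activation event and its termination.

    At ``t_activation`` the event places ``receptor_count`` active receptors
    (RGq) into the system, which catalyse Gq then PLCbeta activation, and --
    provided receptor_count > 0, reflecting recruitment of the lipid-kinase
    complex by the receptors -- switches the constants in ``rate_switches``
    to their primed values.  Receptors always inactivate first-order;
    ``termination="reset"`` additionally restores the switched constants to
    basal after ``termination_timescale`` seconds, ``"inactivation"`` leaves
    them primed so signalling dies through receptor loss alone.
    """

    t_activation: float = 100.0
    receptor_count: float = 5000.0
    rate_switches: tuple[str, ...] = ACTIVATION_SWITCHES
    termination: str = "reset"
    termination_timescale: float = 100.0

    def validate(self) -> None:
        if not self.t_activation > 0:
            raise ModelValidationError("t_activation must be > 0")
        if self.receptor_count < 0:
            raise ModelValidationError("receptor_count must be >= 0")
        if "k17" in self.rate_switches:
            raise ModelValidationError("k17 (SAC1) may not appear in rate_switches")
        if self.termination not in ("reset", "inactivation"):
            raise ModelValidationError(f"unknown termination {self.termination!r}")
        if not self.termination_timescale > 0:
            raise ModelValidationError("termination_timescale must be > 0")


@dataclass
class ModelDefinition:
    """The entire kinetic model as data."""

    name: str
    compartments: dict[str, Compartment]
    species: dict[str, Species]
    rate_constants: dict[str, RateConstant]
    reactions: list[Reaction]
    binding_pairs: list[BindingPair]
    activation: ActivationScheme | None = None
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "ModelDefinition":
        return copy.deepcopy(self)

    def validate(self) -> None:
        if len(self.compartments) != 3:
            raise ModelValidationError("exactly three compartments are required")
        for c in self.compartments.values():
            c.validate()
        for sp in self.species.values():
            sp.validate()
            if sp.compartment not in self.compartments:
                raise ModelValidationError(f"species {sp.name}: unknown compartment")
        for rc in self.rate_constants.values():
            rc.validate()
        for rx in self.reactions:
            for name, _ in rx.reactants + rx.products:
                if name not in self.species:
                    raise ModelValidationError(f"reaction {rx.id}: unknown species {name}")
            if rx.enzyme is not None and rx.enzyme not in self.species:
                raise ModelValidationError(f"reaction {rx.id}: unknown enzyme {rx.enzyme}")
            if rx.rate_constant_id not in self.rate_constants:
                raise ModelValidationError(
                    f"reaction {rx.id}: unknown rate constant {rx.rate_constant_id}"
                )
            if rx.compartment not in self.compartments:
                raise ModelValidationError(f"reaction {rx.id}: unknown compartment")
        for bp in self.binding_pairs:
            for name in (bp.lipid, bp.bp, bp.complex):
                if name not in self.species:
                    raise ModelValidationError(f"binding pair {bp.lipid}: unknown species {name}")
            for rid in (bp.k_on_id, bp.k_off_id):
                if rid not in self.rate_constants:
                    raise ModelValidationError(f"binding pair {bp.lipid}: unknown rate {rid}")
            free = self.species[bp.bp].initial_amount
            bound = self.species[bp.complex].initial_amount
            if not math.isclose(free + bound, bp.bp_total, rel_tol=1e-9, abs_tol=1e-6):
                raise ModelValidationError(
                    f"binding pair {bp.lipid}: free + complex != bp_total"
                )
        if self.activation is not None:
            self.activation.validate()
            for rid in self.activation.rate_switches:
                if rid not in self.rate_constants:
                    raise ModelValidationError(f"rate switch names unknown constant {rid}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def _act(v):
            return "unchanged" if v is None else v

        d = {
            "name": self.name,
            "compartments": {c.name: c.volume for c in self.compartments.values()},
            "species": {
                sp.name: {
                    "compartment": sp.compartment,
                    "initial_amount": sp.initial_amount,
                    "role": sp.role,
                    **(
                        {"lipid_parent": sp.lipid_parent, "bp_parent": sp.bp_parent}
                        if sp.role == "complex"
                        else {}
                    ),
                }
                for sp in self.species.values()
            },
            "rates": {
                rc.id: {"basal": rc.basal_value, "activated": _act(rc.activated_value)}
                for rc in self.rate_constants.values()
            },
            "reactions": [
                {
                    "id": rx.id,
                    "reactants": [[n, s] for n, s in rx.reactants],
                    "products": [[n, s] for n, s in rx.products],
                    "rate": rx.rate_constant_id,
                    "enzyme": rx.enzyme,
                    "compartment": rx.compartment,
                }
                for rx in self.reactions
            ],
            "binding": [
                {
                    "lipid": bp.lipid,
                    "bp": bp.bp,
                    "complex": bp.complex,
                    "k_on": bp.k_on_id,
                    "k_off": bp.k_off_id,
                    "bp_total": bp.bp_total,
                }
                for bp in self.binding_pairs
            ],
            "metadata": dict(self.metadata),
        }
        if self.activation is not None:
            a = self.activation
            d["activation"] = {
                "t_activation": a.t_activation,
                "receptor_count": a.receptor_count,
                "rate_switches": list(a.rate_switches),
                "termination": a.termination,
                "termination_timescale": a.termination_timescale,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDefinition":
        compartments = {n: Compartment(n, v) for n, v in d["compartments"].items()}
        species = {
            n: Species(
                n,
                s["compartment"],
                s["initial_amount"],
                s["role"],
                s.get("lipid_parent"),
                s.get("bp_parent"),
            )
            for n, s in d["species"].items()
        }
        rates = {
            rid: RateConstant(
                rid,
                r["basal"],
                None if r["activated"] == "unchanged" else r["activated"],
            )
            for rid, r in d["rates"].items()
        }
        reactions = [
            Reaction(
                r["id"],
                [(n, s) for n, s in r["reactants"]],
                [(n, s) for n, s in r["products"]],
                r["rate"],
                r.get("enzyme"),
                r.get("compartment", "plasma_membrane"),
            )
            for r in d["reactions"]
        ]
        binding = [
            BindingPair(b["lipid"], b["bp"], b["complex"], b["k_on"], b["k_off"], b["bp_total"])
            for b in d["binding"]
        ]
        activation = None
        if "activation" in d:
            a = d["activation"]
            activation = ActivationScheme(
                a["t_activation"],
                a["receptor_count"],
                tuple(a["rate_switches"]),
                a["termination"],
                a["termination_timescale"],
            )
        model = cls(
            d["name"],
            compartments,
            species,
            rates,
            reactions,
            binding,
            activation,
            dict(d.get("metadata", {})),
        )
        model.validate()
        return model


# ---------------------------------------------------------------------------
# Shipped human-platelet parameterisation (synthetic stand-in calibration)
# ---------------------------------------------------------------------------

#: Human platelet compartment volumes, femtolitres.
PLATELET_VOLUMES = {"plasma_membrane": 1.0, "cytosol": 1.0, "organelles": 1.0}

#: Homeostatic lipid and inositol pools, molecules per cell.  PI4P and
#: PI45P2 totals (free + protein-bound) sit at ~1.5e6 and plasma-membrane
#: PI at ~6e6, with a matching organelle PI reserve and a cytosolic
#: inositol pool feeding PI resynthesis.
PLATELET_LIPIDS = {
    "PI_m": 6.0e6,
    "PI_o": 6.0e6,
    "PI4P": 1.5e6,
    "PI45P2": 1.5e6,
    "DAG": 0.0,
    "PA": 0.0,
    "IP3": 0.0,
    "Ins": 5.0e6,
}

#: Synthetic stand-in copy numbers for the 12 key proteins of a human
#: platelet, chosen at platelet-realistic orders of magnitude.
PLATELET_PROTEOME = {
    "Gaq": 40000.0,
    "smG": 50000.0,
    "PLCb": 20000.0,
    "IP3E": 15000.0,
    "DGK": 10000.0,
    "LPP": 5000.0,
    "CDIPT": 8000.0,
    "OCRL1": 2000.0,
    "PI4K": 4000.0,
    "PIP5K": 5000.0,
    "SAC1": 3000.0,
    "cPLA2": 10000.0,
}

#: Calibrated rate constants (basal, activated-or-None).  Units: 1/s for an
#: effective first-order reaction (rate = k * substrate * enzyme carries the
#: folded per-molecule units).  Basal values place the shipped pools at an
#: exact pre-activation steady state; primed values reproduce the
#: short synchronised PI4P/PI45P2 burst and the halving of membrane PI.
DEFAULT_RATES: dict[str, tuple[float, float | None]] = {
    "k16": (8.333333333333333e-08, 1.0e-06),   # PI4K: PI_m -> PI4P
    "k14": (1.0e-06, 1.3e-05),                  # PIP5K: PI4P -> PI45P2
    "k15": (2.5e-06, 1.25e-05),                 # OCRL1: PI45P2 -> PI4P
    "k17": (1.6666666666666667e-06, None),      # SAC1: PI4P -> PI_m (never switched)
    "k5": (2.0e-05, None),                      # active PLCb: PI45P2 -> IP3 + DAG
    "k6": (6.666666666666667e-06, None),        # IP3E: IP3 -> IPx (fast removal)
    "k7": (2.0e-03, None),                      # IPx -> Ins (slow, lumped)
    "k8": (5.0e-06, None),                      # DGK: DAG -> PA
    "k9": (2.0e-06, None),                      # LPP: PA -> DAG
    "k10": (2.5e-13, None),                     # CDIPT: PA + Ins -> PI_o
    "k11": (1.0e-05, None),                     # PI_o -> PI_m transfer (not activation-regulated)
    "k12": (1.0e-09, 6.0e-07),                 # cPLA2: PI_m -> PI_o recycling (thrombin-activated)
    "k_aG": (2.0e-06, None),                    # Ra-catalysed Gq activation
    "k_dG": (3.0e-01, None),                    # Gq_a deactivation
    "k_aP": (7.0e-10, None),                    # Gq_a-catalysed PLCb activation (with smG)
    "k_dP": (3.0e-01, None),                    # PLCb_a deactivation
    "k_ri": (1.0e-02, None),                    # receptor inactivation
}

#: Binding-protein pools: lipid -> (bp_total, k_on, k_off).  The PI45P2 pool
#: (1.3e6 per cell) is the calibrated buffering capacity that keeps the
#: free lipid available to PLC at ~4e5 molecules.
DEFAULT_BINDING: dict[str, tuple[float, float, float]] = {
    "PI45P2": (1.3e6, 1.375e-06, 0.1),
    "PI4P": (1.2e6, 2.75e-06, 0.1),
    "DAG": (5.0e5, 2.0e-06, 0.1),
    "PA": (5.0e5, 2.0e-06, 0.1),
}


def binding_equilibrium(lipid_total: float, bp_total: float, kd: float) -> float:
    """Equilibrium complex amount for L + B <-> C with dissociation constant kd.

    Root of the conservation quadratic C^2 - (L+B+kd) C + L*B = 0 lying in
    [0, min(L, B)].
    """
    if lipid_total < 0 or bp_total < 0 or kd <= 0:
        raise ValueError("amounts must be >= 0 and kd > 0")
    b = lipid_total + bp_total + kd
    disc = b * b - 4.0 * lipid_total * bp_total
    c = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    return min(max(c, 0.0), lipid_total, bp_total)


def mass_action_rate(
    reaction: Reaction,
    rate_value: float,
    state: dict[str, float],
    volume_factor: float = 1.0,
) -> float:
    """Mass-action flux of one reaction, molecules per second.

    flux = k * prod(reactant^stoich) * enzyme, divided by
    ``volume_factor**(molecularity - 1)``.  With the folded-constant
    convention used throughout the shipped models the volume factor is 1.
    """
    flux = rate_value / volume_factor ** (reaction.molecularity - 1)
    for name, stoich in reaction.reactants:
        amount = state[name]
        if amount < 0:
            raise ValueError(f"negative amount for {name}")
        flux *= amount**stoich
    if reaction.enzyme is not None:
        amount = state[reaction.enzyme]
        if amount < 0:
            raise ValueError(f"negative amount for {reaction.enzyme}")
        flux *= amount
    return flux


def _species_table(proteome: dict[str, float], lipids: dict[str, float],
                   binding: dict[str, tuple[float, float, float]]) -> dict[str, Species]:
    mem, cyt, org = COMPARTMENT_NAMES
    sp: dict[str, Species] = {}

    def add(name, compartment, amount, role, lipid_parent=None, bp_parent=None):
        sp[name] = Species(name, compartment, float(amount), role, lipid_parent, bp_parent)

    # lipid pools: bound lipids are split between free and complex below
    add("PI_m", mem, lipids["PI_m"], "lipid")
    add("PI_o", org, lipids["PI_o"], "lipid")
    for lipid in BOUND_LIPIDS:
        total = lipids[lipid]
        bp_total, k_on, k_off = binding[lipid]
        bound = binding_equilibrium(total, bp_total, k_off / k_on)
        add(lipid, mem, total - bound, "lipid")
        add(f"BP_{lipid}", cyt, bp_total - bound, "binding_protein")
        add(f"{lipid}_BP", mem, bound, "complex",
            lipid_parent=lipid, bp_parent=f"BP_{lipid}")
    add("IP3", cyt, lipids["IP3"], "inositol_phosphate")
    add("IPx", cyt, 0.0, "intermediate")
    add("Ins", cyt, lipids["Ins"], "inositol_phosphate")
    # signalling chain
    add("Ra", mem, 0.0, "receptor")
    add("R_i", mem, 0.0, "receptor")
    add("Gq", mem, proteome["Gaq"], "g_protein")
    add("Gq_a", mem, 0.0, "g_protein")
    add("smG", mem, proteome["smG"], "g_protein")
    add("PLCb", cyt, proteome["PLCb"], "enzyme")
    add("PLCb_a", mem, 0.0, "enzyme")
    # standing enzyme pools
    for prot in ("IP3E", "DGK", "LPP", "CDIPT", "OCRL1", "PI4K", "PIP5K", "SAC1", "cPLA2"):
        comp = cyt if prot in ("IP3E", "CDIPT") else mem
        add(prot, comp, proteome[prot], "enzyme")
    return sp


def _reaction_table() -> list[Reaction]:
    mem = "plasma_membrane"
    cyt = "cytosol"
    org = "organelles"
    return [
        Reaction("r_pi4k", [("PI_m", 1)], [("PI4P", 1)], "k16", "PI4K", mem),
        Reaction("r_pip5k", [("PI4P", 1)], [("PI45P2", 1)], "k14", "PIP5K", mem),
        Reaction("r_ocrl", [("PI45P2", 1)], [("PI4P", 1)], "k15", "OCRL1", mem),
        Reaction("r_sac1", [("PI4P", 1)], [("PI_m", 1)], "k17", "SAC1", mem),
        Reaction("r_plc", [("PI45P2", 1)], [("IP3", 1), ("DAG", 1)], "k5", "PLCb_a", mem),
        Reaction("r_ip3e", [("IP3", 1)], [("IPx", 1)], "k6", "IP3E", cyt),
        Reaction("r_ipx", [("IPx", 1)], [("Ins", 1)], "k7", None, cyt),
        Reaction("r_dgk", [("DAG", 1)], [("PA", 1)], "k8", "DGK", mem),
        Reaction("r_lpp", [("PA", 1)], [("DAG", 1)], "k9", "LPP", mem),
        Reaction("r_cdipt", [("PA", 1), ("Ins", 1)], [("PI_o", 1)], "k10", "CDIPT", cyt),
        Reaction("r_transfer", [("PI_o", 1)], [("PI_m", 1)], "k11", None, org),
        Reaction("r_cpla2", [("PI_m", 1)], [("PI_o", 1)], "k12", "cPLA2", mem),
        Reaction("r_gact", [("Gq", 1)], [("Gq_a", 1)], "k_aG", "Ra", mem),
        Reaction("r_pact", [("PLCb", 1), ("smG", 1)], [("PLCb_a", 1), ("smG", 1)],
                 "k_aP", "Gq_a", mem),
        Reaction("r_rinact", [("Ra", 1)], [("R_i", 1)], "k_ri", None, mem),
        Reaction("r_gdeact", [("Gq_a", 1)], [("Gq", 1)], "k_dG", None, mem),
        Reaction("r_pdeact", [("PLCb_a", 1)], [("PLCb", 1)], "k_dP", None, mem),
    ]


def build_core_model(
    proteome,
    lipid_inits: dict[str, float] | None = None,
    volumes: dict[str, float] | None = None,
    rates: dict[str, tuple[float, float | None]] | None = None,
    binding: dict[str, tuple[float, float, float]] | None = None,
    name: str = "human_platelet_core",
) -> ModelDefinition:
    """Assemble the core PI-cycle model from a proteome and lipid pools.

    ``proteome`` is a mapping protein -> copies/cell (or an object with an
    ``entries`` mapping) covering :data:`KEY_PROTEINS`; ``lipid_inits``
    covers :data:`LIPID_POOLS`.  Bound lipids start at binding equilibrium
    so that the supplied totals partition consistently between free and
    complexed pools.  Raises :class:`MissingDataError` naming every absent
    protein or lipid entry.
    """
    entries = getattr(proteome, "entries", proteome)
    missing = [p for p in KEY_PROTEINS if p not in entries]
    if missing:
        raise MissingDataError("protein", missing)
    lipids = dict(PLATELET_LIPIDS if lipid_inits is None else lipid_inits)
    missing = [l for l in LIPID_POOLS if l not in lipids]
    if missing:
        raise MissingDataError("lipid", missing)
    vols = dict(PLATELET_VOLUMES if volumes is None else volumes)
    rates = dict(DEFAULT_RATES if rates is None else rates)
    binding = dict(DEFAULT_BINDING if binding is None else binding)

    compartments = {n: Compartment(n, float(vols[n])) for n in COMPARTMENT_NAMES}
    species = _species_table({p: float(entries[p]) for p in KEY_PROTEINS}, lipids, binding)
    rate_constants = {rid: RateConstant(rid, b, a) for rid, (b, a) in rates.items()}
    reactions = _reaction_table()
    binding_pairs = []
    for lipid in BOUND_LIPIDS:
        bp_total, k_on, k_off = binding[lipid]
        on_id, off_id = f"kon_{lipid}", f"koff_{lipid}"
        rate_constants[on_id] = RateConstant(on_id, k_on)
        rate_constants[off_id] = RateConstant(off_id, k_off)
        reactions.append(
            Reaction(f"r_on_{lipid}", [(lipid, 1), (f"BP_{lipid}", 1)],
                     [(f"{lipid}_BP", 1)], on_id, None, "plasma_membrane")
        )
        reactions.append(
            Reaction(f"r_off_{lipid}", [(f"{lipid}_BP", 1)],
                     [(lipid, 1), (f"BP_{lipid}", 1)], off_id, None, "plasma_membrane")
        )
        binding_pairs.append(
            BindingPair(lipid, f"BP_{lipid}", f"{lipid}_BP", on_id, off_id, float(bp_total))
        )

    model = ModelDefinition(
        name,
        compartments,
        species,
        rate_constants,
        reactions,
        binding_pairs,
        activation=None,
        metadata={"cell_type": name, "provenance": "synthetic calibration"},
    )
    model.validate()
    return model


def apply_activation(model: ModelDefinition, scheme: ActivationScheme) -> ModelDefinition:
    """Return a copy of ``model`` carrying the GPCR activation scheme.

    Refuses schemes that try to switch k17 (SAC1 is never activation
    regulated) or that name constants without primed values.
    """
    scheme.validate()
    for rid in scheme.rate_switches:
        if rid not in model.rate_constants:
            raise ModelValidationError(f"rate switch names unknown constant {rid}")
        if model.rate_constants[rid].activated_value is None:
            raise ModelValidationError(f"rate {rid} has no activated value to switch to")
    out = model.copy()
    out.activation = replace(scheme)
    out.validate()
    return out


def platelet_model(activated: bool = True, receptor_count: float = 5000.0,
                   t_activation: float = 100.0) -> ModelDefinition:
    """Convenience constructor: the shipped human-platelet core model.

    With ``activated=True`` the default thrombin-like stimulation (all
    Gq-coupled receptors, RGq = 5000, at t = 100 s) is attached.
    """
    model = build_core_model(PLATELET_PROTEOME)
    if activated:
        model = apply_activation(
            model,
            ActivationScheme(t_activation=t_activation, receptor_count=receptor_count),
        )
    return model
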