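"""Shared fixtures: shipped models, trajectories, and toy-network builders."""

from __future__ import annotations

import numpy as np
import pytest

from picycle.model import (
    ActivationScheme,
    Compartment,
    ModelDefinition,
    RateConstant,
    Reaction,
    Species,
    platelet_model,
)
from picycle.simulate import simulate

OBSERVABLE_NAMES = ("PI", "PI4P", "PI45P2", "IP3", "DAG", "PA", "Ins")


def make_toy_model(
    species: dict[str, float],
    reactions: list[tuple],
    rates: dict[str, float],
    activation: ActivationScheme | None = None,
    roles: dict[str, str] | None = None,
) -> ModelDefinition:
    """Minimal valid model: three compartments, no binding pairs.

    ``reactions`` entries are (id, reactants, products, rate_id[, enzyme]).
    """
    roles = roles or {}
    compartments = {
        n: Compartment(n, 1.0) for n in ("plasma_membrane", "cytosol", "organelles")
    }
    sp = {
        name: Species(name, "cytosol", amount, roles.get(name, "enzyme"))
        for name, amount in species.items()
    }
    rcs = {rid: RateConstant(rid, value) for rid, value in rates.items()}
    rxs = []
    for entry in reactions:
        rid, reactants, products, rate_id, *rest = entry
        enzyme = rest[0] if rest else None
        rxs.append(Reaction(rid, list(reactants), list(products), rate_id,
                            enzyme, "cytosol"))
    model = ModelDefinition("toy", compartments, sp, rcs, rxs, [], activation)
    model.validate()
    return model


@pytest.fixture(scope="session")
def platelet():
    """Shipped platelet core model with the default thrombin-like activation."""
    return platelet_model()


@pytest.fixture(scope="session")
def platelet_basal():
    return platelet_model(activated=False)


@pytest.fixture(scope="session")
def platelet_trajectory(platelet):
    """Activated platelet run, 0-2000 s on a 1 s grid."""
    return simulate(platelet, 2000.0, np.linspace(0.0, 2000.0, 2001))
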