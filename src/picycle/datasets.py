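"""Shipped default tables and model file.

All shipped inputs are synthetic stand-ins: the proteome tables are
generated from the platelet template with seeded log-normal between-cell-
type variation, and the model file carries this package's own calibration.
The files live under ``picycle/data`` and are regenerated by
``examples/regenerate_data.py``.
"""

from __future__ import annotations

from importlib import resources

from .celltypes import ProteomeTable
from .io import load_model
from .model import ModelDefinition

__all__ = ["load_core_model", "load_proteome", "PROTEOME_FILES", "data_path"]

PROTEOME_FILES = {
    "human_platelet": "proteome_human_platelet_synthetic.csv",
    "mouse_platelet": "proteome_mouse_platelet_synthetic.csv",
    "hela": "proteome_hela_synthetic.csv",
    "u2os_partial": "proteome_u2os_partial_synthetic.csv",
    "u2os_scanned": "proteome_u2os_scanned_synthetic.csv",
}

MODEL_FILE = "platelet_core_synthetic.yaml"


def data_path(filename: str):
    return resources.files("picycle").joinpath("data", filename)


def load_core_model() -> ModelDefinition:
    """The shipped calibrated human-platelet core model (with activation)."""
    return load_model(data_path(MODEL_FILE))


def load_proteome(name: str) -> ProteomeTable:
    """A shipped proteome table by short name (see :data:`PROTEOME_FILES`)."""
    if name not in PROTEOME_FILES:
        raise KeyError(f"unknown proteome {name!r}; options: {sorted(PROTEOME_FILES)}")
    return ProteomeTable.from_csv(data_path(PROTEOME_FILES[name]))
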