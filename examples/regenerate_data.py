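"""Regenerate every shipped data file under picycle/data from code.

All shipped tables are synthetic stand-ins: copy numbers at realistic
orders of magnitude with seeded log-normal between-cell-type variation.
The scanned U2OS table is computed by the package's own gap-scanning
pipeline against the HeLa reference behaviour, so rebuilding it takes a
few minutes of ODE solves.
"""

from pathlib import Path

import numpy as np

from picycle.celltypes import (
    NUCLEATED_GEOMETRY,
    NUCLEATED_RECEPTOR_COUNT,
    ProteomeTable,
    equilibrate_model,
    rescale_model,
    scan_missing_proteins,
)
from picycle.io import save_model
from picycle.model import PLATELET_PROTEOME, platelet_model
from picycle.simulate import simulate
from picycle.synthetic import generate_proteome

OUT = Path(__file__).resolve().parent.parent / "src" / "picycle" / "data"
U2OS_MISSING = ("Gaq", "IP3E", "OCRL1", "PI4K", "cPLA2")

core = platelet_model()
save_model(core, OUT / "platelet_core_synthetic.yaml")

human = ProteomeTable("human_platelet", dict(PLATELET_PROTEOME))
human.to_csv(OUT / "proteome_human_platelet_synthetic.csv")

# mouse platelet: quarter volume, moderate orthologue divergence
mouse = generate_proteome(human, fold_sd=0.5, seed=3, scale=0.25,
                          cell_type="mouse_platelet")
mouse.to_csv(OUT / "proteome_mouse_platelet_synthetic.csv")

# HeLa: nucleated scale-up with cross-cell-type scatter
hela = generate_proteome(human, fold_sd=0.8, seed=7, scale=17.0, cell_type="hela")
hela.to_csv(OUT / "proteome_hela_synthetic.csv")

# U2OS: correlated with HeLa (two human lines), then 5 entries removed
u2os = generate_proteome(hela, fold_sd=0.45, seed=11, cell_type="u2os")
for p in U2OS_MISSING:
    del u2os.entries[p]
    del u2os.provenance[p]
u2os.to_csv(OUT / "proteome_u2os_partial_synthetic.csv")

# scanned completion against the equilibrated HeLa reference behaviour
grid = np.linspace(0.0, 5000.0, 401)
hela_model = equilibrate_model(
    rescale_model(core, NUCLEATED_GEOMETRY, hela, NUCLEATED_RECEPTOR_COUNT,
                  t_activation=1000.0))
reference = simulate(hela_model, 5000.0, grid)
scanned = scan_missing_proteins(u2os, reference, platelet_model(t_activation=1000.0),
                                base_model=hela_model)
scanned.to_csv(OUT / "proteome_u2os_scanned_synthetic.csv")
print("wrote", sorted(p.name for p in OUT.iterdir()))
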