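"""Scaled time-series sensitivity of IP3 to protein copy numbers.

For each protein p the scaled sensitivity is the dimensionless
log-derivative (dIP3/IP3) / (dp/p), estimated by a central finite
difference at p(1 +/- delta) with delta = 0.2 by default.  Entries where
baseline IP3 sits below a floor (1 molecule) are reported as undefined
rather than propagating meaningless ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._system import compile_model
from .calibrate import PROTEIN_SPECIES
from .model import KEY_PROTEINS, ModelDefinition
from .simulate import simulate_compiled

__all__ = ["SensitivityMatrix", "ip3_sensitivity", "IP3_FLOOR"]

#: Baseline IP3 amounts at or below this (molecules) make the scaled
#: denominator meaningless; such entries are flagged undefined.
IP3_FLOOR = 1.0


@dataclass
class SensitivityMatrix:
    """Proteins x output-times matrix of scaled sensitivities."""

    proteins: list[str]
    times: np.ndarray
    values: np.ndarray   # (n_proteins, n_times); 0 where undefined
    defined: np.ndarray  # boolean mask, same shape
    peak_time: float     # time of the baseline IP3 peak
    peak_values: np.ndarray  # per-protein sensitivity at the peak time

    def row(self, protein: str) -> np.ndarray:
        return self.values[self.proteins.index(protein)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.proteins,
                          columns=[f"{t:g}" for t in self.times])
        df.insert(0, "at_peak", self.peak_values)
        df.index.name = "protein"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def ip3_sensitivity(
    model: ModelDefinition,
    proteins=KEY_PROTEINS,
    delta: float = 0.2,
    times: np.ndarray | None = None,
    t_end: float | None = None,
    observable: str = "IP3",
) -> SensitivityMatrix:
    """Central-difference scaled sensitivity of IP3 to initial protein amounts.

    ``delta`` must lie in (0, 1); each protein is perturbed to p(1 - delta)
    and p(1 + delta) with everything else frozen, and the scaled sensitivity
    (IP3+ - IP3-) / (2 delta IP3_base) evaluated on the output grid.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if t_end is None:
        t_act = model.activation.t_activation if model.activation else 0.0
        t_end = t_act + 1900.0
    if times is None:
        times = np.linspace(0.0, t_end, 201)
    times = np.asarray(times, float)

    cm = compile_model(model)
    missing = [p for p in proteins if PROTEIN_SPECIES.get(p, p) not in cm.index]
    if missing:
        raise KeyError(f"unknown proteins: {missing}")

    base_tc = simulate_compiled(cm, t_end, times)
    base = base_tc.observable(observable)
    peak_i = int(np.argmax(base))

    values = np.zeros((len(proteins), times.size))
    defined = np.zeros_like(values, dtype=bool)
    for i, p in enumerate(proteins):
        j = cm.index[PROTEIN_SPECIES.get(p, p)]
        p0 = cm.y0[j]
        if p0 == 0.0:
            defined[i] = base > IP3_FLOOR  # zero pool: structural zero row
            continue
        lo = cm.y0.copy()
        hi = cm.y0.copy()
        lo[j] = p0 * (1.0 - delta)
        hi[j] = p0 * (1.0 + delta)
        v_lo = simulate_compiled(cm, t_end, times, y0=lo).observable(observable)
        v_hi = simulate_compiled(cm, t_end, times, y0=hi).observable(observable)
        ok = base > IP3_FLOOR
        values[i, ok] = (v_hi[ok] - v_lo[ok]) / (2.0 * delta * base[ok])
        defined[i] = ok

    return SensitivityMatrix(
        proteins=list(proteins),
        times=times,
        values=values,
        defined=defined,
        peak_time=float(times[peak_i]),
        peak_values=values[:, peak_i].copy(),
    )
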