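"""Synthetic experimental data standing in for the collated platelet datasets.

Two generators cover everything the pipeline consumes:

* pseudo time-course datasets emulating thrombin-stimulated platelet
  measurements (n = 10 replicates, mean +/- SEM, multiplicative log-normal
  noise), and
* pseudo proteome tables with controlled log-normal between-cell-type
  variation, standing in for the mouse-platelet, HeLa and U2OS tables.

Neither generator digitises any published curve; they emulate the *format*
and dispersion of such data so that calibration and robustness analyses can
be exercised end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltypes import ProteomeTable
from .model import ModelDefinition
from .simulate import TimeCourse, simulate

__all__ = [
    "ExperimentalDataset",
    "SyntheticTruth",
    "generate_timecourses",
    "generate_proteome",
    "DEFAULT_NOISE_SD",
    "DEFAULT_TIMES",
]

#: Relative (log-normal) noise chosen to emulate the size of typical SEM
#: bars on platelet lipid time courses; a stand-in, not a measured value.
DEFAULT_NOISE_SD = 0.15

#: Default sampling times (s) for a platelet run activated at 100 s.
DEFAULT_TIMES = np.array(
    [0.0, 30.0, 60.0, 90.0, 100.0, 105.0, 110.0, 120.0, 135.0, 150.0,
     180.0, 240.0, 300.0, 450.0, 600.0, 900.0, 1200.0, 1800.0]
)


@dataclass
class ExperimentalDataset:
    """Time-resolved mean +/- SEM for one observable."""

    observable: str
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.mean = np.asarray(self.mean, float)
        self.sem = np.asarray(self.sem, float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SyntheticTruth:
    """A generating model plus its noise description and seed."""

    model: ModelDefinition
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_timecourses(
    truth: SyntheticTruth,
    observables=("PI", "PI4P", "PI45P2", "IP3", "DAG", "PA", "Ins"),
    times: np.ndarray = DEFAULT_TIMES,
    n: int = 10,
    t_end: float | None = None,
) -> dict[str, ExperimentalDataset]:
    """Simulate the truth model and draw noisy replicate datasets.

    Each replicate multiplies the noiseless value by a log-normal factor
    with E[factor] = 1 (log-mean -sd^2/2), so dataset means are unbiased;
    the reported SEM is the replicate standard error.  Identical seeds give
    bit-identical datasets.
    """
    times = np.asarray(times, float)
    if times[0] < 0:
        raise ValueError("sampling times must be >= 0")
    if t_end is None:
        t_end = float(times[-1])
    elif times[-1] > t_end:
        raise ValueError("sampling times extend beyond the simulation horizon")
    tc = simulate(truth.model, t_end, times if times[0] == 0.0 else np.insert(times, 0, 0.0))
    rng = np.random.default_rng(truth.seed)
    sd = truth.noise_sd
    out: dict[str, ExperimentalDataset] = {}
    for obs in observables:
        clean = np.interp(times, tc.times, tc.observable(obs))
        if sd == 0:
            mean, sem = clean.copy(), np.zeros_like(clean)
        else:
            factors = rng.lognormal(-0.5 * sd * sd, sd, size=(n, times.size))
            reps = clean[None, :] * factors
            mean = reps.mean(axis=0)
            sem = reps.std(axis=0, ddof=1) / np.sqrt(n)
        out[obs] = ExperimentalDataset(obs, times, mean, sem, n)
    return out


def generate_proteome(
    template,
    fold_sd: float,
    seed: int,
    scale: float = 1.0,
    cell_type: str = "synthetic",
) -> ProteomeTable:
    """Perturb a template proteome by median-preserving log-normal factors.

    ``fold_sd`` is the standard deviation of the natural log of the
    perturbation factor (0 reproduces ``scale`` times the template exactly);
    ``scale`` applies a uniform volume-like factor first.  Provenance of
    every entry is ``native``.
    """
    if fold_sd < 0:
        raise ValueError("fold_sd must be >= 0")
    entries = getattr(template, "entries", template)
    rng = np.random.default_rng(seed)
    names = list(entries)
    factors = rng.lognormal(0.0, fold_sd, size=len(names)) if fold_sd > 0 else np.ones(len(names))
    return ProteomeTable(
        cell_type,
        {name: float(entries[name]) * scale * f for name, f in zip(names, factors)},
    )


def datasets_to_frame(data: dict[str, ExperimentalDataset]) -> pd.DataFrame:
    rows = []
    for obs, ds in data.items():
        for t, m, s in zip(ds.times, ds.mean, ds.sem):
            rows.append({"observable": obs, "time_s": t, "mean": m, "sem": s, "n": ds.n})
    return pd.DataFrame(rows)


def datasets_to_csv(data: dict[str, ExperimentalDataset], path) -> None:
    datasets_to_frame(data).to_csv(path, index=False)


def datasets_from_csv(path) -> dict[str, ExperimentalDataset]:
    df = pd.read_csv(path)
    out = {}
    for obs, g in df.groupby("observable", sort=False):
        g = g.sort_values("time_s")
        out[str(obs)] = ExperimentalDataset(
            str(obs), g["time_s"].to_numpy(), g["mean"].to_numpy(),
            g["sem"].to_numpy(), int(g["n"].iloc[0]),
        )
    return out
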