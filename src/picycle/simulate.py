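"""Deterministic stiff integration of PI-cycle models with event handling.

Integration uses LSODA (stiff/non-stiff switching) with an analytic
Jacobian.  Activation is handled by stopping at each event time, applying
the discrete changes (receptor injection, rate-constant switch), and
restarting, so the state of untouched species is continuous across events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._system import CompiledModel, compile_model
from .model import ModelDefinition, OBSERVABLES

__all__ = [
    "TimeCourse",
    "SteadyState",
    "SimulationError",
    "simulate",
    "simulate_compiled",
    "find_steady_state",
    "summarize",
    "Summary",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6
#: Amounts in (-NEG_CLIP * max(|y|), 0) are solver noise and clipped to zero.
NEG_CLIP = 1e-9


class SimulationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:g} s)")
        self.last_time = last_time


@dataclass
class TimeCourse:
    """Solver output: a time grid by species matrix of molecule numbers."""

    times: np.ndarray
    species: list[str]
    amounts: np.ndarray  # shape (n_times, n_species)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.amounts = np.asarray(self.amounts, float)
        self._index = {s: i for i, s in enumerate(self.species)}

    def __getitem__(self, species: str) -> np.ndarray:
        if species not in self._index:
            raise KeyError(f"unknown species {species!r}")
        return self.amounts[:, self._index[species]]

    def observable(self, name: str) -> np.ndarray:
        """Observed quantity (lipid observables sum free + bound pools)."""
        names = OBSERVABLES.get(name, (name,))
        cols = [n for n in names if n in self._index]
        if not cols:
            raise KeyError(f"unknown observable {name!r}")
        return sum(self[n] for n in cols)

    def at(self, t: float) -> dict[str, float]:
        row = np.array([np.interp(t, self.times, self.amounts[:, i])
                        for i in range(self.amounts.shape[1])])
        return dict(zip(self.species, row))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, species, amount) frame."""
        n_t, n_s = self.amounts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_s),
                "species": np.tile(np.array(self.species, object), n_t),
                "amount": self.amounts.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        df = pd.read_csv(path)
        wide = df.pivot(index="time", columns="species", values="amount")
        return cls(wide.index.to_numpy(float), list(wide.columns), wide.to_numpy(float))


@dataclass
class SteadyState:
    amounts: dict[str, float]
    residual: float  # max |dX/dt| over species, molecules/s
    converged: bool = True


@dataclass
class Summary:
    """Window summary of one trajectory."""

    peak: float
    time_of_peak: float
    trough: float
    time_of_trough: float
    initial: float
    ratio_to_initial: float
    _times: np.ndarray = None
    _values: np.ndarray = None

    def level_at(self, t: float) -> float:
        return float(np.interp(t, self._times, self._values))


def _segment(cm: CompiledModel, y0, t0, t1, t_eval, rtol, atol):
    if t1 - t0 <= 0:
        return np.empty(0), np.empty((0, y0.size)), y0
    # always integrate to t1 so the hand-off state is exact
    want_end = t_eval.size > 0 and t_eval[-1] == t1
    te = t_eval if want_end else np.append(t_eval, t1)
    sol = solve_ivp(
        cm.rhs, (t0, t1), y0, method="LSODA", jac=cm.jac,
        t_eval=te, rtol=rtol, atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t0
        raise SimulationError(f"LSODA failed: {sol.message}", last)
    y_end = sol.y[:, -1].copy()
    if want_end:
        return sol.t, sol.y.T, y_end
    return sol.t[:-1], sol.y.T[:-1], y_end


def simulate_compiled(
    cm: CompiledModel,
    t_end: float,
    grid: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> TimeCourse:
    """Integrate an already-compiled model (fast path for scans)."""
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if grid is None:
        grid = np.linspace(0.0, t_end, 501)
    grid = np.asarray(grid, float)
    if grid[0] < 0 or grid[-1] > t_end or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within [0, t_end]")
    y = (cm.y0 if y0 is None else np.asarray(y0, float)).copy()

    scheme = cm.activation
    boundaries = [0.0]
    if scheme is not None and scheme.t_activation < t_end:
        boundaries.append(scheme.t_activation)
        t_off = scheme.t_activation + scheme.termination_timescale
        if scheme.termination == "reset" and t_off < t_end:
            boundaries.append(t_off)
    boundaries.append(t_end)

    times_out: list[np.ndarray] = []
    amounts_out: list[np.ndarray] = []
    cm.use_basal()
    include_left = True
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        if include_left:
            mask = (grid >= t0) & (grid <= t1)
        else:
            mask = (grid > t0) & (grid <= t1)
        t_eval = grid[mask]
        ts, ys, y = _segment(cm, y, t0, t1, t_eval, rtol, atol)
        times_out.append(ts)
        amounts_out.append(ys)
        include_left = False
        # discrete changes at the segment boundary just reached
        if scheme is not None and t1 == scheme.t_activation and t1 < t_end:
            y = y.copy()
            y[cm.index["Ra"]] += scheme.receptor_count
            if scheme.receptor_count > 0:
                cm.use_active()
        elif scheme is not None and scheme.termination == "reset" \
                and t1 == scheme.t_activation + scheme.termination_timescale and t1 < t_end:
            cm.use_basal()
    cm.use_basal()

    times = np.concatenate(times_out)
    amounts = np.vstack([a for a in amounts_out if a.size])
    scale = np.abs(amounts).max() if amounts.size else 0.0
    floor = -NEG_CLIP * max(scale, 1.0)
    if amounts.size and amounts.min() < floor:
        worst = float(amounts.min())
        raise SimulationError(f"negative amount {worst:g} beyond clipping band", times[-1])
    np.clip(amounts, 0.0, None, out=amounts)
    return TimeCourse(times, list(cm.species), amounts)


def simulate(
    model: ModelDefinition,
    t_end: float,
    grid: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> TimeCourse:
    """Integrate ``model`` to ``t_end`` seconds on the requested output grid."""
    return simulate_compiled(compile_model(model), t_end, grid, rtol=rtol, atol=atol)


def find_steady_state(
    model: ModelDefinition | CompiledModel,
    tol: float = 1e-8,
    t_max: float = 1e8,
) -> SteadyState:
    """Pre-activation steady state by relaxation.

    Integrates the basal (event-free) system over geometrically growing
    horizons until the scaled residual max |dX/dt| / (|X| + 1) falls below
    ``tol`` (1/s).  Relaxation respects the model's conservation laws, which
    make plain root-finding on dX/dt = 0 rank-deficient.  If the budget
    ``t_max`` is exhausted the best state is returned with
    ``converged=False``.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    cm.use_basal()
    y = cm.y0.copy()
    t_chunk = 1e3
    converged = False
    while True:
        dy = cm.derivative(y)
        scaled = np.abs(dy) / (np.abs(y) + 1.0)
        if scaled.max() < tol:
            converged = True
            break
        if t_chunk > t_max:
            break
        sol = solve_ivp(cm.rhs, (0.0, t_chunk), y, method="LSODA", jac=cm.jac,
                        rtol=1e-10, atol=1e-8)
        if not sol.success:
            break
        y = np.clip(sol.y[:, -1], 0.0, None)
        t_chunk *= 10.0
    dy = cm.derivative(y)
    return SteadyState(dict(zip(cm.species, y)), float(np.abs(dy).max()), converged)


def summarize(tc: TimeCourse, species: str, window: tuple[float, float] | None = None) -> Summary:
    """Peak / trough / ratio-to-initial summary of one species or observable.

    The window must lie inside the trajectory's time range; the
    ratio-to-initial uses the amount on the first grid point (t = 0+).
    """
    values = tc.observable(species)
    if window is None:
        window = (float(tc.times[0]), float(tc.times[-1]))
    t0, t1 = window
    if t0 < tc.times[0] or t1 > tc.times[-1] or t1 <= t0:
        raise ValueError("window outside trajectory range")
    mask = (tc.times >= t0) & (tc.times <= t1)
    t_w, v_w = tc.times[mask], values[mask]
    i_max = int(np.argmax(v_w))
    i_min = int(np.argmin(v_w))
    initial = float(values[0])
    peak = float(v_w[i_max])
    ratio = peak / initial if initial > 0 else np.inf if peak > 0 else 1.0
    return Summary(
        peak=peak,
        time_of_peak=float(t_w[i_max]),
        trough=float(v_w[i_min]),
        time_of_trough=float(t_w[i_min]),
        initial=initial,
        ratio_to_initial=ratio,
        _times=tc.times,
        _values=values,
    )
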