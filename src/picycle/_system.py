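"""Compilation of a ModelDefinition into flat arrays plus numba kernels.

A reaction j contributes flux_j = k_j * prod_m y[factor_idx[j, m]] where the
factor list holds each reactant repeated by its stoichiometry, followed by
the enzyme (if any).  Net stoichiometries are stored sparsely.  The same
arrays drive both the right-hand side and the analytic Jacobian, which keeps
LSODA cheap enough for thousands of solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ModelDefinition

_MAX_FACTORS = 4
_MAX_STOICH = 6


@njit(cache=False)
def _rhs(y, k, fidx, fnum, sidx, sval, snum, out):
    out[:] = 0.0
    n_rx = k.shape[0]
    for j in range(n_rx):
        flux = k[j]
        for m in range(fnum[j]):
            a = y[fidx[j, m]]
            if a < 0.0:
                a = 0.0
            flux *= a
        for s in range(snum[j]):
            out[sidx[j, s]] += sval[j, s] * flux
    return out


@njit(cache=False)
def _jac(y, k, fidx, fnum, sidx, sval, snum, out):
    out[:, :] = 0.0
    n_rx = k.shape[0]
    for j in range(n_rx):
        for m in range(fnum[j]):
            col = fidx[j, m]
            if y[col] < 0.0:
                continue
            d = k[j]
            for mm in range(fnum[j]):
                if mm != m:
                    a = y[fidx[j, mm]]
                    if a < 0.0:
                        a = 0.0
                    d *= a
            for s in range(snum[j]):
                out[sidx[j, s], col] += sval[j, s] * d
    return out


@dataclass
class CompiledModel:
    """Flat-array view of a model, ready for integration."""

    species: list[str]
    index: dict[str, int]
    y0: np.ndarray
    k_basal: np.ndarray
    k_active: np.ndarray          # constants during the activated window
    fidx: np.ndarray
    fnum: np.ndarray
    sidx: np.ndarray
    sval: np.ndarray
    snum: np.ndarray
    activation: object = None     # ActivationScheme or None
    _scratch: np.ndarray = field(default=None, repr=False)
    _jscratch: np.ndarray = field(default=None, repr=False)

    def rhs(self, t, y):
        return _rhs(y, self._k_current, self.fidx, self.fnum,
                    self.sidx, self.sval, self.snum, self._scratch).copy()

    def jac(self, t, y):
        return _jac(y, self._k_current, self.fidx, self.fnum,
                    self.sidx, self.sval, self.snum, self._jscratch).copy()

    def use_basal(self):
        self._k_current = self.k_basal

    def use_active(self):
        self._k_current = self.k_active

    def derivative(self, y, active: bool = False) -> np.ndarray:
        k = self.k_active if active else self.k_basal
        return _rhs(np.asarray(y, float), k, self.fidx, self.fnum,
                    self.sidx, self.sval, self.snum, np.empty_like(self.y0)).copy()


def compile_model(model: ModelDefinition) -> CompiledModel:
    model.validate()
    species = list(model.species)
    index = {name: i for i, name in enumerate(species)}
    y0 = np.array([model.species[s].initial_amount for s in species], float)

    n_rx = len(model.reactions)
    fidx = np.full((n_rx, _MAX_FACTORS), 0, np.int64)
    fnum = np.zeros(n_rx, np.int64)
    sidx = np.zeros((n_rx, _MAX_STOICH), np.int64)
    sval = np.zeros((n_rx, _MAX_STOICH), np.float64)
    snum = np.zeros(n_rx, np.int64)
    k_basal = np.zeros(n_rx)
    k_active = np.zeros(n_rx)

    switches = set(model.activation.rate_switches) if model.activation else set()
    for j, rx in enumerate(model.reactions):
        factors: list[int] = []
        for name, stoich in rx.reactants:
            factors.extend([index[name]] * stoich)
        if rx.enzyme is not None:
            factors.append(index[rx.enzyme])
        if len(factors) > _MAX_FACTORS:
            raise ValueError(f"reaction {rx.id}: kinetic order above {_MAX_FACTORS}")
        fnum[j] = len(factors)
        fidx[j, : len(factors)] = factors
        net = rx.net_stoichiometry()
        if len(net) > _MAX_STOICH:
            raise ValueError(f"reaction {rx.id}: too many net species")
        snum[j] = len(net)
        for s, (name, v) in enumerate(net.items()):
            sidx[j, s] = index[name]
            sval[j, s] = float(v)
        rc = model.rate_constants[rx.rate_constant_id]
        k_basal[j] = rc.basal_value
        if rc.id in switches and rc.activated_value is not None:
            k_active[j] = rc.activated_value
        else:
            k_active[j] = rc.basal_value

    cm = CompiledModel(
        species, index, y0, k_basal, k_active,
        fidx, fnum, sidx, sval, snum,
        activation=model.activation,
        _scratch=np.empty_like(y0),
        _jscratch=np.empty((len(species), len(species))),
    )
    cm.use_basal()
    return cm
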