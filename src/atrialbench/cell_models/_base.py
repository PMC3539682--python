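"""Ionic-model plugin contract.

An ionic model is an ODE system for one myocyte: membrane voltage V_m (mV,
always state 0), Hodgkin–Huxley gating variables (dimensionless, integrated
with the Rush–Larsen exponential update), and concentrations / buffer
occupancies (forward Euler, or an RK4 sub-integrator for states flagged
stiff).  Time is in ms throughout; stimulus current is expressed as a
depolarizing contribution to dV/dt in mV/ms (equivalently pA/pF).

A model implementation supplies three compiled callables operating on flat
state/parameter vectors:

``core(state, params, istim, d, yinf, tau)``
    writes d(state)/dt into ``d`` and, for every gating state, the
    steady-state value and time constant into ``yinf`` / ``tau``.
``step(state, params, dt, istim, d, yinf, tau)``
    advances ``state`` in place by one step (Rush–Larsen + forward Euler,
    plus any per-state sub-integrator override).
``currents(state, params, out)``
    instantaneous sarcolemmal currents, in the model's native convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "IonicModel",
    "ModelError",
    "get_model",
    "list_models",
    "register_model",
    "apply_caf_remodeling",
]


class ModelError(ValueError):
    """Raised for invalid model states or parameter operations."""


@dataclass(frozen=True)
class IonicModel:
    """One ionic model variant, with its compiled integration kernels."""

    name: str
    variant: str  # "control" | "caf"
    state_names: tuple[str, ...]
    state_units: tuple[str, ...]
    param_names: tuple[str, ...]
    params: np.ndarray
    initial_state: np.ndarray
    gating_index: np.ndarray  # states eligible for Rush–Larsen
    stiff_index: np.ndarray  # states integrated with the RK4 sub-integrator
    current_names: tuple[str, ...]
    cai_index: int  # index of cytosolic [Ca2+] (mM), -1 if absent
    cm: float  # membrane capacitance, pF
    caf_scaling: Mapping[str, float]  # parameter name -> cAF factor
    core: Callable = field(repr=False)
    step: Callable = field(repr=False)
    currents_fn: Callable = field(repr=False)
    _kernels: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic introspection -------------------------------------------------

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    @property
    def key(self) -> str:
        return self.name if self.variant == "control" else f"{self.name}-caf"

    def param(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def with_params(self, **updates: float) -> "IonicModel":
        p = self.params.copy()
        for k, v in updates.items():
            p[self.param_names.index(k)] = v
        return replace(self, params=p, _kernels=self._kernels)

    # -- ODE surface ---------------------------------------------------------

    def derivatives(self, state, t: float = 0.0, istim: float = 0.0):
        """d(state)/dt plus (steady-state, time-constant) pairs for gates.

        Returns ``(dstate, yinf, tau)``; ``yinf``/``tau`` are meaningful only
        at ``gating_index`` positions.
        """
        state = np.asarray(state, dtype=np.float64)
        if state.shape != (self.n_state,):
            raise ModelError(
                f"{self.key}: state has shape {state.shape}, "
                f"expected ({self.n_state},)"
            )
        bad = np.flatnonzero(~np.isfinite(state))
        if bad.size:
            names = ", ".join(self.state_names[i] for i in bad)
            raise ModelError(
                f"{self.key}: non-finite state ({names}) at t = {t:g} ms"
            )
        d = np.empty(self.n_state)
        yinf = np.empty(self.n_state)
        tau = np.empty(self.n_state)
        self.core(state, self.params, float(istim), d, yinf, tau)
        return d, yinf, tau

    def step_once(self, state, dt: float, istim: float = 0.0, t: float = 0.0):
        """Advance a copy of ``state`` by one integration step of ``dt`` ms."""
        if dt <= 0:
            raise ModelError("dt must be > 0")
        state = np.array(state, dtype=np.float64)
        d = np.empty(self.n_state)
        yinf = np.empty(self.n_state)
        tau = np.empty(self.n_state)
        self.step(state, self.params, float(dt), float(istim), d, yinf, tau)
        if not math.isfinite(state[0]):
            raise ModelError(f"{self.key}: V_m became non-finite at t = {t:g} ms")
        return state

    def current_snapshot(self, state) -> dict[str, float]:
        """Instantaneous sarcolemmal currents at one state (native units)."""
        out = np.empty(len(self.current_names))
        self.currents_fn(np.asarray(state, dtype=np.float64), self.params, out)
        return dict(zip(self.current_names, out.tolist()))

    # -- compiled protocol kernels (built lazily, memoized per model) --------

    def kernel(self, kind: str):
        if kind not in self._kernels:
            from . import _engine

            builders = {
                "cell": _engine.build_cell_kernel,
                "strand": _engine.build_strand_kernel,
                "patch": _engine.build_patch_kernel,
            }
            self._kernels[kind] = builders[kind](
                self.step, self.currents_fn, self.n_state, len(self.current_names)
            )
        return self._kernels[kind]


# -- registry -----------------------------------------------------------------

_REGISTRY: dict[str, Callable[[], IonicModel]] = {}
_CACHE: dict[str, IonicModel] = {}


def register_model(key: str, builder: Callable[[], IonicModel]) -> None:
    """Register a model builder under ``key`` (e.g. plugin models)."""
    _REGISTRY[key] = builder
    _CACHE.pop(key, None)


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(key: str) -> IonicModel:
    """Look up a model by registry key, e.g. ``"courtemanche"`` or
    ``"nygren-caf"``.  Instances are cached so compiled kernels are shared."""
    if key not in _REGISTRY:
        base, _, suffix = key.rpartition("-")
        if suffix == "caf" and base in _REGISTRY:
            model = apply_caf_remodeling(get_model(base))
            _CACHE[key] = model
            return model
        raise KeyError(
            f"unknown model {key!r}; registered: {', '.join(list_models())}"
        )
    if key not in _CACHE:
        _CACHE[key] = _REGISTRY[key]()
    return _CACHE[key]


# -- chronic-AF electrical remodeling -----------------------------------------

#: Conductance scaling factors representing cAF electrical remodeling:
#: I_to and I_CaL reduced by 65%, I_Kur (I_sus) by 49%, I_K1 increased 110%.
CAF_FACTORS = {"gto": 0.35, "gcal": 0.35, "gkur": 0.51, "gk1": 2.10}


def apply_caf_remodeling(model: IonicModel) -> IonicModel:
    """Return the chronic-AF variant of a control model.

    Scales the model's I_to, I_CaL, I_Kur/I_sus and I_K1 maximal
    conductances by the factors in :data:`CAF_FACTORS` (each model maps
    these roles onto its own parameter names via ``caf_scaling``).  Guarded
    against double application.
    """
    if model.variant != "control":
        raise ModelError(
            f"cAF remodeling already applied to {model.key}; refusing to rescale"
        )
    params = model.params.copy()
    for pname, factor in model.caf_scaling.items():
        i = model.param_names.index(pname)
        params[i] = params[i] * factor
    return replace(model, variant="caf", params=params, _kernels={})
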