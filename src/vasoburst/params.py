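"""Model parameters for the vasopressin-neuron spiking model.

A single neuron is described by :class:`ModelParams`, which collects the
synaptic-input constants, the per-spike increments and half-lives of the
post-spike potentials (HAP, fast DAP, AHP), the intracellular calcium and
dynorphin dynamics, and the calcium-suppressed K+ leak current that generates
phasic bursting.  The five fitted parameter sets ``m1``-``m5`` (each matched
to an in-vivo recorded cell) ship as YAML fixtures under ``vasoburst/data``.

Half-lives (``lambda_*``) are in ms and are converted to time constants via
``tau = lambda / ln 2``; per-step decay multipliers are ``2**(-dt/lambda)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "StoreParams",
    "ParameterError",
    "half_life_to_tau",
    "decay_multiplier",
    "load_params",
    "save_params",
    "PARAM_SET_NAMES",
]

PARAM_SET_NAMES = ("m1", "m2", "m3", "m4", "m5")


class ParameterError(ValueError):
    """Raised when a parameter value violates a model invariant."""


def half_life_to_tau(lambda_x: float) -> float:
    """Convert a half-life (ms) to an exponential time constant (ms).

    ``tau = lambda / ln 2``, so that after ``lambda`` ms a decaying variable
    has halved.
    """
    if lambda_x <= 0:
        raise ParameterError(f"half-life must be positive, got {lambda_x}")
    return lambda_x / math.log(2.0)


def decay_multiplier(lambda_x: float, dt: float = 1.0) -> float:
    """Per-step decay factor ``2**(-dt/lambda)`` for a half-life in ms."""
    if lambda_x <= 0:
        raise ParameterError(f"half-life must be positive, got {lambda_x}")
    return 2.0 ** (-dt / lambda_x)


@dataclass(frozen=True)
class ModelParams:
    """All named constants of the single-neuron model.

    Defaults are the fit to cell v1 (parameter set ``m1``).

    Attributes
    ----------
    I_re : float
        Mean EPSP arrival rate (Hz).
    I_ratio : float
        IPSP rate as a fraction of ``I_re`` (dimensionless).
    e_h, i_h : float
        EPSP / IPSP amplitudes (mV); ``e_h > 0 >= i_h``.
    lambda_syn : float
        PSP half-life (ms).
    k_HAP, lambda_HAP : float
        Hyperpolarising afterpotential increment magnitude (mV) and
        half-life (ms).  The HAP is stored as a negative contribution, so a
        spike adds ``-k_HAP`` mV.
    k_DAP, lambda_DAP : float
        Fast depolarising afterpotential increment (mV) and half-life (ms).
    k_AHP, lambda_AHP : float
        AHP activation factor (mV/nM) and half-life (ms).  The per-spike AHP
        increment is ``-k_AHP * max(0, C - C_AHP)``, so only fast spiking
        (calcium above ``C_AHP``) substantially activates the AHP.
    C_AHP : float
        Minimum intracellular calcium to activate the AHP (nM).
    C_rest : float
        Resting intracellular calcium (nM); calcium relaxes toward this.
    k_C, lambda_C : float
        Calcium increment per spike (nM) and half-life (ms).
    k_D, lambda_D : float
        Dynorphin increment per spike (a.u.) and half-life (ms).
    k_L : float
        Calcium sensitivity of the K+ leak activation sigmoid (nM).
    g_L : float
        Maximum hyperpolarising leak voltage (mV); 0 disables bursting.
    V_rest, V_thresh : float
        Resting and spike-threshold potentials (mV).
    refractory_ms : float
        Absolute refractory period (ms).
    dt : float
        Integration step (ms); the model is defined at 1 ms.
    """

    I_re: float = 600.0
    I_ratio: float = 1.0
    e_h: float = 2.0
    i_h: float = -2.0
    lambda_syn: float = 7.5
    k_HAP: float = 60.0
    lambda_HAP: float = 8.0
    k_DAP: float = 0.0
    lambda_DAP: float = 150.0
    k_AHP: float = 0.00012
    lambda_AHP: float = 10000.0
    C_AHP: float = 200.0
    C_rest: float = 113.0
    k_C: float = 10.0
    lambda_C: float = 2500.0
    k_D: float = 1.68
    lambda_D: float = 10000.0
    k_L: float = 36.0
    g_L: float = 8.5
    V_rest: float = -56.0
    V_thresh: float = -50.0
    refractory_ms: float = 3.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_syn", "lambda_HAP", "lambda_DAP", "lambda_AHP",
                     "lambda_C", "lambda_D"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (self.e_h > 0 >= self.i_h):
            raise ParameterError("require e_h > 0 >= i_h")
        if self.V_rest >= self.V_thresh:
            raise ParameterError("require V_rest < V_thresh")
        if self.g_L < 0:
            raise ParameterError("g_L must be >= 0")
        if self.I_re < 0:
            raise ParameterError("I_re must be >= 0")
        if self.I_ratio < 0:
            raise ParameterError("I_ratio must be >= 0")
        if self.k_L <= 0:
            raise ParameterError("k_L must be positive")
        if self.refractory_ms < 0:
            raise ParameterError("refractory_ms must be >= 0")
        if self.dt != 1.0:
            raise ParameterError("the model is defined at dt = 1 ms")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # Ordering of the packed parameter vector consumed by the numba kernel.
    _VECTOR_FIELDS = (
        "I_re", "I_ratio", "e_h", "i_h", "lambda_syn",
        "k_HAP", "lambda_HAP", "k_DAP", "lambda_DAP",
        "k_AHP", "lambda_AHP", "C_AHP", "C_rest", "k_C", "lambda_C",
        "k_D", "lambda_D", "k_L", "g_L", "V_rest", "V_thresh",
        "refractory_ms",
    )

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._VECTOR_FIELDS],
                        dtype=np.float64)


@dataclass(frozen=True)
class StoreParams:
    """Readily-releasable dynorphin store extension.

    Replaces the fixed per-spike dynorphin increment with release gated by a
    store that is replenished at a rate set by a slow activity signal ``T``
    (interpreted as dendritic vesicle translocation).  Defaults reproduce the
    hypertonic-injection experiment.

    ``k_T`` (a.u./spike) and ``lambda_T`` (ms) drive ``T``;
    ``k_Dstore`` (a.u./ms per unit T) and ``lambda_Dstore`` (ms) drive the
    store; a spike releases one quantum ``D_spike`` (a.u.) only while the
    store exceeds that quantum, and the store is capped at ``D_storecap``.
    """

    k_T: float = 0.00001
    lambda_T: float = 500000.0
    k_Dstore: float = 0.02
    lambda_Dstore: float = 1000000.0
    D_spike: float = 0.1
    D_storecap: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k_T", "lambda_T", "k_Dstore", "lambda_Dstore",
                     "D_spike", "D_storecap"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.D_spike >= self.D_storecap:
            raise ParameterError("require D_spike < D_storecap")

    def to_vector(self) -> np.ndarray:
        return np.array([self.k_T, self.lambda_T, self.k_Dstore,
                         self.lambda_Dstore, self.D_spike, self.D_storecap],
                        dtype=np.float64)


def _fixture_path(name: str):
    return resources.files("vasoburst").joinpath("data", f"{name}.yaml")


def load_params(source: str | Path) -> ModelParams:
    """Load a parameter set by fitted-cell name (``m1``..``m5``) or file path.

    YAML files contain a flat mapping of field name to value; omitted fields
    take the cell-v1 defaults.
    """
    name = str(source)
    if name in PARAM_SET_NAMES:
        text = _fixture_path(name).read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise ParameterError(
                f"unknown parameter set {source!r}: not one of "
                f"{PARAM_SET_NAMES} and no such file")
        text = path.read_text()
    data = yaml.safe_load(text) or {}
    unknown = set(data) - {f.name for f in dataclasses.fields(ModelParams)}
    if unknown:
        raise ParameterError(f"unknown parameter fields: {sorted(unknown)}")
    return ModelParams(**data)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as a YAML mapping."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
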