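"""Stochastic synaptic drive and the osmotic-pressure input model.

Synaptic input arrives as twin Poisson processes: at each 1-ms step the
numbers of EPSPs and IPSPs are Poisson counts with means ``I_re/1000`` and
``I_ratio * I_re / 1000``.  Each PSP perturbs the synaptic membrane component
by a fixed amplitude (``e_h`` or ``i_h``); the summed component decays
exponentially with half-life ``lambda_syn``.

Experimental protocols are described by a :class:`RateSignal` — a piecewise-
constant EPSP rate over time plus optional transient pulses — or by an
osmotic-pressure trajectory that is mapped linearly to input rate
(``I_re = 20 * (O - 280)``, so the physiological 1-8 spikes/s output range
corresponds to ~290-320 mOsmol/l).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, ParameterError, half_life_to_tau

__all__ = [
    "RateSignal",
    "OsmoticState",
    "draw_psp_counts",
    "psp_drive",
    "osmotic_step",
    "osmotic_to_rate",
    "osmotic_rate_array",
]

#: Slope (Hz per mOsmol/l) and offset (mOsmol/l) of the osmotic rate map.
OSMOTIC_SLOPE = 20.0
OSMOTIC_OFFSET = 280.0


@dataclass(frozen=True)
class RateSignal:
    """Piecewise-constant synaptic input rate with optional pulses.

    ``segments`` are ``(start_ms, end_ms, rate_hz)`` triples that must be
    non-overlapping; times not covered by any segment use ``default_rate``.
    ``pulses`` are ``(start_ms, duration_ms, rate_hz)`` triples that override
    the background rate for their duration (e.g. the 1-s pulse-response
    probes).
    """

    segments: tuple = ()
    pulses: tuple = ()
    default_rate: float = 0.0

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(r)) for a, b, r in self.segments)
        object.__setattr__(self, "segments", segs)
        pls = tuple((float(a), float(d), float(r)) for a, d, r in self.pulses)
        object.__setattr__(self, "pulses", pls)
        for a, b, r in segs:
            if b <= a:
                raise ParameterError(f"empty rate segment ({a}, {b})")
            if r < 0:
                raise ParameterError("rates must be >= 0")
        for a, d, r in pls:
            if d <= 0 or r < 0:
                raise ParameterError("pulses need duration > 0 and rate >= 0")
        ordered = sorted(segs)
        for (a1, b1, _), (a2, _, _) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise ParameterError("rate segments overlap")

    @classmethod
    def constant(cls, rate_hz: float) -> "RateSignal":
        return cls(default_rate=rate_hz)

    def rates_per_ms(self, duration_ms: int) -> np.ndarray:
        """EPSP rate (Hz) for each 1-ms step of the simulation window."""
        rates = np.full(int(duration_ms), float(self.default_rate))
        for a, b, r in self.segments:
            rates[int(a):int(b)] = r
        for a, d, r in self.pulses:
            rates[int(a):int(a + d)] = r
        return rates


def draw_psp_counts(I_re, I_ratio, rng_e: np.random.Generator,
                    rng_i: np.random.Generator, n_steps: int | None = None):
    """Draw per-step EPSP and IPSP counts from independent Poisson streams.

    ``I_re`` may be a scalar rate (Hz, with ``n_steps`` giving the length) or
    a per-ms rate array.  Counts have means ``I_re/1000`` and
    ``I_ratio * I_re/1000`` per 1-ms step.
    """
    rate = np.asarray(I_re, dtype=np.float64)
    if np.any(rate < 0):
        raise ParameterError("synaptic input rate must be >= 0")
    if rate.ndim == 0:
        if n_steps is None:
            raise ParameterError("n_steps required with a scalar rate")
        lam_e = np.full(int(n_steps), rate / 1000.0)
    else:
        lam_e = rate / 1000.0
    if I_ratio < 0:
        raise ParameterError("I_ratio must be >= 0")
    e_n = rng_e.poisson(lam_e)
    i_n = rng_i.poisson(I_ratio * lam_e)
    return e_n, i_n


def psp_drive(e_n, i_n, params: ModelParams):
    """Voltage increment (mV) delivered to ``V_syn`` by the given PSP counts."""
    return np.asarray(e_n) * params.e_h + np.asarray(i_n) * params.i_h


@dataclass
class OsmoticState:
    """Osmotic pressure relaxing toward an injection target.

    ``O`` shifts toward ``O_inject`` with time constant ``tau_O`` (ms),
    modelling the delayed systemic effect of an intraperitoneal hypertonic
    saline injection.
    """

    O: float = 295.0
    O_inject: float = 295.0
    tau_O: float = 200000.0

    def __post_init__(self):
        if self.tau_O <= 0:
            raise ParameterError("tau_O must be positive")


def osmotic_step(state: OsmoticState, dt: float = 1.0) -> OsmoticState:
    """Advance the osmotic pressure one step of ``dt`` ms.

    Exact exponential relaxation: the gap to ``O_inject`` shrinks by
    ``exp(-dt/tau_O)`` per step, so ``O = O_inject`` is a fixed point.
    """
    decay = np.exp(-dt / state.tau_O)
    new_O = state.O_inject + (state.O - state.O_inject) * decay
    return OsmoticState(O=new_O, O_inject=state.O_inject, tau_O=state.tau_O)


def osmotic_to_rate(O) -> np.ndarray | float:
    """Map osmotic pressure (mOsmol/l) to EPSP rate ``I_re`` (Hz).

    Linear map ``I_re = 20 * (O - 280)``; pressures below 280 are clamped to
    zero rate (the linear relation is never evaluated there physiologically)
    with a warning.
    """
    O_arr = np.asarray(O, dtype=np.float64)
    rate = OSMOTIC_SLOPE * (O_arr - OSMOTIC_OFFSET)
    if np.any(rate < 0):
        warnings.warn("osmotic pressure below 280 mOsmol/l: input rate "
                      "clamped to 0", stacklevel=2)
        rate = np.clip(rate, 0.0, None)
    return float(rate) if np.ndim(O) == 0 else rate


def osmotic_rate_array(duration_ms: int, O_start: float, O_inject: float,
                       inject_ms: float, tau_O: float = 200000.0):
    """Per-ms input rate for a hypertonic-injection protocol.

    The pressure holds at ``O_start`` until ``inject_ms``, then relaxes
    exponentially toward ``O_inject`` with time constant ``tau_O``.  Returns
    ``(rates_hz, pressures)`` arrays of length ``duration_ms``.
    """
    t = np.arange(int(duration_ms), dtype=np.float64)
    O = np.full(int(duration_ms), float(O_start))
    after = t >= inject_ms
    O[after] = O_inject + (O_start - O_inject) * np.exp(
        -(t[after] - inject_ms) / tau_O)
    return osmotic_to_rate(O), O
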