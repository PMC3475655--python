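"""Single-neuron integrate-and-fire stepper with emergent phasic bursting.

The membrane potential is assembled each 1-ms step as a plain sum

    V = V_rest + V_syn + HAP + DAP + AHP + V_L

where ``V_syn`` is the decaying sum of Poisson-timed PSPs, HAP/DAP/AHP are
exponentially decaying post-spike potentials (HAP and AHP stored with
hyperpolarising, negative sign), and ``V_L`` is the K+ leak contribution.
The leak activation is sigmoidal in the balance of intracellular calcium
(above rest) against dynorphin,

    L   = 1 - tanh((C - C_rest - D) / k_L)
    V_L = -g_L * L

so ``L`` runs over the sigmoid's range (0, 2) and is half-maximal (``L = 1``,
``V_L = -g_L``) at rest.  Rising calcium suppresses the hyperpolarising leak
(the slow DAP) while accumulating dynorphin restores it, terminating bursts
and driving silences of sustained hyperpolarisation (``V_L`` approaching
``-2 g_L``).  A spike is fired when ``V``
crosses ``V_thresh`` outside the 3-ms absolute refractory period; its
waveform is not modelled.  Spike increments take effect from the next step.

Within a step the update order is fixed: decay all variables -> add PSP
input -> recompute L, V_L, V -> threshold test -> apply spike increments.
Decay uses the exact per-step multiplier ``2**(-dt/lambda)`` so the
half-life law holds to machine precision.  Forced (antidromic) spikes bypass
both the threshold and the refractory test but reset the refractory clock
and trigger every spike-dependent increment.

The optional dynorphin-store extension gates the per-spike dynorphin
increment on a readily-releasable store replenished by a slow activity
signal ``T`` (see :class:`vasoburst.params.StoreParams`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParams, StoreParams
from .synaptic import RateSignal, draw_psp_counts

__all__ = [
    "SpikeTrain",
    "SimResult",
    "SimulationError",
    "resting_state",
    "compute_leak",
    "apply_spike",
    "step",
    "simulate",
    "STATE_FIELDS",
    "TRACE_COLUMNS",
]

#: Ordering of the packed state vector.
STATE_FIELDS = ("V_syn", "HAP", "DAP", "AHP", "C", "D", "T", "D_store",
                "t_last_spike")

TRACE_COLUMNS = ("t_ms", "V", "V_syn", "HAP", "DAP", "AHP", "C", "D", "L",
                 "V_L")

_NO_SPIKE = -1.0e12


class SimulationError(RuntimeError):
    """Raised when the neuron state becomes non-finite."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one cell over a simulated duration."""

    times: np.ndarray
    duration_ms: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0
                       or t[-1] > self.duration_ms):
            raise ValueError("spike times must be strictly increasing and "
                             "within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        """Overall firing rate in spikes/s."""
        if self.duration_ms <= 0:
            return 0.0
        return self.n_spikes / (self.duration_ms / 1000.0)

    def isis(self) -> np.ndarray:
        """Interspike intervals (ms)."""
        return np.diff(self.times)


@dataclass
class SimResult:
    """Simulation output: the spike train, final state, optional trace."""

    train: SpikeTrain
    final_state: np.ndarray
    trace: np.ndarray | None = None  # rows follow TRACE_COLUMNS


def resting_state(params: ModelParams) -> np.ndarray:
    """State of a neuron that has never fired: all potentials at zero,
    calcium at rest, no dynorphin, empty store."""
    s = np.zeros(len(STATE_FIELDS), dtype=np.float64)
    s[STATE_FIELDS.index("C")] = params.C_rest
    s[STATE_FIELDS.index("t_last_spike")] = _NO_SPIKE
    return s


def compute_leak(C: float, D: float, params: ModelParams):
    """Leak activation ``L`` and leak voltage ``V_L`` (mV) for given calcium
    and dynorphin levels.

    ``L`` is the sigmoidal activation of the hyperpolarising K+ leak
    current: half-maximal (``L = 1``) when the calcium excess over rest
    equals the dynorphin level, driven toward 0 (leak suppressed, the burst
    plateau) by calcium and toward its maximum of 2 (full hyperpolarisation,
    silence) by dynorphin.  ``g_L`` scales the leak voltage, which equals
    ``-g_L`` at rest.
    """
    x = (C - params.C_rest - D) / params.k_L
    L = 1.0 - np.tanh(x)
    return L, -params.g_L * L


def apply_spike(state: np.ndarray, params: ModelParams,
                store: StoreParams | None = None) -> np.ndarray:
    """Apply all per-spike increments to a copy of ``state``.

    HAP and AHP are decremented (hyperpolarising), DAP incremented, calcium
    incremented by ``k_C``; the AHP increment is gated and scaled by the
    calcium excess over ``C_AHP``, with calcium's own spike increment applied
    first, so only fast spiking substantially activates the AHP.  Dynorphin
    is incremented by ``k_D`` directly, or — with the store extension — only
    when the releasable store holds at least one quantum, which is then
    depleted.
    """
    s = np.array(state, dtype=np.float64)
    i = {f: k for k, f in enumerate(STATE_FIELDS)}
    C = s[i["C"]] + params.k_C
    if C > params.C_AHP:
        s[i["AHP"]] -= params.k_AHP * (C - params.C_AHP)
    s[i["HAP"]] -= params.k_HAP
    s[i["DAP"]] += params.k_DAP
    s[i["C"]] = C
    if store is None:
        s[i["D"]] += params.k_D
    else:
        s[i["T"]] += store.k_T
        if s[i["D_store"]] > store.D_spike:
            s[i["D"]] += params.k_D
            s[i["D_store"]] -= store.D_spike
    return s


@njit(cache=True)
def _run(p, e_counts, i_counts, forced, state0, store_on, sp, trace_every,
         t0):
    n = e_counts.shape[0]
    # unpack parameters (see ModelParams._VECTOR_FIELDS)
    e_h, i_h = p[2], p[3]
    m_syn = 2.0 ** (-1.0 / p[4])
    k_HAP = p[5]
    m_hap = 2.0 ** (-1.0 / p[6])
    k_DAP = p[7]
    m_dap = 2.0 ** (-1.0 / p[8])
    k_AHP = p[9]
    m_ahp = 2.0 ** (-1.0 / p[10])
    C_AHP = p[11]
    C_rest = p[12]
    k_C = p[13]
    m_c = 2.0 ** (-1.0 / p[14])
    k_D = p[15]
    m_d = 2.0 ** (-1.0 / p[16])
    k_L = p[17]
    g_L = p[18]
    V_rest = p[19]
    V_thresh = p[20]
    refrac = p[21]
    # store extension
    k_T = sp[0]
    m_T = 2.0 ** (-1.0 / sp[1])
    k_Dst = sp[2]
    m_Dst = 2.0 ** (-1.0 / sp[3])
    D_spike = sp[4]
    D_cap = sp[5]

    V_syn = state0[0]
    HAP = state0[1]
    DAP = state0[2]
    AHP = state0[3]
    C = state0[4]
    D = state0[5]
    T = state0[6]
    Dst = state0[7]
    t_last = state0[8]

    spikes = np.empty(n, dtype=np.float64)
    nspk = 0
    n_trace = (n + trace_every - 1) // trace_every if trace_every > 0 else 0
    trace = np.empty((n_trace, 10), dtype=np.float64)
    itr = 0
    err_t = -1

    for k in range(n):
        t = t0 + k
        # 1. exact exponential decay of every dynamic variable
        V_syn *= m_syn
        HAP *= m_hap
        DAP *= m_dap
        AHP *= m_ahp
        C = C_rest + (C - C_rest) * m_c
        D *= m_d
        if store_on:
            T *= m_T
            Dst *= m_Dst
            if Dst < D_cap:
                Dst += k_Dst * T
                if Dst > D_cap:
                    Dst = D_cap
        # 2. synaptic input
        V_syn += e_counts[k] * e_h + i_counts[k] * i_h
        # 3. leak and membrane potential
        L = 1.0 - np.tanh((C - C_rest - D) / k_L)
        V_L = -g_L * L
        V = V_rest + V_syn + HAP + DAP + AHP + V_L
        if not np.isfinite(V):
            err_t = k
            break
        if trace_every > 0 and k % trace_every == 0:
            trace[itr, 0] = t
            trace[itr, 1] = V
            trace[itr, 2] = V_syn
            trace[itr, 3] = HAP
            trace[itr, 4] = DAP
            trace[itr, 5] = AHP
            trace[itr, 6] = C
            trace[itr, 7] = D
            trace[itr, 8] = L
            trace[itr, 9] = V_L
            itr += 1
        # 4. threshold test (forced spikes bypass threshold and refractoriness)
        fire = False
        if forced[k] != 0:
            fire = True
        elif V > V_thresh and (t - t_last) >= refrac:
            fire = True
        # 5. spike increments, effective from the next step
        if fire:
            C += k_C
            if C > C_AHP:
                AHP -= k_AHP * (C - C_AHP)
            HAP -= k_HAP
            DAP += k_DAP
            if store_on:
                T += k_T
                if Dst > D_spike:
                    D += k_D
                    Dst -= D_spike
            else:
                D += k_D
            t_last = t
            spikes[nspk] = t
            nspk += 1

    final = np.empty(9, dtype=np.float64)
    final[0] = V_syn
    final[1] = HAP
    final[2] = DAP
    final[3] = AHP
    final[4] = C
    final[5] = D
    final[6] = T
    final[7] = Dst
    final[8] = t_last
    return spikes[:nspk], final, trace[:itr], err_t


_DUMMY_STORE = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0])


def step(state: np.ndarray, params: ModelParams, psp_input: float,
         forced_spike: bool = False, *, store: StoreParams | None = None,
         t: float = 0.0):
    """Advance one 1-ms step given a precomputed PSP voltage increment.

    Returns ``(new_state, spiked)``.  This is a convenience single-step entry
    to the production kernel (the PSP increment is injected as one
    equivalent EPSP count with amplitude ``psp_input``).
    """
    p = params.to_vector().copy()
    p[2] = psp_input  # one "EPSP" carrying the whole increment
    e = np.ones(1, dtype=np.int64)
    i = np.zeros(1, dtype=np.int64)
    forced = np.array([1 if forced_spike else 0], dtype=np.uint8)
    sp = store.to_vector() if store is not None else _DUMMY_STORE
    spikes, final, _, err = _run(p, e, i, forced, np.asarray(state, float),
                                 store is not None, sp, 0, t)
    if err >= 0:
        raise SimulationError(f"non-finite membrane potential at step {err}")
    return final, spikes.size > 0


def _forced_array(n_steps: int, forced_ms) -> np.ndarray:
    forced = np.zeros(n_steps, dtype=np.uint8)
    if forced_ms is not None:
        idx = np.asarray(np.floor(np.asarray(forced_ms, float)), dtype=np.int64)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        forced[idx] = 1
    return forced


def simulate(params: ModelParams, duration_ms: float, *,
             rate=None, seed=None, forced_ms=None,
             store: StoreParams | None = None,
             initial_state: np.ndarray | None = None,
             trace_every: int = 0, t0: float = 0.0) -> SimResult:
    """Simulate one neuron for ``duration_ms`` at 1-ms resolution.

    Parameters
    ----------
    rate
        Synaptic drive: ``None`` uses the constant ``params.I_re``; a scalar
        is a constant rate (Hz); a :class:`RateSignal` or per-ms array gives
        a time-varying protocol.
    seed
        Integer seed or :class:`numpy.random.SeedSequence`.  Two child
        streams (EPSP, IPSP) are spawned from it, so identical seeds give
        bit-identical runs and paired interventions share input noise.
    forced_ms
        Times (ms, relative to the start of this run) of forced antidromic
        spikes.
    store
        Enable the readily-releasable dynorphin store extension.
    initial_state, t0
        Continue from a previous :class:`SimResult` (``final_state``) and
        absolute start time; defaults to the never-fired resting state.
    trace_every
        If > 0, sample the state every ``trace_every`` ms into
        ``SimResult.trace`` (columns :data:`TRACE_COLUMNS`).
    """
    n = int(round(duration_ms))
    if n < 0:
        raise ValueError("duration must be >= 0")
    if n == 0:
        return SimResult(SpikeTrain(np.empty(0), 0.0),
                         resting_state(params) if initial_state is None
                         else np.array(initial_state, float))
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    ss_e, ss_i = ss.spawn(2)
    rng_e = np.random.Generator(np.random.PCG64(ss_e))
    rng_i = np.random.Generator(np.random.PCG64(ss_i))

    if rate is None:
        rate = params.I_re
    if isinstance(rate, RateSignal):
        rate = rate.rates_per_ms(n)
    e_n, i_n = draw_psp_counts(rate, params.I_ratio, rng_e, rng_i, n_steps=n)

    state0 = (resting_state(params) if initial_state is None
              else np.asarray(initial_state, dtype=np.float64))
    sp = store.to_vector() if store is not None else _DUMMY_STORE
    spikes, final, trace, err = _run(
        params.to_vector(), e_n.astype(np.int64), i_n.astype(np.int64),
        _forced_array(n, forced_ms), state0, store is not None, sp,
        int(trace_every), float(t0))
    if err >= 0:
        raise SimulationError(f"non-finite membrane potential at step {err}")
    train = SpikeTrain(spikes - t0, float(n))
    return SimResult(train, final, trace if trace_every > 0 else None)
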