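"""Heterogeneous populations and the in-silico experiment protocols.

Vasopressin cells have no synaptic interconnections and fire asynchronously,
so a population is simulated as independent model neurons sharing a common
input-rate signal but with independently generated PSP noise; the population
output is the summed spike activity.  Cell-to-cell heterogeneity is emulated
by drawing the eight fitting parameters from normal distributions
(:data:`HETEROGENEITY_TABLE` holds the published means and SDs around the
cell-v1 fit).

Protocols implemented here: antidromic stimulation schedules (forced spikes
that trigger or terminate bursts), the input-rate ramp (bursts lengthen and
silences shorten with input), hypertonic-injection with the dynorphin-store
extension (delayed onset of phasic firing), the dynorphin-antagonist
simulation (k_D reduced by a fraction in every cell, paired on identical
input noise), and transient pulse-response probes.

Seeding: a master seed expands to per-cell integer seeds via
``SeedSequence(master).generate_state(n)``; cell ``i`` then uses
``SeedSequence(cell_seed_i)``, from which the simulator spawns its EPSP and
IPSP streams.  Paired control/intervention runs reuse the same per-cell
seeds, so both conditions see bit-identical synaptic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .analysis import BurstSet, burst_summary, detect_bursts
from .model import SimResult, SpikeTrain, simulate
from .params import ModelParams, ParameterError, StoreParams
from .synaptic import RateSignal, osmotic_rate_array

__all__ = [
    "HeterogeneitySpec",
    "HETEROGENEITY_TABLE",
    "PopulationResult",
    "sample_population",
    "simulate_population",
    "antidromic_schedule",
    "input_ramp_experiment",
    "ramp_trends",
    "norbni_experiment",
    "pulse_experiment",
    "hypertonic_experiment",
]

#: Published heterogeneity of the eight fitting parameters around the
#: cell-v1 base: {parameter: (mean, sd)}.
HETEROGENEITY_TABLE = {
    "I_re": (600.0, 0.0),
    "lambda_HAP": (9.0, 1.0),
    "k_DAP": (0.50, 0.25),
    "k_AHP": (0.00012, 0.00004),
    "k_C": (11.0, 1.0),
    "k_D": (2.7, 0.3),
    "lambda_D": (7500.0, 0.0),
    "g_L": (8.5, 1.0),
}

#: Parameters that heterogeneity specs may vary.
_VARIABLE = ("I_re", "lambda_HAP", "k_DAP", "k_AHP", "k_C", "k_D",
             "lambda_D", "g_L")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Normal per-parameter variation: mapping parameter -> (mean, sd)."""

    entries: dict

    def __post_init__(self):
        for name, (mean, sd) in self.entries.items():
            if name not in _VARIABLE:
                raise ParameterError(
                    f"{name!r} is not a heterogeneity parameter "
                    f"(allowed: {_VARIABLE})")
            if sd < 0:
                raise ParameterError(f"SD for {name} must be >= 0")

    @classmethod
    def published(cls) -> "HeterogeneitySpec":
        return cls(dict(HETEROGENEITY_TABLE))


def _valid_draw(name: str, value: float) -> bool:
    if name.startswith("lambda"):
        return value > 0
    return value >= 0


def sample_population(base: ModelParams, spec: HeterogeneitySpec, n: int,
                      seed=None, max_resamples: int = 100) -> list[ModelParams]:
    """Draw ``n`` parameter sets with normal variation around ``base``.

    Each varied parameter is drawn independently; draws violating the
    parameter invariants (negative rates or increments, non-positive
    half-lives) are redrawn, up to ``max_resamples`` attempts.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ParameterError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n):
        overrides = {}
        for name, (mean, sd) in spec.entries.items():
            if sd == 0:
                overrides[name] = float(mean)
                continue
            for attempt in range(max_resamples):
                v = rng.normal(mean, sd)
                if _valid_draw(name, v):
                    overrides[name] = float(v)
                    break
            else:
                raise ParameterError(
                    f"could not draw a valid value for {name} after "
                    f"{max_resamples} attempts")
        cells.append(base.replace(**overrides))
    return cells


@dataclass
class PopulationResult:
    """Per-cell spike trains plus the summed population rate."""

    trains: list
    summed_rate: np.ndarray  # spikes/s per 1-s bin, summed over cells
    duration_ms: float

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    @property
    def mean_rate(self) -> float:
        """Population mean firing rate: total spikes / (n_cells * duration)."""
        total = sum(t.n_spikes for t in self.trains)
        return total / (self.n_cells * self.duration_ms / 1000.0)


def _cell_seed_sequences(master_seed, n: int):
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    return [np.random.SeedSequence(int(s)) for s in ss.generate_state(n)]


def simulate_population(paramlist, duration_ms: float, *, rate=None,
                        master_seed=None, store: StoreParams | None = None,
                        ) -> PopulationResult:
    """Run every cell for ``duration_ms`` with shared rate and independent
    noise; returns the trains and the summed 1-s-binned population rate."""
    n_bins = int(np.ceil(duration_ms / 1000.0))
    summed = np.zeros(n_bins)
    trains = []
    for params, ss in zip(paramlist,
                          _cell_seed_sequences(master_seed, len(paramlist))):
        res = simulate(params, duration_ms, rate=rate, seed=ss, store=store)
        trains.append(res.train)
        counts, _ = np.histogram(res.train.times,
                                 bins=np.arange(n_bins + 1) * 1000.0)
        summed += counts
    return PopulationResult(trains, summed, float(duration_ms))


def antidromic_schedule(freq_hz: float, start_ms: float,
                        duration_ms: float) -> np.ndarray:
    """Evenly spaced forced-spike times emulating antidromic stimulation.

    ``round(freq * duration / 1000)`` spikes at ``1000/freq`` ms spacing
    starting at ``start_ms``.
    """
    if freq_hz <= 0:
        raise ParameterError("stimulation frequency must be positive")
    count = int(round(freq_hz * duration_ms / 1000.0))
    return start_ms + np.arange(count) * (1000.0 / freq_hz)


def input_ramp_experiment(params: ModelParams, rates, duration_ms: float,
                          seed=None) -> pd.DataFrame:
    """Burst measures across increasing constant input rates.

    Runs a fresh simulation per rate level (no carry-over state, avoiding
    hysteresis confounds) and returns one row per level with the burst
    summary plus the overall mean rate.  Spearman trend statistics can be
    computed with :func:`ramp_trends`.
    """
    rates = list(rates)
    if any(b < a for a, b in zip(rates, rates[1:])):
        raise ParameterError("rates must be non-decreasing")
    rows = []
    for level, r in enumerate(rates):
        ss = np.random.SeedSequence((0 if seed is None else seed, level))
        res = simulate(params.replace(I_re=float(r)), duration_ms, seed=ss)
        row = {"I_re": float(r), "mean_rate_hz": res.train.mean_rate}
        row.update(burst_summary(detect_bursts(res.train)))
        rows.append(row)
    return pd.DataFrame(rows)


def ramp_trends(ramp: pd.DataFrame) -> dict:
    """Spearman rank correlations of burst measures against input rate,
    over the levels where bursts were detected."""
    d = ramp[ramp["n_bursts"] > 0]
    out = {}
    for col, key in (("burst_mean_s", "burst"), ("silence_mean_s", "silence"),
                     ("intra_rate_hz", "intra")):
        v = d.dropna(subset=[col])
        out[key] = (float(sstats.spearmanr(v["I_re"], v[col]).statistic)
                    if len(v) >= 3 else np.nan)
    return out


def norbni_experiment(base: ModelParams | None = None,
                      spec: HeterogeneitySpec | None = None, n: int = 100,
                      duration_ms: float = 3_000_000.0,
                      kD_fraction: float = 0.85, seed=None) -> dict:
    """Simulate a competitive dynorphin antagonist on a heterogeneous
    population.

    Samples ``n`` cells, runs each for ``duration_ms`` twice on identical
    input noise — control and with ``k_D`` scaled by ``kD_fraction`` — and
    pools burst and silence durations.  Returns a dict with per-condition
    burst counts, pooled duration arrays, and summary means.
    """
    if not 0 < kD_fraction <= 1:
        raise ParameterError("kD_fraction must be in (0, 1]")
    if base is None:
        base = ModelParams()
    if spec is None:
        spec = HeterogeneitySpec.published()
    ss = np.random.SeedSequence(seed)
    pop_seed, noise_seed = ss.spawn(2)
    cells = sample_population(base, spec, n, seed=pop_seed)
    cell_seeds = _cell_seed_sequences(noise_seed, n)
    out = {}
    for label, frac in (("control", 1.0), ("norbni", kD_fraction)):
        bursts, silences = [], []
        count = 0
        for params, cseed in zip(cells, cell_seeds):
            # re-derive the same entropy so both conditions share input noise
            p = params.replace(k_D=params.k_D * frac)
            res = simulate(p, duration_ms,
                           seed=np.random.SeedSequence(cseed.entropy))
            bs = detect_bursts(res.train)
            count += bs.n_bursts
            bursts.append(bs.bursts["duration_s"].to_numpy())
            silences.append(bs.silences_s)
        out[label] = {
            "n_bursts": count,
            "burst_durations_s": np.concatenate(bursts) if bursts else np.empty(0),
            "silence_durations_s": (np.concatenate(silences) if silences
                                    else np.empty(0)),
        }
        out[label]["burst_mean_s"] = (float(out[label]["burst_durations_s"].mean())
                                      if count else np.nan)
        out[label]["silence_mean_s"] = (
            float(out[label]["silence_durations_s"].mean())
            if out[label]["silence_durations_s"].size else np.nan)
    return out


def pulse_experiment(paramlist, base_rate: float, pulse_rate: float,
                     n_pulses: int = 4, pulse_s: float = 1.0,
                     interval_s: float = 100.0, master_seed=None,
                     lead_in_s: float = 50.0) -> dict:
    """Population response to brief input pulses.

    The background rate is ``base_rate``; ``n_pulses`` pulses of
    ``pulse_rate`` lasting ``pulse_s`` are applied at ``interval_s``
    spacing, the first after ``lead_in_s``.  The response is the population
    mean firing rate over the pulse windows (spikes/s per cell); the
    background mean rate outside pulses is returned for reference.
    """
    starts = lead_in_s + np.arange(n_pulses) * interval_s
    duration_ms = (starts[-1] + interval_s / 2) * 1000.0
    signal = RateSignal(
        default_rate=base_rate,
        pulses=tuple((s * 1000.0, pulse_s * 1000.0, pulse_rate)
                     for s in starts))
    pop = simulate_population(paramlist, duration_ms, rate=signal,
                              master_seed=master_seed)
    windows = [(s * 1000.0, (s + pulse_s) * 1000.0) for s in starts]
    in_pulse = 0
    for train in pop.trains:
        t = train.times
        for a, b in windows:
            in_pulse += int(np.count_nonzero((t >= a) & (t < b)))
    pulse_time_s = n_pulses * pulse_s
    total_spikes = sum(t.n_spikes for t in pop.trains)
    bg_spikes = total_spikes - in_pulse
    bg_time_s = duration_ms / 1000.0 - pulse_time_s
    return {
        "pulse_response_hz": in_pulse / (len(pop.trains) * pulse_time_s),
        "background_rate_hz": bg_spikes / (len(pop.trains) * bg_time_s),
        "population": pop,
    }


def hypertonic_experiment(params: ModelParams, store: StoreParams,
                          O_start: float = 295.0, O_inject: float = 315.0,
                          inject_min: float = 5.0, tau_O: float = 200000.0,
                          duration_min: float = 40.0,
                          burn_in_min: float = 15.0, seed=None) -> dict:
    """Hypertonic-saline injection with the dynorphin-store extension.

    The cell is first burned in at the pre-injection input rate (so the
    slow translocation signal and releasable store start at the equilibrium
    of the pre-injection regime), then run through the injection protocol:
    osmotic pressure relaxes from ``O_start`` toward ``O_inject`` with time
    constant ``tau_O`` starting at ``inject_min``.  Returns the spike train,
    the per-ms rate and pressure arrays, and the injection time.
    """
    ss = np.random.SeedSequence(seed)
    ss_burn, ss_run = ss.spawn(2)
    pre_rate, _ = osmotic_rate_array(1, O_start, O_start, 1.0, tau_O)
    burn = simulate(params, burn_in_min * 60_000.0, rate=float(pre_rate[0]),
                    seed=ss_burn, store=store)
    duration_ms = duration_min * 60_000.0
    rates, pressures = osmotic_rate_array(int(duration_ms), O_start, O_inject,
                                          inject_min * 60_000.0, tau_O)
    res = simulate(params, duration_ms, rate=rates, seed=ss_run, store=store,
                   initial_state=burn.final_state)
    return {
        "train": res.train,
        "rates_hz": rates,
        "pressure": pressures,
        "inject_ms": inject_min * 60_000.0,
    }
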