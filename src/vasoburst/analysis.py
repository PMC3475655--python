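"""Spike-pattern statistics: rates, ISI histogram, hazard, burst measures.

A burst is a train of more than 25 spikes with no interspike interval longer
than 1500 ms; silences are the gaps between successive detected bursts
(partial gaps before the first and after the last burst are censored and
excluded).  Burst duration runs first spike to last spike, and the
intra-burst firing rate of a burst with ``n`` spikes and duration ``d`` s is
``(n - 1) / d`` — i.e. intervals per second — averaged across bursts.

Short-term patterning is read from the ISI histogram and its hazard
function (the probability of a spike in a bin given survival to the bin
start).  Beyond ~150 ms the histogram tail of a phasic cell decays as a
single exponential, indicating Poisson-random late spiking; the tail fit is
a least-squares line on log counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SpikeTrain

__all__ = [
    "BurstSet",
    "HazardCurve",
    "detect_bursts",
    "burst_summary",
    "isi_histogram",
    "hazard_curve",
    "fit_isi_tail",
    "burst_profile",
    "binned_rate",
]

#: Burst definition: strictly more than this many spikes ...
MIN_SPIKES = 25
#: ... with no internal interval longer than this (ms).
MAX_ISI_MS = 1500.0


@dataclass(frozen=True)
class BurstSet:
    """Detected bursts and the silences separating them.

    ``bursts`` has one row per burst with columns ``start_ms``, ``end_ms``,
    ``n_spikes``, ``duration_s``, ``rate_hz``; ``silences_s`` holds the
    inter-burst gap durations (one fewer than the bursts).
    """

    bursts: pd.DataFrame
    silences_s: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def spikes_in_bursts(self) -> int:
        return int(self.bursts["n_spikes"].sum()) if self.n_bursts else 0


@dataclass(frozen=True)
class HazardCurve:
    """Per-bin conditional spike probability given survival to the bin."""

    bin_edges: np.ndarray   # ms, len nbins+1
    hazard: np.ndarray      # in [0, 1]; NaN where no intervals were at risk
    at_risk: np.ndarray     # intervals surviving to each bin start


def detect_bursts(train: SpikeTrain, min_spikes: int = MIN_SPIKES,
                  max_isi_ms: float = MAX_ISI_MS) -> BurstSet:
    """Find maximal runs of spikes with all ISIs <= ``max_isi_ms`` and more
    than ``min_spikes`` spikes."""
    t = np.asarray(train.times, dtype=np.float64)
    cols = ("start_ms", "end_ms", "n_spikes", "duration_s", "rate_hz")
    empty = pd.DataFrame({c: [] for c in cols})
    if t.size == 0:
        return BurstSet(empty, np.empty(0))
    # boundaries where the inter-spike gap breaks a run
    breaks = np.flatnonzero(np.diff(t) > max_isi_ms)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))  # inclusive indices
    counts = ends - starts + 1
    keep = counts > min_spikes
    starts, ends, counts = starts[keep], ends[keep], counts[keep]
    if starts.size == 0:
        return BurstSet(empty, np.empty(0))
    start_ms = t[starts]
    end_ms = t[ends]
    duration_s = (end_ms - start_ms) / 1000.0
    with np.errstate(divide="ignore"):
        rate = np.where(duration_s > 0, (counts - 1) / duration_s, np.nan)
    bursts = pd.DataFrame({
        "start_ms": start_ms, "end_ms": end_ms,
        "n_spikes": counts.astype(int),
        "duration_s": duration_s, "rate_hz": rate,
    })
    silences = (start_ms[1:] - end_ms[:-1]) / 1000.0
    return BurstSet(bursts, silences)


def burst_summary(burstset: BurstSet) -> dict:
    """Mean/SD burst measures in the layout of the fitted-cell tables.

    Returns a dict with ``n_bursts``, ``intra_rate_hz`` (mean of per-burst
    ``(spikes-1)/duration``), ``burst_mean_s``/``burst_sd_s`` and
    ``silence_mean_s``/``silence_sd_s`` (NaN when there are no complete
    silences), plus an ``empty`` flag when no bursts were detected.
    """
    b = burstset.bursts
    if len(b) == 0:
        return {"n_bursts": 0, "empty": True,
                "intra_rate_hz": np.nan, "burst_mean_s": np.nan,
                "burst_sd_s": np.nan, "silence_mean_s": np.nan,
                "silence_sd_s": np.nan}
    sil = burstset.silences_s
    return {
        "n_bursts": len(b),
        "empty": False,
        "intra_rate_hz": float(b["rate_hz"].mean()),
        "burst_mean_s": float(b["duration_s"].mean()),
        "burst_sd_s": float(b["duration_s"].std(ddof=0)),
        "silence_mean_s": float(sil.mean()) if sil.size else np.nan,
        "silence_sd_s": float(sil.std(ddof=0)) if sil.size else np.nan,
    }


def isi_histogram(train: SpikeTrain, bin_ms: float = 10.0,
                  max_ms: float = 500.0):
    """Histogram of interspike intervals over [0, max_ms].

    Returns ``(bin_edges, counts)``; intervals beyond ``max_ms`` are ignored.
    """
    if train.n_spikes < 2:
        raise ValueError("need at least two spikes for an ISI histogram")
    edges = np.arange(0.0, max_ms + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(train.isis(), bins=edges)
    return edges, counts


def hazard_curve(train: SpikeTrain, bin_ms: float = 10.0,
                 max_ms: float = 500.0) -> HazardCurve:
    """Post-spike excitability: P(spike in bin | no spike since interval
    start), from the ISI distribution.

    Bins with no intervals at risk have hazard NaN.
    """
    if train.n_spikes < 2:
        raise ValueError("need at least two spikes for a hazard curve")
    isis = train.isis()
    edges = np.arange(0.0, max_ms + bin_ms / 2, bin_ms)
    deaths, _ = np.histogram(isis, bins=edges)
    # intervals still "alive" (no spike yet) at each bin start
    at_risk = isis.size - np.concatenate(([0], np.cumsum(deaths)[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(at_risk > 0, deaths / at_risk, np.nan)
    return HazardCurve(edges, hazard, at_risk)


def fit_isi_tail(edges: np.ndarray, counts: np.ndarray,
                 t_min_ms: float = 150.0):
    """Fit a single decaying exponential ``A * exp(-b t)`` to the histogram
    tail beyond ``t_min_ms``.

    The fit is ordinary least squares on log counts at bin centres
    (zero-count bins dropped), as is standard for exponential ISI tails;
    returns ``(amplitude, decay_per_ms, r_squared)`` with r^2 on the log
    scale.
    """
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts = np.asarray(counts, dtype=np.float64)
    mask = (edges[:-1] >= t_min_ms) & (counts > 0)
    if mask.sum() < 3:
        raise ValueError("need at least 3 nonempty tail bins to fit")
    x = centres[mask]
    y = np.log(counts[mask])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(intercept)), float(-slope), r2


def burst_profile(train: SpikeTrain, burstset: BurstSet,
                  window_s: float = 50.0, bin_s: float = 1.0):
    """Mean firing rate aligned to burst start (head) and burst end (tail).

    Only bursts at least ``window_s`` long qualify.  Returns
    ``(head, tail)`` arrays of length ``window_s / bin_s`` in spikes/s,
    averaged across qualifying bursts; empty arrays if none qualify.
    """
    t = np.asarray(train.times)
    nbins = int(round(window_s / bin_s))
    qual = burstset.bursts[burstset.bursts["duration_s"] >= window_s]
    if len(qual) == 0:
        return np.empty(0), np.empty(0)
    head = np.zeros(nbins)
    tail = np.zeros(nbins)
    for _, b in qual.iterrows():
        # head bins [start + j, start + j+1), tail bins (end - j-1, end - j]
        h_edges = b["start_ms"] + np.arange(nbins + 1) * bin_s * 1000.0
        head += (np.searchsorted(t, h_edges[1:], side="left")
                 - np.searchsorted(t, h_edges[:-1], side="left"))
        t_edges = b["end_ms"] - np.arange(nbins, -1, -1) * bin_s * 1000.0
        tail += (np.searchsorted(t, t_edges[1:], side="right")
                 - np.searchsorted(t, t_edges[:-1], side="right"))
    head /= len(qual) * bin_s
    tail /= len(qual) * bin_s
    return head, tail


def binned_rate(train: SpikeTrain, bin_s: float = 1.0) -> np.ndarray:
    """Spike rate (spikes/s) in consecutive bins covering the recording."""
    nbins = int(np.ceil(train.duration_ms / (bin_s * 1000.0)))
    if nbins == 0:
        return np.empty(0)
    edges = np.arange(nbins + 1) * bin_s * 1000.0
    counts, _ = np.histogram(train.times, bins=edges)
    return counts / bin_s
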