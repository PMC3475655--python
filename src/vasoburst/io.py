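"""Plain-text readers and writers for spike trains, traces and summaries.

Spike trains are one spike time (ms) per line, with ``#``-prefixed header
lines carrying the simulated duration and the seed; state traces and burst
summaries are CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import BurstSet
from .model import SpikeTrain, TRACE_COLUMNS

__all__ = [
    "write_spike_train",
    "read_spike_train",
    "write_trace",
    "write_burst_summary",
    "write_manifest",
]


def write_spike_train(train: SpikeTrain, path, seed=None) -> None:
    """Write a spike train: '#' headers (duration, seed), one ms value/line."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms {train.duration_ms:.10g}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        for t in train.times:
            fh.write(f"{t:.10g}\n")


def read_spike_train(path) -> SpikeTrain:
    """Read a spike-train text file written by :func:`write_spike_train`.

    The duration header is honoured; a file without one takes the last
    spike time as the duration.
    """
    duration = None
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2 and parts[0] == "duration_ms":
                    duration = float(parts[1])
                continue
            times.append(float(line))
    times = np.asarray(times, dtype=np.float64)
    if duration is None:
        duration = float(times[-1]) if times.size else 0.0
    return SpikeTrain(times, duration)


def write_trace(trace: np.ndarray, path) -> None:
    """Write a sampled state trace as CSV with the standard column layout."""
    pd.DataFrame(trace, columns=list(TRACE_COLUMNS)).to_csv(path, index=False)


def write_burst_summary(summary: dict, path) -> None:
    """One-row CSV in the fitted-cell table layout (intra rate, burst
    mean/SD, silence mean/SD)."""
    row = {
        "Intra(Hz)": summary.get("intra_rate_hz"),
        "Burst Mean(s)": summary.get("burst_mean_s"),
        "Burst SD": summary.get("burst_sd_s"),
        "Silence Mean(s)": summary.get("silence_mean_s"),
        "Silence SD": summary.get("silence_sd_s"),
        "n_bursts": summary.get("n_bursts"),
    }
    pd.DataFrame([row]).to_csv(path, index=False)


def write_curve(path, bin_starts, values, value_name: str = "value") -> None:
    """Write a binned curve (histogram or hazard) as (bin_start, value) CSV."""
    pd.DataFrame({"bin_start": np.asarray(bin_starts),
                  value_name: np.asarray(values)}).to_csv(path, index=False)


def write_manifest(path, config: dict, seed, outputs: list) -> None:
    """Record what produced a run directory: config (and its hash), seed,
    package version, output files."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "version": __version__,
        "outputs": [str(o) for o in outputs],
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
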