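"""Optogenetic identification of glomerulus-connected cells.

Cells receiving input from the light-activated glomerulus are found by
comparing inhalation-aligned PSTHs (4 ms bins) with and without the light
pulse: a cell is light-responsive if, within 50 ms of pulse onset, some
bin's light-evoked mean exceeds the no-light mean by at least one
standard deviation, and the latency is the start of the first such bin.
Cells with implausibly long latencies (beyond a fixed 20 ms cutoff, or
beyond the Tukey upper fence Q3 + 1.5*IQR of the latency sample) are
excluded as likely polysynaptic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["Psth", "psth", "classify_light_response", "latency_exclusion"]


@dataclass(frozen=True)
class Psth:
    """Peri-event time histogram: per-bin mean and across-trial SD of counts."""

    bin_edges: np.ndarray  # seconds relative to event, length n_bins + 1
    mean: np.ndarray  # mean count per trial per bin
    sd: np.ndarray  # across-trial sd of counts per bin
    n_trials: int

    def __post_init__(self) -> None:
        nb = len(self.bin_edges) - 1
        if len(self.mean) != nb or len(self.sd) != nb:
            raise ValueError("inconsistent PSTH lengths")
        if np.any(self.mean < 0) or np.any(self.sd < 0):
            raise ValueError("PSTH statistics must be non-negative")


def psth(
    spike_times,
    event_times,
    bin: float = 0.004,
    window: tuple[float, float] = (-0.05, 0.1),
) -> Psth:
    """Event-aligned PSTH with across-trial variability.

    Counts spikes in ``bin``-wide bins relative to each event over
    ``window`` and returns per-bin mean and SD (ddof=1; zero for a single
    trial) across events.
    """
    if bin <= 0:
        raise ValueError("bin width must be positive")
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("no events supplied")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    lo, hi = window
    # anchor bin edges at the event so bins are [0, 4), [4, 8) ... ms
    n_lo = int(np.ceil(-lo / bin - 1e-9))
    n_hi = int(np.ceil(hi / bin - 1e-9))
    edges = bin * np.arange(-n_lo, n_hi + 1)
    n_bins = n_lo + n_hi
    counts = np.empty((events.size, n_bins))
    for i, t0 in enumerate(events):
        counts[i] = np.histogram(spikes - t0, bins=edges)[0]
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if events.size > 1 else np.zeros(n_bins)
    return Psth(bin_edges=edges, mean=mean, sd=sd, n_trials=int(events.size))


def classify_light_response(
    light: Psth,
    control: Psth,
    k_sd: float = 1.0,
    window: float = 0.05,
    pooled_sd: bool = False,
) -> tuple[bool, Optional[float]]:
    """Light-responsiveness and latency from paired PSTHs.

    Responsive iff some bin starting before ``window`` (relative to pulse
    onset at 0) has ``light.mean > control.mean + k_sd * sd``; the
    latency is the start time of the first such bin. By default ``sd`` is
    the control PSTH's across-trial SD; ``pooled_sd=True`` uses the
    root-mean-square of both conditions' SDs instead.
    """
    if not np.allclose(light.bin_edges, control.bin_edges):
        raise ValueError("PSTHs must share bin structure")
    starts = light.bin_edges[:-1]
    sd = control.sd
    if pooled_sd:
        sd = np.sqrt(0.5 * (control.sd**2 + light.sd**2))
    eligible = (starts >= 0) & (starts < window)
    exceed = eligible & (light.mean > control.mean + k_sd * sd)
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return False, None
    return True, float(starts[idx[0]])


def latency_exclusion(
    latencies: Sequence[float],
    mode: str = "fixed_cutoff",
    cutoff: float = 0.020,
) -> tuple[np.ndarray, float]:
    """Indices of cells whose light-response latency is plausibly direct.

    ``fixed_cutoff`` keeps latencies <= ``cutoff`` (default 20 ms);
    ``iqr`` keeps latencies <= the Tukey upper fence ``Q3 + 1.5*IQR``
    (type-7 linear-interpolation quartiles).

    Returns
    -------
    (kept, bound) : (int ndarray, float)
        Kept indices (in input order) and the bound that was applied.
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("empty latency list")
    if mode == "fixed_cutoff":
        bound = cutoff
    elif mode == "iqr":
        q1, q3 = np.quantile(lat, [0.25, 0.75])  # numpy default is type-7
        bound = float(q3 + 1.5 * (q3 - q1))
    else:
        raise ValueError("mode must be 'fixed_cutoff' or 'iqr'")
    kept = np.flatnonzero(lat <= bound)
    return kept, float(bound)
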