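"""Sniff-cycle detection, representation and selection.

A sniff cycle runs from one inhalation onset to the next. The inhalation
duration ``d_inh`` (onset to inhalation offset) is the timescale that
dilates the firing-rate pattern in the snifflet model, so the quantities
carried by :class:`Sniff` are the onset time, the inhalation offset and
the cycle end.

All times are in seconds; cycle intervals are half-open ``[t_onset, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "Sniff",
    "SniffTrain",
    "detect_sniffs",
    "filter_by_inhalation",
    "first_sniff_after",
    "baseline_sniffs",
]


@dataclass(frozen=True)
class Sniff:
    """One respiration cycle.

    Parameters
    ----------
    t_onset : float
        Inhalation onset (seconds).
    t_inh_end : float
        Inhalation offset; ``t_inh_end - t_onset`` is the inhalation
        duration that sets the dilation factor ``alpha = 1/d_inh``.
    t_end : float
        Onset of the next sniff (or end of record); closes the half-open
        cycle interval ``[t_onset, t_end)``.
    """

    t_onset: float
    t_inh_end: float
    t_end: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_onset) and np.isfinite(self.t_inh_end) and np.isfinite(self.t_end)):
            raise ValueError("sniff times must be finite")
        if not (self.t_onset < self.t_inh_end <= self.t_end):
            raise ValueError(
                f"require t_onset < t_inh_end <= t_end, got "
                f"({self.t_onset}, {self.t_inh_end}, {self.t_end})"
            )

    @property
    def d_inh(self) -> float:
        """Inhalation duration in seconds."""
        return self.t_inh_end - self.t_onset

    @property
    def d_sniff(self) -> float:
        """Full cycle duration in seconds."""
        return self.t_end - self.t_onset

    @property
    def alpha(self) -> float:
        """Temporal dilation factor, reciprocal of the inhalation duration."""
        return 1.0 / self.d_inh


@dataclass(frozen=True)
class SniffTrain:
    """Ordered, non-overlapping sequence of sniff cycles."""

    sniffs: tuple[Sniff, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        sniffs = tuple(self.sniffs)
        object.__setattr__(self, "sniffs", sniffs)
        for a, b in zip(sniffs, sniffs[1:]):
            if not a.t_onset < b.t_onset:
                raise ValueError("sniff onsets must be strictly increasing")
            if a.t_end > b.t_onset + 1e-9:
                raise ValueError("sniff intervals must not overlap")

    @property
    def n(self) -> int:
        return len(self.sniffs)

    def __len__(self) -> int:
        return len(self.sniffs)

    def __iter__(self) -> Iterator[Sniff]:
        return iter(self.sniffs)

    def __getitem__(self, i):
        picked = self.sniffs[i]
        if isinstance(i, slice):
            return SniffTrain(picked)
        return picked

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s.t_onset for s in self.sniffs], dtype=float)

    @property
    def d_inh(self) -> np.ndarray:
        return np.array([s.d_inh for s in self.sniffs], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        t_onset: Sequence[float],
        t_inh_end: Sequence[float],
        t_end: Sequence[float],
    ) -> "SniffTrain":
        return cls(tuple(Sniff(a, b, c) for a, b, c in zip(t_onset, t_inh_end, t_end)))


def detect_sniffs(
    pressure: np.ndarray,
    sample_rate: float,
    *,
    lowpass_hz: float = 25.0,
    baseline_window_s: float = 2.0,
    threshold_mads: float = 1.0,
    invert: bool = False,
) -> SniffTrain:
    """Detect sniff cycles from a nasal-pressure trace.

    Inhalation is taken as a contiguous negative-pressure epoch of the
    smoothed, baseline-subtracted signal (set ``invert=True`` for sensors
    with the opposite polarity). The trace is low-pass filtered, a slow
    baseline (running median over ``baseline_window_s``) is subtracted,
    and inhalation epochs are the intervals between a downward crossing of
    ``-k*MAD`` and the signal's return to zero. Each cycle's ``t_end`` is
    the next cycle's onset; the last cycle is closed with the median cycle
    duration.

    Parameters
    ----------
    pressure : array_like
        Uniformly sampled pressure signal.
    sample_rate : float
        Sampling rate in Hz.

    Returns
    -------
    SniffTrain
        Detected cycles; empty if no threshold crossings are found.
    """
    x = np.asarray(pressure, dtype=float).ravel()
    if x.size == 0:
        return SniffTrain(())
    if not np.all(np.isfinite(x)):
        raise ValueError("pressure trace contains non-finite samples")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if invert:
        x = -x

    # smooth: zero-phase Butterworth low-pass (falls back to raw for short traces)
    nyq = sample_rate / 2.0
    if lowpass_hz < nyq and x.size > 15:
        sos = signal.butter(2, lowpass_hz / nyq, output="sos")
        x = signal.sosfiltfilt(sos, x)

    # subtract slow baseline so drift does not bias the zero level
    win = int(round(baseline_window_s * sample_rate))
    if win >= 3:
        win = min(win if win % 2 == 1 else win + 1, x.size if x.size % 2 == 1 else x.size - 1)
        if win >= 3:
            x = x - ndimage.median_filter(x, size=win, mode="nearest")

    mad = np.median(np.abs(x - np.median(x)))
    thresh = -threshold_mads * mad
    if mad == 0 or not np.any(x < thresh):
        return SniffTrain(())

    below = x < thresh
    neg = x < 0.0
    # inhalation onset: where the negative epoch containing a threshold
    # crossing begins (walk back to the zero crossing); offset: return to >= 0
    labels, n_lab = ndimage.label(neg)
    onsets: list[int] = []
    offsets: list[int] = []
    for lab in range(1, n_lab + 1):
        idx = np.flatnonzero(labels == lab)
        if not below[idx].any():
            continue  # shallow dip, never crossed threshold
        onsets.append(idx[0])
        offsets.append(idx[-1] + 1)

    if not onsets:
        return SniffTrain(())

    t_on = np.array(onsets, dtype=float) / sample_rate
    t_off = np.array(offsets, dtype=float) / sample_rate
    t_off = np.minimum(t_off, x.size / sample_rate)

    t_end = np.empty_like(t_on)
    t_end[:-1] = t_on[1:]
    if t_on.size > 1:
        med_dur = float(np.median(np.diff(t_on)))
    else:
        med_dur = max(2.0 * (t_off[0] - t_on[0]), 1.0 / sample_rate)
    t_end[-1] = t_on[-1] + med_dur
    # guard: inhalation must end within its own cycle
    t_off = np.minimum(t_off, t_end)
    ok = t_off > t_on
    return SniffTrain.from_arrays(t_on[ok], t_off[ok], t_end[ok])


def filter_by_inhalation(train: SniffTrain, min_d_inh: float) -> SniffTrain:
    """Keep sniffs with inhalation duration strictly greater than ``min_d_inh``.

    The analyses focus on slow sniffs (inhalation > 100 ms by default
    elsewhere); this is the corresponding selection primitive.
    """
    if min_d_inh < 0:
        raise ValueError("min_d_inh must be >= 0")
    return SniffTrain(tuple(s for s in train if s.d_inh > min_d_inh))


def first_sniff_after(train: SniffTrain, t_event: float) -> Optional[Sniff]:
    """Return the first sniff with onset at or after ``t_event`` (or None)."""
    if not np.isfinite(t_event):
        raise ValueError("t_event must be finite")
    onsets = train.onsets
    i = int(np.searchsorted(onsets, t_event, side="left"))
    if i >= train.n:
        return None
    return train.sniffs[i]


def baseline_sniffs(
    train: SniffTrain,
    odor_onsets: Iterable[float],
    window: float = 3.0,
) -> SniffTrain:
    """Sniffs whose onset falls in the pre-odor baseline window.

    A sniff qualifies if its onset lies in ``[t_odor - window, t_odor)``
    for any odor onset. Each sniff is returned once even when windows
    overlap.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    onsets = train.onsets
    keep = np.zeros(train.n, dtype=bool)
    for t in odor_onsets:
        keep |= (onsets >= t - window) & (onsets < t)
    return SniffTrain(tuple(s for s, k in zip(train.sniffs, keep) if k))
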