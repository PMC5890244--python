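"""Time discretization and the sniff-phase design mapping.

The snifflet is a length ``K*D`` vector over dilated sniff phase ``u``:
``u`` in ``[0, 1)`` covers the inhalation (first ``D`` bins) and ``[1, K)``
the remainder of the sniff (the other ``(K-1)*D`` bins). Spike counts are
accumulated in short time bins tiling each sniff cycle, and each time bin
is mapped to the snifflet bin its (dilated) center falls in. Four dilation
schemes are supported; the inhalation-reciprocal scheme (``alpha_i =
1/d_inh``) is the model of record, the others exist for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sniffing import Sniff, SniffTrain

__all__ = ["SCHEMES", "BinnedObservation", "snifflet_bin_index", "dilated_phase", "build_design"]

logger = logging.getLogger(__name__)

SCHEMES = ("inhalation", "full_sniff", "two_piece", "none")


def snifflet_bin_index(u, D: int, K: int):
    """Map dilated phase ``u >= 0`` to a snifflet bin index in ``1..K*D``.

    Bins are uniform with width ``1/D`` in dilated phase; ``u >= K`` clamps
    to the last bin (the rate stays at its final value until the next sniff
    resets it). Accepts scalars or arrays.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("dilated phase must be non-negative")
    if D < 1 or K < 1:
        raise ValueError("require D >= 1 and K >= 1")
    j = np.minimum(np.floor(u_arr * D).astype(int) + 1, K * D)
    return j if np.ndim(u) else int(j)


def dilated_phase(t, sniff: Sniff, scheme: str, K: int, d_ref: Optional[float] = None):
    """Dilated phase ``u`` of absolute times ``t`` within ``sniff``.

    Schemes:

    - ``inhalation``: ``u = (t - tau) / d_inh`` (dilation by the
      reciprocal of the inhalation duration).
    - ``full_sniff``: ``u = K * (t - tau) / d_sniff``.
    - ``two_piece``: inhalation mapped to ``[0, 1)`` by ``1/d_inh`` and the
      rest of the sniff to ``[1, K)`` by ``(K - 1)/(d_sniff - d_inh)``.
    - ``none``: no per-sniff dilation, ``u = (t - tau) / d_ref`` with a
      fixed reference duration.
    """
    t = np.asarray(t, dtype=float)
    dt = t - sniff.t_onset
    if scheme == "inhalation":
        return dt / sniff.d_inh
    if scheme == "full_sniff":
        return K * dt / sniff.d_sniff
    if scheme == "two_piece":
        rest = sniff.d_sniff - sniff.d_inh
        u = np.where(
            dt < sniff.d_inh,
            dt / sniff.d_inh,
            1.0 + (K - 1) * (dt - sniff.d_inh) / max(rest, 1e-12),
        )
        return u
    if scheme == "none":
        if d_ref is None or d_ref <= 0:
            raise ValueError("scheme 'none' needs a positive reference duration d_ref")
        return dt / d_ref
    raise ValueError(f"unknown dilation scheme {scheme!r}; choose from {SCHEMES}")


@dataclass(frozen=True)
class BinnedObservation:
    """Spike counts in time bins tiling the analysis sniffs.

    Attributes
    ----------
    y : int array
        Spike count per time bin.
    delta : float
        Nominal bin width in seconds.
    widths : float array
        Actual exposure of each bin (the last bin of a sniff may be
        shorter than ``delta``).
    bin_to_snifflet : int array
        1-based snifflet bin index for each time bin.
    sniff_id : int array
        Index of the sniff each time bin belongs to.
    D, K : int
        Snifflet resolution and relative-duration multiple.
    d_ref : float or None
        Reference duration used by the undilated scheme.
    n_spikes_dropped : int
        Spikes outside all analysis sniffs (excluded from ``y``).
    """

    y: np.ndarray
    delta: float
    widths: np.ndarray
    bin_to_snifflet: np.ndarray
    sniff_id: np.ndarray
    D: int
    K: int
    scheme: str
    d_ref: Optional[float] = None
    n_spikes_dropped: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.y) != len(self.bin_to_snifflet) or len(self.y) != len(self.widths):
            raise ValueError("inconsistent bin arrays")
        if np.any(self.y < 0):
            raise ValueError("spike counts must be non-negative")
        m = self.D * self.K
        if self.y.size and (self.bin_to_snifflet.min() < 1 or self.bin_to_snifflet.max() > m):
            raise ValueError("snifflet bin index out of range")

    @property
    def n_bins(self) -> int:
        return len(self.y)

    @property
    def n_spikes(self) -> int:
        return int(self.y.sum())

    def aggregate(self) -> tuple[np.ndarray, np.ndarray]:
        """Sufficient statistics per snifflet bin.

        Returns ``(n, T)`` where ``n[j]`` is the total spike count mapped
        to snifflet bin ``j`` and ``T[j]`` the total exposure time; the
        Poisson log-likelihood is ``sum_j n[j]*psi[j] - T[j]*exp(psi[j])``.
        """
        m = self.D * self.K
        j0 = self.bin_to_snifflet - 1
        n = np.bincount(j0, weights=self.y, minlength=m) if self.y.size else np.zeros(m)
        T = np.bincount(j0, weights=self.widths, minlength=m) if self.y.size else np.zeros(m)
        return n, T

    def restrict(self, sniff_ids: np.ndarray) -> "BinnedObservation":
        """Observation restricted to a subset of sniffs (for cross-validation)."""
        mask = np.isin(self.sniff_id, sniff_ids)
        return BinnedObservation(
            y=self.y[mask],
            delta=self.delta,
            widths=self.widths[mask],
            bin_to_snifflet=self.bin_to_snifflet[mask],
            sniff_id=self.sniff_id[mask],
            D=self.D,
            K=self.K,
            scheme=self.scheme,
            d_ref=self.d_ref,
            n_spikes_dropped=self.n_spikes_dropped,
        )


def build_design(
    spike_times: np.ndarray,
    sniffs: SniffTrain,
    delta: float,
    D: int,
    K: int,
    scheme: str = "inhalation",
    d_ref: Optional[float] = None,
) -> BinnedObservation:
    """Bin spikes over the sniffs and map time bins to snifflet bins.

    Time bins of width ``delta`` tile each sniff's ``[tau_i, tau_{i+1})``;
    a shorter final bin absorbs the remainder. Each bin's center is mapped
    through the chosen dilation scheme to a snifflet bin. Spikes that fall
    outside every sniff interval are dropped (count logged).

    For the undilated scheme the reference duration defaults to the median
    inhalation duration of ``sniffs``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown dilation scheme {scheme!r}; choose from {SCHEMES}")
    spikes = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spikes) < 0):
        spikes = np.sort(spikes)

    if scheme == "none" and d_ref is None:
        d_ref = float(np.median(sniffs.d_inh)) if sniffs.n else None

    y_parts, w_parts, j_parts, s_parts = [], [], [], []
    n_inside = 0
    for i, sniff in enumerate(sniffs):
        dur = sniff.d_sniff
        n_full = int(np.floor(dur / delta + 1e-9))
        edges = sniff.t_onset + delta * np.arange(n_full + 1)
        rem = sniff.t_end - edges[-1]
        if rem > 1e-9:
            edges = np.append(edges, sniff.t_end)
        if len(edges) < 2:
            edges = np.array([sniff.t_onset, sniff.t_end])
        widths = np.diff(edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.histogram(spikes, bins=edges)[0]
        n_inside += int(counts.sum())
        u = dilated_phase(centers, sniff, scheme, K, d_ref)
        j = snifflet_bin_index(np.maximum(u, 0.0), D, K)
        y_parts.append(counts)
        w_parts.append(widths)
        j_parts.append(j)
        s_parts.append(np.full(len(counts), i, dtype=int))

    n_dropped = spikes.size - n_inside
    if n_dropped:
        logger.info("build_design: dropped %d spikes outside sniff intervals", n_dropped)

    cat = lambda parts, dt: np.concatenate(parts) if parts else np.array([], dtype=dt)
    return BinnedObservation(
        y=cat(y_parts, int).astype(int),
        delta=delta,
        widths=cat(w_parts, float),
        bin_to_snifflet=cat(j_parts, int),
        sniff_id=cat(s_parts, int),
        D=D,
        K=K,
        scheme=scheme,
        d_ref=d_ref,
        n_spikes_dropped=int(n_dropped),
    )
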