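"""Response statistics computed from fitted snifflets.

Once each cell-condition has an odor snifflet and a baseline snifflet,
the response is characterized by the first bin at which the two differ by
more than ``k`` combined posterior standard deviations (in log-rate
space): its sign gives the response polarity and its position the
latency, expressed natively in dilated sniff phase. Downstream summaries
— normalized population curves, concentration-consistency categories,
whole-sniff spike-count profiles — and the associated hypothesis tests
live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import SniffletResults

__all__ = [
    "Polarity",
    "ResponseCall",
    "ConcentrationCategory",
    "first_significant_deviation",
    "normalize_cell_set",
    "normalize_by_peak",
    "population_mean",
    "categorize_concentration",
    "rate_profile",
    "polarity_table_test",
    "latency_cdf_test",
    "compare_rate_profiles",
    "preferred_phase",
]


class Polarity(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    NONE = "none"


class ConcentrationCategory(str, Enum):
    CONSISTENT = "consistent"
    DROPPED = "dropped"
    FLIPPED = "flipped"
    OMITTED = "omitted"


@dataclass(frozen=True)
class ResponseCall:
    """Polarity and latency of the first significant snifflet deviation."""

    polarity: Polarity
    latency_bin: Optional[int] = None  # 1-based snifflet bin
    latency_u: Optional[float] = None  # dilated phase of the bin start

    def __post_init__(self) -> None:
        if (self.polarity is Polarity.NONE) != (self.latency_bin is None):
            raise ValueError("polarity is none iff latency is none")

    def latency_seconds(self, d_inh_ref: float) -> Optional[float]:
        """Latency in seconds for a reference inhalation duration."""
        if self.latency_u is None:
            return None
        return self.latency_u * d_inh_ref


def first_significant_deviation(
    odor_fit: SniffletResults,
    base_fit: SniffletResults,
    k: float = 3.0,
) -> ResponseCall:
    """First ``k``-sigma deviation of the odor snifflet from baseline.

    Scans snifflet bins in order and flags the first bin where
    ``|psi_odor - psi_base| > k * sqrt(var_odor + var_base)`` (log-rate
    space, marginal variances only; the combined sigma treats the two
    posteriors as independent). A positive difference is excitatory. No
    correction is made for scanning many bins.
    """
    if (odor_fit.D, odor_fit.K) != (base_fit.D, base_fit.K):
        raise ValueError("fits must share D and K")
    diff = odor_fit.psi - base_fit.psi
    sigma = np.sqrt(odor_fit.var + base_fit.var)
    exceed = np.abs(diff) > k * sigma
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return ResponseCall(Polarity.NONE)
    j = int(idx[0])
    pol = Polarity.EXCITATORY if diff[j] > 0 else Polarity.INHIBITORY
    return ResponseCall(pol, latency_bin=j + 1, latency_u=j / odor_fit.D)


def normalize_cell_set(fits: Mapping[str, SniffletResults]) -> Dict[str, np.ndarray]:
    """Normalize one cell's rate snifflets jointly across odors.

    A single affine transform is applied to every curve (firing-rate
    scale): subtract the across-odor mean of the value at inhalation
    onset (bin 1), then divide by the across-odor maximum of the centered
    curves. Afterwards the mean onset value is 0 and the global peak is 1.

    Raises
    ------
    ValueError
        If the cell is degenerate (non-positive global max after
        centering) — such constant-best cells are omitted upstream.
    """
    if not fits:
        raise ValueError("need at least one odor")
    curves = {o: np.exp(f.psi) for o, f in fits.items()}
    onset_mean = float(np.mean([c[0] for c in curves.values()]))
    centered = {o: c - onset_mean for o, c in curves.items()}
    gmax = max(float(c.max()) for c in centered.values())
    if gmax <= 0:
        raise ValueError("degenerate cell: no positive excursion after centering")
    return {o: c / gmax for o, c in centered.items()}


def normalize_by_peak(fits: Mapping[str, SniffletResults]) -> Dict[str, np.ndarray]:
    """Normalize a cell's snifflets by its largest-amplitude snifflet.

    Amplitude of one snifflet = maximum over bins of ``|rate - baseline
    rate|`` where the baseline rate is the cell's constant-rate estimate
    ``exp(prior_mean)``. Every curve, expressed as rate deviation from
    that baseline, is divided by the cell's largest amplitude, so the
    peak odor reaches 1 and inhibitory excursions go negative.
    """
    if not fits:
        raise ValueError("need at least one odor")
    any_fit = next(iter(fits.values()))
    base = float(np.exp(any_fit.prior_mean))
    devs = {o: np.exp(f.psi) - base for o, f in fits.items()}
    amp = max(float(np.max(np.abs(d))) for d in devs.values())
    if amp <= 0:
        raise ValueError("degenerate cell: zero peak amplitude")
    return {o: d / amp for o, d in devs.items()}


def population_mean(curves: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and SEM across cells; single-cell SEM is zero."""
    if len(curves) == 0:
        raise ValueError("need at least one cell")
    X = np.vstack(curves)
    mean = X.mean(axis=0)
    if X.shape[0] < 2:
        return mean, np.zeros_like(mean)
    sem = X.std(axis=0, ddof=1) / np.sqrt(X.shape[0])
    return mean, sem


def categorize_concentration(calls: Sequence[ResponseCall]) -> ConcentrationCategory:
    """Concentration-consistency category from three polarity calls.

    - all three non-significant → ``omitted``
    - both polarities observed → ``flipped`` (takes precedence even when a
      concentration also dropped out)
    - some call missing, one polarity present → ``dropped``
    - same polarity at all three → ``consistent``
    """
    if len(calls) != 3:
        raise ValueError("exactly three concentration calls required")
    pols = [c.polarity for c in calls]
    present = {p for p in pols if p is not Polarity.NONE}
    if not present:
        return ConcentrationCategory.OMITTED
    if len(present) == 2:
        return ConcentrationCategory.FLIPPED
    if Polarity.NONE in pols:
        return ConcentrationCategory.DROPPED
    return ConcentrationCategory.CONSISTENT


def rate_profile(
    first_sniff_counts: Mapping[str, float],
    baseline_count: float,
) -> Dict[str, float]:
    """Whole-sniff spike-count response profile across odors.

    ``response(odor) = (count_odor - count_base) / (max_odor - count_base)``
    so baseline maps to 0 and the strongest odor to 1. Raises on the
    degenerate case where no odor exceeds baseline.
    """
    if not first_sniff_counts:
        raise ValueError("need at least one odor")
    cmax = max(first_sniff_counts.values())
    denom = cmax - baseline_count
    if denom == 0:
        raise ValueError("degenerate profile: max odor count equals baseline")
    return {o: (c - baseline_count) / denom for o, c in first_sniff_counts.items()}


def polarity_table_test(calls_a: Iterable[ResponseCall], calls_b: Iterable[ResponseCall]) -> dict:
    """Pearson chi-squared on the 2x2 excitatory/inhibitory table.

    Non-significant cells are excluded, matching how polarity histograms
    are compared between cell populations.
    """
    def counts(calls):
        pols = [c.polarity for c in calls]
        return [sum(p is Polarity.EXCITATORY for p in pols),
                sum(p is Polarity.INHIBITORY for p in pols)]

    table = np.array([counts(calls_a), counts(calls_b)], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared table has an empty margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"test": "pearson_chi2", "statistic": float(chi2), "p": float(p),
            "n": int(table.sum()), "table": table.astype(int).tolist()}


def latency_cdf_test(lat_a: Sequence[float], lat_b: Sequence[float]) -> dict:
    """Two-sample Kolmogorov-Smirnov test on response latencies."""
    a, b = np.asarray(lat_a, float), np.asarray(lat_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("latency samples must be nonempty")
    res = stats.ks_2samp(a, b, method="auto")
    return {"test": "ks_2samp", "statistic": float(res.statistic), "p": float(res.pvalue),
            "n": int(a.size + b.size)}


def compare_rate_profiles(
    profiles_a: Mapping[str, Sequence[float]],
    profiles_b: Mapping[str, Sequence[float]],
) -> Dict[str, dict]:
    """Wilcoxon signed-rank test per odor between paired profile samples."""
    out = {}
    for odor in profiles_a:
        a = np.asarray(profiles_a[odor], float)
        b = np.asarray(profiles_b[odor], float)
        if a.size != b.size or a.size < 2:
            raise ValueError(f"odor {odor!r}: need paired samples of size >= 2")
        d = a - b
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b)
        out[odor] = {"test": "wilcoxon", "statistic": float(stat), "p": float(p), "n": int(a.size)}
    return out


def preferred_phase(base_fit: SniffletResults) -> float:
    """Preferred sniff phase: dilated-phase midpoint of the bin where the
    baseline snifflet rate is maximal (ties go to the earliest bin)."""
    j = int(np.argmax(base_fit.psi))
    return float(base_fit.u_mid[j])
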