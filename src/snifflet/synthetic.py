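"""Ground-truth synthetic datasets for the sniff-warped analysis chain.

The generator emulates the statistical structure the analysis assumes:
sniff trains whose inhalation durations follow a bimodal (fast/slow)
log-normal mixture, per-cell log-rate templates over dilated sniff phase,
inhomogeneous-Poisson spiking produced by dilating each template per
sniff, cell populations in "stereotyped early-excitation" versus
"diverse excitation/inhibition" response modes, concentration series
with per-concentration amplitude scaling and latency shifts, and
light-pulse trials for optogenetically tagged cells.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning (one child per cell, per
condition), so any subset of the dataset is reproducible on its own.
Ground truth (templates, polarities, tags) is returned alongside the
data in the same snifflet parameterization the model fits, making
recovery error well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import dilated_phase, snifflet_bin_index
from .sniffing import Sniff, SniffTrain

__all__ = [
    "SniffParams",
    "LightParams",
    "SyntheticSpec",
    "sample_sniff_train",
    "make_truth_snifflet",
    "sample_spike_train",
    "make_population_dataset",
]


@dataclass(frozen=True)
class SniffParams:
    """Log-normal mixture for inhalation durations plus exhalation law.

    Defaults put 75% of sniffs in the slow mode (median 130 ms) and 25%
    in the fast mode (median 60 ms), mirroring the empirical bimodality
    that motivates restricting analysis to inhalations > 100 ms.
    """

    slow_median: float = 0.130
    fast_median: float = 0.060
    sigma_log: float = 0.25
    fast_weight: float = 0.25
    exhale_median: float = 0.180
    exhale_sigma_log: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.fast_weight <= 1.0):
            raise ValueError("fast_weight must be in [0, 1]")
        if min(self.slow_median, self.fast_median, self.exhale_median) <= 0:
            raise ValueError("medians must be positive")
        if self.sigma_log <= 0 or self.exhale_sigma_log <= 0:
            raise ValueError("log-sigmas must be positive")


@dataclass(frozen=True)
class LightParams:
    """Light-pulse trial settings for optogenetic tagging.

    Tagged cells fire one extra, tightly time-locked spike per pulse with
    probability ``p_spike`` at ``latency`` (Gaussian ``jitter``), the way
    channelrhodopsin-driven cells respond; untagged cells ignore the
    light. The no-light control condition comprises ``n_control``
    inhalation-aligned sniffs (control sniffs greatly outnumber light
    pulses, as they do in a recording session).
    """

    latency: float = 0.006  # s after pulse onset
    jitter: float = 0.0015  # s, SD of the evoked-spike latency
    p_spike: float = 0.8  # evoked-spike probability per pulse
    n_trials: int = 50
    n_control: int = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic population experiment.

    ``odors`` maps odor name to response mode (``stereotyped``,
    ``diverse``, ``inhibitory``, ``constant`` or ``null``);
    ``concentration_effects`` lists per-concentration
    ``(latency_shift_bins, amplitude_scale)`` pairs applied to each
    cell-odor template (a negative scale flips the response polarity).
    """

    n_cells: int = 20
    n_trials_per_condition: int = 60
    odors: Mapping[str, str] = field(default_factory=lambda: {"strong": "stereotyped", "weak": "diverse"})
    concentration_effects: Sequence[Tuple[float, float]] = ((0.0, 1.0),)
    sniff_params: SniffParams = field(default_factory=SniffParams)
    light_params: LightParams = field(default_factory=LightParams)
    tagged_fraction: float = 0.5
    baseline_rate: float = 8.0
    D: int = 30
    K: int = 4
    scheme: str = "inhalation"
    seed: int = 0


def sample_sniff_train(
    n: int,
    params: Optional[SniffParams] = None,
    seed=None,
    t_start: float = 0.0,
) -> SniffTrain:
    """Sample ``n`` consecutive sniff cycles.

    Inhalation durations come from the two-component log-normal mixture
    in ``params``; exhalation durations are log-normal; cycles abut
    (each ``t_end`` is the next onset).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = params or SniffParams()
    if n == 0:
        return SniffTrain(())
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < params.fast_weight
    med = np.where(fast, params.fast_median, params.slow_median)
    d_inh = med * np.exp(params.sigma_log * rng.standard_normal(n))
    d_exh = params.exhale_median * np.exp(params.exhale_sigma_log * rng.standard_normal(n))
    dur = d_inh + d_exh
    onsets = t_start + np.concatenate([[0.0], np.cumsum(dur[:-1])])
    return SniffTrain.from_arrays(onsets, onsets + d_inh, onsets + dur)


def _gp_sample(rng: np.random.Generator, m: int, length_scale: float, sd: float) -> np.ndarray:
    idx = np.arange(m)
    C = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * length_scale**2))
    C[np.diag_indices_from(C)] += 1e-8
    L = np.linalg.cholesky(C)
    return sd * (L @ rng.standard_normal(m))


def make_truth_snifflet(
    mode: str,
    D: int = 30,
    K: int = 4,
    baseline_rate: float = 8.0,
    seed=None,
) -> np.ndarray:
    """Ground-truth log-rate template of length ``K*D``.

    Modes
    -----
    - ``stereotyped``: early excitatory transient — a Gaussian bump (gain
      at least ``log 3``) centered in the first third of the inhalation,
      plus a small smooth random tail later in the sniff.
    - ``diverse``: a smooth Gaussian-process sample (length-scale
      ``~D/3``); the sign of the first excursion is random by symmetry.
    - ``inhibitory``: early negative excursion.
    - ``constant`` / ``null``: flat baseline.
    """
    m = D * K
    b = float(np.log(baseline_rate))
    rng = np.random.default_rng(seed)
    idx = np.arange(m, dtype=float)
    if mode in ("constant", "null"):
        return np.full(m, b)
    if mode == "stereotyped":
        center = rng.uniform(D / 12.0, D / 3.0 - D / 12.0)
        width = rng.uniform(D / 10.0, D / 5.0)
        gain = np.log(3.0) + rng.uniform(0.0, np.log(5.0 / 3.0))
        bump = gain * np.exp(-((idx - center) ** 2) / (2.0 * width**2))
        tail = _gp_sample(rng, m, D / 3.0, 0.3)
        taper = 1.0 / (1.0 + np.exp(-(idx - D) / (D / 8.0)))  # tail only post-inhalation
        psi = b + bump + taper * tail
        # guarantee the early peak dominates
        psi[: D // 3] = np.maximum(psi[: D // 3], b + bump[: D // 3])
        return psi
    if mode == "diverse":
        return b + _gp_sample(rng, m, D / 3.0, 0.8)
    if mode == "inhibitory":
        # suppression is slower and more sustained than the excitatory burst
        center = rng.uniform(D / 12.0, D / 3.0)
        width = rng.uniform(D / 6.0, D / 3.0)
        gain = np.log(3.0) + rng.uniform(0.0, 0.4)
        dip = -gain * np.exp(-((idx - center) ** 2) / (2.0 * width**2))
        return b + dip
    raise ValueError(f"unknown truth mode {mode!r}")


def _rate_on_sniff(psi: np.ndarray, t: np.ndarray, sniff: Sniff, scheme: str,
                   D: int, K: int, d_ref: Optional[float]) -> np.ndarray:
    u = dilated_phase(t, sniff, scheme, K, d_ref)
    j = snifflet_bin_index(np.maximum(u, 0.0), D, K)
    return np.exp(psi[np.asarray(j) - 1])


def sample_spike_train(
    psi: np.ndarray,
    sniffs: SniffTrain,
    D: int = 30,
    K: int = 4,
    scheme: str = "inhalation",
    seed=None,
    d_ref: Optional[float] = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes from a dilated log-rate template.

    Uses thinning against the template's maximum rate, per sniff, so
    spikes occur only within sniff intervals. The generative process is
    the exact inverse of the model's rate equation.
    """
    psi = np.asarray(psi, dtype=float)
    rng = np.random.default_rng(seed)
    if scheme == "none" and d_ref is None:
        d_ref = float(np.median(sniffs.d_inh)) if sniffs.n else None
    rmax = float(np.exp(psi.max())) if psi.size else 0.0
    if rmax <= 0 or not np.isfinite(rmax):
        return np.array([], dtype=float)
    out = []
    for sniff in sniffs:
        n_cand = rng.poisson(rmax * sniff.d_sniff)
        if n_cand == 0:
            continue
        t = np.sort(sniff.t_onset + sniff.d_sniff * rng.random(n_cand))
        accept = rng.random(n_cand) * rmax < _rate_on_sniff(psi, t, sniff, scheme, D, K, d_ref)
        out.append(t[accept])
    return np.concatenate(out) if out else np.array([], dtype=float)


def _shift_template(psi: np.ndarray, b: float, shift_bins: float, scale: float) -> np.ndarray:
    """Apply a concentration effect: scale the deviation from baseline and
    delay it by ``shift_bins`` (edge-padded with baseline)."""
    dev = psi - b
    s = int(round(shift_bins))
    if s > 0:
        dev = np.concatenate([np.zeros(s), dev[:-s]])
    elif s < 0:
        dev = np.concatenate([dev[-s:], np.zeros(-s)])
    return b + scale * dev


def _truth_call(psi: np.ndarray, b: float, thresh: float = 0.35) -> tuple[str, Optional[int]]:
    """Nominal polarity/latency of a template: first bin deviating from
    baseline by more than ``thresh`` log-units."""
    dev = psi - b
    idx = np.flatnonzero(np.abs(dev) > thresh)
    if idx.size == 0:
        return "none", None
    j = int(idx[0])
    return ("excitatory" if dev[j] > 0 else "inhibitory"), j + 1


def make_population_dataset(spec: SyntheticSpec) -> dict:
    """Generate a full population experiment plus ground truth.

    Layout: all cells share one session timeline. Each trial contributes
    a stretch of consecutive sniffs with the odor arriving ~3.2 s in, so
    the three seconds before onset provide baseline sniffs; every cell
    spikes from its baseline template on all sniffs except the first
    sniff after odor onset, which uses the cell's odor-condition
    template. A final light block holds interleaved light-pulse and
    no-light sniffs; tagged cells receive a short-latency rate transient
    after each pulse.

    Returns
    -------
    dict with keys
        ``spikes`` (cell_id, t), ``sniffs`` (sniff_id, t_onset,
        t_inh_end, t_end), ``trials`` (trial_id, odor, concentration,
        t_odor_on, t_light), ``truth`` (templates, polarities, latencies,
        tags, spec echo).
    """
    root = np.random.SeedSequence(spec.seed)
    ss_session, ss_templates, ss_cells, ss_light = root.spawn(4)
    rng_session = np.random.default_rng(ss_session)

    odors = dict(spec.odors)
    concs = list(spec.concentration_effects)
    conditions = [(o, ci) for o in odors for ci in range(len(concs))]
    b = float(np.log(spec.baseline_rate)) if spec.baseline_rate > 0 else float("-inf")
    m = spec.D * spec.K

    # ground-truth templates per cell-odor (concentration effects derive from them)
    tmpl_seeds = ss_templates.spawn(max(spec.n_cells, 1))
    templates: Dict[tuple, np.ndarray] = {}
    truth_calls: Dict[tuple, dict] = {}
    tagged = np.zeros(spec.n_cells, dtype=bool)
    n_tag = int(round(spec.tagged_fraction * spec.n_cells))
    tagged[:n_tag] = True
    for c in range(spec.n_cells):
        cell_rng_seq = tmpl_seeds[c].spawn(len(odors))
        for (odor, mode), sseq in zip(odors.items(), cell_rng_seq):
            base = make_truth_snifflet(mode, spec.D, spec.K, spec.baseline_rate, sseq)
            for ci, (shift, scale) in enumerate(concs):
                psi = _shift_template(base, b, shift, scale)
                templates[(c, odor, ci)] = psi
                pol, lat = _truth_call(psi, b)
                truth_calls[(c, odor, ci)] = {"polarity": pol, "latency_bin": lat}

    # session timeline: trials of consecutive sniffs, odor onset ~3.2 s in
    trial_rows = []
    sniff_rows = []
    spikes: Dict[int, list] = {c: [] for c in range(spec.n_cells)}
    cell_seeds = ss_cells.spawn(max(spec.n_cells, 1))
    cell_rngs = [np.random.default_rng(s) for s in cell_seeds]

    t_cursor = 0.0
    trial_id = 0
    gap = 1.0
    for odor, ci in conditions:
        for _ in range(spec.n_trials_per_condition):
            train = sample_sniff_train(18, spec.sniff_params, rng_session, t_start=t_cursor)
            if train.n == 0:
                continue
            t_odor = t_cursor + 3.2
            # index of first sniff at/after odor onset
            onsets = train.onsets
            k = int(np.searchsorted(onsets, t_odor, side="left"))
            if k >= train.n:
                k = train.n - 1
                t_odor = onsets[k] - 0.01
            for i, s in enumerate(train):
                sniff_rows.append((s.t_onset, s.t_inh_end, s.t_end))
            odor_sniff = SniffTrain((train.sniffs[k],))
            rest = SniffTrain(tuple(s for i, s in enumerate(train) if i != k))
            for c in range(spec.n_cells):
                rng_c = cell_rngs[c]
                base_psi = np.full(m, b)
                if np.isfinite(b):
                    spikes[c].append(
                        sample_spike_train(base_psi, rest, spec.D, spec.K, spec.scheme, rng_c)
                    )
                spikes[c].append(
                    sample_spike_train(
                        templates[(c, odor, ci)], odor_sniff, spec.D, spec.K, spec.scheme, rng_c
                    )
                )
            trial_rows.append((trial_id, odor, ci, t_odor, np.nan))
            trial_id += 1
            t_cursor = train.sniffs[-1].t_end + gap

    # light block: light pulses interspersed among no-light control sniffs
    lp = spec.light_params
    rng_light = np.random.default_rng(ss_light)
    n_block = lp.n_trials + lp.n_control
    light_train = sample_sniff_train(n_block, spec.sniff_params, rng_light, t_start=t_cursor)
    light_on = np.zeros(light_train.n, dtype=bool)
    if lp.n_trials > 0 and light_train.n:
        stride = max(n_block // lp.n_trials, 1)
        light_on[::stride] = True
        light_on[np.cumsum(light_on) > lp.n_trials] = False
    for i, s in enumerate(light_train):
        sniff_rows.append((s.t_onset, s.t_inh_end, s.t_end))
        if light_on[i]:
            trial_rows.append((trial_id, "", -1, np.nan, s.t_onset))
            trial_id += 1
    base_flat = np.full(m, b)
    for c in range(spec.n_cells):
        rng_c = cell_rngs[c]
        if np.isfinite(b):
            spikes[c].append(
                sample_spike_train(base_flat, light_train, spec.D, spec.K, spec.scheme, rng_c)
            )
        if tagged[c]:
            for i, s in enumerate(light_train):
                if light_on[i] and rng_c.random() < lp.p_spike:
                    t_sp = s.t_onset + lp.latency + lp.jitter * rng_c.standard_normal()
                    spikes[c].append(np.array([max(t_sp, s.t_onset + 5e-4)]))

    spikes_df = pd.DataFrame(
        [(c, t) for c in range(spec.n_cells) for t in np.sort(np.concatenate(spikes[c]) if spikes[c] else np.array([]))],
        columns=["cell_id", "t"],
    )
    sniffs_df = pd.DataFrame(sniff_rows, columns=["t_onset", "t_inh_end", "t_end"])
    sniffs_df = sniffs_df.sort_values("t_onset").reset_index(drop=True)
    sniffs_df.insert(0, "sniff_id", np.arange(len(sniffs_df)))
    trials_df = pd.DataFrame(
        trial_rows, columns=["trial_id", "odor", "concentration", "t_odor_on", "t_light"]
    )

    truth = {
        "templates": {f"{c}|{o}|{ci}": templates[(c, o, ci)].tolist() for (c, o, ci) in templates},
        "calls": {f"{c}|{o}|{ci}": truth_calls[(c, o, ci)] for (c, o, ci) in truth_calls},
        "tagged": tagged.tolist(),
        "odor_modes": odors,
        "concentration_effects": [list(x) for x in concs],
        "baseline_rate": spec.baseline_rate,
        "D": spec.D,
        "K": spec.K,
        "scheme": spec.scheme,
        "seed": spec.seed,
    }
    return {"spikes": spikes_df, "sniffs": sniffs_df, "trials": trials_df, "truth": truth}
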