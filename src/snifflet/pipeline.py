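"""End-to-end orchestration: fit every cell-condition, call responses,
categorize concentration series, tag cells from light trials, and write a
report.

Per cell and (odor, concentration): the analysis sniffs are the first
sniff after each trial's odor onset (restricted to inhalations longer
than the slow-sniff threshold); the baseline sniffs come from the three
seconds before each odor onset. Both are fitted with the identical
snifflet machinery and compared with the 3-sigma rule. All steps are
deterministic given the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics, opto
from .io import Dataset
from .model import FitConfig, SniffletModel, fit_constant
from .sniffing import SniffTrain, baseline_sniffs, filter_by_inhalation, first_sniff_after

__all__ = ["AnalysisConfig", "run_full_analysis", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a full pipeline run."""

    fit: FitConfig = field(default_factory=FitConfig)
    min_d_inh: float = 0.100  # slow-sniff threshold, seconds
    baseline_window: float = 3.0  # seconds before odor onset
    sigma_k: float = 3.0  # significance threshold in combined posterior SDs
    opto_k_sd: float = 1.0
    opto_window: float = 0.050
    opto_bin: float = 0.004
    latency_cutoff: float = 0.020
    latency_mode: str = "fixed_cutoff"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "min_d_inh", "baseline_window", "sigma_k", "opto_k_sd", "opto_window",
            "opto_bin", "latency_cutoff", "latency_mode")}
        d["fit"] = {
            "delta": self.fit.delta, "D": self.fit.D, "K": self.fit.K,
            "scheme": self.fit.scheme,
        }
        return d


def _fit_condition(spikes, sniffs: SniffTrain, cfg: AnalysisConfig):
    if sniffs.n == 0:
        return None
    return SniffletModel(spikes, sniffs, cfg.fit).fit()


def run_full_analysis(ds: Dataset, config: Optional[AnalysisConfig] = None) -> dict:
    """Run the full analysis chain on a dataset.

    Returns a results bundle: per cell-condition fits, baseline fits,
    response calls, concentration categories, population summaries and
    opto classifications. Per-cell failures are logged and skipped.
    """
    cfg = config or AnalysisConfig()
    train_all = ds.sniff_train()
    train = filter_by_inhalation(train_all, cfg.min_d_inh)
    odor_trials = ds.trials.dropna(subset=["t_odor_on"])
    odor_onsets = odor_trials["t_odor_on"].to_numpy(float)
    conditions = sorted(
        {(r.odor, int(r.concentration)) for r in odor_trials.itertuples() if r.odor != ""}
    )

    calls_rows = []
    fits = {}
    base_fits = {}
    for cell in ds.cell_ids():
        spikes = ds.spike_times(cell)
        try:
            base_train = baseline_sniffs(train, odor_onsets, cfg.baseline_window)
            base_fit = _fit_condition(spikes, base_train, cfg)
            if base_fit is None:
                logger.warning("cell %s: no baseline sniffs; skipped", cell)
                continue
            base_fits[cell] = base_fit
            for odor, conc in conditions:
                sel = odor_trials[(odor_trials["odor"] == odor)
                                  & (odor_trials["concentration"] == conc)]
                # first sniff of each trial; trials whose first sniff is too
                # fast are excluded, not replaced by a later sniff
                first = [first_sniff_after(train_all, t) for t in sel["t_odor_on"]]
                first = SniffTrain(tuple(dict.fromkeys(
                    s for s in first if s is not None and s.d_inh > cfg.min_d_inh)))
                fit = _fit_condition(spikes, first, cfg)
                if fit is None:
                    continue
                fits[(cell, odor, conc)] = fit
                call = metrics.first_significant_deviation(fit, base_fit, cfg.sigma_k)
                calls_rows.append({
                    "cell_id": cell, "odor": odor, "concentration": conc,
                    "polarity": call.polarity.value,
                    "latency_bin": call.latency_bin if call.latency_bin is not None else np.nan,
                    "latency_u": call.latency_u if call.latency_u is not None else np.nan,
                })
        except Exception:
            logger.exception("cell %s failed; skipped", cell)

    calls_df = pd.DataFrame(
        calls_rows, columns=["cell_id", "odor", "concentration", "polarity",
                             "latency_bin", "latency_u"])

    # concentration categories where a cell-odor has exactly 3 concentrations
    cat_rows = []
    if not calls_df.empty:
        for (cell, odor), grp in calls_df.groupby(["cell_id", "odor"]):
            grp = grp.sort_values("concentration")
            if len(grp) != 3:
                continue
            calls = [
                metrics.ResponseCall(
                    metrics.Polarity(r.polarity),
                    None if pd.isna(r.latency_bin) else int(r.latency_bin),
                    None if pd.isna(r.latency_u) else float(r.latency_u),
                )
                for r in grp.itertuples()
            ]
            cat = metrics.categorize_concentration(calls)
            cat_rows.append({"cell_id": cell, "odor": odor, "category": cat.value})
    cats_df = pd.DataFrame(cat_rows, columns=["cell_id", "odor", "category"])

    # opto tagging from light trials
    opto_rows = []
    light_times = ds.trials.dropna(subset=["t_light"])["t_light"].to_numpy(float)
    if light_times.size:
        control_onsets = np.array(
            [s.t_onset for s in train_all
             if light_times.size and np.min(np.abs(light_times - s.t_onset)) > 1e-6
             and s.t_onset > light_times.min() - 5.0 and s.t_onset < light_times.max() + 5.0]
        )
        for cell in ds.cell_ids():
            spikes = ds.spike_times(cell)
            if control_onsets.size == 0:
                break
            p_light = opto.psth(spikes, light_times, cfg.opto_bin)
            p_ctrl = opto.psth(spikes, control_onsets, cfg.opto_bin)
            responsive, latency = opto.classify_light_response(
                p_light, p_ctrl, cfg.opto_k_sd, cfg.opto_window)
            opto_rows.append({"cell_id": cell, "responsive": responsive,
                              "latency_s": latency if latency is not None else np.nan})
        if opto_rows:
            df = pd.DataFrame(opto_rows)
            resp = df[df["responsive"] & df["latency_s"].notna()]
            if len(resp):
                kept, bound = opto.latency_exclusion(
                    resp["latency_s"].to_numpy(), cfg.latency_mode, cfg.latency_cutoff)
                kept_ids = set(resp.iloc[kept]["cell_id"])
                df["tagged"] = df["cell_id"].isin(kept_ids) & df["responsive"]
                df["bound_used"] = bound
            else:
                df["tagged"] = False
                df["bound_used"] = np.nan
            opto_df = df
        else:
            opto_df = pd.DataFrame(columns=["cell_id", "responsive", "latency_s", "tagged", "bound_used"])
    else:
        opto_df = pd.DataFrame(columns=["cell_id", "responsive", "latency_s", "tagged", "bound_used"])

    # population summaries: peak-normalized mean curves per odor (top concentration set)
    pop = {}
    if fits:
        by_cell: dict = {}
        for (cell, odor, conc), fit in fits.items():
            by_cell.setdefault(cell, {})[(odor, conc)] = fit
        for odor, conc in conditions:
            curves = []
            for cell, cell_fits in by_cell.items():
                if (odor, conc) not in cell_fits:
                    continue
                try:
                    norm = metrics.normalize_by_peak(
                        {f"{o}|{ci}": f for (o, ci), f in cell_fits.items()})
                except ValueError:
                    continue
                curves.append(norm[f"{odor}|{conc}"])
            if curves:
                mean, sem = metrics.population_mean(curves)
                pop[f"{odor}|{conc}"] = {"mean": mean.tolist(), "sem": sem.tolist(),
                                         "n_cells": len(curves)}

    return {
        "config": cfg.to_dict(),
        "fits": fits,
        "baseline_fits": base_fits,
        "calls": calls_df,
        "categories": cats_df,
        "opto": opto_df,
        "population": pop,
        "n_sniffs_analyzed": train.n,
    }


def write_report(results: dict, out_dir) -> list:
    """Write tables, a JSON summary, and diagnostic figures.

    Emits ``calls.csv``, ``categories.csv``, ``opto.csv``, per-fit
    snifflet tables, ``summary.json``, and PNG figures (snifflet grid,
    latency CDFs, category bars). Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name in ("calls", "categories", "opto"):
        f = out / f"{name}.csv"
        results[name].to_csv(f, index=False)
        written.append(f)

    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    summary_fits = {}
    for (cell, odor, conc), fit in results["fits"].items():
        key = f"cell{cell}_{odor}_c{conc}"
        f = fits_dir / f"{key}.csv"
        fit.to_frame().to_csv(f, index=False)
        written.append(f)
        summary_fits[key] = {
            "D": fit.D, "K": fit.K, "scheme": fit.scheme,
            "rho": fit.rho, "delta_prior": fit.delta_prior,
            "prior_mean": fit.prior_mean, "log_evidence": fit.log_evidence,
            "n_sniffs": fit.n_sniffs, "n_spikes": fit.n_spikes,
        }

    summary = {
        "config": results["config"],
        "n_sniffs_analyzed": results["n_sniffs_analyzed"],
        "n_cells": len(results["baseline_fits"]),
        "fits": summary_fits,
        "population": results["population"],
    }
    f = out / "summary.json"
    f.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(f)

    written.extend(_figures(results, out))
    return written


def _figures(results: dict, out: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fits = results["fits"]
    if fits:
        keys = list(fits)[:12]
        ncol = min(4, len(keys))
        nrow = int(np.ceil(len(keys) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
        for ax, key in zip(axes.ravel(), keys):
            fit = fits[key]
            u = fit.u_mid
            ax.plot(u, np.exp(fit.psi), lw=1.5)
            lo = np.exp(fit.psi - np.sqrt(fit.var))
            hi = np.exp(fit.psi + np.sqrt(fit.var))
            ax.fill_between(u, lo, hi, alpha=0.3)
            ax.axvline(1.0, color="k", ls=":", lw=0.7)
            ax.set_title(f"{key[0]} {key[1]} c{key[2]}", fontsize=8)
        for ax in axes.ravel()[len(keys):]:
            ax.axis("off")
        fig.suptitle("Fitted snifflets (rate vs dilated phase)")
        fig.tight_layout()
        f = out / "snifflets.png"
        fig.savefig(f, dpi=100)
        plt.close(fig)
        written.append(f)

    calls = results["calls"]
    if not calls.empty:
        lat = calls.dropna(subset=["latency_u"])
        if len(lat):
            fig, ax = plt.subplots(figsize=(4, 3))
            for odor, grp in lat.groupby("odor"):
                x = np.sort(grp["latency_u"].to_numpy())
                ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=str(odor))
            ax.set_xlabel("latency (dilated phase u)")
            ax.set_ylabel("CDF")
            ax.legend(fontsize=7)
            fig.tight_layout()
            f = out / "latency_cdf.png"
            fig.savefig(f, dpi=100)
            plt.close(fig)
            written.append(f)

    cats = results["categories"]
    if not cats.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        tab = cats.groupby(["odor", "category"]).size().unstack(fill_value=0)
        tab.plot.bar(stacked=True, ax=ax)
        ax.set_ylabel("cells")
        fig.tight_layout()
        f = out / "categories.png"
        fig.savefig(f, dpi=100)
        plt.close(fig)
        written.append(f)
    return written
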