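# snifflet

Sniff-warped statistical analysis of olfactory bulb spike trains.

Mitral/tufted (MT) cells fire in lockstep with respiration, and the
duration of each inhalation stretches the within-sniff firing pattern.
Conventional event-aligned PSTHs smear this structure across sniffs of
different durations. This package fits, per cell and stimulus
condition, a **snifflet**: a log firing-rate pattern over normalized
sniff time that is temporally dilated on each sniff by the reciprocal
of that sniff's inhalation duration,

    r(t) = exp[ Σᵢ ψ(αᵢ (t − τᵢ)) · 1{τᵢ ≤ t < τᵢ₊₁} ],   αᵢ = 1 / d_inh,i

with ψ parameterized as a length K·D vector (D = 30 bins over the
inhalation, (K−1)·D = 90 over the rest of the sniff). Spike counts are
Poisson; ψ gets a squared-exponential (automatic smoothness
determination) Gaussian prior whose scale and length-scale are learned
by Laplace-approximated evidence optimization; the MAP is found by
Newton's method and the posterior summarized by marginal variances.

On top of the fit, the package implements the downstream analyses this
kind of recording calls for:

- **Response calls** — polarity and latency of the first 3σ deviation
  of the odor snifflet from the baseline snifflet (log-rate space,
  marginal variances).
- **Concentration categories** — consistent / dropped / flipped /
  omitted labels for three-concentration series.
- **Population summaries** — peak-normalized mean snifflets ± SEM,
  whole-sniff spike-count response profiles, with Pearson chi-squared,
  Kolmogorov–Smirnov and Wilcoxon signed-rank comparisons.
- **Dilation-scheme comparison** — cross-validated held-out likelihood
  over inhalation / full-sniff / two-piece / undilated schemes.
- **Optogenetic tagging** — light-responsive cell identification from
  4 ms PSTHs (1 SD criterion within 50 ms) with latency-based
  exclusion of putative polysynaptic responders.
- **Sniff handling** — pressure-trace sniff detection, slow-sniff
  (inhalation > 100 ms) filtering, first-sniff-after-odor and
  pre-odor baseline-window selection.
- **Synthetic data** — a seeded generator of sniff trains, ground-truth
  templates (stereotyped / diverse / inhibitory / constant), dilated
  Poisson spiking, concentration series and light-pulse trials, so the
  whole chain is testable end to end with no external data.

It is aimed at systems neuroscientists analyzing respiration-locked
spike trains in awake rodents, and at anyone who wants a worked,
tested implementation of evidence-optimized Poisson GLM fitting with
time warping.

## Worked example

```python
import numpy as np
import snifflet as sn

train = sn.sample_sniff_train(500, seed=1)                 # sniff cycles
psi_true = sn.make_truth_snifflet("stereotyped", seed=2)   # ground truth
spikes = sn.sample_spike_train(psi_true, train, seed=3)    # Poisson spikes

res = sn.SniffletModel(spikes, train).fit()
print(res.summary())
```

```
Snifflet fit (Poisson GLM over dilated sniff phase)
=======================================================
bins (K*D)                  120 (D=30, K=4)
dilation scheme             inhalation
sniffs / spikes             500 / 1669
prior scale exp(rho)        0.1891
prior length-scale (bins)   5.87
prior mean (log sp/s)       2.4071
log evidence                2558.010
peak rate (sp/s)            34.329 at u=0.117
```

The cell fires around exp(2.41) ≈ 11 spikes/s on average within sniffs,
but the fitted pattern peaks at 34 spikes/s early in the inhalation
(dilated phase u = 0.117, i.e. ~12% of the way through the inhalation)
— the stereotyped early excitatory transient the template injected.
The learned prior length-scale (5.9 bins) reflects the smoothness of
the underlying pattern, and the fitted ψ correlates 0.97 with the
generating template. `res.predict(sniff)` renders the rate on any
sniff's real-time support; comparing against a baseline fit with
`sn.first_significant_deviation(res, base)` yields the polarity/latency
response call.

A command-line interface covers the same flow on CSV datasets:

```sh
snifflet simulate --seed 0 --out data/           # synthetic session + truth
snifflet fit --data data/ --cell 0               # one cell, fit summary
snifflet report --data data/ --out report/       # full analysis + figures
snifflet run-all --seed 0 --out run/             # simulate + analyze + report
```

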