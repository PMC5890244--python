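# Methods

## The model

Mitral/tufted (MT) cells in the olfactory bulb fire in tight register
with the respiration cycle, and the duration of each inhalation
stretches or compresses the firing pattern within the cycle. Averaging
across sniffs of different durations therefore smears responses. The
package models the spiking of one cell under one stimulus condition as
an inhomogeneous Poisson process whose rate is a single log-rate
pattern over normalized sniff time — a *snifflet* ψ — dilated on each
sniff by that sniff's inhalation duration:

    r(t) = exp[ Σ_i ψ(α_i (t − τ_i)) · 1{τ_i ≤ t < τ_{i+1}} ]

where τ_i is the i-th inhalation onset, α_i = 1/d_inh,i is the dilation
factor, and the indicator resets the pattern at each new sniff. ψ is a
length K·D vector: the first D bins tile the inhalation (dilated phase
u ∈ [0, 1)), the remaining (K−1)·D bins tile the rest of the sniff
(u ∈ [1, K)); beyond u = K the rate holds at the last bin until the
next sniff resets it. Defaults D = 30, K = 4.

Assumptions worth stating explicitly:

- Poisson counts in Δ-wide time bins (Δ = 5 ms default) with an
  exponential link. The bin-to-pattern map is a nearest-bin indicator
  (piecewise-constant snifflet), evaluated at bin centers.
- No spike-history or cross-cell coupling terms.
- The pattern depends on the condition only, not on the sniff index
  (no adaptation within a condition).

Four dilation schemes are implemented for model comparison:
`inhalation` (α = 1/d_inh, the model of record), `full_sniff`
(u = K·(t−τ)/d_sniff), `two_piece` (inhalation and rest dilated
separately), and `none` (a fixed reference duration, default the median
inhalation duration of the analyzed sniffs). Cross-validated held-out
Poisson log-likelihood (interleaved sniff folds, hyperparameters
re-learned per fold) ranks the schemes.

## Inference

MAP estimation under a Gaussian smoothness prior. The prior covariance
over snifflet bins is a squared-exponential (automatic smoothness
determination) kernel

    C_jk = exp(ρ) · exp(−(j−k)² / 2δ²)

with distance measured in bin index, continuous across the
inhalation/rest boundary, plus 10⁻⁶·exp(ρ) diagonal jitter. The prior
mean is the scalar log(total spikes / total binned time), so the prior
shrinks toward the constant-rate fit and the empty-data limit returns
that constant. With fixed hyperparameters the posterior is log-concave;
damped Newton with backtracking (tolerance 10⁻⁶ on the gradient
max-norm, 100 iterations max) finds the MAP, and a Laplace
approximation supplies the posterior, of which only the marginal
variances are consumed downstream.

Hyperparameters (ρ, δ) are chosen by maximizing the Laplace-approximated
log evidence

    L(ψ̂) − ½(ψ̂−m)ᵀC⁻¹(ψ̂−m) − ½ log|C| − ½ log|H + C⁻¹|

(H the likelihood Hessian at the MAP; the (2π)^{m/2} factors of the
Laplace integral and the prior normalizer cancel, so empty data gives
log evidence exactly 0, and the expression matches direct numerical
quadrature on small problems). The search is a log-spaced 7×7 grid over
exp(ρ) ∈ [10⁻², 10] and δ ∈ [0.5, 60] bins, refined by Nelder–Mead from
the grid optimum — deterministic by construction. Large simulation
studies (the population-level tests and the acceptance script) use
`FitConfig.coarse()`: a 5×5 grid without refinement, trading a little
per-fit accuracy for throughput; single-cell analyses default to the
full search.

A one-parameter constant-rate variant (`fit_constant`) shares the
likelihood and returns its own evidence; a cell-condition is treated as
"constant-best" (and omitted from normalized-population displays) when
the constant model's evidence is at least as high as the full model's.

## Response statistics

Baseline snifflets are fitted with identical machinery on the sniffs
from the 3 s preceding each odor onset. Analysis sniffs are restricted
to inhalations longer than 100 ms (the slow mode of sniffing) and, for
odor conditions, to the first sniff after odor onset — a trial whose
first sniff is fast is excluded, not replaced by a later sniff.

The response call scans snifflet bins in order and flags the first bin
where |ψ_odor − ψ_base| > 3·√(var_odor + var_base), in log-rate space
with marginal variances only; the sign gives the polarity, the bin the
latency (reported natively in dilated phase u; multiply by a reference
inhalation duration for milliseconds). The sum of variances treats the
two posteriors as independent. No multiple-comparison correction is
applied across the K·D bins — a deliberate caveat; the null
false-call rate is instead measured empirically (≲ 5% under the
synthetic null, against a 15% design bound).

Concentration series of three calls are categorized: all
non-significant → *omitted*; both polarities present → *flipped*
(precedence over dropped, since a polarity reversal is the more
specific event); any non-significant call otherwise → *dropped*; else
*consistent*.

Normalizations: the joint cell-set normalization applies one affine
transform to all of a cell's rate curves (zero mean across odors at
inhalation onset, unit global peak); the per-peak normalization divides
rate deviations from the cell's constant-rate estimate by the largest
across-odor absolute deviation ("amplitude" — the source display does
not define its amplitude scale, so this package fixes it as the maximum
absolute rate excursion). Population curves are per-bin means ± SEM.

Hypothesis tests are delegated to scipy.stats: Pearson chi-squared
without continuity correction on 2×2 excitatory/inhibitory tables,
two-sample Kolmogorov–Smirnov on latency samples (non-responders
excluded), Wilcoxon signed-rank per odor on paired spike-count
profiles. Tests cross-check each against closed-form or brute-force
oracles.

## Optogenetic tagging

PSTHs in 4 ms bins, edges anchored at the aligning event, over
[−50, 100] ms. A cell is light-responsive if in any bin starting within
50 ms of the pulse the light-condition mean count exceeds the no-light
mean by at least one across-trial SD of the no-light condition (a
pooled-SD option exists); latency is the first such bin's start. Cells
with latencies beyond a bound — fixed 20 ms by default, or the Tukey
upper fence Q3 + 1.5·IQR with type-7 (linear interpolation) quartiles —
are excluded as likely polysynaptic. The IQR phrasing in the source is
ambiguous between the Tukey fence and 1.5·IQR from the median; the
Tukey fence is implemented and the mode is configurable.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with all randomness flowing from one master seed through
`numpy.random.SeedSequence` spawning (per cell, per condition), so any
subset regenerates identically.

- **Sniff trains**: inhalation durations from a two-component
  log-normal mixture — slow median 130 ms (weight 0.75), fast median
  60 ms (weight 0.25), σ_log 0.25 — reproducing the empirical
  bimodality in which ~75% of sniffs have inhalations > 100 ms;
  exhalations log-normal with median 180 ms; cycles abut.
- **Templates** (length K·D log-rate vectors; baseline 8 spikes/s, a
  plausible MT spontaneous rate and a free parameter): *stereotyped* —
  an early excitatory Gaussian bump (gain ≥ log 3) centered in the
  first third of the inhalation plus a small smooth tail later in the
  sniff; *diverse* — a Gaussian-process draw (length-scale D/3,
  SD 0.8), first-excursion sign random by symmetry; *inhibitory* — a
  sustained early suppression (width D/6–D/3 bins: suppression of these
  neurons is slower and broader than the sharp excitatory transient);
  *constant*/*null* — flat.
- **Spiking**: inhomogeneous Poisson by thinning against the dilated
  template rate, sniff by sniff; validated by time-rescaling (rescaled
  ISIs pass a KS test against Exp(1)).
- **Sessions**: trials of ~18 consecutive sniffs with the odor arriving
  ~3.2 s in (so 3 s of baseline sniffing precede each onset); all cells
  share the session timeline; each cell spikes from its baseline
  template except on the first sniff after odor onset, which uses the
  cell-odor-concentration template. Concentration effects are
  per-concentration (latency-shift, amplitude-scale) pairs applied to
  the template's deviation from baseline; negative scales flip
  polarity. Default 60 trials per condition — a session-scale count
  chosen by a prospective power analysis of the 3σ call (the design
  bounds of ≥80% power for ≥3× transients and ≤15% null false-call
  rate fix the needed trial count; 60 is comfortably within the range
  of awake head-fixed sessions).
- **Light trials**: a block of sniffs with pulses at every ~5th
  inhalation onset (50 pulses, 200 no-light control sniffs); tagged
  cells fire one extra spike per pulse with probability 0.8 at 6 ms
  latency (1.5 ms jitter), the time-locked response characteristic of
  direct channelrhodopsin drive. A rate-bump parameterization spread
  over tens of milliseconds was rejected: it is statistically invisible
  per 4 ms bin at session-scale trial counts, which is not how directly
  driven cells behave.

What the generator does **not** emulate: correlated noise across cells,
spike-history effects (refractoriness, bursting), adaptation across
trials, sniff-frequency changes with behavioral state, or the real
dataset's exact sniff-duration joint distribution. Passing recovery
tests therefore shows the estimator is correct under the model's own
assumptions, not that real MT data satisfy them.

## Numerical choices and degenerate inputs

- ψ is clipped at ±50 inside exponentials to avoid overflow during line
  search; the backtracking Newton accepts only non-decreasing steps.
- Empty observations return the prior-mean fit with covariance C and a
  warning flag; zero-spike conditions use a floored prior mean
  log(0.5/T).
- Ties in the preferred-phase argmax resolve to the earliest bin.
- Degenerate normalizations (no positive excursion, zero amplitude;
  rate profiles with max = baseline) raise rather than emitting NaNs.
- Cross-validation folds interleave sniff indices deterministically; a
  seed is used only when explicit shuffling is requested.

## Problem sizes

Simulation studies use sizes chosen to estimate each quantity with
adequate precision: 20 random instances for the convex-oracle check,
500 sniffs for template recovery (median over 3 replicates in the
acceptance script), 10 seeds per direction for dilation-scheme
identification (3 CV folds, coarse search), 200 cells for call
calibration and power, 40 cells for tagging accuracy, 100 instances
for test-oracle agreement.

## Known limitations

- The stationary smoothness prior must compromise between a sharp early
  transient and a flat tail; sparsely observed late-phase bins (u near
  K occurs only in sniffs with long exhalations) carry wide posteriors
  and some estimation wiggle.
- Detecting inhibition is intrinsically harder than excitation in
  log-rate space (suppression removes the spikes that carry the
  information); flipped concentration series need the full
  hyperparameter search and deep suppression to be called reliably.
- The sniff detector's threshold conventions are not a reproduction of
  any published criterion; inhalation offset on a pressure signal is
  detector-defined.
- The no-reset model variant (patterns from successive sniffs
  overlapping additively) is not implemented.
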