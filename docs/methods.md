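# Methods

## The robustness statistic

The package quantifies robustness as the negated, mean-normalised Fano
factor R = −(σ²/x̄)·(1/m). σ² and x̄ are computed within a group of
observations of one function; m is a pooled grand mean that removes the
function's scale, so R is dimensionless and invariant under rescaling the
function by any k > 0 (σ² scales as k², x̄ and m each as k). For strictly
positive functions R ≤ 0, with equality exactly when the within-group
variance is zero. Because R is normalised by the data's own grand mean it is
a *relative* measure: values are comparable within one analysis, not across
studies.

All four named modes are presets of one grouping engine. A
`GroupingScheme` names the axes the variance runs over (`within_axes`), the
axes that fix a group (`across_key`), and the axes pooled for m (`m_axes`).
Axes in neither set are nuisance axes and are averaged out first — this is
how replicates are averaged per (system, condition) before R(c)/R(s), with
mean and SD of replicate-level results taken only at the end; a
pooled-replicate variant (replicate variance entering σ²) is available via
`average_replicates=False` for sensitivity analysis.

Numerical conventions, chosen once and applied everywhere:

* **Variance**: sample (n−1) by default; `ddof=0` switches to the
  population convention. At triplicate-scale group sizes the difference is
  material, so both are exposed.
* **Zero variance** ⇒ R = 0, even when x̄ = 0. The 0/0 of an all-zero group
  (e.g. a medium in which no strain grows: every rate exactly 0 after
  censoring) is resolved to 0, reading "identically zero performance" as
  maximal stability. This is deliberate and visible in results rather than
  an error, because such groups carry real information (uniform total
  inhibition).
* **x̄ = 0 with σ² > 0** (or m = 0 with σ² > 0) has no meaningful Fano
  factor; the group is reported `missing` with a reason, never ±∞.
* **m pooling**: m always includes the focal group's own values (no
  leave-one-out). For R(t) the grand mean pools over all systems,
  conditions, replicates and timepoints of the function; the pooling axes
  are configurable (`m_axes`) because coarser or finer normalisation can
  both be argued for time-resolved signals.
* Groups smaller than the mode's minimum (2 for c/s, 3 timepoints for t,
  25 cells for p — the usual microscopy sample-size floor) are reported
  missing with a machine-readable reason, never silently dropped.

The efficiency transform (`to_efficiency`) divides yields or rates by a
theoretical maximum before computing R(s), which makes across-system
comparisons meaningful when systems do not share the same theoretical
maximum (different species); with a shared maximum it provably changes
nothing, by scale invariance.

## Growth features

`estimate_growth_features` fits ordinary least squares to ln(signal) in a
sliding window and takes the steepest well-fitting window: mu_max is the
largest slope among windows with R² ≥ `r2_min` (default 0.98) and slope ≥
`mu_min` (default 0.01 /h); lag is where that window's tangent intersects
the baseline log-signal (mean of the first 3 points), clipped to the
screening window. Windows containing non-positive signal are skipped, since
the log is undefined there.

The window default is 27 points (4.5 h at 10-min sampling). This is wider
than the window a first guess might suggest, for a quantified reason: the
slope of a short noisy window has large variance, and taking the *maximum*
over hundreds of windows turns that variance into a systematic upward bias.
At 2% multiplicative noise the median rate error is ~14% with a 9-point
window and ~2–3% with 27 points, while the window remains short relative to
a typical 20–30 h exponential phase. All thresholds are arguments.

Cultures where no window qualifies are scored `grew = False` with mu_max 0
and lag **censored at the screening duration** rather than excluded. This
keeps non-growing strains in the robustness computation — necessary for the
all-zero-group convention above to ever apply — and is flagged via the
emitted `grew` rows.

Yields are (product_end − product_0) / Σ_hexoses max(c_0 − c_end, 0), with
glucose, galactose and mannose as the consumable sugars; xylose and
arabinose never enter the denominator because the screened strains cannot
metabolise pentoses. Negative product deltas (evaporation, noise at low
titres) are floored to zero with a warning flag; zero hexose consumption is
an error, since the ratio is then meaningless.

Phase classification sets the lag interval to [0, lag_h] and ends the
exponential interval at the first window (centre time) past the mu_max
window whose local slope drops below `exp_end_fraction` × mu_max (default
0.5 — robust to plateau noise), or the final time point. Interval
membership for phase means is closed-left/open-right, with the final
interval closed on both ends, so every timepoint belongs to exactly one
phase.

## Biosensor normalisation

corrected = raw − blank − parental; ratio = corrected / corrected_reference.
The reference (normalisation construct or second wavelength) receives the
same background treatment as the signal channel, by symmetry. Points where
either corrected quantity is ≤ 0 are flagged `below_background` and
excluded, not clamped: clamping would deflate σ² and bias R(t)/R(p) toward
zero. Backgrounds may be per-timepoint series or per-screening scalars —
both conventions occur in practice. Channel direction semantics (for the
glycolytic-flux sensor, higher output means *lower* flux) are metadata;
ratios are reported as measured.

## The synthetic screening generator

The generator exists so every pipeline stage can be tested closed-loop
against known truth; it emulates the statistical structure of a
hydrolysate screening, not the biochemistry.

* **Media**: template compositions of seven lignocellulosic hydrolysates
  (four non-woody, three woody) at 100% strength, diluted linearly.
  The inhibitory burden is reduced to one scalar, a weighted sum of
  inhibitor concentrations with aldehydes weighted far above weak acids
  (furfural 1.0, HMF 0.7, formic 0.15, acetic/levulinic 0.10 per g/L),
  reflecting their relative growth toxicity to *S. cerevisiae*.
* **Growth**: flat at the inoculum (0.02 a.u.) through the lag, then
  logistic at rate mu_base·exp(−sensitivity·load) toward a carrying
  capacity of 100 a.u., with mean-preserving multiplicative log-normal
  noise (default CV 2%, typical of scattered-light readouts). The logistic
  was chosen for its closed-form local rate, which gives analytic oracles
  for phase classification. The wide capacity-to-inoculum ratio keeps an
  extended truly-exponential regime so the window estimator's recovery can
  be asserted to 0.1% on noiseless curves. Rates below 0.05 /h produce
  flat noisy curves (no growth); lag lengthens with load as
  lag_base·(1 + 0.6·load).
* **Endpoints**: t0/t_end concentration rows exactly consistent with the
  true yields (ethanol 0.40–0.44, glycerol 0.05–0.07, cell mass 0.10 g/g
  among the default strains; 97% hexose consumption when grown, none
  otherwise), so yield recovery is exact at zero noise.
* **Biosensors**: each channel's true ratio moves smoothly (logistic in
  time, 1 h time constant) from a lag level to an exponential level around
  the strain's lag end; raw/blank/parental/reference rows are emitted so
  `correct_and_normalize` reconstructs the true ratio exactly at zero
  noise. Stress channels shift with medium origin: woody media (weak-acid
  rich) raise the unfolded-protein response, non-woody media (aldehyde
  rich) raise the oxidative-stress response, most strongly in exponential
  phase (×1.5 exponential level, ×1.2 lag level).
* **Single cells**: per-cell values are drawn from 1- or 2-component
  log-normal mixtures around the channel's bulk level; paired dual-readout
  channels (glycolytic flux + OxSR, ribosome + UPR) share the component
  draw and correlate on the log scale within a component, producing the
  two-cloud scatter structure of genuinely heterogeneous populations.
  Ground truth records every cell's component.

What the generator does **not** emulate: mechanistic metabolism (no
diauxie, no Crabtree switch beyond phase-dependent levels), per-compound
inhibition kinetics, instrument drift or well-position effects,
chromophore maturation, or cell-cycle structure in the single-cell
mixtures. Passing closed-loop tests therefore demonstrates that the
*computations* are correct and that injected orderings are recoverable at
realistic noise levels — not that real hydrolysate screenings will be this
well behaved.

## Problem sizes used in verification

The oracle-equivalence checks run every robustness mode against an
independent explicit-loop implementation on 1,000 random tables (2–6
systems × 2–8 conditions × 2–4 replicates, plus time series and cell
snapshots) at 1e-12 tolerance. Recovery rates are measured over 100 seeds:
condition-robustness ranking with cross-condition CVs of 5% vs 30% over
6 conditions × 3 replicates, and population-heterogeneity ordering with
200 cells against an equal-weight mixture at component-mean ratio 2.0 and
component CV 5%. Growth-feature recovery uses 48-h curves sampled every
10 min (289 points) at mu 0.35 /h and lag 4 h, noiseless and at 2% noise.

## Known limitations

* The lag definition (tangent intercept at the initial baseline) is one of
  several in use; estimates from other conventions (e.g. threshold
  crossing) differ systematically by up to a few sampling intervals.
* R carries no uncertainty estimate; with triplicate groups a confidence
  interval on σ²/x̄ would be very wide, and the statistic is intended for
  ranking within a screening rather than formal inference.
* The population mode treats `cell_id` values as unique within a sample;
  identically numbered cells from different samples are distinguished by
  the group key, but duplicated ids *within* one sample would be averaged.
* The grouping engine averages nuisance axes with equal weights; unbalanced
  designs (unequal replicate counts) are therefore averaged per key, not
  weighted by count.
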