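# Methods

`pausekit` analyses how transcriptional pausing by RNA polymerase (RNAP)
changes between two experimental conditions — typically with and without a
trailing, translating ribosome ("coupling") — from three kinds of data:
bulk gel time courses, single-molecule optical-tweezers records, and
consensus-read base counts. A synthetic-data module generates each input
with the statistical structure the estimators assume, so every stage of
the pipeline is testable end to end without instrument data.

## The pause competition model

At a pause-prone template position, on-pathway nucleotide addition (rate
`kn`, s⁻¹) competes with entry into an off-pathway paused state (rate
`kp`). The pause efficiency is the branching ratio

    E = kp / (kp + kn)

A paused RNAP escapes with intrinsic rate `k₋p` back to the
elongation-competent state, where it faces the same branching again.
Pause re-entry lengthens the ensemble-observed (apparent) pause duration:

    T_app = (1/k₋p) / (1 − E),   equivalently  k₋p,app = k₋p (1 − E)

so a drop in E between conditions predicts a duration fold change of
`(1 − E₊)/(1 − E₋)` even when `k₋p` itself is unchanged. The slow paused
state may deepen into a longer-lived "sluggish" state (rate
`k_slow_to_sluggish`, escape `k_sluggish_escape`); this sequential
topology produces the biphasic ensemble decays the two-segment gel fit
resolves. Whether the sluggish state escapes back through the slow state
or directly to elongation is not distinguishable from the data analysed
here; the simulator defaults to direct escape to the elongation-competent
state (after which the molecule re-competes), and the closed forms do not
depend on the choice.

All rates are per second internally. Gel-facing quantities are reported
in the unit of the supplied timepoints (minutes for the worked examples),
declared in the gel CSV header.

## Synthetic data: what it emulates, what it does not

* **Trajectories** are exact event-driven simulations: exponential dwells
  at every position (site-specific `kn` overrides model slow sites under
  limiting rNTP), Gillespie branching at pause sites, re-entry after
  escape, Bernoulli termination at a terminator position. Trajectories
  unfinished at `t_max` are censored.
* **Gels** bin trajectory positions per timepoint into a band × lane
  count matrix; terminated/runoff molecules accumulate in dedicated
  bands. Quantification noise is multiplicative lognormal at CV 10% by
  default — a plausible figure for phosphorimager densitometry.
  Not emulated: background smear, band bleed-through, loading variation
  beyond the per-cell noise (lane totals are implicitly corrected by the
  normalisation anyway).
* **Tweezers records** push a trajectory through the extensible
  worm-like-chain (WLC) forward model at a constant held force, sampled
  at 1333 Hz with white Gaussian noise. Not emulated: drift, bead
  rotation, trap-stiffness miscalibration, force fluctuations — so
  passing recovery tests bound estimator error under ideal instrument
  conditions only.
* **Restart times** scatter lognormally (σ_log 0.5 by default, matching
  an order-of-magnitude spread across tethers) around the piecewise
  Arrhenius median.
* **Base counts** draw per-position errors independently per read, so
  per-read mismatch totals follow the product (Poisson-binomial) model;
  UMI-consensus artefacts and alignment errors are upstream and not
  modelled.

Fixed seeds give bit-identical outputs; the CLI forks one root seed into
named substreams per stage so adding a stage never perturbs another.

## Gel kinetics

Band intensities are normalised per lane to the lane total. The pause
fraction P/T decays as `P₀ e^(−k₋p,app t)`; ordinary least squares on
log₁₀(P/T) versus t gives the apparent escape rate (−slope·ln 10) and the
efficiency (10^intercept). Because not every molecule reaches the site
within the assay, the cumulative fraction at-or-beyond the site (A/T) is
fit to a saturating exponential `F·(1 − e^(−t/τ))`; dividing the raw
intercept by the plateau F gives the arrival-corrected efficiency
(capped and flagged at 1). The arrival functional form is a choice — only
half-maximal times are compared — and the half-time is τ·ln 2.

Biphasic (slow + sluggish) decays are fit by a breakpoint grid search:
every split leaving ≥3 points per segment is tried; within each, the late
segment is fit to the raw log-fractions, its extrapolation subtracted
from the early fractions, and the early segment fit to the log residual
(classic exponential peeling, iterated 4×); the split minimising the SSE
of the summed two-exponential model wins. Peeling is used rather than two
independent raw-segment lines because the early raw slope conflates the
sluggish component — on noiseless mixtures the raw-segment variant
mis-estimates the fast duration by tens of percent, while peeling
recovers both amplitudes and durations to ~0.1%. It also makes the two
intercepts the populations' own amplitudes, which is how the worked
examples tabulate them (slow 35.9% + sluggish 6.8% = total 42.7%).
A small-sample AIC comparison against a single line flags degenerate
(single-exponential, equal-rate, or amplitude-inverted) fits, which then
carry the single-line estimate. Non-positive fractions are dropped (not
clamped) before the log transform. Confidence intervals are nonparametric
bootstrap over timepoints.

The semilog method assumes arrival is fast compared with pause escape;
when the two timescales are comparable the intercept is biased upward by
the arrival convolution. The end-to-end recovery study therefore uses an
elongation rate (5 s⁻¹ over 40 nt) that keeps arrival (~8 s) well below
the pause decay (~2–4 min); condition *contrasts* (rescue fraction,
duration fold) partially cancel the residual bias.

## Trace analysis

* **WLC conversion.** Extension x relates to contour length L through the
  interpolation-formula extensible WLC,
  `x/L = 1 − ½√(kBT/(F·Lp)) + F/K`. Defaults are standard dsDNA values:
  Lp = 45 nm, K = 1200 pN, kBT = 4.11 pN·nm (25 °C), rise 0.34 nm/bp;
  ~3000 bp of handles set the baseline contour. Because the fractional
  extension is independent of L, the inversion is exact (round trip
  < 1e−9). Assisting/opposing geometries differ only in the sign with
  which transcription changes the tether length.
* **Staircase HMM.** Hidden states are integer bp positions; transitions
  are restricted to {stay, +1} with a per-sample step probability set
  from the expected step count; emissions are Gaussian with SD estimated
  from the MAD of first differences; Viterbi decoding returns a monotone
  path (a clearly decreasing signal is rejected — monotonicity is the
  model's contract). At acquisition noise of ~1 nm per 1333 Hz sample
  (≈3 bp), single-sample step timing is not information-theoretically
  attainable; an optional block-averaging decimation (e.g. 10–20
  samples) trades time resolution for SNR. Measured performance, frozen
  in the tests: noiseless staircases are recovered exactly; at 1 bp-
  equivalent noise with 10-sample decimation ≥95% of interior step times
  of ≥60 ms dwells land within 2 analysis samples; at 1 nm noise with
  20-sample decimation ≥90% land within 75 ms.
* **Pauses and pause-free velocity.** Dwells longer than 0.5 s are
  pauses; density is pauses per bp transcribed; the first and last dwells
  (stall and truncation) are excluded by default. Velocities come from a
  first-order Savitzky–Golay differentiator (window = nearest odd sample
  count to 150 ms; 201 samples at 1333 Hz), pause samples removed,
  histogrammed at 0.25 bp/s and fit with two Gaussians — one pinned at
  zero for residual sub-threshold pauses, one at positive velocity whose
  mean is the PFV. A fit whose moving component collapses onto zero is
  flagged undefined rather than reported. Whether the histogram is of
  counts or densities does not affect the fitted means; counts are used.
* **Pause sites and crossing times.** Pause loci are peaks (prominence
  ≥ 5× the median positive residence by default) of the pooled 1-bp
  residence-time histogram of start-aligned traces, optionally restricted
  to a region to avoid stall artefacts. Crossing times are measured
  through a ±2.5 bp window around the locus (entry at first arrival at
  the lower edge, exit at first position beyond the upper edge); traces
  that never exit are censored, excluded from the fit, and counted so
  users can assess bias.
* **Crossing-time mixture.** Durations are fit by maximum likelihood to
  `a₁k₁e^(−k₁t) + a₂k₂e^(−k₂t)` with `a₁+a₂ = 1`, `k₁ > k₂` (enforced by
  parametrising k₂ as a fraction of k₁), multi-start BFGS from
  moment-based and randomised initial points. E = a₂ and τ = 1/k₂. AIC
  against a single exponential plus boundary checks flag degenerate fits.
  No offset models the instrument-limited minimum transit; at the window
  widths used the fast component absorbs it.

## Restart under force

A backtracked, mismatch-bearing RNAP restarts in a median time following
a Bell/Arrhenius law that saturates above Fmax:

    t(F) = t₀·exp(−F·dx/kBT)  for F < Fmax,  constant beyond

Fitting is a bilinear least-squares fit of ln t on the regressor
min(F, knot) — a line of slope −dx/kBT followed by a flat segment,
continuous at the knot — with the knot found by grid search at 0.25 pN
over the observed force range. kBT defaults to 4.11 pN·nm. dx/0.34 nm
converts the transition-state distance to a backtrack depth in
nucleotides. Per-force medians are reported alongside (the natural
summary of lognormal scatter), but the fit uses all points. Bootstrap
CIs resample observations; both 90% and 95% levels are reported. At the
reference design (forces 3–15 pN, ~10 tethers per force, σ_log 0.5) the
estimator is unbiased with a sampling SD of ~23 s on t₀ and ~0.13 nm on
dx (measured over 40 simulated experiments).

## Misincorporation statistics

Per position, the error fraction is the non-reference count over
coverage; the two conditions are contrasted by the relative percent
error, `100·(p₊ − p₋)/p₋` (a ratio variant `100·p₊/p₋` is available),
undefined (NaN, never silent infinity) when the baseline is zero. Each
position's 2×2 (error, correct) × (plus, minus) table gets a two-sided
Fisher exact p-value; a position is called significant when p < 0.05
*and* the error increased — the upper-right region of a volcano plot. Raw
p-values are used by default (Benjamini–Hochberg is deliberately not
applied, matching the reference analysis); U and T are synonyms at the IO
boundary. The mismatch burden reports fractions of reads with 0/1/2/3/>3
mismatches and the fraction with ≥1.

## Problem sizes and numerical choices

Recovery studies in the test suite use sizes at which the estimators'
sampling error is well characterised: 100 replicate gel fits at 12
timepoints and 5% noise; 300 crossing times for the mixture MLE; 70
restart observations; trajectory ensembles of 1.5–8×10³ molecules;
base-count depths of 5×10³–10⁴. Tolerances follow from propagated
binomial/Monte-Carlo standard errors (typically 2–3 SE), not from fixed
percentages. Degenerate inputs (zero lanes, zero coverage, non-monotone
signals, all-censored windows) raise or warn explicitly rather than
returning silent values.

## Known limitations

* The gel estimators assume well-separated arrival and escape
  timescales; no deconvolution is attempted.
* Censored crossing times are excluded, not modelled, so heavy censoring
  biases E downward.
* The staircase HMM assumes strictly forward 1-bp steps; backtracks
  appear as long dwells, not negative steps.
* The restart fit treats the knot grid resolution (0.25 pN) as exact;
  Fmax is only identified to that grid.
* Fisher calls are per-position and uncorrected by design; genome-scale
  use should enable the BH option.
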