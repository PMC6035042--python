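# Methods

## The experiment the package models

In a colocalization single-molecule spectroscopy (CoSMoS) experiment,
RNA molecules are tethered sparsely on a passivated slide surface and a
nuclear extract containing a dye-labeled factor — here a spliceosomal
subcomplex such as U1, U2 or U5 — flows over them. Under alternating-laser
TIRF illumination, a binding event appears as a fluorescent spot
colocalized with a known RNA position; a per-location binary time series of
presence/absence is the primary data. Several RNA species can be deposited
sequentially on one surface and identified by per-round imaging, so their
kinetics are measured under identical conditions, and surface positions
with no RNA serve as controls for nonspecific binding.

The package has three layers: a forward simulator with retained ground
truth (`simulate`, `params`, `acquisition`), interval extraction and I/O
(`traces`, `containers`), and the statistics computed from interval tables
(`stats`), orchestrated by `pipeline` and a thin CLI. An optional image
layer (`imaging`) renders synthetic movies and recovers events by spot
detection, mimicking the acquisition/analysis chain of a real instrument.

## Kinetic model of the simulator

Specific binding at each competent RNA location is an alternating renewal
process: waiting times to the next association are exponential with rate
`k_assoc` (events·location⁻¹·s⁻¹), dwell times are drawn from an
exponential mixture `Σ wᵢ Exp(1/τᵢ)`. The default mixture has a short
(seconds) and a long (>50 s) component, the canonical phenomenology of
transient sampling versus stable engagement. This is deliberately **not** a
multi-state assembly CTMC: a memoryless association process is the simplest
model that generates every statistic the analysis layer computes, and the
ordering/gating of real subcomplex recruitment is unknown. Nothing in the
estimators depends on this choice.

The construct resolves the association rate through its splice-site flags:
zero with no functional 5' splice site (or with a mutated branch-site/3'SS
block when `requires_branch_site` is set, appropriate for a U2-like factor
recruited to the branch site), the base rate with one functional 5'SS, and
`synergy_factor × 2 × k_assoc` with both. The factor multiplies the
*additive* two-site rate, so the frequency ratio
`R = f_both / (f_up + f_down)` recovers it directly and `synergy_factor =
1` is the additivity null.

Superposed on every location — including no-RNA controls — is a second
renewal process of short-lived nonspecific surface binding
(`k_assoc_nonspecific`, single-exponential dwell). Each binder is dye-
labeled with probability `labeling_fraction` (defaults follow measured
labeling of tagged subcomplex pools: 0.3–0.6); only labeled, unbleached
binders are visible. Photobleaching is exponential in cumulative
green-excitation *dose*, which accrues only during green frames of the
alternating schedule. A fraction `frac_active` of RNA locations is
competent for specific binding; the rest (surface-damaged or misfolded
molecules) show only nonspecific events.

Default parameters:

| parameter | default | unit | rationale |
|---|---|---|---|
| `k_assoc_specific` | 5×10⁻⁴ | s⁻¹ | ~1 specific event/RNA per 2,400 s, typical of U2-class recruitment |
| `dwell_mixture` | 0.7·Exp(8 s) + 0.3·Exp(120 s) | — | short sampling + long engagement classes straddling the 50 s split |
| `k_assoc_nonspecific` | 10⁻⁴ | s⁻¹ | sparse short background events at all locations |
| `nonspecific_mean_dwell` | 3 | s | nonspecific events are short-lived |
| `labeling_fraction` | 0.6 | — | measured labeling of the U2-associated tagged pool |
| `bleach_rate` | 10⁻⁴ | s⁻¹ dose | visible loss of long dwells without dominating them |
| `frac_active` | 0.8 | — | not every tethered molecule binds during an experiment |
| `synergy_factor` | 1 | — | additive null unless a synergy is being simulated |

## Acquisition schedule and discretization

The default schedule is 2,400 one-second frames: blocks of 100 green
(factor-channel) frames separated by a single red (RNA-channel) frame. Red
interleaves carry no green data and are treated as *missing*, never as
absence. A frame is scored "present" iff the union of dye-visible spans
overlaps at least 50% of the frame — a concrete, testable discretization
rule. Presence runs separated only by missing frames are merged when
extracting intervals, so a red interleave cannot split one binding event in
two; the merged dwell includes the gap.

Intervals are closed on the left, open on the right, in seconds. An
interval touching the first/last observed frame is left-/right-censored:
its true dwell exceeds the observed span.

## Statistics

**Cumulative dwell distribution.** For construct with N observed locations,
`value(t) = |{intervals with dwell ≥ t}| / N`. The intercept `value(0)` is
the mean number of events per location over the experiment. Censored
intervals enter with their observed span: their true dwell is at least that
long, so they count toward every threshold up to the span and are assumed
nothing beyond it (configurable; how censored dwells should enter these
tails is genuinely open, and the minimal treatment avoids extrapolation).

**Specific binding frequency.** RNA-minus-control difference of the
intercepts, i.e. of mean per-location event counts, optionally divided by
the observed duration to give events·location⁻¹·s⁻¹. Both unit conventions
are computed throughout because per-molecule-per-experiment totals and
per-second rates are both in common use and their ratio to occupancy lands
on different scales.

**Specific occupancy.** With `f_m`/`f_c` the mean fractions of observed
(non-missing) time a spot is present at RNA/control locations,
`occupancy = (f_m − f_c) / (1 − f_c)`. If specific and background binding
are independent, `E[f_m] = s + c − s·c`, making the correction exactly
unbiased for the specific occupancy `s`. The estimate is reported unclamped
(sampling noise can push it below zero). It deliberately *under*-estimates
true occupancy by the labeling fraction, which cancels in comparisons
between constructs measured with the same extract.

**Bootstrap errors.** The resampling unit is always the surface location —
the independent experimental unit — never the event. 2,000 resamples by
default; SE is the SD of the resampled statistics, CIs are 2.5/97.5
percentiles. Compound statistics (occupancy, synergy ratio) resample every
constituent location group independently in each draw.

**Time to first binding.** Per location, the start of the earliest
interval, censored at the observation end if none. The cumulative fraction
bound is fit by maximum likelihood to a background-corrected single
exponential,

    P(t) = A_f (1 − e^{−(k_f + k_bg) t}) + (1 − A_f)(1 − e^{−k_bg t}),

where an active fraction `A_f` binds specifically at `k_f` on top of the
background `k_bg`, and the inactive remainder acquires background events
only. `k_bg` is first estimated from control locations by the censored
exponential MLE (events / total time at risk), then held fixed. Censored
locations contribute survival terms `log S(t)`, avoiding the upward rate
bias of ignoring never-binders. The exact likelihood of the underlying
published background-correction is not printed anywhere accessible, so this
parameterization is documented here and isolated in one function
(`_first_binding_nll`) to be swappable. Optimization is bounded L-BFGS-B
with moment-based initialization; SEs come from the numerically inverted
observed information.

**Synergy ratio.** `R = f_both / (f_up + f_down)` with a joint bootstrap
CI; draws with non-positive denominators are discarded and counted. R = 1
is additivity; the experimentally interesting regime is R > 2.5.

**Intron retention.** The two-color splicing readout conditions on
molecules retaining the exon dye through the entire experiment (removing
degradation/green-bleaching losses from N), then reports the fraction of
that subset retaining the intron dye at each red-frame time, with binomial
SE. Intron-dye photobleaching sets the floor measured in the no-ATP
control; defaults emulate a 40-minute experiment with a ~20% splicing-
competent fraction, lag 600 s, rate 1/600 s⁻¹ and a bleach hazard putting
the no-ATP loss near 1%.

**Rastergrams.** Rows sorted by first-binding time latest→earliest with
never-bound rows on top and ties broken by location id, so output is
reproducible under input shuffling; percent bound carries a binomial SE.

## Image-level layer

The forward model renders each visible dye as a symmetric 2-D Gaussian PSF
(integral = amplitude in photons) over a uniform background, applies
Poisson shot noise and Gaussian read noise, and adds bright persistent
fiducial beads used for drift estimation. Beads are placed away from
tethered molecules (10 px clearance by default) since a bead's PSF tail
otherwise masks dim neighbors — matching practice, where locations near
fiducials are excluded. Recovery averages frames with a five-frame sliding
window, applies a Gaussian matched filter after median background
subtraction, takes local maxima above threshold with centroid sub-pixel
refinement, and assigns spots to the nearest known location within a
radius of 1.5 PSF σ. Drift is the gap-interpolated mean fiducial
displacement; channel registration is a least-squares affine fit of bead
pairs. Detection thresholds and the colocalization radius are calibrated
on synthetic data only; coordinates are 0-based, pixel-center, x→column.

## What the simulator does and does not emulate

It emulates: several RNA species plus controls on one surface, the
alternating 100 green / 1 red frame schedule, exponential-mixture dwells,
partial labeling, dose-dependent photobleaching, nonspecific surface
binding, inactive molecules, field-edge and fiducial-proximity exclusion,
and (in the image layer) PSF, noise, drift and fiducials. It does not
emulate: sequence-dependent kinetics, multi-state assembly pathways and
their memory, dye blinking, spot-detection dropouts on real images,
surface heterogeneity beyond a binary active/inactive split, or stage
drift nonlinearities. Passing recovery tests therefore demonstrates the
estimators are correct for data of this structure, not that real-extract
kinetics follow the generating model.

## Problem sizes and numerical choices

Recovery experiments use 100 RNA + 100 control locations per panel over the
full 2,400 s schedule and 50 replicates — enough for per-replicate
bootstrap SEs of ~10–20% and stable coverage counts; replicate-loop
bootstraps use 500 resamples while single reported experiments use the
full 2,000. The imaging round trip uses a 20×20 µm field (125×125 px at
0.16 µm/px), 240 s and 40 locations at peak SNR 5. Degenerate inputs are
errors, not silent values: fewer than 2 locations for a bootstrap, empty
conditioning sets, `f_c = 1`, non-positive synergy denominators, zero
observed time. All-censored first-binding data yields `A_f = 0` with a
warning. Every RNG stream derives from an explicit seed; per-location
streams hash (master seed, location id) so results do not depend on
iteration order.

## Known limitations

- Frequencies and occupancies are conditional on the labeling fraction;
  only their ratio is labeling-free.
- The dwell-distribution treatment of censored intervals is minimal rather
  than a survival-model correction (no Kaplan–Meier tail reconstruction).
- The renewal model slightly saturates event counts at high rates
  (expected events ≈ T/(1/k + τ̄)), so frequency-based synergy point
  estimates sit a few percent below the encoded factor at the default
  rates; the bootstrap CI covers it.
- The MATLAB interval-container reader is best-effort against the layout
  documented in `docs/schemas.md`; containers from other tools may need
  field-name adjustments.
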