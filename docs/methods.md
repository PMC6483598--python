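# Methods

This note documents the models behind `clockscreen`, the choices made where
the underlying procedures are underdetermined, and what the synthetic-data
generator does and does not emulate.

## Rhythm model and FFT-NLLS

A seedling's luminescence trace over hours t (since the first dawn of
constant light) is modelled as

    x(t) = b0 + b1*t + sum_k a_k cos(2*pi*(t - phi_k)/tau_k) + noise,

fit by iterated seeding and joint refitting:

1. the residual of the current model is projected onto a dense frequency
   grid (least-squares cosine/sine projection, equivalent to the classical
   periodogram on uniform grids but valid for gapped sampling — traces are
   never resampled, actual timestamps are used);
2. the dominant peak seeds a new component (tau, a, phi), and all
   parameters, including the linear baseline, are refit jointly with a
   bounded trust-region least-squares solver using an analytic Jacobian;
3. iteration stops when the newest component's amplitude is not
   distinguishable from zero, or after `max_components` (default 6).

**Significance and RAE.** The cited family of rhythm-analysis tools judges
a component significant when the *joint* confidence region over all fitted
parameters excludes zero amplitude, and defines the relative amplitude
error (RAE) as the ratio of the amplitude's confidence half-width to the
amplitude. We approximate the joint region from the linearized covariance
at the optimum: the marginal standard error of an amplitude is scaled by
sqrt(p * F(0.95; p, n - p)) with p the number of fitted parameters — the
classical projection of the joint ellipsoid onto one axis. This
approximation matters: a marginal t-interval is ~3x narrower at typical p
and lets the strongest spectral peak of pure noise masquerade as a rhythm
(RAE < 0.6), whereas the joint scaling drives noise fits toward RAE ≈ 1.
The approximation is tolerance-tested against brute-force grid-search
profiles in the test suite. Numerical RAE values may still differ slightly
from legacy BRASS/Biodare2 output, whose exact confidence construction is
not published alongside the screen.

**Component selection.** Among fitted components with period inside the
circadian window — default [15, 35] h, a common analysis convention, since
the window used in the original runs is unstated — the component with the
lowest RAE is selected; ties (to 1e-12) go to the larger amplitude. No
in-window component means arrhythmic by construction. A seedling is
arrhythmic when RAE strictly exceeds 0.6; RAE = 0.6 exactly is rhythmic.

**Frequency-separation guard.** A new seed must lie at least 0.8/span in
frequency from every accepted component. Without this, two cosines at
nearly identical frequencies "beat" to imitate the amplitude decay of a
damped rhythm, destabilizing both period and phase; 0.8/span is just under
the spectral resolution limit, so genuinely distinct rhythms (e.g. a 12 h
harmonic next to a 24 h carrier) are unaffected.

**Phase convention.** Phase is the time of the selected component's first
peak after t = 0 (hours after the first dawn of constant light), reported
in [0, tau); all phase arithmetic is circular modulo tau.

**Degenerate inputs.** Ingested luminescence traces need >= 24 samples;
the fitter itself accepts >= 8 samples (qPCR expression series have 17) but
refuses traces spanning less than one period at the window's low edge.
Optimizer failure yields a flagged, unselected fit rather than an
exception; such plants are counted as failed and excluded downstream with a
log entry.

## Screen statistics

- **QC:** a batch passes iff the sample SD (ddof = 1) of its concurrent
  control periods is strictly below 0.75 h. Failing batches contribute
  nothing downstream; their plants are marked `excluded-QC`.
- **Normalization:** within a passing batch the control mean of a metric is
  subtracted from every plant, controls included (their normalized mean is
  0 by construction, making normalization idempotent). Arrhythmic plants
  (RAE > 0.6, or failed fits) are excluded *before* the control mean is
  computed — their period/phase estimates are meaningless — and each
  exclusion is logged.
- **Hit calling:** two-sided Welch's t-test (Satterthwaite degrees of
  freedom) of a population's normalized values against the control pool:
  normalized wildtype plants for period, the entire normalized decoy set
  for phase (the screen's convention, which cancels the general phase shift
  that transgene expression itself causes). The family-wise level
  alpha_family (default 0.05) is Bonferroni-divided by m_tests, defaulting
  to the number of populations in the run — family sizes are inferred from
  the input, never hard-coded, since different libraries were analyzed as
  independent families. Detected subpopulations are additional tests
  against the *same* corrected alpha. Populations with n < 2 are reported
  untestable, never significant.
- **Effect classes:** significant hits are `major` when |mean difference|
  exceeds 1 h (period) or 2 h (phase), else `minor`. A population with two
  or more arrhythmic plants is flagged `arrhythmic-candidate` at pipeline
  level — a possible rhythmicity (rather than period/phase) regulator.
- Phase differences are treated as linear quantities after subtraction,
  matching the normalization convention; this understates differences near
  half a period, a documented limitation of the subtraction-based design.

## Subpopulation detection

Normalized period values are binned into half-open uniform bins
[edge, edge + width) anchored at 0 (the control mean); a value exactly on
an edge joins the upper bin. Default width 0.5 h — the original script's
bin width is not published, so the width is an exposed configuration knob.
Peaks are bins strictly exceeding both neighbours (boundary bins compare to
their single neighbour; the leftmost bin of an equal-count plateau is the
candidate). Troughs are the minimum-count bins between consecutive peaks
(leftmost on ties); a trough bin's members belong to the group on its left.

Peaks are discarded when (a) they hold fewer than `min_n` = 3 seedlings
between flanking troughs, (b) only one bin separates them from another
peak, or (c) the peak count minus the *higher* of its two flanking trough
counts is below `min_prominence` = 3. Whether the original rule compared
against one or both troughs is unrecoverable from the text; comparing
against the higher trough is the conservative reading — it discards
shoulders while retaining genuinely separated modes. Segments beyond the
outermost peaks act as flanking troughs (empty space outside the histogram
counts 0). Discarding proceeds iteratively, weakest peak first; membership
is conserved because regions re-tile after every removal, with the deepest
trough of a merged gap surviving as the division. Two or more survivors
make the population multimodal; each surviving group is forwarded as a
subpopulation test.

## qPCR quantification

ΔCT(t) = CT_target(t) − CT_reference(t); ΔΔCT is taken against the
replicate's own reference point — the first local maximum of −ΔCT, ties to
the earliest timepoint, with a warning (and the global maximum) for
monotone series; rel = 2^−ΔΔCT, exactly 1 at the reference point. Adding a
constant to both channels' CT leaves rel unchanged. Non-finite CT values
drop their timepoint with a log entry.

Genotype comparisons fit each replicate's expression series with the same
FFT-NLLS machinery, exclude arrhythmic replicates (RAE > 0.6), and compare
phases replicate-wise by Welch's t-test at alpha_family/m_tests (default
0.05/3 ≈ 1.67e-2, the three-readout family). Phases are compared on the
circle: all values are unwrapped into the half-period interval around the
reference genotype's phase, and the reported difference is the signed
minimal-magnitude difference modulo the mean fitted period. Phases are kept
in absolute hours (not rescaled to a 24 h circadian scale) — the choice is
documented here because the original platform's convention is unstated.
Amplitude comparisons follow the same procedure without circular handling
and report effect + p-value; with three replicates they are often
underpowered, and the package does not pretend otherwise.

## Synthetic data

`simulate_trace` draws x(t) = baseline + trend·t + amplitude·e^(−λt)·
cos(2π(t−φ)/τ) + N(0, σ²) hourly over 120 h. Defaults: baseline 100,
trend −0.05 h⁻¹ (slow signal decay), amplitude 20, τ 24.2 h, damping
λ = 0.005 h⁻¹ (the gentle amplitude decay of long constant-light
recordings), σ = 4 (signal-to-noise ≈ 5). `simulate_screen` draws per-plant
periods/phases per population spec — control and decoy period SD 0.4 h
(comfortably inside the 0.75 h QC bound, as typical control batches are),
20 plants per population, mixture subgroups with SD 0.2 h (insertion-effect
classes are tight), periods truncated to [15, 35] h to stay inside the fit
window — and can emit either raw traces or the per-plant metric table
directly, plus a ground-truth table sufficient to score every downstream
call. `simulate_qpcr` emulates 3 biological replicates sampled every 3 h
over 48 h: reference CT constant + noise, target CT offset by a cosine in
log2 expression (default amplitude 2 log2-units ≈ 16-fold peak-to-trough),
CT noise SD 0.15 cycles.

All generators are pure functions of (spec, seed). What they do *not*
emulate: plate-position and optical effects, luciferin-availability
artifacts, non-Gaussian and temporally correlated noise, waveform
asymmetry of real clock reporters, or amplitude heterogeneity between
subpopulation and bulk plants. Passing tests therefore demonstrate the
statistical machinery is correct under the declared generating model, not
that real screens are free of systematic artifacts.

## Problem sizes and numerical choices

The verification suite exercises: 50 noiseless traces against a 0.01 h
grid-search period oracle (agreement within one grid step); 200 noisy
damped traces at SNR 5 (median period error < 0.2 h, median circular phase
error < 0.5 h) plus 100 pure-noise traces (≥ 95% arrhythmic); 1000 null
screen families of 20 × 20 for the family-wise error rate and 100 screens
with a planted +1.5 h effect for power; the 55/5 bimodal subpopulation
pattern; and 3-replicate qPCR with a planted 6 h phase delay. Screen-level
statistics run on drawn metric tables (the statistics do not depend on the
trace fitter, which is validated separately); end-to-end trace→hit runs use
smaller designs. The optimizer is scipy's trust-region reflective
least-squares with analytic Jacobians, period bounds [max(1.5·Δt, 2) h,
3·span], amplitude sign normalized into phase, and x-scaling from the
Jacobian; spectra use 8× zero-pad-equivalent frequency resolution capped
below the (pseudo-)Nyquist frequency, where the sine projection of a
uniform grid degenerates.

## Known limitations

- RAE values approximate joint-confidence RAE via a linearization; heavily
  damped or short traces can shift calls near the 0.6 boundary relative to
  legacy tools.
- Linear (non-circular) phase normalization in the screen stage biases
  |differences| near half a period toward zero.
- The histogram detector's bin width (0.5 h) and prominence reading are
  declared defaults, not recovered from the original supplemental script;
  both are configurable.
- Welch's t-test treats plants within a population as exchangeable; batch
  structure beyond the concurrent-control subtraction (e.g. shared plate
  effects) is not modelled.
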