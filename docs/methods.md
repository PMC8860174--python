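# Methods

## Problem and model

An epiretinal prosthesis stimulates retinal ganglion cells (RGCs)
through a multi-electrode array (MEA). Current passed through one
electrode can also depolarize axons of distant RGCs bundled in the nerve
fiber layer. Because the somas of those cells lie off the array, their
contribution to perception cannot be mapped, and their activation
produces poorly controlled, elongated percepts. The *bundle threshold*
`b(e_s)` of a stimulating electrode `e_s` is the lowest current
amplitude at which such off-array (axonal) activation occurs; a
calibration procedure that knows `b(e_s)` for every electrode can keep
stimulation below it.

A recorded voltage trace is modeled as the sum of four independent
components, `y = x + i + s + n`: electrically evoked activity `x`, the
stimulation artifact `i`, spontaneous RGC spiking `s`, and recording
noise `n`. Detection isolates `x` using three physiological
regularities:

1. **Precise spike timing.** Electrically evoked spikes occur at a
   consistent sub-millisecond latency with ~0.1 ms trial-to-trial
   variability, while spontaneous spikes and noise minima are random in
   time relative to the stimulus.
2. **Monotone response.** Over the tested range (0.1–4.1 μA), if a
   reliable evoked spike is recorded at one amplitude, it is also
   recorded at higher amplitudes.
3. **Bidirectional axonal propagation.** An activated axon bundle
   conducts in both directions and, because peripheral bundles run in
   nearly straight lines, the evoked activity reaches at least two
   borders of the rectangular array.

## The detection algorithm

Per stimulating electrode, with voltage tensor `V[a, r, e_r, t]`
(amplitude, repeat, recording electrode, sample):

1. **Artifact subtraction.** `v = V[a] − mean_r V[a_min]` for every
   amplitude `a > a_min`. The artifact is repeat-independent for a fixed
   pulse, so the mean at the lowest amplitude estimates it; the estimate
   is deliberately not rescaled with amplitude (rescaling was found not
   to change outcomes, and an unscaled estimate needs no artifact
   model). The lowest amplitude is consumed as the reference and is not
   a candidate threshold.
2. **Spike times.** `t[a, r, e_r] = argmin_t v` within the analysis
   window 0.3–2 ms after the stimulus (extracellular spikes have
   negative peaks). In samples at 20 kHz the window is the inclusive
   range `[ceil(0.3 ms · fs), floor(2 ms · fs)] = [6, 40]`, m = 35
   candidate samples. Ties break to the earliest sample. The early bound
   skips the large initial artifact; the late bound accommodates evoked
   latency plus propagation across the array.
3. **Signal electrodes.** Under the null of no evoked activity, spike
   times are uniform over the m window samples with variance
   σ₀² = (m² − 1)/12 (= 102 samples² at m = 35). The scaled sample
   variance (n−1)s²/σ₀² is modeled as χ² with n−1 degrees of freedom
   (n = repeats; sample variance uses denominator n−1 to match), and an
   electrode is flagged as signal-carrying when
   `s² < σ₀²·Q_{χ²_{n−1}}(p)/(n−1)` (strict inequality), p = 0.05 by
   default — the algorithm's only statistical hyperparameter. At n = 25,
   m = 35, p = 0.05 the cutoff is ≈ 58.9 samples². The discrete-uniform
   null is platykurtic, so the χ² approximation is conservative: the
   empirical flag rate on pure-noise electrodes is ~1%, below the
   nominal 5%.
4. **Pruning.** `Activated(a_j) = ⋂_{k ≥ j} Signal(a_k)`, computed
   iteratively downward from the top amplitude. This enforces response
   monotonicity and removes electrodes flagged by chance at isolated
   amplitudes. Activated sets are nested by construction.
5. **Threshold.** The lowest amplitude whose activated set touches at
   least two of the four borders (first/last row, first/last column) of
   the rectangular array. Nesting makes the qualifying amplitudes
   upward-closed, so a linear scan from below finds the threshold. If no
   amplitude qualifies the electrode is reported as `NOT_FOUND` —
   explicitly distinct from both 0 and the maximum amplitude, because
   "no bundle activation in the tested range" is a different statement
   from a detected threshold.

A single corner electrode literally lies on two borders and therefore
satisfies the rule alone under the default `literal` corner rule; the
`two-electrode` rule additionally requires distinct electrodes on
distinct borders (a maximum bipartite matching between electrodes and
borders, checked via Hall's condition). Both are exposed because the
informal "two borders" criterion does not resolve the lone-corner case.

Recording electrodes are all included by default — including the
stimulating electrode itself, whose early artifact is handled by the
window's 0.3 ms start — and a configurable exclusion set is available.

## Synthetic scans and ground truth

The simulator generates `y = x + i + s + n` per stimulating electrode:

* **x:** a straight axon path through the stimulation site at a random
  orientation (straight lines model peripheral bundles; curvature is
  second-order at MEA scale). Electrodes within a 45 μm capture radius
  of the path receive a biphasic, negative-peaked spike (−90 μV peak,
  0.05 ms width) at latency = 0.5 ms + |distance along path|/velocity,
  with 1 m/s conduction velocity (so a half-array traverse of ~1 mm
  takes ~1 ms and fits the 2 ms window) and Gaussian latency jitter of
  0.05 ms (~1 sample), the lower end of the observed ~0.1 ms
  variability. The 45 μm radius slightly exceeds the largest possible
  point-to-lattice distance on a 60 μm grid (≈ 42.4 μm), so a straight
  line through the array always has electrodes within reach along its
  whole length, including at its two border exits — which is what makes
  the ground-truth activated set touch two borders.
* **Bundle firing** is Bernoulli per (amplitude, repeat) with a
  probability sigmoidal in grid index, centered half a step below the
  drawn threshold index with slope 0.12 index units: the bundle fires
  with probability ≈ 1.5% one step below threshold and ≈ 98.5% at
  threshold. One uniform draw per repeat is shared across amplitudes
  (monotone coupling), so per-repeat activation is non-decreasing in
  current, the premise of the pruning step. The ground-truth threshold
  is the lowest grid amplitude whose activation probability reaches the
  certainty level (0.95 by default; exactly 1 in clean mode, where the
  sigmoid degenerates to a step).
* **i:** a damped oscillation (2 kHz, τ = 0.05 ms) scaled linearly with
  current and attenuated as 1/(1 + (d/pitch)²) with distance from the
  stimulating electrode. The decay constant places the artifact's bulk
  before the 0.3 ms window start, with in-window residual below the
  noise floor — the operating regime the algorithm assumes (hardware
  artifact reduction plus window blanking). An artifact whose in-window
  residual *grows above* the noise floor is deterministic and
  time-locked, is indistinguishable from an evoked spike to the variance
  test, and biases border-adjacent stimulating electrodes toward early
  thresholds; this is a genuine limitation of mean-subtraction artifact
  handling, not of the simulator.
* **s:** Poisson spontaneous spikes (5 Hz per electrode, −70 μV), at
  most one per ~2.4 ms trace.
* **n:** i.i.d. Gaussian noise, 5 μV standard deviation.

No quantitative spontaneous rate or noise floor is established for this
preparation; 5 Hz and 5 μV are stated defaults chosen as typical
healthy-retina MEA values, not derived quantities. Degenerated-retina
conditions are approximated only by raising the spontaneous rate.

Blocks are deterministic functions of `(seed, stimulating electrode)`
via `numpy.random.SeedSequence`, so scans stream one block at a time
(`SimulatedScan`) without materializing the ~13 GB full-depth tensor;
`simulate_scan` materializes small scans in memory. An optional somatic
component adds a local, unidirectional response a few steps below the
bundle threshold to exercise the fact that local activation alone must
not trip the border rule.

**What the simulator does not model:** curved axon trajectories,
spike-amplitude decay along the axon, electrode-specific noise and
impedance variation, overlapping somatic/axonal waveforms on one
electrode, rhythmic degenerated-retina activity, and artifact waveforms
that violate the in-window-residual assumption. Synthetic recovery
results therefore demonstrate correctness of the algorithmic chain under
the model's assumptions, not performance on real tissue.

## Validation metrics

Two threshold sets are compared on electrodes detected in both
(`NOT_FOUND` on either side excludes the electrode and is reported
separately, mirroring the exclusion of electrodes without a manual
threshold): fraction within ±1 grid step, fraction exactly equal, and
Pearson correlation of threshold amplitudes. On the 10%-per-step
geometric grid, ±1 step equals ±10% of amplitude; agreement uses index
arithmetic because a literal ratio test in [0.9, 1.1] sits exactly on
the float boundary at one step. The chance baseline permutes the
reference within each scan's stratum and pools, reporting mean ± sd over
permutations. The repeat-subsampling curve reruns detection on random
repeat subsets (reference from all repeats or ground truth); the p-value
sweep rethresholds the once-computed spike-time variances per candidate
p, then reruns pruning and the border rule.

## Numerical and design choices

* Variance test in sample units; the unit cancels as long as σ₀² uses
  the same units.
* "All possible time samples" in the null means the analysis window (the
  only region where spike times are defined).
* Argmin ties break to the earliest sample — deterministic and causal.
* Exact zero noise is degenerate: all-constant traces make every argmin
  tie and every electrode trivially time-locked, so the variance test's
  null collapses. The clean verification mode uses a 0.5 μV noise floor
  with zero jitter, no spontaneous activity, no artifact and a
  step-function activation sigmoid; detection then recovers ground truth
  exactly on every electrode under the `two-electrode` corner rule.
  Under the `literal` rule a rare one-step-early detection remains
  possible even on clean scans: a corner electrode lying on the bundle
  path is genuinely time-locked at all supra-threshold amplitudes, so a
  single chance flag of the variance test at one sub-threshold amplitude
  survives pruning and, lying on two borders, qualifies alone. Clean
  detection is never late under either rule (at threshold, every path
  electrode has exactly zero spike-time variance and is always flagged).
* On a pure-noise scan, false detections concentrate at the top
  amplitude, where pruning has no higher amplitudes to intersect away
  chance flags; the false-positive rate is governed by the probability
  that the ~1% chance flags at the top amplitude span two borders.
* Threshold monotonicity in p: lowering p shrinks the cutoff, hence the
  signal and activated sets, so thresholds can only move up or vanish.
* Detection output is invariant to repeat permutation, uniform positive
  rescaling of voltages, and any repeat-independent additive signal
  applied identically at all amplitudes.

## Problem sizes

The packaged synthetic validation scan uses a 16×16 array (256
stimulating electrodes — a quarter-array patch of the 512-electrode,
16×32 layout, keeping every axon path's in-window propagation reach
while scans stay desk-sized), the full 40-level grid, 25 repeats and
48-sample traces. The repeat-subsampling experiment uses 10 random
15-repeat subsets. Unit and property tests use 8×8 / 12-level / 10-repeat
scans.
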