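# Methods

## Physical model

**Rupture kinetics.** Every unfolding domain and the terminal
receptor-ligand handle are modeled as a single sharp barrier with a
force-dependent escape rate k(F) = k₀·exp(F·Δx/k_BT) (Bell). Under a
constant loading rate r this gives the rupture-force density

p(F) = (k₀/r)·exp[(Δx/k_BT)·F − (k₀·k_BT/(r·Δx))·(e^{Δx·F/k_BT} − 1)],

with survival S(F) = exp[−(k₀·k_BT/(r·Δx))·(e^{Δx·F/k_BT} − 1)] and mode
⟨F(r)⟩ = (k_BT/Δx)·ln(r·Δx/(k₀·k_BT)). Samples are drawn by exact
inversion of S, F = (k_BT/Δx)·ln(1 − (r·Δx/(k₀·k_BT))·ln U), which is
nonnegative for U ∈ (0, 1].

**Thermal energy.** k_BT = 4.11 pN·nm (25 °C) throughout; configurable on
`BellEvansParams`.

**Polymer elasticity.** The stretched chain is a worm-like chain in the
interpolated Marko-Siggia form with persistence length L_p = 0.365 nm
(typical polypeptide value). A serial chain of equal-L_p segments is
mathematically a single WLC whose contour length is the sum, so the
simulator tracks one running contour length; the PEG linker's mixed
elasticity is deliberately ignored — the analysis consumes only
contour-length *increments*, which the WLC captures. Both the forward map
and its inversions (extension at force, contour length from a
force/extension pair) are solved by guarded Newton iteration; the relation
is strictly monotone, so the roots are unique.

## Trajectory simulation

At each time step the piezo displacement D = v·t is partitioned between
cantilever deflection d and polymer extension x = D − d by the force
balance k·d = F_wlc(x; L_c), solved by a bracketed Newton iteration seeded
from the previous step. Each active substep accumulates hazard
∫k(F(t))dt against an Exp(1) threshold drawn up-front (fixed draw order ⇒
bit-identical output per seed). When the threshold is crossed:

- the rupture force is interpolated *within* the step from the fraction of
  hazard needed — without this, the discrete integration biases rupture
  forces upward by about half a step's force rise (≈10 pN for the stiff
  handle at 10 kHz);
- the crossing sample is re-balanced with the increased contour length, so
  the recorded trace already shows the post-rupture force (the event's
  ground-truth index is the last fully-loaded sample);
- the ground-truth loading rate is the least-squares dF/dt over the last
  3 nm of polymer extension before rupture — the same window convention
  the event-level estimator uses, so the two are directly comparable.

Defaults define the emulated conditions: spring constant 143 pN/nm,
pulling speed 1600 nm/s (400–3200 for dynamic force spectra), sampling
10 kHz, per-sample Gaussian force noise of 6 pN (typical AFM noise floor),
linear baseline drift 2 pN/s, unit InvOLS factor. The standard construct
is a 35 nm linker (a ~5 kDa PEG tether plus termini), a ddFLN4 fingerprint
(4 nm folded, releasing 15 + 19 = 34 nm in two substeps sharing one set of
Bell parameters, Δx = 0.45 nm, k₀ = 0.35 s⁻¹ → ruptures near 60–90 pN), a
cohesin (4 nm folded, 45 nm release, kinetics of the construct under
study) and a handle rupture at Δx = 0.13 nm, k₀ = 4·10⁻⁶ s⁻¹ (≈650 pN at
these rates). Noise magnitude and drift rate are plausible choices, not
fitted to any instrument.

Step-halving convergence is tested (10 → 20 kHz moves the mean cohesin
rupture force by well under the distribution width).

## Curve correction

Order: InvOLS → baseline → median, all pure functions that append to a
`processing` metadata list.

- **InvOLS**: exact linear rescaling of the deflection by
  reference/measured.
- **Baseline**: mean of the trailing 5% of samples (pure baseline after
  the final detachment) subtracted as a per-curve offset. A linear-in-time
  slope term is available (`fit_drift=True`) but off by default: a slope
  estimated from a ~50-sample tail at 6 pN noise has a standard error of
  hundreds of pN/s and extrapolates to tens of pN of error at the start of
  the trace, whereas true within-curve drift (~2 pN/s over ~0.1 s) is far
  below the noise. The offset term is what absorbs slow session-scale
  drift.
- **Median**: running median (default window 11 samples at 10 kHz — wide
  enough to kill single-sample spikes, narrow enough not to blunt rupture
  edges); edges handled by nearest-value padding.

## Event detection and contour-length measurement

**Detector.** A peak-trough state machine on the smoothed force: track the
running maximum; when the force falls `min_drop` below it, record the
maximum as an event, then ride the drop to its trough and resume only
after the force reloads by `min_drop`/2 (prevents one large rupture from
triggering twice). Default `min_drop` = 15 pN: ~6.5σ above the
median-smoothed noise floor (6 pN raw → ≈2.3 pN smoothed) yet below the
smallest physical drop in the standard construct (a 15 nm release at a
40 pN substep rupture drops only ≈17–25 pN).

**Peak read-out.** The median filter erodes sawtooth apexes (the smoothed
maximum sits roughly half a window early and low), so each event is
refined on the unsmoothed trace: the rupture sample is relocated to the
largest single-step drop near the smoothed peak and the force is read from
a short quadratic fit of the preceding ramp evaluated there — unbiased
under zero-mean noise (unlike the raw maximum) and free of the chord bias
a straight line has on a convex ramp. Because the rupture falls somewhere
inside one sampling interval, the read-out can sit up to one interval's
force rise below the true rupture force; this is an instrument-resolution
limit, not an estimator defect.

**Contact point.** Last zero-crossing of the force before the first event,
located on a heavily median-smoothed copy (window 75): near contact the
chain is so compliant that raw noise keeps crossing zero well into the
ramp. The residual contact offset (a few nm) largely cancels in
contour-length *differences*.

**Contour lengths.** Extension is tip-sample separation (piezo −
deflection) zeroed at contact. Every sample of an inter-event stretch with
F > 15 pN (WLC inversion is ill-conditioned below) is inverted pointwise
to a contour length; the segment estimate is the median. An event's
increment is the contour-length difference between the following and
preceding stretches; segments with fewer than 5 usable samples are flagged
unreliable.

**Loading rates.** Least-squares dF/dt over the last 3 nm of extension
before the peak, fitted on the *unsmoothed* trace (the filter's eroded
pre-peak samples otherwise bias slopes ~20% low); events with fewer than
5 window samples are excluded from dynamic force spectra.

**Fingerprint filter.** A trace is accepted iff it shows (a) the ddFLN4
release: two consecutive substeps summing to 34 ± 5 nm, or a single event
carrying the full 34 ± 5 nm — the substeps merge into one apparent event
when the second fires at low force before the chain reloads (~3% of clean
traces); (b) exactly one other event with a 45 ± 5 nm increment; (c) a
final rupture with nothing after it. Anything else is rejected with a
recorded reason (extra events ⇒ multi-tether, etc.). The ±5 nm tolerance
is a design choice; the 34/45 nm targets are the domain fingerprints.

## Rupture statistics

- **Histogram fits**: bins of fixed width from the origin; the per-bin
  density is fitted with the *bin-averaged* Bell-Evans density
  (S(lo) − S(hi))/width by Levenberg-Marquardt, with moment-based starting
  values (the rupture-force distribution is Gumbel-like, SD ≈
  (π/√6)·k_BT/Δx). Bin-averaging keeps the fit unbiased even at 50 pN
  bins on a ~30 pN-wide distribution, which is what makes the fit
  insensitive to bin size over 10–50 pN. Parameter SDs are square roots of
  the covariance diagonal; a reduced χ² (Poisson bin variance) above 3
  flags non-Bell-shaped data for the KDE path. Default bins: 25 pN for
  unfolding, 50 pN for handle unbinding.
- **KDE modes**: Gaussian kernel, Silverman bandwidth, quadratically
  refined grid maxima with density ≥ 10% of the global maximum; at most
  two modes reported (ascending) for bimodal distributions. FWHM of the
  force KDE provides the error-bar convention for dynamic force spectra.
- **Dynamic force spectrum**: per speed, the most probable loading rate is
  the KDE mode of ln r (rates are log-distributed) and the most probable
  force the force-KDE mode; the ⟨F⟩–ln r relation is fitted unweighted by
  Levenberg-Marquardt seeded from the linear regression (the slope is
  k_BT/Δx, the intercept fixes k₀). Δx is recovered to a few percent; k₀
  is exponentially sensitive to the intercept, so its honest contract is
  agreement within a factor of ~2.
- **Condition comparison**: ΔF = F_bound − F_apo and percent change per
  apo mode (two rows for bimodal apo distributions); the negative-control
  check compares |ΔF| against twice a seeded bootstrap SE of the KDE mode.

## Panel pipeline

One JSON/YAML config drives constructs × conditions × speeds. Per-cell
seeds are derived from the master seed and the cell label (CRC32), so
results are independent of dict ordering and byte-identical across runs;
the config hash is embedded in the report. The analysis path never reads
simulation ground truth — truth is consumed only by the test suite. Cell
failures are reported in place, never silently dropped.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
Bell kinetics, WLC elasticity, cantilever compliance, white force noise,
slow drift, calibration error. It does not emulate instrument-specific
artifacts (hydrodynamic drag, piezo nonlinearity, tilt/virtual deflection,
PEG's force-dependent conformational transition, refolding during
retraction, or dual binding modes of receptor-ligand complexes). Passing
parameter recovery therefore demonstrates the correctness and calibration
of the *analysis chain* under its own model assumptions — not robustness
to every artifact of real instruments.

## Problem sizes

Verification experiments run at desk scale: 2000 ruptures per loading rate
(four rates) for each dynamic-force-spectrum recovery, and 500 simulated
curves for the fingerprint experiment; panels default to 300 accepted
traces per cell at the main speed and 150 per speed for spectra.

## Known limitations

- k₀ recovery spans a factor ~2 even with perfect model match; quoting it
  tighter would be dishonest (the published SDs are of comparable relative
  size).
- The contact-point estimator leaves a few nm of extension offset on noisy
  curves; increments inherit only its force-range-dependent part
  (≲0.5 nm), visible as the ~0.1–0.3 nm positive bias of the measured
  increment medians.
- Per-curve InvOLS *estimation* from baseline noise is out of scope; the
  correction takes explicit scale values (the simulation records the true
  factor in the curve metadata).
- The detector is tuned for sawtooth-type curves with drops ≥ ~15 pN;
  unfolding intermediates with smaller releases would need a smaller
  `min_drop` and a correspondingly lower noise floor.
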