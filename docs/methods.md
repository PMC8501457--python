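# Methods

This note documents the models, numerical choices and known limitations of
`phasorflim`. It describes what the code computes and why the defaults are
what they are; all empirical statements below are the ones the test suite
and `scripts/acceptance.py` themselves compute.

## Decay model and time base

A TCSPC acquisition records, per pixel, a histogram of photon arrival times
over one laser period T (default 10 ns at a 100-MHz repetition rate, 256
bins). Time bin k spans [kΔ, (k+1)Δ) with Δ = T/256 ≈ 39 ps; bin centers
are used wherever a time value is needed. Fluorescence from a mixture of
species is modeled as a sum of exponentials with pre-exponential amplitudes
Aᵢ and lifetimes τᵢ (ns). Because lifetimes are comparable to T, arrivals
are wrapped modulo T ("pile-in"): a component observed inside the window is
Aᵢ·exp(−t/τᵢ)/(1 − e^(−T/τᵢ)). The fitter divides the wrap factor out so
reported amplitudes are per-period pre-exponential amplitudes, the
convention the amplitude-weighted mean lifetime
τₘ = (A₁τ₁ + A₂τ₂)/(A₁ + A₂) expects. A component's photon yield (its share
of detected photons and of phasor weight) is proportional to Aᵢτᵢ, not Aᵢ.

## Simulator

`simulate_decay` draws exactly n photon arrival times: a species is chosen
with probability Aᵢτᵢ/ΣAⱼτⱼ, an exponential arrival is drawn, the IRF is
applied (a time shift for a delta IRF, an additional Gaussian draw
otherwise), and times are wrapped into [0, T) and binned. Exactly-n
sampling (rather than per-bin Poisson) makes photon-conservation checks
exact while being indistinguishable for every analysis in the package,
which conditions on the observed total. `simulate_field` overlays
elliptical cells (nucleus strictly inside) on a background-free border,
draws per-pixel photon counts as Poisson with compartment-specific
expectations split across frames, and applies a per-frame geometric
intensity decay (1 − bleach_rate)^frame. The default phantom gives the
cytoplasm an equal-amplitude 0.4/3.4-ns mixture and the nucleus pure
0.4-ns decay — the free-NADH enrichment of nuclei — with 300 (cytoplasm)
and 150 (nucleus) expected photons per pixel, a realistic budget for a
single accumulated NAD(P)H field.

The Gaussian IRF is the only non-trivial instrument response because its
phasor has the closed form e^(−(ωσ)²/2)·(cos ωt₀, sin ωt₀), which the tests
use as an oracle. The simulator does not model detector afterpulsing,
dead-time, dark counts or spectral bleed-through, and the phantom geometry
is 2-D with sharp compartment boundaries; passing tests therefore validate
the estimators under ideal counting statistics, not robustness to those
instrument artifacts.

## Time-domain fitting

Per (spatially binned) pixel the Neyman-weighted least-squares objective
Σ(y_b − m_b)²/max(y_b, 1) is minimized. Weighted least squares rather than
Poisson maximum likelihood keeps the χ² and F-test machinery exact;
max(y, 1) avoids zero-count singularities. Minimization uses variable
projection: the outer bounded search (trust-region reflective) runs over
lifetimes only, and at each step the amplitudes and baseline are solved by
weighted linear least squares. This both accelerates the fit (1–2 nonlinear
parameters instead of 3–5) and guarantees the single-exponential model is
exactly nested in the double-exponential one, which the model-selection
F-test

F = ((χ²₁ − χ²₂)/(dof₁ − dof₂)) / (χ²₂/dof₂),  p from F(dof₁−dof₂, dof₂)

relies on (order 2 is kept when p < α, default α = 0.05). The linear solve
is unconstrained; if the optimum has a negative amplitude the fit is
clipped and flagged, and flagged fits are excluded downstream. Double fits
start from (0.4, 3.4) ns; single fits from the empirical mean arrival
time. Lifetimes are bounded to [0.001, 50] ns.

Two fit-window modes exist because the acquisition may or may not provide a
measured IRF. Without one (sharp-IRF assumption) the fit is a tail fit from
the maximum bin onward, with bin-center times offset half a bin from the
window start — without the offset, amplitude ratios are biased by
e^(−Δ/2·(1/τ₁−1/τ₂)) (≈4% at 0.4/3.4 ns) even though lifetimes are
unaffected. With an IRF histogram the model is the circular convolution of
the bin-integrated wrapped-exponential kernel with the IRF bin masses over
all bins. Bin-integrating the kernel matters: the exponential density jumps
at t = 0, and point-sampling that bin doubles its mass and biases the
rising edge (χ²/dof ≈ 2.7 and +3% on τ in our checks; ≈1 and unbiased
after integration). A floating non-negative baseline is included by default
to absorb dark counts in real data.

Spatial binning is a sliding 3×3 window (zero-padded edges), preserving
image resolution; pixels whose binned decay reaches 20,000 photons are
eligible for fitting. Choosing the sliding rather than block binning is a
deliberate default where either convention is common in TCSPC practice.

ROI-level lifetime (and bound-fraction) histograms use 50-ps (0.005)
binning and are decomposed into one or two Gaussians by the same nested
F-test; a population's weight is the count it accounts for, and its
standard error is sd/√weight.

## Phasor analysis

The transform is the rectangle rule at bin centers over exactly one period,
so a noise-free single exponential lands within 1e−3 of the universal
semicircle at 256 bins (the analytic phasor g = 1/(1+(ωτ)²),
s = ωτ/(1+(ωτ)²) is exact). The IRF enters phasor space multiplicatively
(convolution theorem, complex convention z = g + i·s), so correction is a
complex division by the IRF phasor. That phasor is estimated from the
brightest binned pixel: its decay is fit (order by F-test) and its measured
phasor divided by the analytic phasor of the fitted model; ties for
brightest resolve to the smallest (row, col), and a failed fit falls back
to the unit IRF with a warning.

The free→bound axis connects the pure-species phasors of 0.4 and 3.4 ns,
computed analytically; the chord length from geometry is asserted against
its closed form at 1e−9. Published instrument-calibrated endpoint
coordinates for this axis are stored as reference metadata
(`phasor.LITERATURE_ENDPOINTS`) but never used in computation: their s
coordinates agree with the analytic values to ~1%, while their g
coordinates are inconsistent with the universal semicircle at 100 MHz, so
an instrument-referenced or transcription origin cannot be excluded. A
pixel's bound fraction is its orthogonal projection onto the axis divided
by the axis length; for any two-species mixture of the calibration
lifetimes this equals A₂τ₂/(A₁τ₁+A₂τ₂) exactly, a property the tests check
to 1e−9. Fractions are kept unclamped for statistics (noise is symmetric
around the endpoints); only rendered maps are clipped to [0, 1].

Histogram windows — 256×256 over g ∈ [0,1] × s ∈ [0,0.6] for the 2-D
phasor histogram, 0.005 bins over [−0.1, 1.1] for bound fractions — are
package choices sized to typical field pixel counts; out-of-range pixels
are tallied, never silently dropped.

## Compartments, bleaching and concentration

Background is thresholded on the total-intensity image (explicit count
threshold, or Otsu when unspecified); nuclear ROI polygons are rasterized
with a pixel-center-in-polygon test (boundary included) and background
takes precedence over ROIs; remaining pixels are cytoplasm. The bleaching
factor b = mean(frame means)/first-frame mean divides measured intensities;
b ≤ 1 for monotone bleaching, and the correction cancels a pure intensity
loss with unchanged decay shape (checked within Poisson error). Corrected
intensities are normalized to the mean vehicle control of the same
replicate — a missing control is an error, never a silent fallback. The
relative concentration proxy is corrected intensity divided by mean
lifetime, removing the quantum-yield (lifetime) dependence of intensity;
it is reported in arbitrary units, not calibrated to molarity.

Per-frame means feeding b are taken over non-background pixels, since
background dilutes the bleaching estimate. How a scanned, line-averaged
acquisition maps onto "frames" is instrument bookkeeping the package does
not infer: the frame series is accepted as data.

## Experiment statistics

The statistical unit is the field of view. The full-interaction linear
model is fit first; if any interaction term is significant at α = 0.05 on
the type II table, the reported ANOVA uses type III sums of squares with
sum-to-zero contrasts (required for type III terms to be interpretable),
otherwise type II. On balanced designs the two coincide, which the tests
verify. All pairwise group comparisons use Tukey's studentized-range
adjustment with the conventional star tiers (\*, \*\*, \*\*\*, \*\*\*\* at
0.05, 0.01, 0.001, 0.0001). Replicate/day is not a model factor by
default. Empty design cells raise an explicit error rather than silently
dropping terms.

## Synthetic demonstration study

`run_demo_experiment` crosses two cell lines × two HER2 treatments × three
metabolic treatments with preset effect directions (rotenone: bound
fraction −0.05, intensity ×1.3; FCCP: +0.05, ×0.8; AG825: −0.03, ×1.15;
nuclear bound fraction 0.15 below cytoplasmic) at 3 fields per condition,
32×32-pixel phantoms and 250 expected photons per cytoplasmic pixel —
sizes chosen so a full study simulates and analyzes in seconds while
keeping field-to-field SEMs far smaller than the preset effects. The demo
uses the phasor branch only; per-pixel double-exponential fitting at these
photon budgets would be gated out by the 20,000-photon rule and is
exercised separately on dense phantoms.

## Known limitations

- Lifetime fitting assumes a common baseline and at most two components;
  triple-exponential decays and global multi-pixel fitting are out of
  scope.
- The IRF phasor estimate assumes the brightest pixel's decay is well
  described by the fitted exponential model; strongly multi-exponential
  bright pixels degrade the reference.
- Only the fundamental harmonic phasor is computed.
- The bound fraction is a photon-yield fraction; converting it to a molar
  free/bound ratio would additionally require the quantum-yield ratio of
  the two species.
- Nuclear segmentation is input-driven (polygons or masks); no automatic
  nucleus detection is attempted.
- 3×3 spatial binning mixes signals across compartment boundaries, pulling
  thin-compartment means toward their surroundings (visible in the README
  example's nuclear bound fraction); analyses needing strict compartment
  purity should erode masks or bin with k = 1.
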