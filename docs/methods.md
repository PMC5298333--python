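# Methods notes

This note records the scientific model behind `plankspectra`, the defaults
and why they hold, and the numerical choices made where the underlying
protocol leaves room.

## Size and biomass conventions

All particle sizes are equivalent spherical diameters (ESD) in μm. For
flow-cytometry particles the biovolume is the sphere (π/6)·ESD³; for imaged
objects it is the prolate spheroid (π/6)·major·minor² from the
equivalent-ellipse axes of the pixel mask (the common convention for scanned
zooplankton, which are elongated). Biomass is wet weight: biovolume ×
1.060 g cm⁻³ (≡ mg mm⁻³), a literature tissue density for mixed plankton.
Note that sphere-equivalent wet weight overstates the mass of translucent or
flattened organisms; it is a bookkeeping convention, not a carbon estimate.

Each particle carries a concentration weight of 1/(sampled volume) in
# L⁻¹, so binned totals are concentrations regardless of how many samples
are pooled.

## Spectrum construction

Size classes are equally spaced in log₁₀ ESD, half-open [lower, upper), with
geometric midpoints. The default 12 classes per decade (~0.083 decades
wide) resolves bands like 200–300 μm and 800–1000 μm while keeping tens of
counts per occupied class in realistic samples; it is configurable and all
conservation identities hold for any class count.

* PSS_i = (Σ weights in class i)/Δs_i with Δs in **mm**, giving # L⁻¹ mm⁻¹.
* WBS_i = Σ (weight × biomass) in class i, in mg L⁻¹. This equals the
  normalized form PSS_i × (mean individual biomass in class i) × Δs_i
  algebraically; the implementation computes the direct sum and asserts the
  identity to relative 1e-12 as an internal consistency check.
* Conservation: Σ PSS_i·Δs_i is the total concentration and Σ WBS_i the
  total biomass concentration, independent of binning.

Slope fits are ordinary least squares of log₁₀ PSS on log₁₀ midpoint.
Zero-count classes are excluded (log undefined); no pseudo-counts are
added, because any pseudo-count choice injects a bias that depends on the
sampled volume. Classes flagged as instrument-gap (below) are excluded by
default. A fit needs ≥ 3 usable classes. Callers fitting sparse spectra
should restrict the fit range to classes with adequate expected counts: for
Poisson counts N, E[log N] < log E[N], so nearly-empty tail classes bias a
log-space fit downward. The stochastic-recovery test fits β = −3.29 samples
of 10⁵ particles over classes with expected counts ≳ 200 and recovers the
exponent within ±0.1 on every one of 50 seeds (max |error| 0.063 at the
frozen configuration; fitting the entire sampled range instead gives errors
up to ~0.15 driven purely by tail classes).

## Instrument domains and merging

The cytometer is quantitative over ~0.5–60 μm; imaged objects are
classifiable above ~150 μm. Merged particle sets therefore have a
structural gap at 60–150 μm: classes wholly inside it are flagged
`unobserved` and skipped by slope fits. Records on the wrong side of their
instrument's domain are flagged `out_of_domain`, never silently dropped.

Thresholding direction: objects are darker than the illuminated background
of a transmissive flatbed scan, so foreground is *below* the grey threshold.
Components use 8-connectivity (follows thin appendages better than
4-connectivity). The minimum component size defaults to 64 px ≈ a 150 μm
disk at 2400 dpi (10.58 μm/px). Border-touching components are flagged and
retained; the flag is exported so users can filter. Touching-object
separation is deliberately not implemented: the acquisition protocol
separates organisms by hand before scanning, and the synthetic plate
renderer enforces non-overlap, so segmentation ground truth is exact.
Single-pixel or collinear masks have degenerate moment axes; they fall back
to a sphere of the area-equivalent diameter so biovolume stays positive.

Class boundaries (phytoplankton pico/nano/micro at 2 and 20 μm; copepod
S/M/L at 600 and 1000 μm) are half-open [lower, upper): the printed ranges
leave the boundary values ambiguous, and half-open intervals make the
assignment deterministic and exhaustive.

Calibration fits use the median FSC of the newly appearing particle class
per filter fraction (the summary statistic is not dictated by the
procedure; the median is robust to the skewed FSC distributions involved).
Conversions more than one decade outside the calibrated FSC span are
flagged `extrapolated`.

## The synthetic community

The generator is descriptive, not dynamical: each population has a
log-normal ESD distribution (base-10 parameters) and a piecewise-linear
expected concentration over days 1–113, matching a 2–8-day sampling cadence.
No nutrient, predation or transport model is implied. Realized counts in
the sampled volume are Poisson; replicate mesocosms differ by a mean-one
multiplicative log-normal factor per (mesocosm, population, day), default
σ = 0.15 on the natural-log scale; the high-CO₂ arm multiplies expected
concentrations of sensitive populations by fixed factors (picoeukaryotes
1.6, the large diatom 1.3, copepods 1.4, hydromedusae 0.8 — the directions
and rough magnitudes such an enrichment experiment reports). Streams are
keyed on (seed, mesocosm index, day index, population index, instrument),
so output is bitwise-reproducible and independent of iteration order.

The default populations: a picoeukaryote wave (~1 μm) peaking at days
57–65 at ~3.7× its initial abundance; a broad 2–15 μm nanophytoplankton
bloom peaking at day 33 and a narrower 4–8 μm second bloom at day 57; a
200–500 μm centric diatom with a single broad peak across days 41–65;
copepods in three size cohorts (small 200–600 μm rising through the bloom,
medium 600–1000 μm declining, large > 1 mm vanishing by day ~49); and
sparse hydromedusae > 1 mm from day 33. Abundance knots are specified as
expected biomass (mg L⁻¹) and converted to concentrations by the analytic
mean individual weight E[(π/6)ESD³]·ρ of the log-normal size distribution,
so the community's expected biomass matches its anchors by construction:
5.26 mg L⁻¹ total (65% copepod) on day 1 and 12.74 mg L⁻¹ on day 57 in the
control arm. The mean-one noise convention (log-normal with μ = −σ²/2)
keeps these anchors unbiased.

The cytometer's analyzed volume is not part of the instrument's printed
protocol and defaults to 50 μL per run, giving O(10⁴) events per sample —
typical for a benchtop instrument and fast to simulate. FSC measurement
noise defaults to a 5% coefficient of variation (mean-one log-normal on the
scatter value); at the default calibration exponent this perturbs inferred
biomass by ≪ 1%.

What the generator does **not** emulate: taxonomic misclassification,
non-spherical cytometer targets (scatter–size scatter beyond the 5% noise),
detritus and marine-snow continuum, within-day patchiness, temporal
autocorrelation of replicate deviations, or sediment-trap losses. A green
pipeline test therefore establishes correctness of the bookkeeping and the
statistical procedures under the stated noise model — not robustness to
instrument artefacts.

### Replicate noise level

σ = 0.15 was adopted as the default replicate variability. Measured across
500 simulated experiments this makes the ×1.4 copepod effect detectable
almost always (rejection rate ≈ 0.98), which is *more* decisive than the
borderline p ≈ 0.06–0.13 outcomes such experiments actually report; the
printed SEs of the motivating campaign imply per-mesocosm CVs of ~0.2–0.35.
The default is kept at 0.15 as the stated world of the generator; users
wanting realistically marginal power should raise `replicate_noise_sd` to
~0.3. This is the one place where the simulator is knowingly cleaner than
the system it imitates.

## Treatment statistics

"Assumption checks accounted for in the t-test" is implemented as: Levene's
test (Brown–Forsythe, median-centred) at α = 0.05 selects pooled vs Welch;
Shapiro–Wilk normality failure is reported but does not trigger a
non-parametric fallback, staying within the t-test family. Tests are
two-sided. Both-arms-constant-and-equal comparisons return p = 1 with a
`degenerate` flag. No multiplicity correction is applied across size
classes (matching per-class α reporting); the expected false-positive count
α·K is attached to every comparison table. Under the null the realized
per-class false-positive rate of this two-stage procedure on log-normal
replicates is ≈ 0.05 (verified over 10⁴ simulated classes, within
[0.03, 0.08]).

Summary-statistics t-tests use t = Δmean/√(SE₁²+SE₂²) with df = n₁+n₂−2
(pooled; exact when n₁ = n₂) or Welch–Satterthwaite from the SEs.

Repeated-experiment calibration checks (null false-positive rate, effect
direction recovery, power) run on a summary-level draw that shares the
generator's noise model but skips per-particle Poisson sampling: for group
totals of hundreds of individuals the counting noise is negligible against
the replicate noise, and this keeps 500-experiment suites in seconds. The
particle-level and summary-level paths are tied together by the pipeline
anchor tests.

Whether per-size-class tests should run on PSS, WBS or raw class biomass is
a free choice; the pipeline tests WBS values (absolute biomass per class)
by default because that is the scale on which treatment effects are
ecologically interpreted, and exposes the choice through its API.

## Known limitations

* Biomass tables are reported in mg L⁻¹ wet weight throughout; biovolume
  (mm³ L⁻¹) differs by the constant density 1.060, and both conventions
  appear in the literature — divide by 1.060 to convert.
* The spectrum slope is sensitive to the fitted size range on sparse
  spectra (see above); no automatic range selection is attempted.
* The simulator's linear knot interpolation cannot produce sharper bloom
  onset than its knot spacing.
* No FCS binary parsing: event tables are delimited text with a documented
  column mapping.
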