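# plankspectra

Plankton particle size spectra spanning ~0.5 μm to beyond 1 mm, built by
combining two instruments that a mesocosm CO₂-perturbation campaign would
deploy: a fluorescence-triggered flow cytometer for the pico- to
microplankton range, and flatbed scan imaging of net-collected
mesozooplankton. The package converts raw instrument records to sized,
weighted particle tables, bins them into normalized abundance and biomass
spectra, and tests replicated treatment contrasts per plankton group and per
size class. A seeded synthetic community generator reproduces the
statistical structure of such an experiment (10 mesocosms in two treatments,
a winter-to-summer bloom succession), so the entire pipeline is testable
without instrument data.

It is aimed at plankton ecologists and method developers who want a small,
fully reproducible reference implementation of size-spectrum bookkeeping
rather than a monolithic imaging suite.

## The measurements

**Flow-cytometry sizing.** Forward scatter (FSC) is converted to equivalent
spherical diameter with a power law calibrated by size-fractionation through
polycarbonate filters:

    ESD = a · FSC^b        (defaults a = 0.0064, b = 0.5262, ESD in μm)

`fit_calibration` recovers (a, b) by least squares on log₁₀ ESD vs log₁₀ FSC
from (pore size, FSC) pairs. Events are retained on the ~0.5–60 μm domain
and classed as pico (< 2 μm), nano (2–20 μm) or micro (> 20 μm).

**Scan morphometry.** Plates are segmented by grey-level threshold (objects
darker than background, 8-connected), components are measured via image
moments, and counts scale to concentrations through the sampling geometry: a
0.17 m × 17 m net tow (≈ 385 L) made up to 500 mL of which 20 mL is imaged,
i.e. 15.4 L effective volume. Objects below ~150 μm are not classifiable
and are dropped; "disturbance" objects are removed before any statistics.
Copepods are classed S (< 600 μm), M (600–1000 μm), L (> 1000 μm) on ESD.

**Spectra.** With logarithmically spaced ESD classes *s* of linear width Δs
(in mm):

    PSS(s) = (abundance in class) / Δs          [# L⁻¹ mm⁻¹]
    WBS(s) = PSS(s) · biomass(s) · Δs           [mg L⁻¹]

where biomass is wet weight from biovolume at 1.060 g cm⁻³. PSS is the
normalized abundance (Sheldon-type) spectrum; WBS is the absolute biomass
per log-spaced class, so Σ WBS equals the community biomass concentration —
an identity the implementation enforces to 1e-12. Spectrum slopes are OLS
fits of log₁₀ PSS on log₁₀ class midpoint over observed, non-empty classes.

**Treatment statistics.** Replicates are summarized as mean ± SE (n = 5 per
arm); per-class contrasts use independent two-sample t-tests at α = 0.05,
with Levene's test choosing between the pooled and Welch variants and
Shapiro–Wilk recorded as a diagnostic. `ttest_from_summary` reproduces
p-values from printed means/SEs alone.

## Worked example

```python
from plankspectra.pipeline import PipelineConfig, run_pipeline, treatment_mean_biomass

cfg = PipelineConfig(seed=1, days=(1, 57))      # pre-bloom day and bloom peak
res = run_pipeline(cfg)
for day in (1, 57):
    m, se = treatment_mean_biomass(res, "Total biomass", day, "control")
    print(f"t{day}: total biomass {m:.2f} +- {se:.2f} mg/L")
print(res.slopes.groupby("day")[["slope", "r_squared"]].mean().round(3))
```

prints

```
t1: total biomass 5.32 +- 0.19 mg/L
t57: total biomass 12.16 +- 0.54 mg/L
     slope  r_squared
day
1   -3.636      0.962
57  -3.628      0.955
```

The default synthetic community is anchored so the control arm carries
≈ 5.26 mg L⁻¹ total wet-weight biomass pre-bloom (65% of it in copepods,
mostly 600–1000 μm adults) and ≈ 12.74 mg L⁻¹ at the bloom peak, by which
point a 200–500 μm diatom dominates and copepod biomass has dropped by
~25% despite rising abundance. The near-linear spectrum slope (≈ −3.6 here,
R² ≈ 0.96) barely moves between the two days even though the biomass
distribution reorganizes completely — the motivating observation for
reporting WBS alongside PSS. Group comparisons on day 57 recover the
simulated CO₂ effects (e.g. copepod total 2.53 vs 3.66 mg L⁻¹).

The same pipeline is available from the shell:

```bash
plankspectra all --seed 1 --day 1 --day 57 --out results/run1
```

which writes particle tables, per-(mesocosm, day) spectra, slope fits,
biomass tables, treatment comparisons, and a run log that suffices to
reproduce the run exactly. Individual stages (`simulate`, `fcm`, `scan`,
`spectra`, `compare`, `report`) consume and produce plain text files.

## Acceptance script

`scripts/acceptance.py` re-runs the default end-to-end pipeline from
scratch (simulation → instrument tables → sizing → spectra → statistics)
for a given seed and writes its JSON summary:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `plankspectra.synthetic` — seeded community simulator, plate renderer
- `plankspectra.flowcytometry` — FSC→ESD calibration and event sizing
- `plankspectra.imaging` — segmentation, morphometry, sampling geometry
- `plankspectra.spectra` — binning, PSS/WBS, slopes, biomass tables
- `plankspectra.stats` — replicate summaries and treatment tests
- `plankspectra.pipeline` / `plankspectra.cli` — orchestration and CLI

See `docs/methods.md` for the model assumptions and numerical choices.
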