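"""Seeded synthetic mesocosm community generator.

Generates per-mesocosm, per-day particle tables (and optional rendered scan
plates) with the statistical structure the downstream analysis assumes, so
every pipeline stage can be exercised against known ground truth:

* each population has a log-normal ESD distribution and a piecewise-linear
  abundance trajectory over the experiment days;
* a CO₂ treatment multiplies the expected concentration of sensitive
  populations by a fixed factor;
* mesocosm replicates vary by a multiplicative log-normal factor per
  (mesocosm, population, day);
* realized particle counts in the sampled volume are Poisson.

The default community emulates a winter-to-summer fjord succession enclosed
in ten mesocosms (two treatments, n = 5): a copepod stock dominated by one
calanoid species shifting from medium/large (600–1000 μm) to small
(200–600 μm) size classes, two nanophytoplankton bloom waves (days ~33 and
~57), a very large centric diatom (200–500 μm ESD) blooming around day 57,
and a picoplankton wave.  Default abundance trajectories are anchored so the
control-treatment community works out to ≈5.26 mg L⁻¹ total wet-weight
biomass on day 1 and ≈12.74 mg L⁻¹ on day 57 when run through the full
pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import draw as _skdraw

from . import flowcytometry as _fcm
from . import imaging as _imaging
from . import spectra as _spectra

#: Default analyzed volume per flow-cytometry run, in litres (50 μL).
DEFAULT_FCM_VOLUME_L = 5.0e-5

#: Default multiplicative replicate noise (sigma on the natural-log scale).
DEFAULT_REPLICATE_NOISE_SD = 0.15

#: Default multiplicative FSC measurement noise (coefficient of variation).
DEFAULT_FSC_NOISE_CV = 0.05

CONTROL = "control"
HIGH_CO2 = "high_co2"
TREATMENTS = (CONTROL, HIGH_CO2)


@dataclass(frozen=True)
class PopulationSpec:
    """One plankton population of the simulated community.

    abundance_knots are (day, concentration # L⁻¹) pairs, linearly
    interpolated between knots and held constant outside them.  The
    treatment multiplier scales the expected concentration in the high-CO₂
    treatment only.  instrument_domain says which instrument(s) detect the
    population: 'fcm', 'imaging' or 'both'.
    """

    name: str
    log_esd_mean: float
    log_esd_sd: float
    abundance_knots: Tuple[Tuple[float, float], ...]
    treatment_multiplier: float = 1.0
    instrument_domain: str = "fcm"
    taxon: str = ""

    def __post_init__(self):
        if self.log_esd_sd < 0:
            raise ValueError("log_esd_sd must be non-negative")
        if self.treatment_multiplier <= 0:
            raise ValueError("treatment multiplier must be positive")
        if self.instrument_domain not in ("fcm", "imaging", "both"):
            raise ValueError("instrument_domain must be fcm, imaging or both")
        knots = tuple((float(d), float(c)) for d, c in self.abundance_knots)
        if not knots:
            raise ValueError("need at least one abundance knot")
        days = [d for d, _ in knots]
        if sorted(days) != days:
            raise ValueError("abundance knots must be sorted by day")
        if any(c < 0 for _, c in knots):
            raise ValueError("knot concentrations must be non-negative")
        object.__setattr__(self, "abundance_knots", knots)
        if not self.taxon:
            object.__setattr__(self, "taxon", self.name)

    def concentration_at(self, day: float) -> float:
        """Linearly interpolated expected concentration (# L⁻¹) on a day."""
        days = np.array([d for d, _ in self.abundance_knots])
        conc = np.array([c for _, c in self.abundance_knots])
        return float(np.interp(day, days, conc))

    def mean_individual_biovolume_mm3(self) -> float:
        """Analytic mean spherical biovolume of one individual, mm³.

        For ESD = 10^Y with Y ~ N(m, s²) (base-10 parameters, ESD in μm):
        E[ESD³] = 10^{3m} · exp((3 s ln10)² / 2).
        """
        m, s = self.log_esd_mean, self.log_esd_sd
        e_d3_um3 = 10.0 ** (3.0 * m) * np.exp(0.5 * (3.0 * s * np.log(10.0)) ** 2)
        return (np.pi / 6.0) * e_d3_um3 * 1e-9

    def mean_individual_biomass_mg(
        self, density_g_cm3: float = _spectra.DEFAULT_DENSITY_G_CM3
    ) -> float:
        return self.mean_individual_biovolume_mm3() * density_g_cm3


@dataclass(frozen=True)
class MesocosmSpec:
    """One enclosed replicate and its treatment assignment."""

    mesocosm_id: str
    treatment: str
    replicate_noise_sd: float = DEFAULT_REPLICATE_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate noise sd must be non-negative")


def knots_from_biomass(
    biomass_knots: Sequence[Tuple[float, float]],
    log_esd_mean: float,
    log_esd_sd: float,
    density_g_cm3: float = _spectra.DEFAULT_DENSITY_G_CM3,
) -> Tuple[Tuple[float, float], ...]:
    """Convert (day, expected biomass mg L⁻¹) anchors to concentration knots.

    Divides each biomass target by the analytic mean individual wet weight of
    the population, so the expected community biomass matches the anchors by
    construction (before sampling noise).
    """
    probe = PopulationSpec(
        name="_probe",
        log_esd_mean=log_esd_mean,
        log_esd_sd=log_esd_sd,
        abundance_knots=((0.0, 0.0),),
    )
    mib = probe.mean_individual_biomass_mg(density_g_cm3)
    return tuple((float(d), float(b) / mib) for d, b in biomass_knots)


def default_populations() -> List[PopulationSpec]:
    """The default simulated community.

    Abundance trajectories are anchored in expected wet-weight biomass
    (mg L⁻¹) and converted to concentrations analytically.  Day-1 anchors
    sum to 5.26 mg L⁻¹ with copepods at 3.43 (65%); day-57 anchors sum to
    12.74 with the large diatom at 6.02 and copepods at 2.58.  Treatment
    multipliers: picoeukaryotes ×1.6, large diatom ×1.3, copepods ×1.4,
    hydromedusae ×0.8.
    """

    def pop(name, taxon, mean_um, log_sd, domain, mult, biomass_knots):
        m = float(np.log10(mean_um))
        return PopulationSpec(
            name=name,
            taxon=taxon,
            log_esd_mean=m,
            log_esd_sd=log_sd,
            abundance_knots=knots_from_biomass(biomass_knots, m, log_sd),
            treatment_multiplier=mult,
            instrument_domain=domain,
        )

    return [
        # Picoeukaryote wave, < 2 μm, peaking around day 57-65 at ~3.7x start.
        pop(
            "picoeukaryotes", "picoeukaryotes", 1.0, 0.10, "fcm", 1.6,
            [(1, 0.15), (33, 0.25), (49, 0.35), (57, 0.55), (65, 0.55), (81, 0.30), (113, 0.20)],
        ),
        # First nanophytoplankton bloom: broad 2-15 μm, peak day 33.
        pop(
            "nanophytoplankton_wave1", "nanophytoplankton", 5.5, 0.22, "fcm", 1.0,
            [(1, 1.63), (20, 2.5), (33, 4.50), (45, 1.5), (57, 0.50), (81, 0.30), (113, 0.30)],
        ),
        # Second, narrower nano bloom: 4-8 μm, peak day 57.
        pop(
            "nanophytoplankton_wave2", "nanophytoplankton", 5.7, 0.08, "fcm", 1.0,
            [(1, 0.0), (41, 0.0), (50, 1.2), (57, 2.90), (65, 1.00), (81, 0.20), (113, 0.10)],
        ),
        # Very large centric diatom, 200-500 μm ESD, single broad peak ~t40-t65.
        pop(
            "coscinodiscus", "coscinodiscus", 300.0, 0.09, "imaging", 1.3,
            [(1, 0.05), (33, 0.50), (41, 3.0), (57, 6.02), (65, 3.0), (81, 0.50), (113, 0.20)],
        ),
        # Copepodite/nauplii cohort, 200-600 μm, developing through the bloom.
        pop(
            "copepod_small", "copepod", 350.0, 0.12, "imaging", 1.4,
            [(1, 0.40), (33, 0.60), (57, 1.73), (81, 0.90), (113, 0.50)],
        ),
        # Medium (adult) copepods, 600-1000 μm, declining from day 1.
        pop(
            "copepod_medium", "copepod", 780.0, 0.055, "imaging", 1.4,
            [(1, 2.85), (33, 2.00), (57, 0.84), (81, 0.50), (113, 0.30)],
        ),
        # Large copepods, > 1 mm, disappearing entirely by the bloom peak.
        pop(
            "copepod_large", "copepod", 1100.0, 0.03, "imaging", 1.4,
            [(1, 0.18), (33, 0.08), (49, 0.0), (113, 0.0)],
        ),
        # Hydromedusae, > 1 mm, appearing mid-experiment in low numbers.
        pop(
            "hydromedusae", "hydromedusae", 1600.0, 0.06, "imaging", 0.8,
            [(1, 0.0), (25, 0.0), (33, 0.05), (57, 0.20), (81, 0.10), (113, 0.05)],
        ),
    ]


def default_mesocosms(
    replicate_noise_sd: float = DEFAULT_REPLICATE_NOISE_SD,
) -> List[MesocosmSpec]:
    """Ten mesocosms: controls M1, M3, M5, M9, M10; high CO₂ M2, M4, M6, M7, M8."""
    control = ("M1", "M3", "M5", "M9", "M10")
    high = ("M2", "M4", "M6", "M7", "M8")
    out = []
    for i, mid in enumerate(sorted(control + high, key=lambda s: int(s[1:]))):
        out.append(
            MesocosmSpec(
                mesocosm_id=mid,
                treatment=CONTROL if mid in control else HIGH_CO2,
                replicate_noise_sd=replicate_noise_sd,
                seed=i,
            )
        )
    return out


DEFAULT_DAYS = (1, 33, 57)


@dataclass
class CommunityTable:
    """Simulated ground truth: one row per particle plus sampled volumes.

    particles columns: mesocosm, treatment, day, group (population name),
    taxon, instrument, esd_um.  volumes columns: mesocosm, day, instrument,
    volume_l.
    """

    particles: pd.DataFrame
    volumes: pd.DataFrame


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def _instrument_volumes(
    pop_domain: str, fcm_volume_l: float, imaging_volume_l: float
) -> List[Tuple[str, float]]:
    if pop_domain == "fcm":
        return [("fcm", fcm_volume_l)]
    if pop_domain == "imaging":
        return [("imaging", imaging_volume_l)]
    return [("fcm", fcm_volume_l), ("imaging", imaging_volume_l)]


def simulate_community(
    populations: Sequence[PopulationSpec],
    mesocosms: Sequence[MesocosmSpec],
    days: Sequence[int],
    seed: int,
    fcm_volume_l: float = DEFAULT_FCM_VOLUME_L,
    geometry: _imaging.SamplingGeometry = _imaging.SamplingGeometry(),
) -> CommunityTable:
    """Draw a full synthetic experiment.

    For each (population, mesocosm, day) the expected count in the sampled
    volume is λ = concentration(day) × volume × treatment multiplier (high
    CO₂ only) × a mean-one log-normal replicate factor; the realized count is
    Poisson(λ) and individual ESDs are log-normal.  Fully reproducible from
    ``seed``: the stream for each (mesocosm, day, population, instrument)
    cell is keyed on indices, not on iteration order.
    """
    if not populations:
        raise ValueError("need at least one population")
    if not mesocosms:
        raise ValueError("need at least one mesocosm")
    days = list(days)
    if sorted(days) != days:
        raise ValueError("days must be sorted")
    imaging_volume_l = _imaging.effective_subsample_volume_l(geometry)

    frames = []
    volumes = []
    for im, meso in enumerate(mesocosms):
        for iday, day in enumerate(days):
            for inst_i, (instrument, volume) in enumerate(
                (("fcm", fcm_volume_l), ("imaging", imaging_volume_l))
            ):
                volumes.append(
                    {
                        "mesocosm": meso.mesocosm_id,
                        "day": day,
                        "instrument": instrument,
                        "volume_l": volume,
                    }
                )
            for ip, pop in enumerate(populations):
                for instrument, volume in _instrument_volumes(
                    pop.instrument_domain, fcm_volume_l, imaging_volume_l
                ):
                    inst_key = 0 if instrument == "fcm" else 1
                    rng = _rng_for(seed, im, iday, ip, inst_key)
                    lam = pop.concentration_at(day) * volume
                    if meso.treatment == HIGH_CO2:
                        lam *= pop.treatment_multiplier
                    if meso.replicate_noise_sd > 0:
                        sd = meso.replicate_noise_sd
                        # mean-one log-normal so anchors stay unbiased
                        lam *= rng.lognormal(-0.5 * sd * sd, sd)
                    n = int(rng.poisson(lam)) if lam > 0 else 0
                    if n == 0:
                        continue
                    esd = 10.0 ** rng.normal(pop.log_esd_mean, pop.log_esd_sd, size=n)
                    frames.append(
                        pd.DataFrame(
                            {
                                "mesocosm": meso.mesocosm_id,
                                "treatment": meso.treatment,
                                "day": day,
                                "group": pop.name,
                                "taxon": pop.taxon,
                                "instrument": instrument,
                                "esd_um": esd,
                            }
                        )
                    )
    cols = ["mesocosm", "treatment", "day", "group", "taxon", "instrument", "esd_um"]
    particles = (
        pd.concat(frames, ignore_index=True)[cols]
        if frames
        else pd.DataFrame(columns=cols)
    )
    return CommunityTable(particles=particles, volumes=pd.DataFrame(volumes))


def fsc_from_esd(
    esd_um,
    calib: _fcm.CalibrationCurve = _fcm.CalibrationCurve(),
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Invert the FSC→ESD power law, with optional multiplicative noise.

    FSC = (esd/a)^(1/b), times a mean-one log-normal factor with coefficient
    of variation ``noise_cv``.  With noise_cv = 0 this is the exact inverse
    of the calibration curve.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    fsc = calib.fsc(esd_um)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("rng required when noise_cv > 0")
        sigma = np.sqrt(np.log1p(noise_cv**2))
        fsc = fsc * rng.lognormal(-0.5 * sigma * sigma, sigma, size=np.shape(fsc) or None)
    return fsc


def community_to_fcm_events(
    table: CommunityTable,
    mesocosm: str,
    day: int,
    calib: _fcm.CalibrationCurve = _fcm.CalibrationCurve(),
    noise_cv: float = DEFAULT_FSC_NOISE_CV,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table (fsc, fluorescent) for one mesocosm/day's FCM particles."""
    p = table.particles
    sel = p[(p["mesocosm"] == mesocosm) & (p["day"] == day) & (p["instrument"] == "fcm")]
    rng = _rng_for(seed, 7001, _stable_hash(mesocosm), day)
    fsc = fsc_from_esd(sel["esd_um"].to_numpy(dtype=float), calib, noise_cv, rng) if len(sel) else np.empty(0)
    return pd.DataFrame({"fsc": fsc, "fluorescent": True})


def community_to_object_table(
    table: CommunityTable,
    mesocosm: str,
    day: int,
    pixel_size_um: float = 25400.0 / _imaging.DEFAULT_DPI,
) -> pd.DataFrame:
    """ZooProcess-style object table for one mesocosm/day's imaged particles.

    Simulated organisms are treated as spheres: the pixel area is the disk of
    the particle's ESD at the given pixel pitch, axes equal the ESD, and
    biovolume is (π/6)·ESD³.  Categories carry the taxon label.
    """
    p = table.particles
    sel = p[(p["mesocosm"] == mesocosm) & (p["day"] == day) & (p["instrument"] == "imaging")]
    esd = sel["esd_um"].to_numpy(dtype=float)
    area_px = np.pi * (esd / 2.0) ** 2 / pixel_size_um**2
    return pd.DataFrame(
        {
            "id": np.arange(len(sel)),
            "area_px": np.round(area_px).astype(int),
            "esd_um": esd,
            "major_um": esd,
            "minor_um": esd,
            "biovolume_mm3": _spectra.sphere_biovolume_mm3(esd),
            "category": sel["taxon"].to_numpy(),
        }
    )


def _stable_hash(text: str) -> int:
    """Deterministic small non-negative integer from a string."""
    h = 0
    for ch in str(text):
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def render_scan_plate(
    objects: Sequence[Tuple[Tuple[float, float], float, float, float]],
    dpi: int = _imaging.DEFAULT_DPI,
    shape: Tuple[int, int] = (512, 512),
    background_grey: int = 230,
    particle_grey: int = 60,
) -> _imaging.ScanImage:
    """Render non-touching ellipses onto a greyscale plate.

    ``objects`` are (center_px (row, col), major_um, minor_um,
    orientation_rad) tuples.  Ellipses must fit inside the canvas and must
    not overlap or touch — the scanning protocol separates organisms by hand,
    and the renderer enforces the same guarantee so segmentation fixtures
    have an unambiguous ground truth.
    """
    if not 0 <= background_grey <= 255 or not 0 <= particle_grey <= 255:
        raise ValueError("grey levels must be 8-bit")
    if particle_grey == background_grey:
        raise ValueError("particle grey must differ from background")
    px_um = _imaging.pixel_size_from_dpi(dpi)
    img = np.full(shape, background_grey, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)
    for (r0, c0), major_um, minor_um, theta in objects:
        if minor_um > major_um:
            raise ValueError("minor axis exceeds major axis")
        a_px = (major_um / px_um) / 2.0
        b_px = (minor_um / px_um) / 2.0
        rr, cc = _skdraw.ellipse(r0, c0, b_px, a_px, rotation=theta)
        if (
            len(rr) == 0
            or rr.min() < 0
            or cc.min() < 0
            or rr.max() >= shape[0]
            or cc.max() >= shape[1]
        ):
            raise ValueError("ellipse outside canvas")
        if occupied[rr, cc].any():
            raise ValueError("overlapping ellipses are not allowed on a plate")
        occupied[rr, cc] = True
        img[rr, cc] = particle_grey
    return _imaging.ScanImage(pixels=img, dpi=dpi)


def simulate_group_biomass(
    populations: Sequence[PopulationSpec],
    mesocosms: Sequence[MesocosmSpec],
    day: int,
    seed: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Summary-level draw of per-(mesocosm, population) biomass on one day.

    Applies the treatment multiplier and the mean-one log-normal replicate
    factor to the analytic expected biomass, skipping particle-level Poisson
    sampling.  For group totals of hundreds of individuals the counting
    noise is negligible next to the replicate noise, so this is the fast
    stand-in used for repeated-experiment statistical checks.
    """
    if rng is None:
        rng = _rng_for(seed, 9001, day)
    rows = []
    for meso in mesocosms:
        for pop in populations:
            expected = pop.concentration_at(day) * pop.mean_individual_biomass_mg()
            if meso.treatment == HIGH_CO2:
                expected *= pop.treatment_multiplier
            sd = meso.replicate_noise_sd
            factor = rng.lognormal(-0.5 * sd * sd, sd) if sd > 0 else 1.0
            rows.append(
                {
                    "mesocosm": meso.mesocosm_id,
                    "treatment": meso.treatment,
                    "day": day,
                    "group": pop.name,
                    "taxon": pop.taxon,
                    "biomass_mg_per_l": expected * factor,
                }
            )
    return pd.DataFrame(rows)


def write_config(path, populations, mesocosms, days, seed) -> None:
    """Serialize a simulator configuration as YAML."""
    import yaml

    doc = {
        "seed": int(seed),
        "days": [int(d) for d in days],
        "populations": [dataclasses.asdict(p) for p in populations],
        "mesocosms": [dataclasses.asdict(m) for m in mesocosms],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_config(path):
    """Load a simulator configuration written by :func:`write_config`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pops = [
        PopulationSpec(
            name=p["name"],
            taxon=p.get("taxon", ""),
            log_esd_mean=p["log_esd_mean"],
            log_esd_sd=p["log_esd_sd"],
            abundance_knots=tuple(tuple(k) for k in p["abundance_knots"]),
            treatment_multiplier=p.get("treatment_multiplier", 1.0),
            instrument_domain=p.get("instrument_domain", "fcm"),
        )
        for p in doc["populations"]
    ]
    mesos = [MesocosmSpec(**m) for m in doc["mesocosms"]]
    return pops, mesos, list(doc["days"]), int(doc["seed"])
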