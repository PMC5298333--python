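"""End-to-end pipeline: simulate → size events/objects → spectra → compare.

The pipeline wires the stages together exactly as a mesocosm campaign would
be processed: flow-cytometry event tables are converted to sized particles
through the FSC→ESD calibration, scan object tables are filtered (minimum
classified size, disturbance removal) and scaled by the net-tow subsampling
geometry, both instrument ranges are merged into one particle set per
(mesocosm, day), log-binned PSS/WBS spectra and slope fits are computed, and
treatment arms are compared per plankton group and per size class.

Everything is driven by a :class:`PipelineConfig` whose defaults are the
study constants: calibration a = 0.0064, b = 0.5262, wet-weight density
1.060 g cm⁻³, net geometry 0.17 m × 17 m with a 20 mL / 500 mL subsample,
2400 dpi scans, 150 μm minimum classified size, α = 0.05.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import flowcytometry as fcm
from . import imaging
from . import spectra
from . import stats
from . import synthetic


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, defaulted to the study constants."""

    seed: int = 0
    days: Tuple[int, ...] = synthetic.DEFAULT_DAYS
    populations: Sequence[synthetic.PopulationSpec] = field(
        default_factory=synthetic.default_populations
    )
    mesocosms: Sequence[synthetic.MesocosmSpec] = field(
        default_factory=synthetic.default_mesocosms
    )
    calibration_a: float = fcm.DEFAULT_CALIBRATION_A
    calibration_b: float = fcm.DEFAULT_CALIBRATION_B
    fcm_volume_l: float = synthetic.DEFAULT_FCM_VOLUME_L
    fsc_noise_cv: float = synthetic.DEFAULT_FSC_NOISE_CV
    geometry: imaging.SamplingGeometry = field(default_factory=imaging.SamplingGeometry)
    dpi: int = imaging.DEFAULT_DPI
    min_esd_um: float = imaging.MIN_CLASSIFIED_ESD_UM
    s_min_um: float = 0.5
    s_max_um: float = 2500.0
    bins_per_decade: int = 12
    crossover_um: Tuple[float, float] = spectra.DEFAULT_CROSSOVER_UM
    density_g_cm3: float = spectra.DEFAULT_DENSITY_G_CM3
    alpha: float = stats.DEFAULT_ALPHA
    df_rule: str = "pooled"
    comparison_day: int = 57

    def __post_init__(self):
        if not self.mesocosms:
            raise ValueError("configuration needs at least one mesocosm")
        if not self.populations:
            raise ValueError("configuration needs at least one population")
        if not self.days:
            raise ValueError("configuration needs at least one sampling day")

    @property
    def calibration(self) -> fcm.CalibrationCurve:
        return fcm.CalibrationCurve(a=self.calibration_a, b=self.calibration_b)

    @property
    def design(self) -> stats.TreatmentDesign:
        return stats.TreatmentDesign(
            assignment={m.mesocosm_id: m.treatment for m in self.mesocosms}
        )


@dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    config: PipelineConfig
    community: synthetic.CommunityTable
    particles: pd.DataFrame
    spectra: Dict[Tuple[str, int], spectra.Spectrum]
    slopes: pd.DataFrame
    biomass_table: pd.DataFrame
    group_comparisons: pd.DataFrame
    class_comparisons: pd.DataFrame
    gap_um: Tuple[float, float]


def _process_mesocosm_day(
    config: PipelineConfig,
    community: synthetic.CommunityTable,
    mesocosm: str,
    day: int,
) -> pd.DataFrame:
    """Instrument-level processing for one (mesocosm, day) sample."""
    events = synthetic.community_to_fcm_events(
        community, mesocosm, day,
        calib=config.calibration, noise_cv=config.fsc_noise_cv, seed=config.seed,
    )
    fcm_particles, _ = fcm.events_to_particles(
        events, config.calibration, config.fcm_volume_l, mesocosm=mesocosm, day=day,
    )
    if len(fcm_particles):
        # cytometry carries no taxon labels; group by phytoplankton size class
        fcm_particles["group"] = fcm.assign_phyto_class(
            fcm_particles["esd_um"].to_numpy(dtype=float)
        )

    objects = synthetic.community_to_object_table(
        community, mesocosm, day,
        pixel_size_um=imaging.pixel_size_from_dpi(config.dpi),
    )
    objects = objects[objects["category"] != "disturbance"]
    objects = objects[objects["esd_um"] >= config.min_esd_um]
    img_particles = imaging.object_table_to_particles(
        objects,
        imaging.effective_subsample_volume_l(config.geometry),
        mesocosm=mesocosm,
        day=day,
        density_g_cm3=config.density_g_cm3,
    )
    combined, _ = spectra.merge_instruments(
        fcm_particles, img_particles, crossover_um=config.crossover_um
    )
    return combined


def run_pipeline(config: PipelineConfig, outdir: Optional[Path] = None) -> PipelineResult:
    """Run every stage; optionally write the full report bundle to ``outdir``.

    Deterministic for a given (config, seed): running twice writes
    byte-identical tables.
    """
    community = synthetic.simulate_community(
        config.populations,
        config.mesocosms,
        list(config.days),
        config.seed,
        fcm_volume_l=config.fcm_volume_l,
        geometry=config.geometry,
    )

    bins = spectra.build_bins(config.s_min_um, config.s_max_um, config.bins_per_decade)
    gap = config.crossover_um

    frames: List[pd.DataFrame] = []
    spectra_by_key: Dict[Tuple[str, int], spectra.Spectrum] = {}
    slope_rows = []
    for meso in config.mesocosms:
        for day in config.days:
            part = _process_mesocosm_day(config, community, meso.mesocosm_id, day)
            frames.append(part)
            spec = spectra.compute_spectrum(part, bins, gap_um=gap)
            spectra_by_key[(meso.mesocosm_id, day)] = spec
            try:
                fit = spectra.fit_slope(spec)
                slope_rows.append(
                    {
                        "mesocosm": meso.mesocosm_id,
                        "day": day,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "n_bins_used": fit.n_bins_used,
                    }
                )
            except ValueError:
                slope_rows.append(
                    {
                        "mesocosm": meso.mesocosm_id,
                        "day": day,
                        "slope": np.nan,
                        "intercept": np.nan,
                        "r_squared": np.nan,
                        "n_bins_used": 0,
                    }
                )

    particles = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    slopes = pd.DataFrame(slope_rows)
    biomass_table = spectra.group_biomass_table(particles)

    design = config.design
    cmp_day = config.comparison_day if config.comparison_day in config.days else config.days[-1]
    day_bio = biomass_table[biomass_table["day"] == cmp_day]
    group_comparisons = stats.compare_by_class(
        day_bio, design, class_column="group", alpha=config.alpha
    )

    # Per-size-class comparison on WBS values at the comparison day.
    rows = []
    for meso in config.mesocosms:
        spec = spectra_by_key[(meso.mesocosm_id, cmp_day)]
        for i in np.nonzero(spec.observed)[0]:
            rows.append(
                {
                    "mesocosm": meso.mesocosm_id,
                    "group": f"bin_{i:03d}",
                    "esd_mid_um": bins.midpoints_um[i],
                    "biomass_mg_per_l": spec.wbs[i],
                }
            )
    wbs_long = pd.DataFrame(rows)
    # only test classes observed in at least one mesocosm
    seen = wbs_long.groupby("group")["biomass_mg_per_l"].sum()
    wbs_long = wbs_long[wbs_long["group"].isin(seen[seen > 0].index)]
    class_comparisons = stats.compare_by_class(
        wbs_long, design, class_column="group", alpha=config.alpha
    )
    mid_by_bin = wbs_long.drop_duplicates("group").set_index("group")["esd_mid_um"]
    class_comparisons.insert(
        1, "esd_mid_um", class_comparisons["class"].map(mid_by_bin).to_numpy()
    )

    result = PipelineResult(
        config=config,
        community=community,
        particles=particles,
        spectra=spectra_by_key,
        slopes=slopes,
        biomass_table=biomass_table,
        group_comparisons=group_comparisons,
        class_comparisons=class_comparisons,
        gap_um=gap,
    )
    if outdir is not None:
        write_report(result, Path(outdir))
    return result


def treatment_mean_biomass(result: PipelineResult, group: str, day: int, treatment: str):
    """Mean ± SE of a biomass-table row across one treatment's mesocosms."""
    design = result.config.design
    mesos = design.control if treatment == "control" else design.high_co2
    tbl = result.biomass_table
    sel = tbl[(tbl["group"] == group) & (tbl["day"] == day)].set_index("mesocosm")
    values = [float(sel["biomass_mg_per_l"].get(m, 0.0)) for m in mesos]
    return stats.summarize(values)


def write_report(result: PipelineResult, outdir: Path) -> None:
    """Write the full report bundle as delimited text files plus a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = result.config

    result.particles.to_csv(outdir / "particles.csv", index=False)
    result.community.volumes.to_csv(outdir / "sampled_volumes.csv", index=False)
    for (meso, day), spec in result.spectra.items():
        spec.to_frame().to_csv(outdir / f"spectrum_{meso}_t{day:03d}.csv", index=False)
    result.slopes.to_csv(outdir / "slope_fits.csv", index=False)
    result.biomass_table.to_csv(outdir / "biomass_table.csv", index=False)
    result.group_comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    result.class_comparisons.to_csv(outdir / "class_comparisons.csv", index=False)

    log = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "days": list(config.days),
        "n_mesocosms": len(config.mesocosms),
        "calibration": {"a": config.calibration_a, "b": config.calibration_b},
        "fcm_volume_l": config.fcm_volume_l,
        "fsc_noise_cv": config.fsc_noise_cv,
        "geometry": dataclasses.asdict(config.geometry),
        "dpi": config.dpi,
        "min_esd_um": config.min_esd_um,
        "bins": {
            "s_min_um": config.s_min_um,
            "s_max_um": config.s_max_um,
            "bins_per_decade": config.bins_per_decade,
        },
        "crossover_um": list(config.crossover_um),
        "density_g_cm3": config.density_g_cm3,
        "alpha": config.alpha,
        "df_rule": config.df_rule,
        "comparison_day": config.comparison_day,
        "expected_false_positives_per_spectrum": result.class_comparisons.attrs.get(
            "expected_false_positives"
        ),
        "populations": [dataclasses.asdict(p) for p in config.populations],
        "mesocosms": [dataclasses.asdict(m) for m in config.mesocosms],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
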