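import numpy as np
import pandas as pd
import pytest

from plankspectra import flowcytometry as fcm
from plankspectra import imaging, synthetic


@pytest.fixture(scope="session")
def calib():
    return fcm.CalibrationCurve()


@pytest.fixture(scope="session")
def geometry():
    return imaging.SamplingGeometry()


@pytest.fixture(scope="session")
def pixel_size():
    return imaging.pixel_size_from_dpi(imaging.DEFAULT_DPI)


def particle_frame(esd_um, weight_per_l=1.0, biomass_mg=None, group="x", **extra):
    """Minimal particle table for binning tests."""
    esd = np.asarray(esd_um, dtype=float)
    if biomass_mg is None:
        from plankspectra.spectra import biomass_from_biovolume, sphere_biovolume_mm3

        bv = sphere_biovolume_mm3(esd)
        biomass_mg = biomass_from_biovolume(bv)
    else:
        bv = np.asarray(biomass_mg, dtype=float) / 1.060
    return pd.DataFrame(
        {
            "mesocosm": extra.get("mesocosm", "M1"),
            "day": extra.get("day", 1),
            "group": group,
            "esd_um": esd,
            "biovolume_mm3": bv,
            "biomass_mg": biomass_mg,
            "weight_per_l": weight_per_l,
            "instrument": extra.get("instrument", "fcm"),
        }
    )


@pytest.fixture(scope="session")
def small_community():
    """Two-population, two-mesocosm table for plumbing tests."""
    pops = [
        synthetic.PopulationSpec(
            name="nano", taxon="nanophytoplankton", log_esd_mean=0.7, log_esd_sd=0.1,
            abundance_knots=((1.0, 2.0e6), (57.0, 4.0e6)), instrument_domain="fcm",
        ),
        synthetic.PopulationSpec(
            name="cop", taxon="copepod", log_esd_mean=2.9, log_esd_sd=0.05,
            abundance_knots=((1.0, 8.0), (57.0, 4.0)), treatment_multiplier=1.4,
            instrument_domain="imaging",
        ),
    ]
    mesos = [
        synthetic.MesocosmSpec(mesocosm_id="M1", treatment="control", replicate_noise_sd=0.1),
        synthetic.MesocosmSpec(mesocosm_id="M2", treatment="high_co2", replicate_noise_sd=0.1),
    ]
    return synthetic.simulate_community(pops, mesos, [1, 57], seed=11)
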