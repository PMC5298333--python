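"""Flow-cytometry event sizing: forward scatter → equivalent spherical diameter.

A flow cytometer reports a dimensionless forward-scatter area (FSC) per
detected particle rather than a physical size.  Size-fractionating a natural
sample through polycarbonate filters of known pore size and re-running each
fraction ties the FSC scale to particle diameter: every increment in pore
size admits a new particle class with higher FSC, and a power law

    ESD = a × FSC^b

fitted through those (pore size, FSC) pairs converts scatter to equivalent
spherical diameter (μm).  The default coefficients a = 0.0064, b = 0.5262
are instrument-specific; refit them for any other cytometer/gain setting.

Event tables are delimited text with at least the columns ``fsc`` and
``fluorescent`` (the instrument triggers on fluorescence, so non-fluorescent
rows are discarded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import spectra as _spectra

#: Power-law coefficients of the default FSC→ESD calibration.
DEFAULT_CALIBRATION_A = 0.0064
DEFAULT_CALIBRATION_B = 0.5262

#: Approximate ESD range (μm) over which fluorescence-triggered counting is
#: considered quantitative for this instrument class.
FCM_SIZE_RANGE_UM = (0.5, 60.0)

#: Phytoplankton size classes on ESD, half-open [lower, upper) in μm.
PHYTO_CLASS_EDGES_UM = (2.0, 20.0)
PHYTO_CLASS_LABELS = ("pico", "nano", "micro")


@dataclass(frozen=True)
class CalibrationCurve:
    """FSC→ESD power law ``esd = a * fsc**b``.

    ``fsc_range`` optionally records the FSC span of the calibration data;
    conversions more than one decade outside it are flagged as extrapolated.
    """

    a: float = DEFAULT_CALIBRATION_A
    b: float = DEFAULT_CALIBRATION_B
    fsc_range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("coefficient a must be positive")
        if not 0 < self.b < 1:
            raise ValueError("exponent b must lie in (0, 1)")

    def esd(self, fsc):
        return esd_from_fsc(fsc, self)

    def fsc(self, esd):
        """Inverse map, ``fsc = (esd / a)**(1/b)``."""
        e = np.asarray(esd, dtype=float)
        if np.any(e <= 0):
            raise ValueError("esd must be positive")
        out = (e / self.a) ** (1.0 / self.b)
        return float(out) if np.isscalar(esd) else out

    def extrapolated(self, fsc) -> np.ndarray:
        """True where ``fsc`` lies > 1 decade outside the calibrated span."""
        f = np.asarray(fsc, dtype=float)
        if self.fsc_range is None:
            return np.zeros(f.shape, dtype=bool)
        lo, hi = self.fsc_range
        return (f < lo / 10.0) | (f > hi * 10.0)


@dataclass(frozen=True)
class CalibrationFit:
    """Result of :func:`fit_calibration`."""

    curve: CalibrationCurve
    r_squared: float
    n_points: int


def esd_from_fsc(fsc, calib: CalibrationCurve = CalibrationCurve()):
    """Convert forward scatter to ESD in μm via the power-law calibration."""
    f = np.asarray(fsc, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fsc must be positive")
    out = calib.a * f**calib.b
    return float(out) if np.isscalar(fsc) else out


def fit_calibration(fractions: Sequence[Tuple[float, float]]) -> CalibrationFit:
    """Fit the FSC→ESD power law from size-fractionation data.

    ``fractions`` are (pore size μm, representative FSC) pairs — one per
    filter, the FSC being the median of the particle class newly appearing at
    that pore size.  Ordinary least squares on log10(ESD) vs log10(FSC)
    yields (a, b).  At least three pairs, strictly increasing in both
    coordinates, are required.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 2 or fr.shape[1] != 2 or fr.shape[0] < 3:
        raise ValueError("need >= 3 (pore_size, fsc) pairs")
    pore, fsc = fr[:, 0], fr[:, 1]
    if np.any(pore <= 0) or np.any(fsc <= 0):
        raise ValueError("pore sizes and FSC values must be positive")
    if np.any(np.diff(pore) <= 0) or np.any(np.diff(fsc) <= 0):
        raise ValueError(
            "fractionation data must be strictly increasing in both pore size "
            "and FSC; check filter order and class assignment"
        )
    res = _sps.linregress(np.log10(fsc), np.log10(pore))
    curve = CalibrationCurve(
        a=float(10.0**res.intercept),
        b=float(res.slope),
        fsc_range=(float(fsc.min()), float(fsc.max())),
    )
    return CalibrationFit(curve=curve, r_squared=float(res.rvalue**2), n_points=len(pore))


def assign_phyto_class(esd_um):
    """Pico/nano/micro class for a positive ESD (μm).

    Half-open bounds: pico [0, 2), nano [2, 20), micro [20, ∞), so 2 μm is
    nano and 20 μm is micro.  Vectorized; returns a scalar for scalar input.
    """
    e = np.asarray(esd_um, dtype=float)
    if np.any(e <= 0):
        raise ValueError("esd must be positive")
    idx = np.searchsorted(np.asarray(PHYTO_CLASS_EDGES_UM), e, side="right")
    labels = np.asarray(PHYTO_CLASS_LABELS)[idx]
    return str(labels) if np.isscalar(esd_um) else labels


@dataclass
class DiscardLog:
    """Bookkeeping for events removed during conversion."""

    n_input: int = 0
    n_non_fluorescent: int = 0
    n_out_of_range: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_non_fluorescent - self.n_out_of_range


def events_to_particles(
    events: pd.DataFrame,
    calib: CalibrationCurve,
    analyzed_volume_l: float,
    size_range_um: Tuple[float, float] = FCM_SIZE_RANGE_UM,
    mesocosm: str = "",
    day: int = 0,
    group: str = "fcm",
) -> Tuple[pd.DataFrame, DiscardLog]:
    """Convert an event table to sized particle records.

    Each retained (fluorescent, in-range) event becomes one particle with the
    calibrated ESD, spherical biovolume (π/6)·ESD³, wet-weight biomass, and a
    concentration weight of 1/analyzed_volume # L^-1.  Events whose ESD falls
    outside ``size_range_um`` are dropped and counted in the returned
    :class:`DiscardLog`; extrapolated conversions are flagged, not dropped.
    """
    if analyzed_volume_l <= 0:
        raise ValueError("analyzed volume must be positive")
    log = DiscardLog(n_input=len(events))
    if len(events) == 0:
        return pd.DataFrame(columns=_spectra.PARTICLE_COLUMNS + ["extrapolated"]), log

    fluor = (
        events["fluorescent"].astype(bool).to_numpy()
        if "fluorescent" in events.columns
        else np.ones(len(events), dtype=bool)
    )
    log.n_non_fluorescent = int(np.sum(~fluor))
    fsc = events.loc[fluor, "fsc"].to_numpy(dtype=float)
    if np.any(fsc <= 0):
        raise ValueError("fsc must be positive for retained events")

    esd = esd_from_fsc(fsc, calib)
    lo, hi = size_range_um
    in_range = (esd >= lo) & (esd <= hi)
    log.n_out_of_range = int(np.sum(~in_range))
    esd, fsc = esd[in_range], fsc[in_range]

    bv = _spectra.sphere_biovolume_mm3(esd)
    particles = pd.DataFrame(
        {
            "mesocosm": mesocosm,
            "day": day,
            "group": group,
            "esd_um": esd,
            "biovolume_mm3": bv,
            "biomass_mg": _spectra.biomass_from_biovolume(bv),
            "weight_per_l": 1.0 / analyzed_volume_l,
            "instrument": "fcm",
            "extrapolated": calib.extrapolated(fsc),
        }
    )
    return particles, log


def read_event_table(path) -> pd.DataFrame:
    """Read a delimited event table with columns (fsc, fluorescent, ...)."""
    df = pd.read_csv(path)
    if "fsc" not in df.columns:
        raise ValueError(f"{path}: expected an 'fsc' column")
    return df
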