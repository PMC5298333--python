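"""Normalized particle size spectra (PSS) and weighted biomass spectra (WBS).

The normalized abundance spectrum divides the particle concentration in each
logarithmically spaced ESD class by the linear width of that class, giving
units of # L^-1 mm^-1.  The weighted biomass spectrum multiplies the PSS back
by the mean individual biomass and the class width, i.e. it is the absolute
wet-weight biomass concentration (mg L^-1) resolved per log-spaced size class.
Both are standard representations of the aquatic (Sheldon-type) size spectrum.

Particle collections are plain :class:`pandas.DataFrame` objects with the
columns listed in :data:`PARTICLE_COLUMNS`; sizes are ESD in μm, biovolume in
mm³, biomass in mg wet weight, and each particle carries a concentration
weight in # L^-1 (the reciprocal of the volume it was sampled from).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

#: Wet-weight tissue density used to convert biovolume to biomass,
#: in g cm^-3 (numerically equal to mg mm^-3).
DEFAULT_DENSITY_G_CM3 = 1.060

#: Column schema for particle tables.
PARTICLE_COLUMNS = [
    "mesocosm",
    "day",
    "group",
    "esd_um",
    "biovolume_mm3",
    "biomass_mg",
    "weight_per_l",
    "instrument",
]


def biomass_from_biovolume(biovolume_mm3, density_g_cm3: float = DEFAULT_DENSITY_G_CM3):
    """Convert biovolume (mm³) to wet-weight biomass (mg).

    1 g cm^-3 equals 1 mg mm^-3, so the conversion is a plain product.
    Accepts scalars or arrays; rejects negative biovolume.
    """
    bv = np.asarray(biovolume_mm3, dtype=float)
    if np.any(bv < 0):
        raise ValueError("biovolume must be non-negative")
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    out = bv * density_g_cm3
    return float(out) if np.isscalar(biovolume_mm3) else out


def sphere_biovolume_mm3(esd_um):
    """Biovolume (mm³) of a sphere with the given ESD in μm."""
    d_mm = np.asarray(esd_um, dtype=float) / 1000.0
    out = (np.pi / 6.0) * d_mm**3
    return float(out) if np.isscalar(esd_um) else out


@dataclass(frozen=True)
class BinGrid:
    """Logarithmically spaced ESD size classes.

    edges_um
        Strictly increasing bin edges in μm, equally spaced in log10.
    widths_mm
        Linear width of each class (upper − lower) converted to mm; this is
        the Δs by which per-class abundance is normalized.
    midpoints_um
        Geometric midpoints, sqrt(lower × upper).

    Bins are half-open ``[lower, upper)`` on ESD.
    """

    edges_um: np.ndarray
    widths_mm: np.ndarray = field(init=False)
    midpoints_um: np.ndarray = field(init=False)

    def __post_init__(self):
        edges = np.asarray(self.edges_um, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] <= 0:
            raise ValueError("bin edges must be positive")
        object.__setattr__(self, "edges_um", edges)
        object.__setattr__(self, "widths_mm", np.diff(edges) / 1000.0)
        object.__setattr__(self, "midpoints_um", np.sqrt(edges[:-1] * edges[1:]))

    @property
    def n_bins(self) -> int:
        return self.edges_um.size - 1

    def assign(self, esd_um) -> np.ndarray:
        """Bin index for each ESD; −1 for values outside the grid."""
        esd = np.asarray(esd_um, dtype=float)
        idx = np.searchsorted(self.edges_um, esd, side="right") - 1
        idx[(esd < self.edges_um[0]) | (esd >= self.edges_um[-1])] = -1
        return idx


def build_bins(s_min_um: float, s_max_um: float, bins_per_decade: int = 12) -> BinGrid:
    """Build a log-spaced :class:`BinGrid` covering ``[s_min, s_max]``.

    Edges sit at ``s_min × 10^(k / bins_per_decade)``; the last edge is the
    first one at or above ``s_max``, so the grid always covers the requested
    range.  The default of 12 bins per decade resolves classes about 0.083
    decades wide.
    """
    if not (0 < s_min_um < s_max_um):
        raise ValueError("require 0 < s_min < s_max")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    n = int(np.ceil(bins_per_decade * np.log10(s_max_um / s_min_um) - 1e-9))
    k = np.arange(n + 1)
    edges = s_min_um * 10.0 ** (k / bins_per_decade)
    return BinGrid(edges_um=edges)


@dataclass
class Spectrum:
    """Binned size spectrum.

    pss
        Normalized abundance per bin, # L^-1 mm^-1.
    wbs
        Absolute biomass concentration per bin, mg L^-1.
    counts
        Raw number of particles per bin.
    observed
        False for bins flagged as instrument-coverage gaps; such bins are
        excluded from slope fits by default.
    n_dropped
        Particles whose ESD fell outside the grid.
    """

    bins: BinGrid
    pss: np.ndarray
    wbs: np.ndarray
    counts: np.ndarray
    observed: np.ndarray
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        b = self.bins
        return pd.DataFrame(
            {
                "esd_lower_um": b.edges_um[:-1],
                "esd_upper_um": b.edges_um[1:],
                "esd_mid_um": b.midpoints_um,
                "width_mm": b.widths_mm,
                "count": self.counts,
                "pss_per_l_per_mm": self.pss,
                "wbs_mg_per_l": self.wbs,
                "observed": self.observed,
            }
        )


def _mark_gap(bins: BinGrid, gap_um) -> np.ndarray:
    observed = np.ones(bins.n_bins, dtype=bool)
    if gap_um is not None:
        lo, hi = gap_um
        inside = (bins.edges_um[:-1] >= lo) & (bins.edges_um[1:] <= hi)
        observed[inside] = False
    return observed


def compute_spectrum(particles: pd.DataFrame, bins: BinGrid, gap_um=None) -> Spectrum:
    """Compute PSS and WBS in one pass over a particle table.

    PSS_i = (Σ weights in bin i) / Δs_i and WBS_i = Σ (biomass × weight) in
    bin i.  The direct biomass sum is checked (to relative 1e-12) against the
    literal normalized form PSS_i × mean individual biomass_i × Δs_i; the two
    are algebraically identical, so a mismatch indicates corrupt input.
    """
    nb = bins.n_bins
    esd = particles["esd_um"].to_numpy(dtype=float) if len(particles) else np.empty(0)
    w = particles["weight_per_l"].to_numpy(dtype=float) if len(particles) else np.empty(0)
    bm = particles["biomass_mg"].to_numpy(dtype=float) if len(particles) else np.empty(0)

    idx = bins.assign(esd)
    inside = idx >= 0
    n_dropped = int(np.sum(~inside))
    idx, w_in, bm_in = idx[inside], w[inside], bm[inside]

    counts = np.bincount(idx, minlength=nb).astype(int)
    conc = np.bincount(idx, weights=w_in, minlength=nb)
    wbs = np.bincount(idx, weights=w_in * bm_in, minlength=nb)
    pss = conc / bins.widths_mm

    # Cross-check the normalized-form identity on non-empty bins.
    nz = conc > 0
    mean_bm = np.zeros(nb)
    mean_bm[nz] = wbs[nz] / conc[nz]
    literal = pss[nz] * mean_bm[nz] * bins.widths_mm[nz]
    if not np.allclose(literal, wbs[nz], rtol=1e-12, atol=0.0):
        raise AssertionError("biomass-spectrum identity violated")

    return Spectrum(
        bins=bins,
        pss=pss,
        wbs=wbs,
        counts=counts,
        observed=_mark_gap(bins, gap_um),
        n_dropped=n_dropped,
    )


def compute_pss(particles: pd.DataFrame, bins: BinGrid, gap_um=None) -> Spectrum:
    """Normalized abundance spectrum; see :func:`compute_spectrum`."""
    return compute_spectrum(particles, bins, gap_um=gap_um)


def compute_wbs(particles: pd.DataFrame, bins: BinGrid, gap_um=None) -> Spectrum:
    """Weighted biomass spectrum; see :func:`compute_spectrum`."""
    return compute_spectrum(particles, bins, gap_um=gap_um)


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    r_squared: float
    n_bins_used: int


def fit_slope(spectrum: Spectrum, size_range_um=None) -> SlopeFit:
    """OLS fit of log10(PSS) against log10(class midpoint).

    Only observed bins with a positive particle count enter the fit (the log
    of an empty class is undefined; no pseudo-counts are added).  An optional
    ESD range restricts the fitted bins.  Requires at least three usable bins.
    """
    b = spectrum.bins
    use = spectrum.observed & (spectrum.counts > 0) & (spectrum.pss > 0)
    if size_range_um is not None:
        lo, hi = size_range_um
        use &= (b.midpoints_um >= lo) & (b.midpoints_um <= hi)
    n = int(use.sum())
    if n < 3:
        raise ValueError(f"need >= 3 usable bins for a slope fit, got {n}")
    x = np.log10(b.midpoints_um[use])
    y = np.log10(spectrum.pss[use])
    res = _sps.linregress(x, y)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_bins_used=n,
    )


DEFAULT_CROSSOVER_UM = (60.0, 150.0)


def merge_instruments(
    fcm: pd.DataFrame,
    imaging: pd.DataFrame,
    crossover_um=DEFAULT_CROSSOVER_UM,
):
    """Concatenate flow-cytometry and imaging particle tables.

    The two instruments cover disjoint size domains that meet at an
    unobserved gap (by default 60–150 μm: above the cytometer's upper limit,
    below the imaging classification minimum).  Records on the wrong side of
    their instrument's crossover are flagged in an ``out_of_domain`` column —
    not dropped.  Returns ``(combined, gap)`` where ``gap`` is the (lo, hi)
    μm interval to pass to :func:`compute_spectrum` so that bins wholly
    inside it are marked unobserved.
    """
    lo, hi = crossover_um
    if not lo < hi:
        raise ValueError("crossover interval must be increasing")
    parts = []
    for df, instrument, bad in (
        (fcm, "fcm", lambda e: e > lo),
        (imaging, "imaging", lambda e: e < hi),
    ):
        if df is None or len(df) == 0:
            continue
        df = df.copy()
        if "instrument" not in df.columns:
            df["instrument"] = instrument
        df["out_of_domain"] = bad(df["esd_um"].to_numpy(dtype=float))
        parts.append(df)
    if parts:
        combined = pd.concat(parts, ignore_index=True)
    else:
        combined = pd.DataFrame(columns=PARTICLE_COLUMNS + ["out_of_domain"])
    return combined, (lo, hi)


#: Copepod body-size classes (μm, half-open [lower, upper)).
COPEPOD_CLASS_EDGES_UM = (150.0, 600.0, 1000.0)
COPEPOD_CLASS_LABELS = (
    "Copepod S (<600 um) & nauplii",
    "Copepod M (600-1000 um)",
    "Copepod L (>1000 um)",
)


def group_biomass_table(
    particles: pd.DataFrame,
    copepod_taxa=("copepod", "nauplii"),
    split_copepods: bool = True,
) -> pd.DataFrame:
    """Per-(mesocosm, day) biomass concentration table in mg L^-1.

    Sums biomass × weight per taxon group.  Copepods (including nauplii) are
    split into S/M/L body-size classes on measured ESD, mirroring the usual
    presentation of mesozooplankton scan data; a copepod-total and a grand
    total row are appended.  Unknown groups are kept under their own label so
    nothing is silently dropped.
    """
    if len(particles) == 0:
        return pd.DataFrame(columns=["mesocosm", "day", "group", "biomass_mg_per_l"])
    df = particles.copy()
    df["biomass_conc"] = df["biomass_mg"] * df["weight_per_l"]

    is_cop = df["group"].isin(copepod_taxa)
    label = df["group"].astype(str)
    if split_copepods and is_cop.any():
        esd = df.loc[is_cop, "esd_um"].to_numpy(dtype=float)
        cls = np.searchsorted(np.asarray(COPEPOD_CLASS_EDGES_UM[1:]), esd, side="right")
        label.loc[is_cop] = np.asarray(COPEPOD_CLASS_LABELS)[cls]

    df["row"] = label
    out = (
        df.groupby(["mesocosm", "day", "row"], observed=True)["biomass_conc"]
        .sum()
        .rename("biomass_mg_per_l")
        .reset_index()
        .rename(columns={"row": "group"})
    )

    extras = []
    for (meso, day), sub in df.groupby(["mesocosm", "day"], observed=True):
        if split_copepods:
            extras.append(
                {
                    "mesocosm": meso,
                    "day": day,
                    "group": "Copepod total",
                    "biomass_mg_per_l": sub.loc[is_cop.reindex(sub.index, fill_value=False), "biomass_conc"].sum()
                    if is_cop.any()
                    else 0.0,
                }
            )
        extras.append(
            {
                "mesocosm": meso,
                "day": day,
                "group": "Total biomass",
                "biomass_mg_per_l": sub["biomass_conc"].sum(),
            }
        )
    out = pd.concat([out, pd.DataFrame(extras)], ignore_index=True)
    return out.sort_values(["mesocosm", "day", "group"]).reset_index(drop=True)


def plot_spectra(spectrum: Spectrum, axes=None):
    """Plot the PSS (log-log) and WBS (semi-log) side by side.

    Returns the two matplotlib axes.  The WBS panel uses a linear y-axis on
    purpose: absolute biomass peaks are invisible on a log scale.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_pss, ax_wbs = axes
    b = spectrum.bins
    ok = spectrum.observed & (spectrum.pss > 0)
    ax_pss.loglog(b.midpoints_um[ok], spectrum.pss[ok], "o-", ms=3)
    ax_pss.set_xlabel("ESD [um]")
    ax_pss.set_ylabel("PSS [# L$^{-1}$ mm$^{-1}$]")
    ax_wbs.semilogx(b.midpoints_um[spectrum.observed], spectrum.wbs[spectrum.observed], "o-", ms=3)
    ax_wbs.set_xlabel("ESD [um]")
    ax_wbs.set_ylabel("WBS [mg L$^{-1}$]")
    return axes


def percent_change(reference: float, value: float) -> float:
    """Percent decrease from ``reference`` to ``value``.

    Positive for a decrease, negative for an increase (a return of −31.6
    means the value rose by 31.6% relative to the reference).
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return (reference - value) / reference * 100.0
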