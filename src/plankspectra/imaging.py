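"""Scan-image morphometry for mesozooplankton subsamples.

Net-collected zooplankton are poured onto glass plates (objects manually
separated so nothing touches), scanned on a flatbed scanner, and segmented by
a grey-level threshold: objects are darker than the illuminated background.
Each connected component is measured (area, equivalent-ellipse axes,
biovolume) and scaled to an in-situ concentration through the sampling
geometry: a vertical net tow of known diameter and depth, made up to a fixed
volume, of which a fixed subsample is imaged.

Size conventions: the area-equivalent spherical diameter (ESD) is
2·sqrt(area/π); biovolume uses the prolate-spheroid form (π/6)·major·minor²
from the equivalent-ellipse axes, the usual convention for scanned
zooplankton morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from . import spectra as _spectra

#: Flatbed scan resolution used for zooplankton plates.
DEFAULT_DPI = 2400

#: Minimum reliably classifiable organism size, μm (approximate).
MIN_CLASSIFIED_ESD_UM = 150.0

#: Default minimum component size in px² — about the pixel count of a
#: 150 μm disk at 2400 dpi (10.58 μm/px), rounded down.
DEFAULT_MIN_AREA_PX = 64

#: Copepod body-size class edges (μm); classes are half-open [lower, upper).
COPEPOD_CLASS_EDGES_UM = (150.0, 600.0, 1000.0)

OBJECT_TABLE_COLUMNS = [
    "id",
    "area_px",
    "esd_um",
    "major_um",
    "minor_um",
    "biovolume_mm3",
    "category",
]


def pixel_size_from_dpi(dpi: int) -> float:
    """Pixel pitch in μm for a scan resolution in dots per inch (25400/dpi)."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return 25400.0 / dpi


@dataclass(frozen=True)
class SamplingGeometry:
    """Net-tow and subsampling geometry linking counts to concentrations."""

    net_diameter_m: float = 0.17
    tow_depth_m: float = 17.0
    madeup_volume_ml: float = 500.0
    subsample_volume_ml: float = 20.0

    def __post_init__(self):
        if min(
            self.net_diameter_m,
            self.tow_depth_m,
            self.madeup_volume_ml,
            self.subsample_volume_ml,
        ) <= 0:
            raise ValueError("all geometry fields must be positive")
        if self.subsample_volume_ml > self.madeup_volume_ml:
            raise ValueError("subsample cannot exceed made-up volume")


def tow_volume_l(geometry: SamplingGeometry) -> float:
    """Water volume filtered by the vertical net tow, in litres."""
    r = geometry.net_diameter_m / 2.0
    return np.pi * r * r * geometry.tow_depth_m * 1000.0


def effective_subsample_volume_l(geometry: SamplingGeometry) -> float:
    """In-situ volume represented by the imaged subsample, in litres."""
    return tow_volume_l(geometry) * geometry.subsample_volume_ml / geometry.madeup_volume_ml


@dataclass(frozen=True)
class ScanImage:
    """8-bit greyscale scan plate with its resolution."""

    pixels: np.ndarray
    dpi: int = DEFAULT_DPI

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("scan image must be a 2-D grey-level array")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def pixel_size_um(self) -> float:
        return pixel_size_from_dpi(self.dpi)


@dataclass
class ObjectMask:
    """One segmented connected component."""

    mask: np.ndarray
    touches_border: bool


@dataclass
class ImagedObject:
    """Morphometric features of one segmented object."""

    pixel_area: int
    esd_um: float
    major_um: float
    minor_um: float
    biovolume_mm3: float
    category: Optional[str] = None
    touches_border: bool = False


def segment_scan(
    image: ScanImage,
    grey_threshold: int,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> List[ObjectMask]:
    """Extract object masks darker than ``grey_threshold``.

    Pixels strictly below the threshold form the foreground (objects are
    darker than the backlit background); 8-connected components smaller than
    ``min_area_px`` are discarded; components touching the image border are
    flagged but kept.  A plate that is foreground everywhere is rejected as
    implausible (wrong threshold or inverted image).
    """
    px = image.pixels
    if not 0 <= grey_threshold <= 255:
        raise ValueError("grey threshold must be within the 8-bit range")
    fg = px < grey_threshold
    if fg.all():
        raise ValueError("entire plate below threshold: implausible scan or threshold")
    labels, n = _skmeasure.label(fg, connectivity=2, return_num=True)
    out: List[ObjectMask] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if int(mask.sum()) < min_area_px:
            continue
        rows, cols = np.nonzero(mask)
        touches = bool(
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == px.shape[0] - 1
            or cols.max() == px.shape[1] - 1
        )
        out.append(ObjectMask(mask=mask, touches_border=touches))
    return out


def measure_object(mask: ObjectMask | np.ndarray, pixel_size_um: float) -> ImagedObject:
    """Measure area, ESD, equivalent-ellipse axes and biovolume of a mask.

    Axes come from second-order image moments (the ellipse with the same
    normalized moments as the region).  Degenerate regions whose moment axes
    collapse (single pixels, perfect lines) fall back to a sphere of the
    area-equivalent diameter so the biovolume stays positive.  Biovolume is
    the prolate spheroid (π/6)·major·minor² in mm³.
    """
    touches = False
    if isinstance(mask, ObjectMask):
        touches = mask.touches_border
        mask = mask.mask
    m = np.asarray(mask, dtype=bool)
    npx = int(m.sum())
    if npx == 0:
        raise ValueError("empty mask")
    area_um2 = npx * pixel_size_um**2
    esd = 2.0 * np.sqrt(area_um2 / np.pi)

    props = _skmeasure.regionprops(m.astype(np.uint8))[0]
    major = props.axis_major_length * pixel_size_um
    minor = props.axis_minor_length * pixel_size_um
    if minor <= 0 or major <= 0:
        major = minor = esd
    major_mm, minor_mm = major / 1000.0, minor / 1000.0
    biovolume = (np.pi / 6.0) * major_mm * minor_mm**2
    return ImagedObject(
        pixel_area=npx,
        esd_um=float(esd),
        major_um=float(major),
        minor_um=float(minor),
        biovolume_mm3=float(biovolume),
        touches_border=touches,
    )


def apply_min_size_filter(
    objects: Sequence[ImagedObject], min_esd_um: float = MIN_CLASSIFIED_ESD_UM
) -> Tuple[List[ImagedObject], int]:
    """Drop objects below the classification size limit; return (kept, n_removed)."""
    kept = [o for o in objects if o.esd_um >= min_esd_um]
    return kept, len(objects) - len(kept)


def remove_disturbances(objects: Sequence[ImagedObject]) -> Tuple[List[ImagedObject], int]:
    """Drop objects categorized as disturbances (bubbles, touching artefacts).

    Every object must carry a category label; "other_biomass" (marine snow,
    fibres) is biological material and is retained.
    """
    if any(o.category is None for o in objects):
        raise ValueError("all objects must carry category labels")
    kept = [o for o in objects if o.category != "disturbance"]
    return kept, len(objects) - len(kept)


def assign_copepod_class(esd_um: float) -> str:
    """S/M/L copepod body-size class for an ESD ≥ 150 μm.

    Half-open bounds: S [150, 600), M [600, 1000), L [1000, ∞), so 600 μm is
    M and 1000 μm is L.
    """
    lo = COPEPOD_CLASS_EDGES_UM[0]
    if esd_um < lo:
        raise ValueError(f"esd below classification minimum of {lo} um")
    if esd_um < COPEPOD_CLASS_EDGES_UM[1]:
        return "S"
    if esd_um < COPEPOD_CLASS_EDGES_UM[2]:
        return "M"
    return "L"


def objects_to_particles(
    objects: Sequence[ImagedObject],
    effective_volume_l: float,
    mesocosm: str = "",
    day: int = 0,
    density_g_cm3: float = _spectra.DEFAULT_DENSITY_G_CM3,
) -> pd.DataFrame:
    """Turn measured objects into particle records at 1/volume # L^-1 each."""
    if effective_volume_l <= 0:
        raise ValueError("effective volume must be positive")
    if not objects:
        return pd.DataFrame(columns=_spectra.PARTICLE_COLUMNS + ["touches_border"])
    bv = np.array([o.biovolume_mm3 for o in objects])
    return pd.DataFrame(
        {
            "mesocosm": mesocosm,
            "day": day,
            "group": [o.category if o.category is not None else "unclassified" for o in objects],
            "esd_um": [o.esd_um for o in objects],
            "biovolume_mm3": bv,
            "biomass_mg": _spectra.biomass_from_biovolume(bv, density_g_cm3),
            "weight_per_l": 1.0 / effective_volume_l,
            "instrument": "imaging",
            "touches_border": [o.touches_border for o in objects],
        }
    )


def process_plate(
    image: ScanImage,
    grey_threshold: int,
    categories: Optional[Sequence[str]] = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> List[ImagedObject]:
    """Segment a plate and measure every retained object.

    ``categories``, if given, are assigned to objects in scan order (top-left
    to bottom-right of the component bounding boxes) — useful when the taxon
    labels of a rendered fixture are known by construction.
    """
    masks = segment_scan(image, grey_threshold, min_area_px=min_area_px)
    objs = [measure_object(m, image.pixel_size_um) for m in masks]
    if categories is not None:
        if len(categories) != len(objs):
            raise ValueError(
                f"{len(categories)} categories supplied for {len(objs)} segmented objects"
            )
        objs = [replace(o, category=c) for o, c in zip(objs, categories)]
    return objs


def write_object_table(objects: Sequence[ImagedObject], path) -> None:
    """Write a ZooProcess-style tab-separated object feature table."""
    rows = [
        {
            "id": i,
            "area_px": o.pixel_area,
            "esd_um": o.esd_um,
            "major_um": o.major_um,
            "minor_um": o.minor_um,
            "biovolume_mm3": o.biovolume_mm3,
            "category": o.category if o.category is not None else "",
            "touches_border": o.touches_border,
        }
        for i, o in enumerate(objects)
    ]
    pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS + ["touches_border"]).to_csv(
        path, sep="\t", index=False
    )


def read_object_table(path) -> pd.DataFrame:
    """Read a ZooProcess-style tab-separated object table.

    Requires the columns in :data:`OBJECT_TABLE_COLUMNS`; any extra columns
    are passed through untouched.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OBJECT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing object-table columns {missing}")
    return df


def object_table_to_particles(
    table: pd.DataFrame,
    effective_volume_l: float,
    mesocosm: str = "",
    day: int = 0,
    density_g_cm3: float = _spectra.DEFAULT_DENSITY_G_CM3,
) -> pd.DataFrame:
    """Particle records from an object feature table (no image needed)."""
    if effective_volume_l <= 0:
        raise ValueError("effective volume must be positive")
    bv = table["biovolume_mm3"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "mesocosm": mesocosm,
            "day": day,
            "group": table["category"].astype(str).to_numpy(),
            "esd_um": table["esd_um"].to_numpy(dtype=float),
            "biovolume_mm3": bv,
            "biomass_mg": _spectra.biomass_from_biovolume(bv, density_g_cm3),
            "weight_per_l": 1.0 / effective_volume_l,
            "instrument": "imaging",
        }
    )
    if "touches_border" in table.columns:
        out["touches_border"] = table["touches_border"].to_numpy()
    return out
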