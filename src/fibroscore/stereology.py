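"""Positive-pixel %-area morphometry and whole-lobule stereology.

Quantitative histomorphometry expresses a stain (PSR, Col1a1, Col3,
aSMA, Gal-3 ...) as positively stained pixels relative (%) to the total
sectional tissue area.  Whole-lobule stereology combines the mean %-area
over serial sections (sampled every 300 um through the lobe) with the
lobule volume measured by fluid displacement (Archimedes principle):

    marker volume = mean %-area / 100  x  lobule volume

Positive-pixel rules are explicit hue/saturation/luminance ranges (or an
exact palette-distance rule for synthetic rasters).  The real-stain
presets are plausible editable starting points, not calibrated against
any commercial analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.color import rgb2gray, rgb2hsv

from .imaging_io import SectionImage, TissueMask

MICROLITRE_PER_ML = 1000.0
MM3_PER_ML = 1000.0
UM3_PER_ML = 1e12


@dataclass
class StainProfile:
    """Positive-pixel rule for one stain.

    ``mode="hsv"``: positive iff hue in ``hue_range`` (wrap-around
    allowed), saturation >= ``min_saturation`` and luminance <=
    ``max_luminance`` (all on [0, 1] scales).  ``mode="palette"``:
    positive iff within ``palette_max_distance`` (RGB euclidean, 0-255
    scale) of ``palette_rgb`` — the exact rule used for synthetic
    fixtures so oracles stay computable.
    """

    name: str
    mode: str = "hsv"
    hue_range: tuple[float, float] = (0.0, 1.0)
    min_saturation: float = 0.0
    max_luminance: float = 1.0
    palette_rgb: tuple[int, int, int] = (0, 0, 0)
    palette_max_distance: float = 60.0

    def __post_init__(self) -> None:
        if self.mode not in ("hsv", "palette"):
            raise ValueError("mode must be 'hsv' or 'palette'")
        lo, hi = self.hue_range
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("hue_range must lie in [0, 1]")
        if not (0.0 <= self.min_saturation <= 1.0 and 0.0 <= self.max_luminance <= 1.0):
            raise ValueError("saturation/luminance thresholds must lie in [0, 1]")

    def positive_mask(self, pixels: np.ndarray) -> np.ndarray:
        rgb = np.asarray(pixels, dtype=np.float64) / 255.0
        if self.mode == "palette":
            d = np.sqrt(
                (
                    (np.asarray(pixels, dtype=np.float64) - np.asarray(self.palette_rgb)) ** 2
                ).sum(axis=2)
            )
            return d <= self.palette_max_distance
        hsv = rgb2hsv(rgb)
        lum = rgb2gray(rgb)
        lo, hi = self.hue_range
        hue = hsv[:, :, 0]
        in_hue = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
        return in_hue & (hsv[:, :, 1] >= self.min_saturation) & (lum <= self.max_luminance)


#: Editable starting-point profiles per stain (uncalibrated for real slides).
STAIN_PRESETS = {
    # picrosirius red: red/magenta hues
    "PSR": StainProfile("PSR", hue_range=(0.90, 0.08), min_saturation=0.25, max_luminance=0.85),
    # trichrome collagen: blue
    "MT": StainProfile("MT", hue_range=(0.52, 0.75), min_saturation=0.15, max_luminance=0.85),
    # DAB-brown immunostains
    "IHC-Col1a1": StainProfile(
        "IHC-Col1a1", hue_range=(0.02, 0.13), min_saturation=0.25, max_luminance=0.70
    ),
}


@dataclass
class AreaFraction:
    """Positive staining as % of the total sectional (tissue) area."""

    percent_positive: float
    n_positive: int
    n_tissue: int
    ident: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_positive <= 100.0):
            raise ValueError("percent must lie in [0, 100]")


@dataclass
class LobuleVolume:
    """Lobe volume from displaced-fluid mass (Archimedes principle)."""

    volume_ml: float
    mass_g: float
    density_g_per_ml: float

    @property
    def volume_mm3(self) -> float:
        return self.volume_ml * MM3_PER_ML

    @property
    def volume_um3(self) -> float:
        return self.volume_ml * UM3_PER_ML


@dataclass
class MarkerVolume:
    """Whole-lobule volume of a stained marker (mean %-area x lobule volume)."""

    volume_ml: float
    mean_percent_area: float
    lobule: LobuleVolume
    single_section_volume_ml: float

    @property
    def volume_mm3(self) -> float:
        return self.volume_ml * MM3_PER_ML

    @property
    def volume_um3(self) -> float:
        return self.volume_ml * UM3_PER_ML


def positive_area_fraction(
    section: SectionImage,
    profile: StainProfile,
    mask: TissueMask,
    denominator: str = "tissue",
) -> AreaFraction:
    """Percent of tissue pixels that are positively stained.

    The denominator is the tissue area by default ("total sectional
    area" with glass background excluded); ``denominator="raster"``
    switches to the full raster area.
    """
    if mask.mask.shape != (section.height, section.width):
        raise ValueError("tissue mask is not congruent with the section")
    if denominator not in ("tissue", "raster"):
        raise ValueError("denominator must be 'tissue' or 'raster'")
    pos = profile.positive_mask(section.pixels)
    n_tissue = int(mask.mask.sum()) if denominator == "tissue" else mask.mask.size
    if n_tissue == 0:
        raise ValueError("section has no tissue pixels; area fraction undefined")
    n_pos = int((pos & mask.mask).sum())
    return AreaFraction(
        percent_positive=100.0 * n_pos / n_tissue,
        n_positive=n_pos,
        n_tissue=n_tissue,
        ident=section.ident,
    )


def lobule_volume_from_displacement(
    mass_g: float, density_g_per_ml: float = 1.0
) -> LobuleVolume:
    """Volume (mL) = displaced-fluid mass / fluid density."""
    if not mass_g > 0:
        raise ValueError("displaced-fluid mass must be positive")
    if not density_g_per_ml > 0:
        raise ValueError("fluid density must be positive")
    return LobuleVolume(
        volume_ml=mass_g / density_g_per_ml, mass_g=mass_g, density_g_per_ml=density_g_per_ml
    )


def whole_lobule_marker_volume(
    area_fractions: Sequence[AreaFraction], volume: LobuleVolume
) -> MarkerVolume:
    """Marker volume = mean %-area across serial sections x lobule volume.

    Also carries the single-section estimate (first/designated section)
    so the two sampling designs can be compared side by side.
    """
    if len(area_fractions) == 0:
        raise ValueError("need at least one area fraction")
    percents = np.array([f.percent_positive for f in area_fractions], dtype=np.float64)
    mean_pct = float(percents.mean())
    return MarkerVolume(
        volume_ml=mean_pct / 100.0 * volume.volume_ml,
        mean_percent_area=mean_pct,
        lobule=volume,
        single_section_volume_ml=float(percents[0]) / 100.0 * volume.volume_ml,
    )


def serial_section_summary(
    fractions: Sequence[float], section_spacing_um: float = 300.0
) -> dict:
    """Representativeness of single sections for the whole-lobule mean.

    Given per-section %-area values sampled at a fixed spacing through
    the lobe, reports the mean, SD, coefficient of variation and each
    section's absolute and relative deviation from the lobule mean.
    """
    vals = np.asarray(list(fractions), dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least two serial sections")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    abs_dev = vals - mean
    rel_dev = abs_dev / mean if mean != 0 else np.full_like(vals, np.nan)
    return {
        "n_sections": int(vals.size),
        "section_spacing_um": float(section_spacing_um),
        "fractions": vals.tolist(),
        "mean": mean,
        "sd": sd,
        "cv": float(cv),
        "abs_deviation": abs_dev.tolist(),
        "rel_deviation": rel_dev.tolist(),
        "max_abs_rel_deviation": float(np.abs(rel_dev).max()) if mean != 0 else float("nan"),
    }
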