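"""Canopy architecture from upward-looking cover photography.

An upward RGB photograph of a grapevine canopy against the sky is binarized
into sky/canopy pixels, the sky gaps are partitioned into large between-crown
gaps and small within-crown gaps, and the gap fractions are converted into
the six canopy-architecture parameters used throughout precision viticulture:

* ``fc``   — canopy cover, 1 minus the total gap fraction,
* ``ff``   — crown cover, 1 minus the large-gap fraction,
* ``phi``  — crown porosity, the within-crown gap fraction ``1 - fc/ff``,
* ``lai``  — leaf area index from the Beer–Lambert inversion
  ``LAI = -ff * ln(phi) / k`` with extinction coefficient ``k``,
* ``omega`` — clumping index
  ``(1 - phi) * ln(1 - fc) / (ln(phi) * fc)``,
* ``lai_e`` — effective (clumping-uncorrected) LAI, ``omega * lai``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_isodata, threshold_otsu

__all__ = [
    "CanopyImage",
    "GapMap",
    "CanopyMetrics",
    "CanopyConfig",
    "BinarizationMethod",
    "crown_porosity",
    "lai_from_porosity",
    "clumping_index",
    "metrics_from_cover_fractions",
    "binarize_canopy",
    "classify_gaps",
    "compute_metrics",
    "analyze_canopy_image",
    "analyze_manifest",
    "load_canopy_image",
]

DEFAULT_EXTINCTION_COEFFICIENT = 0.7
DEFAULT_LARGE_GAP_THRESHOLD = 0.01
#: crown porosity is clamped into this open interval before taking logs
PHI_CLAMP = (1e-6, 1.0 - 1e-6)


class BinarizationMethod(str, Enum):
    otsu = "otsu"
    isodata = "isodata"
    fixed = "fixed"


class CaptureSide(str, Enum):
    east = "east"
    west = "west"
    unknown = "unknown"


@dataclass
class CanopyImage:
    """One upward-looking RGB canopy photograph."""

    pixels: np.ndarray  # rows x cols x 3, uint8
    source_id: str = ""
    capture_side: CaptureSide = CaptureSide.unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("canopy image must be rows x cols x 3")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("canopy image must be at least 64 x 64")


@dataclass
class GapComponent:
    component_id: int
    pixel_count: int
    label: str  # "large" | "small"


@dataclass
class GapMap:
    """Binary sky mask plus (optionally) its labelled connected components."""

    sky_mask: np.ndarray
    total_pixels: int
    components: list[GapComponent] = field(default_factory=list)
    large_gap_threshold: Optional[float] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def gap_fraction(self) -> float:
        return float(np.count_nonzero(self.sky_mask)) / self.total_pixels

    @property
    def large_gap_fraction(self) -> float:
        large = sum(c.pixel_count for c in self.components if c.label == "large")
        return large / self.total_pixels


@dataclass
class CanopyMetrics:
    """The six canopy-architecture parameters for one image (or plant)."""

    fc: float
    ff: float
    phi: float
    lai: float
    lai_e: float
    omega: float
    k: float = DEFAULT_EXTINCTION_COEFFICIENT
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "fc": self.fc,
            "ff": self.ff,
            "phi": self.phi,
            "lai": self.lai,
            "lai_e": self.lai_e,
            "omega": self.omega,
            "k": self.k,
            "warnings": ";".join(self.warnings),
        }


@dataclass
class CanopyConfig:
    method: BinarizationMethod = BinarizationMethod.otsu
    fixed_threshold: Optional[float] = None
    large_gap_threshold: float = DEFAULT_LARGE_GAP_THRESHOLD
    k: float = DEFAULT_EXTINCTION_COEFFICIENT


# ---------------------------------------------------------------------------
# equation engine
# ---------------------------------------------------------------------------

def _clamp_phi(phi: float) -> tuple[float, bool]:
    lo, hi = PHI_CLAMP
    if phi < lo:
        return lo, True
    if phi > hi:
        return hi, True
    return phi, False


def crown_porosity(fc: float, ff: float) -> float:
    """Crown porosity ``phi = 1 - fc/ff`` (within-crown gap fraction)."""
    if ff <= 0:
        raise ValueError("crown cover ff must be positive")
    return 1.0 - fc / ff


def lai_from_porosity(ff: float, phi: float, k: float = DEFAULT_EXTINCTION_COEFFICIENT) -> float:
    """Beer–Lambert LAI inversion ``-ff * ln(phi) / k``."""
    phi, _ = _clamp_phi(phi)
    return -ff * np.log(phi) / k


def clumping_index(fc: float, phi: float) -> float:
    """Foliage clumping index ``(1 - phi) * ln(1 - fc) / (ln(phi) * fc)``.

    Defined as 1 in the degenerate limits ``fc = 0`` (no canopy) and
    ``fc = 1`` (no gaps), where the ratio is indeterminate.
    """
    if fc <= 0.0 or fc >= 1.0:
        return 1.0
    phi, _ = _clamp_phi(phi)
    return (1.0 - phi) * np.log(1.0 - fc) / (np.log(phi) * fc)


def metrics_from_cover_fractions(
    fc: float,
    ff: float,
    k: float = DEFAULT_EXTINCTION_COEFFICIENT,
    phi: Optional[float] = None,
) -> CanopyMetrics:
    """Canopy metrics from cover fractions alone.

    ``phi`` may be supplied explicitly (e.g. a published group mean);
    otherwise it is derived from ``1 - fc/ff``.
    """
    warns: list[str] = []
    if ff <= 0:
        return CanopyMetrics(fc=0.0, ff=0.0, phi=PHI_CLAMP[1], lai=0.0,
                             lai_e=0.0, omega=1.0, k=k,
                             warnings=["image entirely large gap; no crown"])
    if phi is None:
        phi = crown_porosity(fc, ff)
    phi, clamped = _clamp_phi(phi)
    if clamped:
        warns.append("crown porosity clamped at bound")
    lai = float(lai_from_porosity(ff, phi, k))
    omega = float(clumping_index(fc, phi))
    if fc <= 0.0 or fc >= 1.0:
        warns.append("clumping index at limit convention omega = 1")
    lai_e = omega * lai
    return CanopyMetrics(fc=float(fc), ff=float(ff), phi=float(phi), lai=lai,
                         lai_e=float(lai_e), omega=omega, k=k, warnings=warns)


# ---------------------------------------------------------------------------
# image operations
# ---------------------------------------------------------------------------

def binarize_canopy(
    image: CanopyImage,
    method: BinarizationMethod | str = BinarizationMethod.otsu,
    fixed_threshold: Optional[float] = None,
) -> GapMap:
    """Threshold the blue channel into a sky mask (sky is brighter).

    The blue channel offers the best sky/leaf contrast in upward photographs,
    the standard choice in cover photography.
    """
    method = BinarizationMethod(method)
    blue = image.pixels[:, :, 2]
    total = blue.size
    warns: list[str] = []

    if method is BinarizationMethod.fixed:
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method 'fixed'")
        thr = float(fixed_threshold)
    else:
        if blue.min() == blue.max():
            # degenerate image: call it all sky if bright, all canopy if dark
            warns.append("degenerate image: single intensity")
            sky = np.full(blue.shape, blue.flat[0] > 127, dtype=bool)
            return GapMap(sky_mask=sky, total_pixels=total, warnings=warns)
        thr = float(threshold_otsu(blue) if method is BinarizationMethod.otsu
                    else threshold_isodata(blue))
    sky = blue > thr
    return GapMap(sky_mask=sky, total_pixels=total, warnings=warns)


def classify_gaps(gapmap: GapMap, large_gap_threshold: float = DEFAULT_LARGE_GAP_THRESHOLD) -> GapMap:
    """Label 8-connected sky components as large (between-crown) or small.

    A component is *large* iff its pixel count is at least
    ``large_gap_threshold`` times the image area.
    """
    if not 0.0 < large_gap_threshold < 1.0:
        raise ValueError("large_gap_threshold must be in (0, 1)")
    labelled = measure.label(gapmap.sky_mask, connectivity=2)
    cutoff = large_gap_threshold * gapmap.total_pixels
    components = []
    for comp_id in range(1, labelled.max() + 1):
        n = int(np.count_nonzero(labelled == comp_id))
        components.append(GapComponent(comp_id, n, "large" if n >= cutoff else "small"))
    return GapMap(sky_mask=gapmap.sky_mask, total_pixels=gapmap.total_pixels,
                  components=components, large_gap_threshold=large_gap_threshold,
                  warnings=list(gapmap.warnings))


def compute_metrics(gapmap: GapMap, k: float = DEFAULT_EXTINCTION_COEFFICIENT) -> CanopyMetrics:
    """Gap fractions -> six canopy parameters.

    With ``gT`` the total sky fraction and ``gL`` the large-gap fraction:
    ``fc = 1 - gT`` and ``ff = 1 - gL``; the rest follows from the equation
    engine above.
    """
    if gapmap.total_pixels <= 0:
        raise ValueError("empty gap map")
    g_total = gapmap.gap_fraction
    g_large = gapmap.large_gap_fraction
    fc = 1.0 - g_total
    ff = 1.0 - g_large
    if ff <= 0:
        warnings.warn("image entirely large gap; metrics degenerate")
        m = metrics_from_cover_fractions(fc, ff, k)
    else:
        m = metrics_from_cover_fractions(fc, ff, k)
    m.warnings = list(gapmap.warnings) + m.warnings
    return m


def analyze_canopy_image(image: CanopyImage, config: Optional[CanopyConfig] = None) -> CanopyMetrics:
    """Full single-image pipeline: binarize, classify gaps, compute metrics."""
    config = config or CanopyConfig()
    gm = binarize_canopy(image, config.method, config.fixed_threshold)
    gm = classify_gaps(gm, config.large_gap_threshold)
    return compute_metrics(gm, config.k)


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------

def load_canopy_image(path: str | Path, source_id: str = "", side: str = "unknown") -> CanopyImage:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return CanopyImage(pixels=arr[:, :, :3], source_id=source_id or str(path),
                       capture_side=CaptureSide(side))


def analyze_manifest(manifest: str | Path | pd.DataFrame,
                     config: Optional[CanopyConfig] = None) -> pd.DataFrame:
    """Analyze a batch manifest (source_id, path, plant_id, side[, date]).

    Returns one row per image plus one aggregate row per plant (the mean of
    its side images), flagged by ``level``.
    """
    config = config or CanopyConfig()
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    rows = []
    for rec in df.itertuples(index=False):
        img = load_canopy_image(rec.path, source_id=str(rec.source_id),
                                side=getattr(rec, "side", "unknown"))
        m = analyze_canopy_image(img, config)
        row = {"level": "image", "source_id": rec.source_id,
               "plant_id": getattr(rec, "plant_id", rec.source_id)}
        row.update(m.as_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    numeric = ["fc", "ff", "phi", "lai", "lai_e", "omega", "k"]
    for plant, grp in out.groupby("plant_id"):
        mean = grp[numeric].mean()
        rows.append({"level": "plant", "source_id": "", "plant_id": plant,
                     **mean.to_dict(), "warnings": ""})
    return pd.DataFrame(rows)
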