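"""Living-tissue / cell-death quantification from FDA fluorescence images.

A halved grape berry stained with fluorescein diacetate (FDA) fluoresces
green where mesocarp cells are alive. From an RGB microscopy image the
pipeline (i) finds the berry outline automatically, (ii) segments the
green-fluorescing living tissue (LT) inside it, (iii) optionally excludes a
manually supplied seed polygon, and (iv) reports percent living tissue and
its complement, percent berry cell death (BCD = 100 - LT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

__all__ = [
    "FluorescenceImage",
    "BerryMask",
    "SeedRegion",
    "VitalityResult",
    "VitalityConfig",
    "detect_berry_mask",
    "segment_living_tissue",
    "compute_vitality",
    "analyze_berry_image",
    "export_masks",
    "load_fluorescence_image",
]


class Cultivar(str, Enum):
    chardonnay = "chardonnay"
    shiraz = "shiraz"
    other = "other"


@dataclass
class FluorescenceImage:
    pixels: np.ndarray  # rows x cols x 3, uint8
    berry_id: str = ""
    cultivar: Cultivar = Cultivar.other

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("fluorescence image must be rows x cols x 3")
        if self.pixels.size == 0:
            raise ValueError("empty image")


@dataclass
class BerryMask:
    mask: np.ndarray
    contour: np.ndarray  # ordered (row, col) coordinates
    area_px: int


@dataclass
class SeedRegion:
    """Manually cropped seed polygon, (row, col) vertices; may be empty."""

    polygon: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        if len(self.polygon) < 3:
            return np.zeros(shape, dtype=bool)
        return polygon2mask(shape, np.asarray(self.polygon, dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeedRegion":
        df = pd.read_csv(path)
        return cls(polygon=df[["y", "x"]].to_numpy(dtype=float))


@dataclass
class VitalityResult:
    lt_percent: float
    bcd_percent: float
    berry_area_px: int
    seed_area_px: int
    lt_area_px: int
    berry_id: str = ""

    def as_dict(self) -> dict:
        return {
            "berry_id": self.berry_id,
            "lt_percent": self.lt_percent,
            "bcd_percent": self.bcd_percent,
            "berry_area_px": self.berry_area_px,
            "seed_area_px": self.seed_area_px,
            "lt_area_px": self.lt_area_px,
        }


@dataclass
class VitalityConfig:
    closing_radius: int = 3
    min_berry_area_fraction: float = 0.01
    lt_threshold: Optional[float] = None  # None -> automatic (Otsu)


class NoBerryError(ValueError):
    pass


def detect_berry_mask(image: FluorescenceImage, config: Optional[VitalityConfig] = None) -> BerryMask:
    """Find the berry as the largest bright blob on the dark background.

    Overall brightness (channel mean) is thresholded automatically (Otsu),
    the foreground is morphologically closed and hole-filled, and the
    largest 8-connected component is kept.
    """
    config = config or VitalityConfig()
    brightness = image.pixels.astype(float).mean(axis=2)
    if brightness.min() == brightness.max():
        raise NoBerryError("no berry detected: flat image")
    thr = threshold_otsu(brightness)
    fg = brightness > thr
    if config.closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(config.closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labelled = measure.label(fg, connectivity=2)
    if labelled.max() == 0:
        raise NoBerryError("no berry detected: empty foreground")
    sizes = np.bincount(labelled.ravel())[1:]
    biggest = int(sizes.argmax()) + 1
    mask = labelled == biggest
    area = int(sizes.max())
    if area < config.min_berry_area_fraction * brightness.size:
        raise NoBerryError("no berry detected: largest component below minimum area")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return BerryMask(mask=mask, contour=contour, area_px=area)


def segment_living_tissue(
    image: FluorescenceImage,
    berry: BerryMask,
    config: Optional[VitalityConfig] = None,
) -> np.ndarray:
    """Segment green-fluorescing (living) pixels inside the berry mask.

    Each pixel gets a green-dominance score ``g - max(r, b)``; FDA
    fluorescence makes living tissue strongly green-dominant while dead
    mesocarp is dull brown (score near or below zero). The score is
    thresholded with Otsu inside the berry. When both Otsu classes fall on
    the same side of zero the interior is homogeneous (all living or all
    dead) and the sign of the scores decides, so a fully green berry is not
    artificially split in two.
    """
    config = config or VitalityConfig()
    px = image.pixels.astype(np.int32)
    score = px[:, :, 1] - np.maximum(px[:, :, 0], px[:, :, 2])
    inside = score[berry.mask]
    if config.lt_threshold is not None:
        thr = float(config.lt_threshold)
    elif inside.min() == inside.max():
        thr = 0.0
    else:
        thr = float(threshold_otsu(inside))
        lo_mean = inside[inside <= thr].mean()
        hi_mean = inside[inside > thr].mean() if (inside > thr).any() else lo_mean
        if lo_mean > 0:        # both classes green-dominant: all living
            thr = 0.0
        elif hi_mean <= 0:     # both classes non-green: none living
            thr = float(inside.max())
    return (score > thr) & berry.mask


def compute_vitality(
    lt_mask: np.ndarray,
    berry: BerryMask,
    seed: Optional[SeedRegion] = None,
    berry_id: str = "",
) -> VitalityResult:
    """Percent living tissue and cell death over the seed-excluded berry area.

    The BCD mask is the inversion of the LT mask within the effective
    (berry minus seed) area, so ``lt_percent + bcd_percent == 100``.
    """
    lt_mask = np.asarray(lt_mask, dtype=bool)
    if (lt_mask & ~berry.mask).any():
        raise ValueError("lt_mask must be a subset of the berry mask")
    seed_mask = (seed or SeedRegion()).rasterize(berry.mask.shape) & berry.mask
    effective = berry.mask & ~seed_mask
    eff_area = int(np.count_nonzero(effective))
    if eff_area == 0:
        raise ValueError("empty effective area: seed region covers the whole berry")
    lt_area = int(np.count_nonzero(lt_mask & ~seed_mask))
    lt_percent = 100.0 * lt_area / eff_area
    return VitalityResult(
        lt_percent=lt_percent,
        bcd_percent=100.0 - lt_percent,
        berry_area_px=berry.area_px,
        seed_area_px=int(np.count_nonzero(seed_mask)),
        lt_area_px=lt_area,
        berry_id=berry_id,
    )


def analyze_berry_image(
    image: FluorescenceImage,
    seed: Optional[SeedRegion] = None,
    config: Optional[VitalityConfig] = None,
) -> tuple[VitalityResult, BerryMask, np.ndarray]:
    """Full per-berry pipeline; returns (result, berry mask, LT mask)."""
    berry = detect_berry_mask(image, config)
    lt = segment_living_tissue(image, berry, config)
    res = compute_vitality(lt, berry, seed, berry_id=image.berry_id)
    return res, berry, lt


def export_masks(
    result: VitalityResult,
    berry: BerryMask,
    lt_mask: np.ndarray,
    out_dir: str | Path,
    fmt: str = "png",
) -> dict[str, Path]:
    """Write berry/LT/BCD masks as images plus a one-row CSV.

    PNG (lossless) is the default; JPG is offered for compatibility with
    legacy workflows but degrades binary masks.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = result.berry_id or "berry"
    bcd_mask = berry.mask & ~np.asarray(lt_mask, dtype=bool)
    paths = {}
    for name, mask in [("berry", berry.mask), ("lt", lt_mask), ("bcd", bcd_mask)]:
        p = out_dir / f"{stem}_{name}.{fmt}"
        iio.imwrite(p, (np.asarray(mask, dtype=np.uint8) * 255))
        paths[name] = p
    csv_path = out_dir / f"{stem}_vitality.csv"
    pd.DataFrame([result.as_dict()]).to_csv(csv_path, index=False)
    paths["csv"] = csv_path
    return paths


def load_fluorescence_image(path: str | Path, berry_id: str = "",
                            cultivar: str = "other") -> FluorescenceImage:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return FluorescenceImage(pixels=arr[:, :, :3], berry_id=berry_id or str(path),
                             cultivar=Cultivar(cultivar))
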