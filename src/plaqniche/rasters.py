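"""Image-domain operations on segmented amyloid rasters.

Masks arrive as binarized immunostaining signal (amyloid-beta plaques,
IBA1+ myeloid cells, vascular-amyloid labels) at a known physical scale.
This module cleans them, expands plaque signal into a distance-decayed
density halo, splits amyloid into cortical vs vascular compartments, and
quantifies coverage and colocalization fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "MaskRaster",
    "DensityRaster",
    "CleaningSpec",
    "binarize_and_clean",
    "expand_with_decay",
    "partition_vascular",
    "area_coverage",
    "colocalization_fraction",
]


@dataclass(frozen=True)
class MaskRaster:
    """A binary raster with a physical scale.

    pixels: 2D boolean array.
    pixel_size: edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def area_um2(self) -> float:
        """Total foreground area in square micrometres."""
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass(frozen=True)
class DensityRaster:
    """An 8-bit density raster (0-255) with a physical scale."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        px = np.asarray(self.pixels)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("density values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


@dataclass(frozen=True)
class CleaningSpec:
    """Parameters of the binarize-and-clean step.

    intensity_threshold: grayscale cutoff on the 0-255 scale (strict >).
    min_object_area / max_object_area: connected-component size window in
        square micrometres; components outside it are dropped.
    despeckle_radius: median-filter radius in pixels (0 disables).
    close_rounds: number of dilate+erode pairs with a 1-px disc.
    """

    intensity_threshold: float = 183.0
    min_object_area: float = 0.0
    max_object_area: float | None = None
    despeckle_radius: int = 0
    close_rounds: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be in [0, 255]")
        if self.close_rounds < 0 or self.despeckle_radius < 0:
            raise ValueError("rounds and radii must be non-negative")


_DISC1 = morphology.disk(1)  # 8-connected 1-px structuring element


def binarize_and_clean(
    image: np.ndarray, spec: CleaningSpec, pixel_size: float = 1.0
) -> MaskRaster:
    """Threshold a grayscale image and clean the binary result.

    Pipeline: strict threshold, optional median despeckle, ``close_rounds``
    morphological closings with a 1-px disc, then removal of connected
    components (8-connectivity) whose area falls outside the configured
    window. An empty image yields an empty mask.
    """
    image = np.asarray(image)
    mask = image > spec.intensity_threshold
    if spec.despeckle_radius > 0:
        mask = ndimage.median_filter(
            mask, footprint=morphology.disk(spec.despeckle_radius)
        )
    for _ in range(spec.close_rounds):
        mask = ndimage.binary_dilation(mask, structure=_DISC1)
        mask = ndimage.binary_erosion(mask, structure=_DISC1)
    if mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n:
            areas_px = np.bincount(labels.ravel())[1:]
            areas_um2 = areas_px * pixel_size**2
            keep = areas_um2 >= spec.min_object_area
            if spec.max_object_area is not None:
                keep &= areas_um2 <= spec.max_object_area
            keep_ids = np.flatnonzero(keep) + 1
            mask = np.isin(labels, keep_ids)
    return MaskRaster(mask, pixel_size)


#: Band intensities for the decayed expansion: interior then 5 halo bands.
#: Linear decrement floor(255*(1 - k/6)) for band k = ceil(d/band) in 1..5,
#: giving 255 > 212 > 170 > 127 > 85 > 42 > 0.
DECAY_BAND_VALUES = tuple(int(255 * (6 - k) // 6) for k in range(6))


def expand_with_decay(
    mask: MaskRaster, halo_um: float = 100.0, band_um: float = 20.0
) -> DensityRaster:
    """Expand a binary mask into a distance-decayed density halo.

    Pixels inside the mask keep intensity 255. Outside, the intensity drops
    in steps every ``band_um`` micrometres of Euclidean distance from the
    mask: band k = ceil(d / band_um) receives floor(255 * (1 - k/6)), so the
    five default bands are 212, 170, 127, 85 and 42. Beyond ``halo_um`` the
    raster is zero. Distances use the exact Euclidean distance transform on
    pixel centres.
    """
    n_bands = halo_um / band_um
    if abs(n_bands - round(n_bands)) > 1e-9:
        raise ValueError("halo_um must be an integer multiple of band_um")
    px = mask.pixels
    out = np.zeros(px.shape, dtype=np.uint8)
    if not px.any():
        return DensityRaster(out, mask.pixel_size)
    dist = ndimage.distance_transform_edt(~px, sampling=mask.pixel_size)
    out[px] = 255
    halo = (dist > 0) & (dist <= halo_um)
    n_total = int(round(n_bands)) + 1  # interior plus halo bands
    k = np.ceil(dist[halo] / band_um).astype(int)
    out[halo] = np.floor(255.0 * (1.0 - k / (n_total + 0.0))).astype(np.uint8)
    return DensityRaster(out, mask.pixel_size)


def partition_vascular(
    ab_mask: MaskRaster, vascular_labels: MaskRaster, dilation_rounds: int = 2
) -> tuple[MaskRaster, MaskRaster]:
    """Split amyloid into cortical and vascular compartments.

    The vascular label raster is dilated ``dilation_rounds`` times with a
    1-px disc; amyloid overlapping the dilated labels is vascular, the
    residual is cortical. The two outputs partition ``ab_mask``.
    """
    if ab_mask.pixels.shape != vascular_labels.pixels.shape:
        raise ValueError("ab_mask and vascular_labels must share shape")
    grown = vascular_labels.pixels
    for _ in range(dilation_rounds):
        grown = ndimage.binary_dilation(grown, structure=_DISC1)
    vascular = ab_mask.pixels & grown
    cortical = ab_mask.pixels & ~grown
    return (
        MaskRaster(cortical, ab_mask.pixel_size),
        MaskRaster(vascular, ab_mask.pixel_size),
    )


def area_coverage(mask: MaskRaster, region: MaskRaster) -> float:
    """Fraction of ``region`` covered by ``mask`` (e.g. amyloid / gray matter)."""
    region_px = region.pixels
    denom = int(region_px.sum())
    if denom == 0:
        raise ValueError("region is empty: coverage undefined")
    return float((mask.pixels & region_px).sum()) / denom


def colocalization_fraction(
    partner: MaskRaster, target: MaskRaster, region: MaskRaster
) -> float:
    """Fraction of in-region ``target`` signal overlapped by ``partner``.

    Used for IBA1-on-amyloid colocalization: the colocalized area divided by
    the total amyloid area within the region of interest.
    """
    tin = target.pixels & region.pixels
    denom = int(tin.sum())
    if denom == 0:
        raise ValueError("target within region is empty: fraction undefined")
    return float((partner.pixels & tin).sum()) / denom
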