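"""Puncta definition: Otsu thresholding plus connected-component labeling.

The threshold is computed per image and per channel (robust to bleaching
across a movie) with a strictly-above foreground convention, and components
outside a [min_area, max_area] window are discarded — the lower bound rejects
residual single-pixel noise, the upper bound vacuole-scale blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .exceptions import DegenerateImageError, InvalidParameterError

__all__ = ["SegmentationParams", "PunctumObject", "otsu_threshold", "segment_puncta", "segment_mask"]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of puncta segmentation.

    ``min_area``/``max_area`` bound accepted component sizes in pixels;
    ``n_bins`` is the Otsu histogram resolution; connectivity is 8-neighbor.
    """

    min_area: int = 4
    max_area: int = 200
    n_bins: int = 256
    connectivity: int = 2  # skimage convention: 2 == 8-connected

    def __post_init__(self) -> None:
        if not 0 < self.min_area <= self.max_area:
            raise InvalidParameterError("need 0 < min_area <= max_area")
        if self.n_bins < 2:
            raise InvalidParameterError("n_bins must be >= 2")


@dataclass
class PunctumObject:
    """One segmented punctum: an 8-connected pixel region.

    ``pixels`` is an (N, 2) array of (row, col); ``centroid`` is the
    intensity-weighted mean position; ``integrated_intensity`` the sum of the
    source image over the region.
    """

    id: int
    pixels: np.ndarray
    centroid: tuple[float, float]
    area: int
    integrated_intensity: float
    extra_intensities: dict = field(default_factory=dict)


def _between_class_variance(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Between-class variance for every split 'class0 = bins[..t]', vectorized."""
    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    mass = np.cumsum(counts * centers)
    mu0 = np.divide(mass, w0, out=np.zeros_like(mass), where=w0 > 0)
    mu1 = np.divide(mass[-1] - mass, w1, out=np.zeros_like(mass), where=w1 > 0)
    return w0 * w1 * (mu0 - mu1) ** 2


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the boundary maximizing between-class variance.

    Foreground is defined as pixels **strictly above** the returned value;
    ties in the variance are broken toward the lower threshold, making the
    result bit-reproducible. When the image has at most ``n_bins`` distinct
    values the search is exact over those values; otherwise an ``n_bins``-bin
    histogram is used and the returned threshold is a bin edge.

    Raises :class:`DegenerateImageError` on a constant image.
    """
    vals = np.asarray(img, dtype=float).ravel()
    if vals.size == 0:
        raise DegenerateImageError("empty image")
    unique, uc = np.unique(vals, return_counts=True)
    if unique.size < 2:
        raise DegenerateImageError("constant image has no Otsu threshold")
    if unique.size <= n_bins:
        # candidate thresholds: each unique value except the last (foreground nonempty)
        var = _between_class_variance(uc, unique)[:-1]
        return float(unique[int(np.argmax(var))])
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    var = _between_class_variance(counts, centers)[:-1]
    t = int(np.argmax(var))
    return float(edges[t + 1])


def segment_puncta(
    img: np.ndarray, params: SegmentationParams | None = None
) -> list[PunctumObject]:
    """Segment puncta in one (preprocessed) image.

    Binary mask = img > Otsu threshold; 8-connected components labeled;
    components outside [min_area, max_area] discarded; objects returned
    sorted by centroid (row, then col). Propagates
    :class:`DegenerateImageError` for constant images.
    """
    params = params or SegmentationParams()
    img = np.asarray(img, dtype=float)
    thr = otsu_threshold(img, params.n_bins)
    labels = measure.label(img > thr, connectivity=params.connectivity)
    objects: list[PunctumObject] = []
    for region in measure.regionprops(labels, intensity_image=img):
        if not params.min_area <= region.area <= params.max_area:
            continue
        objects.append(
            PunctumObject(
                id=0,  # reassigned after sorting
                pixels=region.coords.copy(),
                centroid=tuple(region.centroid_weighted),
                area=int(region.area),
                integrated_intensity=float(region.image_intensity.sum()),
            )
        )
    objects.sort(key=lambda o: o.centroid)
    for i, obj in enumerate(objects):
        obj.id = i
    return objects


def segment_mask(img: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Boolean foreground mask of the size-filtered puncta of one image."""
    params = params or SegmentationParams()
    mask = np.zeros(np.asarray(img).shape, dtype=bool)
    for obj in segment_puncta(img, params):
        mask[obj.pixels[:, 0], obj.pixels[:, 1]] = True
    return mask
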