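"""Confluence estimation from brightfield/phase-contrast-style images.

The segmentation procedure is classical, three-stage:

1. **Pre-processing** — RGB is collapsed to grayscale (ITU-R BT.601 luma
   weights 0.299/0.587/0.114), a 7x7 median filter suppresses speckle while
   preserving edges, and CLAHE normalizes local contrast so cells of varying
   brightness become comparably distinguishable from the background.
2. **Edge detection** — a Canny detector (Gaussian smoothing, Sobel gradient,
   non-maximum suppression, hysteresis double thresholding) extracts
   one-pixel-thin cell boundaries.  The hysteresis thresholds default to
   fixed fractions of the maximum gradient magnitude so they survive CLAHE's
   contrast normalization.
3. **Post-processing** — morphological dilations close the boundary
   outlines, holes are filled, and matching erosions restore the footprint,
   converting outlines into filled cell regions.

Surface coverage (SC) is the percentage of mask pixels classified as
cell-covered.  Given a seeding density ``c_i`` and the baseline coverage
``SC_i``, cell concentration at a later timepoint is estimated by simple
proportionality::

    c_t = c_i * SC_t / SC_i

which holds below confluence, where covered area grows linearly with the
number of attached cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters
from skimage.exposure import equalize_adapthist
from skimage.morphology import disk

__all__ = [
    "LUMA_WEIGHTS",
    "PipelineConfig",
    "SegmentationResult",
    "CoverageSeries",
    "to_grayscale",
    "preprocess",
    "detect_edges",
    "refine_mask",
    "segment_image",
    "surface_coverage",
    "estimate_concentration",
    "round_significant",
    "coverage_series",
]

#: BT.601 luma weights used for RGB -> grayscale collapse.
LUMA_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the segmentation pipeline.

    ``t_min``/``t_max`` are hysteresis thresholds expressed as fractions of
    the maximum gradient magnitude of the (smoothed) pre-processed image.
    ``struct_radius`` is the disk radius of the morphology structuring
    element; ``n_dilations``/``n_erosions`` default to an equal count so the
    net operation is a closing that approximately preserves area.  The
    closing is kept tight (radius 1, two iterations each way): it only needs
    to seal the small gaps Canny leaves in cell outlines, and a wider closing
    bridges the gaps *between* neighbouring cells, systematically inflating
    coverage in dense cultures.
    """

    median_kernel: int = 7
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    canny_sigma: float = 1.4
    t_min: float = 0.1
    t_max: float = 0.2
    struct_radius: int = 1
    n_dilations: int = 2
    n_erosions: int = 2
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if not self.t_min < self.t_max:
            raise ValueError(
                f"t_min ({self.t_min}) must be strictly below t_max ({self.t_max})"
            )
        if self.n_dilations < 0 or self.n_erosions < 0:
            raise ValueError("dilation/erosion counts must be non-negative")
        if 0 < self.n_dilations < self.n_erosions:
            raise ValueError("n_erosions may not exceed n_dilations")
        if self.struct_radius < 1:
            raise ValueError("struct_radius must be >= 1")


@dataclass(frozen=True)
class SegmentationResult:
    """Binary cell mask plus the derived surface-coverage percentage."""

    mask: np.ndarray
    coverage_percent: float
    config_used: PipelineConfig
    provenance: str = ""


@dataclass(frozen=True)
class CoverageSeries:
    """Per-timepoint mean +/- SD surface coverage over replicate images."""

    timepoints: np.ndarray
    mean_coverage: np.ndarray
    sd_coverage: np.ndarray
    n_images: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint_h": self.timepoints,
                "mean_coverage": self.mean_coverage,
                "sd_coverage": self.sd_coverage,
                "n_images": self.n_images,
            }
        )


def _as_float01(image: np.ndarray) -> np.ndarray:
    """Cast integer images onto [0, 1]; pass floats through."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return (image.astype(float) - info.min) / (info.max - info.min)
    return image.astype(float)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3|4]) raster to a 2-D float image in [0, 1]."""
    image = _as_float01(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ np.asarray(LUMA_WEIGHTS)
    raise ValueError(f"expected a 2-D or (H, W, 3) image, got shape {image.shape}")


def preprocess(image: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Grayscale conversion, median filtering, then CLAHE.

    Returns a float image in [0, 1] with the same spatial dimensions.
    """
    config = config or PipelineConfig()
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if config.median_kernel > min(gray.shape):
        raise ValueError(
            f"median kernel {config.median_kernel} exceeds image extent {gray.shape}"
        )
    filtered = ndi.median_filter(gray, size=config.median_kernel, mode="reflect")
    ty, tx = config.clahe_tiles
    kernel = (max(filtered.shape[0] // ty, 1), max(filtered.shape[1] // tx, 1))
    span = filtered.max() - filtered.min()
    if span == 0:
        # CLAHE of a constant image is ill-posed; a constant image carries no
        # edges anyway.
        return filtered
    return equalize_adapthist(
        np.clip(filtered, 0.0, 1.0), kernel_size=kernel, clip_limit=config.clahe_clip
    )


def detect_edges(
    preprocessed: np.ndarray, config: PipelineConfig | None = None
) -> np.ndarray:
    """Canny edge map with hysteresis thresholds scaled to the gradient range.

    ``t_min``/``t_max`` fractions are multiplied by the maximum Sobel
    gradient magnitude of the Gaussian-smoothed image (the same smoothing the
    detector applies), yielding absolute thresholds.
    """
    config = config or PipelineConfig()
    img = np.asarray(preprocessed, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_edges expects a 2-D grayscale image")
    smoothed = ndi.gaussian_filter(img, sigma=config.canny_sigma, mode="reflect")
    gmax = float(filters.sobel(smoothed).max())
    if gmax <= 1e-10:  # flat image up to floating-point fuzz
        return np.zeros_like(img, dtype=bool)
    return feature.canny(
        img,
        sigma=config.canny_sigma,
        low_threshold=config.t_min * gmax,
        high_threshold=config.t_max * gmax,
    )


def _binary_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=footprint, border_value=0)


def _binary_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # border_value=1: regions touching the frame are not eroded from outside
    # (reflect-style border), so cells cut by the field of view keep their area.
    return ndi.binary_erosion(mask, structure=footprint, border_value=1)


def refine_mask(edges: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Turn an edge outline map into filled cell regions.

    Applies ``n_dilations`` disk dilations, optional hole filling, then
    ``n_erosions`` disk erosions.
    """
    config = config or PipelineConfig()
    mask = np.asarray(edges).astype(bool)
    footprint = disk(config.struct_radius)
    for _ in range(config.n_dilations):
        mask = _binary_dilate(mask, footprint)
    if config.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    for _ in range(config.n_erosions):
        mask = _binary_erode(mask, footprint)
    return mask


def surface_coverage(mask: np.ndarray) -> float:
    """Percentage of foreground pixels: 100 * count(mask) / size(mask)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def segment_image(
    image: np.ndarray, config: PipelineConfig | None = None, provenance: str = ""
) -> SegmentationResult:
    """Full pipeline: preprocess -> Canny -> morphology -> coverage."""
    config = config or PipelineConfig()
    mask = refine_mask(detect_edges(preprocess(image, config), config), config)
    return SegmentationResult(
        mask=mask,
        coverage_percent=surface_coverage(mask),
        config_used=config,
        provenance=provenance,
    )


def estimate_concentration(c_i: float, sc_i: float, sc_t: float) -> float:
    """Concentration estimate ``c_t = c_i * SC_t / SC_i`` (cells/mL).

    ``c_i`` is the seeding density, ``SC_i`` the baseline surface coverage
    (percent) and ``SC_t`` the coverage at the queried timepoint.
    """
    for name, v in (("c_i", c_i), ("sc_i", sc_i), ("sc_t", sc_t)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    return c_i * sc_t / sc_i


def round_significant(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures, half to even.

    Reporting helper matching the a x 10^b presentation of concentration
    estimates.
    """
    if value == 0:
        return 0.0
    exponent = int(np.floor(np.log10(abs(value))))
    scale = 10.0 ** (exponent - digits + 1)
    return float(np.round(value / scale) * scale)


def coverage_series(
    groups: Mapping[float, Sequence[np.ndarray]],
    config: PipelineConfig | None = None,
) -> CoverageSeries:
    """Segment replicate images per timepoint and summarize coverage.

    ``groups`` maps timepoint (hours) to its replicate images (typically
    three fields of view).  SD is the sample standard deviation (ddof=1),
    zero for a single image.
    """
    config = config or PipelineConfig()
    if not groups:
        raise ValueError("no timepoints supplied")
    times = sorted(groups)
    means, sds, counts = [], [], []
    for t in times:
        images = list(groups[t])
        if not images:
            raise ValueError(f"timepoint {t} h has no images")
        covs = np.array(
            [segment_image(img, config).coverage_percent for img in images]
        )
        means.append(float(covs.mean()))
        sds.append(float(covs.std(ddof=1)) if len(covs) > 1 else 0.0)
        counts.append(len(covs))
    return CoverageSeries(
        timepoints=np.array(times, dtype=float),
        mean_coverage=np.array(means),
        sd_coverage=np.array(sds),
        n_images=np.array(counts),
    )
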