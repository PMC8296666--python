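"""Ratiometric plastid quantification from two-channel micrographs.

Plastids are segmented on the chlorophyll autofluorescence channel
alone (smooth -> Phansalkar local threshold -> small-object removal ->
distance-transform watershed), then both channels are quantified within
each region of interest. The reporter (CFP) mean is normalized by the
chlorophyll mean per ROI: because depth-dependent signal attenuation
multiplies both channels identically, the ratio cancels it out, which is
the point of the ratiometric design. Summaries aggregate hierarchically
(ROI -> image -> line) without ever pooling ROIs across images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class TwoChannelImage:
    """One field of view: reporter (CFP) and chlorophyll channels."""

    cfp: np.ndarray
    chl: np.ndarray
    scale: float = 1.0  # intensity full range (e.g. 255 or 4095); 1.0 = already [0,1]
    z_index: int | None = None

    def __post_init__(self) -> None:
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.chl = np.asarray(self.chl, dtype=float)
        if self.cfp.shape != self.chl.shape:
            raise ParameterError("channel shapes differ")
        if (self.cfp < 0).any() or (self.chl < 0).any():
            raise ParameterError("intensities must be non-negative")


@dataclass
class SegmentationConfig:
    """Conventional defaults of the segmentation pipeline, all tunable."""

    gaussian_sigma: float = 2.0  # px, pre-threshold smoothing
    radius: int = 15  # px, Phansalkar local window radius
    p: float = 2.0
    q: float = 10.0
    k: float = 0.25
    r: float = 0.5  # normalized dynamic range of the SD term
    min_area: int = 10  # px, objects smaller than this are dropped
    peak_min_distance: int = 5  # px, watershed seed separation
    min_intensity: float = 0.1  # fraction of dynamic range; guards the
    # local threshold where mean and SD both approach zero (empty background)


@dataclass(frozen=True)
class ROIStats:
    """Fluorescence statistics of one segmented plastid."""

    roi_id: int
    area: int
    mean_cfp: float
    min_cfp: float
    max_cfp: float
    mean_chl: float
    min_chl: float
    max_chl: float

    @property
    def ratio(self) -> float:
        return self.mean_cfp / self.mean_chl


@dataclass(frozen=True)
class GemmaSummary:
    """Per-image mean of ROI ratios (one gemma = one image)."""

    mean_ratio: float
    n_rois: int
    sd: float


@dataclass(frozen=True)
class LineSummary:
    """Per-line mean of image means with its standard error."""

    mean_ratio: float
    se: float
    n_images: int


def phansalkar_threshold(
    img: np.ndarray,
    radius: int = 15,
    p: float = 2.0,
    q: float = 10.0,
    k: float = 0.25,
    r: float = 0.5,
) -> np.ndarray:
    """Local adaptive binarization for low-contrast objects.

    With local mean mu and local SD sigma over a (2*radius+1) square
    window (reflected at the edges), the per-pixel threshold is

        t = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1))

    and a pixel is foreground iff its value exceeds t. Intensities must
    be normalized to [0, 1] first.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ParameterError("expected a 2-D image")
    if radius >= min(img.shape):
        raise ParameterError("radius must be smaller than the image")
    if img.max(initial=0.0) > 1.0 + 1e-9:
        raise ParameterError("normalize intensities to [0, 1] before thresholding")
    size = 2 * radius + 1
    mu = ndi.uniform_filter(img, size=size, mode="reflect")
    mu2 = ndi.uniform_filter(img * img, size=size, mode="reflect")
    sigma = np.sqrt(np.clip(mu2 - mu * mu, 0.0, None))
    t = mu * (1.0 + p * np.exp(-q * mu) + k * (sigma / r - 1.0))
    return img > t


def segment_plastids(
    image: TwoChannelImage | np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Label image of plastids, segmented on the chlorophyll channel only.

    Pipeline: Gaussian smooth -> Phansalkar threshold -> drop objects
    below the minimum area -> distance-transform watershed to split
    touching plastids (seeds are local maxima of the smoothed distance
    map with a minimum separation; ties break toward the lowest label).
    An all-background image yields an empty labeling, not an error.
    """
    if config is None:
        config = SegmentationConfig()
    chl = image.chl / image.scale if isinstance(image, TwoChannelImage) else np.asarray(image, dtype=float)
    if chl.max(initial=0.0) > 1.0:
        chl = chl / chl.max()
    smoothed = gaussian(chl, sigma=config.gaussian_sigma, preserve_range=True)
    mask = phansalkar_threshold(
        smoothed, radius=config.radius, p=config.p, q=config.q, k=config.k, r=config.r
    )
    mask &= smoothed > config.min_intensity
    # drops objects of size <= max_size, hence strictly below min_area
    mask = remove_small_objects(mask, max_size=config.min_area - 1)
    if not mask.any():
        return np.zeros(chl.shape, dtype=int)
    distance = ndi.distance_transform_edt(mask)
    seeds_at = peak_local_max(
        gaussian(distance, sigma=1.0, preserve_range=True),
        min_distance=config.peak_min_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(chl.shape, dtype=int)
    for i, (y, x) in enumerate(seeds_at, start=1):
        markers[y, x] = i
    labels = watershed(-distance, markers, mask=mask)
    # watershed fragments below min_area (seed artifacts) are removed
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for obj, n in zip(ids, counts):
        if n < config.min_area:
            labels[labels == obj] = 0
    # relabel consecutively
    out = np.zeros_like(labels)
    for new_id, obj in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == obj] = new_id
    return out


def quantify_rois(labels: np.ndarray, image: TwoChannelImage) -> list[ROIStats]:
    """Per-ROI area, per-channel mean/min/max, and the CFP/chl ratio.

    ROIs whose chlorophyll mean is zero have no defined ratio and are
    dropped with a logged count.
    """
    if labels.shape != image.chl.shape:
        raise ParameterError("label image and channels differ in shape")
    out: list[ROIStats] = []
    dropped = 0
    for roi_id in np.unique(labels[labels > 0]):
        sel = labels == roi_id
        chl, cfp = image.chl[sel], image.cfp[sel]
        if chl.mean() == 0:
            dropped += 1
            continue
        out.append(
            ROIStats(
                roi_id=int(roi_id),
                area=int(sel.sum()),
                mean_cfp=float(cfp.mean()),
                min_cfp=float(cfp.min()),
                max_cfp=float(cfp.max()),
                mean_chl=float(chl.mean()),
                min_chl=float(chl.min()),
                max_chl=float(chl.max()),
            )
        )
    if dropped:
        log.info("dropped %d ROIs with zero chlorophyll signal", dropped)
    return out


def summarize(rois_per_image: list[list[ROIStats]]) -> tuple[list[GemmaSummary], LineSummary]:
    """Hierarchical ROI -> image -> line aggregation of CFP/chl ratios.

    Each image contributes the mean of its ROI ratios; the line value is
    the mean of image values with its standard error. Images without
    ROIs are excluded with a warning and never pooled.
    """
    summaries: list[GemmaSummary] = []
    for rois in rois_per_image:
        if not rois:
            log.warning("image with zero ROIs excluded from the line summary")
            continue
        ratios = np.array([r.ratio for r in rois])
        summaries.append(
            GemmaSummary(
                mean_ratio=float(ratios.mean()),
                n_rois=len(rois),
                sd=float(ratios.std(ddof=1)) if len(rois) > 1 else 0.0,
            )
        )
    if not summaries:
        raise ParameterError("no image contains any ROI")
    means = np.array([s.mean_ratio for s in summaries])
    se = float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else 0.0
    return summaries, LineSummary(float(means.mean()), se, len(means))
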