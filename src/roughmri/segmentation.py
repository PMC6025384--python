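"""Hybrid semi-automatic brain segmentation.

The pipeline separates the cerebrum from skull and background in a 2-D
gray slice in five steps: (1) intensity inversion, (2) seeded region
growing to find the background component, (3) edge enhancement of the
brain contour (Sobel magnitude thresholded with Otsu, or local adaptive
thresholding), (4) morphological mask construction (remove edges, open,
keep the largest component, fill holes, dilate), and (5) element-wise
multiplication of the original image with the mask to extract the ROI.

Conventions fixed here (the method leaves them open):

* coordinates are 0-based (row, col); the default seed is (30, 30);
* images are floats in [0, 1]; inversion is ``1 - I``;
* region growing accepts a neighbor when ``|I - running region mean| <=
  tolerance``, explored FIFO breadth-first with row-major neighbor order,
  making the order-dependent mean update deterministic;
* the Sobel gradient magnitude is ``|Sx| + |Sy|`` (sum, not Euclidean
  norm) with reflect padding, rescaled by its maximum;
* out-of-image pixels are background for morphology.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SegmentationConfig",
    "StructuringElement",
    "invert",
    "region_grow",
    "sobel_magnitude",
    "adaptive_threshold",
    "erode",
    "dilate",
    "open_mask",
    "build_mask",
    "extract_roi",
    "segment_brain",
    "dice",
    "BrainSegmenter",
]

# Vertical (Qx) and horizontal (Qy) 3x3 gradient templates, applied as
# written.
SOBEL_QX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_QY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclass(frozen=True)
class StructuringElement:
    """Symmetric binary neighborhood for morphology."""

    shape: Literal["disk", "square"] = "disk"
    radius: int = 1

    def footprint(self) -> np.ndarray:
        if self.radius < 1:
            raise ValueError("structuring element radius must be >= 1")
        n = 2 * self.radius + 1
        if self.shape == "square":
            return np.ones((n, n), dtype=bool)
        if self.shape == "disk":
            rr, cc = np.mgrid[-self.radius:self.radius + 1,
                              -self.radius:self.radius + 1]
            return (rr**2 + cc**2) <= self.radius**2
        raise ValueError(f"unknown structuring element shape {self.shape!r}")


@dataclass(frozen=True)
class SegmentationConfig:
    seed: tuple[int, int] = (30, 30)
    grow_tolerance: float = 0.10
    connectivity: Literal[4, 8] = 8
    edge_method: Literal["sobel", "adaptive"] = "sobel"
    sobel_threshold: float | Literal["otsu"] = "otsu"
    adaptive_block: int = 31
    adaptive_offset: float = 0.02
    open_radius: int = 2
    dilate_radius: int = 3

    def validate(self) -> None:
        if self.adaptive_block % 2 == 0 or self.adaptive_block < 3:
            raise ValueError("adaptive_block must be odd and >= 3")
        if self.open_radius < 1 or self.dilate_radius < 1:
            raise ValueError("structuring radii must be >= 1")
        if not (0 < self.grow_tolerance <= 1):
            raise ValueError("grow_tolerance must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    return img


def invert(img: np.ndarray) -> np.ndarray:
    """Intensity inversion ``1 - I`` on a [0, 1] gray image."""
    return 1.0 - _check_image(img)


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    # row-major order over the neighborhood window
    if connectivity == 4:
        return [(-1, 0), (0, -1), (0, 1), (1, 0)]
    return [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def region_grow(img: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Seeded region growing; returns the connected region as a 0/1 mask.

    A pixel joins when its intensity is within ``grow_tolerance`` of the
    running mean of the region grown so far; the frontier is a FIFO queue
    seeded at ``cfg.seed`` with neighbors enqueued in row-major order, so
    the (order-dependent) result is deterministic.
    """
    cfg = cfg or SegmentationConfig()
    img = _check_image(img)
    r0, c0 = cfg.seed
    rows, cols = img.shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"seed {cfg.seed} outside image of shape {img.shape}")
    offsets = _neighbor_offsets(cfg.connectivity)
    mask = np.zeros(img.shape, dtype=np.uint8)
    mask[r0, c0] = 1
    total = img[r0, c0]
    count = 1
    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and not mask[nr, nc]:
                if abs(img[nr, nc] - total / count) <= cfg.grow_tolerance:
                    mask[nr, nc] = 1
                    total += img[nr, nc]
                    count += 1
                    queue.append((nr, nc))
    return mask


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Sum-of-absolute Sobel responses, rescaled to [0, 1].

    Both 3x3 templates are correlated with the image under reflect
    padding; the output is ``(|Sx| + |Sy|) / max`` when the maximum is
    positive, and all zeros for a flat field.
    """
    img = _check_image(img)
    if min(img.shape) < 3:
        raise ValueError("image must be at least 3x3 for the 3x3 templates")
    sx = ndimage.correlate(img, SOBEL_QX, mode="reflect")
    sy = ndimage.correlate(img, SOBEL_QY, mode="reflect")
    mag = np.abs(sx) + np.abs(sy)
    mag[mag < 1e-12] = 0.0  # rounding residue on flat regions is not signal
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return mag


def adaptive_threshold(img: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Local-mean thresholding: 1 where ``I > mean_window + offset``."""
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    img = _check_image(img)
    local_mean = ndimage.uniform_filter(img, size=cfg.adaptive_block, mode="reflect")
    return (img > local_mean + cfg.adaptive_offset).astype(np.uint8)


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D mask")
    return mask.astype(bool)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary Minkowski erosion; outside the image counts as background."""
    return ndimage.binary_erosion(
        _as_bool_mask(mask), structure=se.footprint(), border_value=0
    ).astype(np.uint8)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary Minkowski dilation."""
    return ndimage.binary_dilation(
        _as_bool_mask(mask), structure=se.footprint(), border_value=0
    ).astype(np.uint8)


def open_mask(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological opening: erosion then dilation with the same element.

    Removes protrusions and specks smaller than the structuring element
    while smoothing the contour.
    """
    return dilate(erode(mask, se), se)


def build_mask(
    edges: np.ndarray,
    background: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> np.ndarray:
    """Construct the cerebrum mask from the edge map and background region.

    Pipeline: complement the background, knock out edge (skull contour)
    pixels, open with a disk, keep the largest 8-connected component,
    fill interior holes, and dilate with a disk to recover the margin
    lost to edge removal.  Returns an empty mask (with a warning) when no
    foreground survives.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    edges_b = _as_bool_mask(edges)
    background_b = _as_bool_mask(background)
    if edges_b.shape != background_b.shape:
        raise ValueError("edge map and background mask shapes differ")

    fg = ~background_b & ~edges_b
    fg = open_mask(fg, StructuringElement("disk", cfg.open_radius)).astype(bool)
    if not fg.any():
        import warnings

        warnings.warn("empty foreground after opening; returning empty mask",
                      stacklevel=2)
        return np.zeros(edges_b.shape, dtype=np.uint8)

    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    filled = ndimage.binary_fill_holes(largest)
    return dilate(filled, StructuringElement("disk", cfg.dilate_radius))


def extract_roi(original: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-wise product of the original image with the binary mask."""
    original = _check_image(original)
    mask = _as_bool_mask(mask)
    if original.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return original * mask


def segment_brain(
    img: np.ndarray, cfg: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full five-step segmentation; returns ``(roi, mask)``.

    The ROI is the ORIGINAL (non-inverted) image multiplied by the mask.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    img = _check_image(img)
    inverted = invert(img)
    background = region_grow(inverted, cfg)
    if cfg.edge_method == "sobel":
        mag = sobel_magnitude(img)
        if cfg.sobel_threshold == "otsu":
            if np.ptp(mag) == 0:
                edges = np.zeros_like(mag, dtype=np.uint8)
            else:
                edges = (mag > threshold_otsu(mag)).astype(np.uint8)
        else:
            edges = (mag > float(cfg.sobel_threshold)).astype(np.uint8)
    elif cfg.edge_method == "adaptive":
        edges = adaptive_threshold(img, cfg)
    else:
        raise ValueError(f"unknown edge method {cfg.edge_method!r}")
    mask = build_mask(edges, background, cfg)
    roi = extract_roi(img, mask)
    return roi, mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    a = _as_bool_mask(a)
    b = _as_bool_mask(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


class BrainSegmenter(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`segment_brain`.

    ``transform`` maps a list of 2-D gray images to a list of
    ``(roi, mask)`` pairs; parameters mirror :class:`SegmentationConfig`
    so the stage composes with scikit-learn pipelines and grid search.
    """

    def __init__(
        self,
        seed: tuple[int, int] = (30, 30),
        grow_tolerance: float = 0.10,
        connectivity: int = 8,
        edge_method: str = "sobel",
        sobel_threshold: float | str = "otsu",
        adaptive_block: int = 31,
        adaptive_offset: float = 0.02,
        open_radius: int = 2,
        dilate_radius: int = 3,
    ):
        self.seed = seed
        self.grow_tolerance = grow_tolerance
        self.connectivity = connectivity
        self.edge_method = edge_method
        self.sobel_threshold = sobel_threshold
        self.adaptive_block = adaptive_block
        self.adaptive_offset = adaptive_offset
        self.open_radius = open_radius
        self.dilate_radius = dilate_radius

    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            seed=tuple(self.seed),
            grow_tolerance=self.grow_tolerance,
            connectivity=self.connectivity,
            edge_method=self.edge_method,
            sobel_threshold=self.sobel_threshold,
            adaptive_block=self.adaptive_block,
            adaptive_offset=self.adaptive_offset,
            open_radius=self.open_radius,
            dilate_radius=self.dilate_radius,
        )

    def fit(self, X, y=None):
        self.n_features_in_ = 0  # image-list input; no tabular features
        return self

    def transform(self, X) -> list[tuple[np.ndarray, np.ndarray]]:
        cfg = self._config()
        return [segment_brain(img, cfg) for img in X]
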