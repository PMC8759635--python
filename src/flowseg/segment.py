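"""From flow field to segmented cells.

The chain is the method's machine-vision half: threshold the flow magnitude
(Th, the primary user parameter), morphologically close and fill the binary
mask (smoothing disk), drop small components (size filter, debris removal),
then label what remains and measure per-region morphology. Th is compared
against flow magnitude in pixels/frame on [0, 1]-normalized frames.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .flow import FlowParams, farneback_flow, flow_magnitude
from .frames import ImageFrame, ImageSequence, ValidationError

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "CellRegion",
    "LabeledMask",
    "disk_element",
    "binary_close",
    "threshold_mask",
    "close_and_fill",
    "size_filter",
    "label_and_measure",
    "segment_pair",
    "segment_sequence",
    "regions_table",
]

# 8-connected foreground, 4-connected background (standard duality)
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """The three user-facing knobs.

    th : flow-magnitude threshold in pixels/frame; pixels moving faster are
        cell, the rest background. The one parameter that usually needs
        tuning per data set.
    disk_radius : radius of the smoothing disk used for morphological
        closing (default 1 px; 0 disables closing).
    min_size : minimum connected-component area in pixels (default 1000);
        smaller objects (debris, precipitates) are discarded.
    """

    th: float = 0.05
    disk_radius: int = 1
    min_size: int = 1000

    def __post_init__(self) -> None:
        if not self.th > 0:
            raise ValidationError("th must be positive")
        if self.disk_radius < 0:
            raise ValidationError("disk_radius must be >= 0")
        if self.min_size < 0:
            raise ValidationError("min_size must be >= 0")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean cell/background mask for one frame pair."""

    pixels: np.ndarray
    pair_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("mask must be 2-D")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class CellRegion:
    """Morphology of one labeled object."""

    label: int
    area: int
    perimeter: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open


@dataclass(frozen=True)
class LabeledMask:
    """Integer-labeled objects (0 = background) with per-region properties."""

    labels: np.ndarray
    regions: tuple[CellRegion, ...]
    pair_index: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("labels must be a 2-D integer grid")
        present = np.unique(labels)
        present = present[present > 0]
        if not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValidationError("labels must be consecutive 1..N")
        if len(present) != len(self.regions):
            raise ValidationError("one CellRegion per label required")
        for reg in self.regions:
            if reg.area != int((labels == reg.label).sum()):
                raise ValidationError(f"region {reg.label} area mismatch")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def binary(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.pair_index)

    @classmethod
    def from_binary(cls, mask: BinaryMask) -> "LabeledMask":
        return label_and_measure(mask)


def disk_element(radius: int) -> np.ndarray:
    """Discrete Euclidean disk {(dr, dc): dr^2 + dc^2 <= r^2}."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def binary_close(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a disk: dilation then erosion.

    Out-of-image pixels count as background for the dilation and as
    foreground for the erosion, so closing is extensive (never removes true
    pixels) up to the image border.
    """
    if radius == 0:
        return pixels.astype(bool)
    selem = disk_element(radius)
    dil = ndimage.binary_dilation(pixels, structure=selem, border_value=0)
    return ndimage.binary_erosion(dil, structure=selem, border_value=1)


def threshold_mask(magnitude: np.ndarray, params: SegmentationParams,
                   pair_index: int = 0) -> BinaryMask:
    """Pixels with flow magnitude strictly above Th are cell."""
    mag = np.asarray(magnitude, dtype=np.float64)
    if mag.ndim != 2 or not np.isfinite(mag).all():
        raise ValidationError("magnitude must be a finite 2-D grid")
    return BinaryMask(mag > params.th, pair_index)


def close_and_fill(mask: BinaryMask, params: SegmentationParams) -> BinaryMask:
    """Close with the smoothing disk, then fill enclosed holes.

    Hole filling floods every background region not 4-connected to the image
    border; foreground stays 8-connected throughout the pipeline.
    """
    closed = binary_close(mask.pixels, params.disk_radius)
    filled = ndimage.binary_fill_holes(closed, structure=_STRUCT4)
    return BinaryMask(filled, mask.pair_index)


def size_filter(mask: BinaryMask, params: SegmentationParams) -> BinaryMask:
    """Remove 8-connected components with area strictly below min_size."""
    if params.min_size == 0:
        return mask
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= params.min_size
    keep[0] = False
    return BinaryMask(keep[labels], mask.pair_index)


def label_and_measure(mask: BinaryMask) -> LabeledMask:
    """8-connected labeling (raster order of first pixel) plus region props."""
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    regions = []
    if n:
        for prop in regionprops(labels):
            regions.append(
                CellRegion(
                    label=int(prop.label),
                    area=int(prop.area),
                    perimeter=float(prop.perimeter),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                    bbox=tuple(int(b) for b in prop.bbox),
                )
            )
        regions.sort(key=lambda r: r.label)
    return LabeledMask(labels.astype(np.int32), tuple(regions), mask.pair_index)


def segment_pair(
    frame_t: ImageFrame,
    frame_t1: ImageFrame,
    fparams: FlowParams | None = None,
    sparams: SegmentationParams | None = None,
) -> LabeledMask:
    """Segment one consecutive frame pair; the mask belongs to frame t.

    Composition: optical flow -> magnitude -> Th threshold -> close+fill ->
    size filter -> label. The earlier frame's index is recorded, matching
    the flow's push semantics (pixels of frame t are pushed onto t+1).
    """
    fparams = fparams or FlowParams()
    sparams = sparams or SegmentationParams()
    field = farneback_flow(frame_t, frame_t1, fparams)
    mask = threshold_mask(flow_magnitude(field), sparams, pair_index=frame_t.index)
    mask = close_and_fill(mask, sparams)
    mask = size_filter(mask, sparams)
    return label_and_measure(mask)


def segment_sequence(
    seq: ImageSequence,
    fparams: FlowParams | None = None,
    sparams: SegmentationParams | None = None,
) -> list[LabeledMask]:
    """Segment every consecutive pair: N frames yield N-1 labeled masks."""
    return [segment_pair(a, b, fparams, sparams) for a, b in seq.pairs()]


def regions_table(masks: list[LabeledMask]):
    """Concatenate per-frame region properties into one DataFrame.

    Columns: frame, label, area_px, perimeter_px, centroid_row, centroid_col,
    bbox_min_row, bbox_min_col, bbox_max_row, bbox_max_col (half-open).
    """
    import pandas as pd

    rows = []
    for mask in masks:
        for reg in mask.regions:
            rows.append(
                {
                    "frame": mask.pair_index,
                    "label": reg.label,
                    "area_px": reg.area,
                    "perimeter_px": reg.perimeter,
                    "centroid_row": reg.centroid[0],
                    "centroid_col": reg.centroid[1],
                    "bbox_min_row": reg.bbox[0],
                    "bbox_min_col": reg.bbox[1],
                    "bbox_max_row": reg.bbox[2],
                    "bbox_max_col": reg.bbox[3],
                }
            )
    columns = [
        "frame", "label", "area_px", "perimeter_px", "centroid_row",
        "centroid_col", "bbox_min_row", "bbox_min_col", "bbox_max_row",
        "bbox_max_col",
    ]
    return pd.DataFrame(rows, columns=columns)
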