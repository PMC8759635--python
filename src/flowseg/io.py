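"""Reading time-lapse sequences and writing segmentation outputs.

Sequences come in as multi-page TIFFs or directories of single-frame
TIFF/PNG files (lexicographic order). Outputs go out as 16-bit label TIFFs,
a pooled region CSV and a YAML echo of the effective parameters, tied
together by a JSON manifest.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .flow import FlowParams
from .frames import ImageSequence, ValidationError, normalize_frame
from .segment import LabeledMask, SegmentationParams, label_and_measure, BinaryMask, regions_table

__all__ = ["read_sequence", "read_label_masks", "write_outputs"]

logger = logging.getLogger("flowseg")

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")

# luminance weights for RGB inputs (ITU-R 709, as used by rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def _to_gray(page: np.ndarray, where: str) -> np.ndarray:
    if page.ndim == 3:
        logger.warning("%s is multi-channel; converting to luminance", where)
        if page.shape[-1] == 3:
            return page.astype(np.float64) @ _LUMA
        return page.astype(np.float64).mean(axis=-1)
    if page.ndim != 2:
        raise ValidationError(f"{where}: expected 2-D frame, got shape {page.shape}")
    return page


def _bit_depth_of(arr: np.ndarray) -> int | str:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if np.issubdtype(arr.dtype, np.integer):
        return int(arr.dtype.itemsize * 8)
    return "float"


def read_sequence(path: str | Path) -> ImageSequence:
    """Load a time-lapse from a multi-page TIFF or a directory of frames.

    Frames are normalized to [0, 1] (integer data by full scale, float data
    min-max). Directory frames are ordered by sorted filename; multi-page
    TIFFs by page index. Fewer than two frames or mixed frame sizes are
    rejected.
    """
    path = Path(path)
    raw_frames: list[tuple[str, np.ndarray]] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        for p in files:
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio

                raw_frames.append((p.name, np.asarray(iio.imread(p))))
            else:
                raw_frames.append((p.name, tifffile.imread(p)))
    elif path.is_file():
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        for i, page in enumerate(stack):
            raw_frames.append((f"{path.name}[{i}]", page))
    else:
        raise ValidationError(f"no such input: {path}")

    if len(raw_frames) < 2:
        raise ValidationError(
            f"{path}: found {len(raw_frames)} frame(s); at least 2 are required "
            "(the method is defined on consecutive pairs)"
        )
    frames = []
    shape = None
    for index, (name, raw) in enumerate(raw_frames):
        gray = _to_gray(raw, name)
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise ValidationError(
                f"{name}: frame shape {gray.shape} differs from first frame {shape}"
            )
        bd = _bit_depth_of(np.asarray(raw))
        frames.append(normalize_frame(gray, bd, index=index))
    return ImageSequence(tuple(frames))


def read_label_masks(path: str | Path) -> list[LabeledMask]:
    """Load labeled (or binary) ground-truth/prediction masks.

    Accepts a multi-page TIFF or a directory of TIFF/PNG label images with
    0 = background. Labels are re-run through connected-component labeling
    only if the image is binary; integer labels are kept and compacted to
    consecutive 1..N.
    """
    path = Path(path)
    pages: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        for p in files:
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio

                pages.append(np.asarray(iio.imread(p)))
            else:
                pages.append(tifffile.imread(p))
    elif path.is_file():
        stack = tifffile.imread(path)
        pages = list(stack[None] if stack.ndim == 2 else stack)
    else:
        raise ValidationError(f"no such input: {path}")
    masks = []
    for i, page in enumerate(pages):
        if page.ndim != 2 or not np.issubdtype(page.dtype, np.integer):
            raise ValidationError(f"label image {i} must be a 2-D integer grid")
        labels = np.unique(page)
        labels = labels[labels > 0]
        if len(labels) and np.array_equal(labels, [1]) and page.max() == 1:
            masks.append(label_and_measure(BinaryMask(page > 0, pair_index=i)))
        else:
            compact = np.zeros_like(page, dtype=np.int32)
            for new, old in enumerate(labels, start=1):
                compact[page == old] = new
            from skimage.measure import regionprops

            regs = []
            from .segment import CellRegion

            for prop in regionprops(compact):
                regs.append(
                    CellRegion(
                        label=int(prop.label),
                        area=int(prop.area),
                        perimeter=float(prop.perimeter),
                        centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                        bbox=tuple(int(b) for b in prop.bbox),
                    )
                )
            masks.append(LabeledMask(compact, tuple(regs), pair_index=i))
    return masks


def write_outputs(
    masks: list[LabeledMask],
    outdir: str | Path,
    fparams: FlowParams | None = None,
    sparams: SegmentationParams | None = None,
) -> dict:
    """Write per-frame label TIFFs, a pooled region CSV and a params echo.

    Returns (and writes as ``manifest.json``) a manifest listing every
    artifact. Labels are stored as 16-bit TIFF, capping object counts at
    65535 per frame.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory not writable: {outdir}") from exc

    mask_files = []
    for mask in masks:
        if mask.n_regions > 65535:
            raise ValidationError("more than 65535 objects in one frame")
        name = f"mask_{mask.pair_index:04d}.tif"
        tifffile.imwrite(outdir / name, mask.labels.astype(np.uint16))
        mask_files.append(name)

    table = regions_table(masks)
    table.to_csv(outdir / "regions.csv", index=False)

    params = {
        "flow": asdict(fparams or FlowParams()),
        "segment": asdict(sparams or SegmentationParams()),
    }
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)

    manifest = {
        "masks": mask_files,
        "regions": "regions.csv",
        "params": "params.yaml",
        "n_frames": len(masks),
        "n_regions_total": int(sum(m.n_regions for m in masks)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
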