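"""Image containers and intensity normalization.

All downstream processing operates on frames normalized to [0, 1] so that the
flow-magnitude threshold ``Th`` is comparable across 8/12/16-bit and float
acquisitions. Flow is always reported in pixels/frame at native resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ImageFrame",
    "ImageSequence",
    "normalize_frame",
]

#: minimum side length for frames entering the pipeline (the default pyramid
#: needs room for an 8x8 coarsest level)
MIN_FRAME_SIDE = 16


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _check_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValidationError("frame pixels must be a nonempty 2-D grid")
    if not np.isfinite(pixels).all():
        raise ValidationError("frame contains NaN or Inf pixels")
    if pixels.min() < -1e-12 or pixels.max() > 1 + 1e-12:
        raise ValidationError("frame pixels must lie in [0, 1]; normalize first")
    return np.clip(pixels, 0.0, 1.0)


@dataclass(frozen=True)
class ImageFrame:
    """A single grayscale frame, intensities in [0, 1].

    Parameters
    ----------
    pixels : ndarray
        2-D float grid, values in [0, 1], no NaN/Inf, at least 16x16.
    index : int
        Nonnegative time index of the frame within its sequence.
    source_bit_depth : int or "float"
        Bit depth of the raw acquisition, recorded for provenance only.
    """

    pixels: np.ndarray
    index: int = 0
    source_bit_depth: int | str = "float"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_pixels(self.pixels))
        if self.index < 0:
            raise ValidationError("frame index must be nonnegative")
        h, w = self.pixels.shape
        if h < MIN_FRAME_SIDE or w < MIN_FRAME_SIDE:
            raise ValidationError(
                f"frame must be at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}, got {h}x{w}"
            )

    @classmethod
    def _pyramid_level(
        cls, pixels: np.ndarray, index: int, source_bit_depth: int | str
    ) -> "ImageFrame":
        # Internal constructor for downsampled pyramid levels, which may be
        # smaller than the public 16x16 minimum (down to 8x8).
        obj = object.__new__(cls)
        object.__setattr__(obj, "pixels", _check_pixels(pixels))
        object.__setattr__(obj, "index", index)
        object.__setattr__(obj, "source_bit_depth", source_bit_depth)
        return obj

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ImageSequence:
    """An ordered time-lapse of uniformly sized frames.

    The segmentation method is defined on consecutive frame pairs, so at
    least two frames are required. ``frame_interval`` (seconds) is carried as
    metadata only; displacements are always reported per frame.
    """

    frames: tuple[ImageFrame, ...]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) < 2:
            raise ValidationError(
                "a sequence needs at least 2 frames (the method is defined on "
                "consecutive pairs)"
            )
        shape = frames[0].shape
        for f in frames[1:]:
            if f.shape != shape:
                raise ValidationError(
                    f"frame {f.index} has shape {f.shape}, expected {shape}"
                )
        indices = [f.index for f in frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError("frame indices must be strictly increasing")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def pairs(self):
        """Yield consecutive ``(frame_t, frame_t1)`` pairs."""
        return zip(self.frames[:-1], self.frames[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


def normalize_frame(
    raw_pixels: np.ndarray, bit_depth: int | str, index: int = 0
) -> ImageFrame:
    """Normalize a raw intensity grid to [0, 1] and wrap it as a frame.

    Integer data is divided by the full scale ``2**bit_depth - 1`` so a given
    threshold means the same thing across images of one acquisition; float
    data is min-max rescaled per frame. A constant image maps to all zeros.

    Parameters
    ----------
    raw_pixels : ndarray
        Nonempty, finite 2-D grid.
    bit_depth : {8, 12, 16, "float"}
        Scale of the raw data. Any integer >= 1 is accepted.
    index : int
        Time index recorded on the resulting frame.
    """
    raw = np.asarray(raw_pixels)
    if raw.ndim != 2 or raw.size == 0:
        raise ValidationError("raw pixels must be a nonempty 2-D grid")
    raw = raw.astype(np.float64)
    if not np.isfinite(raw).all():
        raise ValidationError("raw pixels contain NaN or Inf")
    if bit_depth == "float":
        lo, hi = raw.min(), raw.max()
        if hi - lo <= 0:
            norm = np.zeros_like(raw)
        else:
            norm = (raw - lo) / (hi - lo)
    else:
        if not isinstance(bit_depth, (int, np.integer)) or bit_depth < 1:
            raise ValidationError(f"unsupported bit depth: {bit_depth!r}")
        full_scale = float(2**int(bit_depth) - 1)
        if raw.min() < 0 or raw.max() > full_scale:
            raise ValidationError(
                f"values outside [0, {full_scale:.0f}] for {bit_depth}-bit input"
            )
        norm = raw / full_scale
    return ImageFrame(norm, index=index, source_bit_depth=bit_depth)
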