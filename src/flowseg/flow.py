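"""Dense optical flow by Farneback polynomial expansion, written from scratch.

The estimator models every local neighborhood of an image as a quadratic
polynomial f(x) = x'Ax + b'x + c fitted by weighted least squares with a
Gaussian applicability window, and recovers a dense displacement field by
equating the expansions of two consecutive frames. Large displacements are
handled coarse-to-fine over a resolution pyramid built by 2x2 averaging; the
displacement solved at each level seeds the level below it.

Displacements are in pixels/frame at the resolution of the input frames,
with the "push" convention: content at position p in frame t appears at
p + d(p) in frame t+1. ``u`` is the horizontal (column) component and ``v``
the vertical (row) component.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import ImageFrame, ValidationError

__all__ = [
    "FlowParams",
    "PolynomialExpansion",
    "FlowField",
    "build_pyramid",
    "downsample2x",
    "polynomial_expansion",
    "estimate_displacement",
    "farneback_flow",
    "flow_magnitude",
]

#: coarsest pyramid level must be at least this many pixels on a side
MIN_COARSE_SIDE = 8

#: 2x2 systems with determinant below this are treated as motion-free and
#: keep the prior displacement (constant patches carry no motion information)
SINGULAR_DET = 1e-12


@dataclass(frozen=True)
class FlowParams:
    """Tuning knobs of the flow estimator.

    Attributes
    ----------
    pyramid_levels : int
        Number of resolution levels including the original (default 3).
    pyramid_scale : float
        Downsampling factor between levels; fixed at 0.5 (2x2 averaging).
    expansion_window : int
        Odd side length of the polynomial-fit neighborhood (default 5).
    expansion_sigma : float
        Std-dev of the Gaussian applicability weighting the fit towards the
        center of the neighborhood (default 1.1).
    averaging_window : int
        Odd side length of the Gaussian window (sigma = window/6) over which
        the pointwise normal equations are averaged before solving
        (default 9). Wider windows tolerate weaker texture but smear the
        flow support across object boundaries.
    iterations_per_level : int
        Warp-and-resolve iterations at each pyramid level (default 3).
    """

    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    expansion_window: int = 5
    expansion_sigma: float = 1.1
    averaging_window: int = 9
    iterations_per_level: int = 3

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        if self.pyramid_scale != 0.5:
            raise ValidationError("pyramid_scale is fixed at 0.5 (2x2 averaging)")
        for name in ("expansion_window", "averaging_window"):
            val = getattr(self, name)
            if val < 1 or val % 2 == 0:
                raise ValidationError(f"{name} must be odd and positive, got {val}")
        if not self.expansion_sigma > 0:
            raise ValidationError("expansion_sigma must be positive")
        if self.iterations_per_level < 1:
            raise ValidationError("iterations_per_level must be >= 1")

    @staticmethod
    def max_levels(shape: tuple[int, int]) -> int:
        """Largest pyramid depth keeping the coarsest level >= 8x8."""
        side = min(shape)
        levels = 1
        while math.ceil(side / 2) >= MIN_COARSE_SIDE:
            side = math.ceil(side / 2)
            levels += 1
        return levels


@dataclass(frozen=True)
class PolynomialExpansion:
    """Per-pixel quadratic model f(x) = x'Ax + b'x + c of one frame.

    ``A`` is symmetric, so only three coefficient planes are stored
    (a_rr, a_rc, a_cc); ``x`` is the (row, col) offset from the pixel.
    """

    a_rr: np.ndarray
    a_rc: np.ndarray
    a_cc: np.ndarray
    b_r: np.ndarray
    b_c: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        shape = self.c.shape
        for name in ("a_rr", "a_rc", "a_cc", "b_r", "b_c"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValidationError("expansion coefficient grids must share shape")
            if not np.isfinite(arr).all():
                raise ValidationError("expansion coefficients contain NaN/Inf")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c.shape  # type: ignore[return-value]

    def evaluate(self, row: int, col: int, dr: float = 0.0, dc: float = 0.0) -> float:
        """Evaluate the local model of pixel (row, col) at offset (dr, dc)."""
        d = np.array([dr, dc])
        A = np.array(
            [
                [self.a_rr[row, col], self.a_rc[row, col]],
                [self.a_rc[row, col], self.a_cc[row, col]],
            ]
        )
        b = np.array([self.b_r[row, col], self.b_c[row, col]])
        return float(d @ A @ d + b @ d + self.c[row, col])


@dataclass(frozen=True)
class FlowField:
    """Dense displacement field between a consecutive frame pair.

    ``u`` holds horizontal (column) and ``v`` vertical (row) displacement in
    pixels/frame; ``pair_index`` is the time index t of the earlier frame.
    """

    u: np.ndarray
    v: np.ndarray
    pair_index: int = 0

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.float64)
        v = np.asarray(self.v, dtype=np.float64)
        if u.shape != v.shape or u.ndim != 2:
            raise ValidationError("u and v must be 2-D grids of identical shape")
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise ValidationError("flow field contains NaN/Inf")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape: tuple[int, int], pair_index: int = 0) -> "FlowField":
        return cls(np.zeros(shape), np.zeros(shape), pair_index)

    def magnitude(self) -> np.ndarray:
        return flow_magnitude(self)


def flow_magnitude(field: FlowField) -> np.ndarray:
    """Per-pixel Euclidean norm sqrt(u^2 + v^2) of the displacement."""
    return np.hypot(field.u, field.v)


# ---------------------------------------------------------------------------
# resolution pyramid


def downsample2x(pixels: np.ndarray) -> np.ndarray:
    """One decimation step: 2x2 block mean with ceil sizing.

    Odd trailing rows/columns form truncated blocks averaged over the pixels
    they actually contain, so a (2k+1)-long axis maps to k+1 samples.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    h, w = pixels.shape
    row_idx = np.arange(0, h, 2)
    col_idx = np.arange(0, w, 2)
    sums = np.add.reduceat(np.add.reduceat(pixels, row_idx, axis=0), col_idx, axis=1)
    rcount = np.minimum(row_idx + 2, h) - row_idx
    ccount = np.minimum(col_idx + 2, w) - col_idx
    return sums / np.outer(rcount, ccount)


def build_pyramid(frame: ImageFrame, params: FlowParams) -> list[ImageFrame]:
    """Build the resolution pyramid, finest level first.

    Each level is a Gaussian pre-smoothed (sigma = 1, to suppress aliasing)
    then 2x2 block-averaged copy of its parent; level 0 is the input frame
    untouched. Tiny levels (< 4 px on a side) skip the pre-smoothing.
    """
    max_levels = FlowParams.max_levels(frame.shape)
    if params.pyramid_levels > max_levels:
        raise ValidationError(
            f"pyramid_levels={params.pyramid_levels} too deep for "
            f"{frame.shape[0]}x{frame.shape[1]} frame; maximum is {max_levels} "
            f"(coarsest level must be >= {MIN_COARSE_SIDE}x{MIN_COARSE_SIDE})"
        )
    levels = [frame]
    current = frame.pixels
    for _ in range(params.pyramid_levels - 1):
        if min(current.shape) >= 4:
            # 'reflect' keeps the smoothing operator symmetric, so the image
            # mean is preserved exactly through each level
            smoothed = ndimage.gaussian_filter(current, sigma=1.0, mode="reflect")
        else:
            smoothed = current
        current = np.clip(downsample2x(smoothed), 0.0, 1.0)
        levels.append(
            ImageFrame._pyramid_level(current, frame.index, frame.source_bit_depth)
        )
    return levels


# ---------------------------------------------------------------------------
# polynomial expansion


def _expansion_basis(params: FlowParams):
    """1-D applicability and moment kernels plus the 6x6 Gram inverse.

    Basis ordering: [1, r, c, r^2, c^2, rc] with (r, c) the offset from the
    window center. Without per-pixel certainty the Gram matrix is constant
    across the image and can be inverted once.
    """
    n = params.expansion_window // 2
    x = np.arange(-n, n + 1, dtype=np.float64)
    w = np.exp(-(x**2) / (2.0 * params.expansion_sigma**2))
    ww = np.outer(w, w)
    r = x[:, None]
    c = x[None, :]
    basis = [
        np.ones_like(ww),
        r * np.ones_like(c),
        np.ones_like(r) * c,
        r**2 * np.ones_like(c),
        np.ones_like(r) * c**2,
        r * c,
    ]
    G = np.empty((6, 6))
    for i in range(6):
        for j in range(6):
            G[i, j] = np.sum(ww * basis[i] * basis[j])
    G_inv = np.linalg.inv(G)
    return x, w, G_inv


def polynomial_expansion(frame: ImageFrame, params: FlowParams) -> PolynomialExpansion:
    """Fit f(x) = x'Ax + b'x + c at every pixel by weighted least squares.

    The Gaussian-weighted normal equations are evaluated with separable
    correlations (edge replication at the borders), then solved with the
    precomputed Gram inverse.
    """
    img = frame.pixels
    if min(img.shape) < params.expansion_window:
        raise ValidationError(
            f"expansion window {params.expansion_window} exceeds frame "
            f"{img.shape[0]}x{img.shape[1]}"
        )
    x, w, G_inv = _expansion_basis(params)
    k0, k1, k2 = w, w * x, w * x**2

    def corr(image: np.ndarray, krow: np.ndarray, kcol: np.ndarray) -> np.ndarray:
        # correlate1d: out[i] = sum_j k[j] in[i + j - n], so a kernel in
        # natural (-n..n) order pairs basis offset d with sample I(p + d)
        tmp = ndimage.correlate1d(image, krow, axis=0, mode="nearest")
        return ndimage.correlate1d(tmp, kcol, axis=1, mode="nearest")

    # moments m_i = sum_{dr,dc} w(dr)w(dc) basis_i(dr,dc) I(p + (dr,dc))
    m = np.stack(
        [
            corr(img, k0, k0),  # 1
            corr(img, k1, k0),  # r
            corr(img, k0, k1),  # c
            corr(img, k2, k0),  # r^2
            corr(img, k0, k2),  # c^2
            corr(img, k1, k1),  # rc
        ],
        axis=-1,
    )
    coef = m @ G_inv.T  # [c, b_r, b_c, a_rr, a_cc, a_rc]
    return PolynomialExpansion(
        a_rr=coef[..., 3],
        a_rc=coef[..., 5] / 2.0,
        a_cc=coef[..., 4],
        b_r=coef[..., 1],
        b_c=coef[..., 2],
        c=coef[..., 0],
    )


# ---------------------------------------------------------------------------
# displacement estimation


def estimate_displacement(
    expA: PolynomialExpansion,
    expB: PolynomialExpansion,
    prior: FlowField,
    params: FlowParams,
) -> FlowField:
    """Solve for the displacement relating two polynomial expansions.

    Implements the iterative update: sample B's coefficients at positions
    warped by the rounded prior, form the pointwise system
    G = (A_A + A_B)/2 and db = -1/2 (b_B - b_A) + G d_prior, average G'G and
    G'db over the Gaussian ``averaging_window``, and solve the 2x2 system at
    every pixel. Near-singular systems keep the prior. The solved field feeds back
    as the prior for ``iterations_per_level`` rounds.
    """
    if expA.shape != expB.shape or prior.shape != expA.shape:
        raise ValidationError("expansions and prior must share dimensions")
    h, w = expA.shape
    rows, cols = np.mgrid[0:h, 0:w]
    d_r = prior.v.copy()
    d_c = prior.u.copy()

    for _ in range(params.iterations_per_level):
        # the integer displacement actually used for warping must also be the
        # one entering the G*d term, or the linearization overshoots
        di_r = np.rint(d_r)
        di_c = np.rint(d_c)
        wr = np.clip(rows + di_r.astype(np.int64), 0, h - 1)
        wc = np.clip(cols + di_c.astype(np.int64), 0, w - 1)
        di_r = (wr - rows).astype(np.float64)
        di_c = (wc - cols).astype(np.float64)

        a_rr = 0.5 * (expA.a_rr + expB.a_rr[wr, wc])
        a_rc = 0.5 * (expA.a_rc + expB.a_rc[wr, wc])
        a_cc = 0.5 * (expA.a_cc + expB.a_cc[wr, wc])
        db_r = -0.5 * (expB.b_r[wr, wc] - expA.b_r) + a_rr * di_r + a_rc * di_c
        db_c = -0.5 * (expB.b_c[wr, wc] - expA.b_c) + a_rc * di_r + a_cc * di_c

        # normal equations G'G d = G'db, averaged over the window (A symmetric)
        g11 = a_rr**2 + a_rc**2
        g12 = a_rc * (a_rr + a_cc)
        g22 = a_rc**2 + a_cc**2
        h1 = a_rr * db_r + a_rc * db_c
        h2 = a_rc * db_r + a_cc * db_c

        # Gaussian-weighted averaging (sigma = window/6) localizes the flow
        # support better than a box of the same width
        sigma = params.averaging_window / 6.0
        g11, g12, g22, h1, h2 = (
            ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest")
            for arr in (g11, g12, g22, h1, h2)
        )

        det = g11 * g22 - g12**2
        ok = np.abs(det) >= SINGULAR_DET
        safe_det = np.where(ok, det, 1.0)
        sol_r = (g22 * h1 - g12 * h2) / safe_det
        sol_c = (g11 * h2 - g12 * h1) / safe_det
        d_r = np.where(ok, sol_r, d_r)
        d_c = np.where(ok, sol_c, d_c)

    return FlowField(u=d_c, v=d_r, pair_index=prior.pair_index)


def _upsample_flow(field: FlowField, shape: tuple[int, int]) -> FlowField:
    """Bilinearly resize a flow field to a 2x finer grid, doubling its values."""
    from skimage.transform import resize

    u = resize(field.u, shape, order=1, mode="edge", anti_aliasing=False) * 2.0
    v = resize(field.v, shape, order=1, mode="edge", anti_aliasing=False) * 2.0
    return FlowField(u=u, v=v, pair_index=field.pair_index)


def farneback_flow(
    frame_t: ImageFrame, frame_t1: ImageFrame, params: FlowParams | None = None
) -> FlowField:
    """Dense displacement field mapping ``frame_t`` onto ``frame_t1``.

    Coarse-to-fine: the coarsest pyramid level starts from a zero prior; each
    solved field is upsampled (values doubled) to seed the next finer level.

    Returns a full-resolution :class:`FlowField` in pixels/frame, assigned to
    the earlier frame's index.
    """
    params = params or FlowParams()
    if frame_t.shape != frame_t1.shape:
        raise ValidationError("frames must share dimensions")
    pyrA = build_pyramid(frame_t, params)
    pyrB = build_pyramid(frame_t1, params)

    flow: FlowField | None = None
    for levelA, levelB in zip(reversed(pyrA), reversed(pyrB)):
        expA = polynomial_expansion(levelA, params)
        expB = polynomial_expansion(levelB, params)
        if flow is None:
            prior = FlowField.zeros(levelA.shape, pair_index=frame_t.index)
        else:
            prior = _upsample_flow(flow, levelA.shape)
        flow = estimate_displacement(expA, expB, prior, params)
    assert flow is not None
    return flow
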