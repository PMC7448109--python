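"""Lesion quantification from grayscale/RGB rasters.

The pipeline turns a lesion image into two scalar indicators:

* ``area_px`` — pixel area of the (single) lesion, measured by tracing the
  lesion boundary with an eight-direction Freeman chain code and integrating
  the chain (discrete Green's theorem with a Pick-style boundary correction);
* ``mean_gray`` — the mean gray level over the lesion region.

Stages: weighted grayscale conversion, Gaussian smoothing, 2x2
finite-difference gradient, non-maximum suppression, double (hysteresis)
thresholding, largest-component fill, Moore boundary tracing, chain-code
area and mean gray level.

Coordinate convention: arrays are indexed ``[row, col]`` with row 0 at the
top; ``x`` is the column index and ``y`` the row index, increasing downward.
Freeman codes: 0=+x, 1=(+x,-y), 2=-y, 3=(-x,-y), 4=-x, 5=(-x,+y), 6=+y,
7=(+x,+y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "DEFAULT_GRAY_WEIGHTS",
    "FREEMAN_STEPS",
    "GradientField",
    "BoundaryChain",
    "LesionMetrics",
    "ImagingParams",
    "read_image",
    "to_grayscale",
    "gaussian_kernel",
    "smooth",
    "gradient",
    "nonmax_suppress",
    "default_thresholds",
    "hysteresis_threshold",
    "largest_component",
    "fill_region",
    "trace_boundary",
    "label_chain",
    "chain_area",
    "mean_gray_level",
    "extract_lesion_metrics",
]

#: Default RGB -> gray weights (alpha, beta, gamma).  Each weight sits inside
#: its admissible range (alpha 0.25-0.35, beta 0.55-0.65, gamma 0.1-0.2) and
#: the triple sums to 1 so uniform-channel pixels are preserved.
DEFAULT_GRAY_WEIGHTS: tuple[float, float, float] = (0.30, 0.59, 0.11)

_WEIGHT_RANGES = ((0.25, 0.35), (0.55, 0.65), (0.10, 0.20))

#: Freeman code -> (row step, col step).
FREEMAN_STEPS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    1: (-1, 1),
    2: (-1, 0),
    3: (-1, -1),
    4: (0, -1),
    5: (1, -1),
    6: (1, 0),
    7: (1, 1),
}

_STEP_TO_CODE = {step: code for code, step in FREEMAN_STEPS.items()}

# Moore-neighbourhood scan order, clockwise on screen starting at north.
_CLOCKWISE = (2, 1, 0, 7, 6, 5, 4, 3)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class GradientField:
    """2x2 finite-difference gradient of a gray image.

    ``gx``/``gy`` are sampled on the (H-1, W-1) grid of pixel corners;
    ``magnitude = hypot(gx, gy)`` and ``direction = atan2(gy, gx)``.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class BoundaryChain:
    """Closed Freeman chain around one connected region.

    ``start`` is the topmost-then-leftmost boundary pixel, ``codes`` the
    clockwise sequence of direction codes.  ``labels`` carries the
    vertical-step sign s[i] of each code ({1,2,3} -> -1, {0,4} -> 0,
    {5,6,7} -> +1).
    """

    start: tuple[int, int]
    codes: tuple[int, ...]

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(label_chain_code(c) for c in self.codes)

    def points(self) -> list[tuple[int, int]]:
        """Boundary pixels visited by the chain (start first, start not
        repeated at the end)."""
        pts = [self.start]
        r, c = self.start
        for code in self.codes[:-1] if self.codes else ():
            dr, dc = FREEMAN_STEPS[code]
            r, c = r + dr, c + dc
            pts.append((r, c))
        return pts

    def is_closed(self) -> bool:
        dr = sum(FREEMAN_STEPS[c][0] for c in self.codes)
        dc = sum(FREEMAN_STEPS[c][1] for c in self.codes)
        return dr == 0 and dc == 0


@dataclass(frozen=True)
class LesionMetrics:
    """The two image indicators plus the screening flag."""

    area_px: int
    mean_gray: float
    n_pixels: int
    informative: bool

    def to_record(self) -> dict:
        return {
            "area_px": self.area_px,
            "mean_gray": self.mean_gray,
            "n_pixels": self.n_pixels,
            "informative": self.informative,
        }


@dataclass(frozen=True)
class ImagingParams:
    """Preprocessing configuration for :func:`extract_lesion_metrics`."""

    gray_weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS
    sigma: float = 1.4
    radius: int = 2
    t_low: float | None = None  # None -> derived from t_high
    t_high: float | None = None  # None -> 90th percentile of nonzero magnitudes
    low_fraction: float = 0.4
    floor_fraction: float = 0.2
    min_area_px: int = 50
    min_gray: float = 180.0
    pixel_spacing_mm: float | None = None
    min_diameter_mm: float = 15.0
    closing_radius: int = 1


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a float array (HxW gray or HxWx3 RGB)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"), dtype=float)
        else:
            arr = np.asarray(im.convert("RGB"), dtype=float)
    return arr


def write_image(path, arr: np.ndarray) -> None:
    a = np.clip(np.asarray(arr, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(a).save(path)


def _check_gray_weights(w: Sequence[float]) -> tuple[float, float, float]:
    if len(w) != 3:
        raise ValueError("grayscale weights must be a 3-tuple (alpha, beta, gamma)")
    for v, (lo, hi) in zip(w, _WEIGHT_RANGES):
        if not (lo <= v <= hi):
            raise ValueError(
                f"grayscale weight {v} outside admissible range [{lo}, {hi}]"
            )
    return float(w[0]), float(w[1]), float(w[2])


def to_grayscale(img: np.ndarray, weights: Sequence[float] = DEFAULT_GRAY_WEIGHTS) -> np.ndarray:
    """Weighted channel combination ``alpha*R + beta*G + gamma*B``.

    A 2-D array is treated as already-gray and passed through (scaled by the
    weight sum, which is 1 for the defaults).  Output is clipped to [0, 255].
    """
    a, b, g = _check_gray_weights(weights)
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        gray = arr * (a + b + g)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = a * arr[..., 0] + b * arr[..., 1] + g * arr[..., 2]
    else:
        raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")
    return np.clip(gray, 0.0, 255.0)


def gaussian_kernel(sigma: float, radius: int = 2) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of side ``2*radius + 1``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth(gray: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D convolution with reflect padding at the borders."""
    g = np.asarray(gray, dtype=float)
    k = np.asarray(kernel, dtype=float)
    if k.shape[0] > g.shape[0] or k.shape[1] > g.shape[1]:
        raise ValueError("kernel larger than image")
    return ndimage.convolve(g, k, mode="reflect")


def gradient(gray: np.ndarray) -> GradientField:
    """2x2 first-order finite-difference gradient.

    With x = col, y = row::

        Gx = (f[r, c+1] - f[r, c] + f[r+1, c+1] - f[r+1, c]) / 2
        Gy = (f[r+1, c] - f[r, c] + f[r+1, c+1] - f[r, c+1]) / 2

    sampled on the (H-1, W-1) corner grid.
    """
    g = np.asarray(gray, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("gradient needs an image of at least 2x2 pixels")
    gx = 0.5 * (g[:-1, 1:] - g[:-1, :-1] + g[1:, 1:] - g[1:, :-1])
    gy = 0.5 * (g[1:, :-1] - g[:-1, :-1] + g[1:, 1:] - g[:-1, 1:])
    mag = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    return GradientField(gx=gx, gy=gy, magnitude=mag, direction=direction)


def nonmax_suppress(field: GradientField) -> np.ndarray:
    """Keep a pixel's magnitude iff it is >= both neighbours along its
    quantized gradient direction (four sectors: 0, 45, 90, 135 degrees)."""
    mag = field.magnitude
    h, w = mag.shape
    # sector 0: horizontal gradient (compare E/W); 1: diagonal (SE/NW);
    # 2: vertical (S/N); 3: anti-diagonal (SW/NE)
    ang = np.mod(field.direction, np.pi)
    sector = np.floor((ang + np.pi / 8) / (np.pi / 4)).astype(int) % 4

    padded = np.zeros((h + 2, w + 2))
    padded[1:-1, 1:-1] = mag

    def shifted(dr: int, dc: int) -> np.ndarray:
        return padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]

    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    keep = np.zeros_like(mag, dtype=bool)
    for s, (dr, dc) in offsets.items():
        sel = sector == s
        ok = (mag >= shifted(dr, dc)) & (mag >= shifted(-dr, -dc))
        keep |= sel & ok
    out = np.where(keep, mag, 0.0)
    return out


def default_thresholds(
    thinned: np.ndarray, low_fraction: float = 0.4, floor_fraction: float = 0.2
) -> tuple[float, float]:
    """Derive (t_low, t_high) from the thinned magnitudes.

    t_high is the 90th percentile of nonzero values, floored at
    ``floor_fraction`` of the maximum magnitude (on noisy images the
    percentile alone collapses onto the noise floor because weak noise
    responses dominate the count); t_low = low_fraction * t_high.
    """
    nz = thinned[thinned > 0]
    if nz.size == 0:
        return 0.0, 0.0
    t_high = max(float(np.percentile(nz, 90)), floor_fraction * float(nz.max()))
    return low_fraction * t_high, t_high


def hysteresis_threshold(thinned: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Double thresholding with 8-connected weak-edge tracking.

    Pixels >= t_high are strong edges; pixels in [t_low, t_high) survive iff
    8-connected (transitively) to a strong pixel.  Returns a 0/1 map.
    """
    if t_low > t_high:
        raise ValueError("t_low must not exceed t_high")
    mag = np.asarray(thinned, dtype=float)
    strong = mag >= t_high
    weak = mag >= t_low
    if t_high <= 0:
        # degenerate thresholds: everything weak-positive survives
        weak &= mag > 0
        strong = weak
    if not strong.any():
        return np.zeros(mag.shape, dtype=np.uint8)
    labels, _ = ndimage.label(weak, structure=_EIGHT)
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    edge = np.isin(labels, keep)
    return edge.astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component of a binary mask."""
    m = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        raise ValueError("mask has no foreground component")
    if n == 1:
        return m
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def fill_region(edges: np.ndarray, closing_radius: int = 1) -> np.ndarray:
    """Close small contour gaps then fill interior holes."""
    m = np.asarray(edges).astype(bool)
    if closing_radius > 0:
        struct = np.ones((2 * closing_radius + 1,) * 2, dtype=bool)
        m = ndimage.binary_closing(m, structure=struct)
    return ndimage.binary_fill_holes(m)


def trace_boundary(region: np.ndarray) -> BoundaryChain:
    """Moore boundary tracing, clockwise, from the topmost-then-leftmost
    foreground pixel of a single 8-connected component.

    Uses Jacob's stopping criterion (stop on re-entering the start pixel
    with the original backtrack).  Raises on an empty region or on multiple
    components.
    """
    mask = np.asarray(region).astype(bool)
    if not mask.any():
        raise ValueError("empty region")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n > 1:
        raise ValueError(f"region has {n} components; select one first")

    rows, cols = np.nonzero(mask)
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))
    if len(rows) == 1:
        return BoundaryChain(start=start, codes=())

    h, w = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    init_back = (start[0], start[1] - 1)  # west of start is background
    cur, back = start, init_back
    codes: list[int] = []
    first_pixel: tuple[int, int] | None = None
    limit = 4 * len(rows) + 8
    while True:
        bdir = (back[0] - cur[0], back[1] - cur[1])
        istart = _CLOCKWISE.index(_STEP_TO_CODE[bdir])
        nxt = None
        for k in range(1, 9):
            d = _CLOCKWISE[(istart + k) % 8]
            cand = (cur[0] + FREEMAN_STEPS[d][0], cur[1] + FREEMAN_STEPS[d][1])
            if fg(cand):
                prev_d = _CLOCKWISE[(istart + k - 1) % 8]
                nxt = (cand, d, prev_d)
                break
        if nxt is None:  # unreachable: component has >= 2 pixels
            raise RuntimeError("boundary tracing found no neighbour")
        cand, d, prev_d = nxt
        if first_pixel is None:
            first_pixel = cand
        elif cur == start and cand == first_pixel:
            break  # back at the start and about to retrace the first move
        codes.append(d)
        back = (cur[0] + FREEMAN_STEPS[prev_d][0], cur[1] + FREEMAN_STEPS[prev_d][1])
        cur = cand
        if len(codes) > limit:
            raise RuntimeError("boundary tracing did not close")
    return BoundaryChain(start=start, codes=tuple(codes))


def label_chain_code(code: int) -> int:
    """Vertical-step sign of one Freeman code: {1,2,3} -> -1, {0,4} -> 0,
    {5,6,7} -> +1."""
    if code not in FREEMAN_STEPS:
        raise ValueError(f"invalid Freeman code {code!r}")
    return FREEMAN_STEPS[code][0]


def label_chain(chain: BoundaryChain) -> tuple[int, ...]:
    """Labels s[i] for every code of a chain."""
    return tuple(label_chain_code(c) for c in chain.codes)


def chain_area(chain: BoundaryChain) -> int:
    """Pixel count enclosed by a closed chain, boundary included.

    Integrates x dy along the chain (midpoint rule, exact for unit and
    diagonal steps) and adds the Pick correction N/2 + 1 so that interior
    plus boundary lattice pixels are counted.  Must agree exactly with a
    flood-fill pixel count for simple filled regions.
    """
    if not chain.is_closed():
        raise ValueError("chain is not closed")
    n = len(chain.codes)
    if n == 0:
        return 1
    x = float(chain.start[1])
    acc = 0.0
    for code in chain.codes:
        dr, dc = FREEMAN_STEPS[code]
        acc += (x + dc / 2.0) * dr  # s[i] == row-step sign == dr
        x += dc
    return int(round(abs(acc) + n / 2.0 + 1.0))


def mean_gray_level(gray: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of gray values over a nonempty mask."""
    g = np.asarray(gray, dtype=float)
    m = np.asarray(mask).astype(bool)
    if g.shape != m.shape:
        raise ValueError("gray image and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    return float(g[m].mean())


def _informative(area_px: int, mean_gray: float, params: ImagingParams) -> bool:
    if params.pixel_spacing_mm is not None:
        diameter = 2.0 * math.sqrt(area_px * params.pixel_spacing_mm**2 / math.pi)
        area_ok = diameter >= params.min_diameter_mm
    else:
        area_ok = area_px >= params.min_area_px
    return bool(area_ok and mean_gray >= params.min_gray)


def extract_lesion_metrics(img: np.ndarray, params: ImagingParams | None = None) -> LesionMetrics:
    """Full pipeline: grayscale -> smooth -> gradient -> NMS -> hysteresis ->
    largest-component fill -> boundary trace -> chain area + mean gray.

    Returns ``informative=False`` with area 0 and NaN gray when no foreground
    component is found.
    """
    params = params or ImagingParams()
    gray = to_grayscale(img, params.gray_weights)
    kernel = gaussian_kernel(params.sigma, params.radius)
    smoothed = smooth(gray, kernel)
    field = gradient(smoothed)
    thinned = nonmax_suppress(field)

    t_low, t_high = params.t_low, params.t_high
    if t_high is None:
        t_low_auto, t_high = default_thresholds(
            thinned, params.low_fraction, params.floor_fraction
        )
        if t_low is None:
            t_low = t_low_auto
    elif t_low is None:
        t_low = params.low_fraction * t_high

    edges = hysteresis_threshold(thinned, t_low, t_high)
    if not edges.any():
        return LesionMetrics(area_px=0, mean_gray=float("nan"), n_pixels=0, informative=False)

    filled = fill_region(edges, params.closing_radius)
    comp = largest_component(filled)
    chain = trace_boundary(comp)
    # The traced contour is the detected lesion *outline*: the gradient ridge
    # straddles the true boundary, so the filled mask carries a one-pixel ring
    # around the lesion.  Keeping half the ring (interior + N/2 instead of the
    # full Pick count) centres the estimate on the true pixel area.
    area = max(1, chain_area(chain) - len(chain.codes) // 2)

    # the gradient grid is offset half a pixel from the image grid; erode the
    # mask by one pixel (when possible) so boundary-transition pixels do not
    # contaminate the lesion mean
    core = ndimage.binary_erosion(comp)
    sample_mask = core if core.any() else comp
    gray_cropped = gray[: comp.shape[0], : comp.shape[1]]
    mg = mean_gray_level(gray_cropped, sample_mask)
    return LesionMetrics(
        area_px=area,
        mean_gray=mg,
        n_pixels=area,
        informative=_informative(area, mg, params),
    )
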